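"""Expression and bioassay statistics.

Two analyses are implemented:

* relative qPCR quantification by the 2^-ddCt method, with a reference gene
  (cytochrome b in the study this emulates) and a calibrator stage (juvenile),
  followed by one-way ANOVA and Tukey HSD across developmental stages; and
* the proprotein-convertase inhibitor settlement assay: metamorphosis
  proportions are arcsine-square-root transformed and compared across
  treatment groups within each timepoint by one-way ANOVA plus Tukey HSD.

ANOVA runs on -ddCt (the log2 fold change), which is Gaussian under Gaussian
Ct noise; the reported point fold change is 2^(-mean ddCt), so the calibrator
stage has fold 1 by construction.  A raw-scale option is retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

STAGES = ("NauII", "NauVI", "Cyp", "Juv", "Adu")

CT_COLUMNS = ("gene", "stage", "batch", "replicate", "ct")
ASSAY_COLUMNS = ("dose", "vehicle", "timepoint", "batch", "well",
                 "n_meta", "n_total")


class DataError(ValueError):
    pass


def read_ct_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"Ct table missing columns {sorted(missing)}")
    if not ((df["ct"] > 0) & (df["ct"] < 50)).all():
        raise DataError("Ct values must lie in (0, 50)")
    return df


def read_assay_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = set(ASSAY_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"assay table missing columns {sorted(missing)}")
    if (df["n_total"] <= 0).any():
        raise DataError("n_total must be positive in every well")
    if ((df["n_meta"] < 0) | (df["n_meta"] > df["n_total"])).any():
        raise DataError("n_meta must satisfy 0 <= n_meta <= n_total")
    return df


@dataclass
class FoldChangeResult:
    """2^-ddCt fold changes for one gene across stages."""

    gene: str
    calibrator: str
    fold: dict[str, float]                 # stage -> 2^(-mean ddCt)
    replicate_log2: dict[str, np.ndarray]  # stage -> per-replicate -ddCt

    def summary(self) -> pd.DataFrame:
        rows = []
        for stage, vals in self.replicate_log2.items():
            rows.append({
                "gene": self.gene, "stage": stage,
                "fold": self.fold[stage],
                "log2_fold_mean": float(np.mean(vals)),
                "log2_fold_sd": float(np.std(vals, ddof=1)) if len(vals) > 1
                else float("nan"),
                "n": len(vals),
            })
        return pd.DataFrame(rows)


def ddct(records: pd.DataFrame, reference_gene: str,
         calibrator_stage: str = "Juv",
         pairing: str = "replicate") -> dict[str, FoldChangeResult]:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct_target - Ct_reference within the same (stage, batch, replicate)
    cell (``pairing="replicate"``, the default) or against the stage-mean
    reference Ct (``pairing="mean"``); ddCt subtracts the calibrator-stage
    mean dCt; fold = 2^-ddCt.  Per-replicate log2 folds are retained for the
    downstream ANOVA.
    """
    if pairing not in ("replicate", "mean"):
        raise ValueError(f"unknown pairing {pairing!r}")
    df = records.copy()
    ref = df[df["gene"] == reference_gene]
    if ref.empty:
        raise DataError(f"reference gene {reference_gene!r} not in table")
    targets = [g for g in df["gene"].unique() if g != reference_gene]
    results: dict[str, FoldChangeResult] = {}
    key = ["stage", "batch", "replicate"]
    ref_cells = ref.set_index(key)["ct"]
    ref_stage_mean = ref.groupby("stage")["ct"].mean()
    for gene in targets:
        sub = df[df["gene"] == gene]
        dct = {}
        for stage, grp in sub.groupby("stage", sort=False):
            vals = []
            for _, row in grp.iterrows():
                cell = (row["stage"], row["batch"], row["replicate"])
                if pairing == "replicate":
                    if cell not in ref_cells.index:
                        raise DataError(
                            f"reference gene {reference_gene!r} not measured "
                            f"in cell (stage={cell[0]}, batch={cell[1]}, "
                            f"replicate={cell[2]})"
                        )
                    r = float(ref_cells.loc[cell])
                else:
                    r = float(ref_stage_mean.loc[stage])
                vals.append(float(row["ct"]) - r)
            dct[stage] = np.asarray(vals, dtype=float)
        if calibrator_stage not in dct:
            raise DataError(
                f"calibrator stage {calibrator_stage!r} missing for {gene!r}"
            )
        cal_mean = float(np.mean(dct[calibrator_stage]))
        rep_log2 = {s: -(v - cal_mean) for s, v in dct.items()}
        fold = {s: float(2.0 ** np.mean(v)) for s, v in rep_log2.items()}
        results[gene] = FoldChangeResult(gene, calibrator_stage, fold, rep_log2)
    return results


@dataclass
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    degenerate: bool
    pairs: pd.DataFrame    # group1, group2, meandiff, p_adj, sig05, sig01

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        col = "sig05" if alpha >= 0.05 else "sig01"
        return [tuple(r[["group1", "group2"]])
                for _, r in self.pairs.iterrows() if r[col]]

    def summary(self) -> str:
        head = (f"One-way ANOVA: F({self.df_between},{self.df_within}) = "
                f"{self.f_statistic:.4g}, p = {self.p_value:.4g}")
        if self.degenerate:
            head += "  [degenerate: zero variance]"
        return head + "\n" + self.pairs.to_string(index=False)


def anova_tukey(groups: dict[str, Sequence[float]]) -> AnovaTukeyResult:
    """Classical one-way ANOVA with Tukey HSD post hoc comparisons.

    Tukey adjusted p-values come from the studentized-range distribution;
    pair flags are reported at alpha = 0.05 and 0.01 (the 0.01 set is a
    subset of the 0.05 set by construction).  A fully degenerate input (zero
    variance everywhere, equal means) is flagged rather than raising.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("anova_tukey requires >= 2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    for g, a in zip(names, arrays):
        if len(a) < 2:
            raise ValueError(f"group {g!r} needs >= 2 replicates")
    grand = np.concatenate(arrays)
    k, n = len(arrays), len(grand)
    dfb, dfw = k - 1, n - k
    if np.allclose(grand.var(), 0.0):
        pairs = pd.DataFrame([
            {"group1": names[i], "group2": names[j], "meandiff": 0.0,
             "p_adj": 1.0, "sig05": False, "sig01": False}
            for i in range(k) for j in range(i + 1, k)
        ])
        return AnovaTukeyResult(float("nan"), float("nan"), dfb, dfw,
                                True, pairs)
    f_stat, p_val = stats.f_oneway(*arrays)
    labels = np.concatenate([[g] * len(a) for g, a in zip(names, arrays)])
    tk = pairwise_tukeyhsd(grand, labels, alpha=0.05)
    uniq = [str(g) for g in tk.groupsunique]
    g1, g2 = zip(*[(uniq[i], uniq[j])
                   for i in range(len(uniq)) for j in range(i + 1, len(uniq))])
    p_adj = np.asarray(tk.pvalues, dtype=float)
    pairs = pd.DataFrame({
        "group1": g1,
        "group2": g2,
        "meandiff": np.asarray(tk.meandiffs, dtype=float),
        "p_adj": p_adj,
        "sig05": p_adj < 0.05,
        "sig01": p_adj < 0.01,
    })
    return AnovaTukeyResult(float(f_stat), float(p_val), dfb, dfw,
                            False, pairs)


def stage_anova(fold: FoldChangeResult) -> AnovaTukeyResult:
    """ANOVA/Tukey across stages on per-replicate log2 fold changes."""
    return anova_tukey({s: v for s, v in fold.replicate_log2.items()})


def arcsine_sqrt(p) -> np.ndarray | float:
    """Variance-stabilising transform for proportions: arcsin(sqrt(p))."""
    return np.arcsin(np.sqrt(p))


def _group_label(row) -> str:
    if row["dose"] == 0:
        return str(row["vehicle"])
    d = row["dose"]
    return f"{d:g}uM"


@dataclass
class SettlementResult:
    timepoint: int
    anova: AnovaTukeyResult
    versus_control: pd.DataFrame  # group, meandiff, p_adj, tier

    def summary(self) -> str:
        return (f"{self.timepoint} h\n" + self.anova.summary() + "\n"
                + self.versus_control.to_string(index=False))


def _tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def settlement_analysis(wells: pd.DataFrame, control: str = "AFSW"
                        ) -> dict[int, SettlementResult]:
    """Per-timepoint ANOVA/Tukey of arcsine-transformed metamorphosis
    proportions, with the treatment-versus-seawater-control contrasts
    reported with significance tiers (* p<0.05, ** p<0.01, *** p<0.001)."""
    if (wells["n_total"] <= 0).any():
        raise DataError("n_total must be positive")
    df = wells.copy()
    df["group"] = df.apply(_group_label, axis=1)
    df["y"] = arcsine_sqrt(df["n_meta"] / df["n_total"])
    out: dict[int, SettlementResult] = {}
    for tp, sub in df.groupby("timepoint", sort=True):
        groups = {g: grp["y"].to_numpy() for g, grp in sub.groupby("group")}
        res = anova_tukey(groups)
        rows = []
        for _, r in res.pairs.iterrows():
            pair = {r["group1"], r["group2"]}
            if control not in pair:
                continue
            other = (pair - {control}).pop()
            rows.append({"group": other, "meandiff": r["meandiff"],
                         "p_adj": r["p_adj"], "tier": _tier(r["p_adj"])})
        out[int(tp)] = SettlementResult(int(tp), res, pd.DataFrame(rows))
    return out
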