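"""2^-ddCt quantification, ANOVA/Tukey, and the settlement-assay analysis."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import studentized_range

from barnapep.quant import (
    DataError, anova_tukey, arcsine_sqrt, ddct, read_assay_table,
    read_ct_table, settlement_analysis, stage_anova,
)
from barnapep.simulate import (
    default_settlement_scenario, generate_ct_table,
    generate_settlement_counts,
)


def _ct_df(rows):
    return pd.DataFrame(rows, columns=["gene", "stage", "batch",
                                       "replicate", "ct"])


def test_forced_arithmetic_fold_of_four():
    # dCt test = 3, dCt calibrator = 5 -> ddCt = -2 -> fold 4
    df = _ct_df([
        ("tgt", "Cyp", 1, 1, 18.0), ("ref", "Cyp", 1, 1, 15.0),
        ("tgt", "Juv", 1, 1, 20.0), ("ref", "Juv", 1, 1, 15.0),
    ])
    res = ddct(df, "ref", "Juv")["tgt"]
    assert res.fold["Cyp"] == pytest.approx(4.0)
    assert res.fold["Juv"] == pytest.approx(1.0)


def test_identical_pattern_gives_all_folds_one():
    rows = []
    for stage in ("NauVI", "Cyp", "Juv"):
        for rep in (1, 2):
            rows += [("tgt", stage, 1, rep, 21.5), ("ref", stage, 1, rep, 17.0)]
    res = ddct(_ct_df(rows), "ref", "Juv")["tgt"]
    assert all(f == pytest.approx(1.0) for f in res.fold.values())


def test_per_batch_additive_shift_leaves_folds_unchanged():
    rows = []
    for stage, tct in (("Cyp", 18.0), ("Juv", 20.0)):
        for batch in (1, 2):
            shift = 1.7 if batch == 2 else 0.0
            rows += [("tgt", stage, batch, 1, tct + shift),
                     ("ref", stage, batch, 1, 15.0 + shift)]
    res = ddct(_ct_df(rows), "ref", "Juv")["tgt"]
    assert res.fold["Cyp"] == pytest.approx(4.0)


def test_swapping_target_and_reference_inverts_fold():
    df = _ct_df([
        ("a", "Cyp", 1, 1, 18.0), ("b", "Cyp", 1, 1, 15.0),
        ("a", "Juv", 1, 1, 20.0), ("b", "Juv", 1, 1, 15.0),
    ])
    fold_ab = ddct(df, "b", "Juv")["a"].fold["Cyp"]
    fold_ba = ddct(df, "a", "Juv")["b"].fold["Cyp"]
    assert fold_ab == pytest.approx(1.0 / fold_ba)


def test_missing_reference_cell_raises_naming_the_cell():
    df = _ct_df([
        ("tgt", "Cyp", 1, 1, 18.0), ("ref", "Cyp", 1, 1, 15.0),
        ("tgt", "Juv", 1, 1, 20.0), ("ref", "Juv", 1, 1, 15.0),
        ("tgt", "Adu", 2, 3, 21.0),
    ])
    with pytest.raises(DataError, match="Adu.*batch=2.*replicate=3"):
        ddct(df, "ref", "Juv")


def test_mean_pairing_agrees_on_balanced_noiseless_data():
    df = generate_ct_table(
        {"tgt": {"Cyp": 6.0, "Juv": 1.0}}, noise_sd=0.0, seed=0)
    by_rep = ddct(df, "cytb", "Juv", pairing="replicate")["tgt"]
    by_mean = ddct(df, "cytb", "Juv", pairing="mean")["tgt"]
    assert by_rep.fold["Cyp"] == pytest.approx(by_mean.fold["Cyp"])
    with pytest.raises(ValueError):
        ddct(df, "cytb", "Juv", pairing="median")


def test_ct_table_reader_validates(tmp_path):
    p = tmp_path / "ct.tsv"
    p.write_text("gene\tstage\tbatch\treplicate\tct\nx\tCyp\t1\t1\t99\n")
    with pytest.raises(DataError):
        read_ct_table(p)


# --- ANOVA / Tukey --------------------------------------------------------

def test_identical_groups_nothing_significant():
    res = anova_tukey({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0],
                       "c": [1.0, 1.0, 1.0]})
    assert res.degenerate
    assert not res.pairs["sig05"].any()


def test_textbook_fixture_matches_independent_oracle():
    groups = {
        "g1": [6.0, 8.0, 4.0, 5.0, 3.0],
        "g2": [8.0, 12.0, 9.0, 11.0, 6.0],
        "g3": [13.0, 9.0, 11.0, 8.0, 12.0],
    }
    res = anova_tukey(groups)
    # one-way ANOVA from sums of squares, derived by hand
    data = [v for g in groups.values() for v in g]
    grand = sum(data) / len(data)
    ss_b = sum(len(v) * (sum(v) / len(v) - grand) ** 2
               for v in groups.values())
    ss_w = sum((x - sum(v) / len(v)) ** 2
               for v in groups.values() for x in v)
    f_oracle = (ss_b / 2) / (ss_w / 12)
    assert res.f_statistic == pytest.approx(f_oracle)
    assert (res.df_between, res.df_within) == (2, 12)
    # Tukey adjusted p from the studentized range distribution, by hand
    mse = ss_w / 12
    for _, row in res.pairs.iterrows():
        m1 = np.mean(groups[row["group1"]])
        m2 = np.mean(groups[row["group2"]])
        q = abs(m2 - m1) / math.sqrt(mse / 5)
        p_oracle = studentized_range.sf(q, 3, 12)
        assert row["p_adj"] == pytest.approx(p_oracle, abs=1e-6)


def test_alpha01_flags_are_subset_of_alpha05():
    rng = np.random.default_rng(7)
    for _ in range(10):
        groups = {g: rng.normal(rng.uniform(0, 3), 1, size=5)
                  for g in "abcd"}
        res = anova_tukey(groups)
        assert not (res.pairs["sig01"] & ~res.pairs["sig05"]).any()


def test_single_replicate_group_rejected():
    with pytest.raises(ValueError):
        anova_tukey({"a": [1.0], "b": [1.0, 2.0]})


def test_stage_anova_flags_planted_sixfold_cyprid_effect():
    profile = {"sif": {"NauVI": 1.0, "Cyp": 6.0, "Juv": 1.0, "Adu": 1.0}}
    df = generate_ct_table(profile, noise_sd=0.3, seed=42)
    res = stage_anova(ddct(df, "cytb", "Juv")["sif"])
    assert ("Cyp", "Juv") in [tuple(sorted(p))
                              for p in res.significant_pairs(0.05)]


# --- settlement assay -----------------------------------------------------

def test_arcsine_transform_boundaries_and_monotonicity():
    assert arcsine_sqrt(0.0) == 0.0
    assert arcsine_sqrt(1.0) == pytest.approx(math.pi / 2)
    ps = np.linspace(0, 1, 51)
    ys = arcsine_sqrt(ps)
    assert np.all(np.diff(ys) > 0)


def test_equal_proportions_nothing_significant():
    rows = []
    for group, dose, veh in (("AFSW", 0, "AFSW"), ("DMSO", 0, "DMSO"),
                             ("1", 1, "DMSO"), ("10", 10, "DMSO")):
        for tp in (24, 48):
            for w in range(3):
                rows.append({"dose": dose, "vehicle": veh, "timepoint": tp,
                             "batch": 1, "well": w, "n_meta": 14,
                             "n_total": 20})
    res = settlement_analysis(pd.DataFrame(rows))
    for tp in (24, 48):
        assert not res[tp].anova.pairs["sig05"].any()


def test_zero_total_is_a_data_error():
    df = generate_settlement_counts(seed=1)
    df.loc[0, "n_total"] = 0
    with pytest.raises(DataError):
        settlement_analysis(df)


def test_default_scenario_reproduces_inhibition_then_recovery():
    df = generate_settlement_counts(seed=5)
    res = settlement_analysis(df)
    t24 = res[24].versus_control.set_index("group")
    assert t24.loc["10uM", "p_adj"] < 0.05
    assert t24.loc["100uM", "p_adj"] < 0.05
    assert t24.loc["1uM", "p_adj"] >= 0.05
    t48 = res[48].versus_control.set_index("group")
    assert (t48["p_adj"] >= 0.05).all()


def test_assay_reader_validates(tmp_path):
    p = tmp_path / "w.tsv"
    generate_settlement_counts(seed=2).to_csv(p, sep="\t", index=False)
    df = read_assay_table(p)
    assert set(df.columns) >= {"dose", "vehicle", "timepoint", "n_meta"}
    p.write_text("dose\tvehicle\ttimepoint\tbatch\twell\tn_meta\tn_total\n"
                 "0\tAFSW\t24\t1\t1\t5\t0\n")
    with pytest.raises(DataError):
        read_assay_table(p)
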