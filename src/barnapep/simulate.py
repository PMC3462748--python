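"""Synthetic data with known ground truth.

Everything the pipeline consumes can be generated here: precursor proteins
with the canonical tripartite architecture (signal peptide, optional
propeptide spacer, mature peptides joined by basic processing sites),
transcriptomes embedding back-translated precursors among random decoys,
"related-species" homolog queries for the mining step, qPCR Ct tables, and
binomial settlement counts.

Every generator is a pure function of (spec, seed).  Each generated
precursor is self-validated on emission: the annotation rules are run on the
protein and must reproduce the planted signal end, site positions and
(sequence, amidated, pyroglu) peptide triples exactly, so a ground-truth
object can never drift from its FASTA.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from . import annotate as ann
from .config import PipelineConfig
from .io import Transcript

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODONS_FOR = {}
for codon, aa in _CODON_TABLE.forward_table.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
for aa in _CODONS_FOR:
    _CODONS_FOR[aa].sort()

# signal-peptide h-region alphabet: strongly hydrophobic residues that are
# not in the (-3,-1) small set, so the planted cleavage point is unambiguous
_CORE_AA = "LIFMW"
_CORE_P = (0.40, 0.20, 0.15, 0.15, 0.10)
# spacer alphabet: no basics (would create sites), no P (would veto the
# upstream site), no G (would read as an amidation donor), no Q (pyroGlu)
_SPACER_AA = "ASNETDHL"

SITE_RESIDUES = {
    "KR": "KR", "RR": "RR", "RK": "RK", "KK": "KK",
    "mono_R": "R", "multibasic": "KKR",
}


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class Payload:
    """One mature peptide to plant on a precursor."""
    sequence: str
    amidate: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GeneratorError("empty payload")
        if self.sequence.startswith("P"):
            raise GeneratorError(
                f"payload {self.sequence!r} starts with Pro: the upstream "
                "site would be vetoed"
            )
        if self.sequence.endswith("G") and not self.amidate:
            raise GeneratorError(
                f"payload {self.sequence!r} ends with Gly but amidate=False"
            )


@dataclass(frozen=True)
class PrecursorSpec:
    family: str
    payloads: tuple[Payload, ...]
    site_types: tuple[str, ...] = ()   # len(payloads)-1, default all KR
    signal_len: int | None = None      # drawn in 14-20 when None
    spacer_len: int = 0                # leading propeptide spacer; 0 = none
    utr5: tuple[int, int] = (30, 90)
    utr3: tuple[int, int] = (30, 90)

    def __post_init__(self) -> None:
        if not self.payloads:
            raise GeneratorError("spec needs at least one payload")
        sites = self.site_types or ("KR",) * (len(self.payloads) - 1)
        if len(sites) != len(self.payloads) - 1:
            raise GeneratorError("need one site type between adjacent payloads")
        for s in sites:
            if s not in SITE_RESIDUES:
                raise GeneratorError(f"unknown site type {s!r}")
        object.__setattr__(self, "site_types", tuple(sites))


@dataclass(frozen=True)
class PlantedPeptide:
    sequence: str
    amidated: bool
    pyroglu: bool
    family: str


@dataclass(frozen=True)
class PlantedPrecursor:
    family: str
    protein: str
    signal_end: int
    site_positions: tuple[int, ...]    # last residue of each planted site
    peptides: tuple[PlantedPeptide, ...]


@dataclass
class GroundTruth:
    planted: dict[str, PlantedPrecursor]
    decoy_ids: tuple[str, ...] = ()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted": {k: dataclasses.asdict(v)
                        for k, v in self.planted.items()},
            "decoy_ids": list(self.decoy_ids),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        planted = {}
        for k, v in d["planted"].items():
            planted[k] = PlantedPrecursor(
                family=v["family"], protein=v["protein"],
                signal_end=v["signal_end"],
                site_positions=tuple(v["site_positions"]),
                peptides=tuple(PlantedPeptide(**p) for p in v["peptides"]),
            )
        return cls(planted=planted, decoy_ids=tuple(d["decoy_ids"]))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_signal(rng, length: int | None = None) -> str:
    """Synthetic signal peptide: Met + basic n-region + hydrophobic core +
    a 3-residue c-region ending in the (-3,-1)-compliant 'S?A'."""
    rng = _rng(rng)
    if length is None:
        length = int(rng.integers(14, 21))
    n_basic = 1 if length < 15 else int(rng.integers(1, 3))
    core_len = length - 1 - n_basic - 3
    if core_len < 8:
        raise GeneratorError(f"signal length {length} too short for a core")
    core = "".join(rng.choice(list(_CORE_AA), size=core_len, p=_CORE_P))
    return "M" + "K" * n_basic + core + "SFA"


def _spacer(rng, length: int) -> str:
    return "".join(rng.choice(list(_SPACER_AA), size=length))


def generate_precursor(spec: PrecursorSpec, seed
                       ) -> tuple[str, PlantedPrecursor]:
    """Assemble one precursor protein and its ground truth, then verify that
    the annotation rules reproduce the plant exactly."""
    rng = _rng(seed)
    cfg = PipelineConfig()
    signal = make_signal(rng, spec.signal_len)
    parts = [signal]
    expected: list[PlantedPeptide] = []
    site_positions: list[int] = []
    pos = len(signal)

    def add_site(site_type: str) -> None:
        nonlocal pos
        res = SITE_RESIDUES[site_type]
        parts.append(res)
        pos += len(res)
        site_positions.append(pos)

    if spec.spacer_len > 0:
        sp = _spacer(rng, spec.spacer_len)
        parts.append(sp)
        pos += len(sp)
        expected.append(PlantedPeptide(sp, False, False, "spacer"))
        add_site("KR")

    for i, payload in enumerate(spec.payloads):
        if i > 0:
            add_site(spec.site_types[i - 1])
        seq = payload.sequence + ("G" if payload.amidate else "")
        parts.append(seq)
        pos += len(seq)
        expected.append(PlantedPeptide(
            payload.sequence, payload.amidate,
            ann.apply_pyroglu(payload.sequence, cfg), spec.family,
        ))

    protein = "".join(parts)
    truth = PlantedPrecursor(
        family=spec.family, protein=protein, signal_end=len(signal),
        site_positions=tuple(site_positions), peptides=tuple(expected),
    )
    _validate_plant(protein, truth, cfg)
    return protein, truth


def _validate_plant(protein: str, truth: PlantedPrecursor,
                    cfg: PipelineConfig) -> None:
    sig = ann.predict_signal_peptide(protein)
    if not sig.present or sig.cleavage_after != truth.signal_end:
        raise GeneratorError(
            f"planted signal end {truth.signal_end} not recovered "
            f"(got {sig.cleavage_after}); protein={protein!r}"
        )
    sites = ann.find_cleavage_sites(protein, truth.signal_end, cfg)
    accepted = tuple(s.position for s in sites if s.accepted)
    if accepted != truth.site_positions:
        raise GeneratorError(
            f"planted sites {truth.site_positions} != recovered {accepted}; "
            f"protein={protein!r}"
        )
    got = []
    for _, _, seg in ann.excise_peptides(protein, truth.signal_end, sites):
        seq, amid = ann.apply_amidation(seg, cfg.amidation)
        got.append((seq, amid, ann.apply_pyroglu(seq, cfg)))
    want = [(p.sequence, p.amidated, p.pyroglu) for p in truth.peptides]
    if got != want:
        raise GeneratorError(
            f"planted peptides not recovered:\nwant {want}\ngot  {got}\n"
            f"protein={protein!r}"
        )


def back_translate(protein: str, rng) -> str:
    """Back-translate with uniformly chosen synonymous codons."""
    rng = _rng(rng)
    return "".join(rng.choice(_CODONS_FOR[aa]) for aa in protein)


def _random_nt(rng, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def generate_transcriptome(specs: Sequence[PrecursorSpec], n_decoys: int,
                           gc: float = 0.45, seed=0,
                           ) -> tuple[list[Transcript], GroundTruth]:
    """Back-translate one precursor per spec into a transcript (flanked by
    in-frame stops and random UTRs, randomly strand-flipped) and add i.i.d.
    random decoy transcripts with a matched length distribution."""
    rng = _rng(seed)
    transcripts: list[Transcript] = []
    planted: dict[str, PlantedPrecursor] = {}
    for spec in specs:
        protein, truth = generate_precursor(spec, rng)
        cds = back_translate(protein, rng)
        u5 = _random_nt(rng, int(rng.integers(*spec.utr5)), gc)
        u3 = _random_nt(rng, int(rng.integers(*spec.utr3)), gc)
        seq = u5 + "TAA" + cds + "TAA" + u3
        if rng.random() < 0.5:
            comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
            seq = "".join(comp[c] for c in reversed(seq))
        tid = f"planted_{spec.family}"
        transcripts.append(Transcript(id=tid, sequence=seq))
        planted[tid] = truth
    lengths = [len(t.sequence) for t in transcripts] or [600]
    decoy_ids = []
    for i in range(n_decoys):
        L = int(rng.choice(lengths) + rng.integers(-50, 51))
        L = max(L, 60)
        tid = f"decoy_{i:04d}"
        decoy_ids.append(tid)
        transcripts.append(Transcript(id=tid, sequence=_random_nt(rng, L, gc)))
    return transcripts, GroundTruth(planted=planted,
                                    decoy_ids=tuple(decoy_ids))


_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def homolog_query(truth: PlantedPrecursor, rng, window: int = 60,
                  subst_rate: float = 0.2):
    """A 'related-species' reference sequence: a window of the planted
    precursor with conservative (BLOSUM62-nonnegative) substitutions."""
    from .io import ReferencePeptide

    rng = _rng(rng)
    seq = truth.protein[:window]
    out = []
    for aa in seq:
        if rng.random() < subst_rate:
            options = [b for b in _AA20 if b != aa and _BLOSUM62[aa, b] >= 0]
            if options:
                aa = str(rng.choice(options))
        out.append(aa)
    fam = truth.family
    return ReferencePeptide(
        id=f"{fam}_ref", sequence="".join(out), family=fam,
        taxon="synthetic relative",
        description=f"{fam} neuropeptide precursor homolog",
    )


# ---------------------------------------------------------------------------
# qPCR and settlement-assay generators

QPCR_STAGES = ("NauVI", "Cyp", "Juv", "Adu")


def default_fold_profile() -> dict[str, dict[str, float]]:
    """Developmental fold-change profile (relative to the juvenile stage)
    mirroring the reported qualitative pattern: SIFamide ~6-fold and PDH
    ~4-fold up in cyprids, ASTB ~3-fold up in late nauplii and cyprids,
    TRP high in nauplius VI and adult, most genes down in adults."""
    return {
        "sif":   {"NauVI": 2.0, "Cyp": 6.0, "Juv": 1.0, "Adu": 0.5},
        "pdh":   {"NauVI": 2.0, "Cyp": 4.0, "Juv": 1.0, "Adu": 0.5},
        "astb":  {"NauVI": 3.0, "Cyp": 3.0, "Juv": 1.0, "Adu": 0.5},
        "calcia": {"NauVI": 3.0, "Cyp": 3.0, "Juv": 1.0, "Adu": 0.5},
        "trp":   {"NauVI": 3.0, "Cyp": 1.0, "Juv": 1.0, "Adu": 3.0},
        "asta":  {"NauVI": 1.0, "Cyp": 1.0, "Juv": 1.0, "Adu": 0.5},
    }


def generate_ct_table(fold_profile: dict[str, dict[str, float]],
                      ct_ref_mean: float = 18.0, noise_sd: float = 0.3,
                      n_batches: int = 3, n_reps: int = 3, seed=0,
                      reference_gene: str = "cytb",
                      baseline_delta: float = 3.0) -> pd.DataFrame:
    """Simulate a tidy Ct table: the reference gene is constant up to noise;
    each target gene's Ct is ct_ref_mean + baseline_delta - log2(fold) +
    Gaussian noise."""
    rng = _rng(seed)
    for gene, prof in fold_profile.items():
        if any(f <= 0 for f in prof.values()):
            raise GeneratorError(f"{gene}: folds must be positive")
    rows = []
    stages = list(next(iter(fold_profile.values())).keys()) \
        if fold_profile else list(QPCR_STAGES)
    for stage in stages:
        for batch in range(1, n_batches + 1):
            for rep in range(1, n_reps + 1):
                rows.append({
                    "gene": reference_gene, "stage": stage, "batch": batch,
                    "replicate": rep,
                    "ct": ct_ref_mean + rng.normal(0, noise_sd),
                })
                for gene, prof in fold_profile.items():
                    rows.append({
                        "gene": gene, "stage": stage, "batch": batch,
                        "replicate": rep,
                        "ct": ct_ref_mean + baseline_delta
                        - np.log2(prof[stage]) + rng.normal(0, noise_sd),
                    })
    return pd.DataFrame(rows)


def default_settlement_scenario() -> dict[str, tuple[float, float]]:
    """Metamorphosis probabilities (24 h, 48 h) per treatment group: strong
    dose-dependent inhibition at >= 10 uM after 24 h, recovery by 48 h."""
    return {
        "AFSW": (0.70, 0.85),
        "DMSO": (0.70, 0.85),
        "1":    (0.67, 0.85),
        "10":   (0.20, 0.83),
        "100":  (0.08, 0.82),
    }


def generate_settlement_counts(scenario: dict[str, tuple[float, float]]
                               | None = None,
                               n_wells: int = 3, n_batches: int = 3,
                               n_per_well: int = 20, seed=0) -> pd.DataFrame:
    """Binomial settlement counts per well for each group and timepoint."""
    if scenario is None:
        scenario = default_settlement_scenario()
    rng = _rng(seed)
    dose_of = {"AFSW": 0.0, "DMSO": 0.0}
    rows = []
    for group, (p24, p48) in scenario.items():
        for p in (p24, p48):
            if not 0.0 <= p <= 1.0:
                raise GeneratorError(f"{group}: probabilities must be in [0,1]")
        dose = dose_of.get(group)
        if dose is None:
            dose = float(group)
        vehicle = group if group in ("AFSW", "DMSO") else "DMSO"
        for tp, p in ((24, p24), (48, p48)):
            for batch in range(1, n_batches + 1):
                for well in range(1, n_wells + 1):
                    rows.append({
                        "dose": dose, "vehicle": vehicle, "timepoint": tp,
                        "batch": batch, "well": well,
                        "n_meta": int(rng.binomial(n_per_well, p)),
                        "n_total": n_per_well,
                    })
    return pd.DataFrame(rows)
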