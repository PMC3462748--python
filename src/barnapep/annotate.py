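"""Precursor annotation: ORF selection, signal peptide, prohormone
processing sites, excision, and post-translational modifications.

The processing model follows the classical proprotein-convertase picture: the
signal peptide is removed first, the convertases cleave C-terminal of basic
sites (dibasic KR/RR always; RK/KK optionally; a lone Arg only with another
basic residue at -4, -6 or -8; runs of three or more basics as one site; no
cleavage when the site is immediately followed by Pro), carboxypeptidase
trims the exposed basic residues, and a C-terminal Gly left on a product is
converted into an amide.  N-terminal Gln (optionally Glu) cyclises to
pyroglutamate, and Tyr residues in an acidic context are flagged as sulfated.

Signal-peptide prediction is a transparent von-Heijne-style heuristic, not a
re-implementation of any neural-network predictor: a hydrophobic core window
near the N-terminus plus the (-3,-1) small-residue rule at the cleavage site,
with a minimal three-residue c-region between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

from .config import PipelineConfig
from .mining import AlignmentHit, FrameTranslation, six_frame_translate
from .io import Transcript

HYDROPHOBIC = frozenset("AILMFVWC")
SMALL = frozenset("AGSCTV")
BASIC = frozenset("KR")


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class PrecursorCandidate:
    transcript_id: str
    orf_nt_span: tuple[int, int]      # 1-based inclusive, forward strand
    frame: int
    protein: str                      # no stop character
    supporting_hits: tuple[str, ...] = ()
    starts_at_met: bool = True
    rare_confirmed: bool = False      # metadata only (cloning status)

    def __post_init__(self) -> None:
        if not self.protein:
            raise AnnotationError(f"{self.transcript_id}: empty protein")


@dataclass(frozen=True)
class SignalPrediction:
    present: bool
    cleavage_after: int               # last signal residue; 0 if absent
    score: float                      # hydrophobic fraction of the best core


@dataclass(frozen=True)
class CleavageSite:
    position: int                     # 1-based index of the LAST site residue
    start: int                        # 1-based index of the first site residue
    site_type: str                    # KR, RR, RK, KK, mono_R, multibasic
    accepted: bool
    rule: str


@dataclass(frozen=True)
class MaturePeptide:
    start: int
    end: int
    sequence: str
    amidated: bool
    pyroglu: bool
    sulfated_positions: tuple[int, ...]
    family: str = "unknown"
    copy_index: int = 1

    @property
    def display(self) -> str:
        """Render with pQ prefix / -NH2 suffix; coordinates are untouched."""
        s = self.sequence
        if self.pyroglu:
            s = "pQ" + s[1:]
        if self.amidated:
            s = s + "-NH2"
        return s


@dataclass(frozen=True)
class ScreenResult:
    has_signal: bool
    under_length: bool
    has_processing_site: bool

    @property
    def passed(self) -> bool:
        return self.has_signal and self.under_length and self.has_processing_site


@dataclass(frozen=True)
class AnnotatedPrecursor:
    candidate: PrecursorCandidate
    signal: SignalPrediction
    sites: tuple[CleavageSite, ...]
    peptides: tuple[MaturePeptide, ...]
    screen: ScreenResult


def find_orf(hit: AlignmentHit, transcript: Transcript) -> PrecursorCandidate:
    """Extract the precursor ORF around a homology hit.

    The ORF is the maximal stop-to-stop stretch in the hit's frame containing
    the hit span, trimmed to start at the first Met at or upstream of the hit
    within that stretch; without a Met it starts at the stretch boundary and
    is flagged ``starts_at_met=False``.
    """
    frames = {ft.frame: ft for ft in six_frame_translate(transcript)}
    ft = frames[hit.frame]
    pep = ft.peptide
    s0, s1 = hit.subject_span[0] - 1, hit.subject_span[1] - 1  # 0-based
    if "*" in pep[s0:s1 + 1]:
        raise AnnotationError(
            f"{transcript.id}: hit span crosses a stop codon"
        )
    seg_start = pep.rfind("*", 0, s0) + 1          # 0 if no stop upstream
    seg_end = pep.find("*", s1 + 1)
    if seg_end == -1:
        seg_end = len(pep)
    met = pep.find("M", seg_start, s0 + 1)
    if met != -1:
        start, starts_at_met = met, True
    else:
        start, starts_at_met = seg_start, False
    protein = pep[start:seg_end]
    nt_span = ft.nt_span(start + 1, seg_end)
    return PrecursorCandidate(
        transcript_id=transcript.id, orf_nt_span=nt_span, frame=hit.frame,
        protein=protein, supporting_hits=(hit.query_id,),
        starts_at_met=starts_at_met,
    )


def predict_signal_peptide(protein: str) -> SignalPrediction:
    """Heuristic signal-peptide call.

    Present iff (i) some 8-residue window starting within positions 2-23
    (so lying within the first 30 residues) has >= 6 residues from the
    hydrophobic set, and (ii) a cleavage position c in 10-40 with
    c >= core_end + 3 satisfies the (-3,-1) rule: residues c and c-2 are
    small.  The core is the last maximal-scoring window; the cleavage site is
    the earliest qualifying c.  Score is the hydrophobic fraction of the core.
    """
    n = len(protein)
    absent = SignalPrediction(False, 0, 0.0)
    if n < 15:
        return absent
    best_count = 0
    core_end = 0
    for i in range(1, min(23, n - 7)):            # 0-based start; pos 2..23
        window = protein[i:i + 8]
        count = sum(1 for ch in window if ch in HYDROPHOBIC)
        if count >= best_count:
            best_count = count
            core_end = i + 8                      # 1-based end of window
    if best_count < 6:
        return absent
    for c in range(max(10, core_end + 3), min(40, n - 1) + 1):
        if protein[c - 1] in SMALL and protein[c - 3] in SMALL:
            return SignalPrediction(True, c, best_count / 8.0)
    return absent


def find_cleavage_sites(protein: str, signal_end: int,
                        cfg: PipelineConfig | None = None
                        ) -> list[CleavageSite]:
    """Scan for prohormone convertase sites C-terminal of the signal.

    Maximal runs of basic residues are classified atomically: length >= 3 is
    one multibasic site, length 2 a dibasic site, length 1 a candidate
    monobasic site (Arg only).  Returns all candidates, accepted or not,
    sorted by position.
    """
    if cfg is None:
        cfg = PipelineConfig()
    if signal_end >= len(protein):
        raise AnnotationError("signal_end must fall inside the protein")
    n = len(protein)
    runs = []           # (start0, end0) inclusive, maximal basic runs
    i = signal_end      # 0-based first position after the signal
    while i < n:
        if protein[i] in BASIC:
            j = i
            while j + 1 < n and protein[j + 1] in BASIC:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1

    sites: list[CleavageSite] = []
    accepted_mask = [False] * n       # residues consumed by accepted sites

    def followed_by_pro(end0: int) -> bool:
        return (cfg.reject_site_before_pro and end0 + 1 < n
                and protein[end0 + 1] == "P")

    # pass 1: di- and multibasic runs
    mono_runs = []
    for a, b in runs:
        length = b - a + 1
        if length == 1:
            mono_runs.append((a, b))
            continue
        if length >= 3:
            site_type, ok, rule = "multibasic", cfg.accept_multibasic, \
                "run of >=3 basic residues"
        else:
            site_type = protein[a:b + 1]
            ok = {"KR": cfg.accept_kr, "RR": cfg.accept_rr,
                  "RK": cfg.accept_rk, "KK": cfg.accept_kk}[site_type]
            rule = f"dibasic {site_type}"
        if ok and followed_by_pro(b):
            ok, rule = False, rule + " (rejected: followed by Pro)"
        elif not ok:
            rule = rule + " (toggled off)"
        sites.append(CleavageSite(b + 1, a + 1, site_type, ok, rule))
        if ok:
            for k in range(a, b + 1):
                accepted_mask[k] = True

    # pass 2: monobasic Arg, supported by a basic at -4/-6/-8 that is not
    # part of an accepted site or the signal peptide (those residues are
    # removed before the monobasic context exists)
    for a, b in mono_runs:
        if protein[a] != "R":
            continue
        support = False
        for d in (4, 6, 8):
            p = a - d
            if p < 0 or protein[p] not in BASIC:
                continue
            if cfg.mono_ignore_consumed_basics and (accepted_mask[p]
                                                    or p < signal_end):
                continue
            support = True
            break
        ok = cfg.accept_mono_r and support
        rule = "monobasic R with basic at -4/-6/-8" if support else \
            "monobasic R without -4/-6/-8 support"
        if ok and followed_by_pro(b):
            ok, rule = False, rule + " (rejected: followed by Pro)"
        elif not cfg.accept_mono_r and support:
            rule += " (toggled off)"
        sites.append(CleavageSite(b + 1, a + 1, "mono_R", ok, rule))

    sites.sort(key=lambda s: s.position)
    return sites


def screen_precursor(protein: str, signal: SignalPrediction,
                     sites: Sequence[CleavageSite],
                     cfg: PipelineConfig | None = None) -> ScreenResult:
    """Apply the three precursor criteria: signal peptide, at least one
    accepted processing site after the signal, and length strictly below the
    configured maximum (default 300 residues)."""
    if cfg is None:
        cfg = PipelineConfig()
    has_site = any(s.accepted and s.start > signal.cleavage_after
                   for s in sites)
    return ScreenResult(
        has_signal=signal.present,
        under_length=len(protein) < cfg.max_precursor_len,
        has_processing_site=has_site,
    )


def excise_peptides(protein: str, signal_end: int,
                    sites: Sequence[CleavageSite]
                    ) -> list[tuple[int, int, str]]:
    """Cut the proprotein into raw segments between accepted sites.

    Returns (start, end, sequence) with 1-based inclusive coordinates; the
    basic site residues themselves are excluded and empty segments dropped.
    """
    cuts = []
    for s in sorted(sites, key=lambda s: s.position):
        if s.accepted:
            cuts.append((s.start - 1, s.position))   # 0-based [a, b)
    segments = []
    prev = signal_end
    for a, b in cuts + [(len(protein), len(protein))]:
        if a > prev:
            segments.append((prev + 1, a, protein[prev:a]))
        prev = max(prev, b)
    return segments


def apply_amidation(segment: str, enabled: bool = True) -> tuple[str, bool]:
    """Gly-donor amidation: a C-terminal Gly is removed and the preceding
    residue amidated."""
    if enabled and segment.endswith("G") and len(segment) > 1:
        return segment[:-1], True
    return segment, False


def apply_pyroglu(peptide: str, cfg: PipelineConfig | None = None) -> bool:
    """Flag N-terminal Gln (optionally Glu) cyclisation; sequence unchanged."""
    if cfg is None:
        cfg = PipelineConfig()
    if not peptide:
        return False
    return (cfg.pyroglu_gln and peptide[0] == "Q") or \
        (cfg.pyroglu_glu and peptide[0] == "E")


def predict_sulfation(peptide: str, cfg: PipelineConfig | None = None
                      ) -> tuple[int, ...]:
    """Tyr positions (1-based within the peptide) in an acidic context:
    >= cfg.acidic_min Asp/Glu within +/- cfg.sulfation_window residues."""
    if cfg is None:
        cfg = PipelineConfig()
    w, need = cfg.sulfation_window, cfg.acidic_min
    out = []
    for i, ch in enumerate(peptide):
        if ch != "Y":
            continue
        lo, hi = max(0, i - w), min(len(peptide), i + w + 1)
        acidic = sum(1 for c in peptide[lo:hi] if c in "DE")
        if acidic >= need:
            out.append(i + 1)
    return tuple(out)


def annotate_precursor(candidate: PrecursorCandidate,
                       cfg: PipelineConfig | None = None,
                       patterns=None) -> AnnotatedPrecursor:
    """Full annotation of one candidate: signal -> sites -> screen ->
    excision -> PTMs -> family motif assignment."""
    from . import motifs as _motifs

    if cfg is None:
        cfg = PipelineConfig()
    protein = candidate.protein
    signal = predict_signal_peptide(protein)
    signal_end = signal.cleavage_after
    sites = find_cleavage_sites(protein, signal_end, cfg) \
        if signal_end < len(protein) else []
    screen = screen_precursor(protein, signal, sites, cfg)
    segments = excise_peptides(protein, signal_end, sites)
    if patterns is None:
        patterns = _motifs.default_patterns()
    peptides = []
    copy_counter: dict[str, int] = {}
    seen: set[str] = set()
    for seg_start, seg_end, seg in segments:
        seq, amidated = apply_amidation(seg, cfg.amidation)
        end = seg_end - 1 if amidated else seg_end
        pyro = apply_pyroglu(seq, cfg)
        sulf = predict_sulfation(seq, cfg)
        copy_counter[seq] = copy_counter.get(seq, 0) + 1
        if cfg.dedupe_peptides and seq in seen:
            continue
        seen.add(seq)
        pep = MaturePeptide(
            start=seg_start, end=end, sequence=seq, amidated=amidated,
            pyroglu=pyro, sulfated_positions=sulf,
            copy_index=copy_counter[seq],
        )
        assignment = _motifs.match_motif(pep, patterns)
        if assignment is not None:
            pep = MaturePeptide(**{**asdict(pep), "family": assignment.family})
        peptides.append(pep)
    return AnnotatedPrecursor(
        candidate=candidate, signal=signal, sites=tuple(sites),
        peptides=tuple(peptides), screen=screen,
    )


def annotate_protein(protein: str, protein_id: str = "precursor",
                     cfg: PipelineConfig | None = None,
                     patterns=None) -> AnnotatedPrecursor:
    """Annotate a bare protein sequence (e.g. a published precursor)."""
    cand = PrecursorCandidate(
        transcript_id=protein_id, orf_nt_span=(1, 3 * len(protein)),
        frame=1, protein=protein,
    )
    return annotate_precursor(cand, cfg, patterns)


def annotated_precursor_from_dict(d: dict) -> AnnotatedPrecursor:
    """Rebuild the annotation object graph from its JSON form."""
    cand = d["candidate"]
    sig = d["signal"]
    scr = d["screen"]
    return AnnotatedPrecursor(
        candidate=PrecursorCandidate(
            transcript_id=cand["transcript_id"],
            orf_nt_span=tuple(cand["orf_nt_span"]),
            frame=cand["frame"], protein=cand["protein"],
            supporting_hits=tuple(cand["supporting_hits"]),
            starts_at_met=cand["starts_at_met"],
            rare_confirmed=cand["rare_confirmed"],
        ),
        signal=SignalPrediction(**sig),
        sites=tuple(CleavageSite(**s) for s in d["sites"]),
        peptides=tuple(
            MaturePeptide(**{**p, "sulfated_positions":
                             tuple(p["sulfated_positions"])})
            for p in d["peptides"]
        ),
        screen=ScreenResult(**scr),
    )
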