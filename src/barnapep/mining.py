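"""Translated homology search over a transcriptome.

This emulates a tBLASTn screen without the heuristic word-seeding: every
reference peptide is aligned by exact affine-gap Smith-Waterman (through
Bio.Align.PairwiseAligner) against all six frame translations of every
transcript, and alignment significance is scored with the explicit
Karlin-Altschul formula E = K*m*n*exp(-lambda*S) using published gapped
BLOSUM62 constants.  Absolute E-values therefore differ from NCBI BLAST, but
ordering and thresholding behave the same way.

Frame translations are segmented at stop codons before alignment, so an
alignment can never cross a stop - the behaviour of a translated search.

Gap convention: a gap of length L costs ``gap_open + (L - 1) * gap_extend``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .config import ConfigError, PipelineConfig
from .io import Transcript

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)

FRAMES = (1, 2, 3, -1, -2, -3)


def _translate_codon(codon: str) -> str:
    if codon in _STOPS:
        return "*"
    return _TABLE.forward_table.get(codon, "X")


@dataclass(frozen=True)
class FrameTranslation:
    """One of the six conceptual translations of a transcript.

    ``peptide`` uses ``*`` for stop codons.  Coordinates on the peptide are
    1-based; :meth:`nt_span` converts them back to 1-based inclusive
    forward-strand nucleotide coordinates.
    """

    transcript_id: str
    frame: int               # +1,+2,+3 forward; -1,-2,-3 reverse complement
    peptide: str
    transcript_len: int

    def nt_span(self, pep_start: int, pep_end: int) -> tuple[int, int]:
        off = abs(self.frame) - 1
        lo = off + 3 * (pep_start - 1) + 1
        hi = off + 3 * pep_end
        if self.frame > 0:
            return lo, hi
        L = self.transcript_len
        return L - hi + 1, L - lo + 1


def six_frame_translate(t: Transcript) -> list[FrameTranslation]:
    """Translate a transcript in all six frames under the standard code.

    Codons containing N translate to X.  Frames too short for a single codon
    yield an empty peptide.
    """
    out = []
    fwd = t.sequence
    rev = str(Seq(fwd).reverse_complement())
    for frame in FRAMES:
        src = fwd if frame > 0 else rev
        off = abs(frame) - 1
        usable = len(src) - off
        n_codons = usable // 3 if usable > 0 else 0
        pep = "".join(
            _translate_codon(src[off + 3 * i: off + 3 * i + 3])
            for i in range(n_codons)
        )
        out.append(FrameTranslation(t.id, frame, pep, len(fwd)))
    return out


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    transcript_id: str
    frame: int
    raw_score: int
    bit_score: float
    e_value: float
    query_span: tuple[int, int]      # 1-based inclusive on the query
    subject_span: tuple[int, int]    # 1-based inclusive on the frame peptide
    subject_nt_span: tuple[int, int]  # 1-based inclusive, forward strand
    aligned_query: str
    aligned_subject: str


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    try:
        return substitution_matrices.load(name)
    except Exception as exc:
        raise ConfigError(f"unknown substitution matrix {name!r}") from exc


@lru_cache(maxsize=16)
def _make_aligner(matrix: str, gap_open: int, gap_extend: int,
                  mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _load_matrix(matrix)
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


@dataclass(frozen=True)
class LocalAlignment:
    raw_score: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    aligned_query: str
    aligned_subject: str


def local_align(query: str, subject: str, matrix: str = "BLOSUM62",
                gap_open: int = 11, gap_extend: int = 1) -> LocalAlignment:
    """Optimal affine-gap Smith-Waterman local alignment.

    Returns a zero-score, empty alignment when no residue pair scores
    positively.  Traceback is the aligner's deterministic first alignment.
    """
    if not query or not subject:
        raise ValueError("local_align requires non-empty sequences")
    aligner = _make_aligner(matrix, gap_open, gap_extend, "local")
    score = aligner.score(subject, query)  # target=subject, query=query
    if score <= 0:
        return LocalAlignment(0, (0, 0), (0, 0), "", "")
    aln = next(iter(aligner.align(subject, query)))
    s_blocks, q_blocks = aln.aligned  # aligned = (target=subject, query)
    q_start, q_end = int(q_blocks[0][0]) + 1, int(q_blocks[-1][1])
    s_start, s_end = int(s_blocks[0][0]) + 1, int(s_blocks[-1][1])
    a_s, a_q = _aligned_strings_ts(aln)
    return LocalAlignment(int(round(score)), (q_start, q_end),
                          (s_start, s_end), a_q, a_s)


def _aligned_strings_ts(aln) -> tuple[str, str]:
    """Aligned (target, query) strings with '-' gaps."""
    t, q = [], []
    ta, qa = aln.aligned
    pt = pq = None
    for (ts, te), (qs, qe) in zip(ta, qa):
        if pt is not None:
            if ts > pt:
                t.append(str(aln.target[pt:ts]))
                q.append("-" * (ts - pt))
            if qs > pq:
                t.append("-" * (qs - pq))
                q.append(str(aln.query[pq:qs]))
        t.append(str(aln.target[ts:te]))
        q.append(str(aln.query[qs:qe]))
        pt, pq = te, qe
    return "".join(t), "".join(q)


def evalue(raw_score: float, query_len: int, db_len_aa: int,
           lam: float = 0.267, K: float = 0.041) -> float:
    """Karlin-Altschul expected number of chance alignments scoring >= S."""
    if query_len <= 0 or db_len_aa <= 0:
        raise ValueError("query_len and db_len_aa must be positive")
    return K * query_len * db_len_aa * math.exp(-lam * raw_score)


def bit_score(raw_score: float, lam: float = 0.267, K: float = 0.041) -> float:
    return (lam * raw_score - math.log(K)) / math.log(2)


def _segments(peptide: str, min_len: int) -> list[tuple[int, str]]:
    """Maximal stop-free stretches as (0-based offset, subsequence)."""
    segs = []
    start = 0
    for i, ch in enumerate(peptide + "*"):
        if ch == "*":
            if i - start >= min_len:
                segs.append((start, peptide[start:i]))
            start = i + 1
    return segs


_FRAME_ORDER = {f: i for i, f in enumerate(FRAMES)}


def mine_transcriptome(queries: Sequence, transcripts: Sequence[Transcript],
                       cfg: PipelineConfig | None = None
                       ) -> dict[str, list[AlignmentHit]]:
    """Screen all queries against six-frame translations of all transcripts.

    For each query at most ``cfg.top_k`` hits with E-value below
    ``cfg.e_threshold`` are returned, sorted by ascending E-value; at most one
    hit (the best) is reported per transcript.  Ties are broken by raw score,
    then earlier subject start, earlier query start, frame order
    (+1,+2,+3,-1,-2,-3), then transcript id, so the result is invariant under
    shuffling of the input transcript list.
    """
    if cfg is None:
        cfg = PipelineConfig()
    if not queries or not transcripts:
        raise ValueError("mine_transcriptome requires non-empty inputs")

    frames = {t.id: six_frame_translate(t) for t in transcripts}
    db_len_aa = sum(
        len(ft.peptide) - ft.peptide.count("*")
        for fl in frames.values() for ft in fl
    )
    matrix = _load_matrix(cfg.matrix)
    max_diag = max(matrix[a, a] for a in "ACDEFGHIKLMNPQRSTVWY")
    aligner = _make_aligner(cfg.matrix, cfg.gap_open, cfg.gap_extend, "local")

    results: dict[str, list[AlignmentHit]] = {}
    for q in queries:
        qseq = q.sequence
        m = len(qseq)
        # smallest raw score that can reach the E threshold; shorter segments
        # cannot possibly produce it
        s_min = math.log(cfg.karlin_k * m * db_len_aa / cfg.e_threshold) \
            / cfg.karlin_lambda
        min_seg = max(cfg.min_segment_len, int(math.ceil(s_min / max_diag)))
        best: dict[str, tuple[float, FrameTranslation, int, str]] = {}
        for tid, fl in frames.items():
            top = None
            for ft in fl:
                for off, seg in _segments(ft.peptide, min_seg):
                    sc = aligner.score(seg, qseq)
                    if top is None or sc > top[0]:
                        top = (sc, ft, off, seg)
            if top is not None and top[0] > 0:
                best[tid] = top
        hits = []
        for tid, (sc, ft, off, seg) in best.items():
            ev = evalue(sc, m, db_len_aa, cfg.karlin_lambda, cfg.karlin_k)
            if ev >= cfg.e_threshold:
                continue
            la = local_align(qseq, seg, cfg.matrix, cfg.gap_open, cfg.gap_extend)
            s_span = (la.subject_span[0] + off, la.subject_span[1] + off)
            hits.append(AlignmentHit(
                query_id=q.id, transcript_id=tid, frame=ft.frame,
                raw_score=la.raw_score,
                bit_score=bit_score(la.raw_score, cfg.karlin_lambda, cfg.karlin_k),
                e_value=evalue(la.raw_score, m, db_len_aa,
                               cfg.karlin_lambda, cfg.karlin_k),
                query_span=la.query_span, subject_span=s_span,
                subject_nt_span=ft.nt_span(*s_span),
                aligned_query=la.aligned_query,
                aligned_subject=la.aligned_subject,
            ))
        hits.sort(key=lambda h: (h.e_value, -h.raw_score, h.subject_span[0],
                                 h.query_span[0], _FRAME_ORDER[h.frame],
                                 h.transcript_id))
        results[q.id] = hits[:cfg.top_k]
    return results


def hits_to_outfmt6(results: dict[str, list[AlignmentHit]]) -> list[str]:
    """Render hits as BLAST outfmt-6 style tab-separated lines."""
    lines = []
    for qid in results:
        for h in results[qid]:
            pairs = [
                (a, b) for a, b in zip(h.aligned_query, h.aligned_subject)
            ]
            length = len(pairs)
            ident = sum(1 for a, b in pairs if a == b and a != "-")
            mismatch = sum(1 for a, b in pairs
                           if a != b and a != "-" and b != "-")
            gapopen = 0
            in_gap = False
            for a, b in pairs:
                g = a == "-" or b == "-"
                if g and not in_gap:
                    gapopen += 1
                in_gap = g
            pident = 100.0 * ident / length if length else 0.0
            lines.append("\t".join(map(str, [
                h.query_id, h.transcript_id, f"{pident:.1f}", length,
                mismatch, gapopen, h.query_span[0], h.query_span[1],
                h.subject_nt_span[0], h.subject_nt_span[1],
                f"{h.e_value:.2g}", f"{h.bit_score:.1f}",
            ])))
    return lines
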