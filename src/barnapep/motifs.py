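"""Family assignment by terminal motifs, and peptide alignment.

Neuropeptide families are recognisable from short terminal signatures
(FGLamide for A-type allatostatins, W(X6)Wamide for B-type, SIFamide,
the sulfakinin [YF]G[HMF][MLF][RK]Famide core, the orcokinin NFDEIDR
N-terminus, ...).  The default pattern set ships as data
(``data/family_patterns.tsv``); patterns generalise the canonical arthropod
signatures just enough to admit the barnacle variants (Ser7 ASTC, Lys8 and
Met6/Phe6 sulfakinins).

Alignment of family members is exact affine-gap Needleman-Wunsch (through
Bio.Align.PairwiseAligner) plus a deterministic centre-star progressive
multiple alignment; no guide tree is built.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

from .config import ConfigError
from .io import PROTEIN_LETTERS
from .mining import _make_aligner

ANCHORS = ("C-terminal", "N-terminal", "anywhere")


@dataclass(frozen=True)
class MotifPattern:
    family: str
    pattern: str
    anchor: str
    requires_amidation: bool
    regex: re.Pattern

    @classmethod
    def parse(cls, family: str, pattern: str, anchor: str) -> "MotifPattern":
        if anchor not in ANCHORS:
            raise ConfigError(f"{family}: unknown anchor {anchor!r}")
        requires_amid = pattern.endswith("a")
        body = pattern[:-1] if requires_amid else pattern
        rx = []
        i = 0
        while i < len(body):
            ch = body[i]
            if ch == "X":
                if i + 1 < len(body) and body[i + 1] == "(":
                    j = body.find(")", i)
                    if j == -1:
                        raise ConfigError(f"{family}: unclosed repeat in {pattern!r}")
                    n = int(body[i + 2:j])
                    rx.append(".{%d}" % n)
                    i = j + 1
                else:
                    rx.append(".")
                    i += 1
            elif ch == "[":
                j = body.find("]", i)
                if j == -1 or j == i + 1:
                    raise ConfigError(f"{family}: bad alternative set in {pattern!r}")
                alts = body[i + 1:j]
                if not set(alts) <= PROTEIN_LETTERS:
                    raise ConfigError(f"{family}: invalid residues in {pattern!r}")
                rx.append("[" + alts + "]")
                i = j + 1
            elif ch in PROTEIN_LETTERS:
                rx.append(ch)
                i += 1
            else:
                raise ConfigError(
                    f"{family}: unparseable character {ch!r} in {pattern!r}"
                )
        expr = "".join(rx)
        if anchor == "C-terminal":
            expr += "$"
        elif anchor == "N-terminal":
            expr = "^" + expr
        return cls(family, pattern, anchor, requires_amid, re.compile(expr))


@dataclass(frozen=True)
class FamilyAssignment:
    family: str
    start: int    # 1-based inclusive span of the match within the peptide
    end: int


def load_patterns(path: str | Path) -> list[MotifPattern]:
    """Read a pattern file: family TAB pattern TAB anchor, one per line."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ConfigError(f"bad pattern line: {line!r}")
        out.append(MotifPattern.parse(*parts))
    return out


_DEFAULT: list[MotifPattern] | None = None


def default_patterns() -> list[MotifPattern]:
    global _DEFAULT
    if _DEFAULT is None:
        with resources.as_file(
            resources.files("barnapep") / "data" / "family_patterns.tsv"
        ) as p:
            _DEFAULT = load_patterns(p)
    return _DEFAULT


def match_motif(peptide, patterns: Sequence[MotifPattern]
                ) -> FamilyAssignment | None:
    """First matching pattern in priority order, or None.

    A pure function of (sequence, amidated): amidation-requiring patterns
    only match amidated peptides.
    """
    seq = peptide.sequence
    amid = peptide.amidated
    for pat in patterns:
        if pat.requires_amidation and not amid:
            continue
        m = pat.regex.search(seq)
        if m:
            return FamilyAssignment(pat.family, m.start() + 1, m.end())
    return None


def count_isoforms(ap, family: str) -> int:
    """Number of mature-peptide instances on a precursor assigned to a family."""
    return sum(1 for p in ap.peptides if p.family == family)


@dataclass(frozen=True)
class GlobalAlignment:
    score: int
    aligned_a: str
    aligned_b: str


def pairwise_align_global(a: str, b: str, matrix: str = "BLOSUM62",
                          gap_open: int = 11, gap_extend: int = 1
                          ) -> GlobalAlignment:
    """Optimal global affine-gap alignment (end gaps penalised).

    Gap convention matches the local aligner: a gap of length L costs
    ``gap_open + (L-1)*gap_extend``.  Traceback is deterministic.
    """
    if not a or not b:
        raise ValueError("pairwise_align_global requires non-empty sequences")
    aligner = _make_aligner(matrix, gap_open, gap_extend, "global")
    aln = next(iter(aligner.align(a, b)))
    ta, qa = _aligned_from(aln)
    return GlobalAlignment(int(round(aln.score)), ta, qa)


def _aligned_from(aln) -> tuple[str, str]:
    t, q = [], []
    ta, qa = aln.aligned
    pt = pq = 0
    for (ts, te), (qs, qe) in zip(ta, qa):
        if ts > pt:
            t.append(str(aln.target[pt:ts]))
            q.append("-" * (ts - pt))
        if qs > pq:
            t.append("-" * (qs - pq))
            q.append(str(aln.query[pq:qs]))
        t.append(str(aln.target[ts:te]))
        q.append(str(aln.query[qs:qe]))
        pt, pq = te, qe
    if pt < len(aln.target):
        t.append(str(aln.target[pt:]))
        q.append("-" * (len(aln.target) - pt))
    if pq < len(aln.query):
        t.append("-" * (len(aln.query) - pq))
        q.append(str(aln.query[pq:]))
    return "".join(t), "".join(q)


def progressive_msa(peptides: Sequence[str], matrix: str = "BLOSUM62",
                    gap_open: int = 11, gap_extend: int = 1) -> list[str]:
    """Centre-star progressive multiple alignment.

    The centre is the sequence maximising the summed pairwise global score
    (ties broken by input order); the others are merged in input order under
    the once-a-gap-always-a-gap rule.  Removing the gap characters of row i
    reproduces input i exactly.
    """
    seqs = list(peptides)
    if len(seqs) < 2:
        raise ValueError("progressive_msa requires at least 2 sequences")
    n = len(seqs)
    scores = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            sc = pairwise_align_global(seqs[i], seqs[j], matrix,
                                       gap_open, gap_extend).score
            scores[i][j] = scores[j][i] = sc
    center = max(range(n), key=lambda i: (sum(scores[i]), -i))

    master = seqs[center]          # centre row, accumulating gaps
    rows: list[tuple[int, str]] = [(center, master)]
    for j in range(n):
        if j == center:
            continue
        aln = pairwise_align_global(seqs[center], seqs[j], matrix,
                                    gap_open, gap_extend)
        c_aln, s_aln = aln.aligned_a, aln.aligned_b
        new_master, new_rows, new_row = _merge(master, rows, c_aln, s_aln)
        master, rows = new_master, new_rows
        rows.append((j, new_row))
    rows.sort(key=lambda r: r[0])
    return [r for _, r in rows]


def _merge(master: str, rows: list[tuple[int, str]], c_aln: str, s_aln: str):
    """Merge a (centre, sequence) pairwise alignment into the running MSA."""
    out_master = []
    out_rows: list[list[str]] = [[] for _ in rows]
    out_new = []
    i = j = 0
    while i < len(master) or j < len(c_aln):
        a = master[i] if i < len(master) else None
        b = c_aln[j] if j < len(c_aln) else None
        if a is not None and b is not None and (a != "-") and (b != "-"):
            out_master.append(a)
            for k, (_, r) in enumerate(rows):
                out_rows[k].append(r[i])
            out_new.append(s_aln[j])
            i += 1
            j += 1
        elif a == "-" and (b == "-"):
            out_master.append(a)
            for k, (_, r) in enumerate(rows):
                out_rows[k].append(r[i])
            out_new.append(s_aln[j])
            i += 1
            j += 1
        elif a == "-":
            out_master.append(a)
            for k, (_, r) in enumerate(rows):
                out_rows[k].append(r[i])
            out_new.append("-")
            i += 1
        else:  # b == "-" or master exhausted
            out_master.append("-")
            for k in range(len(rows)):
                out_rows[k].append("-")
            out_new.append(s_aln[j])
            j += 1
    new_rows = [(idx, "".join(out_rows[k]))
                for k, (idx, _) in enumerate(rows)]
    return "".join(out_master), new_rows, "".join(out_new)


def write_alignment_fasta(names: Sequence[str], rows: Sequence[str],
                          path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(names, rows):
            fh.write(f">{name}\n{row}\n")


def write_alignment_clustal(names: Sequence[str], rows: Sequence[str],
                            path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        fh.write("CLUSTAL-style alignment\n\n")
        ncol = len(rows[0]) if rows else 0
        pad = max((len(n) for n in names), default=0) + 2
        for start in range(0, ncol, width):
            for name, row in zip(names, rows):
                fh.write(name.ljust(pad) + row[start:start + width] + "\n")
            fh.write("\n")
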