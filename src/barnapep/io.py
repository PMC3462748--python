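"""Reading and writing the pipeline's standard formats.

FASTA handling is delegated to Bio.SeqIO; this module adds alphabet
validation, the curated reference-peptide records, and the mature-peptide
report (TSV and a lossless JSON mirror).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROTEIN_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_LETTERS = frozenset("ACGTN")

#: The family vocabulary, seeded from the published catalog.  Calcitonin-like
#: diuretic hormone isoforms A and B belong to the single family CALCI, which
#: is how the catalog's 17 precursor rows collapse to 16 families/subfamilies.
FAMILIES = (
    "ASTA", "ASTB", "ASTC", "BURSA", "BURSB", "CALCI", "CLDH", "EH",
    "IRP", "ITP", "NPF", "ORCO", "PDH", "SIF", "SULF", "TRP",
)


class FastaParseError(ValueError):
    pass


class AlphabetError(ValueError):
    pass


@dataclass(frozen=True)
class ReferencePeptide:
    """A curated query peptide/precursor with a family label."""

    id: str
    sequence: str
    family: str = "unknown"
    taxon: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"reference peptide {self.id!r} has empty sequence")
        bad = set(self.sequence) - PROTEIN_LETTERS
        if bad:
            raise AlphabetError(
                f"reference peptide {self.id!r} has invalid residues {sorted(bad)}"
            )
        if self.family != "unknown" and self.family not in FAMILIES:
            raise ValueError(f"unknown family label {self.family!r}")


@dataclass(frozen=True)
class Transcript:
    """A nucleotide contig/isotig/singleton from the transcriptome."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r} has empty sequence")
        bad = set(self.sequence) - NUCLEOTIDE_LETTERS
        if bad:
            raise AlphabetError(
                f"transcript {self.id!r} has invalid characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class FastaRecord:
    id: str
    sequence: str
    description: str = ""


def read_fasta(path: str | Path, alphabet: str = "protein",
               strict: bool = True) -> list[FastaRecord]:
    """Read a FASTA file, uppercase the sequences and validate the alphabet.

    Parameters
    ----------
    alphabet : {"protein", "nucleotide"}
    strict : raise :class:`AlphabetError` on out-of-alphabet characters;
        when False, offending records are kept as-is.
    """
    if alphabet == "protein":
        letters = PROTEIN_LETTERS
    elif alphabet == "nucleotide":
        letters = NUCLEOTIDE_LETTERS
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    path = Path(path)
    records: list[FastaRecord] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise FastaParseError(f"{path}: record {i} has an empty id")
        if not seq:
            raise FastaParseError(
                f"{path}: record {i} ({rec.id!r}) has an empty sequence"
            )
        if strict:
            bad = set(seq) - letters
            if bad:
                raise AlphabetError(
                    f"{path}: record {rec.id!r} has characters {sorted(bad)} "
                    f"outside the {alphabet} alphabet"
                )
        # rec.description starts with the id; keep only the free-text part
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(FastaRecord(id=rec.id, sequence=seq, description=desc))
    if not records and path.stat().st_size > 0:
        raise FastaParseError(f"{path}: no FASTA records found (line 1)")
    return records


def write_fasta(records: Iterable, path: str | Path, width: int = 60) -> None:
    """Write records (anything with .id/.sequence) line-wrapped at 60 columns."""
    seqrecs = []
    for r in records:
        desc = getattr(r, "description", "") or ""
        seqrecs.append(SeqRecord(Seq(r.sequence), id=r.id, description=desc))
    writer_width = width
    with open(path, "w") as fh:
        for rec in seqrecs:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            s = str(rec.seq)
            for j in range(0, len(s), writer_width):
                fh.write(s[j:j + writer_width] + "\n")


DEFAULT_EXCLUDE = ("receptor", "signal anchor", "transmembrane")


def filter_reference(records: Sequence, include: Sequence[str],
                     exclude: Sequence[str] = DEFAULT_EXCLUDE) -> list:
    """Keyword screen of reference records by description.

    A record is kept when its description contains at least one *include*
    keyword and none of the *exclude* keywords (case-insensitive substring
    match), mirroring the neuropeptide/hormone/peptide harvest that built the
    local reference database.  Order is preserved.
    """
    if not include:
        raise ValueError("include keyword list must be non-empty")
    inc = [k.lower() for k in include]
    exc = [k.lower() for k in exclude]
    kept = []
    for r in records:
        desc = (getattr(r, "description", "") or "").lower()
        if any(k in desc for k in inc) and not any(k in desc for k in exc):
            kept.append(r)
    return kept


REPORT_COLUMNS = (
    "precursor_id", "peptide_index", "start", "end", "sequence",
    "amidated", "pyroglu", "sulfated_positions", "family",
)


def _peptide_rows(annotations: Sequence) -> list[dict]:
    rows = []
    for ap in annotations:
        pid = ap.candidate.transcript_id
        for i, pep in enumerate(ap.peptides, start=1):
            rows.append({
                "precursor_id": pid,
                "peptide_index": i,
                "start": pep.start,
                "end": pep.end,
                "sequence": pep.sequence,
                "amidated": pep.amidated,
                "pyroglu": pep.pyroglu,
                "sulfated_positions": ",".join(map(str, pep.sulfated_positions)),
                "family": pep.family,
            })
    return rows


def write_report(annotations: Sequence, path: str | Path,
                 format: str = "tsv") -> None:
    """Write one row per mature peptide (TSV) or a lossless JSON mirror."""
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(REPORT_COLUMNS) + "\n")
            for row in _peptide_rows(annotations):
                fh.write("\t".join(str(row[c]) for c in REPORT_COLUMNS) + "\n")
    elif format == "json":
        payload = [dataclasses.asdict(ap) for ap in annotations]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report_json(path: str | Path) -> list:
    """Read a JSON report back into the annotation object graph."""
    from . import annotate as _ann  # local import to avoid a cycle

    with open(path) as fh:
        payload = json.load(fh)
    return [_ann.annotated_precursor_from_dict(d) for d in payload]
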