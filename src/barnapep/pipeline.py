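"""Discovery pipeline: mine -> ORF -> annotate -> screen -> report.

`run_discovery` composes the stages in order and returns the annotated
precursors that pass the three-criterion screen (a flag keeps failures),
plus a RunManifest capturing the config, input digests, seed and per-stage
record counts, so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .annotate import AnnotatedPrecursor, annotate_precursor, find_orf
from .config import PipelineConfig
from .io import Transcript
from .mining import AlignmentHit, mine_transcriptome

log = logging.getLogger("barnapep")


@dataclass
class RunManifest:
    config: dict
    seed: int
    input_digests: dict[str, str]
    stage_counts: dict[str, int]
    version: str = __version__

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _digest(items: Sequence[str]) -> str:
    h = hashlib.sha256()
    for s in items:
        h.update(s.encode())
        h.update(b"\0")
    return h.hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, record: str, cause: Exception):
        super().__init__(f"stage {stage!r}, record {record!r}: {cause}")
        self.stage = stage
        self.record = record


def run_discovery(transcripts: Sequence[Transcript], references: Sequence,
                  cfg: PipelineConfig | None = None, patterns=None,
                  keep_failures: bool = False,
                  allow: Sequence[str] | None = None,
                  deny: Sequence[str] | None = None,
                  ) -> tuple[list[AnnotatedPrecursor], RunManifest]:
    """Run the full in-silico discovery: translated homology mining, ORF
    extraction, precursor annotation and screening.

    The reported family of each precursor is that of its best supporting
    reference query (homology assignment, as in manual BLAST curation);
    individual peptides additionally carry motif-based family labels.
    ``allow``/``deny`` are optional transcript-id lists standing in for
    manual curation; by default everything is automatic.
    """
    if cfg is None:
        cfg = PipelineConfig()
    counts: dict[str, int] = {
        "transcripts": len(transcripts), "queries": len(references),
    }
    annotated: list[AnnotatedPrecursor] = []
    manifest = RunManifest(
        config=cfg.to_dict(), seed=cfg.seed,
        input_digests={
            "transcripts": _digest([t.id + t.sequence for t in transcripts]),
            "references": _digest([r.id + r.sequence for r in references]),
        },
        stage_counts=counts,
    )
    if not transcripts or not references:
        counts.update(hits=0, candidate_transcripts=0, candidates=0,
                      screened=0, reported=0)
        return annotated, manifest

    results = mine_transcriptome(references, transcripts, cfg)
    counts["hits"] = sum(len(h) for h in results.values())

    by_transcript: dict[str, list[AlignmentHit]] = {}
    for qid, hits in results.items():
        for h in hits:
            by_transcript.setdefault(h.transcript_id, []).append(h)
    for tid in by_transcript:
        by_transcript[tid].sort(key=lambda h: (h.e_value, -h.raw_score))
    if allow is not None:
        by_transcript = {t: h for t, h in by_transcript.items() if t in allow}
    if deny:
        by_transcript = {t: h for t, h in by_transcript.items()
                         if t not in set(deny)}
    counts["candidate_transcripts"] = len(by_transcript)

    tmap = {t.id: t for t in transcripts}
    families = {r.id: getattr(r, "family", "unknown") for r in references}
    n_candidates = n_screened = 0
    for tid in sorted(by_transcript):
        hits = by_transcript[tid]
        best = hits[0]
        try:
            cand = find_orf(best, tmap[tid])
        except Exception as exc:
            raise PipelineError("find_orf", tid, exc) from exc
        cand = dataclasses.replace(
            cand, supporting_hits=tuple(h.query_id for h in hits))
        n_candidates += 1
        try:
            ap = annotate_precursor(cand, cfg, patterns)
        except Exception as exc:
            raise PipelineError("annotate", tid, exc) from exc
        if ap.screen.passed:
            n_screened += 1
        if ap.screen.passed or keep_failures:
            annotated.append(ap)
    counts["candidates"] = n_candidates
    counts["screened"] = n_screened
    counts["reported"] = len(annotated)
    for stage, n in counts.items():
        log.info("stage %s: %d records", stage, n)
    return annotated, manifest


def assigned_family(ap: AnnotatedPrecursor, references: Sequence) -> str:
    """Family of the precursor's best supporting reference query."""
    fams = {r.id: getattr(r, "family", "unknown") for r in references}
    if not ap.candidate.supporting_hits:
        return "unknown"
    return fams.get(ap.candidate.supporting_hits[0], "unknown")
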