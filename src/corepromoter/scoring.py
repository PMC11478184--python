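"""Raw and normalized promoter scores for windows and sub-segments.

A segment score is the sum of PSSM log-odds values over a consecutive
stretch of TSS-relative positions; the promoter score is that raw score
divided by the raw score of the reference promoter (pTDH3 by default) on
the same segment.  The reference promoter therefore always scores
exactly 1 after normalization, and negative raw log-odds scores keep
their sign through normalization — no clamping.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ScoringMatrix, encode_sequences
from .seqio import DEFAULT_REFERENCE_ID, PromoterRecord, PromoterSet

logger = logging.getLogger(__name__)


class ScoringError(ValueError):
    """Raised for invalid segments or non-scorable matrices."""


@dataclass(frozen=True)
class Segment:
    """Consecutive, inclusive TSS-relative sub-range of the window."""

    from_pos: int
    to_pos: int

    def __post_init__(self) -> None:
        if self.from_pos > self.to_pos:
            raise ScoringError(
                f"segment start {self.from_pos} exceeds end {self.to_pos}"
            )

    def __len__(self) -> int:
        return self.to_pos - self.from_pos + 1


@dataclass(frozen=True)
class ScoreResult:
    id: str
    segment: Segment
    raw_score: float
    normalized_score: float


def _segment_slice(pssm: ScoringMatrix, segment: Segment) -> slice:
    w = pssm.window
    if not (w.start <= segment.from_pos and segment.to_pos <= w.end):
        raise ScoringError(
            f"segment [{segment.from_pos}, {segment.to_pos}] outside "
            f"window [{w.start}, {w.end}]"
        )
    return slice(w.index(segment.from_pos), w.index(segment.to_pos) + 1)


def segment_score(
    pssm: ScoringMatrix, record: PromoterRecord, segment: Segment | None = None
) -> float:
    """Sum of per-position log-odds over the segment (bits).

    The sequence must span the full PSSM window; the segment defaults to
    the whole window.  Hitting a −inf cell (a zero-probability base under
    pseudocount 0) is an error rather than a silent −inf score.
    """
    w = pssm.window
    segment = segment or Segment(w.start, w.end)
    if len(record.sequence) != len(w):
        raise ScoringError(
            f"record {record.id!r}: length {len(record.sequence)} != "
            f"window length {len(w)}"
        )
    sl = _segment_slice(pssm, segment)
    cols = np.array(["ACGT".index(b) for b in record.sequence[sl]])
    vals = pssm.values[sl][np.arange(len(cols)), cols]
    if np.isneginf(vals).any():
        pos = int(np.where(np.isneginf(vals))[0][0]) + segment.from_pos
        raise ScoringError(
            f"record {record.id!r}: base at position {pos} has zero "
            "probability in the matrix (score undefined); rebuild the "
            "matrix with a pseudocount > 0"
        )
    return float(vals.sum())


def score_set(
    pssm: ScoringMatrix,
    promoters: PromoterSet,
    segment: Segment | None = None,
    reference_id: str = DEFAULT_REFERENCE_ID,
) -> list[ScoreResult]:
    """Score every promoter and normalize by the reference's raw score.

    Normalization uses the reference promoter's score on the *same*
    segment being analyzed, so endpoint scans stay internally
    consistent.  The reference is found by id rather than by taking the
    maximum each run, so adding promoters cannot silently change the
    normalizer; a warning is emitted if another promoter outscores it.
    """
    w = pssm.window
    segment = segment or Segment(w.start, w.end)
    if reference_id not in promoters:
        raise ScoringError(f"reference promoter {reference_id!r} not in set")
    sl = _segment_slice(pssm, segment)
    codes = encode_sequences(promoters)[:, sl]
    vals = pssm.values[sl, :][np.arange(codes.shape[1]), codes]
    if np.isneginf(vals).any():
        bad = promoters.records[int(np.where(np.isneginf(vals).any(axis=1))[0][0])]
        raise ScoringError(
            f"record {bad.id!r} hits a zero-probability matrix cell; "
            "rebuild the matrix with a pseudocount > 0"
        )
    raw = vals.sum(axis=1)
    ref_idx = promoters.ids.index(reference_id)
    ref_raw = float(raw[ref_idx])
    if ref_raw == 0.0:
        raise ScoringError(
            f"reference {reference_id!r} has raw score 0 on segment "
            f"[{segment.from_pos}, {segment.to_pos}]; normalization undefined"
        )
    if (raw > ref_raw).any():
        n_above = int((raw > ref_raw).sum())
        logger.warning(
            "%d promoter(s) outscore the reference %r on segment [%d, %d]",
            n_above, reference_id, segment.from_pos, segment.to_pos,
        )
    return [
        ScoreResult(
            id=rec.id,
            segment=segment,
            raw_score=float(r),
            normalized_score=float(r / ref_raw),
        )
        for rec, r in zip(promoters, raw)
    ]


def write_scores(
    results: list[ScoreResult],
    path: str | Path,
    metadata: dict | None = None,
) -> None:
    """Write score TSV (id, segment, raw, normalized) + JSON sidecar."""
    path = Path(path)
    rows = [
        {
            "id": r.id,
            "segment_from": r.segment.from_pos,
            "segment_to": r.segment.to_pos,
            "raw_score": r.raw_score,
            "normalized_score": r.normalized_score,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    if metadata is not None:
        with open(f"{path}.meta.json", "w") as fh:
            json.dump(metadata, fh, indent=2)
            fh.write("\n")
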