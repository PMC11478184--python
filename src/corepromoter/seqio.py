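"""Promoter sequence and strength-table I/O.

Defines the coordinate convention shared by the whole package: the
transcription start site (TSS) sits at position 0, the core-promoter
window runs from ``start`` to ``end`` inclusive at both ends, and the
default window −49..+10 therefore spans exactly 60 bp.  All sub-window
arithmetic elsewhere goes through :meth:`Window.index`.

Sequences come in as plain multi-record FASTA (one fixed-length window
per record, pre-extracted and strand-resolved upstream of this tool).
Reference promoter strengths come in as a tab-separated table carrying
either raw fluorescence fold-over-background values or pre-computed
normalized strengths.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Fixed base order used by every matrix and serialization in the package.
BASES = "ACGT"

#: Identifier of the default normalizing promoter (the strongest
#: constitutive promoter in the reference set).
DEFAULT_REFERENCE_ID = "pTDH3"


class SeqIOError(ValueError):
    """Raised for malformed sequence or strength inputs."""


@dataclass(frozen=True)
class Window:
    """Inclusive TSS-relative coordinate window.

    The TSS occupies position 0; ``start`` is usually negative
    (upstream) and ``end`` non-negative (downstream).
    """

    start: int = -49
    end: int = 10

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise SeqIOError(
                f"window start {self.start} must not exceed end {self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def length(self) -> int:
        return len(self)

    def index(self, position: int) -> int:
        """Map a TSS-relative position to a 0-based array index."""
        if not self.start <= position <= self.end:
            raise SeqIOError(
                f"position {position} outside window [{self.start}, {self.end}]"
            )
        return position - self.start

    def position(self, index: int) -> int:
        """Inverse of :meth:`index`."""
        if not 0 <= index < len(self):
            raise SeqIOError(f"index {index} outside window of length {len(self)}")
        return index + self.start

    def positions(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class PromoterRecord:
    """One fixed-window promoter sequence, uppercase A/C/G/T only."""

    id: str
    sequence: str


@dataclass
class PromoterSet:
    """An ordered set of equal-length promoter windows aligned at the TSS."""

    window: Window
    records: list[PromoterRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise SeqIOError(f"duplicate promoter id {rec.id!r}")
            seen.add(rec.id)
            _validate_sequence(rec.id, rec.sequence, self.window)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PromoterRecord]:
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def get(self, promoter_id: str) -> PromoterRecord:
        for rec in self.records:
            if rec.id == promoter_id:
                return rec
        raise KeyError(f"promoter {promoter_id!r} not in set")

    def __contains__(self, promoter_id: str) -> bool:
        return any(rec.id == promoter_id for rec in self.records)

    def subset(self, ids: Iterable[str]) -> "PromoterSet":
        """New set restricted to ``ids``, in the order given."""
        return PromoterSet(self.window, [self.get(i) for i in ids])


def _validate_sequence(rec_id: str, sequence: str, window: Window) -> None:
    if len(sequence) != len(window):
        raise SeqIOError(
            f"record {rec_id!r}: length {len(sequence)} != window length {len(window)}"
        )
    bad = set(sequence) - set(BASES)
    if bad:
        raise SeqIOError(
            f"record {rec_id!r}: non-ACGT characters {sorted(bad)!r}"
        )


def read_promoter_fasta(
    path: str | Path,
    window: Window | None = None,
    on_invalid: Literal["reject", "skip"] = "reject",
) -> PromoterSet:
    """Read a FASTA of fixed-length promoter windows.

    The record id is the first whitespace-delimited token of the header
    (robust across EPDnew FASTA export dialects); the rest of the header
    is ignored.  Lowercase bases are uppercased silently.  Records whose
    length does not match the window, or that contain characters outside
    A/C/G/T (including IUPAC ambiguity codes), are errors under
    ``on_invalid='reject'`` and are dropped — with a logged count —
    under ``on_invalid='skip'``.
    """
    window = window or Window()
    if on_invalid not in ("reject", "skip"):
        raise SeqIOError(f"unknown on_invalid policy {on_invalid!r}")
    path = Path(path)
    records: list[PromoterRecord] = []
    n_skipped = 0
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except OSError as exc:
        raise SeqIOError(f"cannot read FASTA {path}: {exc}") from exc
    for rec in parsed:
        seq = str(rec.seq).upper()
        try:
            _validate_sequence(rec.id, seq, window)
        except SeqIOError:
            if on_invalid == "reject":
                raise
            n_skipped += 1
            continue
        records.append(PromoterRecord(id=rec.id, sequence=seq))
    if n_skipped:
        logger.warning(
            "%s: skipped %d invalid record(s), kept %d", path, n_skipped, len(records)
        )
    if not records:
        raise SeqIOError(f"{path}: empty promoter set after validation")
    pset = PromoterSet(window, records)
    pset.n_skipped = n_skipped  # type: ignore[attr-defined]
    return pset


def write_promoter_fasta(promoters: PromoterSet, path: str | Path) -> None:
    """Write a PromoterSet back to FASTA (round-trips exactly)."""
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="")
        for rec in promoters
    ]
    SeqIO.write(seq_records, str(path), "fasta")


@dataclass(frozen=True)
class StrengthRecord:
    """One measured promoter: either a raw fluorescence fold-over-background
    value, a pre-computed normalized strength, or both."""

    id: str
    channel: str
    fold_over_background: float | None = None
    strength: float | None = None

    def __post_init__(self) -> None:
        if self.fold_over_background is None and self.strength is None:
            raise SeqIOError(
                f"record {self.id!r}: needs fold_over_background or strength"
            )
        if self.fold_over_background is not None and not (
            self.fold_over_background > 0
        ):
            raise SeqIOError(
                f"record {self.id!r}: fold_over_background must be > 0 "
                f"(log undefined), got {self.fold_over_background}"
            )


@dataclass
class StrengthTable:
    """Reference strengths for a labeled promoter subset, per channel."""

    reference_id: str = DEFAULT_REFERENCE_ID
    records: list[StrengthRecord] = field(default_factory=list)

    @property
    def channels(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.channel not in out:
                out.append(rec.channel)
        return out

    def channel_records(self, channel: str) -> list[StrengthRecord]:
        recs = [r for r in self.records if r.channel == channel]
        if not recs:
            raise SeqIOError(f"channel {channel!r} not present in strength table")
        return recs

    @property
    def ids(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.id not in out:
                out.append(rec.id)
        return out


def read_strength_table(
    path: str | Path, reference_id: str = DEFAULT_REFERENCE_ID
) -> StrengthTable:
    """Read a tab-separated strength table.

    Requires a header with columns ``id``, ``channel`` and at least one
    of ``fold_over_background`` / ``strength``; lines beginning with
    '#' are comments.  Numeric parsing is strict: a non-numeric or
    non-positive fold value is an error, not a NaN.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except OSError as exc:
        raise SeqIOError(f"cannot read strength table {path}: {exc}") from exc
    required = {"id", "channel"}
    missing = required - set(df.columns)
    if missing:
        raise SeqIOError(f"{path}: missing required column(s) {sorted(missing)}")
    has_fold = "fold_over_background" in df.columns
    has_strength = "strength" in df.columns
    if not has_fold and not has_strength:
        raise SeqIOError(
            f"{path}: needs a fold_over_background or a strength column"
        )
    records: list[StrengthRecord] = []
    for row in df.itertuples(index=False):
        fold = _parse_number(getattr(row, "fold_over_background", None), path, "fold")
        strength = _parse_number(getattr(row, "strength", None), path, "strength")
        records.append(
            StrengthRecord(
                id=str(row.id),
                channel=str(row.channel),
                fold_over_background=fold,
                strength=strength,
            )
        )
    if not records:
        raise SeqIOError(f"{path}: empty strength table")
    return StrengthTable(reference_id=reference_id, records=records)


def _parse_number(raw: object, path: Path, what: str) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if not text or text.upper() in ("NA", "NAN"):
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise SeqIOError(f"{path}: bad {what} value {text!r}") from exc


def write_strength_table(table: StrengthTable, path: str | Path) -> None:
    rows = []
    for rec in table.records:
        rows.append(
            {
                "id": rec.id,
                "channel": rec.channel,
                "fold_over_background": rec.fold_over_background,
                "strength": rec.strength,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
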