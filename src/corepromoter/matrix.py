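"""Position matrices over the TSS-aligned promoter window.

From an aligned set of equal-length sequences we tally a position
frequency matrix (PFM: per-position base counts), convert it to a
position probability matrix (PPM, optionally pseudocounted) and then to
a log-odds position-specific scoring matrix (PSSM) against a background
base distribution.  Scores are in bits (log base 2).  Per-position
information content, IC(p) = 2 + sum_b p_b log2 p_b, summarizes
conservation the way a sequence logo does.

The base order is fixed as A,C,G,T in memory and in every serialization
so matrix files are bit-comparable between runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import BASES, PromoterSet, Window

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Uniform background: the conventional null for log-odds promoter scoring.
UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


class MatrixError(ValueError):
    """Raised for invalid matrix construction or use."""


@dataclass
class PositionFrequencyMatrix:
    """Per-position base counts from an aligned promoter set.

    ``counts`` has shape (L, 4) in A,C,G,T order; every column (position)
    sums to ``n_sequences``.
    """

    window: Window
    counts: np.ndarray
    n_sequences: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.window), 4):
            raise MatrixError(
                f"counts shape {self.counts.shape} != ({len(self.window)}, 4)"
            )
        if (self.counts < 0).any():
            raise MatrixError("negative counts")
        sums = self.counts.sum(axis=1)
        if not (sums == self.n_sequences).all():
            raise MatrixError("every position must sum to n_sequences")


@dataclass
class PositionProbabilityMatrix:
    """Per-position base probabilities; each row sums to 1."""

    window: Window
    probs: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.window), 4):
            raise MatrixError(
                f"probs shape {self.probs.shape} != ({len(self.window)}, 4)"
            )
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise MatrixError("each position's probabilities must sum to 1")


@dataclass
class ScoringMatrix:
    """Log-odds (bits) of per-position probabilities against a background.

    Cells with zero probability (possible at pseudocount 0) are −inf and
    ``has_neg_inf`` is set so that scoring a query through such a cell
    can raise a clear error instead of silently returning −inf.
    """

    window: Window
    values: np.ndarray
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND
    has_neg_inf: bool = field(default=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.window), 4):
            raise MatrixError(
                f"values shape {self.values.shape} != ({len(self.window)}, 4)"
            )
        self.has_neg_inf = bool(np.isneginf(self.values).any())

    def value(self, position: int, base: str) -> float:
        """Log-odds at a TSS-relative position for a base."""
        return float(self.values[self.window.index(position), _BASE_INDEX[base]])


def encode_sequences(promoters: PromoterSet) -> np.ndarray:
    """(n, L) integer matrix of base indices in A,C,G,T order."""
    lut = np.full(128, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        lut[ord(base)] = idx
    rows = [
        lut[np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8)]
        for rec in promoters
    ]
    return np.asarray(rows, dtype=np.int64)


def build_pfm(promoters: PromoterSet) -> PositionFrequencyMatrix:
    """Tally exact per-position base counts across the set."""
    if len(promoters) == 0:
        raise MatrixError("cannot build a PFM from an empty promoter set")
    codes = encode_sequences(promoters)
    L = len(promoters.window)
    counts = np.zeros((L, 4), dtype=np.int64)
    for b in range(4):
        counts[:, b] = (codes == b).sum(axis=0)
    return PositionFrequencyMatrix(
        window=promoters.window, counts=counts, n_sequences=len(promoters)
    )


def pfm_to_ppm(
    pfm: PositionFrequencyMatrix, pseudocount: float = 0.0
) -> PositionProbabilityMatrix:
    """prob(p, b) = (count(p, b) + k) / (n + 4k) with pseudocount k >= 0."""
    if pseudocount < 0:
        raise MatrixError(f"pseudocount must be >= 0, got {pseudocount}")
    denom = pfm.n_sequences + 4.0 * pseudocount
    probs = (pfm.counts + pseudocount) / denom
    return PositionProbabilityMatrix(
        window=pfm.window, probs=probs, pseudocount=float(pseudocount)
    )


def ppm_to_pssm(
    ppm: PositionProbabilityMatrix,
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND,
) -> ScoringMatrix:
    """Log2-odds of each probability against the background base frequency."""
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any() or not np.isclose(bg.sum(), 1.0):
        raise MatrixError(
            f"background must be 4 strictly positive values summing to 1, got {background}"
        )
    with np.errstate(divide="ignore"):
        values = np.log2(ppm.probs / bg)
    return ScoringMatrix(
        window=ppm.window, values=values, background=tuple(float(x) for x in bg)
    )


def information_content(ppm: PositionProbabilityMatrix) -> np.ndarray:
    """Per-position information content in bits, in [0, 2].

    IC(p) = 2 + sum_b prob(p,b) * log2(prob(p,b)), with 0*log2(0) := 0.
    2 bits means a fully conserved position, 0 a uniform one.
    """
    p = ppm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    ic = 2.0 + terms.sum(axis=1)
    return np.clip(ic, 0.0, 2.0)


# ---------------------------------------------------------------------------
# Serialization: TSV body (position, A, C, G, T) + JSON sidecar with
# window, pseudocount, background and n_sequences so results are traceable.

def _matrix_frame(window: Window, body: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(body, columns=list(BASES))
    df.insert(0, "position", list(window.positions()))
    return df


def write_matrix(
    mat: PositionFrequencyMatrix | PositionProbabilityMatrix | ScoringMatrix,
    path: str | Path,
) -> None:
    """Write matrix TSV plus a ``<path>.meta.json`` sidecar."""
    path = Path(path)
    meta: dict[str, object] = {
        "window": {"start": mat.window.start, "end": mat.window.end},
        "base_order": BASES,
    }
    if isinstance(mat, PositionFrequencyMatrix):
        body, kind = mat.counts, "pfm"
        meta["n_sequences"] = mat.n_sequences
    elif isinstance(mat, PositionProbabilityMatrix):
        body, kind = mat.probs, "ppm"
        meta["pseudocount"] = mat.pseudocount
    elif isinstance(mat, ScoringMatrix):
        body, kind = mat.values, "pssm"
        meta["background"] = list(mat.background)
        meta["has_neg_inf"] = mat.has_neg_inf
    else:  # pragma: no cover - type guard
        raise MatrixError(f"cannot serialize {type(mat).__name__}")
    meta["kind"] = kind
    _matrix_frame(mat.window, body).to_csv(path, sep="\t", index=False)
    with open(f"{path}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")


def read_scoring_matrix(path: str | Path) -> ScoringMatrix:
    """Read a PSSM TSV written by :func:`write_matrix`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("position", *BASES):
        if col not in df.columns:
            raise MatrixError(f"{path}: missing column {col!r}")
    positions = df["position"].to_numpy()
    window = Window(int(positions[0]), int(positions[-1]))
    if not (positions == np.asarray(list(window.positions()))).all():
        raise MatrixError(f"{path}: positions are not contiguous")
    values = df[list(BASES)].to_numpy(dtype=float)
    background = UNIFORM_BACKGROUND
    meta_path = Path(f"{path}.meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        if "background" in meta:
            background = tuple(meta["background"])
    return ScoringMatrix(window=window, values=values, background=background)
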