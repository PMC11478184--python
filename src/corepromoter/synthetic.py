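"""Synthetic promoter sets and strength tables with known ground truth.

Sequences are drawn i.i.d. per position from a base-composition
distribution (default mildly AT-rich, as yeast promoter regions are),
with optional conserved columns where a named base is drawn at a stated
conservation level and the remaining mass is split evenly over the other
three bases.  Strengths realize the linear model generatively:

    strength_i = true_C0 + true_C1 * normalized_score_i + eps_i,
    eps ~ Normal(0, noise_sd²).

A single seed drives two independent sub-streams (one for sequences,
one for noise), so regenerating sequences never perturbs noise draws.
Defaults mirror the shape of the reference study — a large background
population of promoter windows with a small labeled subset of 18 — at
desk scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .matrix import ScoringMatrix
from .scoring import Segment, score_set
from .seqio import (
    BASES,
    PromoterRecord,
    PromoterSet,
    StrengthRecord,
    StrengthTable,
    Window,
)


class SyntheticError(ValueError):
    """Raised for invalid generator specifications."""


@dataclass
class SyntheticSpec:
    """Everything needed to generate a reproducible synthetic study.

    ``conserved_positions`` entries are (TSS-relative position, base,
    conservation level); a level of 1.0 fixes the base, and levels below
    0.25 would be *anti*-conserved relative to a uniform background and
    are rejected.
    """

    n_sequences: int = 2000
    window: Window = field(default_factory=Window)
    base_composition: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    conserved_positions: list[tuple[int, str, float]] = field(default_factory=list)
    true_C0: float = 0.025
    true_C1: float = 0.87
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or (comp < 0).any() or not np.isclose(comp.sum(), 1.0):
            raise SyntheticError(
                f"base_composition must be 4 non-negative values summing to 1, "
                f"got {self.base_composition}"
            )
        for pos, base, level in self.conserved_positions:
            if base not in BASES:
                raise SyntheticError(f"conserved base {base!r} not in {BASES}")
            if not 0.25 < level <= 1.0:
                raise SyntheticError(
                    f"conservation level {level} at {pos} must be in (0.25, 1]"
                )
            self.window.index(pos)  # raises if outside the window
        if self.noise_sd < 0:
            raise SyntheticError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_sequences <= 0:
            raise SyntheticError("n_sequences must be positive")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_sequences": self.n_sequences,
            "window": {"start": self.window.start, "end": self.window.end},
            "base_composition": list(self.base_composition),
            "conserved_positions": [
                [p, b, l] for p, b, l in self.conserved_positions
            ],
            "true_C0": self.true_C0,
            "true_C1": self.true_C1,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    # Independent sub-streams keyed on (seed, stream id).
    return np.random.default_rng([spec.seed, stream])


def generate_promoter_set(
    spec: SyntheticSpec, id_prefix: str = "syn"
) -> PromoterSet:
    """Draw ``n_sequences`` windows from the per-position base model."""
    L = len(spec.window)
    probs = np.tile(np.asarray(spec.base_composition, dtype=float), (L, 1))
    for pos, base, level in spec.conserved_positions:
        col = np.full(4, (1.0 - level) / 3.0)
        col[BASES.index(base)] = level
        probs[spec.window.index(pos)] = col
    rng = _rng(spec, 0)
    # Per-position inverse-CDF sampling, vectorized over sequences.
    cum = probs.cumsum(axis=1)
    u = rng.random((spec.n_sequences, L))
    codes = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
    base_arr = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)
    records = [
        PromoterRecord(
            id=f"{id_prefix}{i:05d}",
            sequence=base_arr[row].tobytes().decode("ascii"),
        )
        for i, row in enumerate(codes)
    ]
    return PromoterSet(spec.window, records)


def generate_strengths(
    promoters: PromoterSet,
    pssm: ScoringMatrix,
    spec: SyntheticSpec,
    reference_id: str,
    segment: Segment | None = None,
    channel: str = "synthetic",
    as_fold: bool = False,
    reference_log_fold: float = 4.0,
) -> StrengthTable:
    """Strength table realizing the linear model on normalized scores.

    Scores are computed on ``segment`` (default: the full window) and
    normalized by the reference promoter, then
    strength = true_C0 + true_C1 * score + Normal(0, noise_sd²) noise.
    With ``as_fold`` the table instead carries
    fold = exp(strength * reference_log_fold), the fluorescence-style
    encoding that the log/normalize pipeline maps back to the same
    strengths.
    """
    results = score_set(pssm, promoters, segment=segment, reference_id=reference_id)
    rng = _rng(spec, 1)
    noise = rng.normal(0.0, spec.noise_sd, size=len(results))
    records = []
    for r, eps in zip(results, noise):
        strength = spec.true_C0 + spec.true_C1 * r.normalized_score + float(eps)
        if as_fold:
            records.append(
                StrengthRecord(
                    id=r.id,
                    channel=channel,
                    fold_over_background=float(np.exp(strength * reference_log_fold)),
                )
            )
        else:
            records.append(
                StrengthRecord(id=r.id, channel=channel, strength=strength)
            )
    return StrengthTable(reference_id=reference_id, records=records)


def pick_reference(pssm: ScoringMatrix, promoters: PromoterSet) -> str:
    """Id of the top-scoring promoter on the full window.

    In the real data the normalizer (pTDH3) is also the highest scorer;
    synthetic studies use this helper so that normalized scores land in
    (−inf, 1] the same way.
    """
    from .matrix import encode_sequences

    codes = encode_sequences(promoters)
    vals = pssm.values[np.arange(codes.shape[1]), codes]
    return promoters.ids[int(vals.sum(axis=1).argmax())]
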