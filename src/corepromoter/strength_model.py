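"""The linear score→strength model and everything built on it.

Promoter strength is defined as the natural log of reporter fluorescence
fold-over-background, normalized by the same quantity for the reference
promoter (pTDH3), so the reference has strength 1 by construction.
Strength is then modeled as a linear function of the normalized PSSM
promoter score,

    strength = C0 + C1 * score,

fit by ordinary least squares with full diagnostics (R², adjusted R²,
F-statistic, parameter t-tests, residual table, residual-on-score slope
and normal QQ pairs).  The segment-endpoint scan refits this model on
segments [-49, X] for every X to locate the shortest predictive region;
saturation of fit quality is operationalized with a ΔR² rule.  Fits from
different fluorescence channels or datasets are combined by
inverse-variance weighting.  The published pooled parameters
(C0 = 0.025, C1 = 0.87) drive prediction and a three-way
weak/moderate/strong classification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .matrix import ScoringMatrix
from .scoring import Segment, score_set
from .seqio import DEFAULT_REFERENCE_ID, PromoterSet, StrengthTable

logger = logging.getLogger(__name__)


class ModelError(ValueError):
    """Raised for degenerate designs or invalid model inputs."""


@dataclass
class StrengthVector:
    """Normalized strengths for one fluorescence channel or dataset."""

    channel: str
    entries: list[tuple[str, float]]

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.entries]

    def as_dict(self) -> dict[str, float]:
        return dict(self.entries)


def strengths_from_fold(
    table: StrengthTable, channel: str
) -> StrengthVector:
    """Fluorescence fold-over-background → normalized strength.

    strength_i = ln(fold_i) / ln(fold_ref): the natural log of each fold
    value, divided by the natural log of the reference promoter's fold,
    so the reference maps to exactly 1.  Records that carry a
    pre-computed ``strength`` instead of a fold value are taken as-is.
    """
    recs = table.channel_records(channel)
    folds = {r.id: r.fold_over_background for r in recs}
    pre = {r.id: r.strength for r in recs}
    if all(f is None for f in folds.values()):
        # Pre-normalized input: pass strengths straight through.
        entries = [(r.id, float(r.strength)) for r in recs if r.strength is not None]
        if not entries:
            raise ModelError(f"channel {channel!r} has neither folds nor strengths")
        return StrengthVector(channel=channel, entries=entries)
    ref_fold = folds.get(table.reference_id)
    if ref_fold is None:
        raise ModelError(
            f"reference {table.reference_id!r} missing from channel {channel!r}"
        )
    if ref_fold <= 1.0:
        raise ModelError(
            f"reference fold {ref_fold} <= 1: ln(fold_ref) is not a "
            "positive normalizer"
        )
    log_ref = math.log(ref_fold)
    entries = []
    for r in recs:
        if folds[r.id] is not None:
            entries.append((r.id, math.log(folds[r.id]) / log_ref))
        elif pre[r.id] is not None:
            entries.append((r.id, float(pre[r.id])))
    return StrengthVector(channel=channel, entries=entries)


@dataclass
class LinearFit:
    """Simple-OLS fit of strength on score, with diagnostics.

    For a perfect (zero-residual-variance) fit the standard errors,
    t-statistics and their p-values are reported as NaN rather than
    infinities, and ``perfect`` is set.
    """

    C0: float
    C1: float
    se_C0: float
    se_C1: float
    t_C0: float
    t_C1: float
    p_C0: float
    p_C1: float
    r2: float
    adj_r2: float
    F: float
    p_F: float
    n: int
    residuals: list[tuple[str, float]] = field(default_factory=list)
    residual_slope: float = 0.0
    qq: list[tuple[float, float]] = field(default_factory=list)
    perfect: bool = False

    def to_dict(self) -> dict:
        return {
            "C0": self.C0, "C1": self.C1,
            "se_C0": self.se_C0, "se_C1": self.se_C1,
            "t_C0": self.t_C0, "t_C1": self.t_C1,
            "p_C0": self.p_C0, "p_C1": self.p_C1,
            "r2": self.r2, "adj_r2": self.adj_r2,
            "F": self.F, "p_F": self.p_F,
            "n": self.n, "residual_slope": self.residual_slope,
            "perfect": self.perfect,
        }


def fit_linear(
    scores: list[tuple[str, float]], strengths: StrengthVector
) -> LinearFit:
    """OLS fit of strength = C0 + C1 * score on id-matched pairs.

    Requires at least 3 matched pairs and non-zero score variance.
    Inference follows the usual simple-regression t and F distributions
    with n − 2 degrees of freedom; QQ pairs use plotting positions
    (i − 0.5)/n against standard-normal quantiles.
    """
    strength_map = strengths.as_dict()
    matched = [(i, s) for i, s in scores if i in strength_map]
    if len(matched) < 3:
        raise ModelError(
            f"need >= 3 id-matched (score, strength) pairs, got {len(matched)}"
        )
    ids = [i for i, _ in matched]
    x = np.array([s for _, s in matched], dtype=float)
    y = np.array([strength_map[i] for i in ids], dtype=float)
    if np.ptp(x) == 0.0:
        raise ModelError("all scores identical: degenerate design")

    res = sm.OLS(y, sm.add_constant(x)).fit()
    n = len(x)
    resid = np.asarray(res.resid)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    perfect = ss_res <= 1e-24 * max(ss_tot, 1.0)

    if perfect:
        C0, C1 = float(res.params[0]), float(res.params[1])
        se0 = se1 = t0 = t1 = p0 = p1 = float("nan")
        r2, adj_r2 = 1.0, 1.0
        F, p_F = float("nan"), float("nan")
    else:
        C0, C1 = float(res.params[0]), float(res.params[1])
        se0, se1 = float(res.bse[0]), float(res.bse[1])
        t0, t1 = float(res.tvalues[0]), float(res.tvalues[1])
        p0, p1 = float(res.pvalues[0]), float(res.pvalues[1])
        r2 = float(res.rsquared)
        adj_r2 = float(res.rsquared_adj)
        F = float(res.fvalue)
        p_F = float(res.f_pvalue)

    # Residual-on-score slope: a second OLS checking for model bias
    # (identically 0 for OLS residuals, reported to make that visible).
    xc = x - x.mean()
    residual_slope = float((xc @ resid) / (xc @ xc))

    order = np.argsort(resid)
    pp = (np.arange(1, n + 1) - 0.5) / n
    theo = stats.norm.ppf(pp)
    qq = [(float(t), float(resid[j])) for t, j in zip(theo, order)]

    return LinearFit(
        C0=C0, C1=C1, se_C0=se0, se_C1=se1, t_C0=t0, t_C1=t1,
        p_C0=p0, p_C1=p1, r2=r2, adj_r2=adj_r2, F=F, p_F=p_F, n=n,
        residuals=list(zip(ids, (float(r) for r in resid))),
        residual_slope=residual_slope, qq=qq, perfect=perfect,
    )


@dataclass
class ScanRow:
    """One endpoint of the [-49, X] scan: X plus the fit (or the error)."""

    X: int
    fit: LinearFit | None
    error: str | None = None


def scan_endpoints(
    pssm: ScoringMatrix,
    promoters: PromoterSet,
    strengths: StrengthVector,
    left: int | None = None,
    reference_id: str = DEFAULT_REFERENCE_ID,
) -> list[ScanRow]:
    """Fit the linear model on segments [left, X] for every endpoint X.

    One end stays fixed at the window start (−49 by default) while the
    other extends one position at a time towards and past the TSS,
    giving window-length − 1 rows.  Per-row fit failures (for instance a
    zero reference score on a short segment) are recorded on the row,
    not raised.
    """
    w = pssm.window
    left = w.start if left is None else left
    if left != w.start:
        raise ModelError(
            f"scan must anchor at the window start {w.start}, got {left}"
        )
    rows: list[ScanRow] = []
    for X in range(left + 1, w.end + 1):
        try:
            results = score_set(
                pssm, promoters, Segment(left, X), reference_id=reference_id
            )
            pairs = [(r.id, r.normalized_score) for r in results]
            fit = fit_linear(pairs, strengths)
            rows.append(ScanRow(X=X, fit=fit))
        except (ModelError, ValueError) as exc:
            rows.append(ScanRow(X=X, fit=None, error=str(exc)))
    return rows


def detect_saturation(rows: list[ScanRow], delta: float = 0.01) -> int:
    """Smallest endpoint X* after which R² never improves by >= delta.

    Returns the smallest X* such that r2(X) − r2(X*) < delta for every
    later endpoint X; if fit quality keeps improving, that is the last
    endpoint.  Rows whose fit failed are ignored.
    """
    usable = [(row.X, row.fit.r2) for row in rows if row.fit is not None]
    if not usable:
        raise ModelError("no successful fits in scan rows")
    for i, (X, r2) in enumerate(usable):
        if all(r2_later - r2 < delta for _, r2_later in usable[i + 1:]):
            return X
    return usable[-1][0]  # pragma: no cover - last row always satisfies


@dataclass(frozen=True)
class PooledParameters:
    C0: float
    C1: float
    se_C0: float
    se_C1: float
    n_fits: int


def pool_parameters(fits: list[LinearFit]) -> PooledParameters:
    """Inverse-variance weighted mean of (C0, C1) across fits.

    C_mean = Σ(C_k / SE_k²) / Σ(1 / SE_k²) per parameter, with pooled
    SE = sqrt(1 / Σ(1 / SE_k²)).  A degenerate perfect fit (SE 0 or NaN)
    cannot be weighted and must be excluded by the caller.
    """
    if not fits:
        raise ModelError("pool_parameters needs at least one fit")
    for k, fit in enumerate(fits):
        for se in (fit.se_C0, fit.se_C1):
            if not np.isfinite(se) or se == 0.0:
                raise ModelError(
                    f"fit {k} has undefined or zero standard error "
                    "(perfect fit?); exclude it before pooling"
                )
    def _pool(vals: list[float], ses: list[float]) -> tuple[float, float]:
        w = np.array([1.0 / se**2 for se in ses])
        v = np.array(vals)
        return float((w * v).sum() / w.sum()), float(math.sqrt(1.0 / w.sum()))
    C0, se_C0 = _pool([f.C0 for f in fits], [f.se_C0 for f in fits])
    C1, se_C1 = _pool([f.C1 for f in fits], [f.se_C1 for f in fits])
    return PooledParameters(C0=C0, C1=C1, se_C0=se_C0, se_C1=se_C1,
                            n_fits=len(fits))


@dataclass(frozen=True)
class PublishedModel:
    """Pooled score→strength parameters from the reference characterization
    of 18 constitutive yeast promoters (inverse-variance mean across
    fluorescence channels)."""

    C0: float = 0.025
    C1: float = 0.87
    provenance: str = (
        "error-weighted mean over Venus/mRuby2/mTurquoise2 fits to 18 "
        "constitutive S. cerevisiae promoters"
    )


def predict_strength(normalized_score: float, model: PublishedModel | PooledParameters | None = None) -> float:
    """strength = C0 + C1 * normalized_score."""
    model = model or PublishedModel()
    if not (np.isfinite(model.C0) and np.isfinite(model.C1)):
        raise ModelError("model parameters must be finite")
    return float(model.C0 + model.C1 * normalized_score)


def tertile_thresholds(strengths: StrengthVector) -> tuple[float, float]:
    """Default weak/moderate/strong boundaries: tertiles of the
    reference strength set in use."""
    vals = np.array([s for _, s in strengths.entries], dtype=float)
    t_low, t_high = np.quantile(vals, [1 / 3, 2 / 3])
    return float(t_low), float(t_high)


def classify_strength(
    predicted_strength: float, thresholds: tuple[float, float]
) -> str:
    """weak if < t_low, moderate if in [t_low, t_high), strong if >= t_high."""
    t_low, t_high = thresholds
    if not t_low < t_high:
        raise ModelError(f"thresholds must satisfy t_low < t_high, got {thresholds}")
    if predicted_strength < t_low:
        return "weak"
    if predicted_strength < t_high:
        return "moderate"
    return "strong"


@dataclass
class Prediction:
    """Full prediction report for one query promoter."""

    id: str
    raw_score: float
    normalized_score: float
    predicted_strength: float
    class_label: str
    reference_context: float  # percentile of the raw score in a background set

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "raw_score": self.raw_score,
            "normalized_score": self.normalized_score,
            "predicted_strength": self.predicted_strength,
            "class": self.class_label,
            "background_percentile": self.reference_context,
        }


def score_percentile(raw_score: float, background_scores: np.ndarray) -> float:
    """Percentile (0..100) of a raw score within a background score
    distribution, by the fraction of background scores <= the query."""
    bg = np.asarray(background_scores, dtype=float)
    if bg.size == 0:
        raise ModelError("empty background score distribution")
    return float(100.0 * (bg <= raw_score).mean())
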