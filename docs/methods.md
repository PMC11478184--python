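# Methods

## Coordinate convention

The transcription start site (TSS) is position 0. The core-promoter
window is inclusive at both ends; the default −49..+10 spans exactly
60 bp, with array index `p − start` (so −49 ↦ 0, 0 ↦ 49, +10 ↦ 59).
Segments are inclusive sub-ranges of the window in the same
coordinates. All inputs are pre-extracted, strand-resolved windows;
the package does no genome-coordinate arithmetic and no network
retrieval.

## Matrix model

For an aligned set of n windows of length L, the position frequency
matrix (PFM) holds exact per-position base counts in fixed A,C,G,T
order. Probabilities are

    prob(p, b) = (count(p, b) + k) / (n + 4k)

with pseudocount k ≥ 0 (default 0: with thousands of sequences, zero
counts are improbable, and the default keeps probabilities equal to
observed frequencies). The scoring matrix is the log-odds in bits
against a background distribution (default uniform 0.25):

    value(p, b) = log2(prob(p, b) / background(b)).

At k = 0 a zero count maps to −∞ and the matrix is flagged; scoring a
query through such a cell raises an error naming the position rather
than returning −∞ silently — the remedy is to rebuild with k > 0.
Per-position conservation is summarized as information content
IC(p) = 2 + Σ_b prob·log2(prob) ∈ [0, 2] bits, the quantity a sequence
logo draws; no logo image is rendered, the numbers are emitted as TSV.
Pseudocount, background and window are recorded in every matrix
sidecar so results are traceable.

## Scores and strengths

A segment score is the sum of per-position log-odds over a consecutive
segment; it is exactly additive over any partition of the segment. The
promoter score divides the raw score by the reference promoter's raw
score **on the same segment** (default reference id pTDH3). The
same-segment choice keeps the endpoint scan internally consistent; the
alternative (normalizing sub-segments by the full-window reference
score) only rescales the regressor and leaves R², F and p-values
unchanged, so the choice matters for reported coefficients, not for
fit quality. The reference is located by id, never re-detected as the
maximum, so adding promoters cannot silently change the normalizer;
a warning is logged if anything outscores it. Negative log-odds scores
propagate with sign through normalization.

Strength is ln(fold-over-background) divided by the same quantity for
the reference, so the reference has strength 1 by construction. The
natural log is the documented transform for un-normalized values; the
base cancels in the ratio. Tables carrying pre-normalized strengths
are accepted as-is so either side of the normalization can be
reproduced. A reference fold ≤ 1 is an error (non-positive
normalizer), as is any fold ≤ 0 (log undefined).

## Linear model and diagnostics

strength = C0 + C1·score is fit by ordinary least squares
(statsmodels) on id-matched pairs, requiring n ≥ 3 and non-zero score
variance. Reported diagnostics: coefficient standard errors,
t-statistics and two-sided p-values (n − 2 df), R², adjusted R², the
F-statistic with its p-value, the residual table, the slope of a
second OLS of residuals on scores (identically 0 up to rounding; it is
reported to make model bias visible when users fit residuals against
anything else), and QQ pairs using plotting positions (i − 0.5)/n
against standard-normal quantiles. Perfect fits (zero residual
variance) report R² = 1 with NaN standard errors and a `perfect` flag
instead of infinities, and are rejected by the pooling step.

p-values are reported but never drive automatic decisions, and no
multiple-testing correction is applied across the 59 scan rows; the
scan table is emitted in full so users can apply their own criterion.

## Endpoint scan and saturation

The scan anchors one segment end at the window start and moves the
other end from start+1 to the window end, refitting the model on each
segment's normalized scores — 59 rows for the 60 bp default window.
Row-level fit failures (e.g. a degenerate short segment) are recorded
on the row and skipped downstream. Saturation — the point past which
lengthening the segment no longer appreciably improves fit — is
operationalized as the smallest X* such that r2(X) − r2(X*) < ΔR² for
every later X, with ΔR² = 0.01 by default and configurable; if quality
keeps improving the last endpoint is returned. The rule is a
deliberate sharpening of a qualitative notion; the full scan table is
always written so any other criterion can be applied.

## Pooling and the published model

Fits from different fluorescence channels (or datasets) are combined
per parameter by inverse-variance weighting,
C = Σ(C_k/SE_k²)/Σ(1/SE_k²), with pooled SE = sqrt(1/Σ(1/SE_k²));
weighting by 1/SE² rather than 1/SE is the standard fixed-effect
choice and is recorded in output metadata. Channels are never stacked
into one regression — stacking would let a noisy channel's points
dilute a clean one's fit rather than down-weighting the whole channel.
The published model (C0 = 0.025, C1 = 0.87) is the default for
prediction and is overridable by any user-supplied fit or pooled
estimate.

Prediction refuses to run without an explicit scoring matrix, because
a score is only meaningful against the matrix family the model was
calibrated on; the matrix sidecar's provenance is echoed into every
prediction report. Classification thresholds default to tertiles of
the strength set in use (none are published); the boundary rule is
weak < t_low ≤ moderate < t_high ≤ strong.

## Synthetic data

The generator draws sequences i.i.d. per position from a base
composition (default A,C,G,T = 0.3, 0.2, 0.2, 0.3, reflecting the mild
AT-richness of yeast promoter regions), with optional conserved
columns where a named base is drawn at a stated level in (0.25, 1] and
the rest is split evenly. Strengths realize the model generatively:
strength = true_C0 + true_C1·score + Normal(0, noise_sd²), with
defaults true_C0 = 0.025, true_C1 = 0.87, noise_sd = 0.05 and a
labeled-subset convention of 18 promoters against a 2000-sequence
population — the shape of the reference study at desk scale. A single
seed drives two independent integer-keyed sub-streams (sequences,
noise), so the generator is fully deterministic across runs and
platforms and regenerating sequences does not perturb noise draws.
An optional fold-encoding writes fold = exp(strength·c) so the
fluorescence-side normalization path can be exercised end to end.

What the generator does **not** emulate: TATA boxes, poly(dA:dT)
nucleosome-disfavoring tracts, positional covariance, or any real
promoter grammar beyond user-specified conserved columns. Passing
tests therefore demonstrate that the pipeline's arithmetic, inference
and scan logic are correct under the model's own assumptions — not
that the linear score→strength relationship holds for any particular
real promoter set.

## Verification design and problem sizes

- Matrix construction is checked cell-for-cell against a brute-force
  pure-Python tally on 120 random small sets (≤ 20 sequences, length
  ≤ 12) across pseudocounts and backgrounds, and against the biopython
  motif machinery as an independent implementation.
- Scoring is checked for exact partition additivity and consensus
  maximality on 1000 random instances, and against a per-position loop
  oracle.
- Noiseless generated strengths recover (C0, C1) to 1e−9 with R² = 1
  for 50 random parameter draws.
- Statistical calibration uses 1000 noise replicates under a flat
  (C1 = 0) model — the F-test's type-I error must sit near its nominal
  5% — and 200 replicates under the published parameters for 95% CI
  coverage of C1 at n = 18, noise sd 0.05.
- Scan behavior: with strengths generated from the full-window score,
  the population R²(X) curve is provably non-decreasing (independent
  positions give R² = Var(score_X)/Var(score_full)); the monotonicity
  check uses a labeled set of 400 because finite-sample dips in
  adjacent R² estimates scale roughly as 1/√n and must stay well below
  the 0.02 tolerance (at n = 400 observed dips are ≤ 0.007). With
  strengths generated from a truncated [−49, −10] segment score at
  n = 18, the saturation endpoint lands at X ≤ −5 in ≥ 90% of 100
  seeds.
- OLS identities (F = t², zero residual sum, zero residual-on-score
  slope) are asserted at 1e−6 relative tolerance on every fit the
  tests produce.

The acceptance script runs the full pipeline at the study's canonical
shape (2000-promoter population, 18 labeled, three replicate channels)
and re-estimates all headline quantities from scratch in a few
seconds.

## Known limitations

- The model is a two-parameter linear map from one scalar feature; it
  cannot capture saturation, activator/repressor context (UAS/URS), or
  chromatin effects, and extrapolates linearly outside the score range
  it was calibrated on.
- Only single-stranded, pre-aligned fixed windows are scored: no
  sliding-window genome scanning, no reverse-strand handling, no
  variable-length motif alignment.
- Robust/weighted regression variants and Bayesian fits are out of
  scope, as is inverse design (optimizing a sequence for a target
  strength).
- Classification thresholds are data-dependent by default (tertiles);
  two studies with different labeled sets will draw different
  weak/moderate/strong boundaries unless thresholds are given
  explicitly.
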