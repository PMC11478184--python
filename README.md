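# corepromoter

Sequence-based prediction of core-promoter strength in
*Saccharomyces cerevisiae*.

Constitutive yeast promoters differ over an order of magnitude in the
transcription they drive, and much of that difference is encoded in the
core promoter — the window from −49 to +10 around the transcription
start site (TSS, position 0). This package implements a simple,
transparent model of that relationship for synthetic-biology users who
need to rank or design promoters before going to the bench:

1. **Score.** A position frequency matrix is tallied from a population
   of TSS-aligned 60 bp promoter windows, converted to per-position base
   probabilities (optional pseudocount) and then to a log-odds
   position-specific scoring matrix (PSSM, bits) against a background
   base distribution. A promoter's *segment score* is the sum of its
   per-position log-odds over any sub-window; the *promoter score* s is
   that value normalized by the score of the reference promoter pTDH3,
   the strongest constitutive promoter in the reference set.
2. **Relate.** Promoter *strength* y — the natural log of reporter
   fluorescence fold-over-background, normalized the same way by
   pTDH3 — is modeled by ordinary least squares as

   &nbsp;&nbsp;&nbsp;&nbsp; y = C0 + C1 · s

   with full diagnostics (R², adjusted R², F and t statistics, residual
   table, residual-on-score slope, normal QQ pairs). Fits from
   different fluorescence channels are combined by inverse-variance
   weighting; the published pooled parameters are **C0 = 0.025,
   C1 = 0.87**.
3. **Localize.** An endpoint scan refits the model on segments
   [−49, X] for every X from −48 to +10 and finds the point where R²
   saturates — the shortest region that predicts strength.
4. **Predict.** New 60-mers are scored, mapped to a predicted strength,
   classified as weak / moderate / strong, and placed as a percentile
   within a background score distribution.

A first-class synthetic-data module generates promoter populations and
strength tables with known ground truth, so every stage of the pipeline
is testable without any downloads.

## Worked example

```python
from corepromoter import *

# simulate a study: 2000-promoter population, 18 labeled
spec = SyntheticSpec(n_sequences=2000, seed=1)
population = generate_promoter_set(spec)
pssm = ppm_to_pssm(pfm_to_ppm(build_pfm(population), pseudocount=1.0))
ref = pick_reference(pssm, population)
labeled = population.subset([ref] + [i for i in population.ids if i != ref][:17])

table = generate_strengths(labeled, pssm, spec, ref)
strengths = strengths_from_fold(table, "synthetic")
scores = [(r.id, r.normalized_score) for r in score_set(pssm, labeled, reference_id=ref)]
fit = fit_linear(scores, strengths)
print(f"C0 = {fit.C0:.3f} +/- {fit.se_C0:.3f}")
print(f"C1 = {fit.C1:.3f} +/- {fit.se_C1:.3f}")
print(f"R2 = {fit.r2:.3f}, F = {fit.F:.1f}, p_F = {fit.p_F:.2e}")

rows = scan_endpoints(pssm, labeled, strengths, reference_id=ref)
print(f"scan: {len(rows)} endpoints, saturation at X = {detect_saturation(rows)}")

print(f"predicted strength at normalized score 1.0: {predict_strength(1.0)}")
print(classify_strength(predict_strength(1.0), tertile_thresholds(strengths)))
```

prints

```
C0 = 0.037 +/- 0.009
C1 = 0.885 +/- 0.025
R2 = 0.988, F = 1284.9, p_F = 1.03e-16
scan: 59 endpoints, saturation at X = 9
predicted strength at normalized score 1.0: 0.895
strong
```

The strengths were generated from the full-window score with
C0 = 0.025, C1 = 0.87 and noise sd 0.05; the fit recovers both
parameters within one standard error, and because every position of the
window carries signal here, R² keeps improving essentially to the
window end. The last two lines apply the published model: a promoter
scoring as high as pTDH3 itself (s = 1) is predicted at strength
0.025 + 0.87 = 0.895 and classified as strong against the tertiles of
the labeled strengths.

## Command line

The same workflow is available as a console tool with subcommands
`simulate`, `build-pssm`, `score`, `fit`, `scan` and `predict`:

```sh
corepromoter simulate --n-sequences 2000 --seed 1 --outdir sim/
corepromoter build-pssm --fasta sim/promoters.fasta --pseudocount 1 --outdir mat/
corepromoter scan --fasta sim/promoters.fasta --pssm mat/pssm.tsv \
    --strengths sim/strengths.tsv --channel synthetic \
    --reference-id $(python -c "import json;print(json.load(open('sim/run_config.json'))['reference_id'])") \
    --outdir scan/
```

Every run writes a machine-readable copy of its configuration next to
its outputs; tabular results are TSV with JSON sidecars, and logs go to
stderr. Real studies replace the `simulate` step with a FASTA of
−49..+10 windows (EPD-style extract) and a tab-separated table of
fluorescence fold-over-background values or pre-normalized strengths.

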