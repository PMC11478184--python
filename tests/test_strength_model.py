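"""The score→strength model: fluorescence normalization, OLS fit and
diagnostics, endpoint scan, saturation rule, parameter pooling,
prediction and classification."""

from __future__ import annotations

import math

import numpy as np
import pytest

from corepromoter import (
    LinearFit,
    PublishedModel,
    ScanRow,
    StrengthRecord,
    StrengthTable,
    StrengthVector,
    SyntheticSpec,
    classify_strength,
    detect_saturation,
    fit_linear,
    generate_strengths,
    pool_parameters,
    predict_strength,
    scan_endpoints,
    score_percentile,
    score_set,
    strengths_from_fold,
    tertile_thresholds,
)
from corepromoter.strength_model import ModelError

from conftest import assert_ols_identities


def _vec(pairs):
    return StrengthVector(channel="test", entries=list(pairs))


class TestStrengthsFromFold:
    def _table(self, folds, reference="ref"):
        recs = [StrengthRecord(i, "V", fold_over_background=f)
                for i, f in folds.items()]
        return StrengthTable(reference_id=reference, records=recs)

    def test_log_ratio(self):
        vec = strengths_from_fold(
            self._table({"ref": math.e**4, "other": math.e**2}), "V")
        assert dict(vec.entries) == pytest.approx({"ref": 1.0, "other": 0.5})

    def test_fold_one_gives_zero_strength(self):
        vec = strengths_from_fold(
            self._table({"ref": math.e**2, "flat": 1.0}), "V")
        assert dict(vec.entries)["flat"] == pytest.approx(0.0)

    def test_three_point_hand_arithmetic(self):
        vec = strengths_from_fold(
            self._table({"ref": math.e**2, "a": math.e, "b": math.e**3}), "V")
        assert dict(vec.entries) == pytest.approx(
            {"ref": 1.0, "a": 0.5, "b": 1.5})

    def test_reference_fold_at_most_one_rejected(self):
        with pytest.raises(ModelError, match="normalizer"):
            strengths_from_fold(self._table({"ref": 1.0, "a": 5.0}), "V")

    def test_missing_channel_rejected(self):
        from corepromoter.seqio import SeqIOError
        with pytest.raises(SeqIOError, match="channel"):
            strengths_from_fold(self._table({"ref": 10.0}), "mRuby2")

    def test_prenormalized_strengths_pass_through(self):
        recs = [StrengthRecord("ref", "V", strength=1.0),
                StrengthRecord("a", "V", strength=0.3)]
        vec = strengths_from_fold(StrengthTable(records=recs), "V")
        assert dict(vec.entries) == pytest.approx({"ref": 1.0, "a": 0.3})


class TestFitLinear:
    def test_exact_line_is_perfect(self):
        fit = fit_linear([("a", 0.0), ("b", 1.0), ("c", 2.0)],
                         _vec([("a", 1.0), ("b", 2.0), ("c", 3.0)]))
        assert fit.C0 == pytest.approx(1.0, abs=1e-12)
        assert fit.C1 == pytest.approx(1.0, abs=1e-12)
        assert fit.r2 == 1.0
        assert fit.perfect
        assert math.isnan(fit.se_C1)
        assert all(abs(r) < 1e-12 for _, r in fit.residuals)

    def test_flat_three_points(self):
        """(0,0),(1,1),(2,0): slope 0, intercept = mean = 1/3, r2 = 0."""
        fit = fit_linear([("a", 0.0), ("b", 1.0), ("c", 2.0)],
                         _vec([("a", 0.0), ("b", 1.0), ("c", 0.0)]))
        assert fit.C1 == pytest.approx(0.0, abs=1e-12)
        assert fit.C0 == pytest.approx(1 / 3)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)
        assert fit.F == pytest.approx(0.0, abs=1e-12)
        assert_ols_identities(fit)

    def test_diagnostics_on_noisy_fit(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 18)
        y = 0.025 + 0.87 * x + rng.normal(0, 0.05, 18)
        ids = [f"p{i}" for i in range(18)]
        fit = fit_linear(list(zip(ids, x)), _vec(zip(ids, y)))
        assert_ols_identities(fit)
        assert fit.n == 18
        assert len(fit.qq) == 18
        # QQ theoretical quantiles use plotting positions (i - 0.5)/n
        from scipy import stats
        assert fit.qq[0][0] == pytest.approx(stats.norm.ppf(0.5 / 18))
        assert fit.qq[-1][0] == pytest.approx(stats.norm.ppf(17.5 / 18))
        ordered = [r for _, r in fit.qq]
        assert ordered == sorted(ordered)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ModelError, match=">= 3"):
            fit_linear([("a", 0.0), ("b", 1.0)],
                       _vec([("a", 0.0), ("b", 1.0)]))

    def test_only_matched_ids_used(self):
        fit = fit_linear(
            [("a", 0.0), ("b", 1.0), ("c", 2.0), ("unlabeled", 9.0)],
            _vec([("a", 1.0), ("b", 2.0), ("c", 3.0), ("missing", 0.0)]))
        assert fit.n == 3

    def test_zero_score_variance_rejected(self):
        with pytest.raises(ModelError, match="degenerate"):
            fit_linear([("a", 1.0), ("b", 1.0), ("c", 1.0)],
                       _vec([("a", 0.0), ("b", 1.0), ("c", 2.0)]))


class TestScan:
    def test_row_count_and_noiseless_recovery(self, small_study):
        spec, promoters, pssm, reference_id = small_study
        labeled = promoters.subset(
            [reference_id] + [i for i in promoters.ids if i != reference_id][:17]
        )
        exact = SyntheticSpec(n_sequences=spec.n_sequences, seed=spec.seed,
                              noise_sd=0.0, true_C0=0.1, true_C1=0.8)
        table = generate_strengths(labeled, pssm, exact, reference_id)
        vec = strengths_from_fold(table, "synthetic")
        rows = scan_endpoints(pssm, labeled, vec, reference_id=reference_id)
        assert len(rows) == 59
        assert [r.X for r in rows] == list(range(-48, 11))
        last = rows[-1].fit
        assert last is not None and last.r2 == pytest.approx(1.0)
        assert last.C0 == pytest.approx(0.1, abs=1e-9)
        assert last.C1 == pytest.approx(0.8, abs=1e-9)

    def test_anchor_must_match_window_start(self, small_study):
        _, promoters, pssm, reference_id = small_study
        vec = _vec([(i, 0.5) for i in promoters.ids[:5]])
        with pytest.raises(ModelError, match="anchor"):
            scan_endpoints(pssm, promoters, vec, left=-40,
                           reference_id=reference_id)


class TestDetectSaturation:
    def _rows(self, r2s, start_x=-9):
        def mkfit(r2):
            return LinearFit(C0=0, C1=1, se_C0=0.1, se_C1=0.1, t_C0=0, t_C1=0,
                             p_C0=1, p_C1=1, r2=r2, adj_r2=r2, F=0, p_F=1, n=18)
        return [ScanRow(X=start_x + i, fit=mkfit(r))
                for i, r in enumerate(r2s)]

    def test_plateau_rule(self):
        rows = self._rows([0.1, 0.5, 0.9, 0.905, 0.907])
        assert detect_saturation(rows, delta=0.01) == rows[2].X

    def test_never_saturates_returns_last(self):
        rows = self._rows([0.1, 0.3, 0.5, 0.7, 0.9])
        assert detect_saturation(rows, delta=0.01) == rows[-1].X

    def test_constant_saturates_immediately(self):
        rows = self._rows([0.8, 0.8, 0.8])
        assert detect_saturation(rows, delta=0.01) == rows[0].X

    def test_failed_rows_ignored(self):
        rows = self._rows([0.1, 0.9, 0.9])
        rows.insert(1, ScanRow(X=rows[0].X + 100, fit=None, error="boom"))
        assert detect_saturation(rows, delta=0.01) == rows[2].X

    def test_empty_rows_rejected(self):
        with pytest.raises(ModelError):
            detect_saturation([])


class TestPoolParameters:
    def _fit(self, C0=0.0, C1=1.0, se=0.1):
        return LinearFit(C0=C0, C1=C1, se_C0=se, se_C1=se, t_C0=0, t_C1=0,
                         p_C0=1, p_C1=1, r2=0.9, adj_r2=0.9, F=1, p_F=0.1, n=18)

    def test_equal_errors_reduce_to_mean(self):
        pooled = pool_parameters([self._fit(C1=0.8), self._fit(C1=1.0)])
        assert pooled.C1 == pytest.approx(0.9)
        assert pooled.se_C1 == pytest.approx(0.1 / math.sqrt(2))

    def test_inverse_variance_weighting(self):
        pooled = pool_parameters(
            [self._fit(C1=0.8, se=0.1), self._fit(C1=1.2, se=0.3)])
        expected = (0.8 / 0.01 + 1.2 / 0.09) / (1 / 0.01 + 1 / 0.09)
        assert pooled.C1 == pytest.approx(expected)  # = 0.84
        assert pooled.se_C1 == pytest.approx(math.sqrt(1 / (100 + 1 / 0.09)))

    def test_single_fit_identity(self):
        fit = self._fit(C0=0.02, C1=0.9, se=0.05)
        pooled = pool_parameters([fit])
        assert (pooled.C0, pooled.C1) == pytest.approx((0.02, 0.9))
        assert (pooled.se_C0, pooled.se_C1) == pytest.approx((0.05, 0.05))

    def test_degenerate_se_rejected(self):
        bad = self._fit(se=0.0)
        with pytest.raises(ModelError, match="exclude"):
            pool_parameters([self._fit(), bad])


class TestPredictAndClassify:
    def test_published_model_arithmetic(self):
        assert predict_strength(1.0) == 0.895
        assert predict_strength(0.0) == 0.025
        assert predict_strength(0.5) == pytest.approx(0.46)

    def test_custom_model(self):
        from corepromoter import PooledParameters
        m = PooledParameters(C0=0.1, C1=2.0, se_C0=0.0, se_C1=0.0, n_fits=1)
        assert predict_strength(0.5, m) == pytest.approx(1.1)

    def test_non_finite_model_rejected(self):
        with pytest.raises(ModelError):
            predict_strength(1.0, PublishedModel(C0=float("nan")))

    @pytest.mark.parametrize("value,label", [
        (0.1, "weak"), (0.4, "moderate"), (0.46, "moderate"),
        (0.7, "strong"), (0.9, "strong"),
    ])
    def test_thresholds(self, value, label):
        assert classify_strength(value, (0.4, 0.7)) == label

    def test_invalid_thresholds(self):
        with pytest.raises(ModelError):
            classify_strength(0.5, (0.7, 0.4))

    def test_tertile_thresholds_split_the_set(self):
        vec = _vec([(f"p{i}", v) for i, v in enumerate(np.linspace(0, 1, 18))])
        t_low, t_high = tertile_thresholds(vec)
        labels = [classify_strength(v, (t_low, t_high))
                  for _, v in vec.entries]
        assert labels.count("weak") == 6
        assert labels.count("strong") == 6

    def test_score_percentile(self):
        bg = np.arange(100, dtype=float)
        assert score_percentile(99.0, bg) == pytest.approx(100.0)
        assert score_percentile(-1.0, bg) == pytest.approx(0.0)
        assert score_percentile(49.0, bg) == pytest.approx(50.0)
        with pytest.raises(ModelError):
            score_percentile(1.0, np.array([]))
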