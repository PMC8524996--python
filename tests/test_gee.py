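"""GEE estimation: closed forms, cross-checks, coverage, inference."""

import math
import warnings

import numpy as np
import pytest

from cadeval.classify import CaseOutcome
from cadeval.gee import (
    GeeFit,
    GeeSpec,
    SeparationError,
    Z975,
    build_outcome_records,
    fit_gee,
    fit_gee_arrays,
    format_p,
    ratio_ci,
)


def _clustered_binary(rng, n_clusters=None, p0=0.45, effect=0.1, sigma=0.08):
    n_clusters = n_clusters or int(rng.integers(8, 25))
    y, arm, cl = [], [], []
    for c in range(n_clusters):
        u = rng.normal() * sigma
        for a in (0, 1):
            n = int(rng.integers(8, 25))
            p = float(np.clip(p0 + effect * a + u, 0.02, 0.98))
            y.extend((rng.random(n) < p).astype(float))
            arm.extend([a] * n)
            cl.extend([c] * n)
    return np.array(y), np.array(arm), np.array(cl)


class TestClosedForm:
    def test_independence_ratio_equals_pooled_proportion_ratio(self, rng):
        """With a saturated two-level covariate and independence weights the
        estimating equations are solved by the arm means."""
        spec = GeeSpec(working_correlation="independence", tolerance=1e-12)
        for _ in range(50):
            n_cl = int(rng.integers(4, 12))
            n_per = int(rng.integers(5, 15))
            y, arm, cl = [], [], []
            for c in range(n_cl):
                for a in (0, 1):
                    p = 0.3 + 0.2 * a + 0.1 * rng.random()
                    y.extend((rng.random(n_per) < p).astype(float))
                    arm.extend([a] * n_per)
                    cl.extend([c] * n_per)
            y, arm, cl = map(np.array, (y, arm, cl))
            if y[arm == 0].min() == y[arm == 0].max():
                continue
            if y[arm == 1].min() == y[arm == 1].max():
                continue
            fit = fit_gee_arrays(y, arm, cl, spec)
            expected = y[arm == 1].mean() / y[arm == 0].mean()
            assert fit.ratio == pytest.approx(expected, abs=1e-8)

    def test_identical_arms_give_unit_ratio(self, rng):
        base = (rng.random(60) < 0.5).astype(float)
        y = np.concatenate([base, base])
        arm = np.repeat([0, 1], 60)
        cl = np.tile(np.repeat(np.arange(6), 10), 2)
        fit = fit_gee_arrays(y, arm, cl, GeeSpec())
        assert fit.beta1 == pytest.approx(0.0, abs=1e-10)
        assert fit.ratio == pytest.approx(1.0, abs=1e-10)


class TestStatsmodelsCrossCheck:
    @pytest.mark.parametrize("correlation", ["independence", "exchangeable"])
    def test_agreement_on_clustered_datasets(self, rng, correlation):
        """Point estimates and robust SEs agree with statsmodels' GEE to
        1e-6 relative on 20 random clustered datasets."""
        import statsmodels.api as sm

        spec = GeeSpec(working_correlation=correlation, tolerance=1e-12)
        for _ in range(20):
            y, arm, cl = _clustered_binary(rng)
            mine = fit_gee_arrays(y, arm, cl, spec)
            X = np.column_stack([np.ones_like(arm), arm])
            cov_struct = (
                sm.cov_struct.Independence()
                if correlation == "independence"
                else sm.cov_struct.Exchangeable()
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GEE(
                    y,
                    X,
                    groups=cl,
                    family=sm.families.Binomial(link=sm.families.links.Log()),
                    cov_struct=cov_struct,
                )
                res = model.fit(
                    maxiter=200,
                    ctol=1e-12,
                    start_params=[math.log(y[arm == 0].mean()), 0.0],
                )
            np.testing.assert_allclose(
                [mine.beta0, mine.beta1], res.params, rtol=1e-6, atol=1e-9
            )
            np.testing.assert_allclose(
                np.sqrt(np.diag(mine.robust_cov)), res.bse, rtol=1e-6, atol=1e-9
            )


class TestSandwich:
    def test_symmetric_positive_semidefinite(self, rng):
        for _ in range(10):
            y, arm, cl = _clustered_binary(rng)
            fit = fit_gee_arrays(y, arm, cl, GeeSpec())
            cov = fit.robust_cov
            assert np.allclose(cov, cov.T)
            assert np.linalg.eigvalsh(cov).min() >= -1e-12

    def test_interval_brackets_ratio(self, rng):
        for _ in range(10):
            y, arm, cl = _clustered_binary(rng)
            fit = fit_gee_arrays(y, arm, cl, GeeSpec())
            assert fit.ci_lower <= fit.ratio <= fit.ci_upper
            assert fit.ratio > 0


class TestRatioCi:
    def _fit(self, beta1, se):
        cov = np.array([[0.01, 0.0], [0.0, se**2]])
        r = math.exp(beta1)
        return GeeFit(
            beta0=-0.7,
            beta1=beta1,
            robust_cov=cov,
            ratio=r,
            ci_lower=r * math.exp(-Z975 * se),
            ci_upper=r * math.exp(Z975 * se),
            p_value=1.0 if beta1 == 0 else 0.0,
            converged=True,
            n_clusters=18,
        )

    def test_wald_interval_evaluation(self):
        fit = self._fit(0.0, 0.1)
        ratio, lo, hi, _ = ratio_ci(fit)
        assert ratio == pytest.approx(1.0)
        assert lo == pytest.approx(math.exp(-0.1959964), abs=1e-6)
        assert hi == pytest.approx(math.exp(0.1959964), abs=1e-6)
        assert (lo, hi) == (pytest.approx(0.822, abs=1e-3), pytest.approx(1.216, abs=1e-3))

    def test_unconverged_fit_rejected(self):
        fit = self._fit(0.1, 0.1)
        fit.converged = False
        with pytest.raises(ValueError, match="converge"):
            ratio_ci(fit)

    def test_degenerate_interval_flagged(self):
        with pytest.raises(ValueError, match="degenerate"):
            ratio_ci(self._fit(0.2, 0.0))

    def test_small_p_values_floored_for_display(self):
        assert format_p(1e-6) == "< 0.001"
        assert format_p(0.221) == "0.221"


class TestSeparation:
    def test_constant_arm_raises_naming_the_arm(self, rng):
        y = np.concatenate([np.ones(20), (rng.random(20) < 0.5).astype(float)])
        arm = np.repeat([0, 1], 20)
        cl = np.tile(np.arange(4), 10)
        with pytest.raises(SeparationError, match="arm 0"):
            fit_gee_arrays(y, arm, cl, GeeSpec())


class TestOutcomeRecords:
    def _study_outcomes(self, small_config):
        from cadeval.evaluate import reader_outcomes
        from cadeval.simulate import generate_study

        study = generate_study(small_config)
        return study, reader_outcomes(study.images, study.sessions)

    def test_sensitivity_record_count(self, small_config):
        study, outs = self._study_outcomes(small_config)
        records = build_outcome_records(outs, "sensitivity")
        n_readers = len(study.readers)
        assert len(records) == n_readers * small_config.n_malignant * 2

    def test_accuracy_record_count(self, small_config):
        study, outs = self._study_outcomes(small_config)
        records = build_outcome_records(outs, "accuracy")
        assert len(records) == len(study.readers) * len(study.images) * 2

    def test_ppv_subsets_are_arm_dependent(self, small_config):
        _, outs = self._study_outcomes(small_config)
        records = build_outcome_records(outs, "ppv")
        n0 = sum(1 for r in records if r.arm == 0)
        n1 = sum(1 for r in records if r.arm == 1)
        assert n0 > 0 and n1 > 0
        # positive calls are exactly the TP and FP cases in this generator
        expect = {0: 0, 1: 0}
        for (reader, arm_label), olist in outs.items():
            a = 0 if arm_label == "pre_cad" else 1
            expect[a] += sum(1 for o in olist if o.state in ("TP", "FP"))
        assert (n0, n1) == (expect[0], expect[1])

    def test_unknown_metric_rejected(self, small_config):
        _, outs = self._study_outcomes(small_config)
        with pytest.raises(ValueError, match="unknown metric"):
            build_outcome_records(outs, "f1")

    def test_empty_subset_is_an_error(self):
        outs = {
            ("r1", "pre_cad"): [CaseOutcome("i0", "TN", 0)],
            ("r1", "post_cad"): [CaseOutcome("i0", "TN", 0)],
        }
        with pytest.raises(ValueError, match="sensitivity"):
            build_outcome_records(outs, "sensitivity")


def test_exchangeable_alpha_is_estimated(rng):
    y, arm, cl = _clustered_binary(rng, n_clusters=20, sigma=0.12)
    fit = fit_gee_arrays(y, arm, cl, GeeSpec(working_correlation="exchangeable"))
    assert fit.alpha_hat is not None
    ind = fit_gee_arrays(y, arm, cl, GeeSpec(working_correlation="independence"))
    assert ind.alpha_hat is None
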