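import math

import numpy as np
import pytest
from scipy.optimize import brentq

import stopext as se
from stopext.calibration import (
    CalibrationError,
    GaussianComponent,
    calibration_report,
    posterior_odds,
)


def make_fit(mu_b, mu_p, s2_b, s2_p, w_p=0.5) -> se.MixtureFit:
    return se.MixtureFit(
        benign=GaussianComponent(mu_b, s2_b, 1 - w_p, "B/LB"),
        pathogenic=GaussianComponent(mu_p, s2_p, w_p, "P/LP"),
        log_likelihood=0.0, n=100, seed=0,
    )


class TestFitMixture:
    def test_recovers_planted_components(self):
        rng = np.random.default_rng(0)
        scores = np.concatenate([rng.normal(0.2, 0.05, 1000),
                                 rng.normal(0.8, 0.05, 1000)])
        fit = se.fit_mixture(scores, seed=0)
        assert fit.benign.mu == pytest.approx(0.2, abs=0.02)
        assert fit.pathogenic.mu == pytest.approx(0.8, abs=0.02)

    def test_higher_mean_component_is_pathogenic(self):
        rng = np.random.default_rng(1)
        scores = np.concatenate([rng.normal(0.7, 0.05, 200),
                                 rng.normal(0.1, 0.05, 200)])
        fit = se.fit_mixture(scores, seed=1)
        assert fit.pathogenic.mu > fit.benign.mu

    def test_degenerate_data_rejected(self):
        with pytest.raises(CalibrationError, match="degenerate"):
            se.fit_mixture(np.full(100, 0.5))

    def test_too_few_scores_rejected(self):
        with pytest.raises(CalibrationError):
            se.fit_mixture(np.linspace(0, 1, 5))


class TestLikelihoodRatio:
    def test_midpoint_is_one_with_equal_variances(self):
        fit = make_fit(0.2, 0.8, 0.01, 0.01)
        assert se.likelihood_ratio(0.5, fit) == pytest.approx(1.0)

    def test_closed_form_at_the_pathogenic_mean(self):
        fit = make_fit(0.1, 0.7, 0.01, 0.01)
        expected = math.exp(0.6**2 / (2 * 0.01))
        assert se.likelihood_ratio(0.7, fit) == pytest.approx(expected, rel=1e-9)

    def test_monotone_between_means_with_equal_variances(self):
        fit = make_fit(0.2, 0.8, 0.01, 0.01)
        xs = np.linspace(0.2, 0.8, 50)
        lr = se.likelihood_ratio(xs, fit)
        assert np.all(np.diff(lr) > 0)

    def test_posterior_odds_scales_by_weights(self):
        fit = make_fit(0.2, 0.8, 0.01, 0.01, w_p=0.25)
        assert posterior_odds(0.5, fit) == pytest.approx(1 / 3)


class TestSolveThresholds:
    def test_equal_variance_closed_form(self):
        fit = make_fit(0.2, 0.8, 0.01, 0.01)
        th = se.solve_thresholds(fit, ratio=9)
        expected_upper = 0.5 + 0.01 * math.log(9) / 0.6
        assert th.upper == pytest.approx(expected_upper, abs=1e-12)
        assert th.lower == pytest.approx(1 - expected_upper, abs=1e-12)

    def test_solution_satisfies_the_lr_equation(self):
        fit = make_fit(0.25, 0.75, 0.015, 0.008)  # unequal variances
        th = se.solve_thresholds(fit, ratio=9)
        assert se.likelihood_ratio(th.upper, fit) == pytest.approx(9, abs=1e-9)
        assert se.likelihood_ratio(th.lower, fit) == pytest.approx(1 / 9, abs=1e-9)

    def test_matches_numeric_root_finder(self):
        fit = make_fit(0.2, 0.8, 0.012, 0.006)
        th = se.solve_thresholds(fit, ratio=9)
        f = lambda x: math.log(se.likelihood_ratio(x, fit)) - math.log(9)
        numeric = brentq(f, fit.benign.mu, fit.pathogenic.mu, xtol=1e-14)
        assert th.upper == pytest.approx(numeric, abs=1e-9)

    def test_ratio_one_collapses_to_midpoint(self):
        fit = make_fit(0.2, 0.8, 0.01, 0.01)
        th = se.solve_thresholds(fit, ratio=1)
        assert th.lower == th.upper == pytest.approx(0.5)

    def test_mirror_symmetry(self):
        fit = make_fit(0.2, 0.8, 0.012, 0.006)
        mirrored = make_fit(1 - 0.8, 1 - 0.2, 0.006, 0.012)
        th = se.solve_thresholds(fit, ratio=9)
        mth = se.solve_thresholds(mirrored, ratio=9)
        assert mth.upper == pytest.approx(1 - th.lower, abs=1e-9)
        assert mth.lower == pytest.approx(1 - th.upper, abs=1e-9)

    def test_thresholds_lie_between_the_means(self):
        fit = make_fit(0.3, 0.7, 0.02, 0.01)
        th = se.solve_thresholds(fit, ratio=9)
        assert 0.3 < th.lower < th.upper < 0.7


class TestClassifyScore:
    @pytest.mark.parametrize(
        "score,expected",
        [(0.75, "potentially_PLP"), (0.70, "potentially_PLP"),
         (0.50, "uncertain"), (0.30, "potentially_BLB"),
         (0.05, "potentially_BLB")],
    )
    def test_three_bins_with_inclusive_boundaries(self, score, expected):
        assert se.classify_score(score, se.DEFAULT_THRESHOLDS) == expected

    def test_default_thresholds_are_030_070(self):
        assert (se.DEFAULT_THRESHOLDS.lower,
                se.DEFAULT_THRESHOLDS.upper) == (0.30, 0.70)


def test_classified_mass_matches_component_tail():
    """The fraction called potentially-pathogenic converges to the true
    pathogenic-component mass above the threshold."""
    from scipy.stats import norm

    rng = np.random.default_rng(3)
    n = 10_000
    scores = np.concatenate([rng.normal(0.2, 0.08, n // 2),
                             rng.normal(0.8, 0.08, n // 2)])
    fit = se.fit_mixture(scores, seed=3)
    th = se.solve_thresholds(fit, ratio=9)
    frac = np.mean(scores >= th.upper)
    expected = 0.5 * (
        norm.sf(th.upper, 0.8, 0.08) + norm.sf(th.upper, 0.2, 0.08)
    )
    assert frac == pytest.approx(expected, abs=0.02)


def test_calibration_report_is_json(tmp_path):
    import json

    fit = make_fit(0.2, 0.8, 0.01, 0.01)
    th = se.solve_thresholds(fit)
    report = json.loads(calibration_report(fit, th))
    assert report["thresholds"]["ratio"] == 9.0
    assert report["components"]["P/LP"]["mu"] == 0.8
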