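"""Profile likelihood, confidence intervals, and identifiability classes.

The linear-Gaussian regression model y = theta1 * x + theta0 with known
noise admits closed forms for the profile (a parabola in theta1) and the
95% CI, which anchor the machinery.
"""

import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist

from aktloop.profile import (
    ProfileResult,
    ThresholdSpec,
    classify_identifiability,
    profile_all,
    profile_confidence_interval,
    profile_parameter,
)


def _linear_chi2(x, y, sigma):
    def fun(theta):
        resid = (y - theta[0] * x - theta[1]) / sigma
        return float(resid @ resid)

    return fun


@pytest.fixture(scope="module")
def linear_toy():
    rng = np.random.default_rng(123)
    x = np.linspace(0.5, 3.0, 25)
    sigma = 0.3
    theta_true = np.array([1.3, 0.8])
    y = theta_true[0] * x + theta_true[1] + rng.normal(0, sigma, x.size)
    # closed-form least squares
    design = np.column_stack([x, np.ones_like(x)])
    theta_hat, *_ = np.linalg.lstsq(design / sigma, y / sigma, rcond=None)
    return x, y, sigma, theta_hat


class TestThreshold:
    def test_pointwise_95_threshold_is_chi2_quantile(self):
        th = ThresholdSpec(alpha=0.95, df=1)
        assert th.delta == pytest.approx(3.841458820694124, abs=1e-9)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSpec(alpha=1.2)
        with pytest.raises(ValueError):
            ThresholdSpec(df=0)


class TestProfileParameter:
    def test_profile_matches_analytic_parabola(self, linear_toy):
        x, y, sigma, theta_hat = linear_toy
        fun = _linear_chi2(x, y, sigma)
        prof = profile_parameter(fun, theta_hat, ["slope", "offset"],
                                 [(0.1, 10.0), (-50.0, 50.0)], "slope",
                                 n_grid=8, log_grid=False, inner_maxfun=400)
        # analytic: chi2_PL(t) = chi2_min + (t - hat)^2 / var(slope|profiled)
        design = np.column_stack([x, np.ones_like(x)]) / sigma
        cov = np.linalg.inv(design.T @ design)
        c = 1.0 / cov[0, 0]
        expected = fun(theta_hat) + c * (prof.grid - theta_hat[0]) ** 2
        assert np.allclose(prof.chi2, expected, atol=1e-6)

    def test_profile_value_at_optimum_equals_chi2_min(self, linear_toy):
        x, y, sigma, theta_hat = linear_toy
        fun = _linear_chi2(x, y, sigma)
        prof = profile_parameter(fun, theta_hat, ["slope", "offset"],
                                 [(0.1, 10.0), (-50.0, 50.0)], "slope",
                                 n_grid=5, log_grid=False)
        i = int(np.argmin(np.abs(prof.grid - theta_hat[0])))
        assert prof.chi2[i] == pytest.approx(fun(theta_hat), abs=1e-9)

    def test_inert_parameter_has_flat_profile(self, linear_toy):
        x, y, sigma, theta_hat = linear_toy
        base = _linear_chi2(x, y, sigma)
        fun = lambda theta: base(theta[:2])  # theta[2] unused
        theta3 = np.append(theta_hat, 1.0)
        prof = profile_parameter(fun, theta3, ["slope", "offset", "ghost"],
                                 [(0.1, 10.0), (-5.0, 5.0), (1e-3, 1e3)], "ghost",
                                 n_grid=6, inner_maxfun=200)
        rl, rr = prof.rise()
        eps = 0.05 * ThresholdSpec().delta
        assert rl < eps and rr < eps


class TestConfidenceInterval:
    def test_parabola_ci_matches_closed_form(self):
        theta_hat, c, chi2_min = 2.0, 5.0, 1.7
        grid = np.linspace(0.5, 3.5, 61)
        prof = ProfileResult(name="p", grid=grid,
                             chi2=chi2_min + c * (grid - theta_hat) ** 2,
                             chi2_opt=chi2_min, theta_opt=theta_hat)
        th = ThresholdSpec(alpha=0.95, df=1)
        out = profile_confidence_interval(prof, th)
        half = np.sqrt(th.delta / c)
        assert out.ci_lower == pytest.approx(theta_hat - half, abs=1e-3)
        assert out.ci_upper == pytest.approx(theta_hat + half, abs=1e-3)
        assert classify_identifiability(out).classification == "identifiable"

    def test_one_sided_crossing_is_practical(self):
        grid = np.linspace(1.0, 10.0, 30)
        chi2 = np.where(grid > 5.0, 10.0 * (grid - 5.0) ** 2, 0.0)
        prof = ProfileResult(name="p", grid=grid, chi2=chi2, chi2_opt=0.0, theta_opt=2.0)
        out = classify_identifiability(
            profile_confidence_interval(prof, ThresholdSpec()))
        assert np.isinf(out.ci_lower) and np.isfinite(out.ci_upper)
        assert out.classification == "practically_nonidentifiable"

    def test_flat_profile_is_structural(self):
        grid = np.linspace(1.0, 10.0, 20)
        prof = ProfileResult(name="p", grid=grid, chi2=np.zeros_like(grid),
                             chi2_opt=0.0, theta_opt=5.0)
        out = classify_identifiability(
            profile_confidence_interval(prof, ThresholdSpec()))
        assert np.isinf(out.ci_lower) and np.isinf(out.ci_upper)
        assert out.classification == "structurally_nonidentifiable"

    def test_empty_profile_rejected(self):
        prof = ProfileResult(name="p", grid=np.array([]), chi2=np.array([]),
                             chi2_opt=0.0, theta_opt=0.0)
        with pytest.raises(ValueError, match="empty"):
            profile_confidence_interval(prof)


class TestCoverage:
    def test_pointwise_ci_covers_95_percent(self):
        """For the linear-Gaussian model the profile CI equals the Wald CI
        theta_hat +/- sqrt(Delta) * se; its coverage over simulated datasets
        must be 95% within Monte-Carlo error."""
        rng = np.random.default_rng(77)
        x = np.linspace(0.5, 3.0, 20)
        sigma = 0.4
        theta1_true = 1.1
        design = np.column_stack([x, np.ones_like(x)]) / sigma
        cov = np.linalg.inv(design.T @ design)
        se = np.sqrt(cov[0, 0])
        half = np.sqrt(chi2_dist.ppf(0.95, 1)) * se
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            y = theta1_true * x + 0.8 + rng.normal(0, sigma, x.size)
            theta_hat, *_ = np.linalg.lstsq(design, y / sigma, rcond=None)
            if abs(theta_hat[0] - theta1_true) <= half:
                hits += 1
        assert hits / n_sim == pytest.approx(0.95, abs=0.02)

    def test_machinery_ci_equals_wald_ci_on_one_dataset(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0.5, 3.0, 20)
        sigma = 0.4
        y = 1.1 * x + 0.8 + rng.normal(0, sigma, x.size)
        design = np.column_stack([x, np.ones_like(x)]) / sigma
        theta_hat, *_ = np.linalg.lstsq(design, y / sigma, rcond=None)
        cov = np.linalg.inv(design.T @ design)
        half = np.sqrt(chi2_dist.ppf(0.95, 1) * cov[0, 0])
        fun = _linear_chi2(x, y, sigma)
        # dense grid over a narrow bracket so linear interpolation of the
        # parabola's threshold crossing is sub-millidigit accurate
        prof = profile_parameter(fun, theta_hat, ["slope", "offset"],
                                 [(0.5, 2.0), (-50.0, 50.0)], "slope",
                                 n_grid=80, log_grid=False, inner_maxfun=400)
        out = profile_confidence_interval(prof, ThresholdSpec())
        assert out.ci_lower == pytest.approx(theta_hat[0] - half, abs=2e-3)
        assert out.ci_upper == pytest.approx(theta_hat[0] + half, abs=2e-3)


class TestProfileAll:
    def test_survey_classifies_every_parameter(self, linear_toy):
        x, y, sigma, theta_hat = linear_toy
        fun = _linear_chi2(x, y, sigma)
        survey = profile_all(fun, theta_hat, ["slope", "offset"],
                             [(0.1, 10.0), (-50.0, 50.0)],
                             n_grid=6, log_grid=False, inner_maxfun=200)
        classes = survey.classes()
        assert set(classes) == {"slope", "offset"}
        assert classes["slope"] == "identifiable"
        assert survey.n_nonidentifiable() == 0
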