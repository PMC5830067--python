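"""Class densities, risk curves, equal-error point, sample assignment."""

import numpy as np
import pytest
from scipy import stats

from plscm import (
    ClassDensityModel,
    assign_samples,
    equal_error_point,
    fit_class_densities,
    risk_curve,
    signed_sensitivity,
)
from plscm.class_model import NormalityWarning
from plscm.exceptions import DegenerateDensityError


# the per-class response parameters quoted for the two published models
PLS1_DENS = ClassDensityModel(mu0=0.075, sigma0=0.219, mu1=0.810, sigma1=0.146)
PLS2_DENS = ClassDensityModel(mu0=0.096, sigma0=0.247, mu1=0.846, sigma1=0.162)


class TestFitClassDensities:
    def test_degenerate_class_variance(self):
        y_hat = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(DegenerateDensityError):
            fit_class_densities(y_hat, labels)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(42)
        n = 200
        g0 = rng.normal(0.1, 0.2, n)
        g1 = rng.normal(0.8, 0.15, n)
        y_hat = np.concatenate([g0, g1])
        labels = np.r_[np.zeros(n, int), np.ones(n, int)]
        dens = fit_class_densities(y_hat, labels)
        # within 3 standard errors of the generating truth
        assert abs(dens.mu0 - 0.1) < 3 * 0.2 / np.sqrt(n)
        assert abs(dens.mu1 - 0.8) < 3 * 0.15 / np.sqrt(n)
        assert abs(dens.sigma0 - 0.2) < 3 * 0.2 / np.sqrt(2 * n)
        assert abs(dens.sigma1 - 0.15) < 3 * 0.15 / np.sqrt(2 * n)
        assert dens.normality_ok

    def test_heavy_tailed_class_warns(self):
        rng = np.random.default_rng(1)
        g0 = rng.standard_cauchy(60) * 0.1  # grossly non-normal
        g1 = rng.normal(0.8, 0.1, 30)
        y_hat = np.concatenate([g0, g1])
        labels = np.r_[np.zeros(60, int), np.ones(30, int)]
        with pytest.warns(NormalityWarning):
            dens = fit_class_densities(y_hat, labels)
        assert not dens.normality_ok

    def test_minimum_class_size(self):
        with pytest.raises(Exception, match="3 samples"):
            fit_class_densities(np.array([0.1, 0.2, 0.8]), np.array([0, 0, 1]))


class TestRiskCurve:
    def test_extreme_threshold_limits(self):
        curve = risk_curve(PLS1_DENS, grid_size=501)
        assert curve.alpha[0] > 0.999  # everything rejected at the low end
        assert curve.beta[0] < 1e-3
        assert curve.alpha[-1] < 1e-3
        assert curve.beta[-1] > 0.999

    def test_symmetric_model_midpoint(self):
        """Equal sigmas: alpha and beta coincide exactly at the midpoint."""
        dens = ClassDensityModel(mu0=0.0, sigma0=0.2, mu1=1.0, sigma1=0.2)
        curve = risk_curve(dens, grid_size=2001)
        alpha_mid = np.interp(0.5, curve.thresholds, curve.alpha)
        beta_mid = np.interp(0.5, curve.thresholds, curve.beta)
        assert alpha_mid == pytest.approx(beta_mid, abs=1e-12)

    @pytest.mark.parametrize("dens", [PLS1_DENS, PLS2_DENS])
    def test_monotone_in_threshold(self, dens):
        curve = risk_curve(dens, 1001)
        assert np.all(np.diff(curve.alpha) <= 1e-12)
        assert np.all(np.diff(curve.beta) >= -1e-12)
        assert np.all((curve.alpha >= 0) & (curve.alpha <= 1))

    def test_published_densities_pass_near_equal_error(self):
        """The risk curve of the first model passes within 0.005 of (2%, 2%)."""
        curve = risk_curve(PLS1_DENS, grid_size=4001)
        d = np.hypot(curve.alpha - 0.02, curve.beta - 0.02)
        assert d.min() < 0.005

    def test_grid_size_validation(self):
        with pytest.raises(ValueError):
            risk_curve(PLS1_DENS, grid_size=1)


class TestEqualErrorPoint:
    @pytest.mark.parametrize(
        "dens, expected_pct",
        [(PLS1_DENS, 98), (PLS2_DENS, 97)],
        ids=["patients-vs-healthy", "cases-vs-controls"],
    )
    def test_published_models_round_to_reported_percent(self, dens, expected_pct):
        point = equal_error_point(dens)
        assert point.sensitivity_pct == expected_pct
        assert point.specificity_pct == expected_pct
        assert abs(point.sensitivity - point.specificity) < 1e-6

    def test_symmetric_closed_form(self):
        sigma = 0.3
        dens = ClassDensityModel(mu0=0.0, sigma0=sigma, mu1=1.0, sigma1=sigma)
        point = equal_error_point(dens)
        assert point.threshold == pytest.approx(0.5)
        expected = stats.norm.cdf(1 / (2 * sigma)) * 100
        assert point.sensitivity == pytest.approx(expected)

    def test_numeric_root_matches_closed_form(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            mu0, mu1 = sorted(rng.uniform(0, 1, 2))
            if mu1 - mu0 < 0.05:
                continue
            dens = ClassDensityModel(
                mu0=mu0, sigma0=rng.uniform(0.05, 0.3),
                mu1=mu1, sigma1=rng.uniform(0.05, 0.3),
            )
            curve = risk_curve(dens, grid_size=20001)
            t_grid = curve.thresholds[curve.equal_error_index()]
            t_closed = equal_error_point(dens).threshold
            grid_step = curve.thresholds[1] - curve.thresholds[0]
            assert abs(t_grid - t_closed) <= grid_step

    def test_label_swap_invariance(self):
        swapped = ClassDensityModel(
            mu0=PLS1_DENS.mu1, sigma0=PLS1_DENS.sigma1,
            mu1=PLS1_DENS.mu0, sigma1=PLS1_DENS.sigma0,
        )
        a = equal_error_point(PLS1_DENS)
        b = equal_error_point(swapped)
        assert a.sensitivity == pytest.approx(b.sensitivity)
        assert a.threshold == pytest.approx(b.threshold)

    def test_signed_sensitivity_orientation(self):
        assert signed_sensitivity(PLS1_DENS) == pytest.approx(
            equal_error_point(PLS1_DENS).sensitivity
        )
        inverted = ClassDensityModel(mu0=0.8, sigma0=0.2, mu1=0.1, sigma1=0.2)
        assert signed_sensitivity(inverted) < 50.0

    def test_coincident_means_degenerate(self):
        dens = ClassDensityModel(mu0=0.5, sigma0=0.1, mu1=0.5, sigma1=0.2)
        with pytest.raises(DegenerateDensityError):
            equal_error_point(dens)


class TestAssignSamples:
    def test_tie_at_threshold_goes_to_class_one(self):
        point = equal_error_point(PLS1_DENS)
        assigned, _ = assign_samples(
            np.array([point.threshold]), point, PLS1_DENS
        )
        assert assigned[0] == 1

    def test_class_means_assigned_to_own_class(self):
        point = equal_error_point(PLS1_DENS)
        assigned, confusion = assign_samples(
            np.array([PLS1_DENS.mu0, PLS1_DENS.mu1]),
            point,
            PLS1_DENS,
            labels=np.array([0, 1]),
        )
        np.testing.assert_array_equal(assigned, [0, 1])
        np.testing.assert_array_equal(confusion, [[1, 0], [0, 1]])

    def test_inverted_orientation(self):
        inverted = ClassDensityModel(mu0=0.8, sigma0=0.15, mu1=0.1, sigma1=0.2)
        point = equal_error_point(inverted)
        assigned, _ = assign_samples(
            np.array([0.85, 0.05]), point, inverted
        )
        np.testing.assert_array_equal(assigned, [0, 1])

    def test_monte_carlo_accuracy_matches_model(self):
        """Empirical accuracy on draws from the densities ~ model sensitivity."""
        rng = np.random.default_rng(9)
        n0, n1 = 36, 14
        point = equal_error_point(PLS1_DENS)
        accs = []
        for _ in range(200):
            y_hat = np.concatenate(
                [
                    rng.normal(PLS1_DENS.mu0, PLS1_DENS.sigma0, n0),
                    rng.normal(PLS1_DENS.mu1, PLS1_DENS.sigma1, n1),
                ]
            )
            labels = np.r_[np.zeros(n0, int), np.ones(n1, int)]
            assigned, confusion = assign_samples(y_hat, point, PLS1_DENS, labels)
            accs.append(np.trace(confusion) / confusion.sum())
        assert abs(np.mean(accs) * 100 - point.sensitivity) < 5.0
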