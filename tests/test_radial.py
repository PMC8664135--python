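import math

import numpy as np
import pytest

from petqa.radial import (
    GaussianFit,
    PolynomialFit,
    RadialProfile,
    bin_profile,
    fit_gaussian,
    fit_polynomial,
    fit_quality,
    gauss_metrics,
    poly_metrics,
    raw_contrast,
    to_radial,
)

from conftest import disc_sample, make_sample


def patch_sample(values_3x3, manual=False):
    rows, cols = np.mgrid[-1:2, -1:2]
    offsets = np.stack([rows.ravel(), cols.ravel()], axis=1).astype(float)
    return make_sample(np.asarray(values_3x3, float).ravel(), offsets, manual=manual)


class TestToRadial:
    def test_3x3_geometry(self):
        vals = [[1, 2, 3], [4, 9, 5], [6, 7, 8]]
        prof = to_radial(patch_sample(vals))
        r = np.sort(prof.r)
        assert np.sum(r == 0) == 1
        assert np.sum(np.isclose(r, 1.0)) == 4
        assert np.sum(np.isclose(r, math.sqrt(2))) == 4

    def test_manual_roi_ignores_interior_max(self):
        vals = [[1, 2, 3], [4, 5, 6], [7, 8, 99]]  # max off-center
        auto = to_radial(patch_sample(vals))
        manual = to_radial(patch_sample(vals, manual=True))
        # manual centers on the ROI center: value 5 sits at r=0
        assert manual.values[np.argmin(np.abs(manual.r))] == 5
        assert auto.values[np.argmin(np.abs(auto.r))] == 99

    def test_signed_mode_symmetric(self):
        prof = to_radial(patch_sample([[1, 2, 1], [2, 9, 2], [1, 2, 1]]), mode="signed")
        assert set(np.round(prof.r, 6)) == set(np.round([-math.sqrt(2), -1, 0, 1, math.sqrt(2)], 6))
        np.testing.assert_allclose(np.sort(prof.r), -np.sort(-prof.r)[::-1])

    def test_max_tie_lowest_row_col(self):
        vals = [[9, 1, 1], [1, 1, 1], [1, 1, 9]]
        prof = to_radial(patch_sample(vals))
        # center must be the (row,col)-lexicographically lowest max: top-left
        assert prof.values[np.argmin(prof.r)] == 9
        assert prof.r.max() == pytest.approx(2 * math.sqrt(2))


class TestPolynomialFit:
    def exact_profile(self, coeffs=(100.0, -2.0, 0.5, -0.01)):
        r = np.linspace(0, 5.2, 60)
        y = np.polynomial.polynomial.polyval(r, coeffs)
        return RadialProfile(r=r, values=y), np.array(coeffs)

    @pytest.mark.parametrize("binned", [False, True])
    def test_exact_cubic_recovery(self, binned):
        prof, expected = self.exact_profile()
        fit = fit_polynomial(prof, binned=binned)
        assert fit.converged
        np.testing.assert_allclose(fit.coeffs, expected, rtol=1e-8, atol=1e-8)

    def test_constant_profile(self):
        prof = RadialProfile(r=np.linspace(0, 5, 40), values=np.full(40, 42.0))
        fit = fit_polynomial(prof, sigma_mode="residual")
        assert fit.F0 == pytest.approx(42.0, abs=1e-9)
        np.testing.assert_allclose(fit.coeffs[1:], 0.0, atol=1e-9)
        np.testing.assert_allclose(fit.sigma, 0.0, atol=1e-6)

    def test_matches_normal_equations_oracle(self):
        """OLS solution equals the brute-force normal-equations solve."""
        rng = np.random.default_rng(21)
        for _ in range(10):
            r = rng.uniform(0, 6, size=rng.integers(10, 120))
            y = rng.normal(42, 5, size=len(r))
            fit = fit_polynomial(RadialProfile(r=r, values=y))
            X = np.vander(r, 4, increasing=True)
            oracle = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose(fit.coeffs, oracle, rtol=1e-8, atol=1e-10)

    def test_too_few_radii_not_converged(self):
        prof = RadialProfile(r=np.array([0, 1, 1, 2.0]), values=np.array([5, 4, 4, 3.0]))
        fit = fit_polynomial(prof)
        assert not fit.converged
        assert poly_metrics(fit, 2.0) == (0.0, 0.0)

    def test_bin_profile_angle_average(self):
        r = np.array([0.0, 1.0, 1.0, 1.0, 1.0, math.sqrt(2)])
        v = np.array([9.0, 1.0, 2.0, 3.0, 4.0, 7.0])
        rb, vb, counts = bin_profile(r, v)
        np.testing.assert_allclose(rb, [0.0, 1.0, math.sqrt(2)])
        np.testing.assert_allclose(vb, [9.0, 2.5, 7.0])
        np.testing.assert_array_equal(counts, [1, 4, 1])


class TestPolyMetrics:
    def make_fit(self, f0, f_rmax, r_max=5.0, sigma0=1.0):
        # cubic through (0, f0) and (r_max, f_rmax) with linear shape
        slope = (f_rmax - f0) / r_max
        return PolynomialFit(
            coeffs=np.array([f0, slope, 0.0, 0.0]),
            sigma=np.array([sigma0, 0.1, 0.1, 0.1]),
            see=1.0, chi2=1.0, converged=True,
        )

    def test_contrast_direct_formula(self):
        contrast, _ = poly_metrics(self.make_fit(100.0, 50.0), 5.0)
        assert contrast == pytest.approx(1.0 / 3.0)

    def test_zero_contrast_when_flat(self):
        contrast, _ = poly_metrics(self.make_fit(80.0, 80.0), 5.0)
        assert contrast == pytest.approx(0.0)

    def test_intercept_snr_formula(self):
        fit = self.make_fit(10.0, 10.0, sigma0=2.0)
        _, snr = poly_metrics(fit, 5.0, snr_mode="intercept")
        assert snr == pytest.approx(25.0)

    def test_amplitude_snr_formula(self):
        fit = self.make_fit(52.0, 42.0, sigma0=2.0)
        _, snr = poly_metrics(fit, 5.0)
        assert snr == pytest.approx(25.0)  # ((52-42)/2)^2

    def test_negative_amplitude_scores_zero(self):
        _, snr = poly_metrics(self.make_fit(40.0, 50.0, sigma0=2.0), 5.0)
        assert snr == 0.0

    def test_nonpositive_denominator_warns_to_zero(self):
        contrast, _ = poly_metrics(self.make_fit(1.0, -2.0), 5.0)
        assert contrast == 0.0


class TestRawContrast:
    def test_direct_formula(self):
        s = make_sample([58.0, 40.0, 33.0, 26.0, 47.0])
        assert raw_contrast(s) == pytest.approx(32.0 / 84.0)

    def test_constant_sample(self):
        assert raw_contrast(make_sample([5.0] * 9)) == 0.0

    def test_all_zero_sample(self):
        assert raw_contrast(make_sample([0.0] * 9)) == 0.0


class TestGaussianFit:
    def signed_profile(self, g0=60.0, g1=0.0, g2=2.0, g3=42.0, noise=None, rng=None):
        s = disc_sample()
        prof = to_radial(s, mode="signed")
        r = prof.r
        y = g0 * np.exp(-(((r - g1) / g2) ** 2)) + g3
        if noise and rng is not None:
            y = y + rng.standard_normal(len(r)) * noise
        return RadialProfile(r=r, values=y, signed=True)

    def test_noiseless_recovery(self):
        fit = fit_gaussian(self.signed_profile())
        assert fit.converged
        np.testing.assert_allclose(fit.params, [60.0, 0.0, 2.0, 42.0], atol=1e-6)

    def test_deterministic_rerun(self):
        rng = np.random.default_rng(3)
        prof = self.signed_profile(noise=4.0, rng=rng)
        f1 = fit_gaussian(prof)
        f2 = fit_gaussian(prof)
        np.testing.assert_array_equal(f1.params, f2.params)
        assert f1.iterations == f2.iterations

    def test_flat_noise_often_fails_and_zeroes_metrics(self):
        rng = np.random.default_rng(11)
        failures = 0
        for _ in range(40):
            s = disc_sample(rng=rng)
            fit = fit_gaussian(to_radial(s, mode="signed"))
            if not fit.converged:
                failures += 1
                assert gauss_metrics(fit) == (0.0, 0.0, 0.0)
        assert failures > 0

    def test_iteration_budget_respected(self):
        rng = np.random.default_rng(5)
        fit = fit_gaussian(self.signed_profile(noise=8.0, rng=rng), max_iter=20)
        assert fit.iterations <= 20

    def test_nonconvergence_ordering_background_vs_lesions(self):
        """Flat noise fails most; small bumps fail less; big bumps converge."""
        rng = np.random.default_rng(42)
        rates = []
        for amplitude in (0.0, 14.0, 58.0):
            fails = 0
            reps = 30
            for _ in range(reps):
                s = disc_sample(rng=rng)
                bump = amplitude * np.exp(
                    -(np.hypot(s.offsets[:, 0], s.offsets[:, 1]) / 2.0) ** 2
                )
                s.values = s.values + bump
                if not fit_gaussian(to_radial(s, mode="signed")).converged:
                    fails += 1
            rates.append(fails / reps)
        assert rates[0] >= rates[1] >= rates[2]
        assert rates[0] > rates[2]


class TestGaussMetrics:
    def test_direct_formulas(self):
        fit = GaussianFit(
            params=np.array([60.0, 0.0, 2.0, 42.0]),
            sigma=np.array([5.0, 1.0, 1.0, 1.0]),
            see=1.0, chi2=1.0, converged=True,
        )
        contrast, snr, integral = gauss_metrics(fit)
        assert contrast == pytest.approx(18.0 / 102.0)
        assert snr == pytest.approx(144.0)
        assert integral == pytest.approx(36.0)

    def test_nonconverged_zeros(self):
        assert gauss_metrics(GaussianFit()) == (0.0, 0.0, 0.0)


class TestFitQuality:
    def test_noiseless_fit_is_clean(self):
        r = np.linspace(0, 5.2, 60)
        y = 100 - 2 * r + 0.5 * r**2 - 0.01 * r**3
        fit = fit_polynomial(RadialProfile(r=r, values=y), sigma_mode="residual")
        q = fit_quality(fit)
        assert q.see == pytest.approx(0.0, abs=1e-8)
        assert q.error_ratio == pytest.approx(0.0, abs=1e-8)

    def test_chi2_grows_with_signal_range(self):
        """Fit residuals (hence chi-square) are larger for big lesions whose
        count range is wide than for uniform noise, as expected."""
        rng = np.random.default_rng(8)
        chi_flat, chi_big = [], []
        for _ in range(15):
            flat = disc_sample(rng=rng)
            chi_flat.append(fit_polynomial(to_radial(flat)).chi2)
            big = disc_sample(rng=rng)
            r = np.hypot(big.offsets[:, 0], big.offsets[:, 1])
            big.values = big.values + 58.0 * np.exp(-((r / 3.2) ** 2))
            chi_big.append(fit_polynomial(to_radial(big)).chi2)
        assert np.mean(chi_big) > np.mean(chi_flat)
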