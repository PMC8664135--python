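import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petqa.texture import (
    GLCM_FEATURE_NAMES,
    GLCM_OFFSETS,
    glcm_features,
    glcm_matrix,
    histogram_features,
    normalize_features,
    qq_metrics,
)

from conftest import disc_sample, make_sample


def grid_sample(patch):
    patch = np.asarray(patch, float)
    rows, cols = np.mgrid[0 : patch.shape[0], 0 : patch.shape[1]]
    offsets = np.stack(
        [rows.ravel() - patch.shape[0] / 2, cols.ravel() - patch.shape[1] / 2], axis=1
    )
    return make_sample(patch.ravel(), offsets)


class TestQQ:
    def test_identity_on_unity_line(self):
        rng = np.random.default_rng(0)
        v = rng.normal(42, 5, 90)
        res = qq_metrics(make_sample(v), make_sample(v.copy()))
        assert res.slope == pytest.approx(1.0, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-9)
        assert not res.slope_deviates and not res.intercept_deviates

    def test_scaled_target_doubles_slope(self):
        rng = np.random.default_rng(1)
        b = rng.normal(42, 5, 80)
        res = qq_metrics(make_sample(2 * b), make_sample(b))
        assert res.slope == pytest.approx(2.0, abs=1e-9)
        assert res.intercept == pytest.approx(0.0, abs=1e-6)
        assert res.slope_deviates

    def test_shifted_target_moves_intercept(self):
        rng = np.random.default_rng(2)
        b = rng.normal(42, 5, 80)
        res = qq_metrics(make_sample(b + 10.0), make_sample(b))
        assert res.slope == pytest.approx(1.0, abs=1e-9)
        assert res.intercept == pytest.approx(10.0, abs=1e-6)
        assert res.intercept_deviates and not res.slope_deviates

    def test_unequal_sizes_interpolated(self):
        rng = np.random.default_rng(3)
        res = qq_metrics(
            make_sample(rng.normal(50, 6, 120)), make_sample(rng.normal(42, 5, 85))
        )
        assert len(res.background_q) == 85
        assert np.all(np.diff(res.background_q) >= 0)
        assert np.all(np.diff(res.target_q) >= 0)

    def test_zero_variance_background_errors(self):
        with pytest.raises(ValueError, match="variance"):
            qq_metrics(make_sample(np.arange(20.0)), make_sample(np.full(20, 7.0)))

    def test_too_small_samples_error(self):
        with pytest.raises(ValueError):
            qq_metrics(make_sample(np.arange(5.0)), make_sample(np.arange(20.0)))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1e4, width=32),
            min_size=12,
            max_size=60,
            unique=True,
        )
    )
    def test_property_self_qq_on_unity_line(self, values):
        res = qq_metrics(make_sample(values), make_sample(list(values)))
        assert res.slope == pytest.approx(1.0, abs=1e-9)
        assert res.intercept == pytest.approx(0.0, abs=1e-6 * (1 + max(values)))


def brute_force_glcm(patch, levels, offsets=GLCM_OFFSETS):
    """Enumeration oracle: walk every pixel pair explicitly."""
    patch = np.asarray(patch, float)
    valid = np.isfinite(patch)
    vals = patch[valid]
    vmin, vmax = vals.min(), vals.max()
    if vmax > vmin:
        q = np.clip(np.floor((patch - vmin) / (vmax - vmin) * levels), 0, levels - 1)
    else:
        q = np.zeros_like(patch)
    M = np.zeros((levels, levels))
    nrow, ncol = patch.shape
    for i, j in itertools.product(range(nrow), range(ncol)):
        if not valid[i, j]:
            continue
        for dr, dc in offsets:
            a, b = i + dr, j + dc
            if 0 <= a < nrow and 0 <= b < ncol and valid[a, b]:
                M[int(q[i, j]), int(q[a, b])] += 1
                M[int(q[a, b]), int(q[i, j])] += 1
    return M / M.sum() if M.sum() else M


class TestGLCM:
    def test_constant_patch_degenerate_contract(self):
        f = glcm_features(grid_sample(np.full((5, 5), 3.0)))
        assert (f.energy, f.entropy, f.inertia, f.homogeneity, f.correlation) == (
            1.0, 0.0, 0.0, 1.0, 0.0,
        )

    def test_checkerboard_against_hand_oracle(self):
        board = np.indices((4, 4)).sum(axis=0) % 2 * 10.0
        P = glcm_matrix(board, levels=2, offsets=((0, 1), (1, 0)))
        # E/S neighbors always differ: all mass off-diagonal, split evenly
        np.testing.assert_allclose(P, [[0.0, 0.5], [0.5, 0.0]])
        f = glcm_features(grid_sample(board), levels=2, offsets=((0, 1), (1, 0)))
        assert f.energy == pytest.approx(0.5)
        assert f.entropy == pytest.approx(math.log(2))
        assert f.inertia == pytest.approx(1.0)
        assert f.homogeneity == pytest.approx(0.5)
        assert f.correlation == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle_on_small_patches(self, seed):
        rng = np.random.default_rng(seed)
        shape = rng.integers(3, 7, size=2)
        patch = rng.normal(42, 5, size=tuple(shape))
        if seed % 2:  # knock out some pixels like a circular ROI boundary
            patch[tuple(rng.integers(0, shape[k]) for k in range(2))] = np.nan
        levels = int(rng.integers(2, 9))
        P = glcm_matrix(patch, levels=levels)
        oracle = brute_force_glcm(patch, levels)
        np.testing.assert_allclose(P, oracle, atol=1e-12)

    def test_matrix_symmetric_and_normalized(self):
        rng = np.random.default_rng(9)
        s = disc_sample(rng=rng)
        from petqa.texture import _sample_to_patch

        P = glcm_matrix(_sample_to_patch(s))
        assert P.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(P, P.T)

    def test_feature_ranges(self):
        rng = np.random.default_rng(10)
        f = glcm_features(disc_sample(rng=rng))
        assert 0 < f.energy <= 1
        assert f.entropy >= 0
        assert 0 < f.homogeneity <= 1
        assert abs(f.correlation) <= 1 + 1e-9


class TestNormalizeFeatures:
    def table(self, values):
        return pd.DataFrame(
            {"roi_label": [f"r{i}" for i in range(len(values))], "energy": values}
        )

    def test_divides_by_max(self):
        out = normalize_features(self.table([2.0, 4.0, 8.0]), columns=["energy"])
        np.testing.assert_allclose(out["energy"], [0.25, 0.5, 1.0])

    def test_single_nonzero_gets_one(self):
        out = normalize_features(self.table([0.0, 3.0]), columns=["energy"])
        np.testing.assert_allclose(out["energy"], [0.0, 1.0])

    def test_scale_invariance(self):
        base = self.table([1.5, 2.5, 5.0])
        scaled = self.table([15.0, 25.0, 50.0])
        np.testing.assert_allclose(
            normalize_features(base, columns=["energy"])["energy"],
            normalize_features(scaled, columns=["energy"])["energy"],
        )

    def test_all_zero_column_left_alone(self):
        out = normalize_features(self.table([0.0, 0.0]), columns=["energy"])
        np.testing.assert_array_equal(out["energy"], [0.0, 0.0])

    def test_reference_label_restriction(self):
        t = pd.DataFrame({"roi_label": ["hot-8", "cold-air"], "energy": [2.0, 8.0]})
        out = normalize_features(t, columns=["energy"], reference_labels=["hot-8"])
        np.testing.assert_allclose(out["energy"], [1.0, 4.0])

    def test_needs_two_rois(self):
        with pytest.raises(ValueError):
            normalize_features(self.table([1.0]), columns=["energy"])


class TestHistogram:
    def test_symmetric_sample_zero_skew(self):
        v = np.concatenate([np.linspace(-3, 3, 41)]) + 42
        h = histogram_features(make_sample(v), background_ref=42.0)
        assert h.skewness == pytest.approx(0.0, abs=1e-12)

    def test_skewness_matches_moment_oracle(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        m = v.mean()
        g1 = np.mean((v - m) ** 3) / np.mean((v - m) ** 2) ** 1.5
        h = histogram_features(make_sample(v), background_ref=4.0)
        assert h.skewness == pytest.approx(g1, rel=1e-12)
        g2 = np.mean((v - m) ** 4) / np.mean((v - m) ** 2) ** 2 - 3.0
        assert h.kurtosis == pytest.approx(g2, rel=1e-12)
        assert h.variance == pytest.approx(v.var(ddof=1))

    def test_background_suv_mean_is_unity(self):
        rng = np.random.default_rng(4)
        v = rng.normal(42, 4, 90)
        h = histogram_features(make_sample(v), background_ref=float(v.mean()))
        assert h.suv_mean == pytest.approx(1.0, abs=1e-15)
        assert h.suv_max >= h.suv_mean

    def test_small_sample_errors(self):
        with pytest.raises(ValueError):
            histogram_features(make_sample([1.0, 2.0, 3.0]), background_ref=1.0)

    def test_nonpositive_reference_errors(self):
        with pytest.raises(ValueError):
            histogram_features(make_sample([1.0] * 5), background_ref=0.0)
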