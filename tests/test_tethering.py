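"""Intermodal tethering: pairwise R2, residuals, weighted residual map."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedgrad.datatypes import DegenerateInputError, PairResidualSet
from seedgrad.nulls import variogram_surrogates
from seedgrad.tethering import (
    coefficient_of_variation,
    pair_residuals,
    pairwise_r2,
    subregion_contrast,
    weighted_residual_map,
)


class TestPairwiseR2:
    def test_component_vs_itself_is_one(self, rng):
        g = rng.standard_normal((30, 2))
        r2 = pairwise_r2(g, g)
        assert np.allclose(np.diag(r2), 1.0)

    def test_orthogonalized_component_gives_zero(self, rng):
        a = rng.standard_normal(50)
        b = rng.standard_normal(50)
        b = b - b.mean() - (b - b.mean()) @ (a - a.mean()) / np.sum(
            (a - a.mean()) ** 2
        ) * (a - a.mean())
        r2 = pairwise_r2(a[:, None], b[:, None])
        assert r2[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_six_by_four_selection_yields_24_pairs(self, rng):
        r2 = pairwise_r2(rng.standard_normal((40, 6)), rng.standard_normal((40, 4)))
        assert r2.shape == (6, 4)
        assert r2.size == 24

    def test_constant_component_rejected(self, rng):
        g = rng.standard_normal((20, 2))
        bad = g.copy()
        bad[:, 1] = 7.0
        with pytest.raises(DegenerateInputError):
            pairwise_r2(bad, g)


class TestPairResiduals:
    def test_identical_components_leave_zero_residuals(self, rng):
        a = rng.standard_normal(40)
        res = pair_residuals(a, a.copy())
        assert np.allclose(res.residuals, 0.0, atol=1e-12)
        assert res.r_squared == pytest.approx(1.0)

    def test_orthogonal_predictor_returns_standardized_outcome(self, rng):
        a = rng.standard_normal(60)
        b = rng.standard_normal(60)
        am, bm = a - a.mean(), b - b.mean()
        b_orth = bm - (bm @ am) / (am @ am) * am
        res = pair_residuals(a, b_orth)
        za = (a - a.mean()) / a.std()
        assert np.allclose(res.residuals, za, atol=1e-10)

    def test_matches_bruteforce_normal_equations(self, rng):
        """Residuals agree with an explicit (X'X)^-1 X'y least-squares fit on
        the standardized variables."""
        a = rng.standard_normal(50)
        b = rng.standard_normal(50)
        res = pair_residuals(a, b)
        za = (a - a.mean()) / a.std()
        zb = (b - b.mean()) / b.std()
        X = np.column_stack([np.ones(50), zb])
        beta = np.linalg.solve(X.T @ X, X.T @ za)
        assert np.allclose(res.residuals, za - X @ beta, atol=1e-10)

    def test_residuals_centered_and_uncorrelated_with_predictor(self, rng):
        a, b = rng.standard_normal(45), rng.standard_normal(45)
        res = pair_residuals(a, b)
        zb = (b - b.mean()) / b.std()
        assert abs(res.residuals.sum()) < 1e-10
        assert abs(res.residuals @ zb) < 1e-10

    def test_unexplained_variance_symmetric_in_modalities(self, rng):
        """After standardization the regression direction does not change the
        total unexplained variance (n * (1 - r^2)) or the shared variance."""
        a, b = rng.standard_normal(45), rng.standard_normal(45)
        fwd = pair_residuals(a, b)
        rev = pair_residuals(b, a)
        assert np.sum(fwd.residuals**2) == pytest.approx(
            np.sum(rev.residuals**2), abs=1e-10
        )
        assert fwd.r_squared == pytest.approx(rev.r_squared, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            pair_residuals(np.ones(10), np.arange(10.0))


def _pair(residuals, weight, k=0):
    return PairResidualSet(
        pair_index=k, structural_index=0, functional_index=0,
        residuals=np.asarray(residuals, float), weight=weight, r_squared=0.5,
    )


class TestWeightedResidualMap:
    def test_zero_residuals_give_zero_map(self):
        pairs = [_pair(np.zeros(5), 0.3, k) for k in range(4)]
        assert np.allclose(weighted_residual_map(pairs).values, 0.0)

    def test_single_pair_direct_formula(self):
        wrm = weighted_residual_map([_pair([1.0, -2.0, 0.0], 0.45)])
        assert np.allclose(wrm.values, [0.45, 1.8, 0.0])
        assert wrm.n_pairs == 1

    def test_matches_bruteforce_sum(self, rng):
        pairs = [_pair(rng.standard_normal(7), w, k)
                 for k, w in enumerate([0.2, 0.5, 0.05])]
        expected = sum(p.weight * p.residuals**2 for p in pairs)
        assert np.allclose(weighted_residual_map(pairs).values, expected, atol=1e-12)

    def test_additive_over_pair_subsets(self, rng):
        pairs = [_pair(rng.standard_normal(6), 0.1 + 0.1 * k, k) for k in range(5)]
        full = weighted_residual_map(pairs).values
        split = (
            weighted_residual_map(pairs[:2]).values
            + weighted_residual_map(pairs[2:]).values
        )
        assert np.allclose(full, split, atol=1e-12)

    def test_normalized_weights_sum_to_one(self, rng):
        pairs = [_pair(np.ones(3), w, k) for k, w in enumerate([1.0, 3.0])]
        wrm = weighted_residual_map(pairs, normalize_weights=True)
        assert np.allclose(wrm.values, 1.0)  # sum w_k = 1, residuals^2 = 1

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="voxel count"):
            weighted_residual_map([_pair(np.zeros(4), 0.3), _pair(np.zeros(5), 0.3, 1)])


class TestCoefficientOfVariation:
    def test_constant_positive_vector_is_zero(self):
        assert coefficient_of_variation(np.full(10, 3.3)) == pytest.approx(0.0)

    def test_formula(self):
        v = np.array([2.0, 6.0])  # mean 4, sd 2 (with ddof=1: 2.828)
        expected = 100 * v.std(ddof=1) / v.mean()
        assert coefficient_of_variation(v) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.1, 100.0))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(7)
        v = rng.uniform(0.5, 2.0, 30)
        assert coefficient_of_variation(c * v) == pytest.approx(
            coefficient_of_variation(v), rel=1e-9
        )

    def test_near_zero_mean_rejected(self):
        with pytest.raises(DegenerateInputError):
            coefficient_of_variation(np.array([-1.0, 1.0]))


@pytest.fixture(scope="module")
def voxel_grid():
    from seedgrad.synthetic import make_seed_region

    region = make_seed_region((5, 5, 5), subregion_split=0.5, seed=3)
    coords = region.coords_mm
    dist = np.linalg.norm(coords[:, None] - coords[None], axis=2)
    return region, dist


class TestSubregionContrast:
    def test_constant_map_has_zero_mean_difference(self, voxel_grid, rng):
        region, dist = voxel_grid
        smooth = np.exp(-0.5 * (dist / 1.5) ** 2) @ rng.standard_normal(125)
        ens = variogram_surrogates(smooth, dist, n=49, seed=5)
        obs, p, nd = subregion_contrast(
            np.full(125, 2.0), region.subregion_labels, "mean_diff", ens
        )
        assert obs == pytest.approx(0.0)
        assert p >= 1.0 - 1.0 / (nd.n_perm + 1) - 1e-12

    def test_planted_step_detected(self, voxel_grid, rng):
        """A 3-sd step between subregions is significant against 1000
        variogram surrogates."""
        region, dist = voxel_grid
        base = np.exp(-0.5 * (dist / 1.5) ** 2) @ rng.standard_normal(125)
        base = (base - base.mean()) / base.std()
        planted = base + 3.0 * (region.subregion_labels == "A")
        ens = variogram_surrogates(planted, dist, n=1000, seed=6)
        obs, p, _ = subregion_contrast(
            planted, region.subregion_labels, "mean_diff", ens
        )
        assert p < 0.05

    def test_pvalue_bounds_and_label_swap_invariance(self, voxel_grid, rng):
        region, dist = voxel_grid
        vals = np.exp(-0.5 * (dist / 1.5) ** 2) @ rng.standard_normal(125)
        ens = variogram_surrogates(vals, dist, n=99, seed=8)
        swapped = np.where(region.subregion_labels == "A", "B", "A")
        _, p1, _ = subregion_contrast(vals, region.subregion_labels, "mean_diff", ens)
        _, p2, _ = subregion_contrast(vals, swapped, "mean_diff", ens)
        assert 1.0 / 100 <= p1 <= 1.0
        assert p1 == pytest.approx(p2)

    def test_single_group_rejected(self, voxel_grid, rng):
        region, dist = voxel_grid
        vals = rng.standard_normal(125)
        ens = variogram_surrogates(vals, dist, n=9, seed=9)
        with pytest.raises(ValueError, match="two"):
            subregion_contrast(vals, np.full(125, "A"), "mean_diff", ens)
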