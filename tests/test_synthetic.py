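"""Synthetic-data generators: geometry, planted truth, connectomes."""

import numpy as np
import pytest

from seedgrad import synthetic
from seedgrad.connectome import functional_connectivity
from seedgrad.gradients import DiffusionGradients
from seedgrad.synthetic import (
    make_autocorrelated_map,
    make_network_labels,
    make_parcellation,
    make_seed_region,
    make_sphere_surface,
    make_truth,
    simulate_connectomes,
    simulate_timeseries,
)


class TestSphereSurface:
    def test_icosahedron_counts(self):
        surf = make_sphere_surface(0)
        assert surf.n_vertices == 12
        assert surf.n_faces == 20

    def test_one_subdivision_counts(self):
        # each subdivision multiplies faces by 4; V follows from Euler's formula
        surf = make_sphere_surface(1)
        assert surf.n_vertices == 42
        assert surf.n_faces == 80

    def test_vertices_on_unit_sphere(self):
        surf = make_sphere_surface(2)
        norms = np.linalg.norm(surf.vertices, axis=1)
        assert np.abs(norms - 1.0).max() < 1e-12

    def test_medial_wall_cap_fraction(self):
        surf = make_sphere_surface(3, medial_wall_fraction=0.05)
        frac = surf.medial_wall.mean()
        assert 0.02 <= frac <= 0.08

    def test_negative_subdivisions_rejected(self):
        with pytest.raises(ValueError):
            make_sphere_surface(-1)


class TestParcellation:
    def test_two_parcels_on_icosahedron_cover_all_vertices(self):
        surf = make_sphere_surface(0)
        parc = make_parcellation(surf, 2, seed=0)
        assert set(parc.labels.tolist()) == {0, 1}
        assert len(parc.labels) == 12

    def test_same_seed_is_deterministic(self, sphere3):
        a = make_parcellation(sphere3, 12, seed=5)
        b = make_parcellation(sphere3, 12, seed=5)
        assert np.array_equal(a.labels, b.labels)

    def test_parcels_partition_unmasked_vertices(self):
        surf = make_sphere_surface(3, medial_wall_fraction=0.05)
        parc = make_parcellation(surf, 20, seed=1)
        unmasked = surf.unmasked()
        assert (parc.labels[unmasked] >= 0).all()
        assert (parc.labels[~unmasked] == -1).all()
        sizes = [len(parc.members(p)) for p in parc.parcel_ids]
        assert sum(sizes) == unmasked.sum()

    def test_parcels_are_contiguous(self, sphere3):
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        parc = make_parcellation(sphere3, 15, seed=3)
        edges = sphere3.edges()
        for pid in parc.parcel_ids:
            members = parc.members(pid)
            index = {v: i for i, v in enumerate(members)}
            inner = [
                (index[a], index[b])
                for a, b in edges
                if a in index and b in index
            ]
            rows = [e[0] for e in inner] + [e[1] for e in inner]
            cols = [e[1] for e in inner] + [e[0] for e in inner]
            g = coo_matrix(
                (np.ones(len(rows)), (rows, cols)),
                shape=(len(members), len(members)),
            )
            n_comp, _ = connected_components(g, directed=False)
            assert n_comp == 1

    def test_too_many_parcels_rejected(self, sphere3):
        with pytest.raises(ValueError, match="exceeds"):
            make_parcellation(sphere3, sphere3.n_vertices + 1, seed=0)

    def test_network_labels_cover_parcels(self, parcellation100):
        nets = make_network_labels(parcellation100, 7, seed=4)
        assert nets.shape == (100,)
        assert set(np.unique(nets)) == set(range(7))


class TestSeedRegion:
    def test_split_rounding_rule(self):
        region = make_seed_region((5, 5, 5), subregion_split=0.4, seed=0)
        assert (region.subregion_labels == "A").sum() == 50

    def test_coordinates_distinct(self):
        region = make_seed_region((4, 4, 4), seed=0)
        assert len(np.unique(region.coords_mm, axis=0)) == region.n_voxels

    def test_labels_partition_voxels(self):
        region = make_seed_region((5, 5, 5), subregion_split=0.3, seed=0)
        assert set(region.subregion_labels.tolist()) == {"A", "B"}
        assert len(region.subregion_labels) == 125

    def test_split_follows_planted_axis(self):
        region = make_seed_region((5, 5, 5), subregion_split=0.5, seed=0)
        axis = synthetic.planted_axis_values(region.coords_mm)
        assert axis[region.subregion_labels == "A"].mean() < axis[
            region.subregion_labels == "B"
        ].mean()

    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            make_seed_region((2, 2, 2), seed=0)


class TestSimulateTimeseries:
    def test_shapes(self, parcellation100, seed_region125, truth_coupled):
        vox, par = simulate_timeseries(
            seed_region125, parcellation100, truth_coupled, n_timepoints=10, seed=0
        )
        assert vox.shape == (125, 10)
        assert par.shape == (100, 10)

    def test_same_seed_identical(self, parcellation100, seed_region125, truth_coupled):
        a = simulate_timeseries(
            seed_region125, parcellation100, truth_coupled, n_timepoints=20, seed=9
        )
        b = simulate_timeseries(
            seed_region125, parcellation100, truth_coupled, n_timepoints=20, seed=9
        )
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_unit_weight_reproduces_parcel_series(self, rng):
        """A voxel mixing exactly one parcel with weight 1 and no residual
        noise is that parcel's series."""
        from seedgrad.synthetic import _mix_voxel_series

        parcel_ts = rng.standard_normal((3, 40))
        target = np.array([[0.0, 1.0, 0.0]])
        vox = _mix_voxel_series(target, parcel_ts, noise_sd=0.0, rng=rng)
        assert np.allclose(vox[0], parcel_ts[1], atol=1e-12)

    def test_nonzero_variance(self, parcellation100, seed_region125, truth_coupled):
        vox, par = simulate_timeseries(
            seed_region125, parcellation100, truth_coupled, n_timepoints=50, seed=1
        )
        assert (vox.std(axis=1) > 0).all()
        assert (par.std(axis=1) > 0).all()

    def test_too_few_timepoints_rejected(
        self, parcellation100, seed_region125, truth_coupled
    ):
        with pytest.raises(ValueError):
            simulate_timeseries(
                seed_region125, parcellation100, truth_coupled, n_timepoints=5, seed=0
            )


class TestSimulateConnectomes:
    def test_noisefree_subjects_identical(
        self, parcellation100, seed_region125, truth_coupled
    ):
        s, f, _ = simulate_connectomes(
            seed_region125, parcellation100, truth_coupled, noise_sd=0.0, n_subjects=2
        )
        assert np.array_equal(s[0].values, s[1].values)
        assert np.array_equal(f[0].values, f[1].values)
        r = np.corrcoef(s[0].values.ravel(), s[1].values.ravel())[0, 1]
        assert r > 0.99

    def test_noisy_subjects_share_signal(
        self, parcellation100, seed_region125, truth_coupled
    ):
        # Poisson count noise caps the attainable inter-subject correlation
        # at mean counts of ~50, so the bound is looser than the exact
        # noise-free case above
        s, _, _ = simulate_connectomes(
            seed_region125, parcellation100, truth_coupled,
            noise_sd=0.05, n_subjects=2, n_timepoints=64,
        )
        r = np.corrcoef(s[0].values.ravel(), s[1].values.ravel())[0, 1]
        assert r > 0.75

    def test_full_coupling_aligns_modal_gradients(self, noisefree_connectomes):
        s, f = noisefree_connectomes
        g_s = DiffusionGradients(n_components=3).fit(s).gradients_[:, 0]
        g_f = DiffusionGradients(n_components=3).fit(f).gradients_[:, 0]
        assert abs(np.corrcoef(g_s, g_f)[0, 1]) > 0.99

    def test_functional_entries_bounded(
        self, parcellation100, seed_region125, truth_coupled
    ):
        _, f, _ = simulate_connectomes(
            seed_region125, parcellation100, truth_coupled,
            noise_sd=0.5, n_subjects=1, n_timepoints=64,
        )
        assert np.abs(f[0].values).max() <= 1.0

    def test_structural_counts_nonnegative_integers_when_noisy(
        self, parcellation100, seed_region125, truth_coupled
    ):
        s, _, _ = simulate_connectomes(
            seed_region125, parcellation100, truth_coupled,
            noise_sd=0.2, n_subjects=1, n_timepoints=64,
        )
        vals = s[0].values
        assert (vals >= 0).all()
        assert np.array_equal(vals, np.round(vals))

    def test_sample_correlation_approaches_target(
        self, parcellation100, seed_region125, truth_coupled
    ):
        """Pearson correlations of simulated series concentrate around the
        population target the noise-free limit returns."""
        _, f0, _ = simulate_connectomes(
            seed_region125, parcellation100, truth_coupled, noise_sd=0.0, n_subjects=1
        )
        vox, par = simulate_timeseries(
            seed_region125, parcellation100, truth_coupled,
            n_timepoints=4000, seed=11, noise_sd=0.0,
        )
        sample = functional_connectivity(vox, par).values
        err = np.abs(sample - f0[0].values)
        assert np.median(err) < 0.03


class TestAutocorrelatedMap:
    def test_tiny_length_approaches_white_noise(self, parcellation100):
        pm = make_autocorrelated_map(parcellation100, 1e-4, seed=0)
        cent = parcellation100.centroids
        d = np.arccos(np.clip(cent @ cent.T, -1, 1))
        np.fill_diagonal(d, np.inf)
        nearest = d.argmin(axis=1)
        lag1 = np.corrcoef(pm.values, pm.values[nearest])[0, 1]
        assert abs(lag1) < 0.25

    def test_independent_seeds_uncorrelated(self, parcellation100):
        """Monte Carlo over 500 draws: |r| < 0.2 in at least 95% of pairs."""
        within = 0
        n_draws = 500
        for i in range(n_draws):
            a = make_autocorrelated_map(parcellation100, 0.1, seed=10_000 + 2 * i)
            b = make_autocorrelated_map(parcellation100, 0.1, seed=10_000 + 2 * i + 1)
            r = np.corrcoef(a.values, b.values)[0, 1]
            within += abs(r) < 0.2
        assert within / n_draws >= 0.95

    def test_same_seed_identical(self, parcellation100):
        a = make_autocorrelated_map(parcellation100, 0.5, seed=3)
        b = make_autocorrelated_map(parcellation100, 0.5, seed=3)
        assert np.array_equal(a.values, b.values)

    def test_autocorrelation_increases_with_length(self, parcellation100):
        cent = parcellation100.centroids
        d = np.arccos(np.clip(cent @ cent.T, -1, 1))
        np.fill_diagonal(d, np.inf)
        nearest = d.argmin(axis=1)
        lags = []
        for ell in (0.05, 0.8):
            vals = np.mean(
                [
                    np.corrcoef(
                        (m := make_autocorrelated_map(parcellation100, ell, seed=s)).values,
                        m.values[nearest],
                    )[0, 1]
                    for s in range(30)
                ]
            )
            lags.append(vals)
        assert lags[1] > lags[0]

    def test_bad_length_rejected(self, parcellation100):
        with pytest.raises(ValueError):
            make_autocorrelated_map(parcellation100, 0.0, seed=0)


class TestTruth:
    def test_truth_fields_valid(self, seed_region125, parcellation100):
        t = make_truth(seed_region125, parcellation100, 0.5, seed=2)
        assert t.planted_gradient.shape == (125,)
        assert t.branch_field.shape == (100,)
        assert 0.0 <= t.intermodal_coupling <= 1.0

    def test_invalid_coupling_rejected(self, seed_region125, parcellation100):
        with pytest.raises(ValueError):
            make_truth(seed_region125, parcellation100, 1.5, seed=2)
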