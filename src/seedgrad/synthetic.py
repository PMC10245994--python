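"""Synthetic inputs with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, not the physics of any imaging modality:

* a spherical "cortex" (icosphere) with a contiguous parcellation and an
  optional polar-cap medial-wall analog;
* a small 3-D voxel grid as the seed region, with a planted 1-D spatial
  gradient along an oblique axis and two subregions split along that axis;
* a structural connectome whose expected streamline counts are bilinear in
  (planted gradient x smooth parcel profile), with Poisson counts and
  per-subject log-normal rate jitter away from the noise-free limit;
* a functional connectome realized through latent parcel timeseries mixed
  into voxel timeseries, whose population voxel-parcel correlation is
  proportional to the same bilinear field, with the shared fraction of
  gradient variance between modalities set by ``intermodal_coupling``;
* spatially autocorrelated scalar parcel maps (myelin-like / tracer-like
  covariates and null-calibration inputs).

In the exact noise-free limit (``noise_sd = 0``) both connectomes are
returned as their deterministic population expectations (real-valued counts,
population correlations), so that every downstream stage has a closed-form
target; sampling noise enters only through ``noise_sd`` and finite
timeseries length.
"""

from __future__ import annotations

from typing import List, Optional, Tuple, Union

import numpy as np
import trimesh

from .connectome import functional_connectivity, rescale01
from .datatypes import (
    ConnectivityMatrix,
    Parcellation,
    ParcelMap,
    SeedRegion,
    SyntheticTruth,
    TriangulatedSurface,
)

__all__ = [
    "make_sphere_surface",
    "make_parcellation",
    "make_network_labels",
    "make_seed_region",
    "make_truth",
    "simulate_timeseries",
    "simulate_connectomes",
    "make_autocorrelated_map",
]

# Oblique unit axis defining the planted gradient; deliberately not aligned
# with a single coordinate so grid ties are broken and all three coordinates
# carry signal.
_PLANTED_AXIS = np.array([1.0, 0.45, 0.2])
_PLANTED_AXIS = _PLANTED_AXIS / np.linalg.norm(_PLANTED_AXIS)

# Connectome field parameters (see docs/methods.md): expected structural
# counts are BASE_COUNT * (1 + GAIN * u * c) with voxel loading u in
# [0.2, 1] and parcel profile c in [-1, 1], spanning roughly an order of
# magnitude as streamline counts do; the functional target correlation is
# proportional to the same bilinear field.
_BASE_COUNT = 50.0
_GAIN = 0.9
_FUNC_ROW_NORM = 0.9  # max L2 norm of a voxel's target correlation row
# Fraction of parcels forming the strongly-connected "hub" set of every
# profile; their values are separated from the rest by a clear gap, giving
# the heavy-tailed target distribution streamline counts show in practice.
_PROFILE_TOP_FRACTION = 0.1


def make_sphere_surface(
    n_subdivisions: int, medial_wall_fraction: float = 0.0
) -> TriangulatedSurface:
    """Unit icosphere: icosahedron subdivided ``n_subdivisions`` times.

    ``medial_wall_fraction`` masks that fraction of vertices as a polar cap
    (the synthetic analog of the medial wall).
    """
    if n_subdivisions < 0:
        raise ValueError("n_subdivisions must be >= 0")
    mesh = trimesh.creation.icosphere(subdivisions=n_subdivisions)
    vertices = np.asarray(mesh.vertices, dtype=float)
    vertices = vertices / np.linalg.norm(vertices, axis=1, keepdims=True)
    mask = None
    if medial_wall_fraction > 0:
        z = vertices[:, 2]
        cut = np.quantile(z, 1.0 - medial_wall_fraction)
        mask = z > cut
    return TriangulatedSurface(
        vertices=vertices, faces=np.asarray(mesh.faces, dtype=int), medial_wall=mask
    )


def _vertex_neighbors(surface: TriangulatedSurface) -> List[np.ndarray]:
    nbrs = [[] for _ in range(surface.n_vertices)]
    for a, b in surface.edges():
        nbrs[a].append(b)
        nbrs[b].append(a)
    return [np.array(sorted(n), dtype=int) for n in nbrs]


def make_parcellation(
    surface: TriangulatedSurface, n_parcels: int, seed: int = 0
) -> Parcellation:
    """Contiguous parcels grown from random seed vertices.

    Multi-source breadth-first region growing over the vertex adjacency
    graph with round-robin expansion; ties broken by vertex index.  Masked
    (medial-wall) vertices keep label -1.
    """
    unmasked = np.flatnonzero(surface.unmasked())
    if n_parcels < 2:
        raise ValueError("n_parcels must be >= 2")
    if n_parcels > unmasked.size:
        raise ValueError(
            f"n_parcels={n_parcels} exceeds the {unmasked.size} unmasked vertices"
        )
    rng = np.random.default_rng(seed)
    seeds = rng.choice(unmasked, size=n_parcels, replace=False)
    labels = np.full(surface.n_vertices, -1, dtype=int)
    labels[seeds] = np.arange(n_parcels)
    nbrs = _vertex_neighbors(surface)
    allowed = surface.unmasked()
    frontiers = [[int(s)] for s in seeds]
    while any(frontiers):
        for p in range(n_parcels):
            new_frontier = []
            for v in frontiers[p]:
                for u in nbrs[v]:
                    if allowed[u] and labels[u] == -1:
                        labels[u] = p
                        new_frontier.append(int(u))
            frontiers[p] = sorted(new_frontier)
    # isolated unmasked vertices (possible only on disconnected remainders):
    # assign to the nearest parcel centroid
    orphan = allowed & (labels == -1)
    if orphan.any():
        cents = np.array(
            [surface.vertices[labels == p].mean(axis=0) for p in range(n_parcels)]
        )
        for v in np.flatnonzero(orphan):
            labels[v] = int(
                np.argmin(np.linalg.norm(cents - surface.vertices[v], axis=1))
            )
    parcel_ids = np.arange(n_parcels)
    centroids = np.array(
        [surface.vertices[labels == p].mean(axis=0) for p in parcel_ids]
    )
    centroids = centroids / np.linalg.norm(centroids, axis=1, keepdims=True)
    return Parcellation(labels=labels, parcel_ids=parcel_ids, centroids=centroids)


def make_network_labels(
    parcellation: Parcellation, n_networks: int = 7, seed: int = 0
) -> np.ndarray:
    """Contiguous parcel groupings standing in for resting-state networks.

    Round-robin BFS over the parcel centroid k-nearest-neighbor graph from
    random parcel seeds; returns one network id per parcel.
    """
    n = parcellation.n_parcels
    if not 1 <= n_networks <= n:
        raise ValueError("n_networks must lie in [1, n_parcels]")
    rng = np.random.default_rng(seed)
    # parcel adjacency via centroid proximity (6 nearest neighbors)
    d = np.linalg.norm(
        parcellation.centroids[:, None] - parcellation.centroids[None], axis=2
    )
    np.fill_diagonal(d, np.inf)
    k = min(6, n - 1)
    nbrs = np.argsort(d, axis=1)[:, :k]
    seeds = rng.choice(n, size=n_networks, replace=False)
    net = np.full(n, -1, dtype=int)
    net[seeds] = np.arange(n_networks)
    frontiers = [[int(s)] for s in seeds]
    while any(frontiers):
        for w in range(n_networks):
            new_frontier = []
            for p in frontiers[w]:
                for q in sorted(nbrs[p].tolist()):
                    if net[q] == -1:
                        net[q] = w
                        new_frontier.append(q)
            frontiers[w] = sorted(new_frontier)
    net[net == -1] = 0
    return net


def planted_axis_values(coords_mm: np.ndarray) -> np.ndarray:
    """Planted 1-D gradient: rescaled projection on the oblique axis."""
    return rescale01(np.asarray(coords_mm, float) @ _PLANTED_AXIS)


def make_seed_region(
    grid_shape: Tuple[int, int, int],
    subregion_split: float = 0.5,
    seed: int = 0,
    spacing_mm: float = 1.0,
    origin_mm: Tuple[float, float, float] = (0.0, 0.0, -3.0),
) -> SeedRegion:
    """Cuboidal voxel grid seed region with two subregions.

    Voxels are labeled 'A' / 'B' by splitting the region along the planted
    axis: the ``floor(m * subregion_split)`` voxels lowest on the axis get
    'A' (ordered by axis value, ties by voxel index; deterministic).
    """
    shape = tuple(int(s) for s in grid_shape)
    m = int(np.prod(shape))
    if m < 10:
        raise ValueError("grid must yield at least 10 voxels")
    ii, jj, kk = np.unravel_index(np.arange(m), shape)
    coords = np.column_stack([ii, jj, kk]).astype(float) * spacing_mm
    coords -= coords.mean(axis=0)
    coords += np.asarray(origin_mm, dtype=float)
    axis_vals = planted_axis_values(coords)
    order = np.lexsort((np.arange(m), axis_vals))
    n_a = int(np.floor(m * subregion_split))
    labels = np.full(m, "B", dtype="<U1")
    labels[order[:n_a]] = "A"
    return SeedRegion(
        voxel_ids=np.arange(m), coords_mm=coords, subregion_labels=labels
    )


def make_truth(
    seed_region: SeedRegion,
    parcellation: Parcellation,
    intermodal_coupling: float,
    seed: int = 0,
    branch_correlation_length: float = 0.5,
) -> SyntheticTruth:
    """Bundle the planted gradient, coupling and a branch-density analog."""
    branch = make_autocorrelated_map(
        parcellation, correlation_length=branch_correlation_length, seed=seed + 101
    )
    return SyntheticTruth(
        planted_gradient=planted_axis_values(seed_region.coords_mm),
        intermodal_coupling=float(intermodal_coupling),
        branch_field=branch.values,
        seed=int(seed),
    )


def _signed_axis(values: np.ndarray) -> np.ndarray:
    """Affine map of a vector to [-1, 1]."""
    return 2.0 * rescale01(values) - 1.0


def _modal_axes(seed_region: SeedRegion, truth: SyntheticTruth):
    """Structural voxel loading u (in [0, 1]) and the coupled functional one.

    The loading is kept nonnegative so the within-row ordering of
    connectivity targets never flips along the axis (profiles vary smoothly
    in magnitude, as streamline counts do).  The functional loading shares a
    fraction ``intermodal_coupling`` of its variance with u; the orthogonal
    remainder comes from a second spatial direction of the seed grid,
    Gram-Schmidt-orthogonalized against u.
    """
    # floor keeps every loading strictly positive: no voxel has an exactly
    # flat profile, so per-row sparsification supports are stable
    u = 0.2 + 0.8 * rescale01(truth.planted_gradient)
    perp_raw = seed_region.coords_mm @ np.array([-0.35, 1.0, 0.3])
    uc = u - u.mean()
    pc = perp_raw - perp_raw.mean()
    pc = pc - (pc @ uc) / (uc @ uc) * uc
    if pc.std() == 0:
        raise ValueError("seed grid is degenerate along the orthogonal axis")
    pc = pc / pc.std() * uc.std()
    kappa = truth.intermodal_coupling
    u_f = np.sqrt(kappa) * uc + np.sqrt(1.0 - kappa) * pc + u.mean()
    return u, u_f


def _parcel_profile(parcellation: Parcellation) -> np.ndarray:
    """Parcel connectivity profile c in [-1, 1] from the centroid geometry.

    Parcels are ranked along a smooth centroid axis; the top
    ``_PROFILE_TOP_FRACTION`` become a strongly-connected hub set with values
    in [0.35, 1], the remainder spread over [-1, -0.15].  The value gap at
    the boundary mirrors the heavy-tailed target distribution of streamline
    counts (few strong targets, many weak) and keeps the strongest decile of
    every connectivity profile stable under count noise.
    """
    raw = parcellation.centroids @ np.array([1.0, 0.3, -0.5])
    order = np.argsort(np.argsort(raw, kind="stable"), kind="stable")
    n = len(raw)
    n_top = int(np.ceil(_PROFILE_TOP_FRACTION * n))
    c = np.empty(n)
    hi = order >= n - n_top
    c[hi] = 0.35 + 0.65 * (order[hi] - (n - n_top)) / max(n_top - 1, 1)
    c[~hi] = -1.0 + 0.85 * order[~hi] / max(n - n_top - 1, 1)
    return c


def _structural_rate(u: np.ndarray, c: np.ndarray) -> np.ndarray:
    return _BASE_COUNT * (1.0 + _GAIN * np.outer(u, c))


def _functional_target(u_f: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Population voxel-parcel correlation, proportional to the shared field."""
    field = 1.0 + _GAIN * np.outer(u_f, c)
    row_norms = np.linalg.norm(field, axis=1)
    return field * (_FUNC_ROW_NORM / row_norms.max())


def simulate_timeseries(
    seed_region: SeedRegion,
    parcellation: Parcellation,
    truth: SyntheticTruth,
    n_timepoints: int,
    seed: int,
    noise_sd: float = 0.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Latent parcel timeseries and mixed voxel timeseries.

    Parcel series are i.i.d. standard normal; each voxel series is the
    mixture ``x_v = sum_j T_vj p_j + s_v eps_v`` whose mixture weights ``T``
    follow the planted gradient, with ``s_v`` chosen so every voxel has the
    same total variance ``1 + noise_sd**2`` (the population correlation of
    voxel v with parcel j is then ``T_vj / sqrt(1 + noise_sd**2)``).
    """
    if n_timepoints < 10:
        raise ValueError("n_timepoints must be >= 10")
    g, g_f = _modal_axes(seed_region, truth)
    c = _parcel_profile(parcellation)
    target = _functional_target(g_f, c)
    rng = np.random.default_rng(seed)
    parcel_ts = rng.standard_normal((parcellation.n_parcels, n_timepoints))
    voxel_ts = _mix_voxel_series(target, parcel_ts, noise_sd, rng)
    return voxel_ts, parcel_ts


def _mix_voxel_series(
    target: np.ndarray,
    parcel_ts: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mix parcel latents into voxel series with prescribed weights.

    Residual noise tops every voxel up to total variance ``1 + noise_sd**2``;
    a voxel whose weight row has unit norm at ``noise_sd = 0`` therefore
    receives no noise at all (e.g. weight 1 on a single parcel reproduces
    that parcel's series exactly).
    """
    resid_var = 1.0 + noise_sd**2 - (target**2).sum(axis=1)
    s = np.sqrt(np.maximum(resid_var, 0.0))
    return target @ parcel_ts + s[:, None] * rng.standard_normal(
        (target.shape[0], parcel_ts.shape[1])
    )


def simulate_connectomes(
    seed_region: SeedRegion,
    parcellation: Parcellation,
    truth: SyntheticTruth,
    noise_sd: float = 0.0,
    n_subjects: int = 1,
    n_timepoints: int = 3840,
) -> Tuple[List[ConnectivityMatrix], List[ConnectivityMatrix], SyntheticTruth]:
    """Per-subject structural and functional seed-to-cortex connectomes.

    Structural: expected counts ``BASE * (1 + GAIN * g_v * c_p)``; subjects
    draw Poisson counts around a log-normally jittered rate (jitter scale
    ``noise_sd``, mean-preserving).  Functional: Pearson correlations of
    simulated timeseries (``n_timepoints`` frames).  At ``noise_sd = 0`` both
    are returned as their deterministic population values, identical across
    subjects.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    g, g_f = _modal_axes(seed_region, truth)
    c = _parcel_profile(parcellation)
    rate = _structural_rate(g, c)
    target = _functional_target(g_f, c)
    pids = parcellation.parcel_ids

    structural, functional = [], []
    rng = np.random.default_rng(truth.seed)
    for subj in range(n_subjects):
        if noise_sd == 0:
            s_vals = rate
            f_vals = target
            f_conn = ConnectivityMatrix(
                values=f_vals, modality="functional", parcel_ids=pids,
                seed_region=seed_region,
            )
        else:
            jitter = np.exp(
                noise_sd * rng.standard_normal(rate.shape) - 0.5 * noise_sd**2
            )
            s_vals = rng.poisson(rate * jitter).astype(float)
            ts_seed = int(rng.integers(0, 2**31 - 1))
            voxel_ts, parcel_ts = simulate_timeseries(
                seed_region, parcellation, truth, n_timepoints,
                seed=ts_seed, noise_sd=noise_sd,
            )
            f_conn = functional_connectivity(
                voxel_ts, parcel_ts, parcel_ids=pids, seed_region=seed_region
            )
        structural.append(
            ConnectivityMatrix(
                values=s_vals, modality="structural", parcel_ids=pids,
                seed_region=seed_region,
            )
        )
        functional.append(f_conn)
    return structural, functional, truth


def _sphere_distances(points: np.ndarray) -> np.ndarray:
    dots = np.clip(points @ points.T, -1.0, 1.0)
    return np.arccos(dots)


def make_autocorrelated_map(
    domain: Union[Parcellation, TriangulatedSurface],
    correlation_length: float,
    seed: int,
    parcellation: Optional[Parcellation] = None,
    name: str = "autocorrelated",
) -> ParcelMap:
    """Smooth Gaussian random field on the sphere, parcel-averaged.

    White noise is drawn per location and smoothed with a great-circle
    Gaussian kernel of scale ``correlation_length`` (radians).  Passing a
    Parcellation smooths over parcel centroids directly; passing a surface
    smooths over vertices and then parcel-averages (requires
    ``parcellation``).  The output is standardized to zero mean, unit sd.
    """
    if correlation_length <= 0:
        raise ValueError("correlation_length must be > 0")
    rng = np.random.default_rng(seed)
    if isinstance(domain, Parcellation):
        pts = domain.centroids
        z = rng.standard_normal(len(pts))
        d = _sphere_distances(pts)
        k = np.exp(-0.5 * (d / correlation_length) ** 2)
        vals = k @ z
        out_ids = domain.parcel_ids
    else:
        pts = domain.vertices / np.linalg.norm(domain.vertices, axis=1, keepdims=True)
        z = rng.standard_normal(len(pts))
        d = _sphere_distances(pts)
        k = np.exp(-0.5 * (d / correlation_length) ** 2)
        vertex_vals = k @ z
        if parcellation is None:
            raise ValueError("parcel-averaging a surface field needs a parcellation")
        vals = np.array(
            [
                vertex_vals[parcellation.labels == pid].mean()
                for pid in parcellation.parcel_ids
            ]
        )
        out_ids = parcellation.parcel_ids
    vals = (vals - vals.mean()) / vals.std()
    return ParcelMap(parcel_ids=out_ids, values=vals, name=name)
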