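"""Construction and aggregation of seed-to-cortex connectivity matrices."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .datatypes import ConnectivityMatrix, DegenerateInputError, SeedRegion

__all__ = ["functional_connectivity", "average_connectomes", "rescale01"]


def functional_connectivity(
    voxel_timeseries: np.ndarray,
    parcel_timeseries: np.ndarray,
    parcel_ids: Optional[np.ndarray] = None,
    seed_region: Optional[SeedRegion] = None,
) -> ConnectivityMatrix:
    """Pearson correlation of every seed-voxel series with every parcel series.

    Parameters
    ----------
    voxel_timeseries : (m, T) array
    parcel_timeseries : (n, T) array

    Returns
    -------
    ConnectivityMatrix with modality 'functional', entry (i, j) the Pearson r
    between voxel i and parcel j.

    Raises
    ------
    DegenerateInputError if any series has zero variance (the correlation is
    undefined); the error names the offending series.
    """
    x = np.asarray(voxel_timeseries, dtype=float)
    y = np.asarray(parcel_timeseries, dtype=float)
    if x.ndim != 2 or y.ndim != 2:
        raise ValueError("timeseries blocks must be 2-D (series x timepoints)")
    if x.shape[1] != y.shape[1]:
        raise ValueError(
            f"timepoint counts differ: voxels have {x.shape[1]}, parcels {y.shape[1]}"
        )
    for name, block in (("voxel", x), ("parcel", y)):
        sd = block.std(axis=1)
        # relative threshold: a constant series has sd at rounding level of
        # its mean, not exactly zero
        tol = 1e-12 * np.maximum(1.0, np.abs(block).max(axis=1))
        bad = np.flatnonzero(sd <= tol)
        if bad.size:
            raise DegenerateInputError(
                f"{name} series {bad.tolist()} have zero variance; "
                "Pearson correlation is undefined"
            )
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    r = (xc @ yc.T) / np.outer(
        np.sqrt((xc**2).sum(axis=1)), np.sqrt((yc**2).sum(axis=1))
    )
    np.clip(r, -1.0, 1.0, out=r)
    if parcel_ids is None:
        parcel_ids = np.arange(y.shape[0])
    return ConnectivityMatrix(
        values=r, modality="functional", parcel_ids=parcel_ids, seed_region=seed_region
    )


def average_connectomes(
    matrices: Sequence[ConnectivityMatrix], fisher_z: bool = False
) -> ConnectivityMatrix:
    """Elementwise arithmetic mean of subject-level connectivity matrices.

    All matrices must share shape, modality and parcel ids.  For functional
    matrices a Fisher z-transformed mean is available via ``fisher_z`` but is
    off by default: the plain mean of r values is the group aggregation used
    throughout this package.
    """
    if len(matrices) == 0:
        raise ValueError("need at least one connectome")
    first = matrices[0]
    for m in matrices[1:]:
        if m.modality != first.modality:
            raise ValueError("cannot average connectomes of mixed modality")
        if m.values.shape != first.values.shape:
            raise ValueError("cannot average connectomes of mixed shape")
        if not np.array_equal(m.parcel_ids, first.parcel_ids):
            raise ValueError("cannot average connectomes with different parcel ids")
    stack = np.stack([m.values for m in matrices])
    if fisher_z and first.modality == "functional":
        z = np.arctanh(np.clip(stack, -1 + 1e-15, 1 - 1e-15))
        mean = np.tanh(z.mean(axis=0))
    else:
        mean = stack.mean(axis=0)
    return ConnectivityMatrix(
        values=mean,
        modality=first.modality,
        parcel_ids=first.parcel_ids,
        seed_region=first.seed_region,
    )


def rescale01(values: np.ndarray) -> np.ndarray:
    """Affine rescale of a vector to [0, 1] (min -> 0, max -> 1).

    Order-preserving; raises DegenerateInputError on a constant vector.
    """
    v = np.asarray(values, dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size < 2:
        raise DegenerateInputError("rescale01 needs at least two finite values")
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        raise DegenerateInputError("rescale01 is undefined for a constant vector")
    return (v - lo) / (hi - lo)
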