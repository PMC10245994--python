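"""Projection of seed gradients onto the cortex and network decompositions."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import ConnectivityMatrix, ParcelMap, WeightedResidualMap
from .tethering import pair_residuals, weighted_residual_map

__all__ = [
    "gradient_weighted_cortical_map",
    "cortical_residual_map",
    "network_decomposition",
]


def gradient_weighted_cortical_map(
    conn: ConnectivityMatrix,
    gradient: np.ndarray,
    name: str = "",
) -> ParcelMap:
    """Cortical expression of a seed gradient.

    Each connectivity row is weighted by its voxel's gradient value and the
    weighted rows are averaged: ``map_j = mean_v gradient_v * conn_vj``.
    Linear in the gradient argument.
    """
    g = np.asarray(gradient, dtype=float)
    if g.shape != (conn.values.shape[0],):
        raise ValueError(
            f"gradient length {g.shape} does not match voxel count {conn.values.shape[0]}"
        )
    values = (g[:, None] * conn.values).mean(axis=0)
    return ParcelMap(parcel_ids=conn.parcel_ids, values=values, name=name)


def cortical_residual_map(
    structural_maps: Sequence[ParcelMap],
    functional_maps: Sequence[ParcelMap],
    weights: Sequence[float],
    normalize_weights: bool = False,
) -> WeightedResidualMap:
    """Detethering map across cortical parcels.

    The same variance-weighted residual pipeline as the seed-voxel map,
    applied per structure-function pair of gradient-weighted cortical maps:
    standardize both maps, regress structural on functional, sum weighted
    squared residuals over pairs.
    """
    if not (len(structural_maps) == len(functional_maps) == len(weights)):
        raise ValueError("need one structural map, functional map and weight per pair")
    if len(weights) == 0:
        raise ValueError("need at least one pair")
    ids = structural_maps[0].parcel_ids
    for m in list(structural_maps) + list(functional_maps):
        if not np.array_equal(m.parcel_ids, ids):
            raise ValueError("all maps must share parcel_ids")
    pairs = [
        pair_residuals(
            sm.values, fm.values, weight=float(w), pair_index=k,
        )
        for k, (sm, fm, w) in enumerate(
            zip(structural_maps, functional_maps, weights)
        )
    ]
    return weighted_residual_map(
        pairs, normalize_weights=normalize_weights, domain="cortical_parcels"
    )


def network_decomposition(
    parcel_map: ParcelMap, network_labels: np.ndarray
) -> pd.DataFrame:
    """Group a parcel map by network membership.

    Returns a tidy frame (parcel_id, network, value) with networks ordered by
    their mean value; the mean order is exposed via the categorical ordering
    of the ``network`` column.
    """
    labels = np.asarray(network_labels)
    if labels.shape != parcel_map.values.shape:
        raise ValueError("every parcel needs a network label")
    df = pd.DataFrame(
        {
            "parcel_id": parcel_map.parcel_ids,
            "network": labels,
            "value": parcel_map.values,
        }
    )
    order = (
        df.groupby("network", sort=True)["value"].mean().sort_values().index.tolist()
    )
    df["network"] = pd.Categorical(df["network"], categories=order, ordered=True)
    return df.sort_values(["network", "parcel_id"], ignore_index=True)
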