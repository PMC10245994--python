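"""File formats: GIFTI surfaces/labels/shapes, CSV/NPZ matrices, NIfTI maps.

CSV is the human-readable interchange format (header row of parcel ids,
index column of voxel ids); the NPZ container is the bit-faithful binary
round-trip format.  Surfaces use GIFTI via nibabel; per-voxel seed maps can
be projected back into a NIfTI volume built from the seed grid geometry.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import (
    ConnectivityMatrix,
    GradientSet,
    ParcelMap,
    SeedRegion,
    SyntheticTruth,
    TriangulatedSurface,
)

__all__ = [
    "save_surface_gifti",
    "load_surface_gifti",
    "save_label_gifti",
    "load_label_gifti",
    "save_shape_gifti",
    "load_shape_gifti",
    "connectivity_to_csv",
    "connectivity_from_csv",
    "connectivity_to_npz",
    "connectivity_from_npz",
    "gradients_to_csv",
    "parcel_map_to_csv",
    "parcel_map_from_csv",
    "truth_to_json",
    "truth_from_json",
    "voxel_map_to_nifti",
    "voxel_map_from_nifti",
]


def save_surface_gifti(surface: TriangulatedSurface, path: Union[str, Path]) -> None:
    img = nib.gifti.GiftiImage(
        darrays=[
            nib.gifti.GiftiDataArray(
                surface.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
            ),
            nib.gifti.GiftiDataArray(
                surface.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
            ),
        ]
    )
    nib.save(img, str(path))


def load_surface_gifti(path: Union[str, Path]) -> TriangulatedSurface:
    img = nib.load(str(path))
    vertices = faces = None
    for da in img.darrays:
        if da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
            vertices = np.asarray(da.data, dtype=float)
        elif da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
            faces = np.asarray(da.data, dtype=int)
    if vertices is None or faces is None:
        raise ValueError(f"{path} lacks POINTSET/TRIANGLE arrays")
    return TriangulatedSurface(vertices=vertices, faces=faces)


def save_label_gifti(labels: np.ndarray, path: Union[str, Path]) -> None:
    img = nib.gifti.GiftiImage(
        darrays=[
            nib.gifti.GiftiDataArray(
                np.asarray(labels, dtype=np.int32), intent="NIFTI_INTENT_LABEL"
            )
        ]
    )
    nib.save(img, str(path))


def load_label_gifti(path: Union[str, Path]) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.darrays[0].data, dtype=int)


def save_shape_gifti(values: np.ndarray, path: Union[str, Path]) -> None:
    img = nib.gifti.GiftiImage(
        darrays=[
            nib.gifti.GiftiDataArray(
                np.asarray(values, dtype=np.float32), intent="NIFTI_INTENT_SHAPE"
            )
        ]
    )
    nib.save(img, str(path))


def load_shape_gifti(path: Union[str, Path]) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.darrays[0].data, dtype=float)


def connectivity_to_csv(conn: ConnectivityMatrix, path: Union[str, Path]) -> None:
    voxel_ids = (
        conn.seed_region.voxel_ids
        if conn.seed_region is not None
        else np.arange(conn.values.shape[0])
    )
    df = pd.DataFrame(conn.values, index=voxel_ids, columns=conn.parcel_ids)
    df.index.name = "voxel_id"
    df.to_csv(path)


def connectivity_from_csv(
    path: Union[str, Path],
    modality: str,
    seed_region: Optional[SeedRegion] = None,
) -> ConnectivityMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConnectivityMatrix(
        values=df.to_numpy(float),
        modality=modality,
        parcel_ids=np.array([int(c) for c in df.columns]),
        seed_region=seed_region,
    )


def connectivity_to_npz(conn: ConnectivityMatrix, path: Union[str, Path]) -> None:
    voxel_ids = (
        conn.seed_region.voxel_ids
        if conn.seed_region is not None
        else np.arange(conn.values.shape[0])
    )
    np.savez_compressed(
        path,
        values=conn.values,
        modality=np.array(conn.modality),
        parcel_ids=conn.parcel_ids,
        voxel_ids=voxel_ids,
    )


def connectivity_from_npz(
    path: Union[str, Path], seed_region: Optional[SeedRegion] = None
) -> ConnectivityMatrix:
    with np.load(path) as z:
        return ConnectivityMatrix(
            values=z["values"],
            modality=str(z["modality"]),
            parcel_ids=z["parcel_ids"],
            seed_region=seed_region,
        )


def gradients_to_csv(
    grads: GradientSet, path: Union[str, Path], voxel_ids: Optional[np.ndarray] = None
) -> None:
    """Scores as CSV plus a JSON metadata sidecar (<path>.json)."""
    if voxel_ids is None:
        voxel_ids = np.arange(grads.scores.shape[0])
    df = pd.DataFrame(
        grads.scores,
        index=voxel_ids,
        columns=[f"G{k + 1}" for k in range(grads.n_components)],
    )
    df.index.name = "voxel_id"
    df.to_csv(path)
    meta = {
        "explained_variance": grads.explained_variance.tolist(),
        "kernel_params": grads.kernel_params,
        "embedding_params": grads.embedding_params,
        "modality": grads.modality,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def parcel_map_to_csv(parcel_map: ParcelMap, path: Union[str, Path]) -> None:
    pd.DataFrame(
        {"parcel_id": parcel_map.parcel_ids, "value": parcel_map.values}
    ).to_csv(path, index=False)


def parcel_map_from_csv(path: Union[str, Path], name: str = "") -> ParcelMap:
    df = pd.read_csv(path)
    return ParcelMap(
        parcel_ids=df["parcel_id"].to_numpy(int),
        values=df["value"].to_numpy(float),
        name=name,
    )


def truth_to_json(truth: SyntheticTruth, path: Union[str, Path]) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "planted_gradient": truth.planted_gradient.tolist(),
                "intermodal_coupling": truth.intermodal_coupling,
                "branch_field": truth.branch_field.tolist(),
                "seed": truth.seed,
            },
            indent=2,
        )
    )


def truth_from_json(path: Union[str, Path]) -> SyntheticTruth:
    d = json.loads(Path(path).read_text())
    return SyntheticTruth(
        planted_gradient=np.array(d["planted_gradient"]),
        intermodal_coupling=d["intermodal_coupling"],
        branch_field=np.array(d["branch_field"]),
        seed=d["seed"],
    )


def voxel_map_to_nifti(
    values: np.ndarray, seed_region: SeedRegion, path: Optional[Union[str, Path]] = None
) -> nib.Nifti1Image:
    """Project a per-voxel map back into a NIfTI volume on the seed grid.

    The grid geometry (spacing, origin) is inferred from the voxel
    coordinates; voxels outside the seed region are NaN.
    """
    v = np.asarray(values, dtype=float)
    coords = seed_region.coords_mm
    if v.shape != (len(coords),):
        raise ValueError("value count must match seed voxels")
    spacing = np.array(
        [
            np.min(np.diff(np.unique(np.round(coords[:, k], 9))))
            if len(np.unique(np.round(coords[:, k], 9))) > 1
            else 1.0
            for k in range(3)
        ]
    )
    origin = coords.min(axis=0)
    ijk = np.round((coords - origin) / spacing).astype(int)
    shape = ijk.max(axis=0) + 1
    vol = np.full(shape, np.nan)
    vol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = v
    affine = np.diag(np.append(spacing, 1.0))
    affine[:3, 3] = origin
    img = nib.Nifti1Image(vol, affine)
    if path is not None:
        nib.save(img, str(path))
    return img


def voxel_map_from_nifti(
    path: Union[str, Path], seed_region: SeedRegion
) -> np.ndarray:
    """Read a per-voxel map back from a NIfTI volume on the seed grid.

    Samples the volume at the seed voxel coordinates via the inverse affine;
    coordinates must land on integer grid indices.
    """
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float)
    inv = np.linalg.inv(img.affine)
    ijk = (seed_region.coords_mm @ inv[:3, :3].T) + inv[:3, 3]
    ijk_int = np.round(ijk).astype(int)
    if np.abs(ijk - ijk_int).max() > 1e-6:
        raise ValueError("seed voxel coordinates do not align with the volume grid")
    if (ijk_int < 0).any() or (ijk_int >= vol.shape).any():
        raise ValueError("seed voxel coordinates fall outside the volume")
    return vol[ijk_int[:, 0], ijk_int[:, 1], ijk_int[:, 2]]
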