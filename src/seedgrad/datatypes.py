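"""Core containers shared across the package.

Everything is a light dataclass around numpy arrays with validation at
construction.  Invariants that would silently corrupt downstream stages
(modality-dependent value ranges, label coverage, shape agreement) are
checked eagerly; everything else is left to the operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "DegenerateInputError",
    "TriangulatedSurface",
    "Parcellation",
    "SeedRegion",
    "SeedLabel",
    "ConnectivityMatrix",
    "GradientSet",
    "ParcelMap",
    "PairResidualSet",
    "WeightedResidualMap",
    "NullDistribution",
    "SurrogateEnsemble",
    "SyntheticTruth",
]


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but statistically degenerate
    (constant vector, zero-variance series, empty thresholded label, ...)."""


@dataclass
class TriangulatedSurface:
    """Closed or bounded triangle mesh.

    vertices : (V, 3) float array, mm or unit-sphere coordinates.
    faces : (F, 3) int array of vertex indices.
    medial_wall : optional (V,) bool mask of vertices excluded from analysis
        (the synthetic analog of the medial wall of a cortical hemisphere).
    """

    vertices: np.ndarray
    faces: np.ndarray
    medial_wall: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=0) >= len(self.vertices):
            raise ValueError("face indices out of range")
        if self.medial_wall is not None:
            self.medial_wall = np.asarray(self.medial_wall, dtype=bool)
            if self.medial_wall.shape != (len(self.vertices),):
                raise ValueError("medial_wall must be a (V,) boolean mask")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def unmasked(self) -> np.ndarray:
        """Boolean mask of analysable vertices."""
        if self.medial_wall is None:
            return np.ones(self.n_vertices, dtype=bool)
        return ~self.medial_wall

    def edges(self) -> np.ndarray:
        """Unique undirected mesh edges, (E, 2) sorted pairs."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)


@dataclass
class Parcellation:
    """Vertex-to-parcel assignment on a surface.

    labels : (V,) int array; -1 marks masked (medial wall) vertices.
    parcel_ids : (P,) int array of parcel identifiers, sorted ascending.
    centroids : (P, 3) parcel centroids (on the sphere for spherical surfaces).
    """

    labels: np.ndarray
    parcel_ids: np.ndarray
    centroids: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.parcel_ids = np.asarray(self.parcel_ids, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if len(np.unique(self.parcel_ids)) != len(self.parcel_ids):
            raise ValueError("parcel_ids must be unique")
        present = np.unique(self.labels[self.labels >= 0])
        if not np.isin(present, self.parcel_ids).all():
            raise ValueError("labels contain parcels absent from parcel_ids")
        if self.centroids.shape != (len(self.parcel_ids), 3):
            raise ValueError("centroids must be (P, 3)")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    def members(self, parcel_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == parcel_id)


@dataclass
class SeedRegion:
    """Voxel set constituting the seed of all connectomes.

    Subregion labels 'A'/'B' are the synthetic analogs of the anteromedial
    (septal/diagonal-band) and posterolateral (nucleus-basalis) cholinergic
    cell groups of the basal forebrain.
    """

    voxel_ids: np.ndarray
    coords_mm: np.ndarray
    subregion_labels: np.ndarray
    probability: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.voxel_ids = np.asarray(self.voxel_ids, dtype=int)
        self.coords_mm = np.asarray(self.coords_mm, dtype=float)
        self.subregion_labels = np.asarray(self.subregion_labels)
        if len(np.unique(self.voxel_ids)) != len(self.voxel_ids):
            raise ValueError("voxel_ids must be unique")
        if not np.isfinite(self.coords_mm).all():
            raise ValueError("coords_mm must be finite")
        if self.coords_mm.shape != (len(self.voxel_ids), 3):
            raise ValueError("coords_mm must be (m, 3)")
        if self.subregion_labels.shape != (len(self.voxel_ids),):
            raise ValueError("subregion_labels must cover all voxels")
        if self.probability is not None:
            self.probability = np.asarray(self.probability, dtype=float)
            if ((self.probability < 0) | (self.probability > 1)).any():
                raise ValueError("probability values must lie in [0, 1]")

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_ids)


@dataclass
class SeedLabel:
    """Binary seed label on a surface, with thresholding provenance."""

    vertices: np.ndarray
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=int)
        if self.vertices.size == 0:
            raise DegenerateInputError("seed label is empty")


@dataclass
class ConnectivityMatrix:
    """m seed voxels x n cortical parcels connectivity weights.

    modality 'structural' holds nonnegative streamline-count-like weights;
    'functional' holds Pearson correlations in [-1, 1].
    """

    values: np.ndarray
    modality: str
    parcel_ids: np.ndarray
    seed_region: Optional[SeedRegion] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.parcel_ids = np.asarray(self.parcel_ids, dtype=int)
        if self.modality not in ("structural", "functional"):
            raise ValueError("modality must be 'structural' or 'functional'")
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (voxels x parcels)")
        if self.values.shape[1] != len(self.parcel_ids):
            raise ValueError("values column count must match parcel_ids")
        if not np.isfinite(self.values).all():
            raise ValueError("connectivity values must be finite (no missing entries)")
        if self.modality == "structural" and (self.values < 0).any():
            raise ValueError("structural connectivity must be nonnegative")
        if self.modality == "functional" and (np.abs(self.values) > 1 + 1e-12).any():
            raise ValueError("functional connectivity must lie in [-1, 1]")
        if self.seed_region is not None and self.values.shape[0] != self.seed_region.n_voxels:
            raise ValueError("row count must match seed region voxel count")

    @property
    def shape(self) -> tuple:
        return self.values.shape


@dataclass
class GradientSet:
    """Embedding components ('gradients') of one connectivity modality.

    scores : (m, K) per-voxel component values (unitless embedding scores).
    explained_variance : (K,) fractions, the per-component weights entering
        the weighted-residual (detethering) formula.
    """

    scores: np.ndarray
    explained_variance: np.ndarray
    kernel_params: dict = field(default_factory=dict)
    embedding_params: dict = field(default_factory=dict)
    modality: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be (m, K)")
        k = self.scores.shape[1]
        if self.explained_variance.shape != (k,):
            raise ValueError("explained_variance length must equal component count")
        if (self.explained_variance < -1e-12).any():
            raise ValueError("explained_variance entries must be nonnegative")
        if np.any(np.diff(self.explained_variance) > 1e-12):
            raise ValueError("explained_variance must be non-increasing")
        if self.explained_variance.sum() > 1 + 1e-9:
            raise ValueError("explained_variance must sum to at most 1")

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def component(self, k: int) -> np.ndarray:
        return self.scores[:, k]


@dataclass
class ParcelMap:
    """Scalar value per cortical parcel."""

    parcel_ids: np.ndarray
    values: np.ndarray
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.parcel_ids = np.asarray(self.parcel_ids, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(np.unique(self.parcel_ids)) != len(self.parcel_ids):
            raise ValueError("parcel_ids must be unique")
        if self.values.shape != self.parcel_ids.shape:
            raise ValueError("values must align with parcel_ids")


@dataclass
class PairResidualSet:
    """Residuals of one structural-on-functional component regression."""

    pair_index: int
    structural_index: int
    functional_index: int
    residuals: np.ndarray
    weight: float
    r_squared: float

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.weight <= 0:
            raise ValueError("pair weight must be positive")
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass
class WeightedResidualMap:
    """Variance-weighted sum of squared pair residuals (detethering map)."""

    values: np.ndarray
    n_pairs: int
    domain: str = "seed_voxels"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.domain not in ("seed_voxels", "cortical_parcels"):
            raise ValueError("domain must be 'seed_voxels' or 'cortical_parcels'")
        if (self.values < -1e-12).any():
            raise ValueError("weighted residual values must be nonnegative")


@dataclass
class NullDistribution:
    """Observed statistic plus its permutation/bootstrap null."""

    statistic_name: str
    observed: float
    null_values: np.ndarray
    p_value: float
    n_perm: int
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.null_values = np.asarray(self.null_values, dtype=float)
        if self.n_perm < 1:
            raise ValueError("n_perm must be at least 1")
        lo = 1.0 / (self.n_perm + 1)
        if not (lo - 1e-12 <= self.p_value <= 1 + 1e-12):
            raise ValueError("p_value outside attainable range")


@dataclass
class SurrogateEnsemble:
    """Variogram-matched surrogate maps of a source map."""

    surrogates: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.surrogates = np.asarray(self.surrogates, dtype=float)
        if self.surrogates.ndim != 2:
            raise ValueError("surrogates must be (N, m)")

    @property
    def n_surrogates(self) -> int:
        return self.surrogates.shape[0]


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic dataset.

    planted_gradient : per-seed-voxel scalar, the true 1-D axis both
        modalities express.
    intermodal_coupling : fraction in [0, 1] of gradient variance shared
        between the structural and functional modality.
    branch_field : per-parcel scalar, a spatially autocorrelated synthetic
        analog of an innervation-density covariate map.
    """

    planted_gradient: np.ndarray
    intermodal_coupling: float
    branch_field: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.planted_gradient = np.asarray(self.planted_gradient, dtype=float)
        self.branch_field = np.asarray(self.branch_field, dtype=float)
        if np.ptp(self.planted_gradient) == 0:
            raise ValueError("planted_gradient must have nonzero variance")
        if not (0.0 <= self.intermodal_coupling <= 1.0):
            raise ValueError("intermodal_coupling must lie in [0, 1]")
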