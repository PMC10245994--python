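"""Intermodal structure-function correspondence of gradient sets.

The central quantity is the variance-weighted residual map

    xbar_v = sum_k (w_i,k + w_j,k) * x_k,v**2

where ``k`` runs over structural-functional component pairs, ``w_i`` / ``w_j``
are the explained-variance fractions of the paired components and ``x_k`` the
per-voxel residuals of regressing the (standardized) structural component on
the (standardized) functional one.  Large values mark voxels where the two
modalities' gradients diverge ("detethering").
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .connectome import rescale01
from .datatypes import (
    DegenerateInputError,
    GradientSet,
    NullDistribution,
    PairResidualSet,
    SurrogateEnsemble,
    WeightedResidualMap,
)

__all__ = [
    "pairwise_r2",
    "pair_residuals",
    "make_pair_residuals",
    "weighted_residual_map",
    "coefficient_of_variation",
    "subregion_contrast",
]


def _as_scores(g) -> np.ndarray:
    return g.scores if isinstance(g, GradientSet) else np.asarray(g, dtype=float)


def _standardize(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise DegenerateInputError(f"{name} component is constant")
    return (x - x.mean()) / sd


def pairwise_r2(grads_a, grads_b) -> np.ndarray:
    """Squared Pearson correlation for every component pair (KA x KB)."""
    a, b = _as_scores(grads_a), _as_scores(grads_b)
    if a.shape[0] != b.shape[0]:
        raise ValueError("gradient sets must share voxel count and ordering")
    za = np.column_stack(
        [_standardize(a[:, i], f"A[{i}]") for i in range(a.shape[1])]
    )
    zb = np.column_stack(
        [_standardize(b[:, j], f"B[{j}]") for j in range(b.shape[1])]
    )
    r = (za.T @ zb) / a.shape[0]
    return r**2


def pair_residuals(
    ga_component: np.ndarray,
    gb_component: np.ndarray,
    weight: float = 1.0,
    pair_index: int = 0,
    structural_index: int = 0,
    functional_index: int = 0,
) -> PairResidualSet:
    """OLS residuals of one structural component regressed on one functional.

    Both components are standardized (mean 0, variance 1) first, which makes
    the squared residuals symmetric in the two modalities: the slope is then
    the Pearson correlation and the residual is ``z_a - r * z_b``.
    """
    a = np.asarray(ga_component, dtype=float)
    b = np.asarray(gb_component, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("components must be 1-D and equally long")
    za = _standardize(a, "structural")
    zb = _standardize(b, "functional")
    r = float(za @ zb) / len(za)
    resid = za - r * zb
    return PairResidualSet(
        pair_index=pair_index,
        structural_index=structural_index,
        functional_index=functional_index,
        residuals=resid,
        weight=weight,
        r_squared=min(r**2, 1.0),
    )


def make_pair_residuals(
    grads_structural: GradientSet,
    grads_functional: GradientSet,
    n_structural: Optional[int] = None,
    n_functional: Optional[int] = None,
) -> List[PairResidualSet]:
    """All (structural i, functional j) pair residual sets.

    The pair weight is the sum of the two components' explained-variance
    fractions, matching the detethering formula.
    """
    ka = n_structural if n_structural is not None else grads_structural.n_components
    kb = n_functional if n_functional is not None else grads_functional.n_components
    pairs = []
    k = 0
    for i in range(ka):
        for j in range(kb):
            w = float(
                grads_structural.explained_variance[i]
                + grads_functional.explained_variance[j]
            )
            pairs.append(
                pair_residuals(
                    grads_structural.component(i),
                    grads_functional.component(j),
                    weight=w,
                    pair_index=k,
                    structural_index=i,
                    functional_index=j,
                )
            )
            k += 1
    return pairs


def weighted_residual_map(
    pairs: Sequence[PairResidualSet],
    normalize_weights: bool = False,
    domain: str = "seed_voxels",
) -> WeightedResidualMap:
    """Variance-weighted sum of squared pair residuals.

    ``normalize_weights`` divides the pair weights by their sum; the default
    applies the literal formula with unnormalized weights.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one pair")
    m = len(pairs[0].residuals)
    for p in pairs:
        if len(p.residuals) != m:
            raise ValueError("all pairs must share the voxel count")
    weights = np.array([p.weight for p in pairs], dtype=float)
    if normalize_weights:
        weights = weights / weights.sum()
    values = np.zeros(m)
    for p, w in zip(pairs, weights):
        values += w * p.residuals**2
    return WeightedResidualMap(values=values, n_pairs=len(pairs), domain=domain)


def coefficient_of_variation(values: np.ndarray, epsilon: float = 1e-8) -> float:
    """100 * sd / mean (sample standard deviation).

    Intended for values on a rescaled [0, 1] domain; undefined (and refused)
    when the mean is at or below ``epsilon``.
    """
    v = np.asarray(values, dtype=float)
    mean = v.mean()
    if mean <= epsilon:
        raise DegenerateInputError(
            f"coefficient of variation undefined for mean {mean:.3g} <= {epsilon:.3g}"
        )
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    return float(100.0 * sd / mean)


def _group_statistic(values, in_a, statistic):
    if statistic == "mean_diff":
        return float(values[in_a].mean() - values[~in_a].mean())
    if statistic == "cov_diff":
        return coefficient_of_variation(values[in_a]) - coefficient_of_variation(
            values[~in_a]
        )
    raise ValueError("statistic must be 'mean_diff' or 'cov_diff'")


def subregion_contrast(
    map_values: Union[np.ndarray, WeightedResidualMap],
    labels: np.ndarray,
    statistic: str,
    nulls: SurrogateEnsemble,
    rescale: bool = True,
    seed: Optional[int] = None,
) -> Tuple[float, float, NullDistribution]:
    """Subregion A-minus-B contrast with a surrogate-map permutation null.

    The observed statistic is recomputed on every surrogate map of the
    ensemble (built on the same voxel set); the two-sided p-value uses the
    standard +1 correction.  Values are rescaled to [0, 1] beforehand by
    default, which also keeps the coefficient of variation well defined.
    """
    values = (
        map_values.values
        if isinstance(map_values, WeightedResidualMap)
        else np.asarray(map_values, dtype=float)
    )
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("labels must define exactly two non-empty subregions")
    in_a = labels == groups[0]
    if in_a.all() or not in_a.any():
        raise ValueError("both subregions must be non-empty")
    if nulls.surrogates.shape[1] != values.shape[0]:
        raise ValueError("surrogate ensemble was built on a different voxel set")

    def prep(v):
        if not rescale:
            return v
        try:
            return rescale01(v)
        except DegenerateInputError:
            return v  # constant map: contrast is 0 regardless of scaling

    observed = _group_statistic(prep(values), in_a, statistic)
    null_vals = np.array(
        [
            _group_statistic(prep(s), in_a, statistic)
            for s in nulls.surrogates
        ]
    )
    n = len(null_vals)
    p = (1.0 + np.sum(np.abs(null_vals) >= abs(observed))) / (1.0 + n)
    dist = NullDistribution(
        statistic_name=statistic,
        observed=observed,
        null_values=null_vals,
        p_value=float(p),
        n_perm=n,
        seed=seed,
    )
    return observed, float(p), dist
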