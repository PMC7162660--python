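"""Low-dimensional mode-cluster decomposition.

The high-dimensional modes often share aging patterns; rerunning the
PCA+ICA decomposition at low dimensionality on the same age-weighted matrix
yields candidate "mode-clusters".  The clustering quality of a candidate
dimensionality d is scored by how cleanly each high-dimensional mode
associates with a *single* cluster: for every mode, take the |corr| of its
subject-weight vector with all d cluster subject-weight vectors, and add
(strongest - second strongest) to the cost.  The chosen d maximises the
summed cost.
"""

from __future__ import annotations

import numpy as np

from .containers import ModeClusterSet, ModeSet
from .modes import pca_reduce, project_subject_weights, run_ica
from .utils import abs_corr_matrix, cubic_age_r2, safe_corr

__all__ = ["cluster_cost", "cost_from_abs_corr", "sweep_cluster_dim"]


def cost_from_abs_corr(c: np.ndarray) -> float:
    """Clustering cost from a modes x clusters |corr| matrix.

    Per high-dimensional mode (row): strongest minus second-strongest
    |corr| with any cluster; summed over modes.  For a single cluster the
    second-strongest is defined as 0.
    """
    c = np.atleast_2d(np.asarray(c, float))
    if c.shape[1] < 1:
        raise ValueError("need at least one cluster component")
    if c.shape[1] == 1:
        return float(c[:, 0].sum())
    part = np.sort(c, axis=1)[:, ::-1]
    return float((part[:, 0] - part[:, 1]).sum())


def cluster_cost(high_subject_weights: np.ndarray, low_subject_weights: np.ndarray) -> float:
    """First-minus-second-strongest |corr| summed over high-dimensional modes.

    The cost measures how cleanly each high-dimensional mode associates with
    a *single* low-dimensional cluster; it is invariant to sign flips and
    permutations of either set and lies in [0, n_modes].
    """
    high = np.atleast_2d(np.asarray(high_subject_weights, float))
    low = np.atleast_2d(np.asarray(low_subject_weights, float))
    if high.shape[0] != low.shape[0]:
        raise ValueError("subject counts differ")
    return cost_from_abs_corr(abs_corr_matrix(high.T, low.T))


def sweep_cluster_dim(
    weighted_matrix: np.ndarray,
    deconfounded_matrix: np.ndarray,
    modes: ModeSet,
    age: np.ndarray,
    dims: range | list[int] = range(2, 51),
    rng_seed: int = 0,
) -> ModeClusterSet:
    """Find the cluster dimensionality with the cleanest mode assignment.

    Per candidate d the same age-weighted matrix used for mode discovery is
    PCA+ICA decomposed at dimensionality d; cluster subject weights are
    recomputed by projecting the deconfounded data onto the pseudoinverse of
    the cluster IDP weights (as for the modes themselves); and the cost is
    evaluated against the fixed high-dimensional mode set.  The chosen d is
    the argmax of the cost (ties to the larger d).  Clusters are
    sign-oriented to positive age correlation and ordered by decreasing
    cubic-age-model explained variance; each mode is assigned to its
    highest-|corr| cluster.
    """
    age = np.asarray(age, float).ravel()
    dims = list(dims)
    if not dims:
        raise ValueError("empty dimensionality range")
    cost_by_dim: dict[int, float] = {}
    results: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for d in dims:
        pca = pca_reduce(weighted_matrix, d)
        ica = run_ica(pca, d, rng_seed + d)
        sw = project_subject_weights(deconfounded_matrix, ica.idp_weights)
        cost_by_dim[d] = cluster_cost(modes.subject_weights, sw)
        results[d] = (ica.idp_weights, sw)
    best = max(cost_by_dim.values())
    chosen = max(d for d, c in cost_by_dim.items() if c == best)

    idp_w, sw = results[chosen]
    idp_w = idp_w.copy()
    sw = sw.copy()
    for i in range(idp_w.shape[0]):
        if safe_corr(sw[:, i], age) < 0:
            idp_w[i] *= -1.0
            sw[:, i] *= -1.0
    order_stat = np.array([cubic_age_r2(sw[:, i], age) for i in range(idp_w.shape[0])])
    order = np.argsort(-order_stat)
    clusters = ModeSet(
        idp_w[order],
        sw[:, order],
        order_stat[order],
        np.full(idp_w.shape[0], np.nan),
        pca_dim=chosen,
    )
    assignment = np.argmax(
        abs_corr_matrix(modes.subject_weights.T, clusters.subject_weights.T), axis=1
    )
    return ModeClusterSet(clusters, assignment, cost_by_dim, chosen)
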