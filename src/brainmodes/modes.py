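"""Discovery of reproducible population modes by age-weighted PCA + ICA.

The data matrix (subjects x IDPs) is far more non-Gaussian along the IDP
dimension than along the subject dimension, so ICA is applied to estimate
independent *IDP-weight* vectors: each mode is the rank-1 outer product of
an IDP-weight vector and a subject-weight vector.  Before decomposition
every IDP column is rescaled by ``0.1 + |corr(age, column)|`` to focus the
decomposition on age-related covariation.

Robustness is enforced by split-half reproducibility: ICA is run on the
full sample and on two random half-samples; half-run components are greedily
paired to the full run on |corr| of IDP-weight vectors and a full-run
component counts as reproducible only when both of its paired half-run
components match at |r| above threshold (0.9 by default).  The PCA
dimensionality is chosen to maximise the mean reproducible-component count
over repeated random splits.

Two Monte-Carlo null calibrations quantify how large such correlations get
by chance: :func:`null_max_correlation` for the pairing statistic and
:func:`null_weighting_test` for the age-weighting step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .containers import ModeSet, ReproducibilityReport
from .utils import abs_corr_matrix, cubic_age_r2, safe_corr

__all__ = [
    "age_weight",
    "pca_reduce",
    "run_ica",
    "pair_components",
    "pair_matrix",
    "split_half_reproducibility",
    "sweep_dimensionality",
    "project_subject_weights",
    "finalize_modes",
    "null_max_correlation",
    "null_weighting_test",
    "group_reduce",
    "PCAResult",
    "ICAResult",
]


def age_weight(matrix: np.ndarray, age: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rescale every IDP column by ``0.1 + |corr(age, column)|``.

    Returns the weighted matrix and the per-column weight vector.  A
    zero-variance column receives the floor weight 0.1 (with a warning).
    """
    matrix = np.asarray(matrix, float)
    age = np.asarray(age, float).ravel()
    if matrix.shape[0] != age.size:
        raise ValueError("matrix and age have different numbers of subjects")
    sd = matrix.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("zero-variance column(s); weight floored at 0.1", stacklevel=2)
    ac = age - age.mean()
    an = np.linalg.norm(ac)
    mc = matrix - matrix.mean(axis=0)
    norms = np.linalg.norm(mc, axis=0)
    norms[norms == 0] = np.inf
    r = np.abs(mc.T @ ac) / (norms * an)
    weights = 0.1 + r
    return matrix * weights, weights


@dataclass
class PCAResult:
    """Top-d principal subspace of a column-demeaned matrix.

    ``basis`` (subjects x d) spans the subject-side subspace; ``coords``
    (d x n_idps) are the coordinates of every IDP column in that basis, so
    ``basis @ coords`` reconstructs the demeaned matrix at rank d.
    """

    basis: np.ndarray
    coords: np.ndarray
    eigenvalues: np.ndarray
    column_means: np.ndarray

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum() if self.eigenvalues.size else 1.0
        return self.eigenvalues / total


def pca_reduce(matrix: np.ndarray, d: int) -> PCAResult:
    """SVD-based PCA of the column-demeaned subjects x IDPs matrix."""
    matrix = np.asarray(matrix, float)
    if not (1 <= d <= min(matrix.shape)):
        raise ValueError(f"PCA dimensionality {d} out of range for shape {matrix.shape}")
    mu = matrix.mean(axis=0)
    centred = matrix - mu
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    # full eigenspectrum is kept so sweeps can reuse a single decomposition
    return PCAResult(u[:, :d], s[:d, None] * vt[:d], s**2, mu)


@dataclass
class ICAResult:
    """FastICA decomposition of PCA coordinates in the IDP dimension.

    ``idp_weights`` (d x n_idps) are the unit-variance independent source
    vectors; ``mixing`` (d x d) maps sources back to PCA coordinates, so the
    subject-weight matrix is ``pca.basis @ mixing``.
    """

    idp_weights: np.ndarray
    mixing: np.ndarray
    seed_used: int
    n_iter: int

    def subject_weights(self, basis: np.ndarray) -> np.ndarray:
        return np.asarray(basis) @ self.mixing


def _fastica(
    data: np.ndarray, n_components: int, rng_seed: int, max_restarts: int = 5
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """FastICA with seeded restarts on non-convergence.

    ``data`` is samples x features.  Returns (sources, mixing, seed, n_iter);
    sources are samples x components with unit variance.
    """
    last_err: Exception | None = None
    for attempt in range(max_restarts):
        seed = int(rng_seed) + 7919 * attempt
        ica = FastICA(
            n_components=n_components,
            fun="logcosh",
            whiten="unit-variance",
            max_iter=1000,
            tol=1e-6,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                sources = ica.fit_transform(data)
            except ConvergenceWarning as err:  # retry with a fresh seed
                last_err = err
                continue
            except ValueError as err:
                last_err = err
                continue
        return sources, ica.mixing_, seed, ica.n_iter_
    raise RuntimeError(
        f"FastICA failed to converge after {max_restarts} seeded restarts"
    ) from last_err


def run_ica(pca: PCAResult, d: int, rng_seed: int, max_restarts: int = 5) -> ICAResult:
    """ICA-rotate the d-dimensional PCA coordinates into independent IDP weights."""
    coords = pca.coords
    if coords.shape[0] != d:
        raise ValueError("projected data dimensionality does not match d")
    sources, mixing, seed, n_iter = _fastica(coords.T, d, rng_seed, max_restarts)
    return ICAResult(sources.T, mixing, seed, n_iter)


def pair_matrix(c: np.ndarray, method: str = "greedy") -> tuple[list[tuple[int, int]], np.ndarray]:
    """Pair rows to columns of a square |corr| matrix.

    Greedy scheme: repeatedly take the globally largest remaining entry, fix
    that pair, and delete its row and column.  This can differ from the
    optimal assignment; ``method="hungarian"`` gives the optimal-assignment
    variant for sensitivity checks.  Pairs come back in selection order
    (decreasing score for greedy).
    """
    c = np.atleast_2d(np.asarray(c, float))
    k = c.shape[0]
    if k == 0 or c.shape[1] == 0:
        return [], np.array([])
    if method == "hungarian":
        from scipy.optimize import linear_sum_assignment

        rows, cols = linear_sum_assignment(-c)
        order = np.argsort(-c[rows, cols])
        return [(int(rows[i]), int(cols[i])) for i in order], c[rows, cols][order]
    if method != "greedy":
        raise ValueError(f"unknown pairing method {method!r}")
    work = c.copy()
    pairs: list[tuple[int, int]] = []
    scores = []
    for _ in range(min(c.shape)):
        i, j = np.unravel_index(np.argmax(work), work.shape)
        pairs.append((int(i), int(j)))
        scores.append(work[i, j])
        work[i, :] = -np.inf
        work[:, j] = -np.inf
    return pairs, np.asarray(scores)


def pair_components(
    set_a: np.ndarray, set_b: np.ndarray, method: str = "greedy"
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """One-to-one pairing of two component sets on |corr| of IDP-weight vectors.

    See :func:`pair_matrix` for the greedy scheme and its optimal-assignment
    alternative.  Returns the pairs [(i_a, i_b), ...] and their |corr| scores.
    """
    set_a = np.atleast_2d(set_a)
    set_b = np.atleast_2d(set_b)
    if set_a.shape[0] != set_b.shape[0]:
        raise ValueError("component counts differ")
    if set_a.shape[0] == 0:
        return [], np.array([])
    return pair_matrix(abs_corr_matrix(set_a, set_b), method)


@dataclass
class _SplitRun:
    """One split-half reproducibility evaluation."""

    full: ICAResult | None
    full_pca: PCAResult
    reproducible: np.ndarray  # bool per full-run component
    pair_scores: np.ndarray  # min of the two half-run match |corr| per component
    count: int = field(init=False)

    def __post_init__(self) -> None:
        self.count = int(self.reproducible.sum())


def _split_half_once(
    matrix: np.ndarray,
    d: int,
    r_thresh: float,
    rng: np.random.Generator,
    method: str = "greedy",
) -> _SplitRun:
    n = matrix.shape[0]
    full_pca = pca_reduce(matrix, d)
    try:
        full = run_ica(full_pca, d, int(rng.integers(2**31 - 1)))
    except RuntimeError:
        # non-identifiable data (e.g. Gaussian-only): nothing reproducible
        warnings.warn("full-data ICA did not converge; split counted as 0", stacklevel=3)
        return _SplitRun(None, full_pca, np.zeros(d, bool), np.zeros(d))
    perm = rng.permutation(n)
    halves = (perm[: n // 2], perm[n // 2 :])
    min_scores = np.full(d, np.inf)
    for half in halves:
        half_pca = pca_reduce(matrix[half], d)
        try:
            half_ica = run_ica(half_pca, d, int(rng.integers(2**31 - 1)))
        except RuntimeError:
            warnings.warn("half-sample ICA did not converge", stacklevel=3)
            min_scores[:] = 0.0
            continue
        pairs, scores = pair_components(full.idp_weights, half_ica.idp_weights, method)
        for (i, _), s in zip(pairs, scores):
            min_scores[i] = min(min_scores[i], s)
    reproducible = min_scores > r_thresh
    return _SplitRun(full, full_pca, reproducible, min_scores)


def split_half_reproducibility(
    matrix: np.ndarray,
    d: int,
    n_splits: int = 10,
    r_thresh: float = 0.9,
    rng_seed: int = 0,
    method: str = "greedy",
) -> tuple[float, list[np.ndarray]]:
    """Mean reproducible-component count at PCA dimensionality ``d``.

    Per split: ICA is run on the full data and on two random half-samples;
    both half runs are paired to the full run, and a full-run component is
    reproducible when both paired half components exceed ``r_thresh`` in
    |corr| of their IDP-weight vectors.  Counts are averaged over splits.

    Returns the mean count and the per-split pair-score vectors.
    """
    n = matrix.shape[0]
    if d > n // 2 or d > matrix.shape[1]:
        raise ValueError(f"d={d} exceeds half-sample rank")
    rng = np.random.default_rng(rng_seed)
    counts = []
    score_vectors = []
    for _ in range(n_splits):
        run = _split_half_once(matrix, d, r_thresh, rng, method)
        counts.append(run.count)
        score_vectors.append(run.pair_scores)
    return float(np.mean(counts)), score_vectors


def sweep_dimensionality(
    matrix: np.ndarray,
    dims: range | list[int],
    n_splits: int = 10,
    r_thresh: float = 0.9,
    rng_seed: int = 0,
    method: str = "greedy",
) -> ReproducibilityReport:
    """Evaluate reproducibility over candidate PCA dimensionalities.

    The chosen dimensionality maximises the mean reproducible count; ties go
    to the larger dimensionality (richest description).
    """
    dims = list(dims)
    if not dims:
        raise ValueError("empty dimensionality range")
    counts: dict[int, float] = {}
    pair_corrs: dict[int, list[np.ndarray]] = {}
    for d in dims:
        mean_count, scores = split_half_reproducibility(
            matrix, d, n_splits, r_thresh, rng_seed + d, method
        )
        counts[d] = mean_count
        pair_corrs[d] = scores
    best = max(counts.values())
    chosen = max(d for d, c in counts.items() if c == best)
    return ReproducibilityReport(counts, chosen, pair_corrs)


def project_subject_weights(matrix: np.ndarray, idp_weights: np.ndarray) -> np.ndarray:
    """Subject weights from projecting data onto the pseudoinverse of IDP weights.

    The matrix is column-demeaned first.  Used with the standard
    deconfounded matrix this reproduces a ModeSet's subject weights; used
    with a matrix deconfounded *without* sex it yields the sex-retaining
    subject weights needed for sex-separated aging curves.
    """
    matrix = np.asarray(matrix, float)
    centred = matrix - matrix.mean(axis=0)
    return centred @ np.linalg.pinv(np.atleast_2d(idp_weights))


def finalize_modes(
    weighted_matrix: np.ndarray,
    deconfounded_matrix: np.ndarray,
    chosen_dim: int,
    age: np.ndarray,
    n_runs: int = 30,
    r_thresh: float = 0.9,
    rng_seed: int = 0,
    method: str = "greedy",
) -> ModeSet:
    """Final robust mode estimation at the chosen PCA dimensionality.

    ICA with random split-half evaluation is rerun ``n_runs`` times; the run
    with the highest reproducible count wins (ties: first encountered), and
    only its reproducible full-data components are retained.  Subject
    weights are then recomputed by projecting the *deconfounded* (not
    age-weighted) data onto the pseudoinverse of the retained IDP weights,
    so the age weighting shapes discovery only, not downstream statistics.
    Every mode is sign-oriented to correlate non-negatively with age and
    modes are ordered by decreasing variance explained by a cubic age model.
    """
    age = np.asarray(age, float).ravel()
    rng = np.random.default_rng(rng_seed)
    best: _SplitRun | None = None
    for _ in range(n_runs):
        run = _split_half_once(weighted_matrix, chosen_dim, r_thresh, rng, method)
        if best is None or run.count > best.count:
            best = run
    assert best is not None
    if best.count == 0:
        raise RuntimeError(
            "no reproducible components at the chosen dimensionality; "
            f"best pair scores {np.sort(best.pair_scores)[::-1][:5]}"
        )
    idp_weights = best.full.idp_weights[best.reproducible]
    repro = best.pair_scores[best.reproducible]

    subject_weights = project_subject_weights(deconfounded_matrix, idp_weights)

    # orient: subject weights positively correlated with age
    for i in range(idp_weights.shape[0]):
        if safe_corr(subject_weights[:, i], age) < 0:
            idp_weights[i] *= -1.0
            subject_weights[:, i] *= -1.0

    order_stat = np.array(
        [cubic_age_r2(subject_weights[:, i], age) for i in range(idp_weights.shape[0])]
    )
    order = np.argsort(-order_stat)
    return ModeSet(
        idp_weights[order],
        subject_weights[:, order],
        order_stat[order],
        repro[order],
        pca_dim=chosen_dim,
    )


def _max_abs_corr_null(
    n_samples: int,
    n_vectors: int,
    n_reps: int,
    rng: np.random.Generator,
    batch: int = 2000,
) -> np.ndarray:
    """Per-repetition max |corr| between one random vector and ``n_vectors`` others."""
    maxima = np.empty(n_reps)
    done = 0
    while done < n_reps:
        b = min(batch, n_reps - done)
        probe = rng.standard_normal((b, n_samples))
        others = rng.standard_normal((b, n_vectors, n_samples))
        probe -= probe.mean(axis=1, keepdims=True)
        probe /= np.linalg.norm(probe, axis=1, keepdims=True)
        others -= others.mean(axis=2, keepdims=True)
        others /= np.linalg.norm(others, axis=2, keepdims=True)
        corr = np.abs(np.einsum("bn,bmn->bm", probe, others))
        maxima[done : done + b] = corr.max(axis=1)
        done += b
    return maxima


def null_max_correlation(
    n_samples: int = 62,
    n_vectors: int = 128,
    n_reps: int = 1_000_000,
    rng_seed: int = 0,
    percentiles: tuple[float, ...] = (50.0, 90.0, 99.0),
) -> dict:
    """Null distribution of the maximum |corr| against many random vectors.

    Per repetition one Gaussian vector of length ``n_samples`` is correlated
    with ``n_vectors`` independent Gaussian vectors and the maximum |corr|
    recorded.  This calibrates how large the split-half pairing statistic
    can get purely by chance at the most conservative degrees of freedom.

    Returns ``{"max": ..., "percentiles": {p: value}, "n_reps": ...}``.
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples for a correlation")
    rng = np.random.default_rng(rng_seed)
    # keep per-batch memory around 100-200 MB
    batch = max(1, min(4000, int(2e8 / (8 * (n_vectors + 1) * n_samples))))
    maxima = _max_abs_corr_null(n_samples, n_vectors, n_reps, rng, batch)
    return {
        "max": float(maxima.max()),
        "percentiles": {float(p): float(np.percentile(maxima, p)) for p in percentiles},
        "n_reps": int(n_reps),
    }


def null_weighting_test(
    n_subjects: int = 18707,
    n_modes: int = 128,
    n_reps: int = 100,
    rng_seed: int = 0,
) -> float:
    """Null calibration of the age-weighting step.

    Approximates the "random vector instead of age" control: under the null
    the resulting subject-weight vectors are independent of the probe
    vector, so per repetition one Gaussian probe of length ``n_subjects`` is
    correlated with ``n_modes`` independent Gaussian vectors.  Returns the
    maximum |corr| across all repetitions and modes.
    """
    rng = np.random.default_rng(rng_seed)
    batch = max(1, min(n_reps, int(2e8 / (8 * (n_modes + 1) * n_subjects))))
    maxima = _max_abs_corr_null(n_subjects, n_modes, n_reps, rng, batch)
    return float(maxima.max())


def group_reduce(
    idp_weights: np.ndarray,
    modality_groups: list[str],
    var_explained: float = 0.9,
    max_dim: int = 10,
    retain_frac: float = 0.5,
    rng_seed: int = 0,
) -> dict[str, np.ndarray]:
    """Reduce each modality group of IDPs to representative pseudo-IDPs.

    Per group the modes x group-IDPs block is PCA-reduced (smallest
    dimensionality explaining ``var_explained`` of block variance, capped at
    ``max_dim``) and ICA-rotated; each resulting column pattern across modes
    is one pseudo-IDP.  Components whose maximum |weight| falls below
    ``retain_frac`` of the strongest component's are dropped, but at least
    one pseudo-IDP is always kept per group.

    Returns ``{group: modes x n_pseudo weight matrix}``.
    """
    idp_weights = np.atleast_2d(np.asarray(idp_weights, float))
    groups = np.asarray(modality_groups)
    if groups.size != idp_weights.shape[1]:
        raise ValueError("every IDP must carry a modality-group label")
    n_modes = idp_weights.shape[0]
    out: dict[str, np.ndarray] = {}
    for g in dict.fromkeys(modality_groups):  # preserve first-seen order
        block = idp_weights[:, groups == g]  # modes x Nj
        if block.shape[1] == 1:
            out[g] = block.copy()
            continue
        # PCA over IDPs-as-samples in mode space
        centred = block.T - block.T.mean(axis=0)
        s = np.linalg.svd(centred, compute_uv=False)
        var = s**2
        ratio = np.cumsum(var) / var.sum() if var.sum() > 0 else np.ones_like(var)
        d = int(np.searchsorted(ratio, var_explained) + 1)
        d = min(d, max_dim, block.shape[1], n_modes)
        if d == 1:
            # a single component needs no ICA rotation: dominant SVD axis
            u, sv, _ = np.linalg.svd(block, full_matrices=False)
            mixing = u[:, :1] * sv[:1]
        else:
            try:
                _, mixing, _, _ = _fastica(block.T, d, rng_seed)
            except RuntimeError:
                # degenerate block: fall back to SVD axes
                u, sv, _ = np.linalg.svd(block, full_matrices=False)
                mixing = u[:, :d] * sv[:d]
        maxw = np.abs(mixing).max(axis=0)
        keep = maxw >= retain_frac * maxw.max()
        if not keep.any():
            keep[np.argmax(maxw)] = True
        out[g] = mixing[:, keep]
    return out
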