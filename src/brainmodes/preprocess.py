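"""Cleaning and normalisation of the subjects x IDPs matrix.

The pipeline order is fixed: per-column outlier removal (6 x MAD from the
median), rank-based inverse normal transformation ("quantile
normalisation"), exclusion of subjects with too many missing IDPs, noise
fill of remaining missing cells with N(0, 0.01^2) draws, and finally
confound regression.  Each step is also exposed on its own for reuse (the
non-imaging variables go through the same quantile normalisation and a
sex-separated deconfounding that *includes* age-derived confounds).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata

from .containers import ConfoundTable, IDPMatrix

__all__ = [
    "remove_outliers_mad",
    "quantile_normalise",
    "filter_subjects_by_missingness",
    "impute_missing_noise",
    "deconfound",
    "with_age_confounds",
    "preprocess_idps",
]


def remove_outliers_mad(
    values: np.ndarray, mask: np.ndarray | None = None, k: float = 6.0
) -> tuple[np.ndarray, np.ndarray]:
    """Flag entries further than ``k`` median absolute deviations from the median.

    The MAD is unscaled (no Gaussian consistency factor).  Flagged entries are
    set missing in the returned mask; values are left in place.  A column with
    MAD exactly zero (e.g. constant) flags nothing, with a warning, since the
    rule degenerates there.

    Returns ``(values, updated_mask)``.
    """
    values = np.asarray(values, dtype=float)
    mask = np.zeros_like(values, dtype=bool) if mask is None else mask.copy()
    present = ~mask
    if present.sum() < 2:
        raise ValueError("need at least 2 non-missing values for outlier removal")
    med = np.median(values[present])
    mad = np.median(np.abs(values[present] - med))
    if mad == 0.0:
        warnings.warn("MAD is zero; no outliers flagged", stacklevel=2)
        return values, mask
    flag = present & (np.abs(values - med) > k * mad)
    mask[flag] = True
    return values, mask


def quantile_normalise(
    values: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Rank-based inverse normal transform of the non-missing entries.

    Ranks use Blom offsets, Phi^-1((r - 3/8) / (n + 1/4)), with average ranks
    on ties, yielding an approximately standard-Gaussian column.  Missing
    entries are returned unchanged (callers keep the mask).
    """
    values = np.asarray(values, dtype=float)
    mask = np.zeros_like(values, dtype=bool) if mask is None else np.asarray(mask, bool)
    present = ~mask
    n = int(present.sum())
    if n < 3:
        raise ValueError("need at least 3 non-missing values to quantile normalise")
    out = values.copy()
    ranks = rankdata(values[present], method="average")
    out[present] = ndtri((ranks - 3.0 / 8.0) / (n + 1.0 / 4.0))
    return out


def filter_subjects_by_missingness(
    matrix: IDPMatrix, max_missing: int = 50
) -> tuple[IDPMatrix, list[str]]:
    """Drop subjects with ``max_missing`` or more missing IDPs.

    Returns the reduced matrix (subject order preserved) and the list of
    dropped subject ids.
    """
    counts = matrix.missing_mask.sum(axis=1)
    keep = counts < max_missing
    dropped = [s for s, k in zip(matrix.subject_ids, keep) if not k]
    if not keep.any():
        warnings.warn("all subjects dropped by missingness filter", stacklevel=2)
    reduced = IDPMatrix(
        matrix.values[keep],
        matrix.missing_mask[keep],
        [s for s, k in zip(matrix.subject_ids, keep) if k],
        list(matrix.idp_ids),
        list(matrix.modality_groups),
    )
    return reduced, dropped


def impute_missing_noise(
    matrix: IDPMatrix, sd: float = 0.01, rng_seed: int = 0
) -> np.ndarray:
    """Replace missing cells with close-to-zero noise, N(0, sd^2).

    Assumes columns are already quantile normalised (unit variance), so the
    fills are negligible relative to real signal.  Returns a dense array.
    """
    rng = np.random.default_rng(rng_seed)
    out = matrix.values.copy()
    n_missing = int(matrix.missing_mask.sum())
    out[matrix.missing_mask] = rng.normal(0.0, sd, size=n_missing)
    return out


def _sex_separate(confounds: np.ndarray, sex: np.ndarray) -> np.ndarray:
    """Split every confound column into one column per sex (zero elsewhere)."""
    sex = np.asarray(sex).ravel()
    levels = np.unique(sex)
    cols = []
    for level in levels:
        ind = (sex == level).astype(float)
        cols.append(confounds * ind[:, None])
    return np.column_stack(cols)


def deconfound(
    data: np.ndarray,
    confounds: ConfoundTable | np.ndarray,
    include_age_related: bool = False,
    sex_separated: bool = False,
    sex: np.ndarray | None = None,
) -> np.ndarray:
    """Regress confounds (plus intercept) out of every column of ``data``.

    ``include_age_related=False`` is the IDP pathway (age signal must survive
    into mode discovery); ``True`` is the nIDP pathway.  With
    ``sex_separated`` each confound is zeroed outside each sex before
    regression, to avoid instability for variables existing in one sex only.
    Rank deficiency is handled by the pseudoinverse (with a warning).
    """
    data = np.asarray(data, dtype=float)
    if isinstance(confounds, ConfoundTable):
        conf = confounds.matrix(include_age_related=include_age_related)
        if sex is None and "sex" in confounds.frame.columns:
            sex = confounds.frame["sex"].to_numpy()
    else:
        conf = np.atleast_2d(np.asarray(confounds, dtype=float))
    if conf.shape[0] != data.shape[0]:
        raise ValueError("confounds and data have different numbers of subjects")
    if sex_separated:
        if sex is None:
            raise ValueError("sex vector required for sex-separated deconfounding")
        conf = _sex_separate(conf, sex)
    design = np.column_stack([np.ones(data.shape[0]), conf])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient confound matrix; using pseudoinverse", stacklevel=2)
    beta = np.linalg.pinv(design) @ data
    return data - design @ beta


def with_age_confounds(confounds: ConfoundTable, age: np.ndarray) -> ConfoundTable:
    """Append age, age^2, age^3 columns flagged as age-related.

    The flagged columns are skipped when deconfounding the IDP matrix but
    included for the nIDP pathway.
    """
    age = np.asarray(age, float).ravel()
    frame = confounds.frame.copy()
    for name, col in (("age", age), ("age_sq", age**2), ("age_cu", age**3)):
        frame[name] = col - col.mean()
    return ConfoundTable(frame, age_related=list(confounds.age_related) + ["age", "age_sq", "age_cu"])


def preprocess_idps(
    matrix: IDPMatrix,
    confounds: ConfoundTable,
    k: float = 6.0,
    max_missing: int = 50,
    noise_sd: float = 0.01,
    rng_seed: int = 0,
) -> tuple[np.ndarray, IDPMatrix, list[str]]:
    """Run the full IDP cleaning pipeline.

    Returns ``(dense deconfounded matrix, cleaned IDPMatrix, dropped ids)``.
    The returned :class:`IDPMatrix` reflects the state after quantile
    normalisation and subject filtering (with the updated missingness mask).
    """
    work = matrix.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns are tolerated
        for j in range(work.n_idps):
            _, m = remove_outliers_mad(work.values[:, j], work.missing_mask[:, j], k=k)
            work.missing_mask[:, j] = m
            work.values[:, j] = quantile_normalise(work.values[:, j], work.missing_mask[:, j])
    work, dropped = filter_subjects_by_missingness(work, max_missing=max_missing)
    conf_frame = confounds.frame.loc[work.subject_ids]
    conf = ConfoundTable(conf_frame, age_related=list(confounds.age_related))
    dense = impute_missing_noise(work, sd=noise_sd, rng_seed=rng_seed)
    dense = deconfound(dense, conf, include_age_related=False)
    return dense, work, dropped
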