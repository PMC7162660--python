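"""Two-step bias-corrected brain-age delta modelling.

Step 1 regresses age Y on the modes' subject-weight matrix X:
``Y = X b1 - d1``, so d1 = X b1 - Y is predicted-minus-actual age
(positive = older-appearing brain).  d1 is orthogonal to X rather than to
age, which leaves an age-dependent bias; step 2 removes it by regressing d1
on a design Y2 of [age, age^2, age^3, confounds]: ``d1 = Y2 b2 + d2``.  The
residual d2 is the bias-corrected delta, orthogonal to every Y2 column
including age.

Both steps are linear, so the delta decomposes exactly over modes:
``d1_i = X_i b1_i - a Y`` with an arbitrary per-mode share ``a`` (default
1/n_modes, summing to 1 — its value is immaterial because the a*Y term is
removed by step 2), and the per-mode step-2 residuals d2_i sum to d2.

All regressions demean their inputs and carry an intercept; delta vectors
are therefore mean zero after step 2.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .containers import AgeDesign, DeltaSet

__all__ = [
    "fit_delta_step1",
    "fit_delta_step2",
    "fit_deltas",
    "partial_deltas",
    "mean_abs_delta",
    "fit_age_curves",
    "nonadditive_test",
    "all_in_one_idp_delta",
]


def _residualise(y: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Residual and coefficients of y on [1, design], via pseudoinverse."""
    d = np.column_stack([np.ones(design.shape[0]), design])
    if np.linalg.matrix_rank(d) < d.shape[1]:
        warnings.warn("rank-deficient design; using pseudoinverse", stacklevel=3)
    beta = np.linalg.pinv(d) @ y
    return y - d @ beta, beta


def fit_delta_step1(
    x: np.ndarray, y: np.ndarray, a: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First-step delta: multiple regression of age on subject weights.

    Returns ``(beta1, delta1, delta1_per_mode)`` with
    ``delta1 = Xc beta1 - Yc`` (demeaned X and Y) and
    ``delta1_per_mode[:, i] = Xc_i beta1_i - a Yc``; the per-mode shares a
    sum to 1 over modes so the per-mode columns sum exactly to delta1.
    """
    x = np.atleast_2d(np.asarray(x, float))
    y = np.asarray(y, float).ravel()
    if x.shape[0] != y.size:
        raise ValueError("subject counts differ between X and age")
    n_modes = x.shape[1]
    if a is None:
        a = 1.0 / n_modes
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    if np.linalg.matrix_rank(xc) < n_modes:
        warnings.warn("rank-deficient subject-weight matrix; pseudoinverse", stacklevel=2)
    beta1 = np.linalg.pinv(xc) @ yc
    delta1 = xc @ beta1 - yc
    delta1_per_mode = xc * beta1[None, :] - a * yc[:, None]
    return beta1, delta1, delta1_per_mode


def fit_delta_step2(
    delta1: np.ndarray, delta1_per_mode: np.ndarray, design: AgeDesign
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Second-step bias removal: residualise delta1 on [age, age^2, age^3, confounds].

    Returns ``(beta2_per_mode, delta2, delta2_per_mode)``; delta2 is
    orthogonal to every design column and the per-mode residuals sum to it.
    """
    y2 = design.y2
    delta2, _ = _residualise(np.asarray(delta1, float), y2)
    beta2 = []
    cols = []
    for i in range(delta1_per_mode.shape[1]):
        resid, b = _residualise(delta1_per_mode[:, i], y2)
        cols.append(resid)
        beta2.append(b)
    return np.asarray(beta2), delta2, np.column_stack(cols)


def fit_deltas(
    x: np.ndarray, design: AgeDesign, a: float | None = None, partial: bool = True
) -> DeltaSet:
    """Convenience wrapper running both steps (and optionally partialling)."""
    beta1, d1, d1m = fit_delta_step1(x, design.age, a)
    beta2, d2, d2m = fit_delta_step2(d1, d1m, design)
    part = partial_deltas(d2m) if (partial and d2m.shape[1] >= 2) else None
    n_modes = np.atleast_2d(x).shape[1]
    return DeltaSet(beta1, d1, d1m, a if a is not None else 1.0 / n_modes, beta2, d2, d2m, part)


def partial_deltas(delta_per_mode: np.ndarray) -> np.ndarray:
    """Unique variance of each mode's delta.

    Column i is the residual of delta_i after regressing out every other
    mode's delta (with an intercept).  The same operation applies verbatim
    to subject-weight vectors.
    """
    d = np.atleast_2d(np.asarray(delta_per_mode, float))
    if d.shape[1] < 2:
        raise ValueError("partialling requires at least 2 modes")
    out = np.empty_like(d)
    for i in range(d.shape[1]):
        others = np.delete(d, i, axis=1)
        out[:, i], _ = _residualise(d[:, i], others)
    return out


def mean_abs_delta(delta: np.ndarray) -> float:
    """Mean absolute delta in years (the brain-age 'error')."""
    delta = np.asarray(delta, float).ravel()
    if delta.size == 0:
        raise ValueError("empty delta vector")
    return float(np.mean(np.abs(delta)))


def fit_age_curves(
    values: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray | None = None,
    window: float = 5.0,
    min_bin_n: int = 10,
) -> dict:
    """Cubic age fit plus model-free sliding-window mean curves.

    The cubic fit regresses ``values`` on [1, age, age^2, age^3].  Sliding
    windows of width ``window`` (default 5y, i.e. half-width 2.5y) average
    the data around each 1-year age-bin centre; bins with fewer than
    ``min_bin_n`` subjects are suppressed.  Curves are computed for all
    subjects and, if ``sex`` is given, for each sex separately.

    Returns ``{"coefficients", "centres", "curves": {group: values}}``.
    """
    values = np.asarray(values, float).ravel()
    age = np.asarray(age, float).ravel()
    if age.max() - age.min() < window:
        raise ValueError("age span smaller than the sliding window")
    design = np.column_stack([np.ones_like(age), age, age**2, age**3])
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)

    centres = np.arange(np.ceil(age.min()), np.floor(age.max()) + 1.0)
    half = window / 2.0

    def windowed(sel: np.ndarray) -> np.ndarray:
        out = np.full(centres.size, np.nan)
        for i, c in enumerate(centres):
            inwin = sel & (np.abs(age - c) <= half)
            if inwin.sum() >= min_bin_n:
                out[i] = values[inwin].mean()
        return out

    curves = {"all": windowed(np.ones_like(age, dtype=bool))}
    if sex is not None:
        sex = np.asarray(sex).ravel()
        for label, code in (("female", 0), ("male", 1)):
            sel = sex == code
            if not sel.any():
                warnings.warn(f"empty {label} stratum; curve omitted", stacklevel=2)
                continue
            curves[label] = windowed(sel)
    return {"coefficients": coef, "centres": centres, "curves": curves}


def nonadditive_test(delta2_i: np.ndarray, age: np.ndarray) -> dict:
    """Test whether the *scale* of delta changes across the age range.

    The additive brain-age model treats delta as constant in scale over age;
    an age-dependent scale (e.g. accelerating aging) shows up as a trend in
    |delta| with age.  We regress |delta2| on demeaned age and report the
    slope, its t statistic and the two-sided p (positive slope = delta grows
    with age).
    """
    d = np.abs(np.asarray(delta2_i, float).ravel())
    age = np.asarray(age, float).ravel()
    res = stats.linregress(age - age.mean(), d)
    df = d.size - 2
    t = res.slope / res.stderr if res.stderr > 0 else 0.0
    return {
        "slope": float(res.slope),
        "t": float(t),
        "p": float(res.pvalue),
        "df": int(df),
    }


def all_in_one_idp_delta(
    idp_matrix: np.ndarray, design: AgeDesign, pca_dim: int = 55
) -> DeltaSet:
    """Single brain-age delta from all IDPs with PCA pre-reduction.

    The preprocessed IDP matrix is reduced to ``pca_dim`` principal
    component scores, which then enter the usual two-step delta model as the
    'modes'.  Returns a DeltaSet whose delta2 is the single all-in-one
    bias-corrected delta.
    """
    m = np.asarray(idp_matrix, float)
    centred = m - m.mean(axis=0)
    if pca_dim > min(centred.shape):
        raise ValueError(f"pca_dim {pca_dim} exceeds matrix rank bound")
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    scores = u[:, :pca_dim] * s[:pca_dim]
    return fit_deltas(scores, design, partial=False)
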