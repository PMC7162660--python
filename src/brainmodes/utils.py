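"""Small numerical helpers used across modules."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["abs_corr_matrix", "safe_corr", "cubic_age_r2", "pearson_pvalue", "neglog10_p"]

#: cap on -log10 p in output tables, to avoid underflow artefacts
LOG10P_CAP = 320.0


def safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; 0.0 if either vector has zero variance."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def abs_corr_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """|corr| between every row of ``a`` and every row of ``b``.

    Rows with zero variance yield zero correlation.
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    an = np.linalg.norm(ac, axis=1)
    bn = np.linalg.norm(bc, axis=1)
    an[an == 0] = np.inf
    bn[bn == 0] = np.inf
    c = (ac / an[:, None]) @ (bc / bn[:, None]).T
    return np.abs(np.clip(c, -1.0, 1.0))


def cubic_age_r2(values: np.ndarray, age: np.ndarray) -> float:
    """Fraction of variance explained by a cubic polynomial model of age."""
    values = np.asarray(values, float).ravel()
    age = np.asarray(age, float).ravel()
    design = np.column_stack([np.ones_like(age), age, age**2, age**3])
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    fitted = design @ beta
    total = np.sum((values - values.mean()) ** 2)
    if total == 0.0:
        return 0.0
    resid = np.sum((values - fitted) ** 2)
    return float(max(0.0, 1.0 - resid / total))


def pearson_pvalue(r: float | np.ndarray, n: int | np.ndarray) -> np.ndarray:
    """Two-sided p for a Pearson correlation via the t transform, df = n - 2."""
    r = np.asarray(r, float)
    n = np.asarray(n)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def neglog10_p(p: np.ndarray) -> np.ndarray:
    """-log10 p, capped at :data:`LOG10P_CAP`."""
    p = np.asarray(p, float)
    with np.errstate(divide="ignore"):
        out = -np.log10(p)
    return np.minimum(out, LOG10P_CAP)
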