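"""Desk-scale genetic association for brain-age deltas.

Variant QC (MAF >= 1%, imputation info >= 0.3, Hardy-Weinberg equilibrium
p >= 1e-7), per-variant linear regression of a delta on dosage with
covariates, a seed-reproducible discovery/replication subject split, and
the iterative centimorgan-window peak-clumping algorithm that reduces each
region of high linkage disequilibrium to its single lead variant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypePanel
from .utils import neglog10_p

__all__ = [
    "qc_filter_variants",
    "hwe_pvalues",
    "split_subjects",
    "gwas_linear",
    "clump_peaks",
    "replicate_peaks",
    "bonferroni_threshold",
]


def hwe_pvalues(n_homref: np.ndarray, n_het: np.ndarray, n_homalt: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg equilibrium p per variant (chi-square, 1 df).

    Expected genotype counts follow from the allele frequency implied by the
    observed counts; a chi-square test with one degree of freedom is
    appropriate at the large per-variant counts this pipeline works with.
    """
    n_homref = np.asarray(n_homref, float)
    n_het = np.asarray(n_het, float)
    n_homalt = np.asarray(n_homalt, float)
    n = n_homref + n_het + n_homalt
    p_alt = (2 * n_homalt + n_het) / (2 * n)
    exp = np.stack(
        [n * (1 - p_alt) ** 2, 2 * n * p_alt * (1 - p_alt), n * p_alt**2]
    )
    obs = np.stack([n_homref, n_het, n_homalt])
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.nansum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0), axis=0)
    return stats.chi2.sf(chi2, df=1)


def qc_filter_variants(
    panel: GenotypePanel,
    maf_min: float = 0.01,
    info_min: float = 0.3,
    hwe_p_min: float = 1e-7,
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Apply the three variant quality-control filters.

    A variant is kept iff MAF >= ``maf_min`` AND info >= ``info_min`` AND
    HWE p >= ``hwe_p_min``.  Returns the filtered panel and an exclusion log
    listing each dropped variant with the rule(s) it failed.
    """
    v = panel.variants
    hwe_p = hwe_pvalues(v["n_homref"], v["n_het"], v["n_homalt"])
    fail_maf = v["maf"].to_numpy() < maf_min
    fail_info = v["info"].to_numpy() < info_min
    fail_hwe = hwe_p < hwe_p_min
    keep = ~(fail_maf | fail_info | fail_hwe)
    log_rows = []
    for i in np.flatnonzero(~keep):
        rules = [
            name
            for name, failed in (
                ("maf", fail_maf[i]),
                ("info", fail_info[i]),
                ("hwe", fail_hwe[i]),
            )
            if failed
        ]
        log_rows.append(
            {"variant_id": v["variant_id"].iloc[i], "failed": "+".join(rules)}
        )
    return panel.subset_variants(np.flatnonzero(keep)), pd.DataFrame(
        log_rows, columns=["variant_id", "failed"]
    )


def split_subjects(
    n_subjects: int, discovery_fraction: float = 2.0 / 3.0, rng_seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint discovery/replication index split (seed-reproducible)."""
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n_subjects)
    n_disc = int(round(discovery_fraction * n_subjects))
    return np.sort(perm[:n_disc]), np.sort(perm[n_disc:])


def gwas_linear(
    delta: np.ndarray,
    panel: GenotypePanel,
    covariates: np.ndarray | None = None,
    phenotype: str = "delta",
    cohort: str = "discovery",
) -> pd.DataFrame:
    """Univariate linear regression of a delta on every variant's dosage.

    Covariates (e.g. population-structure components) plus an intercept are
    projected out of both the delta and the dosages; the per-variant effect,
    standard error, t and two-sided p then follow from the residual simple
    regression with df = n - n_covariates - 2.  Monomorphic or
    covariate-collinear dosages yield a flagged row with undefined effect.
    """
    delta = np.asarray(delta, float).ravel()
    n = delta.size
    if panel.dosages.shape[0] != n:
        raise ValueError("delta and panel subject counts differ")
    n_cov = 0 if covariates is None else np.atleast_2d(covariates).shape[1]
    design = np.ones((n, 1))
    if covariates is not None:
        design = np.column_stack([design, covariates])
    proj = np.linalg.pinv(design)
    resid_d = delta - design @ (proj @ delta)
    g = panel.dosages
    resid_g = g - design @ (proj @ g)
    df = n - n_cov - 2
    vg = (resid_g**2).sum(axis=0)
    ok = vg > n * np.finfo(float).eps * max(1.0, float(np.abs(g).max()) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (resid_g * resid_d[:, None]).sum(axis=0) / vg
        rss = (resid_d**2).sum() - beta**2 * vg
        rss = np.maximum(rss, 0.0)
        se = np.sqrt(rss / df / vg)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    out = panel.variants[["variant_id", "chrom", "pos_bp", "pos_cm"]].copy()
    out["phenotype"] = phenotype
    out["cohort"] = cohort
    out["n"] = n
    out["beta"] = np.where(ok, beta, np.nan)
    out["se"] = np.where(ok, se, np.nan)
    out["t"] = np.where(ok, t, np.nan)
    out["p"] = np.where(ok, p, np.nan)
    out["neglog10p"] = np.where(ok, neglog10_p(p), np.nan)
    out["defined"] = ok
    return out


def clump_peaks(
    results: pd.DataFrame, threshold_logp: float = 7.5, window_cm: float = 0.25
) -> pd.DataFrame:
    """Iterative cM-window peak clumping of one phenotype's GWAS results.

    The seed set contains every well-defined variant with
    -log10 p >= ``threshold_logp``.  Repeatedly: report the most significant
    remaining variant, then remove from the set every variant within
    ``window_cm`` of it on the same chromosome (closed interval, including
    itself).  Peaks are returned in discovery order (decreasing
    significance), so any two reported peaks on one chromosome are more than
    ``window_cm`` apart.  Exact significance ties break toward the variant
    appearing first in the results table.
    """
    r = results[results["defined"].fillna(False)] if "defined" in results else results
    r = r[r["neglog10p"] >= threshold_logp]
    if r.empty:
        return r.head(0).copy()
    work = r.sort_values("neglog10p", ascending=False, kind="stable").reset_index(drop=True)
    logp = work["neglog10p"].to_numpy()
    chrom = work["chrom"].to_numpy()
    cm = work["pos_cm"].to_numpy(float)
    alive = np.ones(len(work), dtype=bool)
    peaks = []
    while alive.any():
        idx = np.flatnonzero(alive)
        best = idx[np.argmax(logp[idx])]
        peaks.append(best)
        near = alive & (chrom == chrom[best]) & (np.abs(cm - cm[best]) <= window_cm)
        alive &= ~near
    out = work.iloc[peaks].reset_index(drop=True)
    out["window_cm"] = window_cm
    return out


def replicate_peaks(
    discovery_peaks: pd.DataFrame,
    replication_results: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Validate discovery peaks in the replication cohort.

    A peak validates iff its replication two-sided p < ``alpha`` and the
    effect sign agrees with discovery.  Peaks absent from the replication
    results count as unvalidated (logged).  Returns the annotated peak table
    and summary counts (total peaks, validated peaks, phenotypes with at
    least one peak / one validated peak).
    """
    rep = replication_results.set_index(["phenotype", "variant_id"])
    rows = []
    for _, peak in discovery_peaks.iterrows():
        key = (peak["phenotype"], peak["variant_id"])
        row = peak.to_dict()
        if key not in rep.index:
            row.update(rep_p=np.nan, rep_beta=np.nan, validated=False, missing=True)
        else:
            r = rep.loc[key]
            same_sign = np.sign(r["beta"]) == np.sign(peak["beta"])
            row.update(
                rep_p=float(r["p"]),
                rep_beta=float(r["beta"]),
                validated=bool(r["p"] < alpha and same_sign),
                missing=False,
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        counts = {"n_peaks": 0, "n_validated": 0, "n_phenotypes": 0, "n_phenotypes_validated": 0}
    else:
        counts = {
            "n_peaks": int(len(out)),
            "n_validated": int(out["validated"].sum()),
            "n_phenotypes": int(out["phenotype"].nunique()),
            "n_phenotypes_validated": int(
                out.loc[out["validated"], "phenotype"].nunique()
            ),
        }
    return out, counts


def bonferroni_threshold(base_logp: float = 7.5, n_phenotypes: int = 68) -> float:
    """Multiple-phenotype adjustment of the single-GWAS -log10 p threshold.

    Adds log10(n_phenotypes) to the base threshold (7.5 + log10(68) = 9.33
    for the 62 modes + 6 clusters family).  The returned value is rounded to
    2 decimals for reporting; callers needing the exact value can recompute
    ``base_logp + log10(n)``.
    """
    if n_phenotypes < 1:
        raise ValueError("need at least one phenotype")
    return round(base_logp + np.log10(n_phenotypes), 2)
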