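"""Association scan of brain-age deltas against non-imaging variables.

Deltas (raw or partialled) are correlated with every non-imaging variable
by simple Pearson correlation on pairwise-complete observations, for all
subjects and for each sex separately.  Variables observed in fewer than 40
subjects (within the subgroup) are skipped — the scan never imputes
non-imaging data, so degrees of freedom vary widely between variables and
p-values, not just r values, matter.  Two-sided p comes from the t
transform with n - 2 degrees of freedom; -log10 p is capped at 320 for
output stability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import NIDPTable
from .utils import LOG10P_CAP, neglog10_p, pearson_pvalue

__all__ = ["correlate_nidps", "threshold_report"]

_SUBGROUPS = {"all": None, "female": 0, "male": 1}


def correlate_nidps(
    deltas: pd.DataFrame | dict[str, np.ndarray],
    nidps: NIDPTable,
    sex: np.ndarray | None = None,
    min_n: int = 40,
    subgroups: tuple[str, ...] = ("all",),
    partialled: bool = False,
) -> pd.DataFrame:
    """Pearson association table of every (delta phenotype, variable) pair.

    ``deltas`` maps phenotype id to a per-subject delta vector (aligned with
    the rows of ``nidps.frame``).  ``subgroups`` may include "female"/"male"
    (requires ``sex`` coded 0 = female, 1 = male).  Rows with fewer than
    ``min_n`` pairwise-complete observations, or zero variance within the
    subgroup, are omitted.

    Returns a DataFrame with columns phenotype, variable, group, subgroup,
    partialled, n, r, p, neglog10p.
    """
    if isinstance(deltas, pd.DataFrame):
        deltas = {str(c): deltas[c].to_numpy(float) for c in deltas.columns}
    nidp_values = nidps.frame.to_numpy(float)
    n_subjects = nidp_values.shape[0]
    rows: list[dict] = []
    for sub in subgroups:
        if sub not in _SUBGROUPS:
            raise ValueError(f"unknown subgroup {sub!r}")
        if sub == "all":
            sel = np.ones(n_subjects, dtype=bool)
        else:
            if sex is None:
                raise ValueError("sex vector required for sex-separated scan")
            sel = np.asarray(sex).ravel() == _SUBGROUPS[sub]
        sub_vals = nidp_values[sel]
        present = ~np.isnan(sub_vals)
        for pheno, dvec in deltas.items():
            d = np.asarray(dvec, float).ravel()
            if d.size != n_subjects:
                raise ValueError(f"delta {pheno!r} misaligned with nIDP table")
            dsub = d[sel]
            # pairwise-complete moments, vectorised across variables
            n_used = present.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                x = np.where(present, sub_vals, 0.0)
                w = present.astype(float)
                sx = x.sum(axis=0)
                sy = w.T @ dsub
                sxx = (x**2).sum(axis=0)
                syy = w.T @ dsub**2
                sxy = x.T @ dsub
                cov = sxy - sx * sy / np.maximum(n_used, 1)
                vx = sxx - sx**2 / np.maximum(n_used, 1)
                vy = syy - sy**2 / np.maximum(n_used, 1)
                r = cov / np.sqrt(vx * vy)
            for j, var in enumerate(nidps.variable_ids):
                n = int(n_used[j])
                if n < min_n:
                    continue
                if vx[j] <= 0 or vy[j] <= 0 or not np.isfinite(r[j]):
                    continue  # zero variance within subgroup
                rj = float(np.clip(r[j], -1.0, 1.0))
                p = float(pearson_pvalue(rj, n))
                rows.append(
                    {
                        "phenotype": pheno,
                        "variable": var,
                        "group": nidps.groups[var],
                        "subgroup": sub,
                        "partialled": bool(partialled),
                        "n": n,
                        "r": rj,
                        "p": p,
                        "neglog10p": float(neglog10_p(np.asarray(p))),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "phenotype",
            "variable",
            "group",
            "subgroup",
            "partialled",
            "n",
            "r",
            "p",
            "neglog10p",
        ],
    )


def threshold_report(
    table: pd.DataFrame,
    report_logp: float = 5.0,
    bonferroni_refs: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Report (phenotype, variable) pairs strong in *any* subgroup.

    A pair enters the report when any of its subgroup rows (all/female/male)
    reaches -log10 p > ``report_logp``; all rows of reported pairs are
    returned, annotated with pass flags at each Bonferroni reference
    threshold (defaults: 7.0 for the 62-mode family, 6.0 for the 6-cluster
    family).  Summary counts include the split by correlation sign.
    """
    if bonferroni_refs is None:
        bonferroni_refs = {"modes62": 7.0, "clusters6": 6.0}
    if table.empty:
        empty = table.copy()
        for name in bonferroni_refs:
            empty[f"pass_{name}"] = pd.Series(dtype=bool)
        return empty, {"n_pairs": 0, "n_rows": 0, "n_positive": 0, "n_negative": 0}
    hit = table[table["neglog10p"] > report_logp][["phenotype", "variable"]]
    pairs = set(map(tuple, hit.to_numpy()))
    keep = table.apply(lambda row: (row["phenotype"], row["variable"]) in pairs, axis=1)
    out = table[keep].copy()
    for name, thresh in bonferroni_refs.items():
        out[f"pass_{name}"] = out["neglog10p"] > thresh
    cap_note = f"-log10 p capped at {LOG10P_CAP:g}"
    summary = {
        "n_pairs": len(pairs),
        "n_rows": int(len(out)),
        "n_positive": int((out["r"] > 0).sum()),
        "n_negative": int((out["r"] < 0).sum()),
        "note": cap_note,
    }
    return out, summary
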