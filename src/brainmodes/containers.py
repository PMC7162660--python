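"""Core data containers shared across the pipeline.

Conventions used throughout:

* the IDP data matrix is subjects x IDPs (one row per participant);
* missingness is carried as an explicit boolean mask (``True`` = missing),
  never as sentinel values inside the data array;
* a *mode* is a rank-1 population covariation pattern described by a pair of
  vectors: an IDP-weight vector (one weight per imaging-derived phenotype)
  and a subject-weight vector (one weight per participant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IDPMatrix",
    "ConfoundTable",
    "ModeSet",
    "ReproducibilityReport",
    "ModeClusterSet",
    "AgeDesign",
    "DeltaSet",
    "NIDPTable",
    "GenotypePanel",
]


@dataclass
class IDPMatrix:
    """Subjects x IDPs data with an explicit missingness mask.

    Parameters
    ----------
    values : ndarray of shape (n_subjects, n_idps)
        Phenotype values; entries flagged in ``missing_mask`` are ignored.
    missing_mask : ndarray of bool, same shape
        ``True`` marks a missing cell.
    subject_ids, idp_ids : sequences of str
    modality_groups : sequence of str
        One modality-group label per IDP (e.g. "T1", "dMRI", "rfMRI").
    """

    values: np.ndarray
    missing_mask: np.ndarray
    subject_ids: list[str]
    idp_ids: list[str]
    modality_groups: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != self.missing_mask.shape:
            raise ValueError("values and missing_mask shapes differ")
        n_subj, n_idp = self.values.shape
        if len(self.subject_ids) != n_subj:
            raise ValueError("subject_ids length mismatch")
        if len(self.idp_ids) != n_idp:
            raise ValueError("idp_ids length mismatch")
        if len(self.modality_groups) != n_idp:
            raise ValueError("modality_groups length mismatch")
        if len(set(self.idp_ids)) != n_idp:
            raise ValueError("idp_ids must be unique")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_idps(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "IDPMatrix":
        return IDPMatrix(
            self.values.copy(),
            self.missing_mask.copy(),
            list(self.subject_ids),
            list(self.idp_ids),
            list(self.modality_groups),
        )

    def to_frame(self) -> pd.DataFrame:
        """DataFrame view with NaN in missing cells (for TSV output)."""
        vals = self.values.copy()
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(vals, index=self.subject_ids, columns=self.idp_ids)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, modality_groups: dict[str, str] | list[str]
    ) -> "IDPMatrix":
        vals = df.to_numpy(dtype=float)
        mask = np.isnan(vals)
        vals = np.where(mask, 0.0, vals)
        if isinstance(modality_groups, dict):
            groups = [modality_groups[c] for c in df.columns]
        else:
            groups = list(modality_groups)
        return cls(vals, mask, [str(s) for s in df.index], [str(c) for c in df.columns], groups)


@dataclass
class ConfoundTable:
    """Subjects x confounds design, with age-derived columns flagged.

    Columns flagged in ``age_related`` are excluded when deconfounding the
    IDP matrix (so that age signal survives into mode discovery) but included
    when deconfounding non-imaging variables.
    """

    frame: pd.DataFrame
    age_related: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame.isna().any().any():
            raise ValueError("confound table may not contain missing values")
        if self.frame.columns.duplicated().any():
            raise ValueError("confound column names must be unique")
        unknown = set(self.age_related) - set(self.frame.columns)
        if unknown:
            raise ValueError(f"age_related names not in table: {sorted(unknown)}")

    @property
    def subject_ids(self) -> list[str]:
        return [str(s) for s in self.frame.index]

    def matrix(self, include_age_related: bool = True) -> np.ndarray:
        cols = [
            c
            for c in self.frame.columns
            if include_age_related or c not in self.age_related
        ]
        return self.frame[cols].to_numpy(dtype=float)


@dataclass
class ModeSet:
    """A set of population modes from the PCA+ICA decomposition.

    ``idp_weights`` holds the ICA source vectors (modes x IDPs, mutually
    orthogonal); ``subject_weights`` the per-participant expressions
    (subjects x modes).  Modes are sign-oriented so that every
    subject-weight vector correlates non-negatively with age, and ordered by
    decreasing variance explained by a cubic model of age.
    """

    idp_weights: np.ndarray
    subject_weights: np.ndarray
    order_statistic: np.ndarray
    reproducibility: np.ndarray
    pca_dim: int
    idp_ids: list[str] | None = None
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.idp_weights = np.atleast_2d(np.asarray(self.idp_weights, dtype=float))
        self.subject_weights = np.atleast_2d(np.asarray(self.subject_weights, dtype=float))
        if self.idp_weights.shape[0] != self.subject_weights.shape[1]:
            raise ValueError("mode count mismatch between weight matrices")

    @property
    def n_modes(self) -> int:
        return self.idp_weights.shape[0]


@dataclass
class ReproducibilityReport:
    """Split-half reproducibility summary across the dimensionality sweep."""

    counts: dict[int, float]
    chosen_dim: int
    pair_correlations: dict[int, list[np.ndarray]]

    def __post_init__(self) -> None:
        for d, c in self.counts.items():
            if not (0.0 <= c <= d):
                raise ValueError(f"count {c} out of range for dim {d}")
        best = max(self.counts.values())
        if self.counts[self.chosen_dim] != best:
            raise ValueError("chosen_dim does not attain the maximum count")


@dataclass
class ModeClusterSet:
    """Low-dimensional mode-cluster decomposition.

    ``clusters`` is a :class:`ModeSet` from the low-dimensional ICA;
    ``assignment`` maps each high-dimensional mode to its best-matching
    cluster; ``cost_by_dim`` records the clustering-quality cost at every
    candidate dimensionality.
    """

    clusters: ModeSet
    assignment: np.ndarray
    cost_by_dim: dict[int, float]
    chosen_dim: int


@dataclass
class AgeDesign:
    """Design matrices for brain-age delta modelling.

    ``age_terms`` holds demeaned [age, age^2, age^3] columns; ``confounds``
    any additional confound columns; the concatenation is the second-step
    regression matrix (the bias-correction design).
    """

    age: np.ndarray
    confounds: np.ndarray | None = None
    sex: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.age = np.asarray(self.age, dtype=float).ravel()
        if self.confounds is not None:
            self.confounds = np.atleast_2d(np.asarray(self.confounds, dtype=float))
            if self.confounds.shape[0] != self.age.size:
                raise ValueError("confounds/age length mismatch")
        if self.sex is not None:
            self.sex = np.asarray(self.sex).ravel()
            if self.sex.size != self.age.size:
                raise ValueError("sex/age length mismatch")

    @property
    def age_terms(self) -> np.ndarray:
        a = self.age - self.age.mean()
        powers = np.column_stack([self.age, self.age**2, self.age**3])
        return powers - powers.mean(axis=0)

    @property
    def y2(self) -> np.ndarray:
        """Second-step design: demeaned age, age^2, age^3 plus confounds."""
        parts = [self.age_terms]
        if self.confounds is not None:
            parts.append(self.confounds - self.confounds.mean(axis=0))
        return np.column_stack(parts)


@dataclass
class DeltaSet:
    """Two-step brain-age delta estimates and their per-mode decomposition.

    delta1 is the raw (age-biased) delta, delta2 the bias-corrected delta
    orthogonal to all second-step design columns.  Per-mode columns sum to
    the corresponding total delta exactly.
    """

    beta1: np.ndarray
    delta1: np.ndarray
    delta1_per_mode: np.ndarray
    a: float
    beta2: np.ndarray
    delta2: np.ndarray
    delta2_per_mode: np.ndarray
    partialled_delta2: np.ndarray | None = None

    @property
    def n_modes(self) -> int:
        return self.delta1_per_mode.shape[1]

    @property
    def mean_abs_delta(self) -> float:
        return float(np.mean(np.abs(self.delta2)))


@dataclass
class NIDPTable:
    """Subjects x non-imaging variables, with per-variable group labels.

    Missing data is encoded as NaN in ``frame``; variables may be almost
    entirely missing (the association scan enforces its own minimum-n rule).
    """

    frame: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        missing_groups = set(self.frame.columns) - set(self.groups)
        if missing_groups:
            raise ValueError(f"variables without group label: {sorted(missing_groups)[:5]}")

    @property
    def variable_ids(self) -> list[str]:
        return [str(c) for c in self.frame.columns]


@dataclass
class GenotypePanel:
    """Dosage matrix (subjects x variants) plus per-variant metadata.

    ``variants`` columns: variant_id, chrom, pos_bp, pos_cm, maf, info,
    n_homref, n_het, n_homalt.  Dosages lie in [0, 2] (minor-allele count).
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    subject_ids: list[str]

    REQUIRED = (
        "variant_id",
        "chrom",
        "pos_bp",
        "pos_cm",
        "maf",
        "info",
        "n_homref",
        "n_het",
        "n_homalt",
    )

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        missing = set(self.REQUIRED) - set(self.variants.columns)
        if missing:
            raise ValueError(f"variant table missing columns: {sorted(missing)}")
        if self.dosages.shape != (len(self.subject_ids), len(self.variants)):
            raise ValueError("dosage shape inconsistent with ids/variants")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            warnings.warn("dosages outside [0, 2]", stacklevel=2)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_variants(self, keep: np.ndarray) -> "GenotypePanel":
        keep = np.asarray(keep)
        return GenotypePanel(
            self.dosages[:, keep],
            self.variants.iloc[keep].reset_index(drop=True),
            list(self.subject_ids),
        )

    def subset_subjects(self, keep: np.ndarray) -> "GenotypePanel":
        keep = np.asarray(keep)
        return GenotypePanel(
            self.dosages[keep],
            self.variants.copy(),
            [self.subject_ids[i] for i in keep],
        )
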