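"""Synthetic study generator with planted ground truth.

Emulates the structure of a population imaging study at configurable scale:
a subjects x IDPs matrix built as a sum of planted rank-1 modes (sparse
heavy-tailed IDP weights, so ICA identifiability holds; age-dependent
subject weights), linear confound contamination, Gaussian noise, injected
missingness and gross outliers; genotype dosage panels with block-wise
linkage disequilibrium and planted causal effects on mode subject weights;
and non-imaging variables with planted correlations to mode deltas.

Every generator is fully reproducible from its seed, and the returned
:class:`SyntheticTruth` carries everything parameter-recovery tests need.
The default scale (1000 subjects x 200 IDPs, 5 modes) keeps a full
discovery-to-GWAS run fast; shapes up to the tens of thousands of subjects
are reachable by configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ConfoundTable, GenotypePanel, IDPMatrix, NIDPTable

__all__ = [
    "SimulationConfig",
    "GenotypeConfig",
    "NIDPConfig",
    "SyntheticTruth",
    "generate_idp_dataset",
    "generate_clustered_modes",
    "generate_genotypes",
    "genetic_mode_offsets",
    "generate_nidps",
]

#: default per-mode age profiles: coefficients of (z, z^2, z^3) in
#: standardised age, cycled over modes — a mix of linear, quadratic and
#: cubic age dependence of varying strength
DEFAULT_AGE_PROFILES = (
    (1.0, 0.0, 0.0),
    (0.7, 0.3, 0.0),
    (0.5, 0.0, 0.3),
    (0.9, -0.2, 0.0),
    (0.6, 0.2, 0.2),
)

DEFAULT_CONFOUNDS = ("head_size", "sex", "motion", "table_position", "site", "date_drift")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic subjects x IDPs dataset.

    ``mode_strength`` scales the planted rank-1 terms relative to the
    unit-variance noise; the default gives strong, clearly reproducible
    modes (per-IDP signal fractions of roughly a third for involved IDPs).
    """

    n_subjects: int = 1000
    n_idps: int = 200
    n_planted_modes: int = 5
    age_range: tuple[float, float] = (45.0, 80.0)
    mode_age_profiles: tuple[tuple[float, float, float], ...] | None = None
    idp_weight_sparsity: float = 0.1
    mode_strength: float = 4.0
    noise_sd: float = 1.0
    missing_rate: float = 0.01
    outlier_rate: float = 0.002
    confound_spec: tuple[str, ...] = DEFAULT_CONFOUNDS
    confound_strength: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_modes >= min(self.n_subjects, self.n_idps):
            raise ValueError("n_planted_modes must be < min(n_subjects, n_idps)")
        for name in ("idp_weight_sparsity", "missing_rate", "outlier_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must have min < max")
        unknown = set(self.confound_spec) - set(DEFAULT_CONFOUNDS)
        if unknown:
            raise ValueError(f"unknown confound kinds: {sorted(unknown)}")

    def age_profiles(self) -> list[tuple[float, float, float]]:
        profiles = self.mode_age_profiles or DEFAULT_AGE_PROFILES
        return [profiles[k % len(profiles)] for k in range(self.n_planted_modes)]


@dataclass
class GenotypeConfig:
    """Parameters of the synthetic genotype panel.

    Linkage disequilibrium is simulated by a stationary autoregressive
    latent allele process within blocks of ``block_length_cm``; the
    adjacent-variant latent correlation is ``exp(-spacing / ld_scale_cm)``,
    so correlation decays with genetic distance and vanishes across block
    boundaries.  Genetic positions follow a 1 cM/Mb map.
    """

    n_subjects: int = 1000
    n_variants: int = 500
    n_chromosomes: int = 2
    spacing_bp: int = 5000
    block_length_cm: float = 0.1
    ld_scale_cm: float = 0.05
    maf_range: tuple[float, float] = (0.05, 0.5)
    info_range: tuple[float, float] = (0.8, 1.0)
    causal: tuple[tuple[int, int, float], ...] = ()  # (variant index, mode, effect)
    causal_maf_min: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.block_length_cm < 0:
            raise ValueError("block_length_cm must be >= 0")


@dataclass
class NIDPConfig:
    """Parameters of the synthetic non-imaging variables."""

    n_variables: int = 100
    n_groups: int = 4
    planted_effects: tuple[tuple[int, int, float], ...] = ()  # (variable, mode, r)
    missing_rate: float = 0.1
    include_sub40_variable: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for var, _mode, r in self.planted_effects:
            if not (-1.0 < r < 1.0):
                raise ValueError(f"planted correlation {r} outside (-1, 1)")
            if not (0 <= var < self.n_variables):
                raise ValueError(f"planted variable index {var} out of range")


@dataclass
class SyntheticTruth:
    """Planted ground truth for parameter-recovery tests."""

    true_idp_weights: np.ndarray
    true_subject_weights: np.ndarray
    causal_variants: list[tuple[str, int, float]] = field(default_factory=list)
    planted_nidp_effects: list[tuple[str, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_modes = self.true_idp_weights.shape[0]
        for vid, mode, _ in self.causal_variants:
            if not (0 <= mode < n_modes):
                raise ValueError(f"causal variant {vid} targets unknown mode {mode}")
        for nid, mode, _ in self.planted_nidp_effects:
            if not (0 <= mode < n_modes):
                raise ValueError(f"planted nIDP {nid} targets unknown mode {mode}")


def _confound_columns(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, list[str]]:
    n = config.n_subjects
    cols: dict[str, np.ndarray] = {}
    contaminating: list[str] = []
    spec = config.confound_spec
    if "head_size" in spec:
        cols["head_size"] = rng.normal(0, 1, n)
        contaminating.append("head_size")
    if "sex" in spec:
        cols["sex"] = rng.binomial(1, 0.54, n).astype(float)
        contaminating.append("sex")
    if "motion" in spec:
        cols["motion"] = np.exp(rng.normal(0, 0.5, n))  # right-skewed, as real motion is
        contaminating.append("motion")
    if "table_position" in spec:
        cols["table_position"] = rng.normal(0, 1, n)
        contaminating.append("table_position")
    if "site" in spec:
        cols["site_1"] = rng.binomial(1, 0.5, n).astype(float)
        contaminating.append("site_1")
    if "date_drift" in spec:
        date = rng.uniform(0, 1, n)
        cols["date"] = date
        cols["date_sq"] = date**2
        contaminating += ["date", "date_sq"]
    frame = pd.DataFrame(cols)
    return frame, contaminating


def generate_idp_dataset(
    config: SimulationConfig,
    subject_weight_offsets: np.ndarray | None = None,
) -> tuple[IDPMatrix, ConfoundTable, np.ndarray, SyntheticTruth]:
    """Generate the subjects x IDPs dataset with planted modes.

    The clean signal is the sum of rank-1 outer products of age-dependent
    subject weights and sparse heavy-tailed IDP weights.  Confound
    contamination (linear, per-IDP random loadings), Gaussian noise,
    outliers (offset by 8-12 column SDs, guaranteed to trip the 6-MAD
    rule) and missing cells are then layered on.  ``subject_weight_offsets``
    (subjects x modes) lets callers inject additive genetic effects into the
    planted subject weights before the data matrix is built.

    Returns ``(IDPMatrix, ConfoundTable, age, SyntheticTruth)``.
    """
    rng = np.random.default_rng(config.rng_seed)
    n, p, k = config.n_subjects, config.n_idps, config.n_planted_modes
    age = rng.uniform(*config.age_range, size=n)
    z = (age - age.mean()) / age.std()

    # subject weights: configured polynomial age profile + idiosyncratic N(0,1)
    subject_weights = np.zeros((n, k))
    for i, (c1, c2, c3) in enumerate(config.age_profiles()):
        subject_weights[:, i] = c1 * z + c2 * z**2 + c3 * z**3 + rng.normal(0, 1, n)
    if subject_weight_offsets is not None:
        offs = np.atleast_2d(np.asarray(subject_weight_offsets, float))
        if offs.shape != (n, k):
            raise ValueError("subject_weight_offsets shape mismatch")
        subject_weights = subject_weights + offs

    # IDP weights: sparse Laplace (point mass at 0, heavy tails elsewhere),
    # unit-norm then scaled, so ICA identifiability holds
    idp_weights = np.zeros((k, p))
    for i in range(k):
        nz = rng.random(p) < config.idp_weight_sparsity
        if not nz.any():
            nz[rng.integers(p)] = True
        w = np.zeros(p)
        w[nz] = rng.laplace(0, 1, int(nz.sum()))
        norm = np.linalg.norm(w)
        idp_weights[i] = config.mode_strength * w / (norm if norm > 0 else 1.0)

    data = subject_weights @ idp_weights if k else np.zeros((n, p))

    conf_frame, contaminating = _confound_columns(config, rng)
    if contaminating:
        loadings = rng.normal(0, config.confound_strength, (len(contaminating), p))
        conf_std = conf_frame[contaminating].to_numpy()
        conf_std = (conf_std - conf_std.mean(axis=0)) / np.where(
            conf_std.std(axis=0) > 0, conf_std.std(axis=0), 1.0
        )
        data = data + conf_std @ loadings
    conf_frame.index = [f"s{i:05d}" for i in range(n)]

    data = data + rng.normal(0, config.noise_sd, (n, p))

    # gross outliers: +/- (8-12) column SDs, beyond any 6-MAD fence
    n_out = int(round(config.outlier_rate * n * p))
    if n_out:
        cells = rng.choice(n * p, size=n_out, replace=False)
        rows, cols = np.unravel_index(cells, (n, p))
        sd = data.std(axis=0)
        signs = rng.choice([-1.0, 1.0], size=n_out)
        data[rows, cols] += signs * rng.uniform(8, 12, n_out) * sd[cols]

    mask = rng.random((n, p)) < config.missing_rate

    groups = [f"group{j % 4}" for j in range(p)]
    matrix = IDPMatrix(
        data,
        mask,
        list(conf_frame.index),
        [f"idp{j:04d}" for j in range(p)],
        groups,
    )
    confounds = ConfoundTable(conf_frame)
    truth = SyntheticTruth(idp_weights, subject_weights)
    return matrix, confounds, age, truth


def generate_clustered_modes(
    n_subjects: int = 1000,
    n_idps: int = 200,
    n_clusters: int = 3,
    modes_per_cluster: int = 4,
    cluster_coupling: float = 0.9,
    mode_strength: float = 4.0,
    idp_weight_sparsity: float = 0.1,
    noise_sd: float = 1.0,
    age_range: tuple[float, float] = (45.0, 80.0),
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, SyntheticTruth, np.ndarray]:
    """Plant modes whose subject weights share a small number of cluster factors.

    Each of ``n_clusters`` latent factors is mildly age-linked; every mode's
    subject-weight vector is ``coupling * factor + sqrt(1-coupling^2) *
    idiosyncratic noise``, so modes within a cluster correlate at roughly
    ``coupling^2`` while cross-cluster correlation stays low.  IDP weights
    are sparse Laplace as in :func:`generate_idp_dataset`.

    Returns ``(data, age, truth, cluster_labels)`` where ``cluster_labels``
    gives the planted cluster of each mode.
    """
    rng = np.random.default_rng(rng_seed)
    n_modes = n_clusters * modes_per_cluster
    if n_modes >= min(n_subjects, n_idps):
        raise ValueError("too many planted modes for the requested shape")
    age = rng.uniform(*age_range, size=n_subjects)
    z = (age - age.mean()) / age.std()
    factors = np.column_stack(
        [0.4 * z + rng.normal(0, 1, n_subjects) for _ in range(n_clusters)]
    )
    labels = np.repeat(np.arange(n_clusters), modes_per_cluster)
    idio = np.sqrt(1.0 - cluster_coupling**2)
    subject_weights = (
        cluster_coupling * factors[:, labels]
        + idio * rng.normal(0, 1, (n_subjects, n_modes))
    )
    idp_weights = np.zeros((n_modes, n_idps))
    for i in range(n_modes):
        nz = rng.random(n_idps) < idp_weight_sparsity
        if not nz.any():
            nz[rng.integers(n_idps)] = True
        w = np.zeros(n_idps)
        w[nz] = rng.laplace(0, 1, int(nz.sum()))
        idp_weights[i] = mode_strength * w / np.linalg.norm(w)
    data = subject_weights @ idp_weights + rng.normal(0, noise_sd, (n_subjects, n_idps))
    truth = SyntheticTruth(idp_weights, subject_weights)
    return data, age, truth, labels


def generate_genotypes(
    config: GenotypeConfig,
) -> tuple[GenotypePanel, list[tuple[str, int, float]]]:
    """Generate a dosage panel with block-LD structure and causal metadata.

    Dosages are hard minor-allele counts in {0, 1, 2} from two latent
    Gaussian haplotype processes thresholded at the configured allele
    frequency; within-block latent correlation decays exponentially with cM
    distance, and blocks are independent.  Per-variant MAF and genotype
    counts are computed from the realised genotypes (so Hardy-Weinberg holds
    by construction); the imputation info score is metadata drawn from
    ``info_range``.  Causal variants are drawn with MAF >= ``causal_maf_min``
    so they pass quality control by construction.

    Returns the panel and the causal list [(variant_id, mode, effect)].
    """
    rng = np.random.default_rng(config.rng_seed)
    n, m = config.n_subjects, config.n_variants
    per_chrom = int(np.ceil(m / config.n_chromosomes))
    chrom = np.array([1 + i // per_chrom for i in range(m)])
    pos_bp = np.array(
        [1 + (i % per_chrom) * config.spacing_bp for i in range(m)], dtype=int
    )
    pos_cm = pos_bp / 1e6  # 1 cM per Mb map

    maf_target = rng.uniform(*config.maf_range, size=m)
    causal_idx = {int(v) for v, _, _ in config.causal}
    for v in causal_idx:
        if not (0 <= v < m):
            raise ValueError(f"causal variant index {v} out of range")
        maf_target[v] = rng.uniform(max(config.causal_maf_min, config.maf_range[0]), 0.5)
    thresh = _ndtri(maf_target)

    if config.block_length_cm > 0:
        block = (chrom * 10**9 + (pos_cm / config.block_length_cm).astype(int))
        step = np.abs(np.diff(pos_cm))
        rho = np.exp(-step / config.ld_scale_cm)
        rho = np.where(np.diff(block) != 0, 0.0, rho)
    else:
        rho = np.zeros(m - 1)

    dosages = np.zeros((n, m))
    for _hap in range(2):
        z = np.empty((n, m))
        z[:, 0] = rng.standard_normal(n)
        eps = rng.standard_normal((n, m - 1)) if m > 1 else np.empty((n, 0))
        for j in range(1, m):
            z[:, j] = rho[j - 1] * z[:, j - 1] + np.sqrt(1 - rho[j - 1] ** 2) * eps[:, j - 1]
        dosages += (z < thresh).astype(float)

    freq = dosages.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    maf = np.where(maf == 0, 1e-12, maf)  # monomorphic draws: record tiny MAF
    n_homref = (dosages == 0).sum(axis=0)
    n_het = (dosages == 1).sum(axis=0)
    n_homalt = (dosages == 2).sum(axis=0)
    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{i:06d}" for i in range(m)],
            "chrom": chrom,
            "pos_bp": pos_bp,
            "pos_cm": pos_cm,
            "maf": maf,
            "info": rng.uniform(*config.info_range, size=m),
            "n_homref": n_homref,
            "n_het": n_het,
            "n_homalt": n_homalt,
        }
    )
    panel = GenotypePanel(dosages, variants, [f"s{i:05d}" for i in range(n)])
    causal = [
        (str(variants["variant_id"].iloc[int(v)]), int(mode), float(eff))
        for v, mode, eff in config.causal
    ]
    return panel, causal


def _ndtri(p: np.ndarray) -> np.ndarray:
    from scipy.special import ndtri

    return ndtri(np.asarray(p, float))


def genetic_mode_offsets(
    panel: GenotypePanel,
    causal: list[tuple[str, int, float]],
    n_modes: int,
) -> np.ndarray:
    """Additive subject-weight offsets implied by the causal variants.

    Each causal variant adds effect x (dosage - mean dosage) to its target
    mode's subject weights.  Pass the result to
    :func:`generate_idp_dataset` via ``subject_weight_offsets``.
    """
    offsets = np.zeros((panel.dosages.shape[0], n_modes))
    ids = {vid: i for i, vid in enumerate(panel.variants["variant_id"])}
    for vid, mode, eff in causal:
        g = panel.dosages[:, ids[vid]]
        offsets[:, mode] += eff * (g - g.mean())
    return offsets


def generate_nidps(
    mode_deltas: np.ndarray,
    config: NIDPConfig,
) -> tuple[NIDPTable, list[tuple[str, int, float]]]:
    """Generate non-imaging variables with planted delta correlations.

    ``mode_deltas`` is subjects x modes (typically the per-mode
    bias-corrected deltas, or planted subject weights at generation time).
    A planted effect (variable v, mode k, r) makes variable v equal to
    ``r * standardised delta_k + sqrt(1 - r^2) * noise``, so its population
    correlation with the target delta is r.  Missingness is injected at
    random; with ``include_sub40_variable`` the last variable keeps exactly
    39 observed values (an edge case the association scan must exclude).

    Returns the table and the planted list [(variable_id, mode, r)].
    """
    rng = np.random.default_rng(config.rng_seed)
    deltas = np.atleast_2d(np.asarray(mode_deltas, float))
    n = deltas.shape[0]
    m = config.n_variables
    values = rng.standard_normal((n, m))
    planted: list[tuple[str, int, float]] = []
    var_ids = [f"nidp{j:04d}" for j in range(m)]
    for var, mode, r in config.planted_effects:
        if not (0 <= mode < deltas.shape[1]):
            raise ValueError(f"planted effect targets unknown mode {mode}")
        d = deltas[:, mode]
        dstd = (d - d.mean()) / d.std()
        values[:, var] = r * dstd + np.sqrt(1 - r**2) * rng.standard_normal(n)
        planted.append((var_ids[var], mode, float(r)))
    mask = rng.random((n, m)) < config.missing_rate
    if config.include_sub40_variable:
        if n < 40:
            raise ValueError("need at least 40 subjects for the sub-40 edge case")
        col = np.ones(n, dtype=bool)
        col[rng.choice(n, size=39, replace=False)] = False
        mask[:, m - 1] = col
    vals = values.copy()
    vals[mask] = np.nan
    frame = pd.DataFrame(vals, index=[f"s{i:05d}" for i in range(n)], columns=var_ids)
    groups = {v: f"vargroup{j % config.n_groups}" for j, v in enumerate(var_ids)}
    return NIDPTable(frame, groups), planted
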