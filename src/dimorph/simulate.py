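"""Synthetic data with the exact statistical structure the analysis assumes.

The study generator emulates the design of the bone-aging experiment: two
sexes x five ages (3, 6, 9, 12, 18 months) x four replicates, gene-expression
trajectories drawn from a mixture of polynomial mixed-effects models, a
configurable fraction of sex-discordant genes, and an affine map onto a
lognormal expression scale.  The compendium generator builds collections of
noise datasets with a coordinately regulated signature embedded in a subset,
for exercising the signature-association scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ValidationError
from .profiles import ProfileSet, design_matrices

__all__ = [
    "SimConfig",
    "SimTruth",
    "default_betas",
    "default_D",
    "simulate_timecourse_study",
    "simulate_profile_mixture",
    "simulate_compendium",
]

#: canonical standardized trajectory shapes on a scaled time axis s in [-1,1];
#: each is standardized over the grid before conversion to coefficients, so
#: clusters stay well separated after per-profile standardization
_SHAPES = [
    lambda s: s + 0.4 * s ** 2,        # rise, decelerating
    lambda s: -s + 0.4 * s ** 2,       # fall, then flattening
    lambda s: -(s ** 2) + 0.2 * s,     # mid-life peak
    lambda s: s ** 3 - 0.75 * s,       # S-curve (late rise)
    lambda s: 0.75 * s - s ** 3,       # inverted S-curve
    lambda s: s ** 2 + 0.5 * s ** 3,   # U dip with steep late rise
    lambda s: (s + 0.5) ** 2 - s,      # early dip, late rise
    lambda s: s - (s - 0.5) ** 2,      # early rise, late dip
    lambda s: s ** 3 + 0.3 * s ** 2,   # accelerating rise
    lambda s: -(s ** 3) - 0.3 * s ** 2,  # accelerating fall
]


def default_betas(K: int, age_grid=(3, 6, 9, 12, 18)) -> np.ndarray:
    """Cubic coefficients of K distinct, standardized cluster mean curves.

    Each curve has mean 0 and sample SD 1 over the grid, so it survives the
    pipeline's per-profile standardization with its shape intact.
    """
    if K > len(_SHAPES):
        raise ValidationError(f"at most {len(_SHAPES)} canonical shapes, got K={K}")
    X, _ = design_matrices(age_grid)
    s = X[:, 1]
    betas = np.empty((K, 4))
    for k in range(K):
        curve = _SHAPES[k](s)
        curve = (curve - curve.mean()) / curve.std(ddof=1)
        betas[k] = np.linalg.lstsq(X, curve, rcond=None)[0]
    return betas


def default_D(K: int, scale: float = 0.01) -> np.ndarray:
    """Mild within-cluster heterogeneity: diagonal quadratic random effects."""
    return np.tile(np.diag([2.0 * scale, scale, 0.5 * scale]), (K, 1, 1))


@dataclass
class SimConfig:
    """Generative counterparts of the mixture parameters (pi, beta, D, sigma2).

    Defaults emulate the study design: 2 sexes x ages {3,6,9,12,18} months x
    4 replicates, four well-separated standardized cluster curves, mild
    random-effect heterogeneity, and lognormal per-gene baselines for the
    affine map to expression scale.
    """

    n_genes: int = 1000
    K_true: int = 4
    age_grid: tuple = (3.0, 6.0, 9.0, 12.0, 18.0)
    n_replicates: int = 4
    beta_true: np.ndarray | None = None
    D_true: np.ndarray | None = None
    sigma2_true: float = 0.05
    pi_true: np.ndarray | None = None
    discordant_fraction: float = 0.0
    baseline_mean: float = 100.0
    baseline_sd: float = 15.0
    baseline_lognormal: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.K_true < 1 or self.n_replicates < 1:
            raise ValidationError("n_genes, K_true, n_replicates must be >= 1")
        if self.sigma2_true < 0:
            raise ValidationError("sigma2_true must be >= 0")
        if not 0.0 <= self.discordant_fraction <= 1.0:
            raise ValidationError("discordant_fraction must be in [0, 1]")
        if self.K_true == 1 and self.discordant_fraction > 0:
            raise ValidationError(
                "discordant genes are impossible with a single cluster")
        if self.beta_true is None:
            self.beta_true = default_betas(self.K_true, self.age_grid)
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        if self.beta_true.shape != (self.K_true, 4):
            raise ValidationError("beta_true must be K_true x 4")
        if self.D_true is None:
            self.D_true = default_D(self.K_true)
        self.D_true = np.asarray(self.D_true, dtype=float)
        if self.D_true.shape != (self.K_true, 3, 3):
            raise ValidationError("D_true must be K_true x 3 x 3")
        for k in range(self.K_true):
            w = np.linalg.eigvalsh(self.D_true[k])
            if w.min() < -1e-10:
                raise ValidationError(f"D_true[{k}] is not PSD")
        if self.pi_true is None:
            self.pi_true = np.full(self.K_true, 1.0 / self.K_true)
        self.pi_true = np.asarray(self.pi_true, dtype=float)
        if abs(self.pi_true.sum() - 1.0) > 1e-12 or (self.pi_true < 0).any():
            raise ValidationError("pi_true must be a simplex summing to 1")


@dataclass
class SimTruth:
    """Ground-truth labels and random-effect draws behind a simulated study."""

    gene_ids: list[str]
    male_cluster: np.ndarray      # (G,), labels 1..K_true
    female_cluster: np.ndarray    # (G,)
    b_male: np.ndarray            # (G, 3)
    b_female: np.ndarray          # (G, 3)

    @property
    def discordant(self) -> np.ndarray:
        return self.male_cluster != self.female_cluster

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_id": self.gene_ids,
            "male_cluster": self.male_cluster,
            "female_cluster": self.female_cluster,
            "discordant": self.discordant.astype(int),
        })


def _draw_labels(rng, config: SimConfig):
    G, K = config.n_genes, config.K_true
    male = rng.choice(K, size=G, p=config.pi_true) + 1
    female = male.copy()
    if K > 1 and config.discordant_fraction > 0:
        flip = rng.random(G) < config.discordant_fraction
        # redraw uniformly among the other K-1 labels
        shift = rng.integers(1, K, size=G)
        female[flip] = ((male[flip] - 1 + shift[flip]) % K) + 1
    return male, female


def simulate_timecourse_study(config: SimConfig):
    """Simulate a full two-sex time-course study.

    Returns
    -------
    (ExpressionMatrix, annotation DataFrame, SimTruth)
        Matrix of ``n_genes x (2 * T * n_replicates)`` linear-scale values;
        sample ids encode sex, age and replicate.  Deterministic given
        ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    G, K, R = config.n_genes, config.K_true, config.n_replicates
    ages = np.asarray(config.age_grid, dtype=float)
    T = len(ages)
    X, Z = design_matrices(ages)
    male, female = _draw_labels(rng, config)
    b = {}
    for sex, labels in (("M", male), ("F", female)):
        draws = np.empty((G, 3))
        for k in range(1, K + 1):
            idx = np.where(labels == k)[0]
            if len(idx):
                draws[idx] = rng.multivariate_normal(
                    np.zeros(3), config.D_true[k - 1], size=len(idx),
                    method="cholesky" if _is_pd(config.D_true[k - 1]) else "eigh")
        b[sex] = draws
    gene_ids = [f"G{i + 1:05d}" for i in range(G)]
    sample_ids, sex_col, age_col, rep_col = [], [], [], []
    for sex in ("M", "F"):
        for age in ages:
            for rep in range(1, R + 1):
                sample_ids.append(f"{sex}_{age:g}m_r{rep}")
                sex_col.append(sex)
                age_col.append(age)
                rep_col.append(rep)
    annot = pd.DataFrame({"sample_id": sample_ids, "sex": sex_col,
                          "age_months": age_col, "replicate": rep_col})
    values = np.empty((G, 2 * T * R))
    col = 0
    mean_curves = {
        "M": X @ config.beta_true[male - 1].T + Z @ b["M"].T,   # (T, G)
        "F": X @ config.beta_true[female - 1].T + Z @ b["F"].T,
    }
    for sex in ("M", "F"):
        for t_i in range(T):
            noise = (rng.normal(0.0, np.sqrt(config.sigma2_true), size=(G, R))
                     if config.sigma2_true > 0 else np.zeros((G, R)))
            values[:, col:col + R] = mean_curves[sex][t_i][:, None] + noise
            col += R
    # affine map onto expression scale with per-gene lognormal baselines
    if config.baseline_lognormal:
        base_mu = rng.lognormal(np.log(max(config.baseline_mean, 1e-12)), 0.5,
                                size=G)
        base_sd = rng.lognormal(np.log(max(config.baseline_sd, 1e-12)), 0.3,
                                size=G)
    else:
        base_mu = np.full(G, config.baseline_mean)
        base_sd = np.full(G, config.baseline_sd)
    expr = base_mu[:, None] + base_sd[:, None] * values
    matrix = ExpressionMatrix(gene_ids, sample_ids, expr, scale="linear")
    truth = SimTruth(gene_ids, male, female, b["M"], b["F"])
    return matrix, annot, truth


def _is_pd(D) -> bool:
    return np.linalg.eigvalsh(D).min() > 0


def simulate_profile_mixture(n_profiles: int, config: SimConfig):
    """Draw standardized-scale profiles directly from the mixture model.

    Bypasses the replicate/expression-scale machinery: ``y = X b0 + Z b + e``
    exactly as the clustering model assumes.  Returns a fit-ready ProfileSet
    and the true component labels (1..K).
    """
    rng = np.random.default_rng(config.seed)
    ages = np.asarray(config.age_grid, dtype=float)
    X, Z = design_matrices(ages)
    labels = rng.choice(config.K_true, size=n_profiles, p=config.pi_true) + 1
    Y = np.empty((n_profiles, len(ages)))
    for k in range(1, config.K_true + 1):
        idx = np.where(labels == k)[0]
        if not len(idx):
            continue
        bdraw = rng.multivariate_normal(
            np.zeros(3), config.D_true[k - 1], size=len(idx),
            method="cholesky" if _is_pd(config.D_true[k - 1]) else "eigh")
        Y[idx] = (X @ config.beta_true[k - 1])[None, :] + bdraw @ Z.T
    if config.sigma2_true > 0:
        Y += rng.normal(0.0, np.sqrt(config.sigma2_true), size=Y.shape)
    ids = [(f"P{i + 1:05d}", "M") for i in range(n_profiles)]
    return ProfileSet(ids, ages, Y, standardized=True), labels


def simulate_compendium(signature, n_datasets: int, n_embedded: int,
                        n_samples: int, effect_delta: float, seed: int,
                        n_decoy_genes: int = 200) -> list[ExpressionMatrix]:
    """Build a compendium of datasets, a subset carrying the signature.

    Every dataset contains all signature genes plus ``n_decoy_genes`` decoys,
    with unit-variance Gaussian noise.  The first ``n_embedded`` datasets are
    the carriers: half of their samples (rounded down) have the signature
    genes shifted by ``effect_delta`` times the gene's sign.  Deterministic
    given ``seed``.
    """
    if n_embedded > n_datasets:
        raise ValidationError("n_embedded cannot exceed n_datasets")
    if n_datasets and not signature.entries:
        raise ValidationError("signature is empty")
    rng = np.random.default_rng(seed)
    sig_genes = list(signature.entries)
    signs = np.array([signature.entries[g] for g in sig_genes], dtype=float)
    genes = sig_genes + [f"DECOY{i + 1:04d}" for i in range(n_decoy_genes)]
    out = []
    for d in range(n_datasets):
        values = rng.normal(0.0, 1.0, size=(len(genes), n_samples))
        if d < n_embedded and effect_delta != 0.0:
            shifted = n_samples // 2
            values[:len(sig_genes), :shifted] += effect_delta * signs[:, None]
        sample_ids = [f"DS{d + 1:03d}_S{j + 1:03d}" for j in range(n_samples)]
        out.append(ExpressionMatrix(genes, sample_ids, values, scale="linear"))
    return out
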