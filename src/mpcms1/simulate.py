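"""Synthetic MS1 screens with known ground truth.

The generator emulates the data model the pipeline assumes: log-normal
feature intensities organized into block-correlated modules, additive
condition-specific log2-fold shifts shared within planted condition
groups, per-sample scaling factors (removed later by median-ratio
normalization), and intensity-dependent missingness concentrated below a
low-intensity quantile (the lowest quartile by default), mimicking how
low-abundance MS1 features drop out of consensus maps.

Defaults describe a drug-screen-like layout: 16 conditions of 3
replicates (48 samples), 2,000 features, 12 feature modules, and 3
planted condition groups (a control-like group of 7 conditions, a
strong-effect group of 4, an intermediate group of 5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .types import DesignTable, IntensityMatrix

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Parameters of a simulated MS1 screen.

    ``effect_matrix`` (modules x conditions, log2 shifts) may be given
    explicitly; otherwise it is drawn from the planted group structure with
    per-group effect amplitudes ``group_amplitudes`` (control group 0).
    """

    n_features: int = 2000
    n_modules: int = 12
    module_size: int = 120
    conditions: list[str] = field(default_factory=list)
    replicates: int = 3
    condition_groups: list[int] = field(default_factory=list)  # group id per condition
    group_amplitudes: list[float] = field(default_factory=lambda: [0.0, 2.0, 1.0])
    effect_matrix: np.ndarray | None = None
    base_log_mean: float = 23.0   # log2 of a mid-range MS1 intensity (~8e6)
    base_log_sd: float = 2.0      # spread of feature baseline abundances
    module_latent_sd: float = 0.5  # shared within-module sample-level variation
    feature_noise_sd: float = 0.3
    sample_scale_sd: float = 0.2  # log-normal spread of per-sample factors
    censor_quantile: float = 0.25
    dropout_prob: float = 0.3
    batch_drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.conditions:
            # control-like group of 7, strong group of 4, intermediate group of 5
            self.conditions = (
                [f"CTL{i+1}" for i in range(7)]
                + [f"STR{i+1}" for i in range(4)]
                + [f"INT{i+1}" for i in range(5)]
            )
            self.condition_groups = [0] * 7 + [1] * 4 + [2] * 5
        if not self.condition_groups:
            self.condition_groups = [0] * len(self.conditions)
        if len(self.condition_groups) != len(self.conditions):
            raise ValueError("condition_groups length must match conditions")
        if self.n_modules * self.module_size > self.n_features:
            raise ValueError("module features exceed n_features")
        if not 0 <= self.dropout_prob <= 1 or not 0 <= self.censor_quantile <= 1:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class ScreenTruth:
    """Planted structure: module id per feature (-1 noise) and condition groups."""

    module_labels: np.ndarray
    condition_groups: dict[str, int]
    effect_matrix: np.ndarray
    sample_scales: np.ndarray


def simulate_screen(
    config: SimulationConfig,
) -> tuple[IntensityMatrix, DesignTable, ScreenTruth]:
    """Simulate an aligned MS1 feature table plus design and ground truth."""
    rng = np.random.default_rng(int(config.seed))
    n_cond = len(config.conditions)
    n_samples = n_cond * config.replicates
    sample_ids = [
        f"{cond}_r{r+1}" for cond in config.conditions for r in range(config.replicates)
    ]
    cond_of_sample = np.repeat(np.arange(n_cond), config.replicates)

    labels = np.full(config.n_features, -1, dtype=int)
    for m in range(config.n_modules):
        labels[m * config.module_size : (m + 1) * config.module_size] = m

    if config.effect_matrix is not None:
        effects = np.asarray(config.effect_matrix, dtype=float)
        if effects.shape != (config.n_modules, n_cond):
            raise ValueError("effect_matrix must be modules x conditions")
    else:
        groups = np.asarray(config.condition_groups)
        effects = np.zeros((config.n_modules, n_cond))
        for g in np.unique(groups):
            amp = config.group_amplitudes[g] if g < len(config.group_amplitudes) else 0.0
            if amp == 0:
                continue
            # one shared shift pattern per group: conditions in a group move together
            pattern = rng.normal(0.0, amp, size=config.n_modules)
            effects[:, groups == g] = pattern[:, None]

    base = rng.normal(config.base_log_mean, config.base_log_sd, size=config.n_features)
    log2x = np.tile(base[:, None], (1, n_samples))
    # module-level latent replicate variation, shared by all features of a module
    latent = rng.normal(0.0, config.module_latent_sd, size=(config.n_modules, n_samples))
    for m in range(config.n_modules):
        rows = labels == m
        log2x[rows] += effects[m, cond_of_sample][None, :] + latent[m][None, :]
    log2x += rng.normal(0.0, config.feature_noise_sd, size=log2x.shape)
    if config.batch_drift:
        drift = rng.normal(0.0, config.batch_drift, size=n_samples)
        log2x += drift[None, :]

    scales = np.exp(rng.normal(0.0, config.sample_scale_sd, size=n_samples))
    intensities = np.exp2(log2x) * scales[None, :]

    # intensity-dependent (MNAR) dropout below the censor quantile
    if config.dropout_prob > 0 and config.censor_quantile > 0:
        cutoff = np.quantile(intensities, config.censor_quantile)
        low = intensities < cutoff
        drop = low & (rng.random(intensities.shape) < config.dropout_prob)
        intensities = intensities.astype(float)
        intensities[drop] = np.nan

    matrix = IntensityMatrix(
        values=intensities,
        feature_ids=[f"F{i:05d}" for i in range(config.n_features)],
        sample_ids=sample_ids,
        rt=rng.uniform(0, 900, size=config.n_features),
        mz=rng.uniform(300, 1500, size=config.n_features),
    )
    design = DesignTable(
        sample_ids=sample_ids,
        condition=[config.conditions[c] for c in cond_of_sample],
    )
    truth = ScreenTruth(
        module_labels=labels,
        condition_groups={
            c: int(g) for c, g in zip(config.conditions, config.condition_groups)
        },
        effect_matrix=effects,
        sample_scales=scales,
    )
    return matrix, design, truth


def simulate_sources(
    n_features: int,
    n_samples: int,
    n_sources: int,
    distribution: str = "laplace",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Non-Gaussian sources mixed by a random full-rank matrix, for ICA tests.

    Returns (X, S_true, A_true) with X = S_true @ A_true + noise,
    S_true of shape (n_features, n_sources), A_true (n_sources, n_samples).
    """
    if n_sources > min(n_features, n_samples):
        raise ValueError("n_sources exceeds matrix rank bound")
    rng = np.random.default_rng(int(seed))
    if distribution == "laplace":
        S = rng.laplace(0.0, 1.0, size=(n_features, n_sources))
    elif distribution == "uniform-spiked":
        S = rng.uniform(-1, 1, size=(n_features, n_sources))
        spikes = rng.random(size=S.shape) < 0.05
        S[spikes] *= 8.0
    elif distribution == "gaussian":
        raise ValueError("Gaussian-only sources make ICA unidentifiable")
    else:
        raise ValueError(f"unknown source distribution: {distribution!r}")
    while True:
        A = rng.normal(size=(n_sources, n_samples))
        if np.linalg.matrix_rank(A) == n_sources:
            break
    cond = np.linalg.cond(A)
    logger.info("mixing matrix condition number: %.3g", cond)
    X = S @ A
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=X.shape)
    return X, S, A
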