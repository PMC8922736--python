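"""Two-condition negative-binomial count simulator with outlier contamination.

The generator emulates the statistical structure a DE benchmark assumes:
gene-wise NB counts (variance ``mu + phi * mu**2``), log-normal baseline means
and dispersions, per-sample library-size factors, a configurable proportion of
true DEGs with uniform log2 fold-change magnitudes and random signs, and —
crucially for the failure mode under study — sporadic multiplicative outlier
counts that violate the NB law at a per-entry rate ``epsilon``.

Everything is reproducible from the mandatory integer seed; identical configs
give bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np

from degbench.core_data import ConditionLabels, CountMatrix
from degbench.resampling import GroundTruth

__all__ = [
    "SimulatedDataset",
    "SimulationConfig",
    "simulate_dataset",
    "simulate_null_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a two-condition NB count dataset.

    Parameters
    ----------
    G, n1, n2
        Gene count and per-condition sample sizes.
    pi
        Proportion of true DEGs in [0, 1]; ``round(pi * G)`` genes get a
        nonzero fold change.
    seed
        Mandatory integer seed; the single source of randomness.
    log2fc_min, log2fc_max
        Magnitude law of nonzero effects: |log2 FC| ~ Uniform(min, max) with a
        random sign.
    mean_log_mean, mean_log_sd
        Baseline gene means ``mu_g`` ~ log-normal (natural-log scale).
    disp_log_mean, disp_log_sd
        Gene dispersions ``phi_g`` ~ log-normal (natural-log scale).
    libsize_log_sd, base_depth
        Per-sample factors ``s_j = (base_depth / G) * l_j / mean(l)`` with
        ``l_j`` log-normal(0, libsize_log_sd); the expected count of gene g in
        sample j is ``s_j * mu_g`` (times the fold change in condition 2), so
        the median library size sits near ``base_depth * mean(mu_g)``.
    epsilon, outlier_min, outlier_max
        Each entry is independently replaced, with probability ``epsilon``, by
        ``round(count * m)`` with multiplier ``m`` log-uniform on
        [outlier_min, outlier_max].
    """

    G: int = 5000
    n1: int = 100
    n2: int = 100
    pi: float = 0.05
    seed: int = 0
    log2fc_min: float = 0.5
    log2fc_max: float = 3.0
    mean_log_mean: float = 3.0
    mean_log_sd: float = 1.5
    disp_log_mean: float = -1.5
    disp_log_sd: float = 0.8
    libsize_log_sd: float = 0.3
    base_depth: float = 5e6
    epsilon: float = 0.0
    outlier_min: float = 5.0
    outlier_max: float = 50.0

    def __post_init__(self) -> None:
        if self.G < 1 or self.n1 < 2 or self.n2 < 2:
            raise ValueError("need G >= 1 and at least 2 samples per condition")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must be in [0, 1]")
        if not 0.0 <= self.epsilon < 1.0:
            raise ValueError("epsilon must be in [0, 1)")
        if self.log2fc_min <= 0 or self.log2fc_max < self.log2fc_min:
            raise ValueError("log2 fold-change magnitude range must be positive")
        if self.outlier_min <= 1 or self.outlier_max < self.outlier_min:
            raise ValueError("outlier multiplier range must exceed 1")
        if self.mean_log_sd <= 0 or self.disp_log_sd <= 0 or self.libsize_log_sd < 0:
            raise ValueError("law scale parameters must be positive")
        if self.base_depth <= 0:
            raise ValueError("base_depth must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedDataset:
    """Simulated counts, labels, simulator ground truth, and outlier mask."""

    matrix: CountMatrix
    labels: ConditionLabels
    truth: GroundTruth
    outlier_mask: np.ndarray
    config: SimulationConfig
    true_log2fc: np.ndarray | None = None  # per gene; 0 for non-DEGs
    true_dispersion: np.ndarray | None = None  # per gene
    true_mean: np.ndarray | None = None  # per gene baseline mu_g


def _gene_ids(G: int) -> list[str]:
    width = len(str(G))
    return [f"g{i:0{width}d}" for i in range(1, G + 1)]


def _sample_ids(n1: int, n2: int) -> tuple[list[str], list[str]]:
    return (
        [f"s{j:03d}" for j in range(1, n1 + 1)],
        [f"s{j:03d}" for j in range(n1 + 1, n1 + n2 + 1)],
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one two-condition NB dataset with known truth.

    Counts follow ``NB(mean = s_j * mu_g * f_g^[j in condition 2],
    variance = mean + phi_g * mean^2)`` where ``f_g = 2**log2fc_g`` for the
    ``round(pi * G)`` truth genes and 1 otherwise. Outlier contamination is
    applied entry-wise afterwards and recorded in ``outlier_mask``.
    """
    rng = np.random.default_rng(config.seed)
    G, n1, n2 = config.G, config.n1, config.n2
    n = n1 + n2
    mu = rng.lognormal(config.mean_log_mean, config.mean_log_sd, size=G)
    phi = rng.lognormal(config.disp_log_mean, config.disp_log_sd, size=G)
    lib = rng.lognormal(0.0, config.libsize_log_sd, size=n) if config.libsize_log_sd > 0 else np.ones(n)
    s = (config.base_depth / G) * lib / lib.mean()

    n_deg = int(round(config.pi * G))
    deg_idx = rng.choice(G, size=n_deg, replace=False) if n_deg else np.array([], dtype=int)
    log2fc = np.zeros(G)
    if n_deg:
        mag = rng.uniform(config.log2fc_min, config.log2fc_max, size=n_deg)
        sign = rng.choice([-1.0, 1.0], size=n_deg)
        log2fc[deg_idx] = mag * sign
    fold = 2.0 ** log2fc

    mean = mu[:, None] * s[None, :]
    mean[:, n1:] *= fold[:, None]
    size = (1.0 / phi)[:, None]
    counts = rng.negative_binomial(size, size / (size + mean))

    if config.epsilon > 0:
        mask = rng.random(size=(G, n)) < config.epsilon
        mult = np.exp(
            rng.uniform(np.log(config.outlier_min), np.log(config.outlier_max), size=(G, n))
        )
        counts = np.where(mask, np.rint(counts * mult).astype(np.int64), counts)
    else:
        mask = np.zeros((G, n), dtype=bool)

    gene_ids = _gene_ids(G)
    ids1, ids2 = _sample_ids(n1, n2)
    matrix = CountMatrix(gene_ids, ids1 + ids2, counts.astype(np.int64))
    labels = ConditionLabels(
        ids1 + ids2, ["c1"] * n1 + ["c2"] * n2, level_order=("c1", "c2")
    )
    truth = GroundTruth({gene_ids[i] for i in deg_idx}, "simulator")
    return SimulatedDataset(matrix, labels, truth, mask, config, log2fc, phi, mu)


def simulate_null_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Same generator with the DEG proportion forced to zero (negative control)."""
    return simulate_dataset(replace(config, pi=0.0))
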