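"""Low-expression filtering, TMM scaling factors, CPM, and fold changes.

The filter keeps a gene when its counts-per-million (computed against raw
library sizes) reach a data-driven threshold ``T = 10 / (median library size in
millions)`` in at least ``k`` samples, ``k`` being the size of the smaller
condition group, and its total count across all samples is at least
``min_total_count``. This is a fixed, fully specified rule of the
``filterByExpr`` family.

TMM (trimmed mean of M-values) follows the classical construction: a reference
sample is picked by the 75th-percentile rule, per-sample log-ratios ``M_g`` and
average log-abundances ``A_g`` are doubly trimmed by rank (30% on M, 5% on A,
equal tails), and the factor is ``2`` to the precision-weighted mean of the
surviving ``M_g``. Factors are rescaled to geometric mean one, so
counts-per-million against effective library sizes are invariant to a common
rescaling of all factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.stats

from degbench.core_data import (
    AlignmentError,
    ConditionLabels,
    CountMatrix,
    ValidationError,
)

__all__ = [
    "FilterDecision",
    "NormalizationResult",
    "cpm",
    "filter_low_expression",
    "log2_fold_change",
    "tmm_factors",
]

logger = logging.getLogger(__name__)

_MIN_TRIMMED_GENES = 10


@dataclass
class NormalizationResult:
    """Per-sample library sizes, TMM scaling factors, and effective sizes."""

    sample_ids: list[str]
    library_sizes: np.ndarray
    scaling_factors: np.ndarray

    def __post_init__(self) -> None:
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        self.scaling_factors = np.asarray(self.scaling_factors, dtype=float)
        if (self.scaling_factors <= 0).any():
            raise ValidationError("scaling factors must be positive")
        gm = np.exp(np.mean(np.log(self.scaling_factors)))
        if abs(gm - 1.0) > 1e-9:
            raise ValidationError(f"scaling factors must have geometric mean 1, got {gm}")

    @property
    def effective_library_sizes(self) -> np.ndarray:
        return self.library_sizes * self.scaling_factors


@dataclass
class FilterDecision:
    """Genes surviving the low-expression filter, with the rule parameters."""

    kept_gene_ids: list[str]
    cpm_threshold: float
    min_samples: int
    min_total_count: int


def _check_alignment(matrix: CountMatrix, labels: ConditionLabels) -> None:
    if set(matrix.sample_ids) != set(labels.sample_ids):
        raise AlignmentError("count matrix and labels carry different sample ids")


def filter_low_expression(
    matrix: CountMatrix,
    labels: ConditionLabels,
    min_total_count: int = 15,
) -> FilterDecision:
    """Flag genes with enough expression to be testable.

    A gene is kept iff its raw-library-size CPM is >= ``T`` in at least ``k``
    samples (``k`` = smaller group size, ``T = 10 / median library size in
    millions``) and its total count is >= ``min_total_count``.
    """
    _check_alignment(matrix, labels)
    lib = matrix.library_sizes().astype(float)
    if (lib <= 0).any():
        bad = [matrix.sample_ids[j] for j in np.flatnonzero(lib <= 0)]
        raise ValidationError(f"samples with zero library size: {bad}")
    threshold = 10.0 / (np.median(lib) / 1e6)
    k = min(labels.group_sizes())
    raw_cpm = matrix.counts / lib * 1e6
    enough_samples = (raw_cpm >= threshold).sum(axis=1) >= k
    enough_total = matrix.counts.sum(axis=1) >= min_total_count
    keep = enough_samples & enough_total
    kept = [g for g, flag in zip(matrix.gene_ids, keep) if flag]
    logger.info(
        "low-expression filter kept %d/%d genes (T=%.4g CPM in >=%d samples, total>=%d)",
        len(kept), matrix.n_genes, threshold, k, min_total_count,
    )
    return FilterDecision(kept, threshold, int(k), int(min_total_count))


def _tmm_one_sample(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Weighted doubly trimmed mean of per-gene log ratios, on the log2 scale."""
    positive = (obs > 0) & (ref > 0)
    obs_p = obs[positive] / n_obs
    ref_p = ref[positive] / n_ref
    m = np.log2(obs_p / ref_p)
    a = 0.5 * np.log2(obs_p * ref_p)
    # delta-method variance of M; the trimmed mean below is inverse-variance
    # weighted, so genes measured precisely in both samples dominate
    v = (n_obs - obs[positive]) / (n_obs * obs[positive]) + (
        n_ref - ref[positive]
    ) / (n_ref * ref[positive])
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, v = m[finite], a[finite], v[finite]
    n = m.size
    if n == 0:
        return 0.0
    # equal-tail trimming by rank; average ranks break ties deterministically
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = scipy.stats.rankdata(m)
    rank_a = scipy.stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep.sum() < _MIN_TRIMMED_GENES:
        logger.warning(
            "fewer than %d genes survive TMM trimming; factor set to 1",
            _MIN_TRIMMED_GENES,
        )
        return 0.0
    return float(np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep]))


def tmm_factors(
    matrix: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizationResult:
    """Trimmed-mean-of-M-values scaling factors, geometric mean one.

    The reference sample is the one whose 75th-percentile count/library-size
    ratio is closest to the mean of that quantity across samples (ties broken
    by lowest sample index).
    """
    if matrix.n_samples < 2:
        raise ValidationError("TMM requires at least 2 samples")
    lib = matrix.library_sizes().astype(float)
    if (lib <= 0).any():
        raise ValidationError("TMM requires positive library sizes")
    counts = matrix.counts.astype(float)
    q75 = np.percentile(counts / lib, 75, axis=0)
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    log_factors = np.zeros(matrix.n_samples)
    for j in range(matrix.n_samples):
        if j == ref:
            continue
        log_factors[j] = _tmm_one_sample(
            counts[:, j], counts[:, ref], lib[j], lib[ref], trim_m, trim_a
        )
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return NormalizationResult(list(matrix.sample_ids), lib, factors)


def cpm(matrix: CountMatrix, norm: NormalizationResult | None = None) -> np.ndarray:
    """Counts per million against effective (TMM-scaled) library sizes.

    With ``norm=None`` raw library sizes are used.
    """
    if norm is None:
        eff = matrix.library_sizes().astype(float)
    else:
        if norm.sample_ids != matrix.sample_ids:
            raise AlignmentError("normalization result not aligned to matrix samples")
        eff = norm.effective_library_sizes
    return matrix.counts / eff * 1e6


def log2_fold_change(
    cpm_matrix: np.ndarray,
    labels: ConditionLabels,
    sample_ids: list[str],
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Per-gene log2 ratio of pseudocount-stabilized group-mean CPM.

    Reported as level 2 versus level 1 under ``labels.levels``, i.e. positive
    values mean higher expression in the second condition.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    by_sample = dict(zip(labels.sample_ids, labels.labels))
    level1, level2 = labels.levels
    cols = np.array([by_sample[s] for s in sample_ids])
    idx1 = np.flatnonzero(cols == level1)
    idx2 = np.flatnonzero(cols == level2)
    mean1 = np.asarray(cpm_matrix)[:, idx1].mean(axis=1)
    mean2 = np.asarray(cpm_matrix)[:, idx2].mean(axis=1)
    return np.log2((mean2 + pseudocount) / (mean1 + pseudocount))
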