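"""FDR/power evaluation, permutation-null summaries, and NB goodness of fit.

The evaluation vocabulary follows the standard benchmarking definitions: the
false discovery proportion (FDP) of one analysis is the fraction of
discoveries that are not true DEGs (0 when nothing is discovered), the FDR is
estimated as the mean FDP over replicate datasets, and empirical power is the
fraction of true DEGs discovered. Power comparisons across methods are made
at matched *actual* FDR by interpolating each method's (actual FDR, power)
curve.

The goodness-of-fit diagnostic asks how well one gene's normalized counts
under one condition follow a negative binomial law with a fixed dispersion:
a Pearson chi-square test over the frequency table of rounded values (cells
``0..max`` plus one open tail cell), with "poorness of fit" defined as
``-log10(p)`` — larger means a worse fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats

from degbench.core_data import ConditionLabels, CountMatrix
from degbench.de_methods import DEResult, discoveries, wilcoxon_p
from degbench.normalization import NormalizationResult

__all__ = [
    "EvaluationSummary",
    "GofResult",
    "PermutationSummary",
    "compare_poorness_groups",
    "empirical_power",
    "evaluate_methods",
    "fdp",
    "foldchange_frequency_profile",
    "gof_table",
    "nb_gof_poorness",
    "permutation_summary",
    "power_at_actual_fdr",
]

def fdp(disc: set[str], truth: set[str]) -> float:
    """False discovery proportion: |disc \\ truth| / |disc| (0 if no discoveries)."""
    if not disc:
        return 0.0
    return len(set(disc) - set(truth)) / len(disc)


def empirical_power(disc: set[str], truth: set[str]) -> float:
    """Fraction of true DEGs discovered: |disc ∩ truth| / |truth|."""
    if not truth:
        raise ValueError("truth set must be non-empty for power")
    return len(set(disc) & set(truth)) / len(truth)


@dataclass
class EvaluationSummary:
    """Per-(method, threshold) FDP and power across replicate datasets.

    ``fdp_per_replicate[method]`` and ``power_per_replicate[method]`` hold
    arrays of shape (n_thresholds, R); ``actual_fdr`` and ``power`` are their
    arithmetic means over replicates.
    """

    methods: list[str]
    thresholds: np.ndarray
    R: int
    fdp_per_replicate: dict[str, np.ndarray]
    power_per_replicate: dict[str, np.ndarray]

    def actual_fdr(self, method: str) -> np.ndarray:
        return self.fdp_per_replicate[method].mean(axis=1)

    def power(self, method: str) -> np.ndarray:
        return self.power_per_replicate[method].mean(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for m in self.methods:
            for i, t in enumerate(self.thresholds):
                rows.append(
                    {
                        "method": m,
                        "claimed_fdr": float(t),
                        "actual_fdr": float(self.actual_fdr(m)[i]),
                        "power": float(self.power(m)[i]),
                        "n_replicates": self.R,
                    }
                )
        return pd.DataFrame(rows)


def evaluate_methods(
    results_by_method: Mapping[str, Sequence[DEResult]],
    truths: Sequence[set[str]],
    thresholds: Sequence[float] = (1e-5, 1e-4, 1e-3, 0.01, 0.05),
) -> EvaluationSummary:
    """FDP and empirical power per method, threshold, and replicate.

    ``truths[r]`` is the true-DEG set of replicate ``r``; every method must
    supply exactly one :class:`DEResult` per replicate.
    """
    thresholds = np.asarray(sorted(thresholds), dtype=float)
    R = len(truths)
    fdps: dict[str, np.ndarray] = {}
    powers: dict[str, np.ndarray] = {}
    for method, results in results_by_method.items():
        if len(results) != R:
            raise ValueError(
                f"method {method!r} has {len(results)} results for {R} truth sets"
            )
        f = np.empty((len(thresholds), R))
        w = np.empty((len(thresholds), R))
        for r, (res, truth) in enumerate(zip(results, truths)):
            truth = truth.true_deg_ids if hasattr(truth, "true_deg_ids") else set(truth)
            for i, t in enumerate(thresholds):
                disc = discoveries(res, float(t))
                f[i, r] = fdp(disc, truth)
                w[i, r] = empirical_power(disc, truth)
        fdps[method] = f
        powers[method] = w
    return EvaluationSummary(list(results_by_method), thresholds, R, fdps, powers)


def power_at_actual_fdr(
    summary: EvaluationSummary, query_fdrs: Sequence[float]
) -> pd.DataFrame:
    """Interpolated power at matched actual FDR, per method.

    Each method's (actual FDR, power) pairs across the threshold sweep are
    made non-decreasing in actual FDR by the isotonic upper envelope (running
    maximum after sorting by actual FDR), then linearly interpolated at the
    query FDRs. Queries outside a method's observed range yield ``NaN``.
    """
    query = np.asarray(query_fdrs, dtype=float)
    rows = []
    for m in summary.methods:
        x = summary.actual_fdr(m)
        y = summary.power(m)
        order = np.argsort(x, kind="stable")
        x_sorted = x[order]
        y_hull = np.maximum.accumulate(y[order])
        interp = np.interp(query, x_sorted, y_hull)
        outside = (query < x_sorted[0]) | (query > x_sorted[-1])
        interp[outside] = np.nan
        for q, p in zip(query, interp):
            rows.append({"method": m, "actual_fdr": float(q), "power": float(p)})
    return pd.DataFrame(rows)


@dataclass
class PermutationSummary:
    """Discovery behaviour of one method across permuted-label datasets."""

    gene_ids: list[str]
    original_discoveries: set[str]
    original_count: int
    permutation_counts: np.ndarray  # length B
    identification_frequency: np.ndarray  # per gene, in [0, 1]
    threshold: float

    @property
    def B(self) -> int:
        return len(self.permutation_counts)

    @property
    def exceed_fraction(self) -> float:
        """Fraction of permutations yielding more discoveries than the original."""
        return float(np.mean(self.permutation_counts > self.original_count))

    def genes_at_frequency(self, min_fraction: float) -> set[str]:
        """Genes identified in at least ``min_fraction`` of permutations."""
        mask = self.identification_frequency >= min_fraction
        return {g for g, m in zip(self.gene_ids, mask) if m}

    def genes_at_most_frequency(self, max_fraction: float) -> set[str]:
        """Genes identified in at most ``max_fraction`` of permutations."""
        mask = self.identification_frequency <= max_fraction
        return {g for g, m in zip(self.gene_ids, mask) if m}

    def overlap_with_original(self, min_fraction: float) -> set[str]:
        """Original discoveries also found in >= ``min_fraction`` of permutations."""
        return self.original_discoveries & self.genes_at_frequency(min_fraction)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "identification_frequency": self.identification_frequency,
                "in_original": [g in self.original_discoveries for g in self.gene_ids],
            }
        )


def permutation_summary(
    original: DEResult,
    permuted: Sequence[DEResult],
    threshold: float,
) -> PermutationSummary:
    """Summarize how often a method discovers each gene on permuted labels."""
    if not permuted:
        raise ValueError("need at least one permuted result")
    genes = list(original.gene_ids)
    orig_disc = discoveries(original, threshold)
    counts = np.empty(len(permuted), dtype=int)
    hits = np.zeros(len(genes))
    index = {g: i for i, g in enumerate(genes)}
    for b, res in enumerate(permuted):
        disc = discoveries(res, threshold)
        counts[b] = len(disc)
        for g in disc:
            i = index.get(g)
            if i is not None:
                hits[i] += 1
    freq = hits / len(permuted)
    return PermutationSummary(genes, orig_disc, len(orig_disc), counts, freq, threshold)


def foldchange_frequency_profile(
    summary: PermutationSummary, log2fc: Mapping[str, float]
) -> pd.DataFrame:
    """Original DEGs ranked by |log2 fold change| with permutation frequencies.

    Rows are the original discovery set sorted by absolute log2 fold change
    descending (ties broken by gene id); no smoothing is applied.
    """
    freq = dict(zip(summary.gene_ids, summary.identification_frequency))
    rows = [
        {
            "gene_id": g,
            "abs_log2fc": abs(float(log2fc[g])),
            "frequency": float(freq.get(g, 0.0)),
        }
        for g in summary.original_discoveries
    ]
    rows.sort(key=lambda r: (-r["abs_log2fc"], r["gene_id"]))
    for rank, r in enumerate(rows, start=1):
        r["rank"] = rank
    return pd.DataFrame(rows, columns=["rank", "gene_id", "abs_log2fc", "frequency"])


# ---------------------------------------------------------------------------
# negative-binomial goodness of fit
# ---------------------------------------------------------------------------


def _chi2_logsf(x: float, df: float) -> float:
    """log of the chi-square upper tail, with an asymptotic deep-tail fallback.

    scipy's logsf itself underflows to -inf for extreme statistics at large
    df; there the upper-incomplete-gamma expansion
    ``log Q(a, z) ~ (a-1) log z - z - log Gamma(a) + log(series)`` with
    ``a = df/2, z = x/2`` keeps misfit magnitudes finite and ordered.
    """
    val = float(scipy.stats.chi2.logsf(x, df))
    if np.isfinite(val):
        return val
    a, z = df / 2.0, x / 2.0
    if z <= a:  # not a deep-tail underflow; give up gracefully
        return -np.inf
    series = term = 1.0
    for k in range(1, 8):
        term *= (a - k) / z
        series += term
    return (a - 1.0) * np.log(z) - z - scipy.special.gammaln(a) + np.log(max(series, 1e-12))


@dataclass
class GofRow:
    """Goodness-of-fit outcome for one gene under one condition."""

    mean: float
    dispersion: float
    p_value: float  # NaN when degenerate
    poorness: float  # -log10(p); NaN when degenerate
    degenerate: bool


@dataclass
class GofResult:
    """Per-(gene, condition) NB goodness-of-fit table."""

    gene_ids: list[str]
    conditions: list[str]
    rows: list[GofRow]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "condition": self.conditions,
                "mean": [r.mean for r in self.rows],
                "dispersion": [r.dispersion for r in self.rows],
                "p_value": [r.p_value for r in self.rows],
                "poorness": [r.poorness for r in self.rows],
                "degenerate": [r.degenerate for r in self.rows],
            }
        )

    def poorness_by_gene(self) -> dict[str, float]:
        """Max poorness across conditions per gene (NaN rows ignored)."""
        out: dict[str, float] = {}
        for g, r in zip(self.gene_ids, self.rows):
            if r.degenerate or np.isnan(r.poorness):
                continue
            out[g] = max(out.get(g, -np.inf), r.poorness)
        return out


def nb_gof_poorness(
    values: Sequence[float], dispersion: float, min_obs: int = 8
) -> GofRow:
    """Pearson chi-square NB goodness of fit with fixed dispersion.

    ``values`` are normalized counts of one gene under one condition; they are
    rounded to integers and tabulated over cells ``0..max`` plus one open tail
    cell. The NB law has ``size = 1/dispersion`` fixed and mean equal to the
    sample mean (the fixed-size maximum-likelihood estimate); the degrees of
    freedom are the number of cells minus 2. Poorness is ``-log10(p)``.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    vals = np.rint(np.asarray(values, dtype=float)).astype(np.int64)
    if vals.size < min_obs or (vals < 0).any():
        return GofRow(float("nan"), dispersion, float("nan"), float("nan"), True)
    if np.unique(vals).size == 1:
        return GofRow(float(vals[0]), dispersion, float("nan"), float("nan"), True)
    n = vals.size
    mean = float(vals.mean())
    size = 1.0 / dispersion
    prob = size / (size + mean)
    vmax = int(vals.max())
    # Pearson X^2 over cells 0..vmax plus the open tail (tail observed = 0):
    #   X^2 = sum_v o_v^2 / (n pmf(v)) - n, summing over observed values only,
    # because empty cells contribute their expectation, which telescopes with
    # the tail term (total expectation over all cells is n).
    uniq, obs = np.unique(vals, return_counts=True)
    pmf = scipy.stats.nbinom.pmf(uniq, size, prob)
    if (pmf <= 0).any():
        x2 = np.inf
    else:
        x2 = float(np.sum(obs.astype(float) ** 2 / (n * pmf)) - n)
    tail_mass = float(scipy.stats.nbinom.sf(vmax, size, prob))
    n_cells = (vmax + 1) + (1 if tail_mass > 0 else 0)
    df = n_cells - 2
    if df <= 0:
        return GofRow(mean, dispersion, float("nan"), float("nan"), True)
    if np.isfinite(x2):
        p = float(scipy.stats.chi2.sf(x2, df))
        # -log10(p) evaluated in log space so extreme misfits stay ordered
        # instead of saturating when p underflows
        poorness = float(-_chi2_logsf(x2, df) / np.log(10.0))
    else:
        p = 0.0
        poorness = float("inf")
    return GofRow(mean, dispersion, p, poorness, False)


def gof_table(
    matrix: CountMatrix,
    labels: ConditionLabels,
    dispersions: Mapping[str, float],
    norm: NormalizationResult | None = None,
    min_obs: int = 8,
) -> GofResult:
    """NB goodness of fit per (gene, condition) on normalized counts.

    Counts are divided by per-sample effective size factors (effective
    library size over its mean) before rounding, so library-size variation is
    removed. ``dispersions`` maps gene id to the dispersion to audit; genes
    absent from it are skipped.
    """
    if norm is not None:
        eff = norm.effective_library_sizes
        factors = eff / eff.mean()
    else:
        factors = np.ones(matrix.n_samples)
    normalized = matrix.counts / factors
    by_sample = dict(zip(labels.sample_ids, labels.labels))
    cols = np.array([by_sample[s] for s in matrix.sample_ids])
    gene_ids: list[str] = []
    conditions: list[str] = []
    rows: list[GofRow] = []
    for i, g in enumerate(matrix.gene_ids):
        phi = dispersions.get(g)
        if phi is None:
            continue
        for level in labels.levels:
            vals = normalized[i, cols == level]
            gene_ids.append(g)
            conditions.append(level)
            rows.append(nb_gof_poorness(vals, float(phi), min_obs=min_obs))
    return GofResult(gene_ids, conditions, rows)


def compare_poorness_groups(
    a: Sequence[float], b: Sequence[float]
) -> float:
    """Two-sided rank-sum p-value comparing two groups of poorness values.

    Missing values are dropped; an error is raised if either group is empty
    afterwards.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both poorness groups must be non-empty after dropping NaN")
    return wilcoxon_p(a, b)
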