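"""Differential-expression testing pipelines and multiple-testing control.

Two in-repo pipelines share the same preprocessing (low-expression filter, TMM
factors, CPM):

* :func:`run_wilcoxon_pipeline` — the recommended non-parametric route: a
  two-sided Wilcoxon rank-sum (Mann-Whitney) test per gene on CPM values,
  followed by Benjamini-Hochberg control. Exact null enumeration is used for
  small tie-free groups, a tie-corrected continuity-corrected normal
  approximation otherwise.
* :func:`nb_wald_pipeline` — a deliberately simple negative-binomial Wald
  comparator (gene-wise profile-likelihood dispersion, group-mean model with
  library-size offsets). It is NOT a replica of any published tool; its role
  is to exhibit the failure mode of parametric NB tests on data that violate
  the NB assumption (e.g. sporadic outlier counts).

An adapter (:func:`load_external_result`) lets per-gene p-value tables
produced by external tools enter the evaluation stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import gammaln, xlogy
from statsmodels.stats.multitest import multipletests

from degbench.core_data import ConditionLabels, CountMatrix, ParseError
from degbench.normalization import (
    cpm,
    filter_low_expression,
    log2_fold_change,
    tmm_factors,
)

__all__ = [
    "DEResult",
    "NBFit",
    "benjamini_hochberg",
    "discoveries",
    "load_external_result",
    "nb_wald_pipeline",
    "read_de_result",
    "run_wilcoxon_pipeline",
    "wilcoxon_p",
    "write_de_result",
]

logger = logging.getLogger(__name__)


@dataclass
class DEResult:
    """Per-gene differential-expression output of one method.

    Missing values (``NaN``) mark genes removed by the low-expression filter
    (or genes where the fit failed); ``q_value`` is missing exactly where
    ``p_value`` is.
    """

    gene_ids: list[str]
    statistic: np.ndarray
    log2fc: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    method_name: str

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        for name in ("statistic", "log2fc", "p_value", "q_value"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            setattr(self, name, arr)
        if not np.array_equal(np.isnan(self.p_value), np.isnan(self.q_value)):
            raise ValueError("q_value must be missing exactly where p_value is")

    @property
    def n_tested(self) -> int:
        return int(np.sum(~np.isnan(self.p_value)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "statistic": self.statistic,
                "log2fc": self.log2fc,
                "p_value": self.p_value,
                "q_value": self.q_value,
            }
        )


@dataclass
class NBFit:
    """Gene-wise negative-binomial fit: group means and dispersion.

    The parameterization is ``variance = mu + phi * mu**2`` (``size = 1/phi``).
    Means are on the normalized (per unit of effective library size) scale.
    """

    gene_ids: list[str]
    mean1: np.ndarray
    mean2: np.ndarray
    dispersion: np.ndarray

    @property
    def size(self) -> np.ndarray:
        return 1.0 / self.dispersion


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------


def _pooled_tie_free(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size == pooled.size


def wilcoxon_p(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 25
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    The exact null distribution of the rank-sum statistic is enumerated when
    both group sizes are at most ``exact_limit`` and the pooled values are
    tie-free; otherwise the normal approximation with tie-corrected variance
    and a continuity correction of 1/2 is used, doubling the smaller tail and
    capping at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    exact = (
        x.size <= exact_limit and y.size <= exact_limit and _pooled_tie_free(x, y)
    )
    method = "exact" if exact else "asymptotic"
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def _wilcoxon_p_rows(
    X: np.ndarray, Y: np.ndarray, exact_limit: int = 25
) -> np.ndarray:
    """Row-wise two-sided rank-sum p-values for equal-shape group matrices.

    Applies the same exact/approximate mode rule as :func:`wilcoxon_p` per
    row, batching rows of equal mode into vectorized calls.
    """
    n1, n2 = X.shape[1], Y.shape[1]
    p = np.empty(X.shape[0])
    if n1 <= exact_limit and n2 <= exact_limit:
        pooled = np.concatenate([X, Y], axis=1)
        sorted_pooled = np.sort(pooled, axis=1)
        tie_free = np.all(np.diff(sorted_pooled, axis=1) != 0, axis=1)
    else:
        tie_free = np.zeros(X.shape[0], dtype=bool)
    exact_rows = np.flatnonzero(tie_free)
    approx_rows = np.flatnonzero(~tie_free)
    if exact_rows.size:
        res = scipy.stats.mannwhitneyu(
            X[exact_rows], Y[exact_rows], axis=1,
            alternative="two-sided", method="exact",
        )
        p[exact_rows] = res.pvalue
    if approx_rows.size:
        res = scipy.stats.mannwhitneyu(
            X[approx_rows], Y[approx_rows], axis=1,
            alternative="two-sided", method="asymptotic", use_continuity=True,
        )
        p[approx_rows] = res.pvalue
    return np.minimum(p, 1.0)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; ``NaN`` entries pass through.

    Over the ``m`` non-missing p-values sorted ascending,
    ``q_(i) = min_{j>=i} m * p_(j) / j`` capped at 1, restored to input order.
    """
    p = np.asarray(pvalues, dtype=float)
    missing = np.isnan(p)
    valid = p[~missing]
    if valid.size and (valid.min() < 0 or valid.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    if valid.size:
        q[~missing] = multipletests(valid, method="fdr_bh")[1]
    return q


def discoveries(result: DEResult, threshold: float) -> set[str]:
    """Gene ids with ``q_value < threshold`` (strict inequality)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    with np.errstate(invalid="ignore"):
        mask = result.q_value < threshold
    return {g for g, flag in zip(result.gene_ids, mask) if flag}


# ---------------------------------------------------------------------------
# Wilcoxon pipeline
# ---------------------------------------------------------------------------


def _prepare(
    matrix: CountMatrix,
    labels: ConditionLabels,
    min_total_count: int,
    use_effective_sizes: bool,
):
    decision = filter_low_expression(matrix, labels, min_total_count=min_total_count)
    kept = matrix.select_genes(decision.kept_gene_ids)
    norm = tmm_factors(matrix)
    if use_effective_sizes:
        kept_norm_sizes = norm.effective_library_sizes
    else:
        kept_norm_sizes = norm.library_sizes
    cpm_kept = kept.counts / kept_norm_sizes * 1e6
    by_sample = dict(zip(labels.sample_ids, labels.labels))
    level1, level2 = labels.levels
    cols = np.array([by_sample[s] for s in matrix.sample_ids])
    idx1 = np.flatnonzero(cols == level1)
    idx2 = np.flatnonzero(cols == level2)
    return decision, kept, norm, cpm_kept, idx1, idx2


def _assemble(
    matrix: CountMatrix,
    kept_ids: list[str],
    statistic: np.ndarray,
    log2fc: np.ndarray,
    p_kept: np.ndarray,
    method_name: str,
) -> DEResult:
    index = {g: i for i, g in enumerate(kept_ids)}
    n = matrix.n_genes
    stat = np.full(n, np.nan)
    lfc = np.full(n, np.nan)
    p = np.full(n, np.nan)
    for i, g in enumerate(matrix.gene_ids):
        j = index.get(g)
        if j is not None:
            stat[i] = statistic[j]
            lfc[i] = log2fc[j]
            p[i] = p_kept[j]
    q = benjamini_hochberg(p)
    return DEResult(list(matrix.gene_ids), stat, lfc, p, q, method_name)


def run_wilcoxon_pipeline(
    matrix: CountMatrix,
    labels: ConditionLabels,
    fdr_threshold: float = 0.05,
    exact_limit: int = 25,
    min_total_count: int = 15,
    use_effective_sizes: bool = True,
    pseudocount: float = 1.0,
) -> DEResult:
    """Filter, TMM-normalize, and rank-sum test each gene's CPM values.

    The reported statistic is the rank-sum of the second condition group in
    the pooled per-gene ranking; ``log2fc`` is the pseudocount-stabilized
    log2 ratio of group-mean CPM (condition 2 vs condition 1). ``fdr_threshold``
    is carried for downstream discovery calls and does not affect p-values.
    """
    if not 0 < fdr_threshold < 1:
        raise ValueError("fdr_threshold must be in (0, 1)")
    decision, kept, norm, cpm_kept, idx1, idx2 = _prepare(
        matrix, labels, min_total_count, use_effective_sizes
    )
    if kept.n_genes == 0:
        nan = np.full(matrix.n_genes, np.nan)
        return DEResult(list(matrix.gene_ids), nan, nan.copy(), nan.copy(),
                        nan.copy(), "wilcoxon")
    X = cpm_kept[:, idx1]
    Y = cpm_kept[:, idx2]
    p_kept = _wilcoxon_p_rows(X, Y, exact_limit=exact_limit)
    ranks = scipy.stats.rankdata(cpm_kept[:, np.concatenate([idx1, idx2])], axis=1)
    statistic = ranks[:, X.shape[1]:].sum(axis=1)
    lfc = log2_fold_change(cpm_kept, labels, matrix.sample_ids, pseudocount)
    return _assemble(matrix, kept.gene_ids, statistic, lfc, p_kept, "wilcoxon")


# ---------------------------------------------------------------------------
# negative-binomial Wald comparator
# ---------------------------------------------------------------------------

_PHI_GRID = np.geomspace(1e-4, 10.0, 25)
_NEWTON_TOL = 1e-10
_NEWTON_MAX_ITER = 60


def _nb_group_fit(Y: np.ndarray, offsets: np.ndarray, r: np.ndarray):
    """Vectorized per-gene Newton fit of one group's log-mean.

    ``Y``: genes x samples counts of one group; ``offsets``: effective library
    sizes; ``r`` (genes,): NB size. Returns (beta, info, converged); the mean
    model is ``mu_gj = exp(beta_g) * offsets_j``.
    """
    total = Y.sum(axis=1)
    beta = np.log(np.maximum(total, 0.5) / offsets.sum())
    r = r[:, None]
    converged = np.zeros(Y.shape[0], dtype=bool)
    info = np.empty(Y.shape[0])
    for _ in range(_NEWTON_MAX_ITER):
        mu = np.exp(beta)[:, None] * offsets[None, :]
        score = (r * (Y - mu) / (r + mu)).sum(axis=1)
        info = (r * mu * (Y + r) / (r + mu) ** 2).sum(axis=1)
        step = score / np.maximum(info, 1e-300)
        step = np.clip(step, -5.0, 5.0)
        beta = beta + step
        converged = np.abs(step) < _NEWTON_TOL
        if converged.all():
            break
    mu = np.exp(beta)[:, None] * offsets[None, :]
    info = (r * mu * (Y + r) / (r + mu) ** 2).sum(axis=1)
    return beta, info, converged


def _nb_loglik(Y: np.ndarray, mu: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Row sums of the NB log-likelihood (size ``r``, mean ``mu``)."""
    r = r[:, None]
    ll = (
        gammaln(Y + r) - gammaln(r) - gammaln(Y + 1.0)
        + r * np.log(r / (r + mu))
        + xlogy(Y, mu / (r + mu))
    )
    return ll.sum(axis=1)


def _profile_loglik(
    Y1: np.ndarray, Y2: np.ndarray,
    off1: np.ndarray, off2: np.ndarray,
    phi: np.ndarray,
):
    """Profile log-likelihood over group means for per-gene dispersion ``phi``."""
    r = 1.0 / phi
    b1, i1, c1 = _nb_group_fit(Y1, off1, r)
    b2, i2, c2 = _nb_group_fit(Y2, off2, r)
    mu1 = np.exp(b1)[:, None] * off1[None, :]
    mu2 = np.exp(b2)[:, None] * off2[None, :]
    ll = _nb_loglik(Y1, mu1, r) + _nb_loglik(Y2, mu2, r)
    return ll, b1, b2, i1, i2, c1 & c2


_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def _fit_dispersion(Y1, Y2, off1, off2, grid=_PHI_GRID, refine_iter: int = 15):
    """Gene-wise profile-likelihood dispersion: grid scan + golden-section.

    The search is over log(phi); brackets are the grid neighbours of the best
    grid point (clamped at the grid ends).
    """
    G = Y1.shape[0]
    lls = np.empty((len(grid), G))
    for k, phi in enumerate(grid):
        lls[k], *_ = _profile_loglik(Y1, Y2, off1, off2, np.full(G, phi))
    best = lls.argmax(axis=0)
    log_grid = np.log(grid)
    lo = log_grid[np.maximum(best - 1, 0)]
    hi = log_grid[np.minimum(best + 1, len(grid) - 1)]
    # golden-section on log(phi), vectorized over genes (two evaluations per
    # iteration; per-gene brackets shrink independently)
    for _ in range(refine_iter):
        c = hi - _GOLDEN * (hi - lo)
        d = lo + _GOLDEN * (hi - lo)
        fc, *_ = _profile_loglik(Y1, Y2, off1, off2, np.exp(c))
        fd, *_ = _profile_loglik(Y1, Y2, off1, off2, np.exp(d))
        take_left = fc >= fd
        hi = np.where(take_left, d, hi)
        lo = np.where(take_left, lo, c)
    return np.exp((lo + hi) / 2.0)


def nb_wald_pipeline(
    matrix: CountMatrix,
    labels: ConditionLabels,
    fdr_threshold: float = 0.05,
    min_total_count: int = 15,
    use_effective_sizes: bool = True,
) -> DEResult:
    """Simplified gene-wise negative-binomial Wald test.

    Per kept gene: maximize the NB log-likelihood with group-specific means
    and log-effective-library-size offsets, estimating a single gene-wise
    dispersion by profile likelihood (log-spaced grid refined by
    golden-section search); the Wald statistic is the difference of group
    log-means over its standard error from observed information. No dispersion
    shrinkage and no outlier handling are applied — by design, so that the
    comparator exposes the sensitivity of parametric NB tests to model
    violations.
    """
    if not 0 < fdr_threshold < 1:
        raise ValueError("fdr_threshold must be in (0, 1)")
    decision, kept, norm, _, idx1, idx2 = _prepare(
        matrix, labels, min_total_count, use_effective_sizes
    )
    if kept.n_genes == 0:
        nan = np.full(matrix.n_genes, np.nan)
        return DEResult(list(matrix.gene_ids), nan, nan.copy(), nan.copy(),
                        nan.copy(), "nbwald")
    eff = norm.effective_library_sizes if use_effective_sizes else norm.library_sizes
    Y1 = kept.counts[:, idx1].astype(float)
    Y2 = kept.counts[:, idx2].astype(float)
    off1 = eff[idx1]
    off2 = eff[idx2]
    fit_ok = (Y1.sum(axis=1) > 0) & (Y2.sum(axis=1) > 0)
    G = kept.n_genes
    z = np.full(G, np.nan)
    lfc = np.full(G, np.nan)
    p_kept = np.full(G, np.nan)
    if fit_ok.any():
        rows = np.flatnonzero(fit_ok)
        phi = _fit_dispersion(Y1[rows], Y2[rows], off1, off2)
        _, b1, b2, i1, i2, conv = _profile_loglik(
            Y1[rows], Y2[rows], off1, off2, phi
        )
        se = np.sqrt(1.0 / np.maximum(i1, 1e-300) + 1.0 / np.maximum(i2, 1e-300))
        zr = (b2 - b1) / se
        pr = 2.0 * scipy.stats.norm.sf(np.abs(zr))
        pr = np.minimum(pr, 1.0)
        bad = ~conv
        if bad.any():
            for g in np.asarray(kept.gene_ids)[rows[bad]]:
                logger.warning("NB-Wald fit did not converge for gene %s", g)
            pr[bad] = np.nan
            zr[bad] = np.nan
        z[rows] = zr
        lfc[rows] = (b2 - b1) / np.log(2.0)
        p_kept[rows] = pr
    failed = np.flatnonzero(~fit_ok)
    for g in np.asarray(kept.gene_ids)[failed]:
        logger.warning("NB-Wald skipped gene %s: a condition has zero total count", g)
    return _assemble(matrix, kept.gene_ids, z, lfc, p_kept, "nbwald")


def nb_fit_table(
    matrix: CountMatrix,
    labels: ConditionLabels,
    min_total_count: int = 15,
) -> NBFit:
    """Gene-wise NB group means and profile-likelihood dispersions.

    Convenience for goodness-of-fit audits: returns the same fits the Wald
    comparator uses, restricted to filter-surviving genes with positive counts
    in both conditions.
    """
    decision, kept, norm, _, idx1, idx2 = _prepare(matrix, labels, min_total_count, True)
    eff = norm.effective_library_sizes
    Y1 = kept.counts[:, idx1].astype(float)
    Y2 = kept.counts[:, idx2].astype(float)
    ok = (Y1.sum(axis=1) > 0) & (Y2.sum(axis=1) > 0)
    rows = np.flatnonzero(ok)
    phi = _fit_dispersion(Y1[rows], Y2[rows], eff[idx1], eff[idx2])
    _, b1, b2, *_ = _profile_loglik(Y1[rows], Y2[rows], eff[idx1], eff[idx2], phi)
    ids = [kept.gene_ids[i] for i in rows]
    return NBFit(ids, np.exp(b1), np.exp(b2), phi)


# ---------------------------------------------------------------------------
# external-result adapter and TSV round trip
# ---------------------------------------------------------------------------


def load_external_result(path: str | Path, method_name: str = "external") -> DEResult:
    """Load a per-gene p-value table (TSV: gene_id, p_value[, log2fc]).

    q-values are recomputed with Benjamini-Hochberg so that external methods
    enter the evaluation on the same multiple-testing footing.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "p_value"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: missing required columns {sorted(required - set(df.columns))}"
        )
    p = df["p_value"].to_numpy(dtype=float)
    lfc = (
        df["log2fc"].to_numpy(dtype=float)
        if "log2fc" in df.columns
        else np.full(len(df), np.nan)
    )
    stat = (
        df["statistic"].to_numpy(dtype=float)
        if "statistic" in df.columns
        else np.full(len(df), np.nan)
    )
    q = benjamini_hochberg(p)
    return DEResult(list(df["gene_id"].astype(str)), stat, lfc, p, q, method_name)


def write_de_result(
    result: DEResult,
    path: str | Path,
    fdr_threshold: float | None = None,
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write a result table as TSV with a ``#`` metadata header block."""
    df = result.to_dataframe()
    if fdr_threshold is not None:
        with np.errstate(invalid="ignore"):
            df["discovered"] = (result.q_value < fdr_threshold).astype(int)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# method={result.method_name}\n")
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_de_result(path: str | Path, method_name: str | None = None) -> DEResult:
    """Read a table written by :func:`write_de_result`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    name = method_name or "unknown"
    return DEResult(
        list(df["gene_id"].astype(str)),
        df["statistic"].to_numpy(dtype=float),
        df["log2fc"].to_numpy(dtype=float),
        df["p_value"].to_numpy(dtype=float),
        df["q_value"].to_numpy(dtype=float),
        name,
    )
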