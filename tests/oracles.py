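"""Independent brute-force oracles used to validate the implementation.

These deliberately re-derive results from first principles (enumeration,
naive step-by-step formula evaluation) and share no code with the package.
"""

import itertools
import math

import numpy as np
import scipy.stats


def exact_wilcoxon_two_sided(x, y) -> float:
    """Full enumeration of the rank-sum null over all C(n1+n2, n1) splits.

    Two-sided p-value: fraction of splits whose rank-sum deviates from the
    null mean by at least as much (in absolute value) as the observed one.
    Assumes tie-free pooled values.
    """
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(x)
    n = len(pooled)
    w_obs = sum(ranks[v] for v in x)
    center = n1 * (n + 1) / 2.0
    dev = abs(w_obs - center)
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(1, n + 1), n1):
        total += 1
        if abs(sum(combo) - center) >= dev - 1e-12:
            extreme += 1
    return extreme / total


def bh_rejections_stepup(pvalues, q) -> set:
    """Naive BH: largest i with p_(i) <= i*q/m; reject the first i sorted p's."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    return set(order[:k].tolist())


def tmm_factor_oracle(counts, trim_m=0.30, trim_a=0.05):
    """Step-by-step TMM evaluation with plain Python loops.

    Reference: sample whose 75th-percentile count/library-size ratio is
    closest to the mean of that quantity. Per non-reference sample: M/A
    ratios over genes positive in both, delta-method variances, equal-tail
    rank trimming (30% on M, 5% on A), inverse-variance weighted mean,
    then a geometric-mean-one rescale of all factors.
    """
    counts = np.asarray(counts, dtype=float)
    n_genes, n_samples = counts.shape
    lib = counts.sum(axis=0)
    q75 = [np.percentile(counts[:, j] / lib[j], 75) for j in range(n_samples)]
    mean_q = sum(q75) / n_samples
    ref = min(range(n_samples), key=lambda j: (abs(q75[j] - mean_q), j))
    log_f = [0.0] * n_samples
    for j in range(n_samples):
        if j == ref:
            continue
        ms, as_, vs = [], [], []
        for g in range(n_genes):
            yj, yr = counts[g, j], counts[g, ref]
            if yj <= 0 or yr <= 0:
                continue
            m = math.log2((yj / lib[j]) / (yr / lib[ref]))
            a = 0.5 * math.log2((yj / lib[j]) * (yr / lib[ref]))
            v = (lib[j] - yj) / (lib[j] * yj) + (lib[ref] - yr) / (lib[ref] * yr)
            if math.isfinite(m) and math.isfinite(a):
                ms.append(m)
                as_.append(a)
                vs.append(v)
        n = len(ms)
        if n == 0:
            continue
        rank_m = scipy.stats.rankdata(ms)
        rank_a = scipy.stats.rankdata(as_)
        lo_m, hi_m = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
        lo_a, hi_a = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
        num = den = 0.0
        kept = 0
        for i in range(n):
            if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
                num += ms[i] / vs[i]
                den += 1.0 / vs[i]
                kept += 1
        log_f[j] = num / den if kept >= 10 else 0.0
    factors = np.array([2.0 ** f for f in log_f])
    return factors / np.exp(np.mean(np.log(factors)))


def nb_gof_pearson_naive(values, dispersion):
    """Literal frequency-table Pearson chi-square for the NB law.

    Builds the full observed table over cells 0..max plus an open tail,
    expected counts from NB(size=1/dispersion, mean=sample mean), X^2 over
    cells with positive expectation, df = cells - 2.
    """
    vals = np.rint(np.asarray(values, dtype=float)).astype(int)
    n = vals.size
    mean = vals.mean()
    size = 1.0 / dispersion
    prob = size / (size + mean)
    vmax = vals.max()
    obs = np.bincount(vals, minlength=vmax + 1).astype(float)
    exp = n * scipy.stats.nbinom.pmf(np.arange(vmax + 1), size, prob)
    tail = n * scipy.stats.nbinom.sf(vmax, size, prob)
    obs = np.append(obs, 0.0)
    exp = np.append(exp, tail)
    keep = exp > 0
    x2 = float(np.sum((obs[keep] - exp[keep]) ** 2 / exp[keep]))
    df = int(keep.sum()) - 2
    if df <= 0:
        return float("nan"), df
    return float(scipy.stats.chi2.sf(x2, df)), df
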