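"""Permutation-null and semi-synthetic benchmark construction.

Two constructions turn a two-condition dataset into benchmark material:

* **Permutation-null datasets** (:func:`permute_labels`): the count matrix is
  untouched and the condition labels are uniformly permuted, so any DEG found
  afterwards is a false positive by construction.
* **Semi-synthetic datasets** (:func:`make_semisynthetic`): a subset of known
  true DEGs keeps its original per-condition read counts, while every other
  gene's pooled row is uniformly permuted across the two conditions and split
  back by the original column positions. Selected genes carry real signal;
  all other genes are exchangeable across conditions, giving known positives
  and negatives for FDR/power evaluation.

All randomness is driven by explicit integer seeds; per-gene and
per-replicate sub-streams are derived from ``(seed, index)`` so results do not
depend on traversal order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from degbench.core_data import ConditionLabels, CountMatrix, ValidationError
from degbench.de_methods import DEResult, discoveries

__all__ = [
    "GroundTruth",
    "PermutationSet",
    "SemiSyntheticDataset",
    "define_true_degs",
    "downsample",
    "generate_replicates",
    "make_semisynthetic",
    "permute_labels",
]


def _child_rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def derive_seed(seed: int, index: int) -> int:
    """Deterministic child seed (< 2**31) from a parent seed and an index."""
    return int(np.random.SeedSequence([int(seed), int(index)]).generate_state(1)[0] % (2**31))


@dataclass
class PermutationSet:
    """A batch of uniformly permuted condition-label vectors."""

    base: ConditionLabels
    B: int
    seed: int
    permuted_labels: list[ConditionLabels]

    def __iter__(self):
        return iter(self.permuted_labels)

    def __len__(self) -> int:
        return len(self.permuted_labels)


@dataclass
class GroundTruth:
    """The set of genes treated as truly differentially expressed."""

    true_deg_ids: set[str]
    provenance: str  # "method-intersection" or "simulator"

    def __post_init__(self) -> None:
        self.true_deg_ids = set(self.true_deg_ids)
        if self.provenance not in ("method-intersection", "simulator"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass
class SemiSyntheticDataset:
    """A constructed dataset with known true DEGs and exchangeable negatives."""

    X: CountMatrix
    Y: CountMatrix
    selected_true_degs: set[str]
    replicate_index: int
    seed: int
    condition_names: tuple[str, str] = ("c1", "c2")

    def __post_init__(self) -> None:
        if self.X.gene_ids != self.Y.gene_ids:
            raise ValidationError("X and Y must share gene ids in order")
        self.selected_true_degs = set(self.selected_true_degs)

    def as_matrix_and_labels(self) -> tuple[CountMatrix, ConditionLabels]:
        """Merge the pair back into one matrix plus two-condition labels."""
        counts = np.concatenate([self.X.counts, self.Y.counts], axis=1)
        sample_ids = list(self.X.sample_ids) + list(self.Y.sample_ids)
        matrix = CountMatrix(list(self.X.gene_ids), sample_ids, counts)
        labels = ConditionLabels(
            sample_ids,
            [self.condition_names[0]] * self.X.n_samples
            + [self.condition_names[1]] * self.Y.n_samples,
            level_order=self.condition_names,
        )
        return matrix, labels


def permute_labels(labels: ConditionLabels, B: int, seed: int) -> PermutationSet:
    """Draw ``B`` independent uniform permutations of the label vector.

    The sample order (and hence the count matrix) is untouched; only the
    assignment of condition levels to samples is shuffled. Permutation ``b``
    is driven by the sub-stream ``(seed, b)``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    values = np.array(labels.labels)
    out = []
    for b in range(B):
        rng = _child_rng(seed, b)
        out.append(labels.with_labels(list(values[rng.permutation(values.size)])))
    return PermutationSet(labels, B, seed, out)


def define_true_degs(
    results: Sequence[DEResult], strict_threshold: float = 1e-6
) -> GroundTruth:
    """True DEGs as the intersection of several methods' discoveries.

    Mirrors the convention used when no ground truth exists: a gene counts as
    a true DEG only when every supplied method discovers it at a very small
    FDR threshold (default 1e-6, i.e. 0.0001%).
    """
    if len(results) < 2:
        raise ValueError("need at least two method results to intersect")
    universes = [set(r.gene_ids) for r in results]
    common = set.intersection(*universes)
    if not common:
        raise ValueError("method results share no gene ids")
    truth = set.intersection(*(discoveries(r, strict_threshold) for r in results))
    return GroundTruth(truth, "method-intersection")


def make_semisynthetic(
    X: CountMatrix,
    Y: CountMatrix,
    truth: GroundTruth | set[str],
    select_fraction: float = 0.5,
    seed: int = 0,
    replicate_index: int = 1,
    condition_names: tuple[str, str] = ("c1", "c2"),
) -> SemiSyntheticDataset:
    """Build one semi-synthetic dataset from a two-condition pair.

    ``k = round(select_fraction * |truth|)`` true DEGs are sampled uniformly
    without replacement and keep their original rows in both conditions;
    every other gene's pooled row across ``(X, Y)`` is uniformly permuted
    (per-gene sub-stream ``(seed, 2, gene_index)``) and split back by the
    original column positions, making it exchangeable across conditions.
    """
    if X.gene_ids != Y.gene_ids:
        raise ValidationError("X and Y must share gene ids in order")
    truth_ids = truth.true_deg_ids if isinstance(truth, GroundTruth) else set(truth)
    unknown = truth_ids - set(X.gene_ids)
    if unknown:
        raise ValidationError(f"truth contains unknown gene ids: {sorted(unknown)[:5]}")
    if not 0 < select_fraction <= 1:
        raise ValueError("select_fraction must be in (0, 1]")
    if not truth_ids:
        raise ValueError("cannot select true DEGs from an empty truth set")
    k = int(round(select_fraction * len(truth_ids)))
    select_rng = _child_rng(seed, 1)
    ordered_truth = sorted(truth_ids)
    selected = set(
        np.array(ordered_truth)[
            select_rng.choice(len(ordered_truth), size=k, replace=False)
        ]
    )
    n1 = X.n_samples
    new_x = X.counts.copy()
    new_y = Y.counts.copy()
    for i, gene in enumerate(X.gene_ids):
        if gene in selected:
            continue
        pooled = np.concatenate([X.counts[i], Y.counts[i]])
        rng = _child_rng(seed, 2, i)
        pooled = pooled[rng.permutation(pooled.size)]
        new_x[i] = pooled[:n1]
        new_y[i] = pooled[n1:]
    return SemiSyntheticDataset(
        CountMatrix(list(X.gene_ids), list(X.sample_ids), new_x),
        CountMatrix(list(Y.gene_ids), list(Y.sample_ids), new_y),
        selected,
        replicate_index,
        seed,
        condition_names,
    )


def downsample(ds: SemiSyntheticDataset, n: int, seed: int) -> SemiSyntheticDataset:
    """Keep ``n`` uniformly sampled columns per condition (truth unchanged)."""
    max_n = min(ds.X.n_samples, ds.Y.n_samples)
    if not 2 <= n <= max_n:
        raise ValueError(f"n must be in [2, {max_n}], got {n}")
    rng_x = _child_rng(seed, 3)
    rng_y = _child_rng(seed, 4)
    keep_x = np.sort(rng_x.choice(ds.X.n_samples, size=n, replace=False))
    keep_y = np.sort(rng_y.choice(ds.Y.n_samples, size=n, replace=False))
    return SemiSyntheticDataset(
        ds.X.select_samples([ds.X.sample_ids[j] for j in keep_x]),
        ds.Y.select_samples([ds.Y.sample_ids[j] for j in keep_y]),
        set(ds.selected_true_degs),
        ds.replicate_index,
        seed,
        ds.condition_names,
    )


def generate_replicates(
    X: CountMatrix,
    Y: CountMatrix,
    truth: GroundTruth | set[str],
    R: int = 50,
    select_fraction: float = 0.5,
    seed: int = 0,
    condition_names: tuple[str, str] = ("c1", "c2"),
) -> list[SemiSyntheticDataset]:
    """``R`` independent semi-synthetic replicates with derived seeds."""
    if R < 1:
        raise ValueError("R must be >= 1")
    return [
        make_semisynthetic(
            X, Y, truth,
            select_fraction=select_fraction,
            seed=derive_seed(seed, r),
            replicate_index=r,
            condition_names=condition_names,
        )
        for r in range(1, R + 1)
    ]
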