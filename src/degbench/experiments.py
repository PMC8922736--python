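"""End-to-end experiment drivers composing simulation, resampling, testing,
and evaluation, with seed derivation and manifest provenance.

Four experiment shapes are supported:

* ``permutation-null`` — run methods on the original data and on ``B``
  permuted-label copies; summarize discovery counts and per-gene frequencies.
* ``semi-synthetic`` — build ``R`` semi-synthetic replicates from a parent
  dataset, run methods, and evaluate FDR/power over a threshold grid.
* ``sample-size-sweep`` — the semi-synthetic experiment with each replicate
  additionally down-sampled to a grid of per-condition sample sizes.
* ``deg-proportion-sweep`` — the semi-synthetic experiment repeated over a
  grid of simulated DEG proportions.

Every random draw derives from the single top-level seed through documented
``(seed, index)`` sub-streams, so a manifest suffices to re-run bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from degbench.core_data import ConditionLabels, CountMatrix, split_by_condition
from degbench.de_methods import (
    DEResult,
    discoveries,
    nb_fit_table,
    nb_wald_pipeline,
    run_wilcoxon_pipeline,
    write_de_result,
)
from degbench.evaluation import (
    EvaluationSummary,
    PermutationSummary,
    compare_poorness_groups,
    evaluate_methods,
    gof_table,
    permutation_summary,
)
from degbench.normalization import tmm_factors
from degbench.resampling import (
    derive_seed,
    downsample,
    generate_replicates,
    permute_labels,
)
from degbench.synthetic_data import (
    SimulatedDataset,
    SimulationConfig,
    simulate_dataset,
)

__all__ = [
    "ExperimentConfig",
    "contamination_discovery_contrast",
    "permutation_gof_contrast",
    "run_experiment",
    "run_method",
    "semisynthetic_fdr_benchmark",
]

logger = logging.getLogger(__name__)

_METHODS: dict[str, Callable[..., DEResult]] = {
    "wilcoxon": run_wilcoxon_pipeline,
    "nbwald": nb_wald_pipeline,
}


def run_method(
    name: str, matrix: CountMatrix, labels: ConditionLabels, fdr_threshold: float = 0.05
) -> DEResult:
    """Dispatch a DE method by name (``wilcoxon`` or ``nbwald``)."""
    try:
        fn = _METHODS[name]
    except KeyError:
        raise ValueError(f"unknown method {name!r}; available: {sorted(_METHODS)}")
    return fn(matrix, labels, fdr_threshold=fdr_threshold)


@dataclass
class ExperimentConfig:
    """Declarative description of one benchmark experiment."""

    experiment: str  # permutation-null | semi-synthetic | sample-size-sweep | deg-proportion-sweep
    seed: int
    methods: tuple[str, ...] = ("wilcoxon",)
    B: int = 1000
    R: int = 50
    n_grid: tuple[int, ...] = (2, 4, 8, 16, 32, 64, 100)
    pi_grid: tuple[float, ...] = (0.01, 0.03, 0.05, 0.09, 0.20)
    thresholds: tuple[float, ...] = (1e-5, 1e-4, 1e-3, 0.01, 0.05)
    select_fraction: float = 0.5
    fdr_threshold: float = 0.05
    simulation: SimulationConfig | None = None
    counts_path: str | None = None
    labels_path: str | None = None
    outdir: str = "results/experiment"

    _SHAPES = (
        "permutation-null",
        "semi-synthetic",
        "sample-size-sweep",
        "deg-proportion-sweep",
    )

    def __post_init__(self) -> None:
        if self.experiment not in self._SHAPES:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; expected one of {self._SHAPES}"
            )
        for name in self.methods:
            if name not in _METHODS:
                raise ValueError(f"unknown method {name!r}")
        if not self.methods or not self.thresholds:
            raise ValueError("methods and thresholds must be non-empty")


# ---------------------------------------------------------------------------
# reusable drivers (also the acceptance entry points)
# ---------------------------------------------------------------------------


def _parent_pair(parent: SimulatedDataset):
    X, Y = split_by_condition(parent.matrix, parent.labels)
    return X, Y


def semisynthetic_fdr_benchmark(
    parent: SimulatedDataset,
    R: int = 20,
    select_fraction: float = 0.5,
    thresholds: Sequence[float] = (1e-5, 1e-4, 1e-3, 0.01, 0.05),
    methods: Sequence[str] = ("wilcoxon",),
    n_per_condition: int | None = None,
    seed: int = 0,
) -> EvaluationSummary:
    """FDR/power of DE methods on semi-synthetic replicates of a parent.

    Builds ``R`` semi-synthetic replicates from the parent's simulator truth
    (preserving ``select_fraction`` of it, permuting every other gene's pooled
    row), optionally down-samples each replicate to ``n_per_condition``
    columns per condition, runs each method with per-dataset filtering, and
    evaluates FDP and empirical power against each replicate's selected set.
    """
    X, Y = _parent_pair(parent)
    level1, level2 = parent.labels.levels
    replicates = generate_replicates(
        X, Y, parent.truth, R=R,
        select_fraction=select_fraction,
        seed=derive_seed(seed, 101),
        condition_names=(level1, level2),
    )
    if n_per_condition is not None:
        replicates = [
            downsample(ds, n_per_condition, seed=derive_seed(seed, 200 + ds.replicate_index))
            for ds in replicates
        ]
    results: dict[str, list[DEResult]] = {m: [] for m in methods}
    truths: list[set[str]] = []
    for ds in replicates:
        matrix, labels = ds.as_matrix_and_labels()
        truths.append(set(ds.selected_true_degs))
        for m in methods:
            results[m].append(run_method(m, matrix, labels))
    return evaluate_methods(results, truths, thresholds)


def contamination_discovery_contrast(
    base_config: SimulationConfig,
    n_seeds: int = 20,
    threshold: float = 0.05,
    epsilon: float = 0.05,
) -> pd.DataFrame:
    """Discovery counts of both pipelines on contaminated null data.

    Simulates ``n_seeds`` null datasets (no true DEGs) with outlier rate
    ``epsilon`` and reports, per seed, the number of q < ``threshold``
    discoveries of the Wilcoxon and NB-Wald pipelines. Every discovery is a
    false positive by construction.
    """
    rows = []
    for s in range(n_seeds):
        cfg = replace(
            base_config, pi=0.0, epsilon=epsilon, seed=derive_seed(base_config.seed, 300 + s)
        )
        sim = simulate_dataset(cfg)
        n_wil = len(discoveries(run_wilcoxon_pipeline(sim.matrix, sim.labels), threshold))
        n_nb = len(discoveries(nb_wald_pipeline(sim.matrix, sim.labels), threshold))
        rows.append({"seed_index": s, "wilcoxon": n_wil, "nbwald": n_nb})
    return pd.DataFrame(rows)


def permutation_gof_contrast(
    parent: SimulatedDataset,
    B: int = 50,
    threshold: float = 0.05,
    high_fraction: float = 0.20,
    low_fraction: float = 0.001,
    max_low_group: int = 200,
    seed: int = 0,
    method: str = "nbwald",
) -> dict:
    """NB goodness of fit of frequently- vs rarely-false-positive genes.

    Runs ``method`` on ``B`` permuted-label copies of the parent dataset,
    splits genes into those identified in at least ``high_fraction`` versus at
    most ``low_fraction`` of permutations, and compares the two groups' NB
    goodness-of-fit poorness (max over the two conditions per gene) with a
    two-sided rank-sum test. The rarely-identified group is capped at
    ``max_low_group`` genes (deterministic subsample) to keep the chi-square
    tabulation cheap.
    """
    matrix, labels = parent.matrix, parent.labels
    original = run_method(method, matrix, labels)
    permuted = []
    perms = permute_labels(labels, B, seed=derive_seed(seed, 400))
    for b, plabels in enumerate(perms):
        permuted.append(run_method(method, matrix, plabels))
    summary = permutation_summary(original, permuted, threshold)
    high = summary.genes_at_frequency(high_fraction)
    low = summary.genes_at_most_frequency(low_fraction)
    tested = {g for g, p in zip(original.gene_ids, original.p_value) if not np.isnan(p)}
    high &= tested
    low = sorted((low & tested) - high)
    if len(low) > max_low_group:
        rng = np.random.default_rng(derive_seed(seed, 401))
        low = sorted(np.array(low)[rng.choice(len(low), max_low_group, replace=False)])
    fit = nb_fit_table(matrix, labels)
    disp = dict(zip(fit.gene_ids, fit.dispersion))
    norm = tmm_factors(matrix)
    audit_genes = sorted(high) + list(low)
    sub = matrix.select_genes([g for g in audit_genes if g in disp])
    gof = gof_table(sub, labels, disp, norm=norm)
    poorness = gof.poorness_by_gene()
    high_vals = [poorness[g] for g in high if g in poorness]
    low_vals = [poorness[g] for g in low if g in poorness]
    p_compare = compare_poorness_groups(high_vals, low_vals)
    return {
        "summary": summary,
        "high_genes": high,
        "low_genes": set(low),
        "high_poorness": np.asarray(high_vals),
        "low_poorness": np.asarray(low_vals),
        "rank_sum_p": p_compare,
    }


# ---------------------------------------------------------------------------
# run_experiment: staged pipeline with manifests
# ---------------------------------------------------------------------------


def _write_manifest(path: Path, entries: Mapping[str, object]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for k, v in entries.items():
            fh.write(f"{k}={v}\n")


def _load_or_simulate(config: ExperimentConfig) -> SimulatedDataset:
    if config.counts_path is not None:
        from degbench.core_data import read_count_matrix, read_labels
        from degbench.resampling import GroundTruth

        matrix = read_count_matrix(config.counts_path, "tsv")
        labels = read_labels(config.labels_path)
        return SimulatedDataset(
            matrix, labels, GroundTruth(set(), "simulator"),
            np.zeros(matrix.counts.shape, dtype=bool),
            config.simulation or SimulationConfig(seed=config.seed),
        )
    sim_cfg = config.simulation or SimulationConfig(seed=derive_seed(config.seed, 1))
    return simulate_dataset(sim_cfg)


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute one experiment shape and write its tables plus a manifest.

    Returns a dict with the in-memory summary objects and the output paths.
    Partial outputs are retained if a stage fails; the failing stage is named
    in the raised error.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {
        "experiment": config.experiment,
        "seed": config.seed,
        "methods": ",".join(config.methods),
        "thresholds": ",".join(str(t) for t in config.thresholds),
    }
    stage = "simulate/ingest"
    try:
        parent = _load_or_simulate(config)
        manifest.update(
            {f"simulation.{k}": v for k, v in parent.config.as_dict().items()}
        )
        outputs: dict[str, object] = {"parent": parent}

        if config.experiment == "permutation-null":
            stage = "permute"
            perm_seed = derive_seed(config.seed, 400)
            perms = permute_labels(parent.labels, config.B, seed=perm_seed)
            manifest["B"] = config.B
            manifest["permutation_seeds"] = ",".join(
                str(derive_seed(perm_seed, b)) for b in range(config.B)
            )
            stage = "run methods"
            tables = {}
            for m in config.methods:
                original = run_method(m, parent.matrix, parent.labels)
                permuted = [run_method(m, parent.matrix, pl) for pl in perms]
                stage = "evaluate"
                summary = permutation_summary(original, permuted, config.fdr_threshold)
                path = outdir / f"permutation_summary_{m}.tsv"
                df = summary.to_dataframe()
                with open(path, "wt", encoding="utf-8") as fh:
                    fh.write(f"# method={m}\n# B={config.B}\n")
                    fh.write(f"# original_count={summary.original_count}\n")
                    fh.write(f"# exceed_fraction={summary.exceed_fraction}\n")
                    df.to_csv(fh, sep="\t", index=False)
                tables[m] = summary
                stage = "run methods"
            outputs["summaries"] = tables

        elif config.experiment in ("semi-synthetic", "sample-size-sweep"):
            stage = "resample/run/evaluate"
            n_values: tuple[int | None, ...]
            if config.experiment == "semi-synthetic":
                n_values = (None,)
            else:
                n_values = config.n_grid
            frames = []
            summaries = {}
            for n in n_values:
                summary = semisynthetic_fdr_benchmark(
                    parent,
                    R=config.R,
                    select_fraction=config.select_fraction,
                    thresholds=config.thresholds,
                    methods=config.methods,
                    n_per_condition=n,
                    seed=config.seed,
                )
                df = summary.to_dataframe()
                df.insert(0, "n_per_condition", -1 if n is None else n)
                frames.append(df)
                summaries[n] = summary
            table = pd.concat(frames, ignore_index=True)
            path = outdir / "evaluation_summary.tsv"
            with open(path, "wt", encoding="utf-8") as fh:
                fh.write(f"# seed={config.seed}\n# R={config.R}\n")
                fh.write(f"# select_fraction={config.select_fraction}\n")
                table.to_csv(fh, sep="\t", index=False)
            manifest["R"] = config.R
            outputs["summaries"] = summaries

        else:  # deg-proportion-sweep
            stage = "resample/run/evaluate"
            frames = []
            summaries = {}
            base = parent.config
            for pi in config.pi_grid:
                cfg = replace(base, pi=float(pi), seed=derive_seed(config.seed, int(1e6 * pi)))
                sim = simulate_dataset(cfg)
                summary = semisynthetic_fdr_benchmark(
                    sim,
                    R=config.R,
                    select_fraction=config.select_fraction,
                    thresholds=config.thresholds,
                    methods=config.methods,
                    seed=config.seed,
                )
                df = summary.to_dataframe()
                df.insert(0, "pi", float(pi))
                frames.append(df)
                summaries[pi] = summary
            table = pd.concat(frames, ignore_index=True)
            path = outdir / "evaluation_summary.tsv"
            with open(path, "wt", encoding="utf-8") as fh:
                fh.write(f"# seed={config.seed}\n# R={config.R}\n")
                table.to_csv(fh, sep="\t", index=False)
            outputs["summaries"] = summaries

        _write_manifest(outdir / "manifest.txt", manifest)
        outputs["outdir"] = outdir
        return outputs
    except Exception as exc:
        raise RuntimeError(f"experiment failed in stage '{stage}': {exc}") from exc
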