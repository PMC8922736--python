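#!/usr/bin/env python
"""Simulate the benchmark parent dataset and describe its structure.

Draws the two-condition negative-binomial parent used throughout the
analysis — 5,000 genes, 100 samples per condition, 5% true DEGs, 2% of
entries contaminated by multiplicative outliers. The full count matrix is
bulky and is written under scratch/ (regenerable from the seed); a small
per-gene summary table goes to results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from degbench.core_data import write_count_matrix, write_labels
from degbench.synthetic_data import SimulationConfig, simulate_dataset

SCRATCH = Path("scratch/parent")
OUT = Path("results")
SEED = 1


def main() -> None:
    cfg = SimulationConfig(G=5000, n1=100, n2=100, pi=0.05, epsilon=0.02, seed=SEED)
    sim = simulate_dataset(cfg)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    OUT.mkdir(parents=True, exist_ok=True)
    write_count_matrix(sim.matrix, SCRATCH / "counts.tsv", "tsv",
                       metadata={"seed": SEED, "pi": cfg.pi, "epsilon": cfg.epsilon})
    write_labels(sim.labels, SCRATCH / "labels.tsv")
    (SCRATCH / "truth.txt").write_text(
        "\n".join(sorted(sim.truth.true_deg_ids)) + "\n"
    )
    lib = sim.matrix.library_sizes()
    summary = pd.DataFrame(
        {
            "statistic": [
                "genes", "samples_per_condition", "true_degs",
                "outlier_entry_rate", "median_library_size",
                "median_gene_mean_count",
            ],
            "value": [
                sim.matrix.n_genes, cfg.n1, len(sim.truth.true_deg_ids),
                round(float(sim.outlier_mask.mean()), 5),
                float(np.median(lib)),
                float(np.median(sim.matrix.counts.mean(axis=1))),
            ],
        }
    )
    with open(OUT / "parent_summary.tsv", "wt") as fh:
        fh.write(f"# seed={SEED}\n")
        summary.to_csv(fh, sep="\t", index=False)
    print(f"parent: {sim.matrix.n_genes} genes x {sim.matrix.n_samples} samples, "
          f"{len(sim.truth.true_deg_ids)} true DEGs, "
          f"outlier rate {sim.outlier_mask.mean():.4f}")
    print(f"full dataset under {SCRATCH}/ (regenerable from seed {SEED}); "
          f"summary in {OUT}/parent_summary.tsv")


if __name__ == "__main__":
    main()
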