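"""Benchmark workflows on synthetic data with known ground truth.

These routines wire the simulator into the analysis stages and score the
results against the planted truth: classifier recovery as a function of the
origin separation, DEG false-positive/power behaviour, and PAC stability on
well-separated blob data.  They are used by the test suite and by the
reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classifier import (
    classify_cells,
    select_anchor_cells,
    select_discriminative_genes,
)
from .qc import normalize_counts
from .reporter import quantify_reporter_umis
from .synthetic import SimulationConfig, simulate_dataset
from .trajectory import find_degs, pac_stability

__all__ = [
    "two_origin_config",
    "classifier_recovery",
    "deg_null_and_power",
    "pac_two_blobs",
]


def two_origin_config(
    marker_ln_fc: float = 1.0,
    n_per_group: int = 1070,
    n_genes: int = 1000,
    seed: int = 7,
) -> SimulationConfig:
    """A clean two-origin design (no transition, doublets or contaminants)
    for classifier benchmarking: red oesophageal cells vs the green in vitro
    skin reference."""
    return SimulationConfig(
        n_cells_per_group=n_per_group,
        n_genes=n_genes,
        samples=(("oeOE-D10", "red", "D10"), ("sSKIN", "green", "D10")),
        green_spike_fraction=None,
        transitioning_fraction=0.0,
        doublet_rate=0.0,
        contaminant_fraction=0.0,
        marker_ln_fc=marker_ln_fc,
        seed=seed,
    )


def classifier_recovery(
    marker_ln_fc: float = 1.0,
    n_per_group: int = 1070,
    n_genes: int = 1000,
    n_anchors: int = 70,
    seed: int = 7,
) -> dict:
    """Run the full classifier chain on a simulated two-origin dataset and
    score against the planted origins.

    Returns accuracy and unknown percentages over the non-anchor (test)
    cells.  When the origins are too close for any discriminative gene to
    survive the dual-route selection, every cell is scored "unknown".
    """
    ds = simulate_dataset(
        two_origin_config(marker_ln_fc, n_per_group, n_genes, seed)
    )
    norm = normalize_counts(ds.adata)
    sub_map = {s: "red" for s in ds.config.red_subtranscripts}
    sub_map |= {s: "green" for s in ds.config.green_subtranscripts}
    rexpr = quantify_reporter_umis(ds.reporter_reads, sub_map).reindex(
        norm.obs_names, fill_value=0
    )
    anchors = select_anchor_cells(rexpr, n_target=n_anchors)
    gene_set = select_discriminative_genes(norm, anchors, seed=seed)
    anchor_cells = set(anchors.red_anchors) | set(anchors.green_anchors)
    test_cells = [c for c in norm.obs_names if c not in anchor_cells]
    if not gene_set.final:
        return {
            "n_test": len(test_cells),
            "accuracy_pct": 0.0,
            "unknown_pct": 100.0,
            "n_final_genes": 0,
        }
    calls = classify_cells(norm, gene_set, anchors, cells=test_cells)
    truth = norm.obs.loc[calls.index, "true_origin"]
    return {
        "n_test": len(calls),
        "accuracy_pct": 100.0 * float((calls["label"] == truth).mean()),
        "unknown_pct": 100.0 * float((calls["label"] == "unknown").mean()),
        "n_final_genes": len(gene_set.final),
    }


def _nb_counts(
    rng: np.random.Generator, n: int, n_genes: int, mean: float, r: float
) -> np.ndarray:
    return rng.negative_binomial(r, r / (r + mean), size=(n, n_genes)).astype(float)


def deg_null_and_power(
    n_replicates: int = 200,
    n_cells: int = 100,
    n_genes: int = 1000,
    n_planted: int = 20,
    planted_ln_fc: float = 1.0,
    n_cells_power: int = 200,
    seed: int = 0,
) -> dict:
    """Type-I control under a global null and recovery of planted genes.

    Null: both groups drawn from one negative-binomial distribution; the
    fraction of replicates with zero retained DEGs is reported.  Power: a
    single draw with ``n_planted`` genes shifted by ``planted_ln_fc`` in one
    group; the fraction of planted genes recovered is reported.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    groups = np.array(["a"] * n_cells + ["b"] * n_cells)
    zero = 0
    for _ in range(n_replicates):
        counts = _nb_counts(rng, 2 * n_cells, n_genes, mean=3.0, r=5.0)
        expr = np.log1p(counts / counts.sum(1, keepdims=True) * 1e4)
        degs = find_degs(expr, counts, genes, groups, top_n_abundant=n_genes)
        zero += int(len(degs) == 0)

    groups_p = np.array(["a"] * n_cells_power + ["b"] * n_cells_power)
    counts = _nb_counts(rng, 2 * n_cells_power, n_genes, mean=3.0, r=5.0)
    shifted = 3.0 * np.exp(planted_ln_fc)
    counts[n_cells_power:, :n_planted] = _nb_counts(
        rng, n_cells_power, n_planted, mean=shifted, r=5.0
    )
    expr = np.log1p(counts / counts.sum(1, keepdims=True) * 1e4)
    degs = find_degs(expr, counts, genes, groups_p, top_n_abundant=n_genes)
    recovered = set(degs["gene"]) & set(genes[:n_planted])
    return {
        "null_zero_deg_replicate_pct": 100.0 * zero / n_replicates,
        "n_planted": n_planted,
        "n_planted_recovered": len(recovered),
    }


def pac_two_blobs(
    n_per_blob: int = 100,
    n_dims: int = 10,
    separation: float = 5.0,
    n_subsamples: int = 100,
    seed: int = 0,
) -> dict:
    """PAC at k=2 vs k=5 on two well-separated Gaussian blobs."""
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [
            rng.normal(0.0, 0.5, size=(n_per_blob, n_dims)),
            rng.normal(separation, 0.5, size=(n_per_blob, n_dims)),
        ]
    )
    pac = pac_stability(X, [2, 5], n_subsamples=n_subsamples, seed=seed)
    return {"pac_k2": float(pac[2]), "pac_k5": float(pac[5])}
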