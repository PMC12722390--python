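import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """Default-structure synthetic experiment at reduced size."""
    from lineaconv.synthetic import SimulationConfig, simulate_dataset

    return simulate_dataset(
        SimulationConfig(n_cells_per_group=120, n_genes=1200, seed=42)
    )


@pytest.fixture(scope="session")
def two_origin_run():
    """Classifier chain outputs on a clean two-origin simulation
    (planted separation ln FC = 1, 70 + 70 anchors)."""
    from lineaconv.classifier import (
        classify_cells,
        select_anchor_cells,
        select_discriminative_genes,
    )
    from lineaconv.evaluation import two_origin_config
    from lineaconv.qc import normalize_counts
    from lineaconv.reporter import quantify_reporter_umis
    from lineaconv.synthetic import simulate_dataset

    ds = simulate_dataset(two_origin_config(marker_ln_fc=1.0, seed=7))
    norm = normalize_counts(ds.adata)
    sub_map = {s: "red" for s in ds.config.red_subtranscripts}
    sub_map |= {s: "green" for s in ds.config.green_subtranscripts}
    rexpr = quantify_reporter_umis(ds.reporter_reads, sub_map).reindex(
        norm.obs_names, fill_value=0
    )
    anchors = select_anchor_cells(rexpr, n_target=70)
    genes = select_discriminative_genes(norm, anchors, seed=7)
    calls = classify_cells(norm, genes, anchors)
    return {
        "dataset": ds,
        "norm": norm,
        "reporter_expr": rexpr,
        "anchors": anchors,
        "genes": genes,
        "calls": calls,
    }
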