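#!/usr/bin/env python
"""Apply the cell-inclusion gate and the non-epithelial density filter.

Gate: depth > 8750 UMIs, 2000-8000 expressed genes, mito% < 15, ribo% < 45;
mito/ribo genes removed afterwards; log-CP10K normalisation; then the
first-local-minimum KDE rule on Col1a2/Pdgfra/Ptprc-like contaminant
markers.  Writes the QC table, kept barcodes and marker thresholds under
results/qc/.
"""

import json
from pathlib import Path

from lineaconv import io as lio
from lineaconv.qc import (
    MarkerFilterConfig,
    apply_qc_filters,
    epithelial_marker_filter,
    normalize_counts,
)

OUT = Path("results/qc")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    adata = lio.read_count_dir("results/simulated/counts")
    marker_sets = adata.var["marker_set"]
    mito = list(adata.var_names[marker_sets == "mito"])
    ribo = list(adata.var_names[marker_sets == "ribo"])
    contaminant = list(adata.var_names[marker_sets == "contaminant"])

    filtered, qc = apply_qc_filters(adata, mito, ribo)
    qc.to_csv(OUT / "cell_qc.csv")
    print(f"inclusion gate: kept {filtered.n_obs}/{adata.n_obs} cells")

    norm = normalize_counts(filtered)
    kept, thresholds = epithelial_marker_filter(
        norm, MarkerFilterConfig(marker_genes=tuple(contaminant))
    )
    (OUT / "marker_thresholds.json").write_text(json.dumps(thresholds, indent=2))
    (OUT / "kept_barcodes.txt").write_text("\n".join(kept.obs_names) + "\n")
    n_removed = norm.n_obs - kept.n_obs
    truth_cont = norm.obs["is_contaminant"].astype(bool)
    removed = set(norm.obs_names) - set(kept.obs_names)
    true_pos = sum(1 for c in removed if truth_cont.get(c, False))
    print(f"marker density filter: removed {n_removed} cells "
          f"({true_pos} planted contaminants of {int(truth_cont.sum())})")
    print(f"thresholds: { {k: round(v, 3) if v else v for k, v in thresholds.items()} }")


if __name__ == "__main__":
    main()
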