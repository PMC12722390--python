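"""Plain-text IO: Matrix Market count matrices with barcode/feature tables
(CellRanger layout), reporter FASTA, read-assignment TSV and metadata CSV."""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reporter import ReporterSequence, SubTranscript

__all__ = [
    "write_count_dir",
    "read_count_dir",
    "read_reporter_fasta",
    "write_reporter_fasta",
    "write_subtranscripts_bed",
    "read_assignments_tsv",
    "write_assignments_tsv",
]


def write_count_dir(adata: ad.AnnData, outdir: str | Path) -> Path:
    """Write counts as matrix.mtx + barcodes.tsv + features.tsv (+ obs CSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(adata.X)
    # CellRanger convention stores genes x cells
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), X.T.astype(int))
    (outdir / "barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n")
    (outdir / "features.tsv").write_text("\n".join(adata.var_names) + "\n")
    if len(adata.obs.columns):
        adata.obs.to_csv(outdir / "cells.csv")
    if len(adata.var.columns):
        adata.var.to_csv(outdir / "genes.csv")
    return outdir


def read_count_dir(indir: str | Path) -> ad.AnnData:
    indir = Path(indir)
    X = sp.csr_matrix(scipy.io.mmread(str(indir / "matrix.mtx")).T)
    barcodes = (indir / "barcodes.tsv").read_text().splitlines()
    features = (indir / "features.tsv").read_text().splitlines()
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=barcodes),
        var=pd.DataFrame(index=features),
    )
    cells_csv = indir / "cells.csv"
    if cells_csv.exists():
        obs = pd.read_csv(cells_csv, index_col=0)
        adata.obs = obs.loc[adata.obs_names]
    genes_csv = indir / "genes.csv"
    if genes_csv.exists():
        var = pd.read_csv(genes_csv, index_col=0, keep_default_na=False)
        adata.var = var.loc[adata.var_names]
    return adata


def read_reporter_fasta(path: str | Path) -> dict[str, ReporterSequence]:
    """Read red/green reporter sequences; record ids must start with the
    marker id ('red' or 'green')."""
    out: dict[str, ReporterSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        marker = "red" if rec.id.lower().startswith("red") else (
            "green" if rec.id.lower().startswith("green") else None
        )
        if marker is None:
            raise ValueError(f"cannot infer marker from record id {rec.id!r}")
        out[marker] = ReporterSequence(marker_id=marker, sequence=str(rec.seq).upper())
    if set(out) != {"red", "green"}:
        raise ValueError("FASTA must contain one red and one green record")
    return out


def write_reporter_fasta(
    path: str | Path, red: ReporterSequence, green: ReporterSequence
) -> None:
    recs = [
        SeqRecord(Seq(red.sequence), id="red", description=""),
        SeqRecord(Seq(green.sequence), id="green", description=""),
    ]
    SeqIO.write(recs, str(path), "fasta")


def write_subtranscripts_bed(
    path: str | Path, subtranscripts: dict[str, list[SubTranscript]]
) -> None:
    """BED-like TSV: marker, start, end, name, max_identity."""
    rows = []
    for marker, subs in subtranscripts.items():
        for st in subs:
            rows.append(
                f"{marker}\t{st.start}\t{st.end}\t{st.name}\t{st.max_cross_identity:.4f}"
            )
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


def read_assignments_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", names=["barcode", "umi", "subtranscript_id"], header=0
    )


def write_assignments_tsv(path: str | Path, assignments: pd.DataFrame) -> None:
    assignments[["barcode", "umi", "subtranscript_id"]].to_csv(
        path, sep="\t", index=False
    )
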