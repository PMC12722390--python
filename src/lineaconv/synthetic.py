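"""Seeded synthetic data emulating the two-origin reporter experiment.

The generator produces UMI count matrices with the statistical structure the
downstream stages assume: two cell origins (a tdTomato-marked "red"
oesophageal epithelium and an EGFP-marked "green" in vitro skin reference
spiked in at a small fraction), planted origin-marker genes with a known
natural-log fold change, a continuum of transitioning cells whose marker
means interpolate log-linearly along a latent pseudotime, mitochondrial and
ribosomal gene fractions, per-cell sequencing-depth variation, dropout,
optional doublets and stromal/immune contaminant cells, plus a per-UMI
reporter read table over sub-transcript segments.

Counts follow a negative binomial with a shared dispersion and a per-cell
size factor; dropout is an extra Bernoulli zeroing after the draw.  All
randomness flows from a single integer seed, so identical configurations
yield bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "GraftCountRecord",
    "simulate_dataset",
    "simulate_graft_counts",
    "simulate_reporter_pair",
]

# sample name -> (origin, timepoint); mirrors the heterotypic culture design:
# oesophagus on its own stroma (oeOE) or on skin dermis (oeSKIN) at day 3 and
# day 10, plus the EGFP in vitro skin reference (sSKIN) spiked into day-10
# libraries.
DEFAULT_SAMPLES: tuple[tuple[str, str, str], ...] = (
    ("oeOE-D3", "red", "D3"),
    ("oeSKIN-D3", "red", "D3"),
    ("oeOE-D10", "red", "D10"),
    ("oeSKIN-D10", "red", "D10"),
    ("sSKIN", "green", "D10"),
)


def _default_marker_sets(n_genes: int) -> dict[str, np.ndarray]:
    """Disjoint gene-index sets planted in the simulated matrix.

    Sizes approximate a mouse 10x run: 13 mitochondrial genes, ~90 ribosomal
    protein genes, a handful of stromal/immune contaminant markers and a few
    dozen identity markers per origin, plus transitioning-cell-specific genes.
    """
    sizes = {
        "red_markers": 30,
        "green_markers": 30,
        "tc_markers": 20,
        "mito": 13,
        "ribo": 90,
        "contaminant": 3,
    }
    if n_genes < sum(sizes.values()):
        raise ValueError(
            f"n_genes={n_genes} smaller than the union of default marker sets"
        )
    out: dict[str, np.ndarray] = {}
    start = 0
    for name, size in sizes.items():
        out[name] = np.arange(start, start + size)
        start += size
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic two-origin experiment.

    ``marker_ln_fc`` is the natural-log fold change separating the two
    origins at the planted identity markers; ``transitioning_fraction`` is
    the fraction of oeSKIN-D10 cells placed strictly between the two
    identities on the latent pseudotime axis.  Depth is a lognormal size
    factor in UMIs; ``nb_dispersion`` is the negative-binomial size
    parameter r (variance m + m^2/r).
    """

    n_cells_per_group: int = 300
    n_genes: int = 4000
    samples: tuple[tuple[str, str, str], ...] = DEFAULT_SAMPLES
    green_spike_fraction: float | None = 0.05
    marker_gene_sets: Mapping[str, np.ndarray] | None = None
    marker_ln_fc: float = 1.0
    tc_ln_fc: float = 1.0
    contaminant_ln_fc: float = 3.9
    contaminant_fraction: float = 0.05
    transitioning_fraction: float = 0.15
    depth_lognormal_params: tuple[float, float] = (np.log(20000.0), 0.35)
    mito_fraction: float = 0.05
    ribo_fraction: float = 0.20
    dropout_rate: float = 0.05
    nb_dispersion: float = 5.0
    doublet_rate: float = 0.01
    reporter_umis_mean: float = 20.0
    reporter_leakage: float = 0.005
    pcr_duplicate_rate: float = 0.2
    red_subtranscripts: tuple[str, ...] = tuple(f"red_sub{i}" for i in range(1, 6))
    green_subtranscripts: tuple[str, ...] = tuple(f"green_sub{i}" for i in range(1, 4))
    seed: int = 0

    def resolved_marker_sets(self) -> dict[str, np.ndarray]:
        if self.marker_gene_sets is None:
            return _default_marker_sets(self.n_genes)
        return {k: np.asarray(v, dtype=int) for k, v in self.marker_gene_sets.items()}

    def validate(self) -> None:
        if self.n_cells_per_group <= 0:
            raise ValueError("n_cells_per_group must be positive")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for name, val in [
            ("transitioning_fraction", self.transitioning_fraction),
            ("dropout_rate", self.dropout_rate),
            ("doublet_rate", self.doublet_rate),
            ("contaminant_fraction", self.contaminant_fraction),
            ("reporter_leakage", self.reporter_leakage),
            ("pcr_duplicate_rate", self.pcr_duplicate_rate),
            ("mito_fraction", self.mito_fraction),
            ("ribo_fraction", self.ribo_fraction),
        ]:
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")
        if self.green_spike_fraction is not None and not (
            0.0 < self.green_spike_fraction < 1.0
        ):
            raise ValueError("green_spike_fraction must lie in (0, 1) or be None")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        sets = self.resolved_marker_sets()
        all_idx = np.concatenate([v for v in sets.values()]) if sets else np.array([])
        if all_idx.size and (all_idx.min() < 0 or all_idx.max() >= self.n_genes):
            raise ValueError("marker gene indices outside [0, n_genes)")
        for special in ("mito", "ribo"):
            if special not in sets:
                continue
            for name, idx in sets.items():
                if name in ("mito", "ribo"):
                    continue
                if np.intersect1d(sets[special], idx).size:
                    raise ValueError(
                        f"marker set {name!r} overlaps the {special!r} set"
                    )
        n_union = np.unique(all_idx).size if all_idx.size else 0
        if self.n_genes < n_union:
            raise ValueError("n_genes smaller than the union of marker sets")


@dataclass
class SyntheticDataset:
    """A simulated experiment: counts + per-cell truth + reporter reads."""

    adata: ad.AnnData
    reporter_reads: pd.DataFrame
    config: SimulationConfig

    @property
    def cells(self) -> pd.DataFrame:
        return self.adata.obs

    @property
    def counts(self) -> sp.csr_matrix:
        return self.adata.X


@dataclass(frozen=True)
class GraftCountRecord:
    """Pooled event counts of one grafting condition."""

    condition: str
    events: int
    cells_grafted: int
    n_grafts: int
    per_graft_events: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.events < 0:
            raise ValueError("events must be non-negative")
        if self.n_grafts < 1:
            raise ValueError("n_grafts must be >= 1")
        if self.cells_grafted < self.n_grafts:
            raise ValueError("cells_grafted must be >= n_grafts")


def _group_sizes(config: SimulationConfig) -> list[tuple[str, str, str, int]]:
    red_total = sum(
        config.n_cells_per_group for _, origin, _ in config.samples if origin == "red"
    )
    out = []
    for sample, origin, timepoint in config.samples:
        n = config.n_cells_per_group
        if origin == "green" and config.green_spike_fraction is not None:
            f = config.green_spike_fraction
            n = max(1, int(round(red_total * f / (1.0 - f))))
        out.append((sample, origin, timepoint, n))
    return out


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw a complete synthetic dataset from ``config``.

    Counts are negative binomial around per-cell expected profiles built
    from a shared lognormal base profile times origin-dependent marker
    effects; transitioning cells interpolate marker means log-linearly in
    their latent pseudotime.  Reporter reads place each cell's UMIs on its
    true origin's sub-transcripts with a small leakage rate.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sets = config.resolved_marker_sets()
    n_genes = config.n_genes

    # --- base expression profile (shared across origins) ------------------
    w = rng.lognormal(mean=0.0, sigma=1.5, size=n_genes)
    # identity markers emulate well-expressed genes (keratins, structural
    # genes), keeping them inside the most-abundant window the DEG stage
    # restricts itself to
    for name in ("red_markers", "green_markers", "tc_markers"):
        if name in sets:
            w[sets[name]] *= 8.0
    special = np.zeros(n_genes, dtype=bool)
    for name in ("mito", "ribo"):
        if name in sets:
            special[sets[name]] = True
    if "contaminant" in sets:
        # stromal/immune markers are essentially silent in epithelial cells;
        # only planted contaminant cells express them (zero-inflated density)
        w[sets["contaminant"]] *= 0.002
    plain = ~special
    plain_share = 1.0 - config.mito_fraction - config.ribo_fraction

    # --- per-cell truth ----------------------------------------------------
    groups = _group_sizes(config)
    obs_rows = []
    cell_counter = 0
    for sample, origin, timepoint, n in groups:
        is_trans = np.zeros(n, dtype=bool)
        t = np.where(origin == "red", 0.0, 1.0) * np.ones(n)
        if origin == "red" and sample == "oeSKIN-D10" and config.transitioning_fraction:
            k = int(round(n * config.transitioning_fraction))
            is_trans[:k] = True
            # strictly inside (0, 1): transitioning cells sit between origins
            t[:k] = rng.uniform(0.02, 0.98, size=k)
        for i in range(n):
            obs_rows.append(
                {
                    "barcode": f"cell{cell_counter:06d}",
                    "sample": sample,
                    "origin": origin,
                    "timepoint": timepoint,
                    "true_origin": origin,
                    "true_branch": sample if timepoint != "D3" else "D3",
                    "true_pseudotime": t[i],
                    "is_transitioning": bool(is_trans[i]),
                    "is_doublet": False,
                    "is_contaminant": False,
                }
            )
            cell_counter += 1
    obs = pd.DataFrame(obs_rows).set_index("barcode")
    n_cells = len(obs)

    # contaminant (fibroblast/immune) cells scattered across samples
    n_cont = int(round(n_cells * config.contaminant_fraction))
    if n_cont:
        cont_idx = rng.choice(n_cells, size=n_cont, replace=False)
        obs.iloc[cont_idx, obs.columns.get_loc("is_contaminant")] = True

    # --- expected profiles per cell ---------------------------------------
    t_all = obs["true_pseudotime"].to_numpy()
    eff = np.ones((n_cells, n_genes))
    if "red_markers" in sets:
        eff[:, sets["red_markers"]] *= np.exp(
            config.marker_ln_fc * (1.0 - t_all)
        )[:, None]
    if "green_markers" in sets:
        eff[:, sets["green_markers"]] *= np.exp(config.marker_ln_fc * t_all)[:, None]
    if "tc_markers" in sets and config.tc_ln_fc:
        # transitioning-exclusive activation: flat bump on the middle third
        bump = ((t_all >= 1.0 / 3.0) & (t_all < 2.0 / 3.0)).astype(float)
        eff[:, sets["tc_markers"]] *= np.exp(config.tc_ln_fc * bump)[:, None]
    if "contaminant" in sets and n_cont:
        cont_mask = obs["is_contaminant"].to_numpy()
        eff[np.ix_(cont_mask, sets["contaminant"])] *= np.exp(config.contaminant_ln_fc)

    # per-cell expected profiles are normalised within blocks: the plain
    # block carries plain_share of the depth (marker effects redistribute
    # mass only inside it), while the mito/ribo blocks carry their
    # configured fractions times a per-cell lognormal jitter (mean 1), which
    # produces realistic QC spreads without biasing the mean content
    shares = np.zeros((n_cells, n_genes))
    wp = w[plain][None, :] * eff[:, plain]
    shares[:, plain] = plain_share * wp / wp.sum(axis=1, keepdims=True)
    for name, sigma, frac in (
        ("mito", 0.5, config.mito_fraction),
        ("ribo", 0.25, config.ribo_fraction),
    ):
        if name in sets:
            idx = sets[name]
            jitter = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_cells)
            shares[:, idx] = (
                frac * jitter[:, None] * (w[idx] / w[idx].sum())[None, :]
            )
    shares /= shares.sum(axis=1, keepdims=True)

    mu_depth, sd_depth = config.depth_lognormal_params
    depths = rng.lognormal(mean=mu_depth, sigma=sd_depth, size=n_cells)
    means = shares * depths[:, None]

    # --- negative binomial draw + dropout ----------------------------------
    r = config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + means))
    if config.dropout_rate:
        keep = rng.random(counts.shape) >= config.dropout_rate
        counts = counts * keep

    # --- doublets: sums of two random cells --------------------------------
    n_doub = int(round(n_cells * config.doublet_rate))
    if n_doub:
        pa = rng.choice(n_cells, size=n_doub, replace=False)
        pb = rng.choice(n_cells, size=n_doub, replace=False)
        doub_counts = counts[pa] + counts[pb]
        doub_rows = []
        for k in range(n_doub):
            a = obs.index[pa[k]]
            row = obs.iloc[pa[k]].to_dict()
            row["barcode"] = f"doublet{k:04d}"
            row["is_doublet"] = True
            doub_rows.append(row)
        doub_obs = pd.DataFrame(doub_rows).set_index("barcode")
        obs = pd.concat([obs, doub_obs])
        counts = np.vstack([counts, doub_counts])

    var = pd.DataFrame(index=[f"g{j:05d}" for j in range(n_genes)])
    var["marker_set"] = ""
    for name, idx in sets.items():
        var.iloc[idx, var.columns.get_loc("marker_set")] = name

    adata = ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.int64)),
        obs=obs,
        var=var,
    )
    adata.uns["truth"] = {"seed": config.seed, "marker_ln_fc": config.marker_ln_fc}

    reporter_reads = _simulate_reporter_reads(rng, adata.obs, config)
    return SyntheticDataset(adata=adata, reporter_reads=reporter_reads, config=config)


def _simulate_reporter_reads(
    rng: np.random.Generator, obs: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Per-UMI reporter assignments with leakage and PCR duplicates."""
    subs = {"red": config.red_subtranscripts, "green": config.green_subtranscripts}
    barcodes, umis, sub_ids = [], [], []
    for barcode, row in obs.iterrows():
        n_umis = rng.poisson(config.reporter_umis_mean)
        own = row["true_origin"]
        other = "green" if own == "red" else "red"
        for k in range(n_umis):
            marker = other if rng.random() < config.reporter_leakage else own
            sub = subs[marker][rng.integers(len(subs[marker]))]
            barcodes.append(barcode)
            umis.append(f"{barcode}-u{k:03d}")
            sub_ids.append(sub)
    df = pd.DataFrame(
        {"barcode": barcodes, "umi": umis, "subtranscript_id": sub_ids}
    )
    if config.pcr_duplicate_rate and len(df):
        n_dup = int(round(len(df) * config.pcr_duplicate_rate))
        dup = df.iloc[rng.integers(0, len(df), size=n_dup)]
        df = pd.concat([df, dup], ignore_index=True)
        df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    return df


def simulate_graft_counts(
    rate_per_cell: float,
    cells_per_graft: int,
    n_grafts: int,
    seed: int,
    condition: str = "simulated",
) -> GraftCountRecord:
    """Poisson event counts for a grafting assay.

    Each graft receives ``cells_per_graft`` donor cells and produces
    ``Poisson(rate_per_cell * cells_per_graft)`` hair-follicle events.
    """
    if rate_per_cell < 0:
        raise ValueError("rate_per_cell must be >= 0")
    if cells_per_graft < 1 or n_grafts < 1:
        raise ValueError("cells_per_graft and n_grafts must be >= 1")
    rng = np.random.default_rng(seed)
    per_graft = rng.poisson(rate_per_cell * cells_per_graft, size=n_grafts)
    return GraftCountRecord(
        condition=condition,
        events=int(per_graft.sum()),
        cells_grafted=int(cells_per_graft) * int(n_grafts),
        n_grafts=int(n_grafts),
        per_graft_events=tuple(int(x) for x in per_graft),
    )


# ---------------------------------------------------------------------------
# synthetic reporter sequences
# ---------------------------------------------------------------------------

def simulate_reporter_pair(
    seed: int = 0,
    backbone_length: int = 600,
    n_red_inserts: int = 5,
    n_green_inserts: int = 3,
    insert_length: int = 150,
) -> tuple[str, str, dict[str, list[tuple[int, int]]]]:
    """Construct a *synthetic* (red, green) reporter coding-sequence pair.

    The pair emulates the architecture of the study's reporters without
    reproducing their deposited sequences: both share a homologous backbone,
    and each carries reporter-specific insertions with no counterpart in the
    other (the real red reporter is a tandem dimer, so roughly half of it has
    no green counterpart).  In a global alignment the insertions sit opposite
    gaps, creating the low-cross-identity stretches that sub-transcript
    selection recovers.  Defaults plant 5 red-specific and 3 green-specific
    regions, mirroring the study's reporter design.

    Returns ``(red_sequence, green_sequence, truth)`` where ``truth`` maps
    marker to the [start, end) coordinates of its planted specific regions.
    """
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    n_slots = n_red_inserts + n_green_inserts
    backbone = rng.integers(0, 4, size=backbone_length)
    # alternate red/green insertion slots along the backbone
    slot_bounds = np.linspace(0, backbone_length, n_slots + 1).astype(int)
    owners = []
    nr = ng = 0
    for i in range(n_slots):
        if (i % 2 == 0 and nr < n_red_inserts) or ng >= n_green_inserts:
            owners.append("red"); nr += 1
        else:
            owners.append("green"); ng += 1
    red_parts: list[np.ndarray] = []
    green_parts: list[np.ndarray] = []
    truth: dict[str, list[tuple[int, int]]] = {"red": [], "green": []}
    red_pos = green_pos = 0
    for i, owner in enumerate(owners):
        seg = backbone[slot_bounds[i] : slot_bounds[i + 1]]
        red_parts.append(seg)
        green_parts.append(seg)
        red_pos += len(seg)
        green_pos += len(seg)
        insert = rng.integers(0, 4, size=insert_length)
        if owner == "red":
            red_parts.append(insert)
            truth["red"].append((red_pos, red_pos + insert_length))
            red_pos += insert_length
        else:
            green_parts.append(insert)
            truth["green"].append((green_pos, green_pos + insert_length))
            green_pos += insert_length
    red = np.concatenate(red_parts)
    green = np.concatenate(green_parts)
    return "".join(alphabet[red]), "".join(alphabet[green]), truth
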