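"""Branch assignment, differential expression, expression patterns,
pseudotime trisection, curve smoothing and PAC clustering stability.

The trajectory stage works on basal cells ordered along a fate-conversion
pseudotime running from oesophageal identity (start) to skin identity
(endpoint).  Clusters are assigned to experimental branches by a strict
>75% composition rule; differential expression uses a two-sided Wilcoxon
rank-sum test with Bonferroni correction restricted to the most abundant
genes; per-gene group-mean profiles are affinely scaled to [0, 100] and
hierarchically clustered with a 1 - Pearson distance into expression
patterns; the pseudotime axis is trisected into equal-length Oesophagus /
Transitioning-Cell / Skin intervals; curves are smoothed with a penalised
B-spline (GCV-selected penalty) with a pointwise 95% band; and clustering
stability is scored with the proportion of ambiguous clustering (PAC) of a
subsampled consensus matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "BranchAssignment",
    "ExpressionPattern",
    "StateGroups",
    "SmoothedCurve",
    "assign_branches",
    "find_degs",
    "extract_patterns",
    "trisect_and_select_tc_genes",
    "smooth_along_pseudotime",
    "pac_stability",
]


@dataclass(frozen=True)
class BranchAssignment:
    cluster_branch: dict
    cell_branch: pd.Series
    split_clusters: tuple


@dataclass(frozen=True)
class ExpressionPattern:
    pattern_id: int
    genes: tuple[str, ...]
    profiles: pd.DataFrame  # genes x groups, scaled to [0, 100]


@dataclass(frozen=True)
class StateGroups:
    """Trisection of the pseudotime range into Oesophagus / TC / Skin."""

    groups: pd.Series
    boundaries: tuple[float, float]


@dataclass(frozen=True)
class SmoothedCurve:
    grid: np.ndarray
    fit: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    alpha: float


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def assign_branches(
    clusters: pd.Series, origins: pd.Series, threshold: float = 0.75
) -> BranchAssignment:
    """Assign each cluster to a sample-origin branch by strict majority.

    A cluster joins a branch when more than ``threshold`` of its cells share
    that sample origin; otherwise the cluster is split and each of its cells
    follows its own origin.
    """
    clusters = clusters.astype(str)
    origins = origins.astype(str)
    if not clusters.index.equals(origins.index):
        raise ValueError("clusters and origins must be indexed by the same cells")
    cluster_branch: dict = {}
    split: list = []
    cell_branch = pd.Series(index=clusters.index, dtype=object)
    for cl, members in clusters.groupby(clusters).groups.items():
        if len(members) == 0:
            warnings.warn(f"cluster {cl} is empty; skipped", stacklevel=2)
            continue
        comp = origins.loc[members].value_counts(normalize=True)
        if comp.iloc[0] > threshold:
            cluster_branch[cl] = comp.index[0]
            cell_branch.loc[members] = comp.index[0]
        else:
            cluster_branch[cl] = "split"
            split.append(cl)
            cell_branch.loc[members] = origins.loc[members]
    return BranchAssignment(
        cluster_branch=cluster_branch,
        cell_branch=cell_branch,
        split_clusters=tuple(split),
    )


def _ln_fold_change(
    xa: np.ndarray, xb: np.ndarray, pseudocount: float = 1e-9
) -> np.ndarray:
    """Natural-log fold change of de-logged group means of normalised
    expression (single-cell convention)."""
    ma = np.expm1(xa).mean(axis=0)
    mb = np.expm1(xb).mean(axis=0)
    return np.log(ma + pseudocount) - np.log(mb + pseudocount)


def find_degs(
    expr: np.ndarray | sp.spmatrix,
    counts: np.ndarray | sp.spmatrix,
    gene_names,
    groups: pd.Series | np.ndarray,
    top_n_abundant: int = 1000,
    ln_fc_min: float = 0.25,
    p_adj_max: float = 0.01,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum DEGs over the most abundant genes.

    Genes are ranked by total raw counts and the top ``top_n_abundant``
    tested.  Per pair of groups a two-sided rank-sum test per gene is
    Bonferroni-corrected over the tested genes; records are kept when
    ``|ln_fc| >= ln_fc_min`` and ``p_adj < p_adj_max``.  Returns the union
    over pairs with per-pair provenance.
    """
    groups = pd.Series(np.asarray(groups), name="group")
    labels = groups.unique()
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = groups.value_counts()
    if (sizes < min_cells).any():
        small = sizes[sizes < min_cells].index.tolist()
        raise ValueError(f"groups below {min_cells} cells: {small}")

    expr = _dense(expr)
    total = np.asarray(
        counts.sum(axis=0) if sp.issparse(counts) else np.asarray(counts).sum(axis=0)
    ).ravel()
    gene_names = np.asarray(gene_names)
    top = np.sort(np.argsort(-total, kind="stable")[:top_n_abundant])
    E = expr[:, top]
    names = gene_names[top]
    n_tested = len(top)

    records = []
    for i, ga in enumerate(labels):
        for gb in labels[i + 1 :]:
            A = E[np.asarray(groups == ga)]
            B = E[np.asarray(groups == gb)]
            with np.errstate(invalid="ignore", divide="ignore"):
                p = stats.mannwhitneyu(A, B, axis=0).pvalue
            p = np.where(np.isnan(p), 1.0, p)
            p_adj = np.minimum(p * n_tested, 1.0)  # Bonferroni
            lfc = _ln_fold_change(A, B)
            keep = (np.abs(lfc) >= ln_fc_min) & (p_adj < p_adj_max)
            for j in np.flatnonzero(keep):
                records.append(
                    {
                        "gene": names[j],
                        "pair": f"{ga}|{gb}",
                        "ln_fc": lfc[j],
                        "p": p[j],
                        "p_adj": p_adj[j],
                    }
                )
    return pd.DataFrame.from_records(
        records, columns=["gene", "pair", "ln_fc", "p", "p_adj"]
    )


def scale_profiles(
    expr: np.ndarray | sp.spmatrix,
    gene_names,
    genes,
    groups: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """Per-gene group means affinely mapped to [0, 100] (min -> 0,
    max -> 100); constant-profile genes map to all-0."""
    groups = pd.Series(np.asarray(groups))
    labels = list(pd.unique(groups))
    gene_names = list(gene_names)
    idx = [gene_names.index(g) for g in genes]
    E = _dense(expr)[:, idx]
    means = np.vstack(
        [E[np.asarray(groups == g)].mean(axis=0) for g in labels]
    ).T  # genes x groups
    lo = means.min(axis=1, keepdims=True)
    hi = means.max(axis=1, keepdims=True)
    rng = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(rng > 0, 100.0 * (means - lo) / rng, 0.0)
    return pd.DataFrame(scaled, index=list(genes), columns=labels)


def extract_patterns(
    genes,
    expr: np.ndarray | sp.spmatrix,
    gene_names,
    groups: pd.Series | np.ndarray,
    k_patterns: int,
    linkage_method: str = "average",
    pattern_map: dict[int, int] | None = None,
) -> list[ExpressionPattern]:
    """Cluster scaled group profiles into expression patterns.

    Profiles are clustered hierarchically with 1 - Pearson correlation and
    the tree cut into ``k_patterns`` clusters; constant-profile genes are
    collected in a degenerate pattern 0.  ``pattern_map`` optionally merges
    fine clusters into named coarse patterns.
    """
    groups = pd.Series(np.asarray(groups))
    if groups.nunique() < 2:
        raise ValueError("need at least 2 groups to shape a profile")
    genes = list(genes)
    profiles = scale_profiles(expr, gene_names, genes, groups)
    const = (profiles.max(axis=1) - profiles.min(axis=1)) == 0
    patterns: list[ExpressionPattern] = []
    if const.any():
        patterns.append(
            ExpressionPattern(
                pattern_id=0,
                genes=tuple(profiles.index[const]),
                profiles=profiles.loc[const],
            )
        )
    live = profiles.loc[~const]
    if len(live):
        if len(live) == 1:
            assign = np.array([1])
        else:
            Z = linkage(live.to_numpy(), method=linkage_method, metric="correlation")
            assign = fcluster(Z, t=min(k_patterns, len(live)), criterion="maxclust")
        if pattern_map:
            assign = np.array([pattern_map.get(a, a) for a in assign])
        for pid in sorted(set(assign)):
            mask = assign == pid
            patterns.append(
                ExpressionPattern(
                    pattern_id=int(pid),
                    genes=tuple(live.index[mask]),
                    profiles=live.loc[mask],
                )
            )
    return patterns


def trisect_pseudotime(pseudotime: pd.Series) -> StateGroups:
    """Split the pseudotime range into three equal-length intervals:
    Oesophagus (start), Transitioning Cells, Skin (endpoint)."""
    t = pd.Series(pseudotime, dtype=float)
    if not np.isfinite(t).all():
        raise ValueError("pseudotime must be finite")
    lo, hi = float(t.min()), float(t.max())
    if lo == hi:
        raise ValueError("all cells share one pseudotime value")
    b1 = lo + (hi - lo) / 3.0
    b2 = lo + 2.0 * (hi - lo) / 3.0
    labels = np.where(t < b1, "Oesophagus", np.where(t < b2, "TC", "Skin"))
    return StateGroups(groups=pd.Series(labels, index=t.index), boundaries=(b1, b2))


def trisect_and_select_tc_genes(
    pseudotime: pd.Series,
    expr: np.ndarray | sp.spmatrix,
    counts: np.ndarray | sp.spmatrix,
    gene_names,
    ln_fc_min: float = 0.2,
    deg_kwargs: dict | None = None,
) -> tuple[StateGroups, pd.DataFrame, tuple[str, ...]]:
    """Trisect pseudotime, call DEGs among the three state groups, and keep
    the genes with ``|ln_fc| > ln_fc_min`` between Oesophagus and TC (the
    transition-exclusive set).

    Returns ``(state_groups, deg_table, tc_exclusive_genes)``.
    """
    states = trisect_pseudotime(pseudotime)
    degs = find_degs(expr, counts, gene_names, states.groups, **(deg_kwargs or {}))
    if degs.empty:
        return states, degs, ()
    union_genes = list(pd.unique(degs["gene"]))
    gene_names_l = list(gene_names)
    idx = [gene_names_l.index(g) for g in union_genes]
    E = _dense(expr)[:, idx]
    oe = np.asarray(states.groups == "Oesophagus")
    tc = np.asarray(states.groups == "TC")
    lfc = _ln_fold_change(E[oe], E[tc])
    exclusive = tuple(
        g for g, f in zip(union_genes, lfc) if abs(f) > ln_fc_min
    )
    return states, degs, exclusive


def smooth_along_pseudotime(
    expression: np.ndarray,
    pseudotime: np.ndarray,
    df: int = 10,
    n_grid: int = 100,
    alphas: np.ndarray | None = None,
) -> SmoothedCurve:
    """Penalised B-spline fit of one gene's expression on pseudotime.

    The smoothing penalty is chosen from a log-spaced grid by generalised
    cross-validation; penalties whose fit degenerates (perfect separation on
    noiseless data) are skipped.  Returns the fit and a pointwise 95%
    confidence band on a regular grid.
    """
    y = np.asarray(expression, dtype=float)
    t = np.asarray(pseudotime, dtype=float)
    if y.size != t.size:
        raise ValueError("expression and pseudotime must have equal length")
    if y.size < 10:
        raise ValueError("need at least 10 cells to smooth")
    if np.ptp(t) == 0:
        raise ValueError("constant pseudotime")
    df = min(df, max(4, y.size // 3))
    basis = BSplines(t, df=[df], degree=[3], include_intercept=True)
    n = y.size
    if alphas is None:
        alphas = np.logspace(-6, 6, 13)
    best = None
    for a in alphas:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = GLMGam(y, smoother=basis, alpha=float(a)).fit()
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
            continue
        edf = float(np.sum(res.edf))
        rss = float(np.sum((y - res.predict()) ** 2))
        gcv = n * rss / max(n - edf, 1e-8) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, float(a), res)
    if best is None:
        raise RuntimeError("no smoothing penalty produced a valid fit")
    _, alpha, res = best
    grid = np.linspace(t.min(), t.max(), n_grid)
    Xg = basis.transform(grid[:, None])
    fit = Xg @ res.params
    se = np.sqrt(np.einsum("ij,jk,ik->i", Xg, res.cov_params(), Xg))
    z = stats.norm.ppf(0.975)
    return SmoothedCurve(grid=grid, fit=fit, lo=fit - z * se, hi=fit + z * se, alpha=alpha)


def consensus_matrix(
    X: np.ndarray,
    k: int,
    n_subsamples: int = 100,
    subsample_frac: float = 0.8,
    seed: int = 0,
    n_pcs: int = 50,
) -> np.ndarray:
    """Consensus co-clustering matrix from seeded k-means subsampling.

    Entry (i, j) is the fraction of subsamples containing both i and j in
    which they landed in the same k-means cluster; NaN where a pair was
    never co-sampled.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    m = int(round(n * subsample_frac))
    if k > m:
        raise ValueError("k exceeds the subsample size")
    if m < 2:
        raise ValueError("subsample too small")
    if X.shape[1] > n_pcs:
        X = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)
    rng = np.random.default_rng(seed)
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    for b in range(n_subsamples):
        idx = rng.choice(n, size=m, replace=False)
        km = KMeans(n_clusters=k, random_state=int(rng.integers(2**31)), n_init=10)
        lab = km.fit_predict(X[idx])
        sampled[np.ix_(idx, idx)] += 1
        same = lab[:, None] == lab[None, :]
        together[np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore", divide="ignore"):
        cons = together / sampled
    return cons


def pac_from_consensus(
    cons: np.ndarray, u1: float = 0.1, u2: float = 0.9
) -> float:
    """Proportion of ambiguous clustering: CDF(u2) - CDF(u1) of the
    off-diagonal consensus values."""
    n = cons.shape[0]
    off = cons[~np.eye(n, dtype=bool)]
    off = off[~np.isnan(off)]
    if off.size == 0:
        return 0.0
    return float(np.mean(off <= u2) - np.mean(off <= u1))


def pac_stability(
    X: np.ndarray,
    k_range,
    n_subsamples: int = 100,
    subsample_frac: float = 0.8,
    u1: float = 0.1,
    u2: float = 0.9,
    seed: int = 0,
    n_pcs: int = 50,
) -> pd.Series:
    """PAC score per candidate cluster number k (lower = more stable)."""
    scores = {}
    for k in k_range:
        cons = consensus_matrix(
            X,
            k,
            n_subsamples=n_subsamples,
            subsample_frac=subsample_frac,
            seed=seed,
            n_pcs=n_pcs,
        )
        scores[k] = pac_from_consensus(cons, u1=u1, u2=u2)
    return pd.Series(scores, name="PAC")


def fallback_pseudotime(
    expr: np.ndarray | sp.spmatrix,
    endpoint_mask: np.ndarray,
    gene_subset: np.ndarray | None = None,
) -> np.ndarray:
    """Order cells by correlation to the mean profile of a designated
    endpoint group (reference identity fixed at the trajectory end).

    A simple stand-in for graph-based trajectory inference: pseudotime is
    the min-max-rescaled correlation of each cell to the endpoint centroid.
    """
    E = _dense(expr)
    if gene_subset is not None:
        E = E[:, gene_subset]
    centroid = E[np.asarray(endpoint_mask, dtype=bool)].mean(axis=0)
    Ec = E - E.mean(axis=1, keepdims=True)
    cc = centroid - centroid.mean()
    denom = np.sqrt((Ec**2).sum(axis=1) * (cc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Ec @ cc) / denom
    corr = np.nan_to_num(corr, nan=0.0)
    lo, hi = corr.min(), corr.max()
    return (corr - lo) / (hi - lo) if hi > lo else np.zeros_like(corr)
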