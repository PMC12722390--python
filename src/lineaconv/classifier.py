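"""Semi-supervised tdTomato/EGFP origin classifier.

Training anchors are cells with high, *independent* reporter expression
(own-marker UMIs > 0, other-marker UMIs == 0).  Discriminative genes come
from two routes: (A) the top genes by random-forest Gini importance and
(B) genes significant in Welch's t-test, the two-sample Kolmogorov-Smirnov
test and the Mann-Whitney U test after Benjamini-Hochberg correction; the
final set is the intersection.  Each unlabelled cell's distances (1 minus
correlation over the final gene set) to the two anchor sets are compared by
the minimum-IQR rule: the cell takes the label of the closer distribution
only when the gap between proximal quartiles exceeds the average of the two
standard deviations; otherwise it is "unknown".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnchorSet",
    "DiscriminativeGeneSet",
    "LabelCall",
    "select_anchor_cells",
    "select_discriminative_genes",
    "min_iqr_decision",
    "classify_cells",
]


@dataclass(frozen=True)
class AnchorSet:
    red_anchors: tuple[str, ...]
    green_anchors: tuple[str, ...]
    n_target: int = 70

    def __post_init__(self) -> None:
        if set(self.red_anchors) & set(self.green_anchors):
            raise ValueError("anchor sets must be disjoint")


@dataclass(frozen=True)
class DiscriminativeGeneSet:
    rf_top: tuple[str, ...]
    test_selected: tuple[str, ...]

    @property
    def final(self) -> tuple[str, ...]:
        sel = set(self.test_selected)
        return tuple(g for g in self.rf_top if g in sel)


@dataclass(frozen=True)
class LabelCall:
    barcode: str
    label: str  # red | green | unknown
    q1_red: float
    q1_green: float
    sd_red: float
    sd_green: float
    method: str = "pearson"


def select_anchor_cells(
    reporter_expr: pd.DataFrame,
    n_target: int = 70,
    max_other_umis: int = 0,
) -> AnchorSet:
    """Pick up to ``n_target`` anchors per marker with independent reporter
    expression.

    Eligible cells have own-marker UMIs > 0 and other-marker UMIs <=
    ``max_other_umis`` (0 = strict independence).  Ranking is by own-marker
    UMIs descending, barcode ascending for ties.
    """
    anchors: dict[str, tuple[str, ...]] = {}
    for own, other in (("red_umis", "green_umis"), ("green_umis", "red_umis")):
        eligible = reporter_expr[
            (reporter_expr[own] > 0) & (reporter_expr[other] <= max_other_umis)
        ]
        if eligible.empty:
            raise ValueError(
                f"no cells with independent {own.split('_')[0]} reporter expression"
            )
        ranked = eligible.assign(_bc=eligible.index).sort_values(
            by=[own, "_bc"], ascending=[False, True]
        )
        if len(ranked) < n_target:
            warnings.warn(
                f"only {len(ranked)} eligible {own.split('_')[0]} anchors "
                f"(target {n_target})",
                stacklevel=2,
            )
        anchors[own.split("_")[0]] = tuple(ranked.index[:n_target])
    return AnchorSet(
        red_anchors=anchors["red"], green_anchors=anchors["green"], n_target=n_target
    )


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def select_discriminative_genes(
    adata: ad.AnnData,
    anchors: AnchorSet,
    n_rf_genes: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
    n_trees: int = 500,
) -> DiscriminativeGeneSet:
    """Dual-route discriminative gene selection on anchor expression.

    Route A ranks genes by random-forest Gini importance (fixed seed) and
    keeps the top ``n_rf_genes``.  Route B runs Welch's t, two-sample KS and
    Mann-Whitney U per gene between the two anchor classes, corrects each
    test family with Benjamini-Hochberg, and keeps genes with adjusted
    p < ``alpha`` in all three.  Constant-in-both-classes genes are skipped
    by the tests but remain eligible for the forest.
    """
    red = list(anchors.red_anchors)
    green = list(anchors.green_anchors)
    if len(red) < 2 or len(green) < 2:
        raise ValueError("need at least 2 anchors per class")
    sub = adata[red + green]
    X = _dense(sub.X)
    y = np.array([1] * len(red) + [0] * len(green))
    genes = np.asarray(sub.var_names)

    rf = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    ).fit(X, y)
    imp = rf.feature_importances_
    order = np.lexsort((np.arange(len(genes)), -imp))
    rf_top = tuple(genes[order[:n_rf_genes]])

    Xr, Xg = X[y == 1], X[y == 0]
    constant = (np.ptp(Xr, axis=0) == 0) & (np.ptp(Xg, axis=0) == 0)
    testable = ~constant
    pvals = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        pvals["t"] = stats.ttest_ind(
            Xr[:, testable], Xg[:, testable], axis=0, equal_var=False
        ).pvalue
        pvals["mwu"] = stats.mannwhitneyu(
            Xr[:, testable], Xg[:, testable], axis=0
        ).pvalue
        pvals["ks"] = np.array(
            [
                stats.ks_2samp(Xr[:, j], Xg[:, j]).pvalue
                for j in np.flatnonzero(testable)
            ]
        )
    passed = np.ones(testable.sum(), dtype=bool)
    for fam, p in pvals.items():
        p = np.where(np.isnan(p), 1.0, p)
        rej, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
        passed &= rej
    test_selected = tuple(genes[np.flatnonzero(testable)[passed]])
    return DiscriminativeGeneSet(rf_top=rf_top, test_selected=test_selected)


def min_iqr_decision(
    d_red: np.ndarray, d_green: np.ndarray
) -> tuple[str, float, float, float, float]:
    """Label a cell from its two anchor-distance distributions.

    q1 is the 25th percentile (linear interpolation); the decision gap must
    exceed the mean of the two sample (n-1) standard deviations.  Returns
    ``(label, q1_red, q1_green, sd_red, sd_green)``.
    """
    d_red = np.asarray(d_red, dtype=float)
    d_green = np.asarray(d_green, dtype=float)
    if d_red.size < 2 or d_green.size < 2:
        raise ValueError("need at least 2 distances per anchor set")
    q1_red = float(np.percentile(d_red, 25))
    q1_green = float(np.percentile(d_green, 25))
    sd_red = float(np.std(d_red, ddof=1))
    sd_green = float(np.std(d_green, ddof=1))
    s = 0.5 * (sd_red + sd_green)
    gap = abs(q1_red - q1_green)
    if gap > s and q1_red != q1_green:
        label = "red" if q1_red < q1_green else "green"
    else:
        label = "unknown"
    return label, q1_red, q1_green, sd_red, sd_green


def _rowwise_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of A against each row of B.

    Zero-variance rows yield NaN correlations.
    """
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((A**2).sum(axis=1))
    sb = np.sqrt((B**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (A @ B.T) / np.outer(sa, sb)
    corr[sa == 0, :] = np.nan
    corr[:, sb == 0] = np.nan
    return corr


def _rank_rows(X: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, X)


def classify_cells(
    adata: ad.AnnData,
    genes: DiscriminativeGeneSet,
    anchors: AnchorSet,
    cells: list[str] | None = None,
) -> pd.DataFrame:
    """Label cells by correlation distance to the anchor sets.

    Distance = 1 - correlation over the final discriminative gene set,
    computed on per-gene standardised expression (anchor-pool mean/SD).
    Standardising removes the abundance profile shared by every cell, which
    otherwise dominates the correlation and masks the class signal.  The
    minimum-IQR decision is applied per method (Pearson and Spearman); the
    reported label is the Pearson call, with ``concordant`` flagging
    Spearman agreement.  Cells with zero raw variance over the gene set are
    "unknown".
    """
    final = list(genes.final)
    if not final:
        raise ValueError("empty final discriminative gene set")
    if cells is None:
        anchor_set = set(anchors.red_anchors) | set(anchors.green_anchors)
        cells = [c for c in adata.obs_names if c not in anchor_set]

    Xc = _dense(adata[cells, final].X)
    Ar = _dense(adata[list(anchors.red_anchors), final].X)
    Ag = _dense(adata[list(anchors.green_anchors), final].X)

    degenerate = np.ptp(Xc, axis=1) == 0  # flat raw profile -> unknown
    pool = np.vstack([Ar, Ag])
    mu, sd = pool.mean(axis=0), pool.std(axis=0)
    sd[sd == 0] = 1.0
    Xc = (Xc - mu) / sd
    Ar = (Ar - mu) / sd
    Ag = (Ag - mu) / sd

    results = {}
    for method in ("pearson", "spearman"):
        if method == "spearman":
            Xm, Arm, Agm = _rank_rows(Xc), _rank_rows(Ar), _rank_rows(Ag)
        else:
            Xm, Arm, Agm = Xc, Ar, Ag
        d_red = 1.0 - _rowwise_corr(Xm, Arm)
        d_green = 1.0 - _rowwise_corr(Xm, Agm)
        rows = []
        for i, bc in enumerate(cells):
            if degenerate[i] or np.isnan(d_red[i]).all() or np.isnan(d_green[i]).all():
                rows.append(("unknown", np.nan, np.nan, np.nan, np.nan))
                continue
            label, q1r, q1g, sdr, sdg = min_iqr_decision(d_red[i], d_green[i])
            rows.append((label, q1r, q1g, sdr, sdg))
        results[method] = rows

    out = pd.DataFrame(
        results["pearson"],
        columns=["label", "q1_red", "q1_green", "sd_red", "sd_green"],
        index=pd.Index(cells, name="barcode"),
    )
    out["spearman_label"] = [r[0] for r in results["spearman"]]
    out["concordant"] = out["label"] == out["spearman_label"]
    return out
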