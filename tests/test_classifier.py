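"""Anchor selection, dual-route gene selection and the minimum-IQR rule."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lineaconv.classifier import (
    AnchorSet,
    classify_cells,
    min_iqr_decision,
    select_anchor_cells,
    select_discriminative_genes,
)


def _reporter_df(red, green, barcodes=None):
    idx = barcodes or [f"c{i}" for i in range(len(red))]
    return pd.DataFrame(
        {"red_umis": red, "green_umis": green},
        index=pd.Index(idx, name="barcode"),
    )


class TestAnchorSelection:
    def test_top_independent_cells_selected(self):
        rng = np.random.default_rng(0)
        red = list(rng.integers(1, 100, 100)) + [0] * 100
        green = [0] * 100 + list(rng.integers(1, 100, 100))
        df = _reporter_df(red, green)
        anchors = select_anchor_cells(df, n_target=70)
        assert len(anchors.red_anchors) == 70
        assert len(anchors.green_anchors) == 70
        top_red = df[df.green_umis == 0].nlargest(70, "red_umis")["red_umis"].min()
        assert all(df.loc[a, "red_umis"] >= top_red for a in anchors.red_anchors)

    def test_no_independent_cells_rejected(self):
        df = _reporter_df([5, 3], [2, 4])
        with pytest.raises(ValueError, match="independent"):
            select_anchor_cells(df)

    def test_fewer_than_target_warns(self):
        df = _reporter_df([5] * 10 + [0] * 10, [0] * 10 + [5] * 10)
        with pytest.warns(UserWarning, match="eligible"):
            anchors = select_anchor_cells(df, n_target=70)
        assert len(anchors.red_anchors) == 10

    def test_anchors_exclude_leaky_cells(self, two_origin_run):
        """With 0.5% reporter leakage, anchors come only from cells with
        zero cross-marker UMIs."""
        rexpr = two_origin_run["reporter_expr"]
        anchors = two_origin_run["anchors"]
        assert (rexpr.loc[list(anchors.red_anchors), "green_umis"] == 0).all()
        assert (rexpr.loc[list(anchors.green_anchors), "red_umis"] == 0).all()

    def test_overlapping_anchor_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            AnchorSet(red_anchors=("a", "b"), green_anchors=("b", "c"))


def _anchor_adata(Xr, Xg, n_extra=0, rng=None):
    X = np.vstack([Xr, Xg])
    names = [f"r{i}" for i in range(len(Xr))] + [f"g{i}" for i in range(len(Xg))]
    if n_extra:
        X = np.vstack([X, rng.normal(size=(n_extra, X.shape[1]))])
        names += [f"x{i}" for i in range(n_extra)]
    return ad.AnnData(
        X=X.astype(float),
        obs=pd.DataFrame(index=names),
        var=pd.DataFrame(index=[f"gene{j}" for j in range(X.shape[1])]),
    ), AnchorSet(
        red_anchors=tuple(f"r{i}" for i in range(len(Xr))),
        green_anchors=tuple(f"g{i}" for i in range(len(Xg))),
    )


class TestGeneSelection:
    def test_null_distributions_select_nothing(self):
        """Identical anchor classes (70 + 70, 500 genes): BH at 0.05 keeps
        the final set empty in the vast majority of seeded runs."""
        empty = 0
        runs = 5
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            adata, anchors = _anchor_adata(
                rng.normal(size=(70, 500)), rng.normal(size=(70, 500))
            )
            gs = select_discriminative_genes(adata, anchors, seed=seed)
            empty += int(len(gs.final) == 0)
        assert empty >= runs - 1

    def test_planted_genes_recovered(self):
        rng = np.random.default_rng(3)
        Xr = rng.normal(size=(70, 500))
        Xg = rng.normal(size=(70, 500))
        Xr[:, :10] += 2.0  # planted separation
        adata, anchors = _anchor_adata(Xr, Xg)
        gs = select_discriminative_genes(adata, anchors, seed=0)
        planted = {f"gene{j}" for j in range(10)}
        assert planted <= set(gs.final)
        assert len(gs.rf_top) <= 50

    def test_constant_genes_skipped_by_tests(self):
        rng = np.random.default_rng(4)
        Xr = rng.normal(size=(10, 20))
        Xg = rng.normal(size=(10, 20))
        Xr[:, 0] = Xg[:, 0] = 1.0  # constant in both classes
        adata, anchors = _anchor_adata(Xr, Xg)
        gs = select_discriminative_genes(adata, anchors, seed=0)
        assert "gene0" not in gs.test_selected

    def test_determinism(self):
        rng = np.random.default_rng(5)
        adata, anchors = _anchor_adata(
            rng.normal(size=(20, 100)) + 0.5, rng.normal(size=(20, 100))
        )
        a = select_discriminative_genes(adata, anchors, seed=1)
        b = select_discriminative_genes(adata, anchors, seed=1)
        assert a == b

    def test_too_few_anchors_rejected(self):
        rng = np.random.default_rng(6)
        adata, anchors = _anchor_adata(rng.normal(size=(1, 10)),
                                       rng.normal(size=(5, 10)))
        with pytest.raises(ValueError, match="2 anchors"):
            select_discriminative_genes(adata, anchors)


def _oracle_min_iqr(d_red, d_green):
    """Brute-force percentile (linear interpolation between closest ranks)
    and sample-SD re-implementation, independent of numpy shortcuts."""
    def q1(v):
        v = sorted(v)
        h = (len(v) - 1) * 0.25
        lo = int(np.floor(h))
        hi = min(lo + 1, len(v) - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    def sd(v):
        m = sum(v) / len(v)
        return (sum((x - m) ** 2 for x in v) / (len(v) - 1)) ** 0.5

    qr, qg = q1(d_red), q1(d_green)
    s = 0.5 * (sd(d_red) + sd(d_green))
    if abs(qr - qg) > s and qr != qg:
        return "red" if qr < qg else "green"
    return "unknown"


class TestMinIQR:
    def test_degenerate_separation(self):
        label, qr, qg, sr, sg = min_iqr_decision([0, 0, 0, 0], [1, 1, 1, 1])
        assert label == "red" and (qr, qg) == (0, 1) and sr == sg == 0

    def test_identical_distributions_unknown(self):
        label, *_ = min_iqr_decision([0.3, 0.5, 0.7], [0.3, 0.5, 0.7])
        assert label == "unknown"

    def test_hand_computed_example(self):
        label, qr, qg, sr, sg = min_iqr_decision(
            [0.1, 0.2, 0.3, 0.4], [0.5, 0.6, 0.7, 0.8]
        )
        assert label == "red"
        assert qr == pytest.approx(0.175)
        assert qg == pytest.approx(0.575)
        assert sr == pytest.approx(0.12909944, abs=1e-7)
        assert sg == pytest.approx(0.12909944, abs=1e-7)

    def test_too_few_distances_rejected(self):
        with pytest.raises(ValueError):
            min_iqr_decision([0.1], [0.2, 0.3])

    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d_red = rng.uniform(0, 2, rng.integers(2, 30))
        d_green = rng.uniform(0, 2, rng.integers(2, 30))
        label, *_ = min_iqr_decision(d_red, d_green)
        assert label == _oracle_min_iqr(list(d_red), list(d_green))

    def test_swap_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = rng.uniform(0, 1, 8)
            b = rng.uniform(0, 1, 8)
            l1, *_ = min_iqr_decision(a, b)
            l2, *_ = min_iqr_decision(b, a)
            swap = {"red": "green", "green": "red", "unknown": "unknown"}
            assert l2 == swap[l1]


class TestClassifyCells:
    def test_cell_equal_to_anchor_labelled_red(self):
        # class signal mixes red-up and green-up genes, as marker sets do
        rng = np.random.default_rng(7)
        Xr = rng.normal(0, 1, size=(10, 30))
        Xg = rng.normal(0, 1, size=(10, 30))
        Xr[:, :15] += 2.0
        Xg[:, 15:] += 2.0
        adata, anchors = _anchor_adata(Xr, Xg)
        copy = ad.AnnData(
            X=np.vstack([adata.X, Xr[:1]]),
            obs=pd.DataFrame(index=list(adata.obs_names) + ["probe"]),
            var=adata.var.copy(),
        )
        gs = select_discriminative_genes(adata, anchors, seed=0)
        calls = classify_cells(copy, gs, anchors, cells=["probe"])
        assert calls.loc["probe", "label"] == "red"

    def test_constant_cell_unknown(self):
        rng = np.random.default_rng(8)
        Xr = rng.normal(size=(10, 30))
        Xg = rng.normal(size=(10, 30))
        Xr[:, :15] += 2.0
        Xg[:, 15:] += 2.0
        adata, anchors = _anchor_adata(Xr, Xg)
        flat = ad.AnnData(
            X=np.vstack([adata.X, np.full((1, 30), 2.0)]),
            obs=pd.DataFrame(index=list(adata.obs_names) + ["flat"]),
            var=adata.var.copy(),
        )
        gs = select_discriminative_genes(adata, anchors, seed=0)
        calls = classify_cells(flat, gs, anchors, cells=["flat"])
        assert calls.loc["flat", "label"] == "unknown"

    def test_empty_gene_set_rejected(self, two_origin_run):
        from lineaconv.classifier import DiscriminativeGeneSet

        empty = DiscriminativeGeneSet(rf_top=("a",), test_selected=())
        with pytest.raises(ValueError, match="empty"):
            classify_cells(
                two_origin_run["norm"], empty, two_origin_run["anchors"]
            )

    def test_pure_origin_recovery_on_simulation(self, two_origin_run):
        calls = two_origin_run["calls"]
        truth = two_origin_run["norm"].obs.loc[calls.index, "true_origin"]
        assert (calls["label"] == truth).mean() >= 0.95
        assert (calls["label"] == "unknown").mean() <= 0.05

    def test_label_swap_symmetry_on_simulation(self, two_origin_run):
        """Swapping the red/green anchor sets swaps the labels and leaves
        unknown calls fixed."""
        anchors = two_origin_run["anchors"]
        swapped = AnchorSet(
            red_anchors=anchors.green_anchors,
            green_anchors=anchors.red_anchors,
        )
        norm = two_origin_run["norm"]
        genes = two_origin_run["genes"]
        cells = list(two_origin_run["calls"].index[:200])
        orig = classify_cells(norm, genes, anchors, cells=cells)
        flip = classify_cells(norm, genes, swapped, cells=cells)
        swap = {"red": "green", "green": "red", "unknown": "unknown"}
        assert (flip["label"] == orig["label"].map(swap)).all()
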