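"""CCF arithmetic, binomial-mixture clone clustering, tree enumeration."""

import numpy as np
import pandas as pd
import pytest

import mcltools as m
from mcltools import clonal as C
from conftest import oracle_valid_trees


class TestComputeCcf:
    @pytest.mark.parametrize(
        "vaf,purity,cn,mult,expected",
        [
            (0.25, 1.0, 2, 1, 0.5),
            (0.5, 1.0, 2, 1, 1.0),
            (0.25, 0.5, 2, 1, 1.0),  # 0.25 * 2 / 0.5, clipped at 1
        ],
    )
    def test_closed_forms(self, vaf, purity, cn, mult, expected):
        assert m.compute_ccf(vaf, purity, cn, mult) == pytest.approx(expected)

    def test_zero_purity_rejected(self):
        with pytest.raises(ValueError, match="purity"):
            m.compute_ccf(0.2, 0.0)

    def test_vaf_above_one_rejected(self):
        with pytest.raises(ValueError, match="vaf"):
            m.compute_ccf(1.2, 0.5)

    def test_monotone_in_vaf_and_purity(self):
        vafs = np.linspace(0.01, 0.3, 20)
        ccfs = m.compute_ccf(vafs, 0.8)
        assert (np.diff(ccfs) >= 0).all()
        purities = np.linspace(0.3, 1.0, 20)
        ccfs_p = np.array([m.compute_ccf(0.1, p) for p in purities])
        assert (np.diff(ccfs_p) <= 1e-12).all()

    def test_missing_vaf_gives_missing_ccf(self):
        out = m.compute_ccf(np.array([0.2, np.nan]), 0.8)
        assert np.isnan(out[1]) and not np.isnan(out[0])


def simulate_clusters(ccfs, n_per=50, depth=100, purity=0.8, seed=0):
    """Planted clone clusters: returns (alt, depth) variant x sample tables."""
    rng = np.random.default_rng(seed)
    samples = [f"S{i+1}" for i in range(len(ccfs[0]))]
    rows_a, rows_d, index = [], [], []
    for ci, ccf in enumerate(ccfs):
        for v in range(n_per):
            d = rng.poisson(depth, len(samples)).clip(min=1)
            p = [purity * c / 2.0 for c in ccf]
            a = rng.binomial(d, p)
            rows_a.append(a)
            rows_d.append(d)
            index.append(f"cl{ci}_v{v}")
    alt = pd.DataFrame(rows_a, index=index, columns=samples)
    dep = pd.DataFrame(rows_d, index=index, columns=samples)
    return alt, dep, {s: purity for s in samples}


class TestClusterCcf:
    def test_two_planted_clusters_recovered(self):
        alt, dep, pur = simulate_clusters([(1.0, 1.0), (0.6, 0.1)])
        res = m.cluster_ccf(alt, dep, pur, k_max=5, seed=0)
        assert res.k == 2
        # match recovered to planted by nearest mean CCF
        planted = np.array([[1.0, 1.0], [0.6, 0.1]])
        err = []
        for cl in res.clusters:
            d = np.abs(planted - cl.ccf.to_numpy()).mean(axis=1)
            err.append(d.min())
        assert np.mean(err) <= 0.05

    def test_single_planted_cluster_selects_k1(self):
        alt, dep, pur = simulate_clusters([(0.8, 0.8)], n_per=60, seed=1)
        res = m.cluster_ccf(alt, dep, pur, k_max=4, seed=1)
        assert res.k == 1

    def test_same_seed_identical_assignment(self):
        alt, dep, pur = simulate_clusters([(1.0, 1.0), (0.4, 0.2)], seed=2)
        r1 = m.cluster_ccf(alt, dep, pur, seed=5)
        r2 = m.cluster_ccf(alt, dep, pur, seed=5)
        assert (r1.assignments == r2.assignments).all()

    def test_em_loglik_nondecreasing(self):
        alt, dep, pur = simulate_clusters([(1.0, 1.0), (0.5, 0.3)], seed=3)
        res = m.cluster_ccf(alt, dep, pur, seed=3)
        diffs = np.diff(res.ll_path)
        assert (diffs >= -1e-6).all()

    def test_fewer_than_two_variants_rejected(self):
        alt = pd.DataFrame({"S1": [10]}, index=["v1"])
        dep = pd.DataFrame({"S1": [100]}, index=["v1"])
        with pytest.raises(ValueError, match="2 variants"):
            m.cluster_ccf(alt, dep, {"S1": 0.8})


def ccf_frame(rows, samples=("S1",)):
    return pd.DataFrame(rows, columns=list(samples))


class TestEnumerateTrees:
    def test_chain_and_sibling_both_valid_sibling_first(self):
        ccf = pd.DataFrame({"S1": [1.0, 0.6, 0.3]}, index=["a", "b", "c"])
        enum = m.enumerate_trees(ccf, epsilon=0.05)
        parent_maps = [t.parents for t in enum.trees]
        sibling = {"a": None, "b": "a", "c": "a"}
        chain = {"a": None, "b": "a", "c": "b"}
        assert sibling in parent_maps and chain in parent_maps
        assert enum.trees[0].parents == sibling  # smaller residual slack

    def test_equal_children_exceeding_root_forces_nesting(self):
        ccf = pd.DataFrame({"S1": [1.0, 0.6, 0.6]}, index=["a", "b", "c"])
        enum = m.enumerate_trees(ccf, epsilon=0.05)
        for t in enum.trees:
            kids_of_a = [c for c, p in t.parents.items() if p == "a"]
            assert len(kids_of_a) == 1  # sibling topology (1.2 > 1.05) invalid

    def test_matches_prufer_brute_force_oracle(self):
        """Exhaustive agreement with an independent all-labeled-trees oracle
        on random 4-6 cluster instances."""
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = int(rng.integers(4, 7))
            vals = np.sort(rng.random((n, 2)), axis=0)[::-1]
            ccf = pd.DataFrame(vals, columns=["S1", "S2"],
                               index=[f"c{i}" for i in range(n)])
            founder = ccf["S1"].idxmax()
            enum = m.enumerate_trees(ccf, epsilon=0.05, founder=founder)
            got = sorted(
                tuple(sorted((str(c), str(p)) for c, p in t.parents.items()))
                for t in enum.trees
            )
            want = sorted(
                tuple(sorted((str(c), str(p)) for c, p in parents.items()))
                for parents in oracle_valid_trees(ccf, 0.05, founder)
            )
            assert got == want, f"trial {trial}"

    def test_planted_tree_uniquely_recovered(self, variant_tables, default_cfg):
        """Full path: cascade output -> CCF clustering -> tree enumeration
        recovers exactly the planted 4-clone topology."""
        from mcltools import variants as V

        vt = variant_tables
        cfg = default_cfg
        cs = V.consensus_calls(vt["calls"])
        cs = V.germline_panel_filter(cs, vt["panel"], n_panel_samples=10)
        cs = V.annotate_genes(cs, m.build_gene_panel(cfg))
        cs = V.gene_level_filters(cs, m.build_gene_panel(cfg))
        keys = cs.keys()
        pile = vt["pileup"]
        alt = pile.pivot_table(index=V.KEY_COLS, columns="sample",
                               values="alt_depth")
        dep = pile.pivot_table(index=V.KEY_COLS, columns="sample",
                               values="depth")
        mask = [k in keys for k in alt.index]
        res = m.cluster_ccf(alt[mask], dep[mask], cfg.purity, k_max=6, seed=0)
        assert res.k == 4
        enum = m.enumerate_trees(
            res.ccf_matrix, epsilon=0.05,
            sizes=pd.Series({c.cluster_id: c.size for c in res.clusters}),
        )
        assert len(enum.trees) == 1
        # map recovered clusters to planted clones by nearest CCF profile
        planted = pd.DataFrame(cfg.clone_tree.ccf)  # clones x samples
        mapping = {}
        for cid, row in res.ccf_matrix.iterrows():
            dist = (planted[sorted(planted.columns)] - row[sorted(planted.columns)]
                    ).abs().mean(axis=1)
            mapping[cid] = dist.idxmin()
        got = {mapping[c]: (None if p is None else mapping[p])
               for c, p in enum.trees[0].parents.items()}
        assert got == cfg.clone_tree.parents

    def test_no_valid_tree_reports_violations(self):
        # siblings break the sum rule; either nesting breaks the crossing
        # rule in one of the two samples
        ccf = pd.DataFrame(
            {"S1": [0.30, 0.29, 0.20], "S2": [0.30, 0.20, 0.29]},
            index=["a", "b", "c"],
        )
        enum = m.enumerate_trees(ccf, epsilon=0.01, founder="a")
        assert enum.trees == []
        assert len(enum.violations) > 0


class TestFishplot:
    def test_single_clone_constant_band(self):
        ccf = pd.DataFrame({"T1": [1.0], "T2": [1.0], "T3": [1.0]}, index=["a"])
        tree = C.CloneTree({"a": None}, ccf, 0.0)
        out = m.export_fishplot(tree)
        assert list(out[["T1", "T2", "T3"]].iloc[0]) == [1.0, 1.0, 1.0]

    def test_vanishing_clone_band_terminates(self):
        ccf = pd.DataFrame({"T1": [1.0, 0.5], "T2": [1.0, 0.0]},
                           index=["a", "b"])
        tree = C.CloneTree({"a": None, "b": "a"}, ccf, 0.0)
        out = m.export_fishplot(tree).set_index("clone")
        assert out.loc["b", "T2"] == 0.0

    def test_inconsistent_fractions_rejected(self):
        ccf = pd.DataFrame({"T1": [0.5, 0.9]}, index=["a", "b"])
        tree = C.CloneTree({"a": None, "b": "a"}, ccf, 0.0)
        with pytest.raises(ValueError, match="inconsistent"):
            m.export_fishplot(tree)

    def test_newick_export(self):
        ccf = pd.DataFrame({"T1": [1.0, 0.5, 0.2]}, index=["a", "b", "c"])
        tree = C.CloneTree({"a": None, "b": "a", "c": "b"}, ccf, 0.0)
        assert tree.newick() == "((c)b)a;"
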