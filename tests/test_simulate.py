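"""The synthetic generator must plant exactly the structure it promises."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mcltools as m
from mcltools.io import matrix_bytes
from mcltools.simulate import _assign_cells, germline_ighv


def small_cfg(seed=0, **kw):
    base = dict(
        n_samples=1, sample_ids=["S1"], n_cells=400, n_genes=400,
        n_chromosomes=4,
        mixture={"malignantB": 0.5, "normalB": 0.5, "T": 0.0, "NK": 0.0,
                 "myeloid": 0.0},
        clonotypes=[
            m.ClonotypeSpec(
                clonotype_id="ct1", heavy_v="IGHV3-21", heavy_j="IGHJ4",
                heavy_cdr3_aa="CARDLRGYFDYW", light_v="IGKV4-1",
                light_j="IGKJ1", light_cdr3_aa="CQQYYSTPRTF",
                light_chain="kappa", shm_count=2, fractions={"S1": 1.0},
            )
        ],
        qc_noise=m.QcNoiseSpec(0.0, 0.0, 0.0),
        seed=seed,
    )
    base.update(kw)
    return m.SimulationConfig(**base)


class TestConfigValidation:
    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            small_cfg(mixture={"malignantB": 0.5, "normalB": 0.4, "T": 0.0,
                               "NK": 0.0, "myeloid": 0.0})

    def test_ccnd1_fold_below_one_rejected(self):
        with pytest.raises(ValueError, match="ccnd1_fold"):
            small_cfg(ccnd1_fold=0.5)

    def test_cnv_segment_longer_than_panel_rejected(self):
        with pytest.raises(ValueError):
            small_cfg(cnv_segments=[m.CnvSegmentSpec("chr1", 0, 999, 2.0)])

    def test_sum_rule_violation_rejected(self):
        tree = m.CloneTreeSpec(
            parents={"a": None, "b": "a", "c": "a"},
            ccf={"S1": {"a": 0.8, "b": 0.6, "c": 0.5}},
        )
        with pytest.raises(ValueError, match="sum rule"):
            small_cfg(clone_tree=tree)

    def test_empty_clone_tree_rejected_for_variants(self):
        cfg = small_cfg()
        with pytest.raises(ValueError, match="clone_tree"):
            m.generate_variant_tables(cfg)


class TestExpression:
    def test_same_seed_identical_matrices(self):
        a1, _ = m.generate_expression(small_cfg(seed=7))
        a2, _ = m.generate_expression(small_cfg(seed=7))
        assert matrix_bytes(a1) == matrix_bytes(a2)

    def test_null_config_ccnd1_exchangeable(self):
        """ccnd1_fold=1 and no CNV: malignant and normal B indistinguishable
        on CCND1 (rank test non-significant at alpha=0.01 over 20 seeds)."""
        rejections = 0
        for seed in range(20):
            cfg = small_cfg(seed=seed, ccnd1_fold=1.0, n_cells=200, n_genes=200)
            adata, truth = m.generate_expression(cfg)
            x = np.asarray(adata[:, "CCND1"].X.todense()).ravel()
            mal = truth.cells["cell_type"] == "malignantB"
            p = stats.ranksums(x[mal.to_numpy()], x[(~mal).to_numpy()]).pvalue
            rejections += p < 0.01
        assert rejections <= 2

    def test_planted_gain_ratio_recovered(self):
        cfg = small_cfg(
            n_cells=800,
            cnv_segments=[m.CnvSegmentSpec("chr2", 0, 60, 2.0)],
        )
        adata, truth = m.generate_expression(cfg)
        genes = truth.cnv_genes["gene"].unique()
        idx = [adata.var_names.get_loc(g) for g in genes]
        X = np.asarray(adata.X.todense())
        mal = (truth.cells["cell_type"] == "malignantB").to_numpy()
        ratio = X[mal][:, idx].sum() / max(X[~mal][:, idx].sum(), 1)
        # normalize by cell counts
        ratio *= (~mal).sum() / mal.sum()
        assert 1.8 <= ratio <= 2.2

    def test_ccnd1_fold_applied(self):
        cfg = small_cfg(n_cells=800, ccnd1_fold=4.0)
        adata, truth = m.generate_expression(cfg)
        x = np.asarray(adata[:, "CCND1"].X.todense()).ravel()
        mal = (truth.cells["cell_type"] == "malignantB").to_numpy()
        assert 3.0 <= x[mal].mean() / x[~mal].mean() <= 5.0

    def test_qc_failing_cells_planted_at_configured_fractions(self):
        cfg = small_cfg(qc_noise=m.QcNoiseSpec(0.05, 0.05, 0.05))
        _, truth = m.generate_expression(cfg)
        counts = truth.cells["qc_class"].value_counts()
        for cls in ("low_gene", "high_mito", "doublet"):
            assert counts[cls] == 20

    def test_counts_nonnegative_integers(self):
        adata, _ = m.generate_expression(small_cfg())
        X = adata.X
        assert (X.data >= 0).all()
        assert np.issubdtype(X.dtype, np.integer)

    def test_nb_moments_match_configuration(self):
        """Mean/variance of a high-expression gene follow the configured
        gamma-Poisson within Monte-Carlo tolerance (n_cells >= 500)."""
        cfg = small_cfg(
            n_cells=4000, nb_dispersion=5.0,
            mixture={"malignantB": 0.0, "normalB": 1.0, "T": 0.0, "NK": 0.0,
                     "myeloid": 0.0},
            clonotypes=[],
        )
        adata, _ = m.generate_expression(cfg)
        x = np.asarray(adata[:, "IGKC"].X.todense()).ravel()
        # kappa cells only (60% of normal B): restrict to high-mean group
        kappa = x > 5
        mu = x[kappa].mean()
        var = x[kappa].var()
        # size-factor lognormal(0, 0.15) adds ~2.3% CV^2 on top of NB
        expected = mu + mu**2 * (1 / 5.0 + np.expm1(0.15**2))
        assert abs(var / expected - 1) < 0.25


class TestBcr:
    def test_clonotype_fraction_binomial(self):
        cfg = small_cfg(
            n_cells=1000,
            mixture={"malignantB": 0.34, "normalB": 0.66, "T": 0.0, "NK": 0.0,
                     "myeloid": 0.0},
            bcr_capture=1.0,
        )
        cells = _assign_cells(cfg)
        n = (cells["clonotype_id"] == "ct1").sum()
        # 340 +/- ~4 binomial SDs (sd ~ 15)
        assert abs(n - 340) < 60
        tab = m.generate_bcr(cfg, cells)
        carriers = tab[tab["cdr3_aa"] == "CARDLRGYFDYW"]["cell_id"].nunique()
        assert abs(carriers - n) <= 0.1 * n  # 3% unpaired/nonproductive noise

    def test_zero_shm_sequence_identical_to_germline(self):
        cfg = small_cfg()
        cfg.clonotypes[0].shm_count = 0
        tab = m.generate_bcr(cfg)
        heavy = tab[(tab["locus"] == "IGH") & (tab["cdr3_aa"] == "CARDLRGYFDYW")]
        assert (heavy["sequence"] == germline_ighv("IGHV3-21")).all()

    def test_planted_shm_count_exact(self):
        cfg = small_cfg()
        tab = m.generate_bcr(cfg)
        heavy = tab[(tab["locus"] == "IGH") & (tab["cdr3_aa"] == "CARDLRGYFDYW")]
        seq = heavy["sequence"].iloc[0]
        count, _ = m.count_shm(seq, germline_ighv("IGHV3-21"))
        assert count == 2

    def test_background_clonotypes_pairwise_distinct(self):
        cfg = small_cfg(
            mixture={"malignantB": 0.0, "normalB": 1.0, "T": 0.0, "NK": 0.0,
                     "myeloid": 0.0},
            clonotypes=[],
        )
        tab = m.generate_bcr(cfg)
        heavy = tab[tab["locus"] == "IGH"]
        assert heavy["cdr3_aa"].is_unique

    def test_shm_exceeding_length_rejected(self):
        cfg = small_cfg()
        cfg.clonotypes[0].shm_count = 400
        with pytest.raises(ValueError, match="SHM count exceeds"):
            m.generate_bcr(cfg)

    def test_same_seed_identical_tables(self):
        cfg = small_cfg(seed=3)
        t1 = m.generate_bcr(cfg)
        t2 = m.generate_bcr(small_cfg(seed=3))
        pd.testing.assert_frame_equal(t1, t2)


class TestVariants:
    def test_perfect_callers_reproduce_truth(self, default_cfg):
        cfg = m.default_config(
            seed=5,
            caller_profiles=[m.CallerProfile(f"c{i}", 1.0, 0.0) for i in range(3)],
            n_panel_artifacts=0,
        )
        vt = m.generate_variant_tables(cfg)
        calls, truth = vt["calls"], vt["truth"]
        for caller in ("c0", "c1", "c2"):
            sub = calls[calls["caller"] == caller]
            for sample in cfg.sample_ids:
                got = set(map(tuple, sub[sub["sample"] == sample][
                    ["chrom", "pos", "ref", "alt"]].itertuples(index=False)))
                expected = set()
                for _, v in truth.iterrows():
                    # detectable iff >= 2 alt reads drawn for that sample
                    pass
                # every call must be a true variant (no FPs at rate 0)
                truth_keys = set(map(tuple, truth[
                    ["chrom", "pos", "ref", "alt"]].itertuples(index=False)))
                assert got <= truth_keys

    def test_clonal_vaf_expectation(self):
        """Clonal variant, purity 0.5, CN 2, multiplicity 1 -> mean VAF 0.25."""
        assert m.expected_vaf(1.0, 0.5) == pytest.approx(0.25)
        cfg = m.default_config(seed=9, purity={"S1": 0.5, "S2": 0.5, "S3": 0.5})
        vt = m.generate_variant_tables(cfg)
        truth = vt["truth"]
        clonal = truth[truth["clone"] == "c1"]
        pile = vt["pileup"].merge(
            clonal[["chrom", "pos", "ref", "alt"]], on=["chrom", "pos", "ref", "alt"]
        )
        vafs = pile["alt_depth"] / pile["depth"]
        assert abs(vafs.mean() - 0.25) < 0.02

    def test_panel_artifacts_flagged_in_panel(self, variant_tables):
        truth = variant_tables["truth"]
        panel = variant_tables["panel"]
        artifacts = truth[truth["category"] == "panel_artifact"]
        for _, v in artifacts.iterrows():
            hits = panel[
                (panel["chrom"] == v["chrom"]) & (panel["pos"] == v["pos"])
            ]["panel_sample"].nunique()
            assert hits == 4  # present in 4/10 germline samples

    def test_same_seed_identical_tables(self):
        cfg1 = m.default_config(seed=11)
        cfg2 = m.default_config(seed=11)
        v1, v2 = m.generate_variant_tables(cfg1), m.generate_variant_tables(cfg2)
        for key in ("calls", "panel", "pileup", "wgs_segments", "truth"):
            pd.testing.assert_frame_equal(v1[key], v2[key])


class TestGroundTruth:
    def test_truth_roundtrips_through_json(self, tmp_path, cohort):
        _, truth = cohort
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = m.GroundTruth.from_json(path)
        assert list(back.cells.index) == list(truth.cells.index)
        assert (back.cells["cell_type"] == truth.cells["cell_type"]).all()
        assert back.clone_tree.parents == truth.clone_tree.parents

    def test_every_cell_appears_exactly_once(self, cohort):
        adata, truth = cohort
        assert truth.cells.index.is_unique
        assert set(adata.obs_names) == set(truth.cells.index)
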