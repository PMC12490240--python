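"""Consensus rule, panel/gene filters, paired rescue, replayable trail."""

import numpy as np
import pandas as pd
import pytest

import mcltools as m
from mcltools import variants as V


def call_row(sample="S1", chrom="chr1", pos=100, ref="A", alt="T",
             caller="c1", vaf=0.3, depth=100):
    return dict(sample=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
                caller=caller, vaf=vaf, depth=depth)


class TestConsensus:
    def test_two_of_five_callers_retained(self):
        calls = pd.DataFrame(
            [call_row(caller=f"c{i}") for i in range(2)]
            + [call_row(pos=200, caller="c0")]
        )
        cs = V.consensus_calls(calls)
        assert len(cs.variants) == 1
        assert cs.variants.iloc[0]["pos"] == 100
        assert cs.variants.iloc[0]["n_callers"] == 2

    def test_single_caller_dropped(self):
        cs = V.consensus_calls(pd.DataFrame([call_row()]))
        assert len(cs.variants) == 0
        assert cs.trail[0]["n_before"] == 1

    def test_empty_tables(self):
        cs = V.consensus_calls(pd.DataFrame(
            columns=["sample", "chrom", "pos", "ref", "alt", "caller",
                     "vaf", "depth"]))
        assert len(cs.variants) == 0

    def test_duplicate_caller_rows_deduplicated(self):
        calls = pd.DataFrame([call_row(), call_row(), call_row(caller="c2")])
        with pytest.warns(UserWarning, match="dedup"):
            cs = V.consensus_calls(calls)
        assert cs.variants.iloc[0]["n_callers"] == 2


def make_cs(positions, sample="S1"):
    calls = pd.DataFrame(
        [call_row(sample=sample, pos=p, caller=c)
         for p in positions for c in ("c1", "c2")]
    )
    return V.consensus_calls(calls)


def panel_rows(pos, samples, vaf=0.1):
    return [dict(panel_sample=s, chrom="chr1", pos=pos, ref="A", alt="T",
                 vaf=vaf, depth=100) for s in samples]


class TestPanelFilter:
    def test_four_of_ten_dropped(self):
        cs = make_cs([100])
        panel = pd.DataFrame(panel_rows(100, [f"P{i}" for i in range(4)]))
        out = V.germline_panel_filter(cs, panel, n_panel_samples=10)
        assert len(out.variants) == 0

    def test_two_of_ten_kept(self):
        cs = make_cs([100])
        panel = pd.DataFrame(panel_rows(100, ["P1", "P2"]))
        out = V.germline_panel_filter(cs, panel, n_panel_samples=10)
        assert len(out.variants) == 1

    def test_exactly_three_of_ten_dropped_by_default_but_kept_strict(self):
        """The parenthetical 3/10 reading drops at exactly 30%; strict mode
        requires > 30%."""
        cs = make_cs([100])
        panel = pd.DataFrame(panel_rows(100, ["P1", "P2", "P3"]))
        default = V.germline_panel_filter(cs, panel, n_panel_samples=10)
        strict = V.germline_panel_filter(cs, panel, n_panel_samples=10,
                                         strict=True)
        assert len(default.variants) == 0
        assert len(strict.variants) == 1

    def test_empty_panel_leaves_set_unchanged(self):
        cs = make_cs([100])
        with pytest.warns(UserWarning, match="panel"):
            out = V.germline_panel_filter(cs, pd.DataFrame(
                columns=["panel_sample", "chrom", "pos", "ref", "alt",
                         "vaf", "depth"]))
        assert len(out.variants) == 1

    def test_zero_vaf_panel_rows_do_not_count(self):
        cs = make_cs([100])
        panel = pd.DataFrame(panel_rows(100, [f"P{i}" for i in range(5)], vaf=0.0))
        out = V.germline_panel_filter(cs, panel, n_panel_samples=10)
        assert len(out.variants) == 1


def pileup_row(sample, pos, depth, alt_depth):
    return dict(sample=sample, chrom="chr1", pos=pos, ref="A", alt="T",
                depth=depth, alt_depth=alt_depth)


class TestRescuePaired:
    def make_pair_cs(self, pos=100, sample="S2"):
        return make_cs([pos], sample=sample)

    def test_low_partner_coverage_unassessable(self):
        cs = self.make_pair_cs()  # relapse-only variant in S2
        pile = pd.DataFrame([pileup_row("S1", 100, 2, 0)])
        out = V.rescue_paired(cs, pile, ("S1", "S2"))
        assert out.variants.iloc[0]["status_S1_S2"] == "unassessable"

    def test_clean_partner_confirms_specific(self):
        cs = self.make_pair_cs()
        pile = pd.DataFrame([pileup_row("S1", 100, 30, 0)])
        out = V.rescue_paired(cs, pile, ("S1", "S2"))
        assert out.variants.iloc[0]["status_S1_S2"] == "S2_specific"

    def test_partner_alt_reads_relabel_shared(self):
        cs = self.make_pair_cs()
        pile = pd.DataFrame([pileup_row("S1", 100, 30, 4)])
        out = V.rescue_paired(cs, pile, ("S1", "S2"))
        assert out.variants.iloc[0]["status_S1_S2"] == "shared"

    def test_missing_pileup_unassessable_not_dropped(self):
        cs = self.make_pair_cs()
        pile = pd.DataFrame([pileup_row("S1", 999, 30, 0)])
        out = V.rescue_paired(cs, pile, ("S1", "S2"))
        assert len(out.variants) == 1
        assert out.variants.iloc[0]["status_S1_S2"] == "unassessable"

    def test_never_adds_variant_keys(self, variant_tables):
        cs = V.consensus_calls(variant_tables["calls"])
        out = V.rescue_paired(cs, variant_tables["pileup"], ("S1", "S2"))
        assert out.keys() == cs.keys()
        assert len(out.variants) == len(cs.variants)


class TestGeneFilters:
    def annotation(self):
        return pd.DataFrame(
            {
                "gdi": {"NOISY": 2500.0, "ATM": 2500.0, "OK": 100.0,
                        "SILENT": 100.0},
                "fpkm": {"NOISY": 5.0, "ATM": 5.0, "OK": 5.0, "SILENT": 0.4},
            }
        )

    def cs_with_genes(self, genes):
        calls = pd.DataFrame(
            [dict(call_row(pos=100 + i, caller=c)) for i, _ in enumerate(genes)
             for c in ("c1", "c2")]
        )
        cs = V.consensus_calls(calls)
        cs.variants["gene"] = list(genes)
        return cs

    def test_high_gdi_dropped_atm_exempt(self):
        cs = self.cs_with_genes(["NOISY", "ATM", "OK"])
        out = V.gene_level_filters(cs, self.annotation())
        assert set(out.variants["gene"]) == {"ATM", "OK"}

    def test_fpkm_boundary_strict(self):
        ann = self.annotation()
        ann.loc["EDGE"] = {"gdi": 100.0, "fpkm": 0.5}
        cs = self.cs_with_genes(["SILENT", "EDGE"])
        out = V.gene_level_filters(cs, ann)
        assert set(out.variants["gene"]) == {"EDGE"}  # 0.5 kept, 0.4 dropped

    def test_unannotated_gene_kept_and_flagged(self):
        cs = self.cs_with_genes(["MYSTERY"])
        out = V.gene_level_filters(cs, self.annotation())
        assert len(out.variants) == 1
        assert bool(out.variants.iloc[0]["unannotated"])


class TestRecurrence:
    def test_two_patients_reportable(self):
        rep = V.recurrence_annotation({"p1": {"TP53"}, "p2": {"TP53"}}, ["ATM"])
        assert "TP53" in rep

    def test_single_patient_known_gene_reportable(self):
        rep = V.recurrence_annotation({"p1": {"CCND1"}}, ["CCND1"])
        assert "CCND1" in rep

    def test_single_patient_unknown_gene_excluded(self):
        rep = V.recurrence_annotation({"p1": {"RANDO"}}, ["CCND1"])
        assert "RANDO" not in rep

    def test_empty_known_list_warns(self):
        with pytest.warns(UserWarning, match="known-gene"):
            rep = V.recurrence_annotation({"p1": {"G1"}, "p2": {"G1"}}, [])
        assert rep == {"G1"}


class TestCnvSegments:
    def seg(self, cn, chrom="chr1", start=1, end=100):
        return dict(chrom=chrom, start=start, end=end, copy_number=cn)

    def test_threshold_inclusivity(self):
        out = m.classify_cnv_segments(pd.DataFrame(
            [self.seg(2.3), self.seg(1.7), self.seg(2.0)]))
        assert list(out["class"]) == ["amplified", "deleted", "neutral"]

    def test_ig_locus_segments_removed(self):
        segs = pd.DataFrame([self.seg(4.0, chrom="chr14", start=100, end=200),
                             self.seg(4.0, chrom="chr5")])
        ig = pd.DataFrame([dict(chrom="chr14", start=150, end=400)])
        out = m.classify_cnv_segments(segs, ig)
        assert list(out["chrom"]) == ["chr5"]

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError, match="[Ii]nverted"):
            m.classify_cnv_segments(pd.DataFrame(
                [self.seg(2.0, start=100, end=50)]))

    def test_negative_copy_number_rejected(self):
        with pytest.raises(ValueError):
            m.classify_cnv_segments(pd.DataFrame([self.seg(-1.0)]))


class TestCascade:
    def run_cascade(self, vt, cfg):
        panel_genes = m.build_gene_panel(cfg)
        cs = V.consensus_calls(vt["calls"])
        cs = V.germline_panel_filter(cs, vt["panel"],
                                     n_panel_samples=cfg.n_panel_samples)
        cs = V.annotate_genes(cs, panel_genes)
        cs = V.gene_level_filters(cs, panel_genes)
        cs = V.rescue_paired(cs, vt["pileup"], ("S1", "S2"))
        return cs

    def test_precision_recall_on_planted_truth(self, variant_tables, default_cfg):
        cs = self.run_cascade(variant_tables, default_cfg)
        truth = variant_tables["truth"]
        true_keys = set(map(tuple, truth.loc[
            truth["category"] == "true", V.KEY_COLS].itertuples(index=False)))
        out_keys = cs.keys()
        tp = len(out_keys & true_keys)
        assert tp / len(out_keys) >= 0.9  # precision
        assert tp / len(true_keys) >= 0.9  # recall

    def test_output_is_subset_of_input_at_every_stage(self, variant_tables,
                                                      default_cfg):
        cs = self.run_cascade(variant_tables, default_cfg)
        sizes = [r["n_after"] for r in cs.trail if r["dropped"] is not None]
        befores = [r["n_before"] for r in cs.trail]
        assert all(a <= b for a, b in zip(sizes, befores))

    def test_trail_is_replayable(self, variant_tables, default_cfg):
        cs = self.run_cascade(variant_tables, default_cfg)
        initial = V.consensus_calls(variant_tables["calls"], min_callers=1).variants
        replayed = V.replay_trail(initial, cs.trail)
        got = set(map(tuple, replayed[["sample"] + V.KEY_COLS]
                      .itertuples(index=False)))
        want = set(map(tuple, cs.variants[["sample"] + V.KEY_COLS]
                       .itertuples(index=False)))
        assert got == want
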