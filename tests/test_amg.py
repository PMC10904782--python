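"""Boundary trimming, AMG curation rules, MM exclusivity, habitat tallies."""

import pandas as pd
import pytest

from vamp.amg import (
    AmgCall,
    GeneAnnotation,
    PathwayMap,
    classify_mm,
    curate_amg,
    curate_contig,
    habitat_association,
    load_default_pathway_map,
    trim_host_boundary,
)


def mk_genes(categories, contig="ctg", ko=None, pfam=None, amg_ko="K00577", amg_pfam="PF09472"):
    """Gene list from a category layout; 'AMG' marks the candidate."""
    genes = []
    pos = 1
    for i, cat in enumerate(categories, start=1):
        if cat == "AMG":
            genes.append(
                GeneAnnotation(contig, i, pos, pos + 299, "+", "amg_candidate", amg_ko, amg_pfam)
            )
        else:
            genes.append(GeneAnnotation(contig, i, pos, pos + 299, "+", cat))
        pos += 300
    return genes


@pytest.fixture(scope="module")
def pmap():
    return load_default_pathway_map()


class TestTrimHostBoundary:
    def test_pure_phage_contig_untrimmed(self):
        genes = mk_genes(["phage", "hallmark", "phage", "phage"])
        trim = trim_host_boundary(genes)
        assert trim.trimmed_left == 0 and trim.trimmed_right == 0
        assert trim.kept_start == 1 and trim.kept_end == 4

    def test_four_leading_cellular_genes_trimmed(self):
        genes = mk_genes(["cellular"] * 4 + ["phage"] * 6)
        trim = trim_host_boundary(genes)
        assert trim.trimmed_left == 4 and trim.trimmed_right == 0
        assert trim.kept_start == 5

    def test_short_terminal_run_kept(self):
        genes = mk_genes(["cellular", "cellular"] + ["phage"] * 6)
        trim = trim_host_boundary(genes, min_run=3)
        assert trim.trimmed_left == 0

    def test_right_end_trimming(self):
        genes = mk_genes(["phage"] * 6 + ["cellular"] * 3)
        trim = trim_host_boundary(genes)
        assert trim.trimmed_right == 3 and trim.kept_end == 6

    def test_hallmark_blocks_trimming(self):
        genes = mk_genes(["cellular", "hallmark", "cellular", "cellular"] + ["phage"] * 4)
        trim = trim_host_boundary(genes)
        assert trim.trimmed_left == 0  # run with >= min_run genes would cross the hallmark

    def test_whole_contig_host_like(self):
        genes = mk_genes(["cellular"] * 5)
        trim = trim_host_boundary(genes)
        assert trim.whole_contig_host_like

    def test_mixed_run_fraction_threshold(self):
        # hypothetical inside the run: fraction 3/4 = 0.75 >= 0.7 -> 4 trimmed
        genes = mk_genes(["cellular", "hypothetical", "cellular", "cellular"] + ["phage"] * 6)
        assert trim_host_boundary(genes).trimmed_left == 4

    def test_run_never_ends_on_virus_like_gene(self):
        # a trailing hypothetical after the cellular block is kept
        genes = mk_genes(["cellular", "cellular", "cellular", "hypothetical"] + ["phage"] * 6)
        assert trim_host_boundary(genes).trimmed_left == 3


class TestCurateAmg:
    def run(self, layout, pmap, **kw):
        genes = mk_genes(layout, **{k: v for k, v in kw.items() if k in ("amg_ko", "amg_pfam")})
        calls = curate_contig(genes, pmap, **{k: v for k, v in kw.items() if k == "window"})
        assert len(calls) == 1
        return calls[0]

    def test_flanked_consistent_accepted(self, pmap):
        call = self.run(["hallmark", "phage", "AMG", "phage", "phage"], pmap)
        assert call.status == "accepted" and not call.rejection_reasons

    def test_terminal_candidate_rejected_not_flanked(self, pmap):
        call = self.run(["hallmark", "phage", "phage", "phage", "AMG"], pmap)
        assert call.rejection_reasons == {"not_flanked"}

    def test_transposon_in_window_rejected(self, pmap):
        call = self.run(["hallmark", "transposon", "AMG", "phage", "phage"], pmap)
        assert call.rejection_reasons == {"transposon_context"}

    def test_transposon_outside_window_ignored(self, pmap):
        layout = ["transposon"] + ["phage"] * 6 + ["AMG"] + ["phage"] * 3
        call = self.run(layout, pmap, window=5)
        assert call.status == "accepted"

    def test_inconsistent_pfam_rejected(self, pmap):
        call = self.run(
            ["hallmark", "phage", "AMG", "phage", "phage"], pmap, amg_pfam="PF99999"
        )
        assert call.rejection_reasons == {"annotation_inconsistent"}

    def test_missing_pfam_is_inconsistent(self, pmap):
        call = self.run(["hallmark", "phage", "AMG", "phage", "phage"], pmap, amg_pfam=None)
        assert "annotation_inconsistent" in call.rejection_reasons

    def test_missing_ko_rejected(self, pmap):
        call = self.run(
            ["hallmark", "phage", "AMG", "phage", "phage"], pmap, amg_ko=None, amg_pfam=None
        )
        assert "no_ko" in call.rejection_reasons

    def test_host_region_candidate_rejected(self, pmap):
        layout = ["cellular", "cellular", "AMG", "cellular", "cellular", "phage", "hallmark"] + ["phage"] * 3
        call = self.run(layout, pmap)
        assert "in_host_region" in call.rejection_reasons

    def test_no_virus_like_gene_in_window_rejected(self, pmap):
        layout = ["phage"] + ["hypothetical"] * 6 + ["AMG"] + ["hypothetical"] * 6 + ["phage"]
        call = self.run(layout, pmap, window=5)
        assert call.rejection_reasons == {"not_flanked"}

    def test_reasons_accumulate_independently(self, pmap):
        # terminal AND transposon AND bad pfam: all three reasons present
        layout = ["hallmark", "phage", "phage", "transposon", "AMG"]
        call = self.run(layout, pmap, amg_pfam="PF99999")
        assert call.rejection_reasons == {
            "not_flanked",
            "transposon_context",
            "annotation_inconsistent",
        }

    def test_candidate_not_on_contig_rejected(self, pmap):
        genes = mk_genes(["hallmark", "phage", "AMG", "phage", "phage"])
        orphan = GeneAnnotation("ctg", 99, 1, 300, "+", "amg_candidate", "K00577", "PF09472")
        trim = trim_host_boundary(genes)
        with pytest.raises(ValueError, match="not found"):
            curate_amg(orphan, genes, trim, pmap)

    def test_accepted_call_cannot_carry_reasons(self):
        with pytest.raises(ValueError):
            AmgCall("c", 1, "K1", "accepted", frozenset({"no_ko"}))


class TestClassifyMm:
    def test_trichotomy(self, pmap):
        assert classify_mm("K00577", pmap) == "exclusive_mm"   # only MM modules
        assert classify_mm("K00925", pmap) == "shared_mm"      # MM + non-MM modules
        assert classify_mm("K03594", pmap) == "non_mm"         # no MM module
        assert classify_mm("K99999", pmap) == "non_mm"         # unknown KO, warned

    def test_custom_map_subset_rule(self):
        pm = PathwayMap(
            ko_to_modules={"K1": frozenset({"MMa"}), "K2": frozenset({"MMa", "gly"}), "K3": frozenset({"gly"})},
            mm_modules=frozenset({"MMa"}),
            ko_to_pfams={},
        )
        assert classify_mm("K1", pm) == "exclusive_mm"
        assert classify_mm("K2", pm) == "shared_mm"
        assert classify_mm("K3", pm) == "non_mm"

    def test_mm_modules_must_exist(self):
        with pytest.raises(ValueError):
            PathwayMap(
                ko_to_modules={"K1": frozenset({"a"})},
                mm_modules=frozenset({"missing"}),
                ko_to_pfams={},
            )


def call(ko, contig, mm_class="exclusive_mm", status="accepted"):
    reasons = frozenset() if status == "accepted" else frozenset({"no_ko"})
    return AmgCall(contig, 3, ko, status, reasons, mm_class)


class TestHabitatAssociation:
    def test_single_amg_single_habitat(self):
        summary = habitat_association([call("K1", "c1")], {"c1": "rumen"})
        assert summary.matrix.loc["K1", "rumen"] == 1
        assert summary.habitat_breadth["K1"] == 1

    def test_breadth_partition_counts(self):
        # 3 KOs in one habitat each, 2 KOs spanning two habitats
        calls = [
            call("K1", "c1"), call("K2", "c2"), call("K3", "c3"),
            call("K4", "c4"), call("K4", "c5"),
            call("K5", "c6"), call("K5", "c7"),
        ]
        habs = {"c1": "rumen", "c2": "rumen", "c3": "marine", "c4": "rumen",
                "c5": "marine", "c6": "lake", "c7": "marine"}
        summary = habitat_association(calls, habs)
        assert summary.n_single_habitat == 3 and summary.n_multi_habitat == 2
        assert summary.amgs_per_habitat["rumen"] == 3

    def test_rejected_and_non_mm_calls_excluded(self):
        calls = [call("K1", "c1"), call("K2", "c2", status="rejected"), call("K3", "c3", mm_class="non_mm")]
        summary = habitat_association(calls, {"c1": "rumen", "c2": "rumen", "c3": "rumen"})
        assert list(summary.matrix.index) == ["K1"]

    def test_grand_total_equals_accepted_mm_contig_tallies(self):
        calls = [call("K1", "c1"), call("K1", "c2"), call("K2", "c1")]
        habs = {"c1": "rumen", "c2": "marine"}
        summary = habitat_association(calls, habs)
        assert int(summary.matrix.to_numpy().sum()) == 3

    def test_order_invariance(self):
        calls = [call("K1", "c1"), call("K2", "c2"), call("K1", "c3")]
        habs = {"c1": "a", "c2": "b", "c3": "a"}
        m1 = habitat_association(calls, habs).matrix
        m2 = habitat_association(list(reversed(calls)), habs).matrix
        pd.testing.assert_frame_equal(m1, m2)

    def test_missing_habitat_label_raises(self):
        with pytest.raises(KeyError, match="c1"):
            habitat_association([call("K1", "c1")], {})
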