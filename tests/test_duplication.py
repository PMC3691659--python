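"""Duplication funnel: multi-contig genes, overlap screen, redundancy check,
nature classification and the reference-duplication flag."""

import numpy as np
import pytest

from syntenymap.duplication import (
    classify_nature,
    contig_pair_check,
    find_multi_contig_genes,
    overlap_screen,
    ref_duplication_check,
)
from syntenymap.models import DuplicationCall, GeneAnnotation, GeneRecord
from syntenymap.published_tables import build_duplication_fixture

from conftest import make_anchor, make_hit


def gene_hits(spec):
    """spec: list of (contig, gene, s_start, s_end)."""
    return [make_hit(c, g, s_start=s, s_end=e, aln_length=e - s + 1)
            for c, g, s, e in spec]


class TestFindMultiContigGenes:
    def test_single_contig_excluded(self):
        anchors = [make_anchor("geneA", "Chr1", 1, 2000)]
        hits = gene_hits([("gc1", "geneA", 1, 500)])
        assert find_multi_contig_genes(anchors, hits) == []

    def test_three_contigs_included_with_all_hits(self):
        anchors = [make_anchor("geneA", "Chr1", 1, 2000)]
        hits = gene_hits([("gc1", "geneA", 1, 500), ("gc2", "geneA", 1, 500),
                          ("gc3", "geneA", 400, 900)])
        (cand,) = find_multi_contig_genes(anchors, hits)
        assert cand.contig_ids == ("gc1", "gc2", "gc3")
        assert len(cand.hits) == 3

    def test_evalue_filter_applies(self):
        anchors = [make_anchor("geneA", "Chr1", 1, 2000)]
        hits = [make_hit("gc1", "geneA"), make_hit("gc2", "geneA", evalue=1e-5)]
        assert find_multi_contig_genes(anchors, hits) == []


class TestOverlapScreen:
    def test_boundary_overlap_51_is_split_gene(self):
        anchors = [make_anchor("geneA", "Chr1", 1, 2000)]
        hits = gene_hits([("gc1", "geneA", 1, 300), ("gc2", "geneA", 250, 600)])
        cands = find_multi_contig_genes(anchors, hits)
        result = overlap_screen(cands, min_overlap_bp=100)
        assert result.overlapping == []
        assert len(result.split_gene) == 1

    def test_overlap_151_is_retained(self):
        anchors = [make_anchor("geneA", "Chr1", 1, 2000)]
        hits = gene_hits([("gc1", "geneA", 1, 300), ("gc2", "geneA", 150, 600)])
        cands = find_multi_contig_genes(anchors, hits)
        result = overlap_screen(cands, min_overlap_bp=100)
        (cand,) = result.overlapping
        assert cand.best_overlap_bp == 151
        assert cand.best_pair == ("gc1", "gc2")

    def test_symmetry_in_contig_order(self):
        anchors = [make_anchor("geneA", "Chr1", 1, 2000)]
        fwd = overlap_screen(find_multi_contig_genes(
            anchors, gene_hits([("gc1", "geneA", 1, 300), ("gc2", "geneA", 150, 600)])))
        rev = overlap_screen(find_multi_contig_genes(
            anchors, gene_hits([("gc2", "geneA", 150, 600), ("gc1", "geneA", 1, 300)])))
        assert fwd.overlapping[0].best_overlap_bp == rev.overlapping[0].best_overlap_bp


def screened_candidate(gene="geneA", pair=("gc1", "gc2")):
    anchors = [make_anchor(gene, "Chr1", 1, 2000)]
    hits = gene_hits([(pair[0], gene, 1, 500), (pair[1], gene, 1, 500)])
    return overlap_screen(find_multi_contig_genes(anchors, hits)).overlapping


LENGTHS = {"gc1": 2000, "gc2": 1500}


class TestContigPairCheck:
    def test_no_mutual_alignment_emits_call(self):
        cands = screened_candidate()
        self_hits = [make_hit("gc1", "gc1", aln_length=2000, q_end=2000, s_end=2000)]
        (call,) = contig_pair_check(cands, self_hits, LENGTHS)
        assert call.gene_id == "geneA"
        assert call.flags == ()

    def test_redundant_pair_dropped(self):
        cands = screened_candidate()
        self_hits = [
            make_hit("gc1", "gc1", aln_length=2000, q_end=2000, s_end=2000),
            make_hit("gc1", "gc2", aln_length=1450, q_start=1, q_end=1450,
                     s_start=1, s_end=1450),
        ]
        # 1450/1500 = 0.967 of the shorter contig -> assembly duplicate
        assert contig_pair_check(cands, self_hits, LENGTHS) == []

    def test_partial_coverage_flagged_ambiguous(self):
        cands = screened_candidate()
        self_hits = [
            make_hit("gc1", "gc1", aln_length=2000, q_end=2000, s_end=2000),
            make_hit("gc1", "gc2", aln_length=1000, q_start=1, q_end=1000,
                     s_start=1, s_end=1000),
        ]
        (call,) = contig_pair_check(cands, self_hits, LENGTHS)
        assert "ambiguous" in call.flags

    def test_short_alignments_ignored(self):
        cands = screened_candidate()
        self_hits = [make_hit("gc1", "gc2", aln_length=80, q_end=80, s_end=80)]
        (call,) = contig_pair_check(cands, self_hits, LENGTHS)
        assert call.flags == ()

    def test_unsearched_contigs_flagged_uncheckable(self, caplog):
        cands = screened_candidate()
        with caplog.at_level("WARNING"):
            (call,) = contig_pair_check(cands, [], LENGTHS)
        assert "uncheckable" in call.flags


class TestClassifyNature:
    def make_call(self):
        return DuplicationCall("geneA", ("gc1", "gc2"), overlap_bp=200)

    @pytest.mark.parametrize(
        "placements,expected",
        [
            ({"gc1": ("scf1", "LG8"), "gc2": ("scf1", "LG8")}, "intra_chr"),
            ({"gc1": ("scf1", "LG8"), "gc2": ("scf2", "LG12")}, "inter_chr"),
            ({"gc1": ("scf1", "LG8"), "gc2": ("scf2", "LG8")}, "intra_chr"),
            ({"gc1": ("scf1", "LG8")}, "unplaced"),
        ],
    )
    def test_placement_rules(self, placements, expected):
        (call,) = classify_nature([self.make_call()], placements)
        assert call.nature == expected


class TestRefDuplicationCheck:
    def test_two_distinct_loci_flagged(self):
        fx = build_duplication_fixture()
        calls = ref_duplication_check(
            [c for c in fx.calls if c.gene_id == "ENSDARG00000020857"],
            fx.ref_annotation, fx.ref_self_hits,
        )
        (call,) = calls
        assert call.ref_duplicated
        assert call.ref_locations == (
            ("Chr1", 40426579, 40445530),
            ("Chr7", 73934667, 73961321),
        )

    def test_single_locus_not_flagged(self):
        ann = GeneAnnotation([GeneRecord("g1", "Chr1", 100, 2000)])
        hits = [make_hit("g1", "Chr1", bitscore=2000, s_start=100, s_end=2000)]
        (call,) = ref_duplication_check(
            [DuplicationCall("g1", ("a", "b"), 200)], ann, hits
        )
        assert not call.ref_duplicated

    def test_low_score_loci_ignored(self):
        ann = GeneAnnotation([GeneRecord("g1", "Chr1", 100, 2000)])
        hits = [make_hit("g1", "Chr1", bitscore=2000, s_start=100, s_end=2000),
                make_hit("g1", "Chr5", bitscore=900, s_start=1, s_end=1000)]
        (call,) = ref_duplication_check(
            [DuplicationCall("g1", ("a", "b"), 200)], ann, hits
        )
        assert not call.ref_duplicated

    def test_overlapping_loci_collapse_to_one(self):
        ann = GeneAnnotation([GeneRecord("g1", "Chr1", 100, 2000)])
        hits = [make_hit("g1", "Chr1", bitscore=2000, s_start=100, s_end=2000),
                make_hit("g1", "Chr1", bitscore=1500, s_start=500, s_end=1800)]
        (call,) = ref_duplication_check(
            [DuplicationCall("g1", ("a", "b"), 200)], ann, hits
        )
        assert not call.ref_duplicated


def test_funnel_monotonicity_random():
    """multi-contig genes >= overlap survivors >= emitted calls."""
    rng = np.random.default_rng(17)
    anchors = [make_anchor(f"g{i}", "Chr1", 10_000 * i + 1, 10_000 * i + 3_000)
               for i in range(30)]
    hits = []
    for i in range(30):
        for k in range(int(rng.integers(1, 4))):
            s = int(rng.integers(1, 1500))
            hits.append(make_hit(f"gc{rng.integers(0, 12)}", f"g{i}",
                                 s_start=s, s_end=s + int(rng.integers(60, 400))))
    multi = find_multi_contig_genes(anchors, hits)
    screen = overlap_screen(multi)
    lengths = {f"gc{i}": 2000 for i in range(12)}
    calls = contig_pair_check(screen.overlapping, [], lengths)
    assert len(multi) >= len(screen.overlapping) >= len(calls)
    assert len(screen.overlapping) + len(screen.split_gene) == len(multi)


def test_published_duplication_table_reproduced():
    """The transcribed duplicated-gene table yields its own printed tallies:
    34 inter-chromosomal + 1 intra-chromosomal, 30 duplicated in the
    reference genome."""
    fx = build_duplication_fixture()
    calls = classify_nature(fx.calls, fx.placements)
    calls = ref_duplication_check(calls, fx.ref_annotation, fx.ref_self_hits)
    assert len(calls) == 35
    assert sum(c.nature == "inter_chr" for c in calls) == 34
    assert sum(c.nature == "intra_chr" for c in calls) == 1
    assert sum(c.ref_duplicated for c in calls) == 30
    for c in calls:
        assert c.nature == fx.expected_nature[c.gene_id]
        assert c.ref_duplicated == fx.expected_ref_duplicated[c.gene_id]


def test_planted_duplication_classification(clean_dataset, clean_result):
    """Zero noise: planted tandem vs dispersed duplications classified
    intra vs inter with no errors."""
    _, dataset = clean_dataset
    got = {d.gene_id: d.nature for d in clean_result.duplication_calls}
    want = {
        g: ("intra_chr" if kind == "tandem_intra" else "inter_chr")
        for g, kind in dataset.truth.duplications
    }
    assert got == want
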