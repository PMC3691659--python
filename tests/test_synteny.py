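"""Block detection: maximal-run semantics vs a brute-force oracle, summary
arithmetic, and the homologous-chromosome calling rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syntenymap.models import ChromosomeTally, UNASSIGNED
from syntenymap.published_tables import (
    EXPECTED_HOMOLOGS,
    build_homolog_block_evidence,
    build_tally,
)
from syntenymap.synteny import (
    block_summary,
    call_homologous_chromosomes,
    detect_blocks,
    intergenic_gaps,
    intergenic_gaps_of,
)

from conftest import annotation_of, make_anchor


def anchors_from_gaps(gaps_bp, gene_len=1000, chrom="ChrX", bac="ctg1", start=1_000_000):
    """Build a contig's anchors with the given intergenic gaps."""
    anchors = []
    pos = start
    for i, gap in enumerate([None] + list(gaps_bp)):
        if gap is not None:
            # intergenic gap is start_{i+1} - end_i
            pos = (pos + gene_len - 1) + gap
        anchors.append(make_anchor(f"g{i:02d}", chrom, pos, pos + gene_len - 1, bac=bac))
    return anchors


def brute_force_blocks(positions, max_gap):
    """Independent oracle: enumerate all maximal runs over sorted intervals.

    positions: list of (start, end) sorted by start. A run [i..j] is valid
    when every consecutive gap start_{k+1} - end_k <= max_gap; it is maximal
    when it cannot extend in either direction.
    """
    n = len(positions)
    runs = []
    for i in range(n):
        for j in range(i, n):
            ok = all(
                positions[k + 1][0] - positions[k][1] <= max_gap
                for k in range(i, j)
            )
            if not ok:
                continue
            left_ext = i > 0 and positions[i][0] - positions[i - 1][1] <= max_gap
            right_ext = j < n - 1 and positions[j + 1][0] - positions[j][1] <= max_gap
            if not left_ext and not right_ext:
                runs.append((i, j))
    return runs


class TestDetectBlocks:
    def test_eleven_gene_block_with_published_gaps(self):
        """Gap list from the largest well-supported block: one 1.3 Mb block."""
        gaps_kb = [350, 41, 73, 199, 15, 66, 65, 215, 98, 171]
        anchors = anchors_from_gaps([g * 1000 for g in gaps_kb])
        blocks = detect_blocks(anchors, annotation_of(anchors))
        assert len(blocks) == 1
        assert blocks[0].n_genes == 11
        assert list(blocks[0].gaps_bp) == [g * 1000 for g in gaps_kb]

    def test_two_megabase_internal_gap_does_not_split(self):
        """The sparse 2.49 Mb block: gaps 107 kb, 225 kb and 2 Mb stay joined."""
        anchors = anchors_from_gaps([107_000, 225_000, 2_000_000])
        blocks = detect_blocks(anchors, annotation_of(anchors))
        assert len(blocks) == 1
        assert blocks[0].n_genes == 4

    def test_five_megabase_gap_splits_and_min_genes_prunes(self):
        anchors = anchors_from_gaps([5_000_000, 100_000])
        blocks = detect_blocks(anchors, annotation_of(anchors))
        assert len(blocks) == 1
        assert blocks[0].n_genes == 2
        assert blocks[0].gene_ids == ("g01", "g02")

    def test_unassigned_genes_excluded(self):
        anchors = anchors_from_gaps([50_000, 50_000])
        anchors.append(make_anchor("gU", UNASSIGNED, 10, 1000))
        blocks = detect_blocks(anchors, annotation_of(anchors))
        assert len(blocks) == 1
        assert "gU" not in blocks[0].gene_ids

    def test_occurrence_numbering_in_chromosome_order(self):
        anchors = (
            anchors_from_gaps([40_000], start=50_000_000)
            + anchors_from_gaps([30_000], start=1_000_000)[0:2]
        )
        # rebuild ids to avoid collisions: two separated 2-gene runs, one contig
        anchors = [
            make_anchor("a1", "ChrX", 1_000_000, 1_000_999),
            make_anchor("a2", "ChrX", 1_040_000, 1_040_999),
            make_anchor("b1", "ChrX", 50_000_000, 50_000_999),
            make_anchor("b2", "ChrX", 50_040_000, 50_040_999),
        ]
        blocks = detect_blocks(anchors, annotation_of(anchors))
        assert [(b.occurrence, b.gene_ids) for b in blocks] == [
            (1, ("a1", "a2")),
            (2, ("b1", "b2")),
        ]
        summary = block_summary(blocks)
        assert list(summary.table["contig"]) == ["ctg1 (1)", "ctg1 (2)"]

    def test_partition_property_random(self):
        rng = np.random.default_rng(11)
        anchors = []
        for c in range(3):
            pos = 1
            for i in range(rng.integers(3, 12)):
                pos += int(rng.integers(1_000, 6_000_000))
                anchors.append(
                    make_anchor(f"c{c}g{i}", "ChrY", pos, pos + 999, bac=f"ctg{c}")
                )
        blocks = detect_blocks(anchors, annotation_of(anchors))
        seen = set()
        for b in blocks:
            for gid in b.gene_ids:
                key = (gid, b.bac_contig_id, b.ref_chromosome)
                assert key not in seen
                seen.add(key)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    gaps=st.lists(
        st.integers(min_value=0, max_value=8_000_000), min_size=0, max_size=11
    ),
    max_gap=st.sampled_from([1_000_000, 3_000_000, 5_000_000]),
    min_genes=st.sampled_from([2, 3]),
)
def test_oracle_equivalence(gaps, max_gap, min_genes):
    """detect_blocks equals the brute-force maximal-run enumerator."""
    anchors = anchors_from_gaps(gaps)
    positions = [(a.gene.start, a.gene.end) for a in anchors]
    expected = [
        tuple(f"g{k:02d}" for k in range(i, j + 1))
        for i, j in brute_force_blocks(positions, max_gap)
        if j - i + 1 >= min_genes
    ]
    blocks = detect_blocks(
        anchors, annotation_of(anchors), min_genes=min_genes, max_gap_bp=max_gap
    )
    assert [b.gene_ids for b in blocks] == expected


def test_gap_monotonicity():
    """Larger max_gap never increases the number of maximal runs (merging
    only); smaller min_genes never decreases the surviving block count.

    Note the run-level statement is the one that holds universally: with
    min_genes > 1 two discarded singleton runs can merge into one *new*
    surviving block when the gap threshold grows.
    """
    rng = np.random.default_rng(3)
    gaps = [int(rng.integers(0, 7_000_000)) for _ in range(10)]
    anchors = anchors_from_gaps(gaps)
    ann = annotation_of(anchors)
    counts = [
        len(detect_blocks(anchors, ann, min_genes=1, max_gap_bp=g))
        for g in [500_000, 1_000_000, 3_000_000, 6_000_000, 10_000_000]
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:]))
    by_min = [len(detect_blocks(anchors, ann, min_genes=m)) for m in [2, 3, 4, 6]]
    assert all(a >= b for a, b in zip(by_min, by_min[1:]))


class TestIntergenicGaps:
    def test_arithmetic(self):
        a = [make_anchor("g1", "ChrX", 100, 200), make_anchor("g2", "ChrX", 500, 600)]
        assert intergenic_gaps_of(a) == [300]

    def test_adjacent_boundary(self):
        a = [make_anchor("g1", "ChrX", 100, 200), make_anchor("g2", "ChrX", 201, 300)]
        assert intergenic_gaps_of(a) == [1]

    def test_overlap_clamped_with_warning(self, caplog):
        a = [make_anchor("g1", "ChrX", 100, 250), make_anchor("g2", "ChrX", 200, 300)]
        with caplog.at_level("WARNING"):
            assert intergenic_gaps_of(a) == [0]
        assert "overlapping" in caplog.text

    def test_block_accessor_matches_stored(self):
        anchors = anchors_from_gaps([50_000, 70_000])
        (block,) = detect_blocks(anchors, annotation_of(anchors))
        assert intergenic_gaps(block) == list(block.gaps_bp)


class TestBlockSummary:
    def test_empty(self):
        s = block_summary([])
        assert s.table.empty
        assert (s.n_contigs, s.total_genes, s.total_span_kb) == (0, 0, 0)

    def test_totals_conservation(self):
        anchors = anchors_from_gaps([50_000, 60_000]) + [
            make_anchor("h1", "ChrX", 90_000_000, 90_000_999, bac="ctg2"),
            make_anchor("h2", "ChrX", 90_100_000, 90_100_999, bac="ctg2"),
        ]
        s = block_summary(detect_blocks(anchors, annotation_of(anchors)))
        assert s.total_genes == int(s.table["n_genes"].sum())
        assert s.total_span_kb == int(s.table["span_kb"].sum())
        assert s.n_contigs == 2


class TestHomologCalling:
    def test_single_chromosome_self_satisfying(self):
        anchors = anchors_from_gaps([50_000, 50_000, 50_000], chrom="Chr9")
        blocks = detect_blocks(anchors[:2], annotation_of(anchors)) + detect_blocks(
            [make_anchor("x1", "Chr9", 99_000_000, 99_000_999),
             make_anchor("x2", "Chr9", 99_100_000, 99_100_999)],
            annotation_of(anchors + [make_anchor("x1", "Chr9", 99_000_000, 99_000_999),
                                     make_anchor("x2", "Chr9", 99_100_000, 99_100_999)]),
        )
        tally = ChromosomeTally("sp", {"Chr9": 4}, 4)
        call = call_homologous_chromosomes(tally, blocks)
        assert call.homologous_chromosomes == ["Chr9"]

    def test_empty_tally_empty_call(self):
        call = call_homologous_chromosomes(ChromosomeTally("sp", {}, 0), [])
        assert call.homologous_chromosomes == []

    @pytest.mark.parametrize("species", list(EXPECTED_HOMOLOGS))
    def test_published_assignments_reproduced(self, species):
        """The hit-count + block rule reproduces the published calls,
        including the chromosome-1 exclusion in pufferfish (many hits, one
        2-gene block)."""
        call = call_homologous_chromosomes(
            build_tally(species), build_homolog_block_evidence(species)
        )
        assert call.homologous_chromosomes == EXPECTED_HOMOLOGS[species]

    def test_pufferfish_chr1_excluded_by_block_rule(self):
        evidence = call_homologous_chromosomes(
            build_tally("pufferfish"), build_homolog_block_evidence("pufferfish")
        ).evidence
        assert evidence["Chr1"].hit_count == 14
        assert evidence["Chr1"].n_blocks == 1
        assert evidence["Chr1"].max_block_genes == 2

    def test_evidence_recorded_for_uncalled_chromosomes(self):
        call = call_homologous_chromosomes(
            build_tally("zebrafish"), build_homolog_block_evidence("zebrafish")
        )
        assert "Chr6" in call.evidence  # 9 hits, 0 blocks, not called
        assert call.evidence["Chr6"].n_blocks == 0
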