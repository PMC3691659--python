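"""Marker -> BAC contig -> BES -> genome contig anchoring chain."""

import numpy as np
import pytest

from syntenymap.anchoring import (
    anchor_genome_contigs,
    collect_bes,
    contigs_for_linkage_group,
)
from syntenymap.models import BacContig, MappedBacContig, Marker

from conftest import make_hit


def mk_marker(mid, lg, cm, clone, end="F"):
    return Marker(mid, lg, cm, clone, end)


@pytest.fixture
def small_map():
    return [
        BacContig("ctg1", frozenset({"A", "B"})),
        BacContig("ctg2", frozenset({"C"})),
    ]


class TestContigsForLinkageGroup:
    def test_single_marker_pulls_its_contig(self, small_map):
        mapped = contigs_for_linkage_group(
            [mk_marker("M1", "LG8", 44.5, "A")], small_map, "LG8"
        )
        assert [m.contig_id for m in mapped] == ["ctg1"]
        assert mapped[0].cM_positions == frozenset({44.5})

    def test_two_clones_same_contig_accumulate_cm_set(self, small_map):
        markers = [mk_marker("M1", "LG8", 42.0, "A"), mk_marker("M2", "LG8", 44.5, "B")]
        (mapped,) = contigs_for_linkage_group(markers, small_map, "LG8")
        assert mapped.cM_positions == frozenset({42.0, 44.5})

    def test_unresolvable_clone_skipped_with_warning(self, small_map, caplog):
        markers = [mk_marker("M1", "LG8", 1.0, "ZZZ"), mk_marker("M2", "LG8", 2.0, "C")]
        with caplog.at_level("WARNING"):
            mapped = contigs_for_linkage_group(markers, small_map, "LG8")
        assert [m.contig_id for m in mapped] == ["ctg2"]
        assert "ZZZ" in caplog.text

    def test_absent_linkage_group_is_empty_not_error(self, small_map, caplog):
        with caplog.at_level("WARNING"):
            assert contigs_for_linkage_group([], small_map, "LG99") == []
        assert "LG99" in caplog.text


class TestCollectBes:
    def test_both_ends_counted(self, small_map):
        mapped = [MappedBacContig(contig=small_map[0])]
        index = {"A": {"F", "R"}, "B": {"F", "R"}}
        assert len(collect_bes(mapped, index)) == 4

    def test_single_archived_end(self, small_map):
        mapped = [MappedBacContig(contig=small_map[1])]
        assert collect_bes(mapped, {"C": {"F"}}) == ["C.F"]

    def test_clone_without_bes_contributes_nothing(self, small_map):
        mapped = [MappedBacContig(contig=small_map[0])]
        assert collect_bes(mapped, {"A": {"F"}}) == ["A.F"]


def mapped_contig(contig_id="ctg1", clones=("A", "B"), cms=(44.5,)):
    contig = BacContig(contig_id, frozenset(clones))
    markers = [mk_marker(f"M{i}", "LG8", cm, clones[0]) for i, cm in enumerate(cms)]
    return MappedBacContig(contig=contig, markers=markers)


class TestAnchorGenomeContigs:
    def test_bitscore_boundary_at_threshold(self):
        mapped = [mapped_contig()]
        reject = make_hit("A.F", "gc1", bitscore=399.9)
        accept = make_hit("A.F", "gc2", bitscore=400.0)
        anchored = anchor_genome_contigs([reject, accept], mapped)
        assert [a.genome_contig_id for a in anchored] == ["gc2"]

    def test_evalue_filter(self):
        mapped = [mapped_contig()]
        anchored = anchor_genome_contigs(
            [make_hit("A.F", "gc1", evalue=1e-9), make_hit("A.R", "gc2", evalue=1e-10)],
            mapped,
        )
        assert [a.genome_contig_id for a in anchored] == ["gc2"]

    def test_two_bes_one_genome_contig_merge_supports(self):
        mapped = [mapped_contig()]
        hits = [make_hit("A.F", "gc1", bitscore=500),
                make_hit("B.R", "gc1", bitscore=650)]
        (anchored,) = anchor_genome_contigs(hits, mapped)
        assert len(anchored.supports) == 2
        assert anchored.best_bes_hit.bitscore == 650

    def test_unknown_bes_skipped_with_warning(self, caplog):
        mapped = [mapped_contig()]
        with caplog.at_level("WARNING"):
            anchored = anchor_genome_contigs([make_hit("NOPE.F", "gc1")], mapped)
        assert anchored == []
        assert "NOPE.F" in caplog.text

    def test_contig_under_two_bacs_kept_under_both(self, caplog):
        mapped = [mapped_contig("ctg1", ("A",)), mapped_contig("ctg2", ("C",))]
        hits = [make_hit("A.F", "gc1"), make_hit("C.F", "gc1")]
        with caplog.at_level("WARNING"):
            anchored = anchor_genome_contigs(hits, mapped)
        assert {(a.genome_contig_id, a.bac_contig_id) for a in anchored} == {
            ("gc1", "ctg1"), ("gc1", "ctg2")
        }
        assert "multiple BAC contigs" in caplog.text

    def test_cm_inheritance_is_full_marker_set(self):
        mapped = [mapped_contig(cms=(42.0, 44.5))]
        (anchored,) = anchor_genome_contigs([make_hit("A.F", "gc1")], mapped)
        assert anchored.cM_positions == frozenset({42.0, 44.5})


def random_hits(rng, n=120):
    hits = []
    for _ in range(n):
        hits.append(
            make_hit(
                query=f"{rng.choice(['A', 'B'])}.{rng.choice(['F', 'R'])}",
                subject=f"gc{rng.integers(1, 20)}",
                bitscore=float(rng.uniform(200, 900)),
                evalue=float(10.0 ** -rng.integers(5, 60)),
            )
        )
    return hits


def test_threshold_monotonicity_grid():
    """Raising bit_min or lowering e_max never adds an anchored contig."""
    rng = np.random.default_rng(0)
    mapped = [mapped_contig()]
    hits = random_hits(rng)
    bit_grid = [250.0, 400.0, 600.0, 800.0]
    e_grid = [1e-5, 1e-10, 1e-20, 1e-40]
    for e_max in e_grid:
        sets = [
            {(a.genome_contig_id, a.bac_contig_id)
             for a in anchor_genome_contigs(hits, mapped, e_max=e_max, bit_min=b)}
            for b in bit_grid
        ]
        for loose, strict in zip(sets, sets[1:]):
            assert strict <= loose
    for bit_min in bit_grid:
        sets = [
            {(a.genome_contig_id, a.bac_contig_id)
             for a in anchor_genome_contigs(hits, mapped, e_max=e, bit_min=bit_min)}
            for e in e_grid
        ]
        for loose, strict in zip(sets, sets[1:]):
            assert strict <= loose


def test_provenance_chain_on_synthetic_data(clean_dataset, clean_result):
    """Every anchored genome contig traces back to >= 1 mapped marker."""
    _, dataset = clean_dataset
    marker_contigs = set()
    clone_to_contig = {
        c: contig.contig_id
        for contig in dataset.physical_map
        for c in contig.clone_ids
    }
    for m in dataset.markers:
        if m.linkage_group == "LG8":
            marker_contigs.add(clone_to_contig[m.clone_id])
    assert all(a.bac_contig_id in marker_contigs for a in clean_result.anchored)


def test_zero_noise_anchoring_recovers_planted_contig_set(clean_dataset, clean_result):
    _, dataset = clean_dataset
    planted = {
        gcid for gcid, (bac, lg) in dataset.placements.items() if lg == "LG8"
    }
    assert {a.genome_contig_id for a in clean_result.anchored} == planted
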