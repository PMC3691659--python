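"""Fusion-junction contigs: side thresholds, symmetry, mate-pair evidence."""

from syntenymap.fusion import (
    find_fusion_contigs,
    flag_linkage_corroboration,
    mate_pair_evidence,
)
from syntenymap.models import BacContig, HomologyCall, Marker
from syntenymap.synteny import detect_blocks

from conftest import annotation_of, make_anchor


def contig_anchors(bac, chrom, n, start):
    return [
        make_anchor(f"{bac}_{chrom}_g{i}", chrom, start + i * 100_000,
                    start + i * 100_000 + 999, bac=bac)
        for i in range(n)
    ]


def blocks_for(spec):
    """spec: list of (bac, chrom, n_genes, start). Returns detected blocks."""
    anchors = []
    for bac, chrom, n, start in spec:
        anchors.extend(contig_anchors(bac, chrom, n, start))
    return detect_blocks(anchors, annotation_of(anchors))


def call(chroms):
    return HomologyCall(species="sp", homologous_chromosomes=list(chroms), evidence={})


class TestFindFusionContigs:
    def test_eleven_four_split_is_candidate(self):
        blocks = blocks_for([("ctg2577", "Chr2", 11, 1_000_000),
                             ("ctg2577", "Chr7", 4, 1_000_000)])
        (cand,) = find_fusion_contigs(blocks, call(["Chr2", "Chr7"]))
        assert (cand.side_a.chromosome, cand.side_a.n_genes) == ("Chr2", 11)
        assert (cand.side_b.chromosome, cand.side_b.n_genes) == ("Chr7", 4)

    def test_four_three_split_is_candidate(self):
        blocks = blocks_for([("ctg2102", "Chr2", 4, 1_000_000),
                             ("ctg2102", "Chr7", 3, 1_000_000)])
        (cand,) = find_fusion_contigs(blocks, call(["Chr2", "Chr7"]))
        assert cand.bac_contig_id == "ctg2102"

    def test_minority_side_of_one_rejected(self):
        # the 1-gene side never forms a block at min_genes=2, so no candidate
        blocks = blocks_for([("ctg1", "Chr2", 5, 1_000_000),
                             ("ctg1", "Chr7", 1, 1_000_000)])
        assert find_fusion_contigs(blocks, call(["Chr2", "Chr7"])) == []

    def test_side_threshold_respected(self):
        blocks = blocks_for([("ctg1", "Chr2", 5, 1_000_000),
                             ("ctg1", "Chr7", 2, 1_000_000)])
        assert find_fusion_contigs(blocks, call(["Chr2", "Chr7"]),
                                   min_side_genes=3) == []

    def test_uncalled_chromosome_never_forms_side(self):
        blocks = blocks_for([("ctg1", "Chr2", 5, 1_000_000),
                             ("ctg1", "Chr9", 5, 1_000_000)])
        assert find_fusion_contigs(blocks, call(["Chr2", "Chr7"])) == []

    def test_fewer_than_two_called_chromosomes(self):
        blocks = blocks_for([("ctg1", "Chr2", 5, 1_000_000)])
        assert find_fusion_contigs(blocks, call(["Chr2"])) == []

    def test_symmetry_of_side_labels(self):
        spec_ab = [("ctg1", "Chr2", 4, 1_000_000), ("ctg1", "Chr7", 6, 1_000_000)]
        cand_ab = find_fusion_contigs(blocks_for(spec_ab), call(["Chr2", "Chr7"]))
        cand_ba = find_fusion_contigs(blocks_for(spec_ab[::-1]), call(["Chr7", "Chr2"]))
        assert [(c.side_a, c.side_b) for c in cand_ab] == [
            (c.side_a, c.side_b) for c in cand_ba
        ]
        assert cand_ab[0].side_a.n_genes >= cand_ab[0].side_b.n_genes

    def test_three_chromosome_contig_yields_pairwise_candidates(self):
        blocks = blocks_for([("ctg1", "Chr1", 3, 1_000_000),
                             ("ctg1", "Chr2", 3, 1_000_000),
                             ("ctg1", "Chr3", 3, 1_000_000)])
        cands = find_fusion_contigs(blocks, call(["Chr1", "Chr2", "Chr3"]))
        pairs = {(c.side_a.chromosome, c.side_b.chromosome) for c in cands}
        assert len(cands) == 3
        assert pairs == {("Chr1", "Chr2"), ("Chr1", "Chr3"), ("Chr2", "Chr3")}


class TestMatePairEvidence:
    def setup_method(self):
        blocks = blocks_for([("ctg1", "Chr2", 2, 1_000_000),
                             ("ctg1", "Chr7", 2, 1_000_000)])
        (self.cand,) = find_fusion_contigs(blocks, call(["Chr2", "Chr7"]))
        self.pm = [BacContig("ctg1", frozenset({"cl1", "cl2", "cl3"}))]
        self.gene_a = self.cand.side_a.gene_ids[0]
        self.gene_b = self.cand.side_b.gene_ids[0]

    def test_straddling_clone_supports(self):
        bes_gene = {"cl1.F": self.gene_a, "cl1.R": self.gene_b}
        (cand,) = mate_pair_evidence([self.cand], bes_gene, self.pm)
        assert cand.mate_pair_support == ["cl1"]

    def test_same_side_clone_does_not_support(self):
        bes_gene = {"cl2.F": self.gene_a, "cl2.R": self.cand.side_a.gene_ids[1]}
        (cand,) = mate_pair_evidence([self.cand], bes_gene, self.pm)
        assert cand.mate_pair_support == []

    def test_single_end_clone_is_insufficient(self):
        bes_gene = {"cl3.F": self.gene_a}
        (cand,) = mate_pair_evidence([self.cand], bes_gene, self.pm)
        assert cand.mate_pair_support == []


def test_linkage_corroboration_flag():
    blocks = blocks_for([("ctg1", "Chr2", 2, 1_000_000),
                         ("ctg1", "Chr7", 2, 1_000_000)])
    cands = find_fusion_contigs(blocks, call(["Chr2", "Chr7"]))
    pm = [BacContig("ctg1", frozenset({"cl1", "cl2"}))]
    markers = [Marker("M1", "LG8", 44.5, "cl1", "F"),
               Marker("M2", "LG8", 44.4, "cl2", "R")]
    (cand,) = flag_linkage_corroboration(cands, markers, pm, "LG8")
    assert cand.linkage_corroborated
    (cand,) = flag_linkage_corroboration(cands, markers[:1], pm, "LG8")
    assert not cand.linkage_corroborated


def test_planted_fusion_recovery_exact(clean_dataset, clean_result):
    """Zero noise: planted fusion contigs recovered with precision = recall = 1,
    sides matching the planted per-side gene counts, and every candidate's
    sides inside the homology call."""
    _, dataset = clean_dataset
    sp = clean_result.species["ref"]
    found = {c.bac_contig_id: c for c in sp.fusion_candidates}
    assert set(found) == set(dataset.truth.fusion_contigs)
    called = set(sp.homology_call.homologous_chromosomes)
    for cid, sides in dataset.truth.fusion_contigs.items():
        cand = found[cid]
        got = {cand.side_a.chromosome: cand.side_a.n_genes,
               cand.side_b.chromosome: cand.side_b.n_genes}
        assert got == sides
        assert set(got) <= called
        assert cand.mate_pair_support  # planted straddling clone found
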