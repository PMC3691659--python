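"""Seeded synthetic dataset generator with planted ground truth.

Produces the full set of pipeline inputs — linkage map, physical map, BES
FASTA, genome-contig FASTA, reference annotation, and every hit table — for
a toy target genome whose BAC contigs carry genes drawn from the first few
reference chromosomes in locally conserved clusters, with planted fusion
contigs (genes from two homologous chromosomes), tandem and dispersed
duplications, unassigned-scaffold genes, and optional hit-table noise.

The reference is laid out in *clusters* of neighboring genes separated by
large (> block-splitting) gaps; a planted synteny block is exactly one
cluster carried by one BAC contig, so the truth for every downstream stage
is known by construction. Sequence content is synthetic filler: homology is
expressed through the hit tables, not through alignable sequence.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io_formats
from .errors import SizingError
from .models import BacContig, GeneRecord, HomologyHit, Marker, UNASSIGNED


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults are the regression conditions used throughout the test suite:
    two homologous reference chromosomes of 60 genes each, 20 BAC contigs,
    3 fusion contigs, 8 duplicated genes (half tandem), 5% of genes on
    unassigned scaffolds, noise off.
    """

    seed: int = 0
    n_ref_chromosomes: int = 2
    genes_per_chromosome: int = 60
    n_bac_contigs: int = 20
    genes_per_contig_range: tuple[int, int] = (2, 8)
    n_homologous_chromosomes: int = 2
    block_length_range: tuple[int, int] = (2, 4)
    max_intergenic_gap_bp: int = 200_000
    n_fusion_contigs: int = 3
    n_duplicated_genes: int = 8
    frac_tandem_duplications: float = 0.5
    frac_unassigned_genes: float = 0.05
    hit_noise_rate: float = 0.0

    #: reference gap separating clusters; must exceed any block-splitting
    #: threshold the pipeline will use (default detector: 3 Mb).
    cluster_gap_bp: tuple[int, int] = (4_000_000, 6_000_000)

    def __post_init__(self) -> None:
        if self.n_ref_chromosomes < 2:
            raise ValueError("need >= 2 reference chromosomes")
        if self.n_homologous_chromosomes not in (2, 3):
            raise ValueError("n_homologous_chromosomes must be 2 or 3")
        if self.n_homologous_chromosomes > self.n_ref_chromosomes:
            raise ValueError("more homologous chromosomes than chromosomes")
        if self.block_length_range[0] < 2:
            raise ValueError("block_length_range minimum must be >= 2")
        for frac in (self.frac_tandem_duplications, self.frac_unassigned_genes,
                     self.hit_noise_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        for count in (self.genes_per_chromosome, self.n_bac_contigs,
                      self.n_fusion_contigs, self.n_duplicated_genes):
            if count < 0:
                raise ValueError("counts must be non-negative")


@dataclass
class PlantedTruth:
    """Ground truth for every downstream stage, recorded at planting time."""

    #: (bac_contig_id, occurrence, ref_chromosome, ordered gene ids)
    blocks: list[tuple[str, int, str, tuple[str, ...]]]
    #: bac_contig_id -> {chromosome: side gene count}
    fusion_contigs: dict[str, dict[str, int]]
    #: (gene_id, kind) with kind in {tandem_intra, inter}
    duplications: list[tuple[str, str]]
    homologous_chromosomes: set[str]
    #: every planted (non-duplicate-copy) gene id, for recovery checks
    planted_genes: set[str] = field(default_factory=set)

    def to_json(self) -> str:
        return json.dumps(
            {
                "blocks": [list(b[:3]) + [list(b[3])] for b in self.blocks],
                "fusion_contigs": self.fusion_contigs,
                "duplications": [list(d) for d in self.duplications],
                "homologous_chromosomes": sorted(self.homologous_chromosomes),
                "planted_genes": sorted(self.planted_genes),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        data = json.loads(text)
        return cls(
            blocks=[(b[0], b[1], b[2], tuple(b[3])) for b in data["blocks"]],
            fusion_contigs=data["fusion_contigs"],
            duplications=[tuple(d) for d in data["duplications"]],
            homologous_chromosomes=set(data["homologous_chromosomes"]),
            planted_genes=set(data["planted_genes"]),
        )


@dataclass
class TargetDataset:
    """Everything generate_target emits, in memory."""

    markers: list[Marker]
    physical_map: list[BacContig]
    bes_records: list[tuple[str, str]]
    genome_contig_records: list[tuple[str, str]]
    bes_hits: list[HomologyHit]
    contig_gene_hits: list[HomologyHit]
    self_hits: list[HomologyHit]
    ref_gene_hits: list[HomologyHit]
    placements: dict[str, tuple[str, str]]
    truth: PlantedTruth

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {cid: len(seq) for cid, seq in self.genome_contig_records}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def generate_reference(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[GeneRecord], list[tuple[str, str]]]:
    """Generate the reference annotation and (filler) chromosome sequences.

    Genes are placed non-overlapping and position-sorted, in clusters of
    block_length_range size separated by cluster_gap_bp, so that cluster
    membership is recoverable from coordinates alone. A
    frac_unassigned_genes share of extra genes goes on UNASSIGNED.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes: list[GeneRecord] = []
    for c in range(1, config.n_ref_chromosomes + 1):
        chrom = f"Chr{c}"
        pos = 1_000_000
        placed = 0
        while placed < config.genes_per_chromosome:
            size = int(rng.integers(config.block_length_range[0],
                                    config.block_length_range[1] + 1))
            size = min(size, config.genes_per_chromosome - placed)
            for k in range(size):
                length = int(rng.integers(1_000, 5_001))
                placed += 1
                genes.append(
                    GeneRecord(
                        gene_id=f"{chrom}_g{placed:03d}",
                        chromosome=chrom,
                        start=pos,
                        end=pos + length - 1,
                        strand="+" if rng.random() < 0.5 else "-",
                        name=f"synthetic gene {chrom}:{placed}",
                    )
                )
                if k < size - 1:
                    pos += length + int(rng.integers(10_000, config.max_intergenic_gap_bp + 1))
                else:
                    pos += length + int(rng.integers(*config.cluster_gap_bp))
    n_unassigned = round(
        config.frac_unassigned_genes * config.n_ref_chromosomes * config.genes_per_chromosome
    )
    pos = 1
    for k in range(1, n_unassigned + 1):
        length = int(rng.integers(1_000, 5_001))
        genes.append(
            GeneRecord(
                gene_id=f"UN_g{k:03d}",
                chromosome=UNASSIGNED,
                start=pos,
                end=pos + length - 1,
                strand=".",
                name=f"synthetic unassigned gene {k}",
            )
        )
        pos += length + 10_000
    sequences = [
        (f"Chr{c}", _random_seq(rng, 2_000))
        for c in range(1, config.n_ref_chromosomes + 1)
    ]
    return genes, sequences


def _clusters_of(genes: list[GeneRecord], split_gap: int = 3_000_000) -> list[list[GeneRecord]]:
    """Recover gene clusters from coordinates: runs split at gaps > split_gap."""
    genes = sorted(genes, key=lambda g: g.start)
    clusters: list[list[GeneRecord]] = [[genes[0]]] if genes else []
    for prev, cur in zip(genes, genes[1:]):
        if cur.start - prev.end > split_gap:
            clusters.append([cur])
        else:
            clusters[-1].append(cur)
    return clusters


def generate_target(
    config: SimConfig,
    annotation: list[GeneRecord],
    rng: np.random.Generator | None = None,
) -> TargetDataset:
    """Plant blocks, fusions and duplications; emit all inputs plus truth."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)

    hom_chroms = [f"Chr{c}" for c in range(1, config.n_homologous_chromosomes + 1)]
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chromosome, []).append(g)
    unassigned_pool = [g for g in annotation if g.chromosome == UNASSIGNED]

    # cluster pools, shuffled per chromosome; drop clusters below block minimum
    pools: dict[str, list[list[GeneRecord]]] = {}
    for chrom in hom_chroms:
        clusters = [
            cl for cl in _clusters_of(by_chrom.get(chrom, []))
            if len(cl) >= config.block_length_range[0]
        ]
        order = rng.permutation(len(clusters))
        pools[chrom] = [clusters[i] for i in order]

    n_normal = config.n_bac_contigs - config.n_fusion_contigs
    if n_normal < 0:
        raise SizingError("more fusion contigs than BAC contigs")
    available = sum(len(p) for p in pools.values())
    if config.n_fusion_contigs * 2 + n_normal > available:
        raise SizingError(
            f"config demands >= {config.n_fusion_contigs * 2 + n_normal} gene "
            f"clusters but the reference provides {available}"
        )

    # ---- plant contigs -------------------------------------------------
    contig_clusters: dict[str, list[tuple[str, list[GeneRecord]]]] = {}
    fusion_ids: list[str] = []
    for i in range(1, config.n_bac_contigs + 1):
        contig_id = f"ctg{i:04d}"
        picked: list[tuple[str, list[GeneRecord]]] = []
        if i <= config.n_fusion_contigs:
            # one cluster from each of two homologous chromosomes
            chrom_a, chrom_b = (
                hom_chroms[:2]
                if len(hom_chroms) == 2
                else [hom_chroms[j] for j in sorted(rng.choice(len(hom_chroms), 2, replace=False))]
            )
            for chrom in (chrom_a, chrom_b):
                if not pools[chrom]:
                    raise SizingError(f"no clusters left on {chrom} for fusion contig")
                picked.append((chrom, pools[chrom].pop()))
            fusion_ids.append(contig_id)
        else:
            chrom = max(hom_chroms, key=lambda c: len(pools[c]))
            if not pools[chrom]:
                raise SizingError("no clusters left for a normal contig")
            picked.append((chrom, pools[chrom].pop()))
            n_genes = len(picked[0][1])
            if (
                rng.random() < 0.5
                and pools[chrom]
                and n_genes + len(pools[chrom][-1]) <= config.genes_per_contig_range[1]
            ):
                picked.append((chrom, pools[chrom].pop()))
        contig_clusters[contig_id] = picked

    # sprinkle unassigned genes onto random contigs (excluded from blocks)
    contig_extras: dict[str, list[GeneRecord]] = {c: [] for c in contig_clusters}
    planted_unassigned: list[GeneRecord] = []
    contig_id_list = sorted(contig_clusters)
    for g in unassigned_pool:
        host = contig_id_list[int(rng.integers(len(contig_id_list)))]
        contig_extras[host].append(g)
        planted_unassigned.append(g)

    # ---- duplications --------------------------------------------------
    planted_gene_objs: dict[str, tuple[str, GeneRecord]] = {}  # gene -> (contig, record)
    for contig_id, picked in contig_clusters.items():
        for _, cluster in picked:
            for g in cluster:
                planted_gene_objs[g.gene_id] = (contig_id, g)
    dup_pool = sorted(planted_gene_objs)
    if config.n_duplicated_genes > len(dup_pool):
        raise SizingError("more duplicated genes requested than planted genes")
    dup_idx = sorted(rng.choice(len(dup_pool), config.n_duplicated_genes, replace=False))
    dup_genes = [dup_pool[i] for i in dup_idx]
    n_tandem = round(config.frac_tandem_duplications * config.n_duplicated_genes)
    duplications: list[tuple[str, str]] = [
        (g, "tandem_intra" if k < n_tandem else "inter") for k, g in enumerate(dup_genes)
    ]

    # extra BAC contigs on a second linkage group host the dispersed copies
    n_inter = config.n_duplicated_genes - n_tandem
    other_lg = "LG9"
    other_bacs = [f"ctgX{i:03d}" for i in range(1, max(1, (n_inter + 1) // 2) + 1)] if n_inter else []

    # ---- clones, markers, BES records ---------------------------------
    # each genome contig gets its own supporting BES, so a contig needs
    # enough clone ends for all its genes, sprinkled unassigned genes and
    # hosted tandem copies
    tandem_hosted: dict[str, int] = {}
    for gene_id, kind in duplications:
        if kind == "tandem_intra":
            host = planted_gene_objs[gene_id][0]
            tandem_hosted[host] = tandem_hosted.get(host, 0) + 1
    ends_needed: dict[str, int] = {}
    for contig_id in contig_id_list:
        n_genes = sum(len(cl) for _, cl in contig_clusters[contig_id])
        ends_needed[contig_id] = (
            n_genes + len(contig_extras[contig_id]) + tandem_hosted.get(contig_id, 0)
        )

    physical_map: list[BacContig] = []
    markers: list[Marker] = []
    bes_records: list[tuple[str, str]] = []
    clones_by_contig: dict[str, list[str]] = {}
    cm_grid = np.round(np.arange(0.0, 30.01, 0.5), 1)
    marker_n = 0
    for contig_id in contig_id_list + other_bacs:
        lg = other_lg if contig_id.startswith("ctgX") else "LG8"
        n_clones = max(
            int(rng.integers(4, 9)), -(-ends_needed.get(contig_id, 0) // 2)
        )
        clones = [f"{contig_id}c{k}" for k in range(1, n_clones + 1)]
        clones_by_contig[contig_id] = clones
        physical_map.append(BacContig(contig_id=contig_id, clone_ids=frozenset(clones)))
        for clone in clones:
            for end in ("F", "R"):
                bes_records.append((f"{clone}.{end}", _random_seq(rng, 300)))
        base_cm = float(rng.choice(cm_grid))
        n_markers = int(rng.integers(1, 4))
        for k in range(n_markers):
            marker_n += 1
            cm = max(0.0, round(base_cm + [0.0, 0.1, -0.1][k % 3], 1))
            markers.append(
                Marker(
                    marker_id=f"M{marker_n:04d}",
                    linkage_group=lg,
                    position_cM=cm,
                    clone_id=clones[k % n_clones],
                    end="F" if k % 2 == 0 else "R",
                )
            )

    # ---- genome contigs and hit tables --------------------------------
    genome_contig_records: list[tuple[str, str]] = []
    bes_hits: list[HomologyHit] = []
    contig_gene_hits: list[HomologyHit] = []
    self_hits: list[HomologyHit] = []
    placements: dict[str, tuple[str, str]] = {}
    gc_counter = 0

    def new_genome_contig(bac_id: str, lg: str) -> str:
        nonlocal gc_counter
        gc_counter += 1
        gcid = f"gctg{gc_counter:05d}"
        genome_contig_records.append((gcid, _random_seq(rng, int(rng.integers(1_500, 3_001)))))
        placements[gcid] = (bac_id, lg)
        return gcid

    def add_bes_hit(bes_id: str, gcid: str) -> None:
        bes_hits.append(
            HomologyHit(
                query_id=bes_id,
                subject_id=gcid,
                pct_identity=float(np.round(rng.uniform(95, 100), 1)),
                aln_length=300,
                q_start=1,
                q_end=300,
                s_start=1,
                s_end=300,
                evalue=float(10.0 ** -rng.integers(50, 121)),
                bitscore=float(np.round(rng.uniform(450, 900), 1)),
            )
        )

    def add_gene_hit(gcid: str, gene: GeneRecord, s_lo: int = 1, s_hi: int | None = None,
                     bit_lo: float = 500, bit_hi: float = 1500) -> None:
        if s_hi is None:
            s_hi = min(gene.length, 900)
        contig_gene_hits.append(
            HomologyHit(
                query_id=gcid,
                subject_id=gene.gene_id,
                pct_identity=float(np.round(rng.uniform(80, 100), 1)),
                aln_length=s_hi - s_lo + 1,
                q_start=1,
                q_end=s_hi - s_lo + 1,
                s_start=s_lo,
                s_end=s_hi,
                evalue=float(10.0 ** -rng.integers(30, 101)),
                bitscore=float(np.round(rng.uniform(bit_lo, bit_hi), 1)),
            )
        )

    gene_to_primary_gc: dict[str, str] = {}
    fusion_first_gc: dict[str, dict[str, str]] = {}
    bes_cursor: dict[str, int] = {}
    bes_cycle_by_contig: dict[str, list[str]] = {}
    for contig_id in contig_id_list:
        clones = clones_by_contig[contig_id]
        bes_cycle = [f"{cl}.{e}" for cl in clones for e in ("F", "R")]
        bes_cycle_by_contig[contig_id] = bes_cycle
        is_fusion = contig_id in fusion_ids
        # fusion contigs reserve clone 1's two ends to straddle the junction
        bes_cursor[contig_id] = 2 if is_fusion else 0
        if is_fusion:
            fusion_first_gc[contig_id] = {}
        all_genes = [
            (chrom, g) for chrom, cluster in contig_clusters[contig_id] for g in cluster
        ] + [(UNASSIGNED, g) for g in contig_extras[contig_id]]
        for chrom, gene in all_genes:
            gcid = new_genome_contig(contig_id, "LG8")
            gene_to_primary_gc[gene.gene_id] = gcid
            if is_fusion and chrom in [c for c, _ in contig_clusters[contig_id]] and \
                    chrom not in fusion_first_gc[contig_id]:
                fusion_first_gc[contig_id][chrom] = gcid
                side_index = list(fusion_first_gc[contig_id]).index(chrom)
                add_bes_hit(f"{clones[0]}.{'FR'[side_index]}", gcid)
            else:
                add_bes_hit(bes_cycle[bes_cursor[contig_id] % len(bes_cycle)], gcid)
                bes_cursor[contig_id] += 1
            add_gene_hit(gcid, gene)

    # duplicate copies: a second genome contig hitting the same gene region
    inter_cursor = 0
    for gene_id, kind in duplications:
        host_contig, gene = planted_gene_objs[gene_id]
        if kind == "tandem_intra":
            gcid = new_genome_contig(host_contig, "LG8")
            cycle = bes_cycle_by_contig[host_contig]
            add_bes_hit(cycle[bes_cursor[host_contig] % len(cycle)], gcid)
            bes_cursor[host_contig] += 1
        else:
            bac = other_bacs[inter_cursor % len(other_bacs)]
            inter_cursor += 1
            gcid = new_genome_contig(bac, other_lg)
        # overlapping subject interval, slightly weaker than the primary hit
        add_gene_hit(gcid, gene, bit_lo=460, bit_hi=499)
        primary = gene_to_primary_gc[gene_id]
        # partial mutual alignment: clearly below redundancy, above min length
        for qa, qb in ((primary, gcid), (gcid, primary)):
            self_hits.append(
                HomologyHit(
                    query_id=qa, subject_id=qb,
                    pct_identity=96.0, aln_length=150,
                    q_start=11, q_end=160, s_start=11, s_end=160,
                    evalue=1e-40, bitscore=250.0,
                )
            )

    # identity rows mark every genome contig as having entered the self search
    for gcid, seq in genome_contig_records:
        n = len(seq)
        self_hits.append(
            HomologyHit(
                query_id=gcid, subject_id=gcid, pct_identity=100.0,
                aln_length=n, q_start=1, q_end=n, s_start=1, s_end=n,
                evalue=0.0, bitscore=2 * n,
            )
        )

    # reference loci of each planted gene (for the reference-duplication check)
    ref_gene_hits: list[HomologyHit] = []
    for gene_id in sorted(planted_gene_objs):
        g = planted_gene_objs[gene_id][1]
        ref_gene_hits.append(
            HomologyHit(
                query_id=gene_id, subject_id=g.chromosome,
                pct_identity=100.0, aln_length=g.length,
                q_start=1, q_end=g.length, s_start=g.start, s_end=g.end,
                evalue=0.0, bitscore=2000.0,
            )
        )

    # ---- noise ---------------------------------------------------------
    if config.hit_noise_rate > 0:
        bes_hits = _perturb_bes(bes_hits, bes_records, genome_contig_records, config, rng)
        contig_gene_hits = _perturb_gene_hits(
            contig_gene_hits, genome_contig_records, annotation, config, rng
        )

    # ---- truth ---------------------------------------------------------
    truth_blocks: list[tuple[str, int, str, tuple[str, ...]]] = []
    for contig_id in contig_id_list:
        by_c: dict[str, list[list[GeneRecord]]] = {}
        for chrom, cluster in contig_clusters[contig_id]:
            by_c.setdefault(chrom, []).append(cluster)
        for chrom in sorted(by_c):
            clusters = sorted(by_c[chrom], key=lambda cl: min(g.start for g in cl))
            for occ, cluster in enumerate(clusters, start=1):
                ordered = tuple(
                    g.gene_id for g in sorted(cluster, key=lambda g: (g.start, g.end))
                )
                truth_blocks.append((contig_id, occ, chrom, ordered))
    fusion_truth = {
        cid: {chrom: len(cluster) for chrom, cluster in contig_clusters[cid]}
        for cid in fusion_ids
    }
    truth = PlantedTruth(
        blocks=truth_blocks,
        fusion_contigs=fusion_truth,
        duplications=duplications,
        homologous_chromosomes=set(hom_chroms),
        planted_genes=set(planted_gene_objs) | {g.gene_id for g in planted_unassigned},
    )

    return TargetDataset(
        markers=sorted(markers, key=lambda m: (m.linkage_group, m.position_cM, m.marker_id)),
        physical_map=physical_map,
        bes_records=bes_records,
        genome_contig_records=genome_contig_records,
        bes_hits=bes_hits,
        contig_gene_hits=contig_gene_hits,
        self_hits=self_hits,
        ref_gene_hits=ref_gene_hits,
        placements=placements,
        truth=truth,
    )


def _perturb_bes(hits, bes_records, genome_contig_records, config, rng):
    """Drop true rows at rate/2; add spurious rows, half with bitscore < 400."""
    kept = [h for h in hits if rng.random() >= config.hit_noise_rate / 2]
    n_spurious = round(config.hit_noise_rate * len(hits))
    bes_ids = [b for b, _ in bes_records]
    gc_ids = [g for g, _ in genome_contig_records]
    for k in range(n_spurious):
        low = k % 2 == 0  # half below the bit-score filter, to exercise it
        kept.append(
            HomologyHit(
                query_id=bes_ids[int(rng.integers(len(bes_ids)))],
                subject_id=gc_ids[int(rng.integers(len(gc_ids)))],
                pct_identity=float(np.round(rng.uniform(80, 95), 1)),
                aln_length=int(rng.integers(50, 301)),
                q_start=1, q_end=100, s_start=1, s_end=100,
                evalue=1e-20,
                bitscore=float(np.round(rng.uniform(100, 399) if low else rng.uniform(401, 449), 1)),
            )
        )
    return kept


def _perturb_gene_hits(hits, genome_contig_records, annotation, config, rng):
    kept = [h for h in hits if rng.random() >= config.hit_noise_rate / 2]
    n_spurious = round(config.hit_noise_rate * len(hits))
    gc_ids = [g for g, _ in genome_contig_records]
    gene_ids = [g.gene_id for g in annotation]
    for _ in range(n_spurious):
        kept.append(
            HomologyHit(
                query_id=gc_ids[int(rng.integers(len(gc_ids)))],
                subject_id=gene_ids[int(rng.integers(len(gene_ids)))],
                pct_identity=float(np.round(rng.uniform(70, 90), 1)),
                aln_length=int(rng.integers(40, 200)),
                q_start=1, q_end=100, s_start=1, s_end=100,
                evalue=1e-15,
                bitscore=float(np.round(rng.uniform(100, 450), 1)),
            )
        )
    return kept


def block_recovery(
    detected, truth: PlantedTruth, min_jaccard: float = 0.5
) -> tuple[float, float]:
    """Precision and recall of detected blocks against the planted blocks.

    A detected block matches a planted one when contig and chromosome agree
    and the gene-set Jaccard index is >= min_jaccard (so a block missing one
    dropped-hit gene still counts as recovered). Matching is one-to-one,
    greedy in input order.
    """
    truth_sets = [
        (cid, chrom, frozenset(genes)) for cid, _occ, chrom, genes in truth.blocks
    ]
    unmatched = set(range(len(truth_sets)))
    n_matched_det = 0
    for block in detected:
        genes = frozenset(block.gene_ids)
        for j in sorted(unmatched):
            cid, chrom, tgenes = truth_sets[j]
            if cid != block.bac_contig_id or chrom != block.ref_chromosome:
                continue
            inter = len(genes & tgenes)
            union = len(genes | tgenes)
            if union and inter / union >= min_jaccard:
                unmatched.discard(j)
                n_matched_det += 1
                break
    n_det = len(list(detected))
    precision = n_matched_det / n_det if n_det else 1.0
    recall = (len(truth_sets) - len(unmatched)) / len(truth_sets) if truth_sets else 1.0
    return precision, recall


def generate_dataset(config: SimConfig) -> tuple[list[GeneRecord], TargetDataset]:
    """Reference plus target in one call, a single generator threaded through."""
    rng = np.random.default_rng(config.seed)
    annotation, _seqs = generate_reference(config, rng)
    dataset = generate_target(config, annotation, rng)
    return annotation, dataset


def write_dataset(
    annotation: list[GeneRecord], dataset: TargetDataset, outdir: str | Path
) -> dict[str, Path]:
    """Write all input files plus truth.json; returns path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "linkage_map": outdir / "linkage_map.tsv",
        "physical_map": outdir / "physical_map.tsv",
        "bes_fasta": outdir / "bes.fasta",
        "genome_contigs_fasta": outdir / "genome_contigs.fasta",
        "annotation": outdir / "annotation.tsv",
        "bes_hits": outdir / "bes_hits.tsv",
        "contig_gene_hits": outdir / "contig_gene_hits.tsv",
        "self_hits": outdir / "self_hits.tsv",
        "ref_gene_hits": outdir / "ref_gene_hits.tsv",
        "placements": outdir / "placements.tsv",
        "truth": outdir / "truth.json",
    }
    io_formats.write_linkage_map(dataset.markers, paths["linkage_map"])
    io_formats.write_physical_map(dataset.physical_map, paths["physical_map"])
    io_formats.write_fasta(dataset.bes_records, paths["bes_fasta"])
    io_formats.write_fasta(dataset.genome_contig_records, paths["genome_contigs_fasta"])
    io_formats.write_gene_annotation(annotation, paths["annotation"])
    io_formats.write_hits_tabular(dataset.bes_hits, paths["bes_hits"])
    io_formats.write_hits_tabular(dataset.contig_gene_hits, paths["contig_gene_hits"])
    io_formats.write_hits_tabular(dataset.self_hits, paths["self_hits"])
    io_formats.write_hits_tabular(dataset.ref_gene_hits, paths["ref_gene_hits"])
    with open(paths["placements"], "w") as fh:
        fh.write("contig_id\tscaffold\tlinkage_group\n")
        for gcid in sorted(dataset.placements):
            scaf, lg = dataset.placements[gcid]
            fh.write(f"{gcid}\t{scaf}\t{lg}\n")
    paths["truth"].write_text(dataset.truth.to_json())
    return paths


def config_from_dict(data: dict) -> SimConfig:
    """Build a SimConfig from a plain dict (e.g. parsed YAML), tuples restored."""
    kwargs = dict(data)
    for key in ("genes_per_contig_range", "block_length_range", "cluster_gap_bp"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    allowed = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(kwargs) - allowed
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimConfig(**kwargs)
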