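"""Fusion-junction contigs: physical contigs spanning two reference chromosomes.

A BAC contig whose genes fall into syntenic blocks on two *called*
homologous chromosomes (with enough genes on each side) should harbor the
fusion junction of the two ancestral chromosome segments. Mate-pair BES
evidence — one clone whose forward- and reverse-end-linked genes land on the
two different sides — corroborates a junction at sub-contig (clone insert)
scale.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .io_formats import split_bes_id
from .models import BacContig, FusionCandidate, FusionSide, Marker, SyntenyBlock

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIDE_GENES = 2


def find_fusion_contigs(
    blocks: Sequence[SyntenyBlock],
    homology_call,
    min_side_genes: int = DEFAULT_MIN_SIDE_GENES,
) -> list[FusionCandidate]:
    """Identify BAC contigs with blocks on two called homologous chromosomes.

    A contig is a candidate for an (A, B) chromosome pair iff it owns >= 1
    block on each and each side totals >= min_side_genes genes. Contigs
    touching three called chromosomes yield pairwise candidates. Sides are
    ordered by descending gene count, ties broken lexicographically, so the
    candidate set is invariant to side labeling. Fewer than two called
    chromosomes yields an empty result.
    """
    called = list(homology_call.homologous_chromosomes)
    if len(called) < 2:
        return []
    per_contig: dict[str, dict[str, list[SyntenyBlock]]] = defaultdict(lambda: defaultdict(list))
    for b in blocks:
        if b.ref_chromosome in called:
            per_contig[b.bac_contig_id][b.ref_chromosome].append(b)

    candidates: list[FusionCandidate] = []
    for contig_id in sorted(per_contig):
        chrom_blocks = per_contig[contig_id]
        for chrom_a, chrom_b in combinations(sorted(chrom_blocks), 2):
            sides = []
            for chrom in (chrom_a, chrom_b):
                gene_ids: list[str] = []
                for blk in chrom_blocks[chrom]:
                    gene_ids.extend(blk.gene_ids)
                gene_ids = sorted(set(gene_ids))
                sides.append(FusionSide(chromosome=chrom, n_genes=len(gene_ids), gene_ids=tuple(gene_ids)))
            if any(s.n_genes < min_side_genes for s in sides):
                continue
            sides.sort(key=lambda s: (-s.n_genes, s.chromosome))
            candidates.append(
                FusionCandidate(bac_contig_id=contig_id, side_a=sides[0], side_b=sides[1])
            )
    return candidates


def mate_pair_evidence(
    candidates: Iterable[FusionCandidate],
    bes_gene: Mapping[str, str],
    physical_map: Iterable[BacContig],
) -> list[FusionCandidate]:
    """Fill mate_pair_support: clones whose two end-linked genes straddle sides.

    ``bes_gene`` maps a BES id ("clone.end") to the gene its hit genome
    contig was assigned (composed upstream from the BES->contig and
    contig->gene hit chains). A clone supports its contig's candidate when
    its F-linked gene and R-linked gene lie on the two different sides;
    clones with one archived end, or with both genes on one side, do not.
    Candidates without support are still reported, support empty.
    """
    clones_by_contig: dict[str, frozenset[str]] = {
        c.contig_id: c.clone_ids for c in physical_map
    }
    out = []
    for cand in candidates:
        side_a = set(cand.side_a.gene_ids)
        side_b = set(cand.side_b.gene_ids)
        support: list[str] = []
        for clone in sorted(clones_by_contig.get(cand.bac_contig_id, frozenset())):
            gene_f = bes_gene.get(f"{clone}.F")
            gene_r = bes_gene.get(f"{clone}.R")
            if gene_f is None or gene_r is None:
                continue
            pair = {gene_f, gene_r}
            if (gene_f in side_a and gene_r in side_b) or (
                gene_f in side_b and gene_r in side_a
            ):
                support.append(clone)
                logger.info(
                    "mate-pair support for %s: clone %s links %s",
                    cand.bac_contig_id,
                    clone,
                    sorted(pair),
                )
        cand.mate_pair_support = support
        out.append(cand)
    return out


def flag_linkage_corroboration(
    candidates: Iterable[FusionCandidate],
    markers: Iterable[Marker],
    physical_map: Iterable[BacContig],
    lg: str,
) -> list[FusionCandidate]:
    """Set linkage_corroborated when >= 2 of a contig's markers map to ``lg``.

    Stands in for a physical-map re-clustering check: independent genetic
    placements of two clones of the contig on the same linkage group argue
    against a fingerprinting misassembly as the cause of the mixed-chromosome
    signal.
    """
    clone_to_contig: dict[str, str] = {}
    for contig in physical_map:
        for clone in contig.clone_ids:
            clone_to_contig[clone] = contig.contig_id
    marker_count: dict[str, int] = defaultdict(int)
    for m in markers:
        if m.linkage_group == lg and m.clone_id in clone_to_contig:
            marker_count[clone_to_contig[m.clone_id]] += 1
    out = []
    for cand in candidates:
        cand.linkage_corroborated = marker_count.get(cand.bac_contig_id, 0) >= 2
        out.append(cand)
    return out
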