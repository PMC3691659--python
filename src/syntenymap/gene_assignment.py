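"""Gene assignment: anchored genome contigs -> unique gene set + tallies.

Each anchored genome contig is reduced to its single best protein/gene hit
(the funnel 951 contigs -> 287 unique genes implies a one-gene-per-contig
reduction); contigs hitting the same gene merge into one anchor whose
contig, BAC-contig and cM sets accumulate. An optional multi-gene-per-contig
mode keeps every above-threshold hit instead, for contigs that genuinely
span two genes.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable

from .anchoring import DEFAULT_E_MAX, _hit_order
from .models import (
    AnchoredContig,
    ChromosomeTally,
    GeneAnchor,
    GeneAnnotation,
    HomologyHit,
    UNASSIGNED,
)

logger = logging.getLogger(__name__)


def assign_genes(
    anchored_contigs: Iterable[AnchoredContig],
    contig_gene_hits: Iterable[HomologyHit],
    annotation: GeneAnnotation,
    e_max: float = DEFAULT_E_MAX,
    multi_gene_per_contig: bool = False,
) -> list[GeneAnchor]:
    """Assign reference genes to anchored genome contigs and merge by gene.

    ``contig_gene_hits`` are translated hits: query = genome contig id,
    subject = gene id. Per contig the best-bitscore gene is retained (ties:
    lower evalue, then lexicographic gene id) unless multi_gene_per_contig.
    Hits to subjects absent from the annotation are skipped with a warning.
    """
    anchors_by_contig: dict[str, list[AnchoredContig]] = defaultdict(list)
    for ac in anchored_contigs:
        anchors_by_contig[ac.genome_contig_id].append(ac)

    hits_by_contig: dict[str, list[HomologyHit]] = defaultdict(list)
    for hit in contig_gene_hits:
        if hit.evalue > e_max:
            continue
        if hit.query_id not in anchors_by_contig:
            continue
        if hit.subject_id not in annotation:
            logger.warning(
                "hit %s->%s: subject not in annotation, skipped",
                hit.query_id,
                hit.subject_id,
            )
            continue
        hits_by_contig[hit.query_id].append(hit)

    merged: dict[str, GeneAnchor] = {}
    for contig_id in sorted(hits_by_contig):
        hits = sorted(hits_by_contig[contig_id], key=_hit_order)
        if multi_gene_per_contig:
            chosen = _best_per_gene(hits)
        else:
            chosen = [hits[0]]
        for hit in chosen:
            gene_id = hit.subject_id
            anchor = merged.get(gene_id)
            if anchor is None:
                anchor = GeneAnchor(
                    gene_id=gene_id,
                    gene=annotation[gene_id],
                    genome_contig_ids=set(),
                    bac_contig_ids=set(),
                    cM_positions=set(),
                    best_hit=hit,
                )
                merged[gene_id] = anchor
            anchor.genome_contig_ids.add(contig_id)
            for ac in anchors_by_contig[contig_id]:
                anchor.bac_contig_ids.add(ac.bac_contig_id)
                anchor.cM_positions.update(ac.cM_positions)
            if _hit_order(hit) < _hit_order(anchor.best_hit):
                anchor.best_hit = hit
    return [merged[g] for g in sorted(merged)]


def _best_per_gene(hits: list[HomologyHit]) -> list[HomologyHit]:
    best: dict[str, HomologyHit] = {}
    for hit in hits:
        prev = best.get(hit.subject_id)
        if prev is None or _hit_order(hit) < _hit_order(prev):
            best[hit.subject_id] = hit
    return [best[g] for g in sorted(best)]


def classify_multiplicity(
    gene_anchors: Iterable[GeneAnchor],
) -> tuple[list[GeneAnchor], list[GeneAnchor]]:
    """Partition anchors into (single genome contig, multiple contigs)."""
    single = [a for a in gene_anchors if len(a.genome_contig_ids) == 1]
    multi = [a for a in gene_anchors if len(a.genome_contig_ids) > 1]
    return single, multi


def tally_by_chromosome(
    gene_anchors: Iterable[GeneAnchor],
    annotation: GeneAnnotation,
    species: str,
) -> ChromosomeTally:
    """Count each unique gene once under its annotated chromosome.

    Genes on unplaced reference scaffolds are counted under UNASSIGNED; the
    total equals the number of anchors resolvable in this annotation.
    """
    counts: dict[str, int] = defaultdict(int)
    for anchor in gene_anchors:
        if anchor.gene_id not in annotation:
            continue
        counts[annotation[anchor.gene_id].chromosome] += 1
    counts = dict(counts)
    return ChromosomeTally(species=species, counts=counts, total=sum(counts.values()))
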