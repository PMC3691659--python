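"""Microsynteny block detection and homologous-chromosome calling.

A conserved microsynteny block is a set of adjacent reference genes that are
homologous to a set of genes co-located within a single BAC contig of the
target. Because linkage resolution stacks genes, within-block order is taken
from reference coordinates; a contig's genes on one chromosome are split
into maximal runs wherever consecutive reference genes are farther apart
than ``max_gap_bp``.

Homologous chromosomes are the chromosomes with a high number of gene hits,
operationalized as: hit count >= min_fraction x the best chromosome's count,
AND at least min_blocks detected syntenic blocks (a chromosome with many
scattered hits but a single small block is not called — cf. the pufferfish
chromosome-1 exclusion).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .models import (
    ChromosomeEvidence,
    ChromosomeTally,
    GeneAnchor,
    GeneAnnotation,
    HomologyCall,
    SyntenyBlock,
    UNASSIGNED,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_GENES = 2
DEFAULT_MAX_GAP_BP = 3_000_000
DEFAULT_MIN_FRACTION = 0.45
DEFAULT_MIN_BLOCKS = 2


def detect_blocks(
    gene_anchors: Iterable[GeneAnchor],
    annotation: GeneAnnotation,
    min_genes: int = DEFAULT_MIN_GENES,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
) -> list[SyntenyBlock]:
    """Detect conserved microsynteny blocks.

    Genes are grouped by (BAC contig, reference chromosome) — an anchor
    supported by several BAC contigs contributes to each — sorted by
    reference start, and split into maximal runs whose consecutive
    intergenic distances are <= max_gap_bp. Runs shorter than ``min_genes``
    are discarded. Surviving runs are numbered 1..k per (contig,
    chromosome) in chromosome order. Genes on UNASSIGNED scaffolds are
    excluded and counted in a skipped-gene report (logged).
    """
    groups: dict[tuple[str, str], list[GeneAnchor]] = defaultdict(list)
    n_skipped = 0
    for anchor in gene_anchors:
        record = annotation.by_id.get(anchor.gene_id, anchor.gene)
        if record.chromosome == UNASSIGNED:
            n_skipped += 1
            continue
        for bac_contig in anchor.bac_contig_ids:
            groups[(bac_contig, record.chromosome)].append(anchor)
    if n_skipped:
        logger.info("detect_blocks: %d genes on unassigned scaffolds skipped", n_skipped)

    blocks: list[SyntenyBlock] = []
    for (bac_contig, chrom) in sorted(groups):
        genes = sorted(
            groups[(bac_contig, chrom)], key=lambda a: (a.gene.start, a.gene.end, a.gene_id)
        )
        runs: list[list[GeneAnchor]] = [[genes[0]]]
        for prev, cur in zip(genes, genes[1:]):
            if cur.gene.start - prev.gene.end > max_gap_bp:
                runs.append([cur])
            else:
                runs[-1].append(cur)
        surviving = [run for run in runs if len(run) >= min_genes]
        for occurrence, run in enumerate(surviving, start=1):
            span = run[-1].gene.end - run[0].gene.start + 1
            blocks.append(
                SyntenyBlock(
                    bac_contig_id=bac_contig,
                    occurrence=occurrence,
                    ref_chromosome=chrom,
                    genes=tuple(run),
                    span_bp=span,
                    gaps_bp=tuple(intergenic_gaps_of(run)),
                )
            )
    blocks.sort(key=lambda b: (b.ref_chromosome, b.genes[0].gene.start, b.bac_contig_id))
    return blocks


def intergenic_gaps_of(genes: Sequence[GeneAnchor]) -> list[int]:
    """Intergenic spaces (gene sizes excluded) between consecutive genes.

    gap_i = start_{i+1} - end_i; overlapping genes yield 0 with a warning.
    """
    gaps: list[int] = []
    for prev, cur in zip(genes, genes[1:]):
        gap = cur.gene.start - prev.gene.end
        if gap < 0:
            logger.warning(
                "overlapping genes %s and %s: gap clamped to 0",
                prev.gene_id,
                cur.gene_id,
            )
            gap = 0
        gaps.append(gap)
    return gaps


def intergenic_gaps(block: SyntenyBlock) -> list[int]:
    """Intergenic gaps of a block, recomputed from its genes."""
    return intergenic_gaps_of(block.genes)


def _round_half_away(x: float) -> int:
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


@dataclass
class BlockSummary:
    """Per-block rows plus the totals a summary table prints."""

    table: pd.DataFrame  # columns: block, contig, n_genes, span_kb
    n_contigs: int
    total_genes: int
    total_span_kb: int


def block_summary(blocks: Sequence[SyntenyBlock]) -> BlockSummary:
    """Summarize blocks the way the comparison tables print them.

    One row per block in input order: contig label (with " (k)" suffix only
    when the contig splits into several blocks on that chromosome), gene
    count, span in kb rounded half-away-from-zero. Totals: number of
    distinct contigs, total genes, and the sum of the rounded kb spans.
    """
    k_per_contig: dict[tuple[str, str], int] = defaultdict(int)
    for b in blocks:
        k_per_contig[(b.bac_contig_id, b.ref_chromosome)] += 1
    rows = []
    for i, b in enumerate(blocks, start=1):
        split = k_per_contig[(b.bac_contig_id, b.ref_chromosome)] > 1
        rows.append(
            {
                "block": i,
                "contig": b.label(split),
                "n_genes": b.n_genes,
                "span_kb": _round_half_away(b.span_bp / 1000),
            }
        )
    table = pd.DataFrame(rows, columns=["block", "contig", "n_genes", "span_kb"])
    n_contigs = len({b.bac_contig_id for b in blocks})
    total_genes = int(table["n_genes"].sum()) if rows else 0
    total_span = int(table["span_kb"].sum()) if rows else 0
    return BlockSummary(
        table=table,
        n_contigs=n_contigs,
        total_genes=total_genes,
        total_span_kb=total_span,
    )


def call_homologous_chromosomes(
    tally: ChromosomeTally,
    blocks: Sequence[SyntenyBlock],
    min_fraction: float = DEFAULT_MIN_FRACTION,
    min_blocks: int = DEFAULT_MIN_BLOCKS,
) -> HomologyCall:
    """Call the chromosomes homologous to the linkage group.

    A chromosome is called iff its gene-hit count is >= min_fraction of the
    best chromosome's count and it carries >= min_blocks syntenic blocks.
    Evidence is recorded for every chromosome, called or not; UNASSIGNED is
    tallied but never a call candidate. The called list is ordered by
    descending hit count.
    """
    block_stats: dict[str, list[SyntenyBlock]] = defaultdict(list)
    for b in blocks:
        block_stats[b.ref_chromosome].append(b)

    evidence: dict[str, ChromosomeEvidence] = {}
    chroms = set(tally.counts) | set(block_stats)
    for chrom in sorted(chroms):
        chrom_blocks = block_stats.get(chrom, [])
        evidence[chrom] = ChromosomeEvidence(
            hit_count=tally.counts.get(chrom, 0),
            n_blocks=len(chrom_blocks),
            max_block_genes=max((b.n_genes for b in chrom_blocks), default=0),
        )

    candidates = {c for c in chroms if c != UNASSIGNED}
    if not candidates:
        return HomologyCall(species=tally.species, homologous_chromosomes=[], evidence=evidence)
    max_hits = max(evidence[c].hit_count for c in candidates)
    called = [
        c
        for c in candidates
        if evidence[c].hit_count >= min_fraction * max_hits
        and evidence[c].n_blocks >= min_blocks
    ]
    called.sort(key=lambda c: (-evidence[c].hit_count, c))
    for c in sorted(candidates, key=lambda c: (-evidence[c].hit_count, c)):
        logger.info(
            "homolog call %s %s: hits=%d blocks=%d max_block=%d -> %s",
            tally.species,
            c,
            evidence[c].hit_count,
            evidence[c].n_blocks,
            evidence[c].max_block_genes,
            "CALLED" if c in called else "not called",
        )
    return HomologyCall(
        species=tally.species, homologous_chromosomes=called, evidence=evidence
    )
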