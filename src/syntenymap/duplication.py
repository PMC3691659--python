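"""Duplicated-gene identification and classification.

The funnel: genes hit by multiple genome contigs -> genes whose contigs hit
*overlapping* regions of the gene (same region twice = two gene copies;
non-overlapping regions = different exons of one split gene) -> contig-pair
alignment check discarding pairs that are near-identical along their whole
length (unmerged assembly duplicates, not biology). Survivors are classified
intra- vs inter-chromosomal from scaffold/linkage-group placements, and
checked for duplication in the reference genome via a high-stringency
reference hit table.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .anchoring import DEFAULT_E_MAX, _hit_order
from .models import DuplicationCall, GeneAnchor, GeneAnnotation, HomologyHit

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP_BP = 100
DEFAULT_MIN_ALN_LEN = 100
DEFAULT_MIN_REF_SCORE = 1000.0
DEFAULT_REDUNDANCY_FRACTION = 0.9
AMBIGUOUS_COVERAGE = 0.5


@dataclass
class DuplicationCandidate:
    """A gene hit by >= 2 genome contigs, with all qualifying hits."""

    gene_id: str
    contig_ids: tuple[str, ...]
    hits: tuple[HomologyHit, ...]
    best_pair: tuple[str, str] | None = None
    best_overlap_bp: int = 0


@dataclass
class OverlapScreenResult:
    overlapping: list[DuplicationCandidate] = field(default_factory=list)
    split_gene: list[DuplicationCandidate] = field(default_factory=list)


def find_multi_contig_genes(
    gene_anchors: Iterable[GeneAnchor],
    contig_gene_hits: Iterable[HomologyHit],
    e_max: float = DEFAULT_E_MAX,
) -> list[DuplicationCandidate]:
    """Genes whose significant hit set spans >= 2 genome contigs.

    All hits at or below ``e_max`` count, regardless of the best-hit
    reduction used for gene assignment: duplication detection must see every
    genomic region similar to the gene.
    """
    anchored_genes = {a.gene_id for a in gene_anchors}
    by_gene: dict[str, list[HomologyHit]] = defaultdict(list)
    for hit in contig_gene_hits:
        if hit.evalue > e_max:
            continue
        if hit.subject_id in anchored_genes:
            by_gene[hit.subject_id].append(hit)
    out: list[DuplicationCandidate] = []
    for gene_id in sorted(by_gene):
        hits = sorted(by_gene[gene_id], key=_hit_order)
        contigs = tuple(sorted({h.query_id for h in hits}))
        if len(contigs) >= 2:
            out.append(DuplicationCandidate(gene_id=gene_id, contig_ids=contigs, hits=hits))
    return out


def _pair_overlap(hits_a: Sequence[HomologyHit], hits_b: Sequence[HomologyHit]) -> int:
    """Max overlap (bp) between any subject intervals of the two contigs."""
    best = 0
    for ha in hits_a:
        for hb in hits_b:
            ov = min(ha.s_end, hb.s_end) - max(ha.s_start, hb.s_start) + 1
            best = max(best, ov)
    return best


def overlap_screen(
    candidates: Iterable[DuplicationCandidate],
    min_overlap_bp: int = DEFAULT_MIN_OVERLAP_BP,
) -> OverlapScreenResult:
    """Split multi-contig genes into overlapping (duplication-like) vs split.

    Overlap is measured on the gene's own coordinate system (the subject
    intervals of the contig->gene hits): two contigs matching the *same*
    stretch of the gene by >= min_overlap_bp look like two copies; contigs
    matching disjoint stretches look like exons of one gene split across
    draft contigs. The result is symmetric in contig order.
    """
    result = OverlapScreenResult()
    for cand in candidates:
        by_contig: dict[str, list[HomologyHit]] = defaultdict(list)
        for h in cand.hits:
            by_contig[h.query_id].append(h)
        best_pair, best_ov = None, 0
        for ca, cb in combinations(sorted(by_contig), 2):
            ov = _pair_overlap(by_contig[ca], by_contig[cb])
            if ov > best_ov:
                best_pair, best_ov = (ca, cb), ov
        if best_pair is not None and best_ov >= min_overlap_bp:
            cand.best_pair = best_pair
            cand.best_overlap_bp = best_ov
            result.overlapping.append(cand)
        else:
            result.split_gene.append(cand)
    return result


def _pair_coverage(
    contig_a: str,
    contig_b: str,
    self_hits_by_pair: Mapping[tuple[str, str], list[HomologyHit]],
    contig_lengths: Mapping[str, int],
    min_len: int,
    e_max: float,
) -> float:
    """Fraction of the shorter contig covered by qualifying mutual alignments."""
    short = contig_a if contig_lengths[contig_a] <= contig_lengths[contig_b] else contig_b
    short_len = contig_lengths[short]
    intervals: list[tuple[int, int]] = []
    for qa, qb in ((contig_a, contig_b), (contig_b, contig_a)):
        for hit in self_hits_by_pair.get((qa, qb), ()):
            if hit.aln_length < min_len or hit.evalue > e_max:
                continue
            iv = (hit.q_start, hit.q_end) if qa == short else (hit.s_start, hit.s_end)
            intervals.append(iv)
    if not intervals:
        return 0.0
    intervals.sort()
    covered, cur_s, cur_e = 0, *intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e + 1:
            covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s + 1
    return covered / short_len


def contig_pair_check(
    candidates: Iterable[DuplicationCandidate],
    self_hits: Iterable[HomologyHit],
    contig_lengths: Mapping[str, int],
    min_len: int = DEFAULT_MIN_ALN_LEN,
    e_max: float = DEFAULT_E_MAX,
    redundancy_fraction: float = DEFAULT_REDUNDANCY_FRACTION,
) -> list[DuplicationCall]:
    """Drop contig pairs that are redundant copies; emit duplication calls.

    Two contigs both matching the gene region could be one locus assembled
    twice. The pair's mutual alignments (>= min_len bp, <= e_max, from the
    contig-vs-contig self search) are merged on the shorter contig; coverage
    >= redundancy_fraction drops the candidate as an assembly duplicate,
    coverage in [0.5, redundancy_fraction) is flagged ``ambiguous`` but
    kept, below that the pair is accepted as two distinct loci. A candidate
    whose contigs never appear in the self-hit search is kept flagged
    ``uncheckable``.
    """
    self_hits = list(self_hits)
    by_pair: dict[tuple[str, str], list[HomologyHit]] = defaultdict(list)
    searched: set[str] = set()
    for hit in self_hits:
        searched.add(hit.query_id)
        if hit.query_id != hit.subject_id:
            by_pair[(hit.query_id, hit.subject_id)].append(hit)

    calls: list[DuplicationCall] = []
    for cand in candidates:
        if cand.best_pair is None:
            continue
        ca, cb = cand.best_pair
        flags: list[str] = []
        if ca not in searched and cb not in searched:
            logger.warning(
                "gene %s: contigs %s/%s absent from self-hit search, uncheckable",
                cand.gene_id,
                ca,
                cb,
            )
            flags.append("uncheckable")
        else:
            coverage = _pair_coverage(ca, cb, by_pair, contig_lengths, min_len, e_max)
            if coverage >= redundancy_fraction:
                logger.info(
                    "gene %s: pair %s/%s redundant (coverage %.2f), dropped",
                    cand.gene_id,
                    ca,
                    cb,
                    coverage,
                )
                continue
            if coverage >= AMBIGUOUS_COVERAGE:
                flags.append("ambiguous")
        calls.append(
            DuplicationCall(
                gene_id=cand.gene_id,
                supporting_contig_pair=(ca, cb),
                overlap_bp=cand.best_overlap_bp,
                flags=tuple(flags),
            )
        )
    return calls


def classify_nature(
    calls: Iterable[DuplicationCall],
    contig_placements: Mapping[str, tuple[str | None, str | None]],
) -> list[DuplicationCall]:
    """Classify each call intra- vs inter-chromosomal from placements.

    ``contig_placements`` maps genome contig -> (scaffold, linkage group).
    Same scaffold, or both placed on one linkage group -> intra_chr (tandem
    or intra-chromosomal). Different scaffolds mapped to different linkage
    groups -> inter_chr. Anything unplaced -> unplaced.
    """
    out = []
    for call in calls:
        ca, cb = call.supporting_contig_pair
        scaf_a, lg_a = contig_placements.get(ca, (None, None))
        scaf_b, lg_b = contig_placements.get(cb, (None, None))
        if scaf_a is not None and scaf_a == scaf_b:
            call.nature = "intra_chr"
        elif lg_a is not None and lg_b is not None:
            call.nature = "intra_chr" if lg_a == lg_b else "inter_chr"
        else:
            call.nature = "unplaced"
        out.append(call)
    return out


def ref_duplication_check(
    calls: Iterable[DuplicationCall],
    ref_annotation: GeneAnnotation,
    ref_self_hits: Iterable[HomologyHit],
    min_score: float = DEFAULT_MIN_REF_SCORE,
) -> list[DuplicationCall]:
    """Flag genes also duplicated in the reference genome.

    ``ref_self_hits`` are high-stringency hits of each duplicated gene back
    to the reference genome: query = gene id, subject = reference
    chromosome, subject interval = locus coordinates. A gene is
    ref_duplicated iff >= 2 distinct loci reach ``min_score``; the top two
    loci (by score) are recorded with coordinates.
    """
    by_gene: dict[str, list[HomologyHit]] = defaultdict(list)
    for hit in ref_self_hits:
        by_gene[hit.query_id].append(hit)
    out = []
    for call in calls:
        loci: list[tuple[float, str, int, int]] = []
        for hit in sorted(by_gene.get(call.gene_id, ()), key=_hit_order):
            if hit.bitscore < min_score:
                continue
            candidate = (hit.bitscore, hit.subject_id, hit.s_start, hit.s_end)
            if not any(_same_locus(candidate, kept) for kept in loci):
                loci.append(candidate)
        call.ref_duplicated = len(loci) >= 2
        call.ref_locations = tuple((c, s, e) for _, c, s, e in loci[:2])
        if not call.ref_duplicated:
            call.ref_locations = tuple((c, s, e) for _, c, s, e in loci[:1])
        out.append(call)
    return out


def _same_locus(a: tuple[float, str, int, int], b: tuple[float, str, int, int]) -> bool:
    """Two hits describe one locus when they overlap on the same chromosome."""
    _, chrom_a, sa, ea = a
    _, chrom_b, sb, eb = b
    return chrom_a == chrom_b and min(ea, eb) - max(sa, sb) + 1 > 0
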