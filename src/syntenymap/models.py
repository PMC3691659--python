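"""Typed records shared by every pipeline stage.

Coordinate convention throughout: 1-based, inclusive, base pairs, on the
reference forward strand. Reverse-strand hits are normalized at parse time
and flagged via ``subject_reversed``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

#: Reserved chromosome token for reference genes not placed on any chromosome.
UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class Marker:
    """A genetically mapped, BAC-end-derived microsatellite marker."""

    marker_id: str
    linkage_group: str
    position_cM: float
    clone_id: str
    end: str  # "F" or "R"

    def __post_init__(self) -> None:
        if self.position_cM < 0:
            raise ValueError(f"marker {self.marker_id}: negative cM position")
        if self.end not in ("F", "R"):
            raise ValueError(f"marker {self.marker_id}: end must be F or R")


@dataclass(frozen=True)
class BacContig:
    """A physical-map contig: a fingerprint-assembled group of BAC clones."""

    contig_id: str
    clone_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.clone_ids:
            raise ValueError(f"BAC contig {self.contig_id} has no clones")


@dataclass(frozen=True)
class HomologyHit:
    """One BLAST-style tabular hit, coordinates normalized to q_start <= q_end."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    mismatch: int = 0
    gapopen: int = 0
    subject_reversed: bool = False

    def __post_init__(self) -> None:
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: unnormalized interval"
            )
        if self.evalue < 0 or self.bitscore < 0:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: negative evalue/bitscore"
            )


@dataclass(frozen=True)
class GeneRecord:
    """A reference gene: id, chromosome (may be UNASSIGNED), 1-based span."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.start <= 0:
            raise ValueError(f"gene {self.gene_id}: coordinates are 1-based")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class GeneAnnotation:
    """Reference gene set indexed by id and by chromosome (position-sorted).

    UNASSIGNED genes are kept and reachable by id but excluded from the
    per-chromosome indices, mirroring how unplaced scaffolds are tallied
    separately and never enter block detection.
    """

    def __init__(self, genes: list[GeneRecord]):
        self.by_id: dict[str, GeneRecord] = {}
        for g in genes:
            if g.gene_id in self.by_id:
                raise ValueError(f"duplicate gene id {g.gene_id}")
            self.by_id[g.gene_id] = g
        self.by_chromosome: dict[str, list[GeneRecord]] = {}
        for g in genes:
            if g.chromosome == UNASSIGNED:
                continue
            self.by_chromosome.setdefault(g.chromosome, []).append(g)
        for chrom in self.by_chromosome:
            self.by_chromosome[chrom].sort(key=lambda g: (g.start, g.end, g.gene_id))

    def __len__(self) -> int:
        return len(self.by_id)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.by_id

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self.by_id[gene_id]

    def genes(self) -> list[GeneRecord]:
        return list(self.by_id.values())

    def neighbors(self, gene: GeneRecord) -> tuple[GeneRecord | None, GeneRecord | None]:
        """Flanking genes on the same chromosome, by start position."""
        chrom = self.by_chromosome.get(gene.chromosome, [])
        starts = [g.start for g in chrom]
        i = bisect.bisect_left(starts, gene.start)
        left = chrom[i - 1] if i > 0 else None
        right = chrom[i + 1] if i + 1 < len(chrom) else None
        return left, right


@dataclass
class MappedBacContig:
    """A BAC contig pulled onto a linkage group by its mapped markers.

    When one end sequence of one clone maps genetically, the whole contig
    inherits the position: the contig carries the full cM set of all its
    mapped markers (stacked positions are real, not an error).
    """

    contig: BacContig
    markers: list[Marker] = field(default_factory=list)

    @property
    def contig_id(self) -> str:
        return self.contig.contig_id

    @property
    def cM_positions(self) -> frozenset[float]:
        return frozenset(m.position_cM for m in self.markers)


@dataclass
class AnchoredContig:
    """A draft genome contig anchored to a BAC contig by a filtered BES hit."""

    genome_contig_id: str
    bac_contig_id: str
    best_bes_hit: HomologyHit
    cM_positions: frozenset[float]
    supports: tuple[HomologyHit, ...] = ()


@dataclass
class GeneAnchor:
    """A unique reference gene anchored to the linkage group.

    Accumulates every genome contig and BAC contig that supports it; the
    cM set is the union over supporting BAC contigs (no averaging — linkage
    resolution genuinely stacks genes).
    """

    gene_id: str
    gene: GeneRecord
    genome_contig_ids: set[str]
    bac_contig_ids: set[str]
    cM_positions: set[float]
    best_hit: HomologyHit


@dataclass
class ChromosomeTally:
    """Per-chromosome counts of unique gene hits for one reference species."""

    species: str
    counts: dict[str, int]
    total: int

    def __post_init__(self) -> None:
        if self.total != sum(self.counts.values()):
            raise ValueError("tally total does not equal sum of counts")


@dataclass
class SyntenyBlock:
    """A conserved microsynteny block.

    An ordered run of anchored genes that co-locate in one BAC contig of the
    target and within one bounded segment of one reference chromosome.
    ``occurrence`` numbers split contigs 1..k in chromosome order, matching
    the "ctgNNNN (k)" table convention.
    """

    bac_contig_id: str
    occurrence: int
    ref_chromosome: str
    genes: tuple[GeneAnchor, ...]
    span_bp: int
    gaps_bp: tuple[int, ...]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.genes)

    def label(self, split: bool) -> str:
        return f"{self.bac_contig_id} ({self.occurrence})" if split else self.bac_contig_id


@dataclass(frozen=True)
class ChromosomeEvidence:
    """Evidence backing (or failing) a homologous-chromosome call."""

    hit_count: int
    n_blocks: int
    max_block_genes: int


@dataclass
class HomologyCall:
    """Chromosomes of one reference species called homologous to the LG."""

    species: str
    homologous_chromosomes: list[str]
    evidence: dict[str, ChromosomeEvidence]


@dataclass(frozen=True)
class FusionSide:
    chromosome: str
    n_genes: int
    gene_ids: tuple[str, ...]


@dataclass
class FusionCandidate:
    """A BAC contig whose genes fall on two homologous reference chromosomes,
    evidencing an evolutionary fusion junction inside the contig."""

    bac_contig_id: str
    side_a: FusionSide
    side_b: FusionSide
    mate_pair_support: list[str] = field(default_factory=list)
    linkage_corroborated: bool = False


@dataclass
class DuplicationCall:
    """A gene judged duplicated in the target genome."""

    gene_id: str
    supporting_contig_pair: tuple[str, str]
    overlap_bp: int
    nature: str = "unplaced"  # intra_chr | inter_chr | unplaced
    ref_duplicated: bool = False
    ref_locations: tuple[tuple[str, int, int], ...] = ()
    flags: tuple[str, ...] = ()
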