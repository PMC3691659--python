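"""Anchoring chain: mapped markers -> BAC contigs -> BESs -> genome contigs.

The core idea: when one end sequence of one BAC clone is genetically mapped,
the entire fingerprint contig is mapped, so every end sequence of every
clone in that contig inherits the linkage position. Those end sequences then
pull draft genome contigs onto the linkage group through filtered
nucleotide hits (E-value and bit-score thresholds).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Mapping

from .models import AnchoredContig, BacContig, HomologyHit, MappedBacContig, Marker
from .io_formats import split_bes_id

logger = logging.getLogger(__name__)

DEFAULT_E_MAX = 1e-10
DEFAULT_BIT_MIN = 400.0


def contigs_for_linkage_group(
    markers: Iterable[Marker],
    physical_map: Iterable[BacContig],
    lg: str,
) -> list[MappedBacContig]:
    """Return every BAC contig containing >= 1 clone of an lg-mapped marker.

    Each returned contig is annotated with all of its markers' cM values.
    Markers whose clone is not in the physical map are skipped with a
    warning; an absent linkage group yields an empty result, not an error.
    """
    clone_to_contig: dict[str, BacContig] = {}
    for contig in physical_map:
        for clone in contig.clone_ids:
            clone_to_contig[clone] = contig

    by_contig: dict[str, MappedBacContig] = {}
    n_lg_markers = 0
    for marker in markers:
        if marker.linkage_group != lg:
            continue
        n_lg_markers += 1
        contig = clone_to_contig.get(marker.clone_id)
        if contig is None:
            logger.warning(
                "marker %s: clone %s not in physical map, skipped",
                marker.marker_id,
                marker.clone_id,
            )
            continue
        mapped = by_contig.setdefault(contig.contig_id, MappedBacContig(contig=contig))
        mapped.markers.append(marker)
    if n_lg_markers == 0:
        logger.warning("linkage group %s has no markers in the map", lg)
    return [by_contig[cid] for cid in sorted(by_contig)]


def collect_bes(
    bac_contigs: Iterable[MappedBacContig],
    bes_index: Mapping[str, set[str]],
) -> list[str]:
    """Union of all archived BES ids over all clones of the given contigs.

    ``bes_index`` maps clone_id -> available ends; clones with no archived
    end sequence contribute nothing.
    """
    bes_ids: set[str] = set()
    for mapped in bac_contigs:
        for clone in mapped.contig.clone_ids:
            for end in bes_index.get(clone, ()):
                bes_ids.add(f"{clone}.{end}")
    return sorted(bes_ids)


def anchor_genome_contigs(
    bes_hits: Iterable[HomologyHit],
    mapped_contigs: Iterable[MappedBacContig],
    e_max: float = DEFAULT_E_MAX,
    bit_min: float = DEFAULT_BIT_MIN,
) -> list[AnchoredContig]:
    """Filter BES->genome-contig hits and anchor surviving genome contigs.

    Hits failing either threshold (evalue > e_max or bitscore < bit_min) are
    discarded. Per (BES, genome contig) only the best hit is kept
    (higher bitscore, then lower evalue, then lexicographic subject id).
    Each surviving genome contig is reported once per supporting BAC contig,
    carrying that contig's inherited cM set; a genome contig hit by BESs
    from two different BAC contigs is kept under both with a logged
    conflict, preserving the evidence for downstream inspection.
    """
    clone_to_mapped: dict[str, MappedBacContig] = {}
    for mapped in mapped_contigs:
        for clone in mapped.contig.clone_ids:
            clone_to_mapped[clone] = mapped

    # best hit per (BES, genome contig)
    best: dict[tuple[str, str], HomologyHit] = {}
    for hit in bes_hits:
        if hit.evalue > e_max or hit.bitscore < bit_min:
            continue
        clone, _end = split_bes_id(hit.query_id)
        if not clone or clone not in clone_to_mapped:
            logger.warning("hit from unknown BES %s skipped", hit.query_id)
            continue
        key = (hit.query_id, hit.subject_id)
        prev = best.get(key)
        if prev is None or _hit_order(hit) < _hit_order(prev):
            best[key] = hit

    # group surviving supports by (genome contig, BAC contig)
    grouped: dict[tuple[str, str], list[HomologyHit]] = defaultdict(list)
    for (bes_id, genome_contig), hit in best.items():
        clone, _ = split_bes_id(bes_id)
        mapped = clone_to_mapped[clone]
        grouped[(genome_contig, mapped.contig_id)].append(hit)

    bacs_per_genome_contig: dict[str, set[str]] = defaultdict(set)
    for genome_contig, bac_contig in grouped:
        bacs_per_genome_contig[genome_contig].add(bac_contig)
    for genome_contig, bacs in bacs_per_genome_contig.items():
        if len(bacs) > 1:
            logger.warning(
                "genome contig %s supported by BESs of multiple BAC contigs: %s",
                genome_contig,
                ", ".join(sorted(bacs)),
            )

    mapped_by_id = {m.contig_id: m for m in clone_to_mapped.values()}
    anchored: list[AnchoredContig] = []
    for (genome_contig, bac_contig) in sorted(grouped):
        supports = sorted(grouped[(genome_contig, bac_contig)], key=_hit_order)
        anchored.append(
            AnchoredContig(
                genome_contig_id=genome_contig,
                bac_contig_id=bac_contig,
                best_bes_hit=supports[0],
                cM_positions=mapped_by_id[bac_contig].cM_positions,
                supports=tuple(supports),
            )
        )
    return anchored


def _hit_order(hit: HomologyHit) -> tuple:
    """Deterministic preference order: higher bitscore, lower evalue, then id."""
    return (-hit.bitscore, hit.evalue, hit.subject_id, hit.query_id)
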