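"""Comparative-map text output in a MapChart-compatible layout.

One chart file per called reference chromosome (loci = genes, positions in
Mb with two decimals) plus one central linkage-group file (loci = BAC
contigs at their minimum marker cM, one decimal). Marker color classes
encode homologous-chromosome membership: one class per single chromosome
plus a "both" class for contigs whose genes hit two called chromosomes —
these are the fusion-junction candidates on the drawn map.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

from .models import GeneAnchor, HomologyCall, SyntenyBlock

#: MapChart label color codes, cycled over called chromosomes; "both" is last.
_CLASS_COLORS = ["green", "red", "orange"]
_BOTH_COLOR = "blue"


def write_comparative_map(
    gene_anchors: Iterable[GeneAnchor],
    blocks: Sequence[SyntenyBlock],
    homology_call: HomologyCall,
    out: str | Path,
    lg: str = "LG8",
) -> list[Path]:
    """Emit MapChart-style .mct files under ``out`` (a directory prefix).

    Returns the written paths. With no blocks, files are header-only.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    called = list(homology_call.homologous_chromosomes)
    class_of = {c: _CLASS_COLORS[i % len(_CLASS_COLORS)] for i, c in enumerate(called)}

    anchors = list(gene_anchors)
    written: list[Path] = []

    # one chart per called chromosome: genes at Mb positions
    for chrom in called:
        path = out / f"chr_{chrom}.mct"
        lines = [f"group {chrom}"]
        genes = sorted(
            (a for a in anchors if a.gene.chromosome == chrom),
            key=lambda a: a.gene.start,
        )
        for a in genes:
            lines.append(f"{a.gene_id}\t{a.gene.start / 1e6:.2f}")
        path.write_text("\n".join(lines) + "\n")
        written.append(path)

    # central linkage-group chart: contigs at min cM, color-classed
    contig_chroms: dict[str, set[str]] = defaultdict(set)
    for b in blocks:
        if b.ref_chromosome in called:
            contig_chroms[b.bac_contig_id].add(b.ref_chromosome)
    contig_cm: dict[str, float] = {}
    for a in anchors:
        for bac in a.bac_contig_ids:
            if a.cM_positions:
                low = min(a.cM_positions)
                contig_cm[bac] = min(contig_cm.get(bac, low), low)
    lines = [f"group {lg}"]
    for bac in sorted(contig_chroms, key=lambda c: (contig_cm.get(c, 0.0), c)):
        chroms = contig_chroms[bac]
        color = _BOTH_COLOR if len(chroms) > 1 else class_of[next(iter(chroms))]
        cm = contig_cm.get(bac, 0.0)
        lines.append(f"{bac}\t{cm:.1f}\tC{color}")
    path = out / f"lg_{lg}.mct"
    path.write_text("\n".join(lines) + "\n")
    written.append(path)
    return written
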