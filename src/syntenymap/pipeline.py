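"""End-to-end orchestration: anchor -> genes -> tally -> blocks -> homologs
-> fusions -> duplications, per reference species, with TSV outputs and a
run manifest recording thresholds and per-stage counts (the funnels).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import io_formats
from .anchoring import (
    DEFAULT_BIT_MIN,
    DEFAULT_E_MAX,
    anchor_genome_contigs,
    collect_bes,
    contigs_for_linkage_group,
    _hit_order,
)
from .duplication import (
    DEFAULT_MIN_ALN_LEN,
    DEFAULT_MIN_OVERLAP_BP,
    DEFAULT_MIN_REF_SCORE,
    DEFAULT_REDUNDANCY_FRACTION,
    classify_nature,
    contig_pair_check,
    find_multi_contig_genes,
    overlap_screen,
    ref_duplication_check,
)
from .errors import StageError
from .fusion import (
    DEFAULT_MIN_SIDE_GENES,
    find_fusion_contigs,
    flag_linkage_corroboration,
    mate_pair_evidence,
)
from .gene_assignment import assign_genes, classify_multiplicity, tally_by_chromosome
from .maps import write_comparative_map
from .models import GeneAnnotation, GeneRecord, HomologyHit
from .synteny import (
    DEFAULT_MAX_GAP_BP,
    DEFAULT_MIN_BLOCKS,
    DEFAULT_MIN_FRACTION,
    DEFAULT_MIN_GENES,
    block_summary,
    call_homologous_chromosomes,
    detect_blocks,
)

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    e_max: float = DEFAULT_E_MAX
    bit_min: float = DEFAULT_BIT_MIN
    min_genes: int = DEFAULT_MIN_GENES
    max_gap_bp: int = DEFAULT_MAX_GAP_BP
    min_fraction: float = DEFAULT_MIN_FRACTION
    min_blocks: int = DEFAULT_MIN_BLOCKS
    min_side_genes: int = DEFAULT_MIN_SIDE_GENES
    min_overlap_bp: int = DEFAULT_MIN_OVERLAP_BP
    min_len: int = DEFAULT_MIN_ALN_LEN
    min_score: float = DEFAULT_MIN_REF_SCORE
    redundancy_fraction: float = DEFAULT_REDUNDANCY_FRACTION


@dataclass
class SpeciesInput:
    name: str
    annotation_path: Path
    gene_hits_path: Path


@dataclass
class PipelineConfig:
    """File-based configuration mirroring the run.yaml layout field-for-field."""

    linkage_map: Path
    physical_map: Path
    bes_fasta: Path
    genome_contigs_fasta: Path
    bes_hits: Path
    species: list[SpeciesInput]
    lg: str = "LG8"
    self_hits: Path | None = None
    ref_gene_hits: Path | None = None
    placements: Path | None = None
    outdir: Path | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        thresholds = Thresholds(**raw.pop("thresholds", {}))
        species = [
            SpeciesInput(
                name=s["name"],
                annotation_path=Path(s["annotation"]),
                gene_hits_path=Path(s["gene_hits"]),
            )
            for s in raw.pop("species")
        ]
        paths = {
            k: Path(v) if v is not None and k not in ("lg", "seed", "log_level") else v
            for k, v in raw.items()
        }
        return cls(species=species, thresholds=thresholds, **paths)

    def validate_paths(self) -> None:
        required = [self.linkage_map, self.physical_map, self.bes_fasta,
                    self.genome_contigs_fasta, self.bes_hits]
        required += [s.annotation_path for s in self.species]
        required += [s.gene_hits_path for s in self.species]
        for p in (self.self_hits, self.ref_gene_hits, self.placements):
            if p is not None:
                required.append(p)
        missing = [str(p) for p in required if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


@dataclass
class SpeciesResult:
    name: str
    gene_anchors: list
    tally: object
    blocks: list
    summary: object
    homology_call: object
    fusion_candidates: list


@dataclass
class PipelineResult:
    mapped_contigs: list
    bes_ids: list[str]
    anchored: list
    species: dict[str, SpeciesResult]
    duplication_calls: list
    split_genes: list
    multi_contig_candidates: list
    manifest: dict


def run_stages(
    markers,
    physical_map,
    bes_index: Mapping[str, set[str]],
    bes_hits: list[HomologyHit],
    species_inputs: list[tuple[str, GeneAnnotation, list[HomologyHit]]],
    lg: str = "LG8",
    self_hits: list[HomologyHit] | None = None,
    contig_lengths: Mapping[str, int] | None = None,
    ref_gene_hits: list[HomologyHit] | None = None,
    extra_placements: Mapping[str, tuple[str, str]] | None = None,
    thresholds: Thresholds | None = None,
) -> PipelineResult:
    """Run the full chain on in-memory inputs.

    ``species_inputs`` is a list of (name, annotation, contig->gene hits);
    the first species drives the duplication analysis. Errors abort with
    the stage name attached.
    """
    th = thresholds or Thresholds()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, str(exc)) from exc

    mapped = stage("anchor", contigs_for_linkage_group, markers, physical_map, lg)
    bes_ids = stage("anchor", collect_bes, mapped, bes_index)
    anchored = stage(
        "anchor", anchor_genome_contigs, bes_hits, mapped,
        e_max=th.e_max, bit_min=th.bit_min,
    )
    passing = [h for h in bes_hits if h.evalue <= th.e_max and h.bitscore >= th.bit_min]
    n_bes_with_hits = len({h.query_id for h in passing} & set(bes_ids))

    species_results: dict[str, SpeciesResult] = {}
    for name, annotation, gene_hits in species_inputs:
        anchors = stage("genes", assign_genes, anchored, gene_hits, annotation, e_max=th.e_max)
        tally = stage("tally", tally_by_chromosome, anchors, annotation, name)
        blocks = stage(
            "blocks", detect_blocks, anchors, annotation,
            min_genes=th.min_genes, max_gap_bp=th.max_gap_bp,
        )
        summary = stage("blocks", block_summary, blocks)
        call = stage(
            "homologs", call_homologous_chromosomes, tally, blocks,
            min_fraction=th.min_fraction, min_blocks=th.min_blocks,
        )
        fusions = stage(
            "fusions", find_fusion_contigs, blocks, call, min_side_genes=th.min_side_genes
        )
        bes_gene = _compose_bes_gene(bes_hits, anchored, anchors, th)
        fusions = stage("fusions", mate_pair_evidence, fusions, bes_gene, physical_map)
        fusions = stage(
            "fusions", flag_linkage_corroboration, fusions, markers, physical_map, lg
        )
        species_results[name] = SpeciesResult(
            name=name, gene_anchors=anchors, tally=tally, blocks=blocks,
            summary=summary, homology_call=call, fusion_candidates=fusions,
        )

    # duplication funnel on the first species
    dup_calls, split_genes, multi = [], [], []
    if species_inputs:
        name, annotation, gene_hits = species_inputs[0]
        anchors = species_results[name].gene_anchors
        multi = stage("duplications", find_multi_contig_genes, anchors, gene_hits, e_max=th.e_max)
        screen = stage("duplications", overlap_screen, multi, min_overlap_bp=th.min_overlap_bp)
        split_genes = screen.split_gene
        lengths = dict(contig_lengths or {})
        for h in gene_hits:
            lengths.setdefault(h.query_id, max(1500, h.q_end))
        dup_calls = stage(
            "duplications", contig_pair_check, screen.overlapping,
            self_hits if self_hits is not None else [], lengths,
            min_len=th.min_len, e_max=th.e_max,
            redundancy_fraction=th.redundancy_fraction,
        )
        placements: dict[str, tuple[str, str]] = {}
        for ac in anchored:
            placements.setdefault(ac.genome_contig_id, (ac.bac_contig_id, lg))
        if extra_placements:
            for k, v in extra_placements.items():
                placements.setdefault(k, tuple(v))
        dup_calls = stage("duplications", classify_nature, dup_calls, placements)
        if ref_gene_hits is not None:
            dup_calls = stage(
                "duplications", ref_duplication_check, dup_calls, annotation,
                ref_gene_hits, min_score=th.min_score,
            )

    manifest = {
        "linkage_group": lg,
        "thresholds": vars(th),
        "counts": {
            "markers": sum(1 for m in markers if m.linkage_group == lg),
            "bac_contigs": len(mapped),
            "bes": len(bes_ids),
            "bes_with_hits": n_bes_with_hits,
            "anchored_genome_contigs": len({a.genome_contig_id for a in anchored}),
            "species": {
                name: {
                    "unique_genes": len(r.gene_anchors),
                    "single_contig_genes": len(classify_multiplicity(r.gene_anchors)[0]),
                    "multi_contig_genes": len(classify_multiplicity(r.gene_anchors)[1]),
                    "blocks": len(r.blocks),
                    "homologous_chromosomes": r.homology_call.homologous_chromosomes,
                    "fusion_contigs": len(r.fusion_candidates),
                }
                for name, r in species_results.items()
            },
            "duplication_funnel": {
                "multi_contig_genes": len(multi),
                "overlapping": len(multi) - len(split_genes),
                "split_genes": len(split_genes),
                "calls": len(dup_calls),
            },
        },
    }
    return PipelineResult(
        mapped_contigs=mapped,
        bes_ids=bes_ids,
        anchored=anchored,
        species=species_results,
        duplication_calls=dup_calls,
        split_genes=split_genes,
        multi_contig_candidates=multi,
        manifest=manifest,
    )


def _compose_bes_gene(bes_hits, anchored, gene_anchors, th: Thresholds) -> dict[str, str]:
    """BES id -> assigned gene, composed through its best genome-contig hit."""
    contig_gene: dict[str, str] = {}
    for anchor in gene_anchors:
        for gcid in anchor.genome_contig_ids:
            contig_gene[gcid] = anchor.gene_id
    best_contig: dict[str, HomologyHit] = {}
    for hit in bes_hits:
        if hit.evalue > th.e_max or hit.bitscore < th.bit_min:
            continue
        prev = best_contig.get(hit.query_id)
        if prev is None or _hit_order(hit) < _hit_order(prev):
            best_contig[hit.query_id] = hit
    return {
        bes: contig_gene[hit.subject_id]
        for bes, hit in best_contig.items()
        if hit.subject_id in contig_gene
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based entry point: read inputs, run stages, write the bundle."""
    config.validate_paths()
    markers = io_formats.read_linkage_map(config.linkage_map)
    physical_map = io_formats.read_physical_map(config.physical_map)
    bes_records = io_formats.read_fasta(config.bes_fasta)
    bes_index = io_formats.bes_index_from_fasta(bes_records)
    genome_records = io_formats.read_fasta(config.genome_contigs_fasta)
    contig_lengths = {r.id: len(r.seq) for r in genome_records}
    bes_hits = io_formats.read_hits_tabular(config.bes_hits)
    species_inputs = []
    for sp in config.species:
        ann = GeneAnnotation(io_formats.read_gene_annotation(sp.annotation_path))
        hits = io_formats.read_hits_tabular(sp.gene_hits_path)
        species_inputs.append((sp.name, ann, hits))
    self_hits = (
        io_formats.read_hits_tabular(config.self_hits) if config.self_hits else None
    )
    ref_gene_hits = (
        io_formats.read_hits_tabular(config.ref_gene_hits) if config.ref_gene_hits else None
    )
    extra_placements = None
    if config.placements:
        extra_placements = read_placements(config.placements)

    result = run_stages(
        markers, physical_map, bes_index, bes_hits, species_inputs,
        lg=config.lg, self_hits=self_hits, contig_lengths=contig_lengths,
        ref_gene_hits=ref_gene_hits, extra_placements=extra_placements,
        thresholds=config.thresholds,
    )
    result.manifest["inputs"] = {
        str(p): _sha256(p)
        for p in [config.linkage_map, config.physical_map, config.bes_fasta,
                  config.genome_contigs_fasta, config.bes_hits]
    }
    if config.outdir is not None:
        write_bundle(result, config, Path(config.outdir))
    return result


def read_placements(path: str | Path) -> dict[str, tuple[str, str]]:
    placements: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            placements[f[idx["contig_id"]]] = (f[idx["scaffold"]], f[idx["linkage_group"]])
    return placements


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_bundle(result: PipelineResult, config: PipelineConfig, outdir: Path) -> None:
    """Write every stage table, the comparative maps and the manifest."""
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "anchored.tsv", "w") as fh:
        fh.write("genome_contig_id\tbac_contig_id\tbitscore\tevalue\tcM_positions\n")
        for a in result.anchored:
            cms = ",".join(f"{c:g}" for c in sorted(a.cM_positions))
            fh.write(
                f"{a.genome_contig_id}\t{a.bac_contig_id}\t"
                f"{a.best_bes_hit.bitscore:g}\t{a.best_bes_hit.evalue:g}\t{cms}\n"
            )
    for name, sp in result.species.items():
        with open(outdir / f"genes_{name}.tsv", "w") as fh:
            fh.write("gene_id\tchromosome\tstart\tend\tgenome_contigs\tbac_contigs\tcM_positions\n")
            for g in sp.gene_anchors:
                fh.write(
                    f"{g.gene_id}\t{g.gene.chromosome}\t{g.gene.start}\t{g.gene.end}\t"
                    f"{','.join(sorted(g.genome_contig_ids))}\t"
                    f"{','.join(sorted(g.bac_contig_ids))}\t"
                    f"{','.join(f'{c:g}' for c in sorted(g.cM_positions))}\n"
                )
        with open(outdir / f"tally_{name}.tsv", "w") as fh:
            fh.write("chromosome\tn_gene_hits\n")
            for chrom in sorted(sp.tally.counts):
                fh.write(f"{chrom}\t{sp.tally.counts[chrom]}\n")
            fh.write(f"Total\t{sp.tally.total}\n")
        with open(outdir / f"blocks_{name}.tsv", "w") as fh:
            fh.write("chromosome\tcontig\toccurrence\tn_genes\tspan_bp\tgenes\n")
            for b in sp.blocks:
                fh.write(
                    f"{b.ref_chromosome}\t{b.bac_contig_id}\t{b.occurrence}\t"
                    f"{b.n_genes}\t{b.span_bp}\t{','.join(b.gene_ids)}\n"
                )
        with open(outdir / f"homologs_{name}.tsv", "w") as fh:
            fh.write("chromosome\thit_count\tn_blocks\tmax_block_genes\tcalled\n")
            ev = sp.homology_call.evidence
            for chrom in sorted(ev, key=lambda c: (-ev[c].hit_count, c)):
                called = chrom in sp.homology_call.homologous_chromosomes
                fh.write(
                    f"{chrom}\t{ev[chrom].hit_count}\t{ev[chrom].n_blocks}\t"
                    f"{ev[chrom].max_block_genes}\t{int(called)}\n"
                )
        with open(outdir / f"fusions_{name}.tsv", "w") as fh:
            fh.write(
                "bac_contig\tchrom_a\tgenes_a\tchrom_b\tgenes_b\t"
                "mate_pair_support\tlinkage_corroborated\n"
            )
            for c in sp.fusion_candidates:
                fh.write(
                    f"{c.bac_contig_id}\t{c.side_a.chromosome}\t{c.side_a.n_genes}\t"
                    f"{c.side_b.chromosome}\t{c.side_b.n_genes}\t"
                    f"{','.join(c.mate_pair_support)}\t{int(c.linkage_corroborated)}\n"
                )
        write_comparative_map(
            sp.gene_anchors, sp.blocks, sp.homology_call, outdir / f"map_{name}",
            lg=config.lg,
        )
    with open(outdir / "duplications.tsv", "w") as fh:
        fh.write(
            "gene_id\tcontig_a\tcontig_b\toverlap_bp\tnature\t"
            "ref_duplicated\tref_locations\tflags\n"
        )
        for d in result.duplication_calls:
            locs = ";".join(f"{c}:{s}-{e}" for c, s, e in d.ref_locations)
            fh.write(
                f"{d.gene_id}\t{d.supporting_contig_pair[0]}\t{d.supporting_contig_pair[1]}\t"
                f"{d.overlap_bp}\t{d.nature}\t{int(d.ref_duplicated)}\t{locs}\t"
                f"{','.join(d.flags)}\n"
            )
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=1, sort_keys=True))
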