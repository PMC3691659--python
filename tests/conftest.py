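"""Shared fixtures: synthetic datasets and helpers to run the pipeline."""

from __future__ import annotations

import pytest

from syntenymap.models import GeneAnchor, GeneAnnotation, GeneRecord, HomologyHit
from syntenymap.pipeline import Thresholds, run_stages
from syntenymap.synthetic import SimConfig, generate_dataset


def bes_index_of(dataset) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for bes_id, _seq in dataset.bes_records:
        clone, _, end = bes_id.rpartition(".")
        index.setdefault(clone, set()).add(end)
    return index


def run_dataset(annotation, dataset, thresholds: Thresholds | None = None):
    return run_stages(
        dataset.markers,
        dataset.physical_map,
        bes_index_of(dataset),
        dataset.bes_hits,
        [("ref", GeneAnnotation(annotation), dataset.contig_gene_hits)],
        lg="LG8",
        self_hits=dataset.self_hits,
        contig_lengths=dataset.contig_lengths,
        ref_gene_hits=dataset.ref_gene_hits,
        extra_placements=dataset.placements,
        thresholds=thresholds,
    )


@pytest.fixture(scope="session")
def clean_dataset():
    """Default study conditions, zero noise, seed 1."""
    annotation, dataset = generate_dataset(SimConfig(seed=1))
    return annotation, dataset


@pytest.fixture(scope="session")
def clean_result(clean_dataset):
    annotation, dataset = clean_dataset
    return run_dataset(annotation, dataset)


def make_hit(
    query="q", subject="s", bitscore=500.0, evalue=1e-50,
    q_start=1, q_end=100, s_start=1, s_end=100, aln_length=100,
) -> HomologyHit:
    return HomologyHit(
        query_id=query, subject_id=subject, pct_identity=95.0,
        aln_length=aln_length, q_start=q_start, q_end=q_end,
        s_start=s_start, s_end=s_end, evalue=evalue, bitscore=bitscore,
    )


def make_anchor(
    gene_id: str, chrom: str, start: int, end: int, bac: str = "ctg1",
) -> GeneAnchor:
    record = GeneRecord(gene_id=gene_id, chromosome=chrom, start=start, end=end)
    return GeneAnchor(
        gene_id=gene_id, gene=record,
        genome_contig_ids={f"gc_{gene_id}"}, bac_contig_ids={bac},
        cM_positions={44.5}, best_hit=make_hit(f"gc_{gene_id}", gene_id),
    )


def annotation_of(anchors) -> GeneAnnotation:
    return GeneAnnotation([a.gene for a in anchors])
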