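"""Readers and writers for every external format the pipeline touches.

All tabular inputs are TSV with a header line; lines starting with ``#`` are
provenance comments and are skipped. Every reader validates and rejects
malformed rows with the line number; nothing is silently repaired.

Coordinates in annotation files are 1-based inclusive (ENSEMBL-style
"Chr1: 40,426,579-40,445,530" spans). Converters to and from 0-based
half-open BED intervals exist only at this boundary.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError
from .models import BacContig, GeneRecord, HomologyHit, Marker

logger = logging.getLogger(__name__)

LINKAGE_MAP_COLUMNS = ["marker_id", "linkage_group", "position_cM", "clone_id", "end"]
PHYSICAL_MAP_COLUMNS = ["contig_id", "clone_id"]
ANNOTATION_COLUMNS = ["gene_id", "chromosome", "start", "end", "strand", "name"]


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _data_lines(handle: TextIO) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-comment, non-blank lines."""
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield lineno, line.split("\t")


def _header_indices(fields: list[str], required: list[str], path: Path) -> dict[str, int]:
    index = {name: i for i, name in enumerate(fields)}
    for col in required:
        if col not in index:
            raise FormatError(f"{path}: missing required column {col!r}")
    return index


# ---------------------------------------------------------------------------
# linkage map


def read_linkage_map(path: str | Path) -> list[Marker]:
    """Read a genetic linkage map TSV into Markers.

    Columns: marker_id, linkage_group, position_cM, clone_id, end.
    Rows come back sorted by (linkage_group, position_cM, marker_id).
    """
    path = Path(path)
    markers: list[Marker] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        lines = _data_lines(fh)
        try:
            _, header = next(lines)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header line")
        idx = _header_indices(header, LINKAGE_MAP_COLUMNS, path)
        for lineno, fields in lines:
            try:
                marker = Marker(
                    marker_id=fields[idx["marker_id"]],
                    linkage_group=fields[idx["linkage_group"]],
                    position_cM=float(fields[idx["position_cM"]]),
                    clone_id=fields[idx["clone_id"]],
                    end=fields[idx["end"]],
                )
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}: bad linkage-map row ({exc})", line=lineno)
            if marker.marker_id in seen:
                raise ValidationError(
                    f"{path}: duplicate marker_id {marker.marker_id} (line {lineno})"
                )
            seen.add(marker.marker_id)
            markers.append(marker)
    markers.sort(key=lambda m: (m.linkage_group, m.position_cM, m.marker_id))
    return markers


def write_linkage_map(markers: Iterable[Marker], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(LINKAGE_MAP_COLUMNS) + "\n")
        for m in markers:
            fh.write(
                f"{m.marker_id}\t{m.linkage_group}\t{m.position_cM:g}\t{m.clone_id}\t{m.end}\n"
            )


# ---------------------------------------------------------------------------
# physical map


def read_physical_map(path: str | Path) -> list[BacContig]:
    """Read BAC physical-map membership (one row per contig/clone pair).

    A clone may belong to exactly one contig; duplicate identical rows
    collapse, conflicting rows raise naming the clone.
    """
    path = Path(path)
    membership: dict[str, set[str]] = {}
    clone_owner: dict[str, str] = {}
    with _open_text(path) as fh:
        lines = _data_lines(fh)
        try:
            _, header = next(lines)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header line")
        idx = _header_indices(header, PHYSICAL_MAP_COLUMNS, path)
        for lineno, fields in lines:
            try:
                contig_id = fields[idx["contig_id"]]
                clone_id = fields[idx["clone_id"]]
            except IndexError:
                raise FormatError(f"{path}: too few columns", line=lineno)
            if not contig_id or not clone_id:
                raise FormatError(f"{path}: empty contig or clone id", line=lineno)
            owner = clone_owner.get(clone_id)
            if owner is not None and owner != contig_id:
                raise ValidationError(
                    f"{path}: clone {clone_id} listed under contigs "
                    f"{owner} and {contig_id} (line {lineno})"
                )
            clone_owner[clone_id] = contig_id
            membership.setdefault(contig_id, set()).add(clone_id)
    return [
        BacContig(contig_id=cid, clone_ids=frozenset(clones))
        for cid, clones in sorted(membership.items())
    ]


def write_physical_map(contigs: Iterable[BacContig], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(PHYSICAL_MAP_COLUMNS) + "\n")
        for contig in contigs:
            for clone in sorted(contig.clone_ids):
                fh.write(f"{contig.contig_id}\t{clone}\n")


# ---------------------------------------------------------------------------
# BLAST-style tabular hits


def read_hits_tabular(path: str | Path) -> list[HomologyHit]:
    """Read 12-column BLAST tabular hits (outfmt-6 dialect, no header).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore. Subject coordinates with sstart > send are
    normalized and flagged ``subject_reversed``.
    """
    path = Path(path)
    hits: list[HomologyHit] = []
    with _open_text(path) as fh:
        for lineno, fields in _data_lines(fh):
            if len(fields) != 12:
                raise FormatError(
                    f"{path}: expected 12 tab-separated columns, got {len(fields)}",
                    line=lineno,
                )
            try:
                pident = float(fields[2])
                length = int(fields[3])
                mismatch = int(fields[4])
                gapopen = int(fields[5])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric field ({exc})", line=lineno)
            reversed_subject = sstart > send
            if reversed_subject:
                sstart, send = send, sstart
            if qstart > qend:
                qstart, qend = qend, qstart
            hits.append(
                HomologyHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=pident,
                    aln_length=length,
                    mismatch=mismatch,
                    gapopen=gapopen,
                    q_start=qstart,
                    q_end=qend,
                    s_start=sstart,
                    s_end=send,
                    evalue=evalue,
                    bitscore=bitscore,
                    subject_reversed=reversed_subject,
                )
            )
    return hits


def write_hits_tabular(hits: Iterable[HomologyHit], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for h in hits:
            sstart, send = h.s_start, h.s_end
            if h.subject_reversed:
                sstart, send = send, sstart
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:g}",
                        h.aln_length,
                        h.mismatch,
                        h.gapopen,
                        h.q_start,
                        h.q_end,
                        sstart,
                        send,
                        f"{h.evalue:g}",
                        f"{h.bitscore:g}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# gene annotation


def read_gene_annotation(path: str | Path) -> list[GeneRecord]:
    """Read a BED-like gene annotation TSV with 1-based inclusive spans."""
    path = Path(path)
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        lines = _data_lines(fh)
        try:
            _, header = next(lines)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header line")
        idx = _header_indices(header, ANNOTATION_COLUMNS, path)
        for lineno, fields in lines:
            try:
                gene = GeneRecord(
                    gene_id=fields[idx["gene_id"]],
                    chromosome=fields[idx["chromosome"]],
                    start=int(fields[idx["start"]].replace(",", "")),
                    end=int(fields[idx["end"]].replace(",", "")),
                    strand=fields[idx["strand"]],
                    name=fields[idx["name"]],
                )
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}: bad annotation row ({exc})", line=lineno)
            if gene.gene_id in seen:
                raise ValidationError(
                    f"{path}: duplicate gene_id {gene.gene_id} (line {lineno})"
                )
            seen.add(gene.gene_id)
            genes.append(gene)
    return genes


def write_gene_annotation(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chromosome}\t{g.start}\t{g.end}\t{g.strand}\t{g.name}\n"
            )


def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def from_bed_interval(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# FASTA


def split_bes_id(seq_id: str) -> tuple[str, str]:
    """Split a BES id "<clone>.<end>" into (clone_id, end).

    Ids without a trailing ".F"/".R" are tolerated (empty clone/end) with a
    logged warning — they simply never join the clone chain.
    """
    if "." in seq_id:
        clone, _, end = seq_id.rpartition(".")
        if end in ("F", "R") and clone:
            return clone, end
    logger.warning("sequence id %r does not follow the clone.end convention", seq_id)
    return "", ""


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a multi-FASTA; duplicate ids are a validation error."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id}")
        seen.add(rec.id)
    return records


def write_fasta(records: Iterable[tuple[str, str] | SeqRecord], path: str | Path) -> None:
    """Write records (SeqRecords or (id, sequence) pairs) as multi-FASTA."""
    out = []
    for rec in records:
        if isinstance(rec, SeqRecord):
            out.append(SeqRecord(rec.seq, id=rec.id, description=""))
        else:
            seq_id, seq = rec
            out.append(SeqRecord(Seq(seq), id=seq_id, description=""))
    SeqIO.write(out, str(path), "fasta")


def bes_index_from_fasta(records: Iterable[SeqRecord]) -> dict[str, set[str]]:
    """Map clone_id -> set of archived ends, from BES FASTA ids."""
    index: dict[str, set[str]] = {}
    for rec in records:
        clone, end = split_bes_id(rec.id)
        if clone:
            index.setdefault(clone, set()).add(end)
    return index
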