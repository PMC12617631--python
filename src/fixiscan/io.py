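"""Readers and writers for all external formats.

Gene tables (custom TSV and GFF3), Pfam domain-hit tables, GTDB-style
taxonomy, newick trees and iTOL annotation datasets. All TSVs are UTF-8,
tab-separated; lines starting with ``#`` are ignored as comments.
"""

from __future__ import annotations

import logging
import os
from collections import defaultdict
from pathlib import Path
from typing import Iterable, TextIO

import dendropy

from .errors import ParseError, ValidationError
from .records import (
    DomainHit,
    GeneRecord,
    Lineage,
    Strand,
    TaxonomyMap,
    assign_ranks,
    parse_gtdb_lineage,
)

logger = logging.getLogger(__name__)

GENE_TABLE_COLUMNS = [
    "genome_id",
    "contig_id",
    "gene_id",
    "start",
    "end",
    "strand",
    "protein_id",
    "labels",
]

DOMAIN_HIT_COLUMNS = ["protein_id", "accession", "ali_start", "ali_end", "evalue"]


def _iter_data_lines(handle: TextIO) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping comments/blanks."""
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        yield lineno, line


def _parse_strand(token: str, path: str, lineno: int) -> Strand:
    if token == "+":
        return Strand.FORWARD
    if token == "-":
        return Strand.REVERSE
    raise ParseError(f"bad strand {token!r} (expected '+' or '-')", path, lineno)


def _parse_coord(token: str, what: str, path: str, lineno: int) -> int:
    try:
        value = int(token)
    except ValueError:
        raise ParseError(f"bad {what} {token!r} (not an integer)", path, lineno)
    if value < 1:
        raise ParseError(f"bad {what} {value} (must be >= 1)", path, lineno)
    return value


def _check_unique_proteins(genes: list[GeneRecord]) -> None:
    seen: dict[tuple[str, str], str] = {}
    for g in genes:
        if g.protein_id is None:
            continue
        key = (g.genome_id, g.protein_id)
        if key in seen:
            raise ValidationError(
                f"genome {g.genome_id}: duplicate protein_id {g.protein_id!r} "
                f"(genes {seen[key]} and {g.gene_id})"
            )
        seen[key] = g.gene_id


def read_gene_table(path: str | Path, dialect: str = "TSV") -> list[GeneRecord]:
    """Read a gene table; returns records sorted by (genome, contig, start)
    with per-contig ranks assigned.

    dialect "TSV": header with the GENE_TABLE_COLUMNS; labels is a
    semicolon-joined (possibly empty) field. dialect "GFF3": standard
    9-column GFF3; only ``gene`` features are kept, protein id and marker
    labels come from the ``protein_id`` and ``marker`` attributes.
    """
    dialect = dialect.upper()
    if dialect == "TSV":
        genes = _read_gene_table_tsv(path)
    elif dialect == "GFF3":
        genes = _read_gene_table_gff3(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    genes = assign_ranks(genes)
    _check_unique_proteins(genes)
    return genes


def _read_gene_table_tsv(path: str | Path) -> list[GeneRecord]:
    path = str(path)
    genes: list[GeneRecord] = []
    with open(path, encoding="utf-8") as fh:
        lines = _iter_data_lines(fh)
        try:
            _, header = next(lines)
        except StopIteration:
            raise ParseError("empty gene table (no header)", path)
        cols = header.split("\t")
        if cols != GENE_TABLE_COLUMNS:
            raise ParseError(
                f"bad header {cols!r}, expected {GENE_TABLE_COLUMNS!r}", path, 1
            )
        for lineno, line in lines:
            fields = line.split("\t")
            if len(fields) != len(GENE_TABLE_COLUMNS):
                raise ParseError(
                    f"expected {len(GENE_TABLE_COLUMNS)} columns, got {len(fields)}",
                    path,
                    lineno,
                )
            genome_id, contig_id, gene_id, start_s, end_s, strand_s, prot, labels_s = (
                fields
            )
            start = _parse_coord(start_s, "start", path, lineno)
            end = _parse_coord(end_s, "end", path, lineno)
            if end < start:
                raise ParseError(f"end {end} < start {start}", path, lineno)
            labels = frozenset(x for x in labels_s.split(";") if x)
            genes.append(
                GeneRecord(
                    genome_id=genome_id,
                    contig_id=contig_id,
                    rank=0,
                    gene_id=gene_id,
                    start=start,
                    end=end,
                    strand=_parse_strand(strand_s, path, lineno),
                    protein_id=prot or None,
                    labels=labels,
                )
            )
    return genes


def _parse_gff3_attributes(column: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in column.split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key] = value
    return attrs


def _read_gene_table_gff3(path: str | Path) -> list[GeneRecord]:
    path = str(path)
    genes: list[GeneRecord] = []
    n_dropped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in _iter_data_lines(fh):
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"expected 9 GFF3 columns, got {len(fields)}", path, lineno
                )
            seqid, _source, ftype, start_s, end_s, _score, strand_s, _phase, attr_s = (
                fields
            )
            if ftype != "gene":
                n_dropped += 1
                continue
            attrs = _parse_gff3_attributes(attr_s)
            start = _parse_coord(start_s, "start", path, lineno)
            end = _parse_coord(end_s, "end", path, lineno)
            if end < start:
                raise ParseError(f"start {start} > end {end}", path, lineno)
            protein_id = attrs.get("protein_id") or None
            if protein_id is None:
                n_dropped += 1  # non-coding gene feature
                continue
            labels = frozenset(x for x in attrs.get("marker", "").split(",") if x)
            genes.append(
                GeneRecord(
                    genome_id=attrs.get("genome_id", os.path.basename(path)),
                    contig_id=seqid,
                    rank=0,
                    gene_id=attrs.get("ID", f"{seqid}:{start}"),
                    start=start,
                    end=end,
                    strand=_parse_strand(strand_s, path, lineno),
                    protein_id=protein_id,
                    labels=labels,
                )
            )
    if n_dropped:
        logger.info("GFF3 %s: dropped %d non-coding/non-gene features", path, n_dropped)
    return genes


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.genome_id,
                        g.contig_id,
                        g.gene_id,
                        str(g.start),
                        str(g.end),
                        g.strand.value,
                        g.protein_id or "",
                        ";".join(sorted(g.labels)),
                    ]
                )
                + "\n"
            )


def strip_accession_version(accession: str) -> str:
    """PF00403.28 -> PF00403 (pfam_scan emits versioned accessions)."""
    return accession.split(".", 1)[0]


def read_domain_hits(path: str | Path) -> dict[str, list[DomainHit]]:
    """Read a pfam_scan-style TSV of domain hits.

    Returns protein_id -> hits sorted by ali_start (ties: smaller evalue
    first). Versioned accessions are stripped; accessions failing the
    PF##### pattern raise.
    """
    path = str(path)
    hits: dict[str, list[DomainHit]] = defaultdict(list)
    with open(path, encoding="utf-8") as fh:
        lines = _iter_data_lines(fh)
        try:
            _, header = next(lines)
        except StopIteration:
            raise ParseError("empty domain-hit table (no header)", path)
        if header.split("\t") != DOMAIN_HIT_COLUMNS:
            raise ParseError(
                f"bad header, expected {DOMAIN_HIT_COLUMNS!r}", path, 1
            )
        for lineno, line in lines:
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(f"expected 5 columns, got {len(fields)}", path, lineno)
            protein_id, accession, s, e, ev = fields
            try:
                hit = DomainHit(
                    protein_id=protein_id,
                    accession=strip_accession_version(accession),
                    ali_start=int(s),
                    ali_end=int(e),
                    evalue=float(ev),
                )
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno)
            hits[protein_id].append(hit)
    for protein_id in hits:
        hits[protein_id].sort(key=lambda h: (h.ali_start, h.evalue))
    return dict(hits)


def write_domain_hits(
    hits: dict[str, list[DomainHit]], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(DOMAIN_HIT_COLUMNS) + "\n")
        for protein_id in hits:
            for h in hits[protein_id]:
                fh.write(
                    f"{h.protein_id}\t{h.accession}\t{h.ali_start}\t{h.ali_end}"
                    f"\t{h.evalue:g}\n"
                )


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read genome_id -> GTDB lineage TSV; order rank mandatory."""
    path = str(path)
    lineages: dict[str, Lineage] = {}
    with open(path, encoding="utf-8") as fh:
        lines = _iter_data_lines(fh)
        try:
            _, header = next(lines)
        except StopIteration:
            raise ParseError("empty taxonomy table (no header)", path)
        if header.split("\t") != ["genome_id", "lineage"]:
            raise ParseError("bad header, expected genome_id<TAB>lineage", path, 1)
        for lineno, line in lines:
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"expected 2 columns, got {len(fields)}", path, lineno)
            genome_id, lineage_str = fields
            if genome_id in lineages:
                raise ValidationError(f"genome {genome_id}: duplicate lineage entry")
            lin = parse_gtdb_lineage(lineage_str)
            if lin.taxon("order") is None:
                raise ValidationError(
                    f"genome {genome_id}: lineage lacks an order (o__) field"
                )
            lineages[genome_id] = lin
    return TaxonomyMap(lineages)


def write_taxonomy(taxonomy: TaxonomyMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("genome_id\tlineage\n")
        for genome_id, lineage in taxonomy.items():
            fh.write(f"{genome_id}\t{lineage.to_gtdb_string()}\n")


# -- trees -------------------------------------------------------------------

def read_tree(path: str | Path) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValidationError("tree has duplicate leaf labels")
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def tree_from_string(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


# -- iTOL --------------------------------------------------------------------

#: copy-number bin colours (0..7+), a white-to-dark ramp.
_BIN_COLORS = [
    "#f7fbff", "#deebf7", "#c6dbef", "#9ecae1",
    "#6baed6", "#4292c6", "#2171b5", "#084594",
]


def write_itol_datasets(summaries, out_dir: str | Path) -> list[Path]:
    """Emit iTOL annotation datasets for a list of OrderSummary objects.

    One DATASET_MULTIBAR file per ATPase variant (fields = copy-number
    bins 0..7+) and one DATASET_SIMPLEBAR file for the cbb3-cluster
    proportion. Returns the written paths.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValidationError("no order summaries to write")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"cannot create iTOL output directory {out_dir}: {exc}")

    variants = list(summaries[0].copy_dist)
    written: list[Path] = []
    for variant in variants:
        p = out_dir / f"itol_copy_number_{variant.lower()}.txt"
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("DATASET_MULTIBAR\n")
            fh.write("SEPARATOR TAB\n")
            fh.write(f"DATASET_LABEL\t{variant} copy number\n")
            fh.write("COLOR\t#2171b5\n")
            fh.write(
                "FIELD_LABELS\t"
                + "\t".join([f"copies_{i}" for i in range(7)] + ["copies_7plus"])
                + "\n"
            )
            fh.write("FIELD_COLORS\t" + "\t".join(_BIN_COLORS) + "\n")
            fh.write("DATA\n")
            for s in summaries:
                props = s.copy_dist[variant]
                fh.write(
                    s.order + "\t" + "\t".join(f"{p_:.6f}" for p_ in props) + "\n"
                )
        written.append(p)

    p = out_dir / "itol_cbb3_cluster.txt"
    with open(p, "w", encoding="utf-8") as fh:
        fh.write("DATASET_SIMPLEBAR\n")
        fh.write("SEPARATOR TAB\n")
        fh.write("DATASET_LABEL\tcbb3-Cox gene cluster proportion\n")
        fh.write("COLOR\t#b2182b\n")
        fh.write("FIELD_LABELS\tcbb3_cluster_proportion\n")
        fh.write("DATA\n")
        for s in summaries:
            fh.write(f"{s.order}\t{s.cbb3_proportion:.6f}\n")
    written.append(p)
    return written


def parse_itol_data_rows(path: str | Path) -> dict[str, list[float]]:
    """Re-parse the DATA section of an iTOL dataset (round-trip checks)."""
    rows: dict[str, list[float]] = {}
    in_data = False
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line == "DATA":
                in_data = True
                continue
            if not in_data or not line:
                continue
            fields = line.split("\t")
            rows[fields[0]] = [float(x) for x in fields[1:]]
    return rows
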