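"""End-to-end orchestration: classify and aggregate stages.

Each stage reads the formats in :mod:`fixiscan.io`, writes its outputs
atomically (tmp file + rename) and records a run manifest JSON with a
config hash, input checksums and per-stage counts. The manifest's
timestamp is the only non-deterministic output field.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

from . import io as fio
from .aggregate import (
    DEFAULT_MAX_COPY_BIN,
    GenomeSummary,
    collapse_to_rank,
    order_summary_rows,
    prune_tree,
    summarize_genome,
    summarize_order,
)
from .architecture import (
    DEFAULT_MAX_OVERLAP_FRACTION,
    DEFAULT_SIGNATURES,
    MatchMode,
    Variant,
    call_variants,
)
from .context import extract_all_contexts
from .errors import ValidationError
from .markers import (
    DEFAULT_MARKER_SET,
    DEFAULT_MIN_MARKERS,
    MarkerSet,
    classify_cluster,
    genome_has_cbb3_cluster,
)
from .records import group_by_genome

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genes: str
    domain_hits: str
    taxonomy: str
    tree: str | None = None
    out_dir: str = "fixiscan_out"
    dialect: str = "TSV"
    match_mode: str = MatchMode.EXACT.value
    min_markers: int = DEFAULT_MIN_MARKERS
    cbb3_mode: str = "run"
    max_gap_bp: int | None = None
    max_copy_bin: int = DEFAULT_MAX_COPY_BIN
    max_overlap_fraction: float = DEFAULT_MAX_OVERLAP_FRACTION

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w", encoding="utf-8") as fh:
        fh.write(text)
    os.replace(tmp, path)


def _write_manifest(
    cfg: PipelineConfig, out_dir: Path, stage: str, counts: dict[str, int]
) -> None:
    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    inputs = {}
    for p in [cfg.genes, cfg.domain_hits, cfg.taxonomy, cfg.tree]:
        if p and Path(p).exists():
            inputs[p] = _sha256_file(p)
    manifest = {
        "stage": stage,
        "config": cfg.to_dict(),
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "input_checksums": inputs,
        "counts": counts,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    _atomic_write(
        out_dir / f"manifest_{stage}.json",
        json.dumps(manifest, indent=1, sort_keys=True) + "\n",
    )


CLUSTER_REPORT_COLUMNS = [
    "genome_id",
    "contig_id",
    "focal_protein",
    "variant",
    "n_markers",
    "classification",
    "n_members",
    "upstream_count",
    "downstream_count",
    "member_gene_ids",
    "member_labels",
]


def run_classify(
    cfg: PipelineConfig,
    markers: MarkerSet = DEFAULT_MARKER_SET,
    signatures=DEFAULT_SIGNATURES,
) -> dict[str, Path]:
    """Variant calling + context extraction + FixI-like classification.

    Writes cluster_calls.tsv, genome_summaries.tsv and a manifest.
    Returns the output paths.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mode = MatchMode(cfg.match_mode)

    genes = fio.read_gene_table(cfg.genes, dialect=cfg.dialect)
    hits = fio.read_domain_hits(cfg.domain_hits)
    taxonomy = fio.read_taxonomy(cfg.taxonomy)

    calls = call_variants(
        hits,
        signatures=signatures,
        mode=mode,
        max_overlap_fraction=cfg.max_overlap_fraction,
    )
    positive = [c for c in calls.values() if c.variant is not Variant.NONE]
    contexts = extract_all_contexts(genes, positive, max_gap_bp=cfg.max_gap_bp)
    cluster_calls = [
        classify_cluster(
            cluster, call, markers=markers, min_markers=cfg.min_markers
        )
        for cluster, call in contexts
    ]

    # genome summaries
    by_genome = group_by_genome(genes)
    protein_genome = {
        g.protein_id: g.genome_id for g in genes if g.protein_id is not None
    }
    calls_by_genome: dict[str, list] = {gid: [] for gid in by_genome}
    for call in positive:
        calls_by_genome[protein_genome[call.protein_id]].append(call)
    summaries = []
    for gid in sorted(by_genome):
        if gid not in taxonomy:
            raise ValidationError(f"genome {gid} missing from taxonomy")
        cbb3 = genome_has_cbb3_cluster(
            by_genome[gid],
            markers=markers,
            min_markers=cfg.min_markers,
            mode=cfg.cbb3_mode,
        )
        summaries.append(summarize_genome(gid, calls_by_genome[gid], cbb3))

    # cluster report TSV
    lines = ["\t".join(CLUSTER_REPORT_COLUMNS)]
    for cc in sorted(
        cluster_calls, key=lambda c: (c.cluster.genome_id, c.variant.protein_id)
    ):
        cl = cc.cluster
        labels = sorted({lab for m in cl.members for lab in m.labels})
        lines.append(
            "\t".join(
                [
                    cl.genome_id,
                    cl.contig_id,
                    cc.variant.protein_id,
                    cc.variant.variant.value,
                    str(cc.n_markers),
                    cc.classification.value,
                    str(len(cl.members)),
                    str(cl.upstream_count),
                    str(cl.downstream_count),
                    ";".join(m.gene_id for m in cl.members),
                    ";".join(labels),
                ]
            )
        )
    cluster_path = out_dir / "cluster_calls.tsv"
    _atomic_write(cluster_path, "\n".join(lines) + "\n")

    # genome summary TSV
    variants = sorted({v for s in summaries for v in s.copy_number})
    header = ["genome_id"] + [f"copy_{v}" for v in variants] + ["cbb3_present"]
    rows = ["\t".join(header)]
    for s in summaries:
        rows.append(
            "\t".join(
                [s.genome_id]
                + [str(s.copy_number.get(v, 0)) for v in variants]
                + ["1" if s.cbb3_present else "0"]
            )
        )
    summary_path = out_dir / "genome_summaries.tsv"
    _atomic_write(summary_path, "\n".join(rows) + "\n")

    _write_manifest(
        cfg,
        out_dir,
        "classify",
        {
            "n_genes": len(genes),
            "n_proteins_with_hits": len(hits),
            "n_genomes": len(by_genome),
            "n_variant_calls": len(positive),
            "n_fixi_like": sum(
                1 for c in cluster_calls if c.classification.value == "FIXI_LIKE"
            ),
            "n_cbb3_genomes": sum(1 for s in summaries if s.cbb3_present),
        },
    )
    logger.info("classify: %d variant calls in %d genomes", len(positive), len(by_genome))
    return {"cluster_calls": cluster_path, "genome_summaries": summary_path}


def read_genome_summaries(path: str | Path) -> list[GenomeSummary]:
    """Read back the genome_summaries.tsv written by run_classify."""
    summaries = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        variant_cols = [c for c in header if c.startswith("copy_")]
        for line in fh:
            fields = dict(zip(header, line.rstrip("\n").split("\t")))
            summaries.append(
                GenomeSummary(
                    genome_id=fields["genome_id"],
                    copy_number={
                        c[len("copy_") :]: int(fields[c]) for c in variant_cols
                    },
                    cbb3_present=fields["cbb3_present"] == "1",
                )
            )
    return summaries


def run_aggregate(cfg: PipelineConfig) -> dict[str, Path]:
    """Per-order aggregation + tree prune/collapse + iTOL export.

    Requires run_classify outputs in cfg.out_dir.
    """
    out_dir = Path(cfg.out_dir)
    summary_path = out_dir / "genome_summaries.tsv"
    if not summary_path.exists():
        raise ValidationError(
            f"classify outputs not found in {out_dir} (run classify first)"
        )
    summaries = read_genome_summaries(summary_path)
    taxonomy = fio.read_taxonomy(cfg.taxonomy)
    orders = summarize_order(summaries, taxonomy, max_bin=cfg.max_copy_bin)

    rows = order_summary_rows(orders)
    n_bins = cfg.max_copy_bin + 1
    header = (
        ["order", "variant", "n_genomes"]
        + [f"p{i}" for i in range(n_bins)]
        + ["cbb3_proportion"]
    )
    lines = ["\t".join(header)]
    for row in rows:
        lines.append(
            "\t".join(
                [row["order"], row["variant"], str(row["n_genomes"])]
                + [f"{row[f'p{i}']:.6f}" for i in range(n_bins)]
                + [f"{row['cbb3_proportion']:.6f}"]
            )
        )
    order_path = out_dir / "order_summaries.tsv"
    _atomic_write(order_path, "\n".join(lines) + "\n")

    outputs = {"order_summaries": order_path}
    outputs["itol"] = fio.write_itol_datasets(orders, out_dir / "itol")

    if cfg.tree:
        tree = fio.read_tree(cfg.tree)
        leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
        genome_ids = {s.genome_id for s in summaries}
        if not genome_ids <= leaves:
            diff = sorted(genome_ids.symmetric_difference(leaves))
            raise ValidationError(
                "tree/summary leaf mismatch (symmetric difference): "
                + ", ".join(diff[:20])
                + ("..." if len(diff) > 20 else "")
            )
        pruned = prune_tree(tree, genome_ids)
        collapsed = collapse_to_rank(pruned, taxonomy, rank="order")
        pruned_path = out_dir / "pruned.nwk"
        collapsed_path = out_dir / "collapsed_orders.nwk"
        fio.write_tree(pruned, pruned_path)
        fio.write_tree(collapsed, collapsed_path)
        outputs["pruned_tree"] = pruned_path
        outputs["collapsed_tree"] = collapsed_path

    _write_manifest(
        cfg,
        out_dir,
        "aggregate",
        {
            "n_genomes": len(summaries),
            "n_orders": len(orders),
        },
    )
    return outputs
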