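"""Co-directional gene-neighborhood (strand-run) extraction.

The genomic-context unit is the maximal run of consecutive genes on one
contig sharing the focal gene's strand: starting from the focal gene the
run extends upstream and downstream one gene at a time and stops at the
first strand flip, the contig end, or (optionally) an intergenic gap
larger than ``max_gap_bp``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .architecture import Variant, VariantCall
from .errors import FixiscanError, ValidationError
from .records import GeneRecord, group_by_contig


@dataclass(frozen=True)
class ContextCluster:
    genome_id: str
    contig_id: str
    focal_gene: GeneRecord
    members: tuple[GeneRecord, ...]  # contiguous ranks, focal included
    upstream_count: int
    downstream_count: int

    def __post_init__(self) -> None:
        assert self.upstream_count + self.downstream_count + 1 == len(self.members)


def _gap_bp(left: GeneRecord, right: GeneRecord) -> int:
    """Intergenic distance between two rank-adjacent genes (bp; can be
    negative for overlapping genes)."""
    return right.start - left.end - 1


def extract_strand_run(
    contig_genes: list[GeneRecord],
    focal_rank: int,
    max_gap_bp: int | None = None,
) -> ContextCluster:
    """Maximal same-strand run containing the focal gene.

    ``contig_genes`` must be the rank-ordered genes of one contig.
    Upstream/downstream are in genomic coordinates (left/right of the
    focal gene on the contig), regardless of focal strand.
    """
    if focal_rank < 0 or focal_rank >= len(contig_genes):
        raise FixiscanError(
            f"focal_rank {focal_rank} out of range for contig of "
            f"{len(contig_genes)} genes"
        )
    focal = contig_genes[focal_rank]
    strand = focal.strand

    left = focal_rank
    while left > 0:
        nxt = contig_genes[left - 1]
        if nxt.strand != strand:
            break
        if max_gap_bp is not None and _gap_bp(nxt, contig_genes[left]) > max_gap_bp:
            break
        left -= 1
    right = focal_rank
    while right < len(contig_genes) - 1:
        nxt = contig_genes[right + 1]
        if nxt.strand != strand:
            break
        if max_gap_bp is not None and _gap_bp(contig_genes[right], nxt) > max_gap_bp:
            break
        right += 1

    members = tuple(contig_genes[left : right + 1])
    return ContextCluster(
        genome_id=focal.genome_id,
        contig_id=focal.contig_id,
        focal_gene=focal,
        members=members,
        upstream_count=focal_rank - left,
        downstream_count=right - focal_rank,
    )


def extract_all_contexts(
    genes: list[GeneRecord],
    calls: list[VariantCall],
    max_gap_bp: int | None = None,
) -> list[tuple[ContextCluster, VariantCall]]:
    """One context cluster per called ATPase (variant != NONE).

    Overlapping clusters from distinct ATPases are kept separately.
    Raises if any called protein is absent from the gene tables.
    """
    by_contig = group_by_contig(genes)
    # protein ids are unique per genome and globally unique in practice
    by_protein: dict[str, GeneRecord] = {}
    for g in genes:
        if g.protein_id is not None:
            by_protein.setdefault(g.protein_id, g)

    wanted = [c for c in calls if c.variant is not Variant.NONE]
    orphans = [c.protein_id for c in wanted if c.protein_id not in by_protein]
    if orphans:
        raise ValidationError(
            "variant calls reference proteins absent from the gene tables: "
            + ", ".join(sorted(orphans))
        )

    out: list[tuple[ContextCluster, VariantCall]] = []
    for call in wanted:
        g = by_protein[call.protein_id]
        contig = by_contig[(g.genome_id, g.contig_id)]
        cluster = extract_strand_run(contig, g.rank, max_gap_bp=max_gap_bp)
        out.append((cluster, call))
    return out
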