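"""FixI-like cluster classification and genome-level cbb3-cluster detection.

A context cluster is FixI-like when its focal ATPase has the 1-domain
architecture and at least ``min_markers`` distinct cbb3-oxidase subunit
markers (e.g. ccoN/ccoO/ccoP, a.k.a. fixN/fixO/fixP) lie inside the same
co-directional run. All other ATPase contexts stay unclassified — they
may be CopA-like detoxification pumps or other metal transporters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .architecture import Architecture, Variant, VariantCall
from .context import ContextCluster, extract_strand_run
from .records import GeneRecord, group_by_contig

#: cbb3-Cox subunit marker tags used by default (gene-label matching).
DEFAULT_CBB3_LABELS = frozenset(
    {"ccoN", "ccoO", "ccoP", "ccoQ", "fixN", "fixO", "fixP", "fixC"}
)

DEFAULT_MIN_MARKERS = 2


@dataclass(frozen=True)
class MarkerSet:
    """Named set of marker gene labels and/or Pfam accessions."""

    name: str
    member_labels: frozenset[str] = field(default_factory=frozenset)
    member_accessions: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.member_labels and not self.member_accessions:
            raise ValueError(f"marker set {self.name!r} is empty")


DEFAULT_MARKER_SET = MarkerSet(name="cbb3_subunits", member_labels=DEFAULT_CBB3_LABELS)


class Classification(Enum):
    FIXI_LIKE = "FIXI_LIKE"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class ClusterCall:
    cluster: ContextCluster
    variant: VariantCall
    n_markers: int
    classification: Classification


def _markers_of_gene(
    gene: GeneRecord,
    markers: MarkerSet,
    architectures: dict[str, Architecture] | None = None,
) -> frozenset[str]:
    found = gene.labels & markers.member_labels
    if markers.member_accessions and architectures and gene.protein_id:
        arch = architectures.get(gene.protein_id)
        if arch is not None:
            found |= frozenset(arch.accessions) & markers.member_accessions
    return found


def count_markers(
    cluster: ContextCluster,
    markers: MarkerSet = DEFAULT_MARKER_SET,
    architectures: dict[str, Architecture] | None = None,
) -> int:
    """Distinct marker labels/accessions among cluster members, the focal
    ATPase excluded. Two genes with the same label count once."""
    found: set[str] = set()
    for g in cluster.members:
        if g is cluster.focal_gene or g.gene_id == cluster.focal_gene.gene_id:
            continue
        found |= _markers_of_gene(g, markers, architectures)
    return len(found)


def classify_cluster(
    cluster: ContextCluster,
    variant: VariantCall,
    markers: MarkerSet = DEFAULT_MARKER_SET,
    min_markers: int = DEFAULT_MIN_MARKERS,
    architectures: dict[str, Architecture] | None = None,
) -> ClusterCall:
    """FIXI_LIKE iff the focal ATPase is 1-domain and >= min_markers
    distinct cbb3 subunits share its strand run."""
    if min_markers < 1:
        raise ValueError("min_markers must be >= 1")
    n = count_markers(cluster, markers, architectures)
    fixi = variant.variant is Variant.ONE_DOMAIN and n >= min_markers
    return ClusterCall(
        cluster=cluster,
        variant=variant,
        n_markers=n,
        classification=Classification.FIXI_LIKE if fixi else Classification.UNCLASSIFIED,
    )


def genome_has_cbb3_cluster(
    genome_genes: list[GeneRecord],
    markers: MarkerSet = DEFAULT_MARKER_SET,
    min_markers: int = DEFAULT_MIN_MARKERS,
    mode: str = "run",
    architectures: dict[str, Architecture] | None = None,
) -> bool:
    """Genome-level cbb3-Cox gene-cluster presence.

    mode "run" (default): true iff some contig holds a co-directional
    strand run containing >= min_markers distinct markers (same run
    semantics as context extraction, seeded at each marker gene).
    mode "anywhere": true iff >= min_markers distinct markers occur
    anywhere in the genome, clustered or not.
    """
    if mode == "anywhere":
        found: set[str] = set()
        for g in genome_genes:
            found |= _markers_of_gene(g, markers, architectures)
        return len(found) >= min_markers
    if mode != "run":
        raise ValueError(f"unknown cbb3 mode {mode!r}")

    for contig in group_by_contig(genome_genes).values():
        for g in contig:
            if not _markers_of_gene(g, markers, architectures):
                continue
            run = extract_strand_run(contig, g.rank)
            distinct: set[str] = set()
            for m in run.members:
                distinct |= _markers_of_gene(m, markers, architectures)
            if len(distinct) >= min_markers:
                return True
    return False
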