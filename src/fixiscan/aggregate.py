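"""Per-order aggregation and phylogeny collapsing.

Genome-level variant calls are tallied into copy numbers, genomes are
grouped by taxonomic order, and each order is summarised by (a) the
proportion of genomes carrying 0..7+ copies of each ATPase variant and
(b) the proportion of genomes encoding a cbb3-Cox gene cluster. The
reference phylogeny is pruned to the analysed genomes and collapsed to
one leaf per order for display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy

from .architecture import Variant, VariantCall
from .errors import ValidationError
from .records import TaxonomyMap

logger = logging.getLogger(__name__)

#: copy numbers are binned 0,1,...,6,7+ (8 bins) for display
DEFAULT_MAX_COPY_BIN = 7


@dataclass(frozen=True)
class GenomeSummary:
    genome_id: str
    copy_number: dict[str, int]  # variant name -> count
    cbb3_present: bool


@dataclass(frozen=True)
class OrderSummary:
    order: str
    n_genomes: int
    copy_dist: dict[str, tuple[float, ...]]  # variant name -> 8 proportions
    cbb3_proportion: float


def summarize_genome(
    genome_id: str,
    calls: list[VariantCall],
    cbb3_present: bool,
    variants: tuple[str, ...] = (Variant.ONE_DOMAIN.value, Variant.TWO_DOMAIN.value),
) -> GenomeSummary:
    """Count calls per variant for one genome (NONE calls excluded)."""
    counts = {v: 0 for v in variants}
    for c in calls:
        if c.variant is Variant.NONE:
            continue
        if c.variant.value in counts:
            counts[c.variant.value] += 1
    return GenomeSummary(
        genome_id=genome_id, copy_number=counts, cbb3_present=cbb3_present
    )


def bin_copy_number(copies: int, max_bin: int = DEFAULT_MAX_COPY_BIN) -> int:
    """Copy numbers >= max_bin all land in the top ("7+") bin."""
    return min(copies, max_bin)


def summarize_order(
    genomes: list[GenomeSummary],
    taxonomy: TaxonomyMap,
    max_bin: int = DEFAULT_MAX_COPY_BIN,
) -> list[OrderSummary]:
    """Group genomes by order and compute binned copy-number proportions
    and the cbb3 co-occurrence proportion. Output sorted by order name;
    independent of genome input order."""
    by_order: dict[str, list[GenomeSummary]] = {}
    for g in genomes:
        order = taxonomy.order_of(g.genome_id)  # raises if missing
        by_order.setdefault(order, []).append(g)

    summaries: list[OrderSummary] = []
    n_bins = max_bin + 1
    for order in sorted(by_order):
        members = by_order[order]
        n = len(members)
        variants = sorted({v for g in members for v in g.copy_number})
        dist: dict[str, tuple[float, ...]] = {}
        for v in variants:
            bins = [0] * n_bins
            for g in members:
                bins[bin_copy_number(g.copy_number.get(v, 0), max_bin)] += 1
            dist[v] = tuple(b / n for b in bins)
        cbb3_prop = sum(1 for g in members if g.cbb3_present) / n
        summaries.append(
            OrderSummary(
                order=order, n_genomes=n, copy_dist=dist, cbb3_proportion=cbb3_prop
            )
        )
    return summaries


# -- tree operations ---------------------------------------------------------

def prune_tree(tree: dendropy.Tree, keep: set[str]) -> dendropy.Tree:
    """Prune to the given leaf set; unary nodes are collapsed with their
    branch lengths summed onto the retained child edge."""
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = keep - leaf_labels
    if missing:
        raise ValidationError(
            "keep-set contains unknown leaves: " + ", ".join(sorted(missing))
        )
    pruned = tree.clone(depth=1)
    pruned.retain_taxa([t for t in pruned.taxon_namespace if t.label in keep])
    pruned.purge_taxon_namespace()
    return pruned


def collapse_to_rank(
    tree: dendropy.Tree,
    taxonomy: TaxonomyMap,
    rank: str = "order",
) -> dendropy.Tree:
    """Replace each maximal monophyletic set of same-taxon leaves by one
    leaf named for the taxon.

    Non-monophyletic taxa: the largest clade keeps the bare taxon name,
    further clades get ``name_2``, ``name_3``, ... (by decreasing size)
    and a warning is logged.
    """
    collapsed = tree.clone(depth=1)

    def taxon_of_leaf(leaf) -> str:
        gid = leaf.taxon.label
        name = taxonomy.lineage(gid).taxon(rank) if gid in taxonomy else None
        if name is None:
            raise ValidationError(f"leaf {gid} has no taxon at rank {rank!r}")
        return name

    # bottom-up: a node is "pure" if all its leaves share one taxon
    pure: dict[int, str | None] = {}
    for node in collapsed.postorder_node_iter():
        if node.is_leaf():
            pure[id(node)] = taxon_of_leaf(node)
        else:
            kinds = {pure[id(c)] for c in node.child_nodes()}
            pure[id(node)] = kinds.pop() if len(kinds) == 1 else None

    # maximal pure nodes: pure nodes whose parent is not pure
    clades_by_taxon: dict[str, list] = {}
    for node in collapsed.preorder_node_iter():
        taxon = pure[id(node)]
        if taxon is None:
            continue
        parent = node.parent_node
        if parent is not None and pure[id(parent)] is not None:
            continue
        clades_by_taxon.setdefault(taxon, []).append(node)

    for taxon, nodes in sorted(clades_by_taxon.items()):
        nodes.sort(key=lambda nd: -len(nd.leaf_nodes()))
        if len(nodes) > 1:
            logger.warning(
                "taxon %s is not monophyletic: split into %d clades", taxon, len(nodes)
            )
        for i, node in enumerate(nodes):
            label = taxon if i == 0 else f"{taxon}_{i + 1}"
            node.clear_child_nodes()
            node.taxon = collapsed.taxon_namespace.new_taxon(label=label)

    collapsed.suppress_unifurcations()
    collapsed.purge_taxon_namespace()
    return collapsed


# -- tabular export ----------------------------------------------------------

def order_summary_rows(summaries: list[OrderSummary]) -> list[dict]:
    """Flatten to one row per order x variant (for the summary TSV)."""
    rows = []
    for s in summaries:
        for variant, dist in sorted(s.copy_dist.items()):
            row = {
                "order": s.order,
                "variant": variant,
                "n_genomes": s.n_genomes,
            }
            for i, p in enumerate(dist):
                row[f"p{i}"] = p
            row["cbb3_proportion"] = s.cbb3_proportion
            rows.append(row)
    return rows
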