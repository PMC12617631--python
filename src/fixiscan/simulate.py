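"""Synthetic genome/taxonomy/tree generator with planted ground truth.

Emulates the statistical structure of the comparative-genomics dataset:
genomes are ordered, stranded gene lists; ATPase proteins carry Pfam
hits spelling one of the two variant signatures; cbb3-Cox marker genes
are planted as co-directional runs; a 1-domain ATPase may be embedded
inside such a run (the FixI-like configuration); genomes carry GTDB-like
lineages grouped into orders, and a random coalescent-style tree keeps
orders monophyletic by construction.

Planted blocks are insulated from each other by opposite-strand filler
genes, so the expected classification of every planted ATPase holds by
construction and the emitted truth file is exact.

All randomness flows through a single numpy PCG64 generator seeded from
``SimConfig.seed``, so outputs are byte-identical across runs and
platforms for a fixed configuration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .architecture import Variant
from .errors import ConfigError, ValidationError
from .records import DomainHit, GeneRecord, Lineage, Strand, TaxonomyMap

GENE_LENGTH_BP = 900
INTERGENIC_GAP_BP = 100

#: markers planted in a cbb3 run (3 distinct subunits)
PLANTED_MARKERS = ("ccoN", "ccoO", "ccoP")

#: signature hit templates: accession -> (ali_start, ali_end)
_ONE_DOMAIN_HITS = (
    ("PF00403", 5, 70),
    ("PF00122", 120, 300),
    ("PF00702", 320, 500),
)
_TWO_DOMAIN_HITS = (
    ("PF00403", 5, 70),
    ("PF00403", 80, 145),
    ("PF00122", 180, 360),
    ("PF00702", 380, 560),
)

SIGNATURE_ACCESSIONS = frozenset({"PF00403", "PF00122", "PF00702"})

DEFAULT_DECOY_POOL = (
    "PF00005",  # ABC transporter
    "PF00067",  # cytochrome P450
    "PF00072",  # response regulator receiver
    "PF00196",  # GerE HTH
    "PF01061",  # ABC-2 transporter
    "PF07690",  # MFS
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a modest alphaproteobacterial panel: 10 orders of
    20 genomes, small multi-contig assemblies, realistic copy-number
    spread for the two ATPase variants, cbb3 clusters in ~70% of
    genomes, and 80% of 1-domain ATPases co-localized with a cbb3 run.
    """

    n_orders: int = 10
    genomes_per_order: int = 20
    genes_per_contig: tuple[int, int] = (25, 45)
    contigs_per_genome: int = 2
    copy_number_probs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            Variant.ONE_DOMAIN.value: (0.25, 0.55, 0.15, 0.05),
            Variant.TWO_DOMAIN.value: (0.55, 0.30, 0.10, 0.05),
        }
    )
    p_cbb3_cluster: float = 0.7
    p_fixi_colocalization: float = 0.8
    strand_flip_prob: float = 0.15
    p_decoy: float = 0.1
    decoy_domain_pool: tuple[str, ...] = DEFAULT_DECOY_POOL
    scramble_orders: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_orders < 1 or self.genomes_per_order < 1:
            raise ConfigError("need at least one order and one genome per order")
        lo, hi = self.genes_per_contig
        if lo < 1 or hi < lo:
            raise ConfigError(f"bad genes_per_contig range ({lo}, {hi})")
        if self.contigs_per_genome < 1:
            raise ConfigError("need at least one contig per genome")
        for v, probs in self.copy_number_probs.items():
            if not probs or any(p < 0 or p > 1 for p in probs):
                raise ConfigError(f"bad probability vector for {v}")
            if not math.isclose(sum(probs), 1.0, abs_tol=1e-9):
                raise ConfigError(f"copy_number_probs[{v}] does not sum to 1")
        for p, name in [
            (self.p_cbb3_cluster, "p_cbb3_cluster"),
            (self.p_fixi_colocalization, "p_fixi_colocalization"),
            (self.strand_flip_prob, "strand_flip_prob"),
            (self.p_decoy, "p_decoy"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if SIGNATURE_ACCESSIONS & set(self.decoy_domain_pool):
            raise ConfigError("decoy pool collides with the variant signatures")
        # largest planted block: markers + embedded ATPase + 2 insulators
        largest_block = len(PLANTED_MARKERS) + 1 + 2
        if hi < largest_block:
            raise ConfigError(
                f"genes_per_contig max {hi} too small to host a planted "
                f"cbb3 run ({largest_block} genes)"
            )


@dataclass(frozen=True)
class PlantedAtpase:
    protein_id: str
    genome_id: str
    variant: str
    embedded_in_marker_run: bool


@dataclass(frozen=True)
class GenomeTruth:
    genome_id: str
    order: str
    copy_number: dict[str, int]
    cbb3_present: bool


@dataclass
class SyntheticTruth:
    genomes: dict[str, GenomeTruth]
    atpases: list[PlantedAtpase]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genomes": {gid: asdict(g) for gid, g in sorted(self.genomes.items())},
            "atpases": [asdict(a) for a in self.atpases],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        genomes = {
            gid: GenomeTruth(**g) for gid, g in payload["genomes"].items()
        }
        atpases = [PlantedAtpase(**a) for a in payload["atpases"]]
        return cls(genomes=genomes, atpases=atpases)


@dataclass
class SyntheticDataset:
    genes: list[GeneRecord]
    domain_hits: dict[str, list[DomainHit]]
    taxonomy: TaxonomyMap
    newick: str
    truth: SyntheticTruth


# -- internal block model ----------------------------------------------------

@dataclass
class _Gene:
    labels: tuple[str, ...] = ()
    is_protein: bool = True
    role: str = "filler"  # filler | marker | atpase | insulator
    variant: str | None = None
    embedded: bool | None = None


def _make_atpase_gene(variant: str, embedded: bool) -> _Gene:
    return _Gene(role="atpase", variant=variant, embedded=embedded)


def _marker_run_genes(
    rng: np.random.Generator, atpase: _Gene | None
) -> list[_Gene]:
    genes = [_Gene(labels=(m,), role="marker") for m in PLANTED_MARKERS]
    if atpase is not None:
        pos = int(rng.integers(0, len(genes) + 1))
        genes.insert(pos, atpase)
    return genes


def generate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Generate gene tables, domain hits, taxonomy, tree and truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    variants = sorted(cfg.copy_number_probs)
    genes: list[GeneRecord] = []
    hits: dict[str, list[DomainHit]] = {}
    lineages: dict[str, Lineage] = {}
    truth_genomes: dict[str, GenomeTruth] = {}
    truth_atpases: list[PlantedAtpase] = []
    genomes_by_order: dict[str, list[str]] = {}

    for oi in range(cfg.n_orders):
        order = f"Order_{oi + 1:02d}"
        genomes_by_order[order] = []
        for gi in range(cfg.genomes_per_order):
            genome_id = f"G{oi + 1:02d}_{gi + 1:03d}"
            genomes_by_order[order].append(genome_id)
            lineages[genome_id] = Lineage(
                (
                    ("domain", "Bacteria"),
                    ("phylum", "Pseudomonadota"),
                    ("class", "Alphaproteobacteria"),
                    ("order", order),
                    ("family", f"f_{order}"),
                    ("genus", f"g_{genome_id}"),
                    ("species", ""),
                )
            )

            # copy numbers per variant
            copy_number = {
                v: int(
                    rng.choice(
                        len(cfg.copy_number_probs[v]), p=cfg.copy_number_probs[v]
                    )
                )
                for v in variants
            }

            # plan planted blocks
            blocks: list[list[_Gene]] = []
            any_marker_run = False
            n_one = copy_number.get(Variant.ONE_DOMAIN.value, 0)
            for _ in range(n_one):
                embedded = bool(rng.random() < cfg.p_fixi_colocalization)
                atp = _make_atpase_gene(Variant.ONE_DOMAIN.value, embedded)
                if embedded:
                    blocks.append(_marker_run_genes(rng, atp))
                    any_marker_run = True
                else:
                    blocks.append([atp])
            for v in variants:
                if v == Variant.ONE_DOMAIN.value:
                    continue
                for _ in range(copy_number.get(v, 0)):
                    blocks.append([_make_atpase_gene(v, False)])
            if rng.random() < cfg.p_cbb3_cluster:
                blocks.append(_marker_run_genes(rng, None))
                any_marker_run = True

            # distribute blocks over contigs
            contig_blocks: list[list[list[_Gene]]] = [
                [] for _ in range(cfg.contigs_per_genome)
            ]
            for block in blocks:
                contig_blocks[int(rng.integers(0, cfg.contigs_per_genome))].append(
                    block
                )

            gene_counter = 0
            for ci in range(cfg.contigs_per_genome):
                contig_id = f"{genome_id}_c{ci + 1}"
                target = int(
                    rng.integers(cfg.genes_per_contig[0], cfg.genes_per_contig[1] + 1)
                )
                planted = contig_blocks[ci]
                planted_size = sum(len(b) + 2 for b in planted)  # + insulators
                n_filler = max(target - planted_size, len(planted) + 1, 1)

                # contig = interleave of filler singletons and insulated blocks
                segments: list[tuple[str, list[_Gene]]] = [
                    ("filler", [_Gene()]) for _ in range(n_filler)
                ]
                positions = rng.choice(
                    len(segments) + 1, size=len(planted), replace=False
                ) if planted else []
                for pos, block in sorted(
                    zip([int(p) for p in positions], planted), reverse=True
                ):
                    segments.insert(pos, ("block", block))

                # resolve strands
                placed: list[tuple[_Gene, Strand]] = []
                filler_strand = (
                    Strand.FORWARD if rng.random() < 0.5 else Strand.REVERSE
                )
                for kind, seg_genes in segments:
                    if kind == "filler":
                        if rng.random() < cfg.strand_flip_prob:
                            filler_strand = filler_strand.flipped()
                        placed.append((seg_genes[0], filler_strand))
                    else:
                        block_strand = (
                            Strand.FORWARD if rng.random() < 0.5 else Strand.REVERSE
                        )
                        ins = block_strand.flipped()
                        placed.append((_Gene(role="insulator"), ins))
                        for bg in seg_genes:
                            placed.append((bg, block_strand))
                        placed.append((_Gene(role="insulator"), ins))

                for rank, (pg, strand) in enumerate(placed):
                    gene_counter += 1
                    gene_id = f"{genome_id}_g{gene_counter:05d}"
                    protein_id = f"P_{gene_id}"
                    start = 1 + rank * (GENE_LENGTH_BP + INTERGENIC_GAP_BP)
                    record = GeneRecord(
                        genome_id=genome_id,
                        contig_id=contig_id,
                        rank=rank,
                        gene_id=gene_id,
                        start=start,
                        end=start + GENE_LENGTH_BP - 1,
                        strand=strand,
                        protein_id=protein_id,
                        labels=frozenset(pg.labels),
                    )
                    genes.append(record)

                    if pg.role == "atpase":
                        templates = (
                            _ONE_DOMAIN_HITS
                            if pg.variant == Variant.ONE_DOMAIN.value
                            else _TWO_DOMAIN_HITS
                        )
                        hits[protein_id] = [
                            DomainHit(
                                protein_id=protein_id,
                                accession=acc,
                                ali_start=s,
                                ali_end=e,
                                evalue=1e-30,
                            )
                            for acc, s, e in templates
                        ]
                        truth_atpases.append(
                            PlantedAtpase(
                                protein_id=protein_id,
                                genome_id=genome_id,
                                variant=pg.variant,
                                embedded_in_marker_run=bool(pg.embedded),
                            )
                        )
                    elif pg.role == "filler" and rng.random() < cfg.p_decoy:
                        n_decoys = int(rng.integers(1, 4))
                        accs = rng.choice(
                            len(cfg.decoy_domain_pool), size=n_decoys, replace=True
                        )
                        hits[protein_id] = [
                            DomainHit(
                                protein_id=protein_id,
                                accession=cfg.decoy_domain_pool[int(a)],
                                ali_start=10 + 200 * j,
                                ali_end=150 + 200 * j,
                                evalue=1e-10,
                            )
                            for j, a in enumerate(accs)
                        ]

            truth_genomes[genome_id] = GenomeTruth(
                genome_id=genome_id,
                order=order,
                copy_number=copy_number,
                cbb3_present=any_marker_run,
            )

    newick = _random_tree(genomes_by_order, rng, cfg.scramble_orders)
    taxonomy = TaxonomyMap(lineages)
    truth = SyntheticTruth(genomes=truth_genomes, atpases=truth_atpases)
    return SyntheticDataset(
        genes=genes, domain_hits=hits, taxonomy=taxonomy, newick=newick, truth=truth
    )


def _join_random(labels: list[str], rng: np.random.Generator) -> str:
    """Coalescent-style random joining into a newick subtree string."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b1 = round(float(rng.exponential(0.1)) + 0.01, 6)
        b2 = round(float(rng.exponential(0.1)) + 0.01, 6)
        merged = f"({nodes[i]}:{b1},{nodes[j]}:{b2})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0]


def _random_tree(
    genomes_by_order: dict[str, list[str]],
    rng: np.random.Generator,
    scramble: bool,
) -> str:
    order_subtrees = []
    all_leaf_lists = []
    for order in sorted(genomes_by_order):
        leaves = list(genomes_by_order[order])
        all_leaf_lists.append(leaves)
        order_subtrees.append(_join_random(leaves, rng))
    if scramble and len(all_leaf_lists) >= 2:
        # swap one leaf label between the first two orders to break
        # monophyly (exercises the suffixed-collapse rule)
        a, b = all_leaf_lists[0][0], all_leaf_lists[1][0]
        order_subtrees = [
            s.replace(f"{a}:", "§TMP§:").replace(f"{b}:", f"{a}:").replace(
                "§TMP§:", f"{b}:"
            )
            for s in order_subtrees
        ]
    return _join_random(order_subtrees, rng) + ";"


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset in the exact formats the readers consume."""
    from . import io as fio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": out_dir / "genes.tsv",
        "domain_hits": out_dir / "domain_hits.tsv",
        "taxonomy": out_dir / "taxonomy.tsv",
        "tree": out_dir / "tree.nwk",
        "truth": out_dir / "truth.json",
    }
    fio.write_gene_table(dataset.genes, paths["genes"])
    fio.write_domain_hits(
        dict(sorted(dataset.domain_hits.items())), paths["domain_hits"]
    )
    fio.write_taxonomy(dataset.taxonomy, paths["taxonomy"])
    with open(paths["tree"], "w", encoding="utf-8") as fh:
        fh.write(dataset.newick + "\n")
    dataset.truth.to_json(paths["truth"])
    return paths


# -- truth comparison --------------------------------------------------------

def truth_compare(
    truth: SyntheticTruth,
    variant_calls: dict[str, "object"],
    cluster_calls: list,
    genome_summaries: list,
) -> list[str]:
    """Exact-match comparison of pipeline output against planted truth.

    Returns a list of human-readable mismatch descriptions (empty on a
    noiseless run). Raises on genome-id-space mismatch.
    """
    from .architecture import VariantCall
    from .markers import Classification

    truth_gids = set(truth.genomes)
    out_gids = {g.genome_id for g in genome_summaries}
    if truth_gids != out_gids:
        raise ValidationError(
            "genome id spaces differ: truth-only="
            + ",".join(sorted(truth_gids - out_gids))
            + " output-only="
            + ",".join(sorted(out_gids - truth_gids))
        )

    mismatches: list[str] = []

    for planted in truth.atpases:
        call: VariantCall | None = variant_calls.get(planted.protein_id)
        if call is None or call.variant.value != planted.variant:
            mismatches.append(
                f"variant call for {planted.protein_id}: expected "
                f"{planted.variant}, got {call.variant.value if call else 'missing'}"
            )

    expected_class = {
        p.protein_id: (
            Classification.FIXI_LIKE
            if p.embedded_in_marker_run and p.variant == Variant.ONE_DOMAIN.value
            else Classification.UNCLASSIFIED
        )
        for p in truth.atpases
    }
    for cc in cluster_calls:
        pid = cc.variant.protein_id
        exp = expected_class.get(pid)
        if exp is not None and cc.classification is not exp:
            mismatches.append(
                f"cluster classification for {pid}: expected {exp.value}, "
                f"got {cc.classification.value}"
            )

    by_gid = {g.genome_id: g for g in genome_summaries}
    for gid, gt in truth.genomes.items():
        gs = by_gid[gid]
        if gs.copy_number != gt.copy_number:
            mismatches.append(
                f"copy numbers for {gid}: expected {gt.copy_number}, "
                f"got {gs.copy_number}"
            )
        if gs.cbb3_present != gt.cbb3_present:
            mismatches.append(
                f"cbb3 presence for {gid}: expected {gt.cbb3_present}, "
                f"got {gs.cbb3_present}"
            )
    return mismatches
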