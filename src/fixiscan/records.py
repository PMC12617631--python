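"""Core record types for genes, domain hits and taxonomy.

Coordinates are 1-based inclusive (GFF convention) in every dialect; the
``rank`` of a gene is its 0-based position along its contig ordered by
start coordinate. A genome is represented simply as the list of its
:class:`GeneRecord` objects; grouping helpers live alongside.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum

from .errors import ValidationError

PFAM_ACCESSION_RE = re.compile(r"^PF\d{5}$")


class Strand(Enum):
    FORWARD = "+"
    REVERSE = "-"

    def flipped(self) -> "Strand":
        return Strand.REVERSE if self is Strand.FORWARD else Strand.FORWARD

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class GeneRecord:
    """One gene on a contig.

    ``protein_id`` is ``None`` for non-coding features (which the readers
    drop by default); ``labels`` carries marker tags such as cbb3-subunit
    names (ccoN, ccoO, ...).
    """

    genome_id: str
    contig_id: str
    rank: int
    gene_id: str
    start: int
    end: int
    strand: Strand
    protein_id: str | None = None
    labels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"gene {self.gene_id}: start {self.start} < 1")
        if self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.rank < 0:
            raise ValidationError(f"gene {self.gene_id}: negative rank")


@dataclass(frozen=True)
class DomainHit:
    """A Pfam domain hit on one protein (alignment coords in aa, 1-based)."""

    protein_id: str
    accession: str
    ali_start: int
    ali_end: int
    evalue: float

    def __post_init__(self) -> None:
        if not PFAM_ACCESSION_RE.match(self.accession):
            raise ValidationError(
                f"protein {self.protein_id}: accession {self.accession!r} "
                "does not match PF#####"
            )
        if self.ali_start < 1 or self.ali_end < self.ali_start:
            raise ValidationError(
                f"protein {self.protein_id}: bad alignment coords "
                f"({self.ali_start}, {self.ali_end})"
            )
        if self.evalue < 0:
            raise ValidationError(f"protein {self.protein_id}: negative e-value")

    @property
    def length(self) -> int:
        return self.ali_end - self.ali_start + 1


# GTDB one-letter rank prefixes, canonical order domain -> species.
GTDB_RANKS = (
    ("d", "domain"),
    ("p", "phylum"),
    ("c", "class"),
    ("o", "order"),
    ("f", "family"),
    ("g", "genus"),
    ("s", "species"),
)
_PREFIX_TO_RANK = {p: r for p, r in GTDB_RANKS}


@dataclass(frozen=True)
class Lineage:
    """A GTDB-style lineage: ordered (rank, taxon) pairs down to species."""

    ranks: tuple[tuple[str, str], ...]

    def taxon(self, rank: str) -> str | None:
        for r, name in self.ranks:
            if r == rank:
                return name or None
        return None

    @property
    def order(self) -> str:
        name = self.taxon("order")
        if name is None:
            raise ValidationError("lineage has no order rank")
        return name

    def to_gtdb_string(self) -> str:
        by_rank = dict(self.ranks)
        return ";".join(
            f"{p}__{by_rank.get(r, '')}" for p, r in GTDB_RANKS
        )


class TaxonomyMap:
    """genome_id -> Lineage, with order-rank guaranteed present."""

    def __init__(self, lineages: dict[str, Lineage]):
        for gid, lin in lineages.items():
            if lin.taxon("order") is None:
                raise ValidationError(f"genome {gid}: lineage lacks an order (o__)")
        self._lineages = dict(lineages)

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self._lineages

    def __len__(self) -> int:
        return len(self._lineages)

    def __iter__(self):
        return iter(self._lineages)

    def lineage(self, genome_id: str) -> Lineage:
        return self._lineages[genome_id]

    def order_of(self, genome_id: str) -> str:
        if genome_id not in self._lineages:
            raise ValidationError(f"genome {genome_id} missing from taxonomy")
        return self._lineages[genome_id].order

    def items(self):
        return self._lineages.items()


def parse_gtdb_lineage(lineage: str) -> Lineage:
    """Parse ``d__...;p__...;o__...`` into rank/taxon pairs.

    Missing trailing ranks are allowed; unknown prefixes rejected.
    """
    pairs: list[tuple[str, str]] = []
    for fieldstr in lineage.split(";"):
        fieldstr = fieldstr.strip()
        if not fieldstr:
            continue
        if len(fieldstr) < 3 or fieldstr[1:3] != "__":
            raise ValidationError(f"malformed lineage field {fieldstr!r}")
        prefix, name = fieldstr[0], fieldstr[3:]
        if prefix not in _PREFIX_TO_RANK:
            raise ValidationError(f"unknown rank prefix {prefix!r} in {fieldstr!r}")
        pairs.append((_PREFIX_TO_RANK[prefix], name))
    return Lineage(tuple(pairs))


def group_by_contig(
    genes: list[GeneRecord],
) -> dict[tuple[str, str], list[GeneRecord]]:
    """Group genes by (genome_id, contig_id), each list rank-ordered."""
    out: dict[tuple[str, str], list[GeneRecord]] = defaultdict(list)
    for g in genes:
        out[(g.genome_id, g.contig_id)].append(g)
    for key in out:
        out[key].sort(key=lambda g: g.rank)
    return dict(out)


def group_by_genome(genes: list[GeneRecord]) -> dict[str, list[GeneRecord]]:
    out: dict[str, list[GeneRecord]] = defaultdict(list)
    for g in genes:
        out[g.genome_id].append(g)
    return dict(out)


def assign_ranks(genes: list[GeneRecord]) -> list[GeneRecord]:
    """Re-derive per-contig ranks from coordinates.

    Sort key within a contig: (start, end, gene_id) — the deterministic
    tie-break for identical starts.
    """
    by_contig: dict[tuple[str, str], list[GeneRecord]] = defaultdict(list)
    for g in genes:
        by_contig[(g.genome_id, g.contig_id)].append(g)
    out: list[GeneRecord] = []
    for key in sorted(by_contig):
        contig = sorted(by_contig[key], key=lambda g: (g.start, g.end, g.gene_id))
        for rank, g in enumerate(contig):
            out.append(
                GeneRecord(
                    genome_id=g.genome_id,
                    contig_id=g.contig_id,
                    rank=rank,
                    gene_id=g.gene_id,
                    start=g.start,
                    end=g.end,
                    strand=g.strand,
                    protein_id=g.protein_id,
                    labels=g.labels,
                )
            )
    return out
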