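"""Domain-architecture construction and P-type ATPase variant calling.

An architecture is the N→C ordered tuple of Pfam accessions on one
protein after resolving overlapping hits. Two architectures define the
Cu-transporting P-type ATPase variants of interest:

* 1-domain variant: PF00403–PF00122–PF00702 — a single N-terminal
  heavy-metal-associated domain (HMBD, PF00403) followed by the E1-E2
  ATPase (PF00122) and haloacid-dehalogenase-like hydrolase (PF00702)
  domains.
* 2-domain variant: PF00403–PF00403–PF00122–PF00702 — the same body with
  a duplicated HMBD, the hallmark of CopA-like detoxification ATPases.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .errors import FixiscanError
from .records import DomainHit


class Variant(Enum):
    ONE_DOMAIN = "ONE_DOMAIN"
    TWO_DOMAIN = "TWO_DOMAIN"
    NONE = "NONE"


class MatchMode(Enum):
    EXACT = "EXACT"
    SUBSEQUENCE = "SUBSEQUENCE"


@dataclass(frozen=True)
class Architecture:
    protein_id: str
    accessions: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.accessions)


@dataclass(frozen=True)
class ArchitectureSignature:
    name: str
    accessions: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.accessions:
            raise ValueError(f"signature {self.name!r} is empty")

    @classmethod
    def from_string(cls, name: str, dashed: str) -> "ArchitectureSignature":
        """Build from a dash-separated accession string, e.g.
        ``"PF00403-PF00122-PF00702"``."""
        return cls(name=name, accessions=tuple(dashed.split("-")))


@dataclass(frozen=True)
class VariantCall:
    protein_id: str
    variant: Variant


#: The two variant signatures; longer signature first so that the
#: 2-domain variant takes precedence in SUBSEQUENCE matching.
DEFAULT_SIGNATURES: tuple[ArchitectureSignature, ...] = (
    ArchitectureSignature.from_string(
        Variant.TWO_DOMAIN.value, "PF00403-PF00403-PF00122-PF00702"
    ),
    ArchitectureSignature.from_string(
        Variant.ONE_DOMAIN.value, "PF00403-PF00122-PF00702"
    ),
)

DEFAULT_MAX_OVERLAP_FRACTION = 0.5


def _overlap_aa(a: DomainHit, b: DomainHit) -> int:
    return max(0, min(a.ali_end, b.ali_end) - max(a.ali_start, b.ali_start) + 1)


def _conflicts(a: DomainHit, b: DomainHit, max_overlap_fraction: float) -> bool:
    shorter = min(a.length, b.length)
    return _overlap_aa(a, b) > max_overlap_fraction * shorter


def build_architecture(
    hits: list[DomainHit],
    max_overlap_fraction: float = DEFAULT_MAX_OVERLAP_FRACTION,
) -> Architecture:
    """Resolve overlapping hits and emit the N→C accession tuple.

    Among hits overlapping by more than ``max_overlap_fraction`` of the
    shorter hit, only the better hit survives — smaller e-value first,
    ties broken by longer alignment, then lexicographic accession. The
    result is independent of input row order.
    """
    if not hits:
        return Architecture(protein_id="", accessions=())
    protein_ids = {h.protein_id for h in hits}
    if len(protein_ids) != 1:
        raise FixiscanError(
            f"build_architecture got hits for multiple proteins: {sorted(protein_ids)}"
        )
    (protein_id,) = protein_ids

    # greedy by quality: best hits claim their interval first
    by_quality = sorted(
        hits,
        key=lambda h: (h.evalue, -h.length, h.accession, h.ali_start, h.ali_end),
    )
    surviving: list[DomainHit] = []
    for cand in by_quality:
        if not any(_conflicts(cand, kept, max_overlap_fraction) for kept in surviving):
            surviving.append(cand)
    surviving.sort(key=lambda h: (h.ali_start, h.ali_end, h.accession))
    return Architecture(
        protein_id=protein_id, accessions=tuple(h.accession for h in surviving)
    )


def _contains_contiguous(haystack: tuple[str, ...], needle: tuple[str, ...]) -> bool:
    n = len(needle)
    return any(haystack[i : i + n] == needle for i in range(len(haystack) - n + 1))


def classify_variant(
    arch: Architecture,
    signatures: tuple[ArchitectureSignature, ...] = DEFAULT_SIGNATURES,
    mode: MatchMode = MatchMode.EXACT,
) -> VariantCall:
    """Call the ATPase variant of one architecture.

    Signatures are tried longest-first so a protein matching the
    2-domain signature is never also called 1-domain. EXACT requires the
    whole architecture to equal the signature; SUBSEQUENCE requires the
    signature to occur as a contiguous run inside the architecture.
    """
    ordered = sorted(signatures, key=lambda s: len(s.accessions), reverse=True)
    for sig in ordered:
        if mode is MatchMode.EXACT:
            matched = arch.accessions == sig.accessions
        else:
            matched = _contains_contiguous(arch.accessions, sig.accessions)
        if matched:
            return VariantCall(protein_id=arch.protein_id, variant=Variant(sig.name))
    return VariantCall(protein_id=arch.protein_id, variant=Variant.NONE)


def call_variants(
    hits_by_protein: dict[str, list[DomainHit]],
    signatures: tuple[ArchitectureSignature, ...] = DEFAULT_SIGNATURES,
    mode: MatchMode = MatchMode.EXACT,
    max_overlap_fraction: float = DEFAULT_MAX_OVERLAP_FRACTION,
) -> dict[str, VariantCall]:
    """Architecture + variant call for every protein with hits."""
    calls: dict[str, VariantCall] = {}
    for protein_id, hits in hits_by_protein.items():
        arch = build_architecture(hits, max_overlap_fraction=max_overlap_fraction)
        if not arch.accessions:
            calls[protein_id] = VariantCall(protein_id=protein_id, variant=Variant.NONE)
            continue
        calls[protein_id] = classify_variant(arch, signatures=signatures, mode=mode)
    return calls
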