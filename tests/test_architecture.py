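import random

import pytest
from hypothesis import given, settings, strategies as st

from fixiscan.architecture import (
    Architecture,
    DEFAULT_SIGNATURES,
    MatchMode,
    Variant,
    build_architecture,
    classify_variant,
)
from fixiscan.errors import FixiscanError
from fixiscan.records import DomainHit


def hit(acc, start, end, evalue=1e-20, protein="p1"):
    return DomainHit(
        protein_id=protein, accession=acc, ali_start=start, ali_end=end, evalue=evalue
    )


def brute_force_call(accessions: tuple[str, ...], mode: MatchMode) -> Variant:
    """Independent matcher: try every signature at every offset."""
    for sig in sorted(DEFAULT_SIGNATURES, key=lambda s: -len(s.accessions)):
        n = len(sig.accessions)
        if mode is MatchMode.EXACT:
            ok = accessions == sig.accessions
        else:
            ok = any(
                tuple(accessions[i : i + n]) == sig.accessions
                for i in range(len(accessions) - n + 1)
            )
        if ok:
            return Variant(sig.name)
    return Variant.NONE


class TestBuildArchitecture:
    def test_three_nonoverlapping_hits_in_nc_order(self):
        arch = build_architecture(
            [hit("PF00403", 5, 70), hit("PF00122", 120, 300), hit("PF00702", 320, 500)]
        )
        assert arch.accessions == ("PF00403", "PF00122", "PF00702")

    def test_empty_hit_list_gives_empty_architecture(self):
        assert build_architecture([]).accessions == ()

    def test_overlapping_hits_resolved_by_evalue(self):
        # overlap (40..70) = 31 aa > 0.5 * 61 (shorter hit) -> conflict
        arch = build_architecture(
            [hit("PF00403", 5, 70, evalue=1e-30), hit("PF00122", 40, 100, evalue=1e-5)]
        )
        assert arch.accessions == ("PF00403",)

    def test_mixed_protein_ids_rejected(self):
        with pytest.raises(FixiscanError):
            build_architecture([hit("PF00403", 5, 70), hit("PF00122", 120, 300, protein="p2")])

    def test_order_independence(self):
        hits = [
            hit("PF00403", 5, 70),
            hit("PF00403", 40, 100, evalue=1e-5),
            hit("PF00122", 120, 300),
            hit("PF00702", 320, 500),
        ]
        ref = build_architecture(hits)
        rnd = random.Random(3)
        for _ in range(20):
            shuffled = hits[:]
            rnd.shuffle(shuffled)
            assert build_architecture(shuffled) == ref

    def test_exhaustive_pairwise_overlap_agrees(self):
        """2-hit instances vs an exhaustive pairwise-overlap oracle."""
        rnd = random.Random(11)
        for _ in range(300):
            a = hit("PF00403", rnd.randint(1, 50), rnd.randint(50, 120), 10 ** -rnd.randint(2, 40))
            b = hit("PF00122", rnd.randint(1, 50), rnd.randint(50, 120), 10 ** -rnd.randint(2, 40))
            overlap = max(0, min(a.ali_end, b.ali_end) - max(a.ali_start, b.ali_start) + 1)
            conflict = overlap > 0.5 * min(a.length, b.length)
            arch = build_architecture([a, b])
            if not conflict:
                assert len(arch.accessions) == 2
            else:
                best = min([a, b], key=lambda h: (h.evalue, -h.length, h.accession))
                assert arch.accessions == (best.accession,)


ACCS = ["PF00403", "PF00122", "PF00702", "PF00005", "PF07690"]


class TestClassifyVariant:
    @pytest.mark.parametrize(
        "accessions,expected",
        [
            (("PF00403", "PF00122", "PF00702"), Variant.ONE_DOMAIN),
            (("PF00403", "PF00403", "PF00122", "PF00702"), Variant.TWO_DOMAIN),
            ((), Variant.NONE),
            (("PF00403", "PF00122"), Variant.NONE),
        ],
    )
    def test_printed_signatures_exact(self, accessions, expected):
        arch = Architecture(protein_id="p", accessions=accessions)
        assert classify_variant(arch, mode=MatchMode.EXACT).variant is expected

    def test_triplicated_hmbd_exact_none_subsequence_two_domain(self):
        arch = Architecture(
            protein_id="p",
            accessions=("PF00403", "PF00403", "PF00403", "PF00122", "PF00702"),
        )
        assert classify_variant(arch, mode=MatchMode.EXACT).variant is Variant.NONE
        assert (
            classify_variant(arch, mode=MatchMode.SUBSEQUENCE).variant
            is Variant.TWO_DOMAIN
        )

    @given(
        st.lists(st.sampled_from(ACCS), min_size=0, max_size=8),
        st.sampled_from([MatchMode.EXACT, MatchMode.SUBSEQUENCE]),
    )
    @settings(max_examples=400, deadline=None, derandomize=True)
    def test_matches_brute_force(self, accessions, mode):
        arch = Architecture(protein_id="p", accessions=tuple(accessions))
        assert classify_variant(arch, mode=mode).variant is brute_force_call(
            tuple(accessions), mode
        )

    @given(st.lists(st.sampled_from(ACCS), min_size=0, max_size=6))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_two_domain_prefix_never_called_one_domain(self, tail):
        accessions = ("PF00403", "PF00403", "PF00122", "PF00702") + tuple(tail)
        call = classify_variant(
            Architecture(protein_id="p", accessions=accessions),
            mode=MatchMode.SUBSEQUENCE,
        )
        assert call.variant is not Variant.ONE_DOMAIN

    @given(st.lists(st.sampled_from(ACCS), min_size=0, max_size=8))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_exact_calls_subset_of_subsequence_calls(self, accessions):
        arch = Architecture(protein_id="p", accessions=tuple(accessions))
        exact = classify_variant(arch, mode=MatchMode.EXACT).variant
        subseq = classify_variant(arch, mode=MatchMode.SUBSEQUENCE).variant
        if exact is not Variant.NONE:
            assert subseq is not Variant.NONE
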