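"""Binding-site search and amplicon enumeration.

The deep check is equivalence with the exhaustive gap-layout enumeration
reference on random instances; the planted examples pin the coordinate
conventions and the edit-budget thresholds.
"""

import numpy as np
import pytest

from gmoscreen import (
    DetectionMethod,
    PCRParams,
    enumerate_amplicons,
    find_binding_sites,
    reverse_complement,
)
from gmoscreen.reference import reference_binding_sites
from gmoscreen.synthetic import mutate_site

from conftest import random_seq, substitute_interior


@pytest.fixture(scope="module")
def primer():
    return random_seq(np.random.default_rng(101), 20)


def plant(rng, core, flank=30):
    return random_seq(rng, flank) + core + random_seq(rng, flank)


class TestBindingSites:
    def test_planted_exact_site_plus_strand(self, primer):
        rng = np.random.default_rng(1)
        template = random_seq(rng, 10) + primer + random_seq(rng, 10)
        sites = find_binding_sites(primer, template)
        assert len(sites) == 1
        s = sites[0]
        assert (s.strand, s.start, s.end, s.mismatches, s.gap_bases) == (
            "plus", 10, 30, 0, 0,
        )

    def test_planted_exact_site_minus_strand(self, primer):
        rng = np.random.default_rng(2)
        template = random_seq(rng, 10) + reverse_complement(primer) + random_seq(rng, 10)
        sites = find_binding_sites(primer, template)
        assert len(sites) == 1
        assert sites[0].strand == "minus"
        assert sites[0].interval == (10, 30)
        assert sites[0].is_perfect

    def test_five_substitutions_rejected(self, primer):
        rng = np.random.default_rng(3)
        core = substitute_interior(primer, (2, 6, 10, 14, 17))
        template = plant(rng, core)
        assert find_binding_sites(primer, template) == []
        assert reference_binding_sites(primer, template) == []

    @pytest.mark.parametrize("mm,gaps", [(2, 0), (0, 2), (2, 2)])
    def test_sites_at_budget_boundary_reported(self, primer, mm, gaps):
        rng = np.random.default_rng(mm * 10 + gaps)
        core = substitute_interior(primer, (4, 15)[:mm]) if mm else primer
        if gaps:
            core = core[:9] + core[9 + gaps :]  # interior deletion
        template = plant(rng, core)
        plus = [s for s in find_binding_sites(primer, template) if s.strand == "plus"]
        assert [(s.mismatches, s.gap_bases) for s in plus] == [(mm, gaps)]

    @pytest.mark.parametrize("mm,gaps", [(3, 0), (0, 3)])
    def test_sites_beyond_either_budget_rejected(self, primer, mm, gaps):
        rng = np.random.default_rng(mm * 10 + gaps)
        core = substitute_interior(primer, (4, 10, 16)[:mm]) if mm else primer
        if gaps:
            core = core[:9] + core[9 + gaps :]
        template = plant(rng, core)
        assert find_binding_sites(primer, template) == []

    def test_negative_budgets_rejected(self, primer):
        with pytest.raises(ValueError):
            find_binding_sites(primer, primer * 3, max_mismatches=-1)
        with pytest.raises(ValueError):
            find_binding_sites(primer, primer * 3, max_gaps=-1)

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            find_binding_sites("ACGTACGT", "ACGTACGT" * 10)

    def test_degenerate_primer_codes_count_as_matches(self, primer):
        rng = np.random.default_rng(8)
        degenerate = "N" + primer[1:10] + "R" + primer[11:]
        core = primer[:10] + ("A" if primer[10] in "AG" else primer[10]) + primer[11:]
        template = plant(rng, core)
        plus = [s for s in find_binding_sites(degenerate, template) if s.strand == "plus"]
        assert plus and plus[0].mismatches <= 1  # N always matches; R covers A/G

    def test_matches_reference_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            L = int(rng.integers(15, 26))
            p = random_seq(rng, L)
            T = int(rng.integers(L, 301))
            t = random_seq(rng, T)
            if rng.random() < 0.6:  # plant a degraded copy to make hits likely
                pos = int(rng.integers(0, T - L + 1))
                degraded = mutate_site(p, (0, L), int(rng.integers(0, 4)),
                                       int(rng.integers(0, 2**31)))
                t = t[:pos] + degraded + t[pos + L :]
            assert find_binding_sites(p, t) == reference_binding_sites(p, t)


class TestAmplicons:
    @pytest.fixture()
    def method(self):
        rng = np.random.default_rng(55)
        return DetectionMethod(
            "M1", "element_specific", "t", random_seq(rng, 20), random_seq(rng, 20)
        )

    def test_intended_pair_coordinates(self, method):
        rng = np.random.default_rng(4)
        t = (
            random_seq(rng, 5)
            + method.primer1
            + random_seq(rng, 30)
            + reverse_complement(method.primer2)
            + random_seq(rng, 5)
        )
        hits = enumerate_amplicons(method, t)
        assert len(hits) == 1
        h = hits[0]
        assert (h.pair_kind, h.start, h.end, h.amplicon_length) == ("p1_p2", 5, 75, 70)
        assert h.total_edits == 0 and not h.is_self_pair

    def test_amplicon_length_bounds(self, method):
        rng = np.random.default_rng(6)
        for spacer, lengths in [(460, [500]), (461, []), (560, [])]:
            t = (
                random_seq(rng, 5)
                + method.primer1
                + random_seq(rng, spacer)
                + reverse_complement(method.primer2)
                + random_seq(rng, 5)
            )
            assert [h.amplicon_length for h in enumerate_amplicons(method, t)] == lengths

    def test_minimum_length_boundary(self):
        # primers that are reverse complements of one 20-mer site give the
        # shortest possible amplicon (20, fully overlapping footprints)
        rng = np.random.default_rng(61)
        site = random_seq(rng, 20)
        m20 = DetectionMethod(
            "M20", "element_specific", "t", site, reverse_complement(site)
        )
        t = random_seq(rng, 25) + site + random_seq(rng, 25)
        hits = [h for h in enumerate_amplicons(m20, t) if h.pair_kind == "p1_p2"]
        assert [h.amplicon_length for h in hits] == [20]

        # a one-base stagger yields a 19-base span: rejected at the default
        # lower bound, present when the bound is relaxed
        t2 = random_seq(rng, 30) + random_seq(rng, 21) + random_seq(rng, 30)
        m19 = DetectionMethod(
            "M19", "element_specific", "t",
            t2[31:51], reverse_complement(t2[30:50]),
        )
        assert enumerate_amplicons(m19, t2) == []
        relaxed = PCRParams(amplicon_min=19)
        hits19 = enumerate_amplicons(m19, t2, params=relaxed)
        assert [h.amplicon_length for h in hits19] == [19]

    def test_self_pairing_forward_with_forward(self, method):
        rng = np.random.default_rng(7)
        t = method.primer1 + random_seq(rng, 30) + reverse_complement(method.primer1)
        hits = enumerate_amplicons(method, t)
        assert [h.pair_kind for h in hits] == ["p1_p1"]
        assert hits[0].is_self_pair

    def test_primer_swap_symmetry(self, method):
        rng = np.random.default_rng(9)
        t = (
            random_seq(rng, 20)
            + method.primer1
            + random_seq(rng, 60)
            + reverse_complement(method.primer2)
            + random_seq(rng, 20)
        )
        swapped = DetectionMethod(
            "M1", "element_specific", "t", method.primer2, method.primer1
        )
        a = {(h.start, h.end, h.total_edits)
             for h in enumerate_amplicons(method, t) if h.pair_kind == "p1_p2"}
        b = {(h.start, h.end, h.total_edits)
             for h in enumerate_amplicons(swapped, t) if h.pair_kind == "p1_p2"}
        assert a == b != set()

    def test_strand_symmetry_of_hit_multiset(self, method):
        rng = np.random.default_rng(10)
        for _ in range(5):
            t = (
                random_seq(rng, 15)
                + method.primer1
                + random_seq(rng, 40)
                + reverse_complement(method.primer1)
                + random_seq(rng, 25)
                + method.primer2
                + random_seq(rng, 50)
                + reverse_complement(method.primer2)
                + random_seq(rng, 15)
            )
            fwd = sorted(
                (h.pair_kind, h.amplicon_length, h.total_edits)
                for h in enumerate_amplicons(method, t)
            )
            # on the reverse complement, primer1/primer2 roles mirror
            rev = sorted(
                (h.pair_kind, h.amplicon_length, h.total_edits)
                for h in enumerate_amplicons(method, reverse_complement(t))
            )
            assert fwd == rev

    def test_every_hit_respects_budgets_and_bounds(self, small_panel):
        params = PCRParams()
        for event in small_panel.events[:3]:
            for method in small_panel.methods:
                for h in enumerate_amplicons(method, event.sequences[0], params=params):
                    assert params.amplicon_min <= h.amplicon_length <= params.amplicon_max
                    for site in (h.left_site, h.right_site):
                        assert site.mismatches <= params.max_mismatches
                        assert site.gap_bases <= params.max_gaps
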