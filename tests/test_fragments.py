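"""Fragment ladders, isoform-specific ions and tryptic digestion.

Specificity is checked against a brute-force residue-window oracle and
digestion against exhaustive enumeration over cleavage-site bitmasks.
"""

from itertools import combinations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from simc.chem import ModKind, Modification, Peptide, peptide_mass
from simc.fragments import (
    CleavageRule,
    IsobaricGroup,
    digest,
    find_specific_ions,
    generate_fragments,
)
from simc.histone import k27_r40, l20_r52

AA = "ACDEFGHIKLMNPQRSTVWY"


def ladder_by_slot(p, series=("b", "y"), max_charge=2):
    return {
        (f.series, f.index, f.charge): f.mz
        for f in generate_fragments(p, series, max_charge)
    }


class TestGenerateFragments:
    def test_y13_doubly_charged_discriminating_pair(self, iso_a, iso_b):
        # the flagship discriminating ion pair of the pentamethyl isoforms
        assert ladder_by_slot(iso_a)[("y", 13, 2)] == pytest.approx(
            667.3886, abs=5e-4
        )
        assert ladder_by_slot(iso_b)[("y", 13, 2)] == pytest.approx(
            674.3964, abs=5e-4
        )

    def test_y1_of_arginine_terminus(self, iso_a):
        assert ladder_by_slot(iso_a)[("y", 1, 1)] == pytest.approx(
            175.1190, abs=5e-4
        )

    def test_ladder_completeness(self, iso_a):
        ions = generate_fragments(iso_a, ("b", "y"), max_charge=2)
        n = len(iso_a.sequence)
        for series in "by":
            for z in (1, 2):
                assert sum(
                    1 for f in ions if f.series == series and f.charge == z
                ) == n - 1

    @given(st.text(alphabet=AA, min_size=2, max_size=12))
    def test_by_complementarity_exact(self, seq):
        p = Peptide(seq)
        slots = ladder_by_slot(p, max_charge=1)
        from simc.chem import PROTON

        n = len(seq)
        for i in range(1, n):
            b_neutral = slots[("b", i, 1)] - PROTON
            y_neutral = slots[("y", n - i, 1)] - PROTON
            assert b_neutral + y_neutral == pytest.approx(
                peptide_mass(p), abs=1e-9
            )

    def test_invalid_max_charge(self, iso_a):
        with pytest.raises(ValueError):
            generate_fragments(iso_a, max_charge=0)


def window_oracle(group, series, index):
    """Brute force: a slot discriminates iff the summed modification mass
    inside the fragment's residue window differs between every isoform pair."""
    peps = list(group.isoforms.values())
    n = len(peps[0].sequence)
    start, end = peps[0].start_position, peps[0].end_position
    if series == "b":
        window = range(start, start + index)
    else:
        window = range(end - index + 1, end + 1)
    sums = [
        sum(m.delta for s, m in p.mods.items() if s in window) for p in peps
    ]
    return all(abs(a - b) > 1e-6 for a, b in combinations(sums, 2))


class TestSpecificIons:
    def test_pentamethyl_pair_slots(self, pair):
        spec = find_specific_ions(pair, ("b", "y"), (1, 2))
        for ions in spec.values():
            y_idx = sorted({f.index for f in ions if f.series == "y"})
            b_idx = sorted({f.index for f in ions if f.series == "b"})
            assert y_idx == list(range(5, 14))
            assert b_idx == list(range(1, 10))

    def test_matches_window_oracle(self, pair):
        spec = find_specific_ions(pair, ("b", "y"), (1,))
        found = {(f.series, f.index) for f in next(iter(spec.values()))}
        n = len(next(iter(pair.isoforms.values())).sequence)
        for series in "by":
            for index in range(1, n):
                assert (
                    (series, index) in found
                ) == window_oracle(pair, series, index)

    def test_duplicated_isoform_yields_empty_set(self, iso_a):
        group = IsobaricGroup(isoforms={"a": iso_a, "a2": iso_a})
        spec = find_specific_ions(group)
        assert all(len(v) == 0 for v in spec.values())

    def test_adjacent_sites_leave_single_discriminating_slot(self):
        # isoforms differing only at adjacent K36/K37: exactly y4 and b10
        a = Peptide("KSAPATGGVKKPHR", 27, {
            36: Modification(ModKind.METHYL, 3),
            37: Modification(ModKind.METHYL, 2),
        })
        b = Peptide("KSAPATGGVKKPHR", 27, {
            36: Modification(ModKind.METHYL, 2),
            37: Modification(ModKind.METHYL, 3),
        })
        spec = find_specific_ions(
            IsobaricGroup(isoforms={"a": a, "b": b}), ("b", "y"), (1,)
        )
        slots = {(f.series, f.index) for f in spec["a"]}
        assert slots == {("y", 4), ("b", 10)}

    def test_non_isobaric_isoforms_rejected(self, iso_a):
        other = k27_r40(3, 3)
        with pytest.raises(ValueError, match="isobaric"):
            IsobaricGroup(isoforms={"a": iso_a, "b": other})

    def test_paired_specific_ions_differ_by_methyl_multiples(self, pair):
        spec = find_specific_ions(pair, ("y",), (2,))
        a, b = (sorted(v, key=lambda f: f.index) for v in spec.values())
        for fa, fb in zip(a, b):
            diff = abs(fa.mz - fb.mz) * fa.charge / 14.015650
            assert diff == pytest.approx(round(diff), abs=1e-4)
            assert round(diff) >= 1


def bitmask_digest_oracle(p: Peptide, rule: CleavageRule):
    """All products over every cut/no-cut assignment of cleavable sites,
    keeping those with at most max_missed internal cleavable sites."""
    sites = [
        pos
        for pos in range(p.start_position, p.end_position)
        if rule.is_cleavable(p, pos)
    ]
    products = set()
    for mask in range(2 ** len(sites)):
        cuts = [s for k, s in enumerate(sites) if mask >> k & 1]
        bounds = [p.start_position - 1] + cuts + [p.end_position]
        for lo, hi in zip(bounds, bounds[1:]):
            internal = sum(1 for s in sites if lo + 1 <= s < hi)
            if internal <= rule.max_missed_cleavages:
                products.add((lo + 1, hi))
    return products


class TestDigest:
    def test_modified_long_peptide_yields_k27_r40_fully_cleaved(self):
        long_pep = l20_r52(3, 2)
        rule = CleavageRule(max_missed_cleavages=0)
        products = digest(long_pep, rule)
        spans = {(q.start_position, q.end_position) for q in products}
        assert (27, 40) in spans
        k27r40 = next(q for q in products if q.start_position == 27)
        assert k27r40.sequence == "KSAPATGGVKKPHR"
        assert set(k27r40.mods) == {27, 36}

    def test_unmodified_long_peptide_cuts_k27(self):
        products = digest(l20_r52(), CleavageRule(max_missed_cleavages=5))
        spans = {(q.start_position, q.end_position) for q in products}
        fully = {
            (q.start_position, q.end_position)
            for q in digest(l20_r52(), CleavageRule(max_missed_cleavages=0))
        }
        assert (27, 40) not in fully  # K27 cleavable when unmethylated
        assert (28, 40) in spans  # S28-R40 via one missed cleavage at K36
        assert (27, 36) in spans  # K27-K36 via one missed cleavage at K27

    def test_proline_always_blocks(self):
        # K37 is followed by P38: no product may end at 37
        for mods in [(0, 0), (3, 2), (1, 1)]:
            for q in digest(l20_r52(*mods)):
                assert q.end_position != 37

    def test_monomethyl_lysine_still_cleavable(self):
        products = digest(
            l20_r52(k27_methyls=1), CleavageRule(max_missed_cleavages=0)
        )
        ends = {q.end_position for q in products}
        assert 27 in ends  # cut after monomethyl-K27

    def test_acetyl_lysine_blocks(self):
        p = Peptide("AKGR", 1, {2: Modification(ModKind.ACETYL, 1)})
        spans = {
            (q.start_position, q.end_position)
            for q in digest(p, CleavageRule(max_missed_cleavages=0))
        }
        assert spans == {(1, 4)}

    def test_no_cleavage_sites_returns_input(self):
        p = Peptide("GAVLI")
        products = digest(p)
        assert len(products) == 1
        assert products[0].sequence == "GAVLI"

    @pytest.mark.parametrize("mods", [(0, 0), (3, 2), (2, 3), (1, 2)])
    @pytest.mark.parametrize("missed", [0, 2, 5])
    def test_matches_bitmask_oracle(self, mods, missed):
        p = l20_r52(*mods)
        rule = CleavageRule(max_missed_cleavages=missed)
        got = {(q.start_position, q.end_position) for q in digest(p, rule)}
        assert got == bitmask_digest_oracle(p, rule)

    def test_products_inherit_protein_numbering(self):
        for q in digest(l20_r52(3, 2)):
            for site in q.mods:
                assert q.start_position <= site <= q.end_position
                assert q.residue_at(site) == "K"
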