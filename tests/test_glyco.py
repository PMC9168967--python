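"""Glycan compositions, structures, fragments and feature classification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycosite import glyco
from glycosite.glyco import (
    Composition,
    GlycanStructure,
    composition_mass,
    enumerate_structures,
    oxonium_mz,
    parse_composition,
    parse_structure,
    serialize_composition,
    theoretical_B_ions,
    theoretical_Y_ions,
)

# Independent residue-mass table for oracle summation (kept separate from the
# package constants on purpose).
ORACLE_MASS = {"N": 203.079373, "H": 162.052824, "F": 146.057909, "S": 291.095417}


def oracle_mass(text: str) -> float:
    total, i = 0.0, 0
    while i < len(text):
        letter, i = text[i], i + 1
        j = i
        while j < len(text) and text[j].isdigit():
            j += 1
        total += ORACLE_MASS[letter] * int(text[i:j])
        i = j
    return total


class TestCompositionMass:
    def test_empty_composition_is_zero(self):
        assert composition_mass(Composition()) == 0.0

    @pytest.mark.parametrize(
        "text",
        ["N5H4F1S1", "N2H3", "N4H5F1", "N1S1", "N6H7F3S3"],
    )
    def test_matches_independent_summation_oracle(self, text):
        comp = parse_composition(text)
        assert composition_mass(comp) == pytest.approx(oracle_mass(text), abs=1e-9)

    def test_negative_count_rejected(self):
        with pytest.raises(glyco.GlycanCompositionError):
            composition_mass(Composition(-1, 0, 0, 0))

    @given(
        a=st.tuples(*[st.integers(0, 6)] * 4),
        b=st.tuples(*[st.integers(0, 6)] * 4),
    )
    def test_mass_additivity(self, a, b):
        ca, cb = Composition(*a), Composition(*b)
        assert composition_mass(ca + cb) == pytest.approx(
            composition_mass(ca) + composition_mass(cb), abs=1e-9
        )


class TestOxonium:
    @pytest.mark.parametrize(
        "text,expected",
        [("N2", 407.17), ("N1S1", 495.18), ("N2S1", 698.26)],
    )
    def test_diagnostic_b_ion_mz(self, text, expected):
        assert round(oxonium_mz(parse_composition(text)), 2) == expected

    def test_hexnac2_fuc_matches_oracle(self):
        mz = oxonium_mz(parse_composition("N2F1"))
        assert mz == pytest.approx(oracle_mass("N2F1") + 1.007276, abs=1e-9)

    def test_empty_fragment_rejected(self):
        with pytest.raises(glyco.GlycanCompositionError):
            oxonium_mz(Composition())

    def test_charge_two_halves_protonated_mass(self):
        c = parse_composition("N2S1")
        assert oxonium_mz(c, 2) == pytest.approx(
            (composition_mass(c) + 2 * 1.007276) / 2
        )


class TestCompositionText:
    @pytest.mark.parametrize(
        "text,counts",
        [
            ("N5H4F1S1", (5, 4, 1, 1)),
            ("N2H3", (2, 3, 0, 0)),
            ("H3", (0, 3, 0, 0)),
        ],
    )
    def test_parse(self, text, counts):
        assert parse_composition(text) == Composition(*counts)

    @pytest.mark.parametrize("text", ["N4H5F1", "N2H3", "N1S1", "N12H2"])
    def test_round_trip(self, text):
        assert serialize_composition(parse_composition(text)) == text

    @pytest.mark.parametrize("bad", ["X2", "N", "N2Q1", "2N"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(glyco.GlycanCompositionError):
            parse_composition(bad)


def brute_force_enumerate(comp, library):
    """Independent combination oracle: try every core x bounded motif
    multiset and keep exact composition matches."""
    motifs = sorted(library, key=lambda m: m.name)
    found = set()
    for kind in glyco.CORE_KINDS:
        residual = comp - glyco.core_composition(kind)
        if not residual.is_nonnegative():
            continue
        max_count = residual.total()
        for n in range(0, min(glyco.MAX_BRANCHES, max_count) + 1):
            for combo in itertools.combinations_with_replacement(motifs, n):
                total = Composition()
                for m in combo:
                    total = total + m.composition
                if total != residual:
                    continue
                if sum(1 for m in combo if m.family != "Mannose") > glyco.MAX_NON_MANNOSE_ANTENNAE:
                    continue
                found.add(GlycanStructure(kind, combo).canonical)
    return found


class TestEnumeration:
    def test_bare_core_forced(self, library):
        structures = enumerate_structures(parse_composition("N2H3"), library)
        assert [s.canonical for s in structures] == ["C|"]

    def test_fig2f_composition_yields_at_least_seven_isoforms(self, library):
        assert len(enumerate_structures(parse_composition("N4H5F1"), library)) >= 7

    def test_lacdinac_and_bisecting_assemblies_coexist(self, library):
        cans = [s.canonical for s in enumerate_structures(parse_composition("N5H4"), library)]
        assert any("LacdiNAc" in c for c in cans)
        assert any(c.startswith("CB|") and "LacNAc" in c for c in cans)

    def test_sub_core_composition_gives_empty_set(self, library):
        assert enumerate_structures(parse_composition("N1H1"), library) == []

    @pytest.mark.parametrize(
        "text", ["N2H3", "N3H3", "N2H5", "N4H5F1", "N5H4", "N3H4S1", "N4H4F1"]
    )
    def test_agrees_with_brute_force_oracle(self, text, library):
        comp = parse_composition(text)
        got = {s.canonical for s in enumerate_structures(comp, library)}
        assert got == brute_force_enumerate(comp, library)

    def test_compositions_exact_and_duplicate_free(self, library):
        comp = parse_composition("N4H5F1")
        structures = enumerate_structures(comp, library)
        assert all(s.composition == comp for s in structures)
        cans = [s.canonical for s in structures]
        assert len(cans) == len(set(cans))


class TestStructureEncoding:
    def test_round_trip_identity(self, library):
        for text in ["C|LacNAc,LacNAc-S", "CF|LacNAc,LacdiNAc-S", "CB|", "C|Man2"]:
            assert parse_structure(text, library).canonical == text

    def test_branch_permutation_invariance(self, library):
        a = GlycanStructure("plain", (library.get("LacNAc"), library.get("LacdiNAc-S")))
        b = GlycanStructure("plain", (library.get("LacdiNAc-S"), library.get("LacNAc")))
        assert a.canonical == b.canonical

    def test_composition_is_core_plus_branches(self, library):
        s = parse_structure("CF|LacNAc,LacdiNAc-S", library)
        assert s.composition.serialize() == "N5H4F1S1"


class TestFragmentIons:
    def test_sialylated_lacdinac_branch_yields_diagnostic_b_ions(self, library):
        s = parse_structure("CF|LacNAc,LacdiNAc-S", library)
        mzs = {round(mz, 2) for _, mz in theoretical_B_ions(s)}
        assert {407.17, 495.18, 698.26} <= mzs

    def test_bare_core_has_only_single_residue_oxonium_ions(self, library):
        s = parse_structure("C|", library)
        assert all(c.total() == 1 for c, _ in theoretical_B_ions(s))

    def test_b_ions_sorted_and_deduplicated(self, library):
        s = parse_structure("C|LacNAc-FS,LacdiNAc-S", library)
        ions = theoretical_B_ions(s)
        mzs = [mz for _, mz in ions]
        assert mzs == sorted(mzs)
        assert len({c for c, _ in ions}) == len(ions)

    def test_b_ions_match_per_branch_prefix_oracle(self, library):
        s = parse_structure("CB|LacNAc-S,LacNAc-S", library)
        got = {c for c, _ in theoretical_B_ions(s)}
        # oracle: enumerate suffix fragments of each branch by hand
        lacnac_s = library.get("LacNAc-S")
        expected = set()
        for codes in [("Hex",), ("HexNAc", "Hex")]:
            for dec in [(), ("NeuAc",)]:
                expected.add(glyco.comp_from_codes(codes + dec))
        expected |= {glyco.comp_from_codes([c]) for c in ("HexNAc", "Hex", "NeuAc")}
        assert got == expected

    def test_y0_is_peptide_plus_proton(self, library):
        s = parse_structure("C|LacNAc,LacNAc", library)
        ions = theoretical_Y_ions(s, 1500.0, (1,))
        y0 = [mz for c, z, mz in ions if c.total() == 0]
        assert y0 == [pytest.approx(1501.007276)]

    def test_core_fucosylated_structure_has_fucose_shifted_core_y_ion(self, library):
        s = parse_structure("CF|LacNAc,LacNAc", library)
        comps = {c for c, _, _ in theoretical_Y_ions(s, 1500.0, (1,))}
        assert parse_composition("N2H3F1") in comps

    def test_y_ion_mz_matches_mass_ladder_oracle(self, library):
        s = parse_structure("CF|LacNAc,LacdiNAc-S", library)
        pep = 1740.8123
        for comp, z, mz in theoretical_Y_ions(s, pep, (2, 3)):
            expected = (pep + oracle_mass(comp.serialize()) + z * 1.007276) / z
            if comp.total() == 0:
                expected = (pep + z * 1.007276) / z
            assert mz == pytest.approx(expected, abs=1e-9)

    def test_by_complementarity_on_branch_fragments(self, library):
        """mass(fragment) + mass(structure minus fragment) == mass(structure)."""
        for text in ["C|LacNAc,LacNAc-S", "CF|LacNAc,LacdiNAc-S", "CB|LacNAc,LacNAc"]:
            s = parse_structure(text, library)
            total = composition_mass(s.composition)
            for frag, _ in theoretical_B_ions(s):
                rest = s.composition - frag
                assert rest.is_nonnegative()
                assert composition_mass(frag) + composition_mass(rest) == pytest.approx(
                    total, abs=1e-9
                )


class TestClassifyFeatures:
    def test_man5_is_oligo_mannose(self, library):
        f = glyco.classify_features(parse_structure("C|Man2", library))
        assert f.subtype == "oligo_mannose"
        assert f.n_fucose == 0

    def test_fig2e_structure_features(self, library):
        f = glyco.classify_features(parse_structure("CF|LacNAc,LacdiNAc-S", library))
        assert f.has_lacdinac and f.has_core_fucose
        assert f.n_sialic == 1
        assert f.subtype == "complex"

    def test_triantennary_with_antenna_and_core_fucose(self, library):
        f = glyco.classify_features(
            parse_structure("CF|LacNAc-F,LacNAc-F,LacNAc", library)
        )
        assert f.n_fucose == 3
        assert f.antenna_fucose and f.has_core_fucose
        assert f.n_antennae == 3

    def test_hybrid_mixes_hexnac_and_mannose_antennae(self, library):
        f = glyco.classify_features(parse_structure("C|LacNAc-S,Man2", library))
        assert f.subtype == "hybrid"

    @settings(max_examples=50, deadline=None)
    @given(data=st.data())
    def test_fucose_count_equals_composition_fucose(self, data, library):
        motifs = sorted(library, key=lambda m: m.name)
        names = data.draw(
            st.lists(st.sampled_from([m.name for m in motifs]), min_size=0, max_size=4)
        )
        kind = data.draw(st.sampled_from(glyco.CORE_KINDS))
        s = GlycanStructure(kind, tuple(library.get(n) for n in names))
        f = glyco.classify_features(s)
        assert f.n_fucose == s.composition.fuc
        assert f.n_sialic == s.composition.neuac
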