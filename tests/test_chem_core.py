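"""Formula arithmetic, amino-acid tables and isotope patterns."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cuspec.chem_core import (
    AMINO_ACIDS,
    DEFAULT_ELEMENTS,
    ChemError,
    MolecularFormula,
    UnknownAminoAcidError,
    UnknownElementError,
    complex_formula,
    isotope_pattern,
    load_tables,
    monoisotopic_mass,
    nominal_mass,
)
from oracle_utils import brute_isotope_bins

F = MolecularFormula.from_string


class TestMasses:
    @pytest.mark.parametrize(
        "formula, expected",
        [("H2O", 18), ("CO2", 44), ("C4H7NO", 85), ("C4H9N", 71), ("Cu", 63)],
    )
    def test_nominal(self, formula, expected):
        assert nominal_mass(F(formula)) == expected

    @pytest.mark.parametrize(
        "formula, expected",
        [("H2O", 18.0106), ("Cu", 62.9296), ("C2H3NO", 57.0215)],
    )
    def test_monoisotopic(self, formula, expected):
        assert monoisotopic_mass(F(formula)) == pytest.approx(expected, abs=1e-4)

    def test_empty_formula_rejected(self):
        with pytest.raises(ChemError):
            nominal_mass(MolecularFormula())
        with pytest.raises(ChemError):
            monoisotopic_mass(MolecularFormula())

    def test_unknown_element_named(self):
        with pytest.raises(UnknownElementError, match="Xx"):
            nominal_mass(MolecularFormula({"Xx": 1}))

    def test_charge_does_not_alter_mass(self):
        assert F("H2O").nominal_mass() == F("H2O").replace_charge(1).nominal_mass()

    @given(
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "S", "Cu"]),
            st.integers(min_value=0, max_value=20),
            min_size=1,
        ).filter(lambda d: any(v > 0 for v in d.values())),
        st.sampled_from(["C", "H", "N", "O", "S"]),
    )
    def test_mass_monotone_under_element_addition(self, counts, extra):
        f = MolecularFormula(counts)
        g = f + MolecularFormula({extra: 1})
        assert g.nominal_mass() > f.nominal_mass() >= 0
        assert g.monoisotopic_mass() > f.monoisotopic_mass() >= 0

    def test_subtraction_cannot_go_negative(self):
        with pytest.raises(ChemError):
            F("H2O") - F("C")


class TestElementTable:
    def test_abundances_sum_to_one(self):
        for el in DEFAULT_ELEMENTS.values():
            assert sum(i.abundance for i in el.isotopes) == pytest.approx(
                1.0, abs=1e-6
            )

    def test_copper_doublet_convention(self):
        cu = DEFAULT_ELEMENTS["Cu"]
        assert len(cu.isotopes) == 2
        assert sorted(i.abundance for i in cu.isotopes) == [0.31, 0.69]


class TestAminoAcids:
    def test_covers_20_proteinogenic(self):
        assert len(AMINO_ACIDS) == 20

    def test_residue_is_free_minus_water(self):
        for aa in AMINO_ACIDS.values():
            assert aa.residue_nominal() == aa.free_nominal() - 18

    @pytest.mark.parametrize(
        "code, free_nominal",
        [("Gly", 75), ("Asp", 133), ("His", 155), ("Phe", 165), ("Tyr", 181)],
    )
    def test_reference_free_masses(self, code, free_nominal):
        assert AMINO_ACIDS[code].free_nominal() == free_nominal


class TestIsotopePattern:
    def test_copper_doublet(self):
        p = isotope_pattern(F("Cu"))
        assert len(p.peaks) == 2
        (m1, r1), (m2, r2) = p.peaks
        assert r1 == 100.0
        assert m2 - m1 == pytest.approx(1.9982, abs=1e-3)
        assert r2 / r1 == pytest.approx(31 / 69, abs=1e-3)

    def test_water_single_dominant_peak(self):
        p = isotope_pattern(F("H2O"), min_rel_intensity=1.0)
        assert len(p.peaks) == 1
        assert p.peaks[0][1] == 100.0

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ChemError):
            isotope_pattern(F("Cu"), min_rel_intensity=0.0)
        with pytest.raises(ChemError):
            isotope_pattern(F("Cu"), min_rel_intensity=100.0)

    @pytest.mark.parametrize(
        "counts",
        [
            {"Cu": 1},
            {"C": 4, "H": 7, "N": 1, "O": 1},
            {"C": 20, "H": 30, "Cu": 1, "N": 4, "O": 7},
            {"C": 9, "H": 12, "Cu": 1, "N": 1, "O": 2, "S": 1},
        ],
    )
    def test_matches_brute_force_enumeration(self, counts):
        """Convolution equals an independent multinomial enumeration."""
        p = isotope_pattern(MolecularFormula(counts), min_rel_intensity=0.01)
        oracle = brute_isotope_bins(counts)
        base = max(oracle.values())
        expected = {m: 100.0 * (v / base) for m, v in oracle.items()
                    if 100.0 * (v / base) >= 0.01}
        got = p.binned()
        assert set(got) == set(expected)
        for m in expected:
            assert got[m] == pytest.approx(expected[m], rel=1e-9)

    @given(
        st.fixed_dictionaries(
            {},
            optional={
                "C": st.integers(1, 20),
                "H": st.integers(1, 30),
                "N": st.integers(0, 5),
                "O": st.integers(0, 8),
                "S": st.integers(0, 1),
            },
        )
    )
    def test_any_one_copper_pattern_keeps_doublet(self, organic):
        """The A+2/A ratio of a one-copper species never drops below the
        pure-copper 0.449 and stays a usable doublet (>= 0.40)."""
        counts = {k: v for k, v in organic.items() if v > 0}
        counts["Cu"] = 1
        p = isotope_pattern(MolecularFormula(counts), min_rel_intensity=0.01)
        bins = p.binned()
        base = round(p.base_mz)
        assert bins.get(base + 2, 0.0) / bins[base] >= 0.40


class TestComplexFormula:
    @pytest.mark.parametrize(
        "ligands, bonds, waters, metal, polarity, expected",
        [
            (["Gly", "Phe"], 0, 0, "Cu", "+", 302),
            (["Gly", "Phe"], 0, 0, "Cu", "-", 300),
            (["His", "Asp"], 1, 0, "Cu", "-", 330),
            (["Phe", "Asp"], 0, 0, "Cu", "+", 360),
            (["Phe", "Asp"], 0, 0, "Cu", "-", 358),
            (["Tyr", "Ser", "Thr"], 1, 2, "Cu", "-", 483),
            (["Gly"], 0, 0, None, "+", 76),
        ],
    )
    def test_reported_quasi_molecular_ions(
        self, ligands, bonds, waters, metal, polarity, expected
    ):
        ion = complex_formula(ligands, bonds, waters, metal, polarity)
        assert ion.nominal_mz == expected

    @given(st.permutations(["Gly", "Phe", "Asp", "Val"]))
    def test_symmetric_under_ligand_reordering(self, order):
        ref = complex_formula(["Asp", "Gly", "Phe", "Val"], 2, 1, "Cu", "-")
        got = complex_formula(list(order), 2, 1, "Cu", "-")
        assert got.formula == ref.formula
        assert got.nominal_mz == ref.nominal_mz

    def test_invalid_inputs_rejected(self):
        with pytest.raises(UnknownAminoAcidError, match="Xyz"):
            complex_formula(["Xyz"], 0, 0)
        with pytest.raises(ChemError):
            complex_formula(["Gly"], 1, 0)  # bonds > n-1
        with pytest.raises(ChemError):
            complex_formula([], 0, 0)


class TestConfigOverride:
    def test_yaml_tables_merge_over_defaults(self, tmp_path):
        cfg = tmp_path / "tables.yaml"
        cfg.write_text(
            "elements:\n"
            "  Zn:\n"
            "    isotopes: [[63.9291, 0.492], [65.9260, 0.277],"
            " [66.9271, 0.040], [67.9248, 0.185], [69.9253, 0.006]]\n"
            "amino_acids:\n"
            "  Hyp: C5H9NO3\n"
        )
        elements, aas = load_tables(cfg)
        assert "Cu" in elements and "Zn" in elements
        assert elements["Zn"].nominal_mass == 64
        assert aas["Hyp"].free_nominal() == 131
        assert len(aas) == 21
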