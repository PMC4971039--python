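"""Neutral-loss annotation of CID product ions."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cuspec.chem_core import ChemError
from cuspec.fragment_annotate import (
    LossLibrary,
    annotate_chain,
    annotate_products,
    cu_fragment_mz,
    flag_cu_products,
    formula_matches_mz,
)
from cuspec.isotope_screen import PeakList
import numpy as np


class TestLossLibrary:
    def test_default_contains_small_losses_and_residues(self):
        labels = {e.label for e in LossLibrary.default()}
        assert {"H2O", "2H2O", "CO", "CO2", "NH3", "C2H3NO", "H2"} <= labels
        assert "Gly" in labels and "Gly(res)" in labels
        assert len([l for l in labels if l.endswith("(res)")]) == 20

    def test_ligand_restricted_library(self):
        labels = {e.label for e in LossLibrary.for_ligands(["Thr", "Tyr"])}
        assert "Thr" in labels and "Val" not in labels

    def test_duplicate_labels_rejected(self):
        e = list(LossLibrary.default())[:1]
        with pytest.raises(ChemError):
            LossLibrary(e + e)


class TestCuFragment:
    @pytest.mark.parametrize(
        "code, polarity, expected",
        [("Phe", "+", 227), ("Phe", "-", 225), ("Gly", "+", 137),
         ("His", "-", 215)],
    )
    def test_single_amino_acid_copper_fragments(self, code, polarity, expected):
        assert cu_fragment_mz(code, polarity) == expected

    def test_unknown_code_rejected(self):
        with pytest.raises(ChemError):
            cu_fragment_mz("Xyz", "+")


class TestAnnotation:
    def test_single_co2_loss(self):
        lib = LossLibrary.for_ligands(["Val", "Phe", "Ala"])
        (a,) = annotate_products(429, [385], lib)
        assert a.explained
        assert a.losses == ("CO2",)
        assert a.n_h2_adjustments == 0

    def test_alanine_loss_with_hydrogen_gain(self):
        lib = LossLibrary.for_ligands(["Val", "Phe", "Ala"])
        (a,) = annotate_products(385, [298], lib)
        assert a.losses == ("Ala",) and a.n_h2_adjustments == -1

    def test_printed_three_step_chain(self):
        """483 -2H2O-> 447 -C2H3NO-> 390 -Thr+H2-> 273."""
        lib = LossLibrary.for_ligands(["Tyr", "Ser", "Thr"])
        anns = annotate_chain([483, 447, 390, 273], lib)
        assert [(a.losses, a.n_h2_adjustments) for a in anns] == [
            (("2H2O",), 0),
            (("C2H3NO",), 0),
            (("Thr",), -1),
        ]

    def test_one_step_losses_found_directly(self):
        """Oracle: a product equal to precursor minus one library entry is
        always explained in a single step with no H2 fiddling."""
        lib = LossLibrary.for_ligands(["Gly", "Phe"])
        for entry in lib:
            if entry.label == "H2":
                continue
            prec = 400
            (a,) = annotate_products(prec, [prec - entry.nominal], lib)
            assert a.explained
            assert len(a.losses) == 1 and a.n_h2_adjustments == 0
            assert a.net_loss_mass(lib) == entry.nominal

    def test_conservation_of_mass_on_all_outputs(self):
        lib = LossLibrary.default()
        prods = [385, 298, 273, 199, 137, 130]
        for a in annotate_products(429, prods, lib):
            if a.explained:
                assert a.net_loss_mass(lib) == a.parent_mz - a.product_mz

    def test_unexplained_product_returned_unannotated(self):
        lib = LossLibrary(
            [e for e in LossLibrary.default() if e.label == "H2O"]
        )
        (a,) = annotate_products(400, [301], lib, max_steps=2, max_h2=1)
        assert not a.explained and a.losses == ()

    def test_product_above_precursor_rejected_by_name(self):
        with pytest.raises(ChemError, match="431"):
            annotate_products(429, [431])

    @given(st.integers(min_value=1, max_value=3))
    def test_pure_h2_differences_use_adjustment_channel(self, k):
        (a,) = annotate_products(400, [400 - 2 * k])
        assert a.explained and a.losses == () and a.n_h2_adjustments == k


class TestTable2Chains:
    """All five reported complexes' product chains, annotated with the
    ligand-restricted library, reproduce the printed interpretations."""

    CHAINS = [
        (["Phe", "Asp"], [360, 247], [(("Asp(res)",), -1)]),
        (["Gly", "Phe"], [302, 227, 199], [(("Gly",), 0), (("CO",), 0)]),
        (["Val", "Phe", "Ala"], [429, 385, 298],
         [(("CO2",), 0), (("Ala",), -1)]),
        (["Tyr", "Ser", "Thr"], [483, 447, 390, 273],
         [(("2H2O",), 0), (("C2H3NO",), 0), (("Thr",), -1)]),
        (["His", "Asp"], [330, 185], [(("Asp(res)", "CO"), 1)]),
    ]

    @pytest.mark.parametrize("ligands, chain, expected", CHAINS)
    def test_chain(self, ligands, chain, expected):
        lib = LossLibrary.for_ligands(ligands)
        anns = annotate_chain(chain, lib)
        assert all(a.explained for a in anns)
        assert [(a.losses, a.n_h2_adjustments) for a in anns] == expected


class TestCuFlags:
    def test_planted_fragment_flagged(self, table2_spectrum):
        spectrum, manifest = table2_spectrum
        products = [float(c["mz"]) for c in manifest["complexes"]]
        flags = flag_cu_products(products, spectrum)
        assert all(flags.values())

    def test_product_without_partner_not_flagged(self):
        sp = PeakList.from_peaks([(86, 500.0), (300, 1000.0), (302, 449.0)])
        flags = flag_cu_products([86, 300], sp)
        assert flags[86] is False
        assert flags[300] is True

    def test_empty_spectrum_all_false(self):
        sp = PeakList(np.array([]), np.array([]))
        assert flag_cu_products([86, 130], sp) == {86.0: False, 130.0: False}


class TestSmallFragments:
    @pytest.mark.parametrize(
        "formula, mz, matches",
        [("C4H7NO", 86, True), ("C4H9N", 72, True), ("C4H7NO", 90, False)],
    )
    def test_neutral_formula_matches_within_one_hydrogen(
        self, formula, mz, matches
    ):
        assert formula_matches_mz(formula, mz) is matches
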