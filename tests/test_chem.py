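"""Exact-mass arithmetic: formula templates, adducts, scan constants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pyteomics_mass

from lipidcc import chem
from lipidcc.chem import (
    ADDUCTS,
    AcylChain,
    Adduct,
    ChemicalFormula,
    FormulaError,
    LipidSpecies,
    SpeciesError,
    acyl_anion_mz,
    formula_of_species,
    headgroup_scan,
    monoisotopic_mass,
    nominal_mz,
    parse_species,
    precursor_mz,
)

F = ChemicalFormula.from_string


class TestChemicalFormula:
    def test_arithmetic_is_elementwise(self):
        assert F("C3H6O") + F("H2O") == F("C3H8O2")
        assert F("C3H8O2") - F("H2O") == F("C3H6O")

    def test_subtraction_below_zero_is_an_error(self):
        with pytest.raises(FormulaError):
            F("CH4") - F("O")

    @given(
        st.dictionaries(st.sampled_from("CHNOP"), st.integers(0, 60), max_size=5),
        st.dictionaries(st.sampled_from("CHNOP"), st.integers(0, 60), max_size=5),
    )
    @settings(max_examples=100, derandomize=True)
    def test_mass_is_additive_and_addition_commutes(self, a, b):
        fa, fb = ChemicalFormula.from_dict(a), ChemicalFormula.from_dict(b)
        assert fa + fb == fb + fa
        assert monoisotopic_mass(fa + fb) == pytest.approx(
            monoisotopic_mass(fa) + monoisotopic_mass(fb), abs=1e-9
        )
        assert (fa + fb) - fb == fa

    @pytest.mark.parametrize(
        "text,expected",
        [("H2O", 18.010565), ("C3H6O", 58.041865), ("", 0.0), ("C2H2", 26.015650)],
    )
    def test_masses(self, text, expected):
        assert monoisotopic_mass(F(text)) == pytest.approx(expected, abs=1e-5)

    def test_masses_agree_with_pyteomics(self):
        # independent element-mass source
        for text in ("C3H6O", "C2H8NO4P", "C44H80NO8P", "C18H34O2"):
            ours = monoisotopic_mass(F(text))
            theirs = pyteomics_mass.calculate_mass(formula=text)
            assert ours == pytest.approx(theirs, abs=1e-4)

    def test_named_constants_are_self_consistent(self):
        assert chem.PB_MASS_SHIFT == pytest.approx(
            monoisotopic_mass(chem.ACETONE), abs=1e-9
        )
        assert chem.PE_HEADGROUP_LOSS_MASS == pytest.approx(141.0191, abs=1e-4)
        assert chem.C2H2_MASS == pytest.approx(26.0157, abs=1e-4)
        assert monoisotopic_mass(chem.ACETATE) == pytest.approx(59.0133, abs=1e-4)


class TestAcylChain:
    def test_position_validation(self):
        AcylChain(18, 2, (9, 12))
        with pytest.raises(SpeciesError):
            AcylChain(18, 2, (9,))  # wrong length
        with pytest.raises(SpeciesError):
            AcylChain(18, 2, (12, 9))  # not increasing
        with pytest.raises(SpeciesError):
            AcylChain(18, 1, (18,))  # out of bounds
        with pytest.raises(SpeciesError):
            AcylChain(18, 12)  # beyond geometric capacity

    def test_species_shape_validation(self):
        with pytest.raises(SpeciesError):
            LipidSpecies("PE", (AcylChain(16, 0),))  # diacyl needs 2 chains
        with pytest.raises(SpeciesError):
            LipidSpecies("FA", (AcylChain(16, 0, linkage="O-alkyl"),))
        with pytest.raises(SpeciesError):
            LipidSpecies("SM", (AcylChain(16, 0), AcylChain(18, 1)))


class TestSpeciesNotation:
    @pytest.mark.parametrize(
        "text,species_name,cc_name",
        [
            ("PE 16:0_18:1(Δ9)", "PE 34:1", "PE 16:0_18:1(Δ9)"),
            ("PE 17:0_22:4(7,10,13,16)", "PE 39:4", "PE 17:0_22:4(Δ7,10,13,16)"),
            ("PC O-16:1/16:0", "PC 32:1", "PC O-16:1_16:0"),
        ],
    )
    def test_parse_and_render(self, text, species_name, cc_name):
        sp = parse_species(text)
        assert sp.name("species") == species_name
        assert sp.name("cc") == cc_name
        assert parse_species(sp.name("cc")) == sp


class TestFormulaTemplates:
    @pytest.mark.parametrize(
        "text,formula,mass",
        [
            ("PE 17:0_22:4", "C44H80NO8P", 781.5622),  # printed reference mass
            ("PE 16:0_18:1", "C39H76NO8P", 717.5309),
            ("FA 18:1", "C18H34O2", 282.2559),
        ],
    )
    def test_reference_species(self, text, formula, mass):
        sp = parse_species(text)
        assert formula_of_species(sp) == F(formula)
        assert monoisotopic_mass(formula_of_species(sp)) == pytest.approx(
            mass, abs=1e-4
        )

    def test_templates_match_building_block_assembly(self):
        # oracle: glycerol + phosphate + headgroup alcohol + fatty acids,
        # minus one water per condensation (4 for diacyl GP; 3 for PA)
        heads = {
            "PE": F("C2H7NO"), "PC": F("C5H13NO"), "PG": F("C3H8O3"),
            "PI": F("C6H12O6"), "PS": F("C3H7NO3"), "PA": F(""),
        }
        rng = np.random.default_rng(42)
        for _ in range(200):
            subclass = list(heads)[rng.integers(len(heads))]
            c1, c2 = rng.integers(10, 23, size=2)
            d1 = rng.integers(0, 5)
            d2 = rng.integers(0, 5)
            sp = LipidSpecies(subclass, (AcylChain(int(c1), int(d1)),
                                         AcylChain(int(c2), int(d2))))
            acids = F(f"C{c1}H{2 * c1 - 2 * d1}O2") + F(f"C{c2}H{2 * c2 - 2 * d2}O2")
            n_waters = 3 if subclass == "PA" else 4
            assembled = (
                F("C3H8O3") + F("H3PO4") + heads[subclass] + acids
                - n_waters * F("H2O")
            )
            assert formula_of_species(sp) == assembled
            assert monoisotopic_mass(formula_of_species(sp)) == pytest.approx(
                monoisotopic_mass(assembled), abs=1e-6
            )

    def test_ether_chain_modifies_template(self):
        diacyl = parse_species("PC 16:1_16:0")
        ether = parse_species("PC O-16:1_16:0")
        # ether: -O +2H relative to the diacyl template
        assert formula_of_species(ether) + F("O") == formula_of_species(diacyl) + F("H2")


class TestPrecursorMz:
    def test_printed_values(self, pe341, fa181):
        assert precursor_mz(pe341, "[M+H]+") == pytest.approx(718.5381, abs=1e-4)
        assert nominal_mz(precursor_mz(pe341, "[M+H]+") + 0.1) == 719  # unit view
        assert precursor_mz(fa181, "[M-H]-") == pytest.approx(281.2486, abs=1e-4)

    def test_zero_delta_adduct_gives_neutral_mass(self, pe341):
        neutral = Adduct("[M]", "+", 0.0)
        assert precursor_mz(pe341, neutral) == pytest.approx(717.5309, abs=1e-4)

    def test_polarity_mismatch_is_flagged(self, pe341):
        pc = parse_species("PC 16:0_18:1")
        with pytest.raises(chem.AdductError):
            precursor_mz(pc, "[M-H]-")  # PC ionizes as acetate adduct, not [M-H]-

    def test_proton_adduct_spacing(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            c1, c2 = rng.integers(10, 23, size=2)
            sp = LipidSpecies("PE", (AcylChain(int(c1), 0), AcylChain(int(c2), 1)))
            gap = precursor_mz(sp, "[M+H]+") - precursor_mz(sp, "[M-H]-")
            assert gap == pytest.approx(2 * chem.PROTON_MASS, abs=1e-9)


class TestAcylAnion:
    @pytest.mark.parametrize(
        "c,d,mz,tol",
        # the 2:0 reference is the bare CH3COO formula mass; the computed
        # deprotonated-acid m/z sits one electron mass (0.55 mDa) above it
        [(16, 0, 255.2330, 1e-4), (18, 1, 281.2486, 1e-4), (2, 0, 59.0133, 1e-3)],
    )
    def test_reference_anions(self, c, d, mz, tol):
        assert acyl_anion_mz(AcylChain(c, d)) == pytest.approx(mz, abs=tol)

    def test_ether_chain_has_no_anion(self):
        assert acyl_anion_mz(AcylChain(16, 1, linkage="O-alkyl")) is None


class TestHeadgroupScan:
    @pytest.mark.parametrize(
        "subclass,polarity,mode,value,nominal",
        [
            ("PE", "+", "NLS", 141.0191, 141),
            ("PC", "+", "PIS", 184.0733, 184),
            ("PG", "-", "PIS", 152.9958, 153),
            ("PI", "-", "PIS", 241.0119, 241),
        ],
    )
    def test_scan_constants(self, subclass, polarity, mode, value, nominal):
        d = headgroup_scan(subclass, polarity)
        assert d.mode == mode
        assert d.value == pytest.approx(value, abs=1e-4)
        assert d.nominal == nominal

    def test_unsupported_pair_raises(self):
        with pytest.raises(SpeciesError):
            headgroup_scan("PA", "+")
        with pytest.raises(SpeciesError):
            headgroup_scan("PE", "-")
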