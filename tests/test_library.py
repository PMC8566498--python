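"""Shorthand grammar, catalogue expansion and fragment-rule prediction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import entry_from_name
from oxpclib.chem import (
    AdductKind,
    ElementComposition,
    H2O,
    H2O2,
    METHYL_FORMATE,
    TRIMETHYLAMINE,
    monoisotopic_mass,
    ppm_error,
)
from oxpclib.library import (
    AcylSpec,
    FunctionalClass,
    LibraryError,
    ModCatalogueEntry,
    build_entry,
    expand_catalogue,
    export_library,
    load_catalogue,
    load_library,
    parse_acyl,
    parse_shorthand,
    predict_fragments,
    save_catalogue,
    species_composition,
    within_element_bounds,
)


class TestParsing:
    def test_oxidized_species_with_unknown_sn_positions(self):
        sn1, sn2, link = parse_shorthand("PC16:0_18:2;O2")
        assert (sn1.carbons, sn1.double_bonds, sn1.added_O) == (16, 0, 0)
        assert (sn2.carbons, sn2.double_bonds, sn2.added_O) == (18, 2, 2)
        assert link == "_"

    def test_unmodified_species_with_known_positions(self):
        sn1, sn2, link = parse_shorthand("PC16:0/18:2")
        assert sn2.added_O == 0 and link == "/"

    def test_truncated_carboxyl_species(self):
        _, sn2, _ = parse_shorthand("PC16:0_9:0;COOH")
        assert sn2.truncated
        assert sn2.functional_class is FunctionalClass.CARBOXYL_TERMINAL
        # azelaic acid (nonanedioic) as the free acid
        assert sn2.composition() == ElementComposition.from_formula("C9H16O4")

    @pytest.mark.parametrize(
        "suffix, added_O, h_delta, fc",
        [
            (";O", 1, 0, FunctionalClass.NONE),
            (";O2", 2, 0, FunctionalClass.NONE),
            (";O3", 3, 0, FunctionalClass.NONE),
            (";OOH", 2, 0, FunctionalClass.HYDROPEROXIDE),
            (";oxo", 1, -2, FunctionalClass.OXO),
            (";O-H2", 1, -2, FunctionalClass.NONE),
            (";O2-H2", 2, -2, FunctionalClass.NONE),
        ],
    )
    def test_suffix_grammar(self, suffix, added_O, h_delta, fc):
        spec = parse_acyl(f"18:2{suffix}")
        assert (spec.added_O, spec.h_delta, spec.functional_class) == (added_O, h_delta, fc)

    @pytest.mark.parametrize("bad", ["PC16:0", "PE16:0_18:2", "PC16:0_18:2;XYZ", "16:0_18:2"])
    def test_malformed_names_raise_with_token(self, bad):
        with pytest.raises(LibraryError):
            parse_shorthand(bad)


class TestComposition:
    @pytest.mark.parametrize(
        "name, formula",
        [
            ("PC16:0/18:2", "C42H80NO8P"),
            ("PC16:0_18:2;O2", "C42H80NO10P"),
            ("PC16:0_9:0;COOH", "C33H64NO10P"),
        ],
    )
    def test_species_composition(self, name, formula):
        sn1, sn2, _ = parse_shorthand(name)
        assert species_composition(sn1, sn2) == ElementComposition.from_formula(formula)

    def test_carboxyl_species_deprotonated_precursor(self):
        entry = entry_from_name("PC16:0_9:0;COOH")
        assert entry.neutral_mass == pytest.approx(665.4268, abs=5e-4)
        mz = entry.precursor(AdductKind.DEPROTONATED_NEG).value
        assert abs(ppm_error(mz, 664.4190)) <= 5.0
        assert entry.primary_negative_adduct is AdductKind.DEPROTONATED_NEG

    def test_element_bounds(self):
        assert within_element_bounds(ElementComposition.from_formula("C42H80NO10P"))
        assert not within_element_bounds(ElementComposition.from_formula("C20H40NO6P"))
        assert within_element_bounds(ElementComposition.from_formula("C26H48NO6P"))


class TestExpansion:
    def test_bundled_catalogue_expands_to_465(self, catalogue, full_library):
        assert len(catalogue) == 155
        assert len(full_library) == 465
        assert len({e.name for e in full_library}) == 465

    def test_single_product(self):
        cat = [ModCatalogueEntry(sn2=parse_acyl("18:2;O2"))]
        assert len(expand_catalogue(cat, [parse_acyl("16:0")])) == 1

    def test_product_rule(self):
        cats = [ModCatalogueEntry(sn2=parse_acyl("18:2;O2")),
                ModCatalogueEntry(sn2=parse_acyl("18:2;OOH"))]
        out = expand_catalogue(cats, [parse_acyl("16:0"), parse_acyl("18:0")])
        assert len(out) == 4 and len({e.name for e in out}) == 4

    def test_duplicate_catalogue_keys_rejected(self):
        cat = [ModCatalogueEntry(sn2=parse_acyl("18:2;O2"))] * 2
        with pytest.raises(LibraryError, match="duplicate"):
            expand_catalogue(cat, [parse_acyl("16:0")])

    def test_name_round_trip_over_whole_library(self, full_library):
        for entry in full_library:
            sn1, sn2, _ = parse_shorthand(entry.name)
            assert sn1.composition_key() == entry.sn1.composition_key()
            assert sn2.composition_key() == entry.sn2.composition_key()


class TestFragmentRules:
    def test_truncated_aldehyde_negative_mode(self):
        entry = entry_from_name("PC16:0_8:1;O")
        frags = {f.rule_id: f.mz.value for f in predict_fragments(entry, "-")}
        assert abs(ppm_error(frags["R1"], 255.2324)) <= 5  # [16:0]-
        assert abs(ppm_error(frags["R2"], 157.0864)) <= 5  # [C8H13O3]-
        assert abs(ppm_error(frags["R4"], 620.3927)) <= 5  # [M-CH3]-

    def test_hydroperoxide_positive_mode_h2o2_loss(self):
        entry = entry_from_name("PC16:0_18:2;OOH")
        frags = {f.rule_id: f.mz.value for f in predict_fragments(entry, "+")}
        assert abs(ppm_error(frags["R8"], 756.5544)) <= 5

    def test_carboxyl_species_trimethylamine_loss_and_methylated_acyl(self):
        entry = entry_from_name("PC16:0_9:0;COOH")
        frags = {f.rule_id: f.mz.value for f in predict_fragments(entry, "-")}
        assert abs(ppm_error(frags["R5"], 605.3455)) <= 5
        assert abs(ppm_error(frags["R6"], 201.1126)) <= 5
        assert "R4" not in frags  # no formate-adduct channel for carboxylates

    def test_fragment_mass_conservation(self, pc160_library):
        for entry in pc160_library[:40]:
            for pol, deltas in (
                ("-", {"R4": METHYL_FORMATE, "R5": TRIMETHYLAMINE}),
                ("+", {"R7": H2O, "R8": H2O2}),
            ):
                adduct = (
                    entry.primary_negative_adduct if pol == "-" else AdductKind.PROTONATED_POS
                )
                prec = entry.precursor(adduct).value
                for frag in predict_fragments(entry, pol):
                    if frag.rule_id in deltas:
                        assert prec - frag.mz.value == pytest.approx(
                            deltas[frag.rule_id], abs=1e-4
                        )

    def test_oxfa_plus_sn1_plus_backbone_closes_composition(self, pc160_library):
        from oxpclib.library import GPC_BACKBONE

        water2 = 2 * ElementComposition.from_formula("H2O")
        for entry in pc160_library:
            if entry.sn2.truncated:
                continue
            total = GPC_BACKBONE + entry.sn1.composition() + entry.sn2.composition() - water2
            assert total == entry.composition


class TestCatalogueIO:
    def test_csv_round_trip(self, catalogue, tmp_path):
        path = tmp_path / "cat.csv"
        save_catalogue(catalogue, path)
        back = load_catalogue(path)
        assert [e.key() for e in back] == [e.key() for e in catalogue]

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(LibraryError):
            load_catalogue(path)

    def test_schema_violation_reports_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "name_suffix,carbons,double_bonds,added_O,h_delta,functional_class,truncated\n"
            ";O2,18,2,2,0,epoxide_or_hydroxide,0\n"
            ";OOH,xx,2,2,0,hydroperoxide,0\n"
        )
        with pytest.raises(LibraryError, match="row 3"):
            load_catalogue(path)

    @pytest.mark.parametrize("fmt", ["csv", "json"])
    def test_library_export_round_trip(self, pc160_library, tmp_path, fmt):
        path = tmp_path / f"lib.{fmt}"
        export_library(pc160_library, path, fmt)
        back = load_library(path)
        assert [e.name for e in back] == [e.name for e in pc160_library]
        assert [e.composition for e in back] == [e.composition for e in pc160_library]

    def test_mgf_export_is_readable(self, pc160_library, tmp_path):
        from pyteomics import mgf

        path = tmp_path / "lib.mgf"
        export_library(pc160_library[:5], path, "mgf")
        with mgf.MGF(str(path)) as reader:
            recs = list(reader)
        assert len(recs) == 5
        assert recs[0]["params"]["pepmass"][0] == pytest.approx(
            pc160_library[0].precursor(pc160_library[0].primary_negative_adduct).value,
            abs=1e-3,
        )


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    carbons=st.integers(4, 22),
    dbs=st.integers(0, 6),
    added_O=st.integers(0, 3),
    dehydro=st.booleans(),
)
def test_generated_acyl_names_reparse(carbons, dbs, added_O, dehydro):
    if 2 * carbons - 2 * dbs - (2 if dehydro else 0) <= 0:
        return
    if added_O == 0 and dehydro:
        return  # the suffix grammar has no plain dehydro class
    spec = AcylSpec(carbons, dbs, added_O=added_O, h_delta=-2 if dehydro else 0)
    back = parse_acyl(spec.name)
    assert back.composition_key() == spec.composition_key()
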