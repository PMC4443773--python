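"""InChI layer parsing, SMILES stereo-tag inventory, phosphate normalization."""

import pytest

from stereofid.fixtures import _compile_template
from stereofid.identifiers import (
    InChILayers,
    Untranslatable,
    count_undefined_chiral,
    gen_canonical_smiles,
    gen_inchi,
    normalize_phosphate_tags,
    parse_inchi_layers,
    reassemble_inchi,
)
from stereofid.chem_io import Atom, Bond, BondOrder, StructureRecord

# standard-InChI output for L-alanine, frozen from the configured backend
L_ALANINE_INCHI = "InChI=1S/C3H7NO2/c1-2(4)3(5)6/h2H,4H2,1H3,(H,5,6)/t2-/m0/s1"


def test_parse_named_sublayers():
    layers = parse_inchi_layers(L_ALANINE_INCHI)
    assert layers.version_prefix == "1S"
    assert layers.formula == "C3H7NO2"
    assert layers.c == "1-2(4)3(5)6"
    assert layers.h == "2H,4H2,1H3,(H,5,6)"
    assert layers.b is None
    assert layers.t == "2-"
    assert layers.m == "0"
    assert layers.s == "1"


def test_absent_layer_is_none_not_empty():
    layers = parse_inchi_layers("InChI=1S/CH4/h1H4")
    assert layers.t is None
    assert layers.b is None
    assert layers.c is None


def test_non_inchi_string_raises():
    with pytest.raises(ValueError):
        parse_inchi_layers("C3H7NO2")


@pytest.mark.parametrize(
    "t_layer,expected",
    [("2-,3?", 1), (None, 0), ("2?,5?,8-", 2)],
)
def test_count_undefined_chiral(t_layer, expected):
    layers = InChILayers(
        raw="", version_prefix="1S", formula="X", segments=("X",), t=t_layer
    )
    assert count_undefined_chiral(layers) == expected


def test_reassemble_round_trip_across_suite(fixture_set):
    """parse/reassemble is byte-exact for every InChI the suite generates."""
    from stereofid.screening import screen_record

    checked = 0
    for record, _ in fixture_set:
        if screen_record(record).rejected:
            continue
        layers = gen_inchi(record)
        assert not isinstance(layers, Untranslatable)
        assert reassemble_inchi(parse_inchi_layers(layers.raw)) == layers.raw
        checked += 1
    assert checked >= 30


def test_gen_inchi_methane_no_stereo_layers():
    layers = gen_inchi(_compile_template("methane", "C"))
    assert layers.formula == "CH4"
    assert layers.c is None
    assert layers.t is None


def test_gen_inchi_l_alanine(fixture_records):
    layers = gen_inchi(fixture_records["single-l-alanine"])
    assert layers.raw == L_ALANINE_INCHI


def test_enantiomers_same_t_different_m(fixture_records):
    l_layers = gen_inchi(fixture_records["single-l-alanine"])
    d_layers = gen_inchi(fixture_records["single-d-alanine"])
    assert l_layers.t == d_layers.t
    assert l_layers.m != d_layers.m


def test_placeholder_record_is_a_precondition_error(fixture_records):
    with pytest.raises(ValueError):
        gen_inchi(fixture_records["placeholder-r-glycine"])
    with pytest.raises(ValueError):
        gen_canonical_smiles(fixture_records["placeholder-r-glycine"])


def test_untranslatable_is_typed_not_a_crash():
    # a pentavalent carbon defeats structure perception
    atoms = [Atom(i, "C", float(i), 0.0, 0.0) for i in range(6)]
    bonds = [Bond(0, i, BondOrder.SINGLE) for i in range(1, 6)]
    bad = StructureRecord("bad", "bad", atoms, bonds)
    assert isinstance(gen_inchi(bad), Untranslatable)
    assert isinstance(gen_canonical_smiles(bad), Untranslatable)


def test_smiles_profile_single_stereocenter(fixture_records):
    profile = gen_canonical_smiles(fixture_records["single-l-alanine"])
    assert profile.tetrahedral_tags == 1
    assert profile.ez_tags == 0


def test_smiles_profile_trans_butene_two_directional_chars():
    profile = gen_canonical_smiles(_compile_template("t2b", "C/C=C/C"))
    assert profile.ez_tags == 2
    assert profile.tetrahedral_tags == 0


def test_smiles_profile_achiral_normalized_equals_canonical(fixture_records):
    profile = gen_canonical_smiles(fixture_records["achiral-ethanol"])
    assert profile.tetrahedral_tags == 0
    assert profile.normalized == profile.canonical


def test_double_at_counts_once():
    profile = gen_canonical_smiles(_compile_template("dala", "C[C@@H](N)C(=O)O"))
    assert profile.tetrahedral_tags == 1  # "@@" is one descriptor group


def test_phosphate_tags_removed(fixture_records):
    profile = gen_canonical_smiles(fixture_records["phosphate-methyl-ethyl"])
    assert profile.tetrahedral_tags == 1
    assert profile.phosphorus_tags_removed == 1
    assert "@" not in profile.normalized
    assert profile.effective_tetrahedral_tags == 0


def test_phosphate_normalization_spares_carbon_centers(fixture_records):
    profile = gen_canonical_smiles(fixture_records["single-l-alanine"])
    renorm = normalize_phosphate_tags(profile)
    assert renorm.normalized == profile.canonical
    assert renorm.phosphorus_tags_removed == 0


def test_phosphate_normalization_idempotent(fixture_records):
    profile = gen_canonical_smiles(fixture_records["phosphate-ethyl-isopropyl"])
    assert normalize_phosphate_tags(normalize_phosphate_tags(profile)) == (
        normalize_phosphate_tags(profile)
    )


def test_identifier_generation_deterministic(fixture_records):
    record = fixture_records["multi-l-threonine"]
    assert gen_inchi(record).raw == gen_inchi(record).raw
    assert gen_canonical_smiles(record) == gen_canonical_smiles(record)


def test_fully_annotated_fixtures_have_no_undefined_markers(fixture_set):
    from stereofid.screening import screen_record

    for record, spec in fixture_set:
        if screen_record(record).rejected or spec.expected_undefined:
            continue
        layers = gen_inchi(record)
        assert count_undefined_chiral(layers) == 0, spec.fixture_id
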