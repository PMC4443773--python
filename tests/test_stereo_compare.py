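"""Verdict taxonomy, census counting, frequency tabulation."""

import pytest

from stereofid.chem_io import Atom, Bond, BondOrder, StructureRecord
from stereofid.fixtures import _compile_template, corrupt
from stereofid.identifiers import gen_canonical_smiles, gen_inchi
from stereofid.stereo_compare import (
    PAIR_LABELS,
    UNTRANSLATABLE_ROW,
    PairClassification,
    UntranslatablePair,
    Verdict,
    census,
    classify_pair,
    compare_inchi,
    compare_smiles,
    tabulate,
)


def _layers(smiles, name="x"):
    return gen_inchi(_compile_template(name, smiles))


def _profile(smiles, name="x"):
    return gen_canonical_smiles(_compile_template(name, smiles))


@pytest.mark.parametrize(
    "before,after,expected",
    [
        # identical molecules
        ("C[C@H](N)C(=O)O", "C[C@H](N)C(=O)O", Verdict.SAME),
        # enantiomers: t equal, m flips (extended mode catches it)
        ("C[C@H](N)C(=O)O", "C[C@@H](N)C(=O)O", Verdict.CHIRAL_INVERSION),
        # one of two centers flipped: t itself changes
        ("C[C@@H](O)[C@H](N)C(=O)O", "C[C@H](O)[C@H](N)C(=O)O", Verdict.CHIRAL_INVERSION),
        # defined vs partially undefined: "?" appears in t
        ("C[C@@H](O)[C@H](N)C(=O)O", "C[C@@H](O)C(N)C(=O)O", Verdict.CHIRAL_MISSING),
        # single center, annotation dropped entirely: t layer vanishes
        ("C[C@H](N)C(=O)O", "CC(N)C(=O)O", Verdict.CHIRAL_MISSING),
        # E vs Z: only the b sublayer sign flips
        ("C/C=C/C(=O)O", "C/C=C\\C(=O)O", Verdict.CIS_TRANS_INVERSION),
        # defined vs undefined double bond: b layer vanishes
        ("C/C=C/C(=O)O", "CC=CC(=O)O", Verdict.CIS_TRANS_MISSING),
        # connectivity change dominates everything
        ("CCO", "COC", Verdict.ELSE_UNMATCHED),
        # formula change
        ("CCO", "CCCO", Verdict.ELSE_UNMATCHED),
        # achiral pair: absent-vs-absent stereo layers are a match
        ("CCO", "CCO", Verdict.SAME),
    ],
)
def test_compare_inchi_taxonomy(before, after, expected):
    verdict = compare_inchi(_layers(before, "b"), _layers(after, "a"))
    assert verdict.verdict == expected


def test_strict_paper_mode_is_blind_to_whole_molecule_mirror():
    """With t-only comparison an enantiomer pair reads as SAME; the extended
    mode consults m and catches it — the reason m is parsed at all."""
    l_ala, d_ala = _layers("C[C@H](N)C(=O)O"), _layers("C[C@@H](N)C(=O)O")
    assert compare_inchi(l_ala, d_ala, mode="strict-paper").verdict == Verdict.SAME
    assert compare_inchi(l_ala, d_ala, mode="extended").verdict == Verdict.CHIRAL_INVERSION


@pytest.mark.parametrize(
    "before,after,expected",
    [
        ("C[C@H](N)C(=O)O", "C[C@H](N)C(=O)O", Verdict.SAME),
        # all @-descriptors lost, same skeleton
        ("C[C@@H](O)[C@H](N)C(=O)O", "CC(O)C(N)C(=O)O", Verdict.CHIRAL_MISSING),
        # one descriptor flipped, counts equal
        ("C[C@H](N)C(=O)O", "C[C@@H](N)C(=O)O", Verdict.CHIRAL_INVERSION),
        # directional-bond flip only
        ("C/C=C/C(=O)O", "C/C=C\\C(=O)O", Verdict.CIS_TRANS_INVERSION),
        # directional chars lost
        ("C/C=C/C(=O)O", "CC=CC(=O)O", Verdict.CIS_TRANS_MISSING),
        # different skeleton
        ("CCO", "COC", Verdict.ELSE_UNMATCHED),
    ],
)
def test_compare_smiles_taxonomy(before, after, expected):
    verdict = compare_smiles(_profile(before, "b"), _profile(after, "a"))
    assert verdict.verdict == expected


def test_verdicts_symmetric_under_swap(fixture_records):
    pairs = [
        ("single-l-alanine", "invert_one_stereocenter"),
        ("multi-l-threonine", "remove_stereo_annotation"),
        ("ez-crotonic-e", "flip_double_bond_ez"),
        ("ez-pentenol", "remove_ez_annotation"),
        ("achiral-ethanol", "add_methyl"),
    ]
    for fixture_id, mode in pairs:
        record = fixture_records[fixture_id]
        corrupted = corrupt(record, mode, seed=11).record
        for channel in ("inchi", "smiles"):
            forward = classify_pair(record, corrupted, channel=channel)
            backward = classify_pair(corrupted, record, channel=channel)
            assert forward.verdict == backward.verdict, (fixture_id, mode, channel)


def test_reflexivity_all_fixtures(fixture_set):
    from stereofid.screening import screen_record

    for record, spec in fixture_set:
        if screen_record(record).rejected:
            continue
        for channel in ("inchi", "smiles"):
            outcome = classify_pair(record, record, channel=channel)
            assert outcome.verdict == Verdict.SAME, (spec.fixture_id, channel)


def test_untranslatable_pair_withheld_and_bucketed():
    atoms = [Atom(i, "C", float(i), 0.0, 0.0) for i in range(6)]
    bonds = [Bond(0, i, BondOrder.SINGLE) for i in range(1, 6)]
    bad = StructureRecord("bad", "bad", atoms, bonds)
    good = _compile_template("good", "CCO")
    outcome = classify_pair(good, bad, channel="inchi")
    assert isinstance(outcome, UntranslatablePair)
    table = tabulate([PairClassification("bad", PAIR_LABELS[0], outcome)])
    assert table.loc[UNTRANSLATABLE_ROW, PAIR_LABELS[0]] == 1
    assert table[PAIR_LABELS[0]].sum() == 1


def test_census_matches_fixture_manifest(fixture_set):
    from stereofid.screening import screen_record

    kept = [(r, s) for r, s in fixture_set if not screen_record(r).rejected]
    row = census([r for r, _ in kept], "initial_2d")
    specs = [s for _, s in kept]
    assert row.total == len(kept)
    assert row.chiral_tag_count_inchi == sum(
        1 for s in specs if s.expected_stereocenters > 0
    )
    assert row.chiral_tag_count_smiles == sum(
        1 for s in specs if s.expected_stereocenters + s.expected_p_tags > 0
    )
    assert row.cis_trans_count_inchi == sum(1 for s in specs if s.expected_ez_bonds > 0)
    assert row.cis_trans_count_smiles == sum(1 for s in specs if s.expected_ez_bonds > 0)
    assert row.undefined_chiral_entries == sum(
        1 for s in specs if s.expected_undefined > 0
    )


def test_census_no_alkenes_zero_cis_trans():
    records = [_compile_template(f"r{i}", smi) for i, smi in enumerate(["CCO", "CC(C)O", "CCN"])]
    row = census(records, "initial_2d")
    assert row.cis_trans_count_inchi == 0
    assert row.cis_trans_count_smiles == 0


def test_census_unknown_stage_raises():
    with pytest.raises(ValueError):
        census([], "after_lunch")


def test_tabulate_columns_sum_to_pair_counts():
    record = _compile_template("r", "C[C@H](N)C(=O)O")
    same = classify_pair(record, record, channel="inchi")
    items = [
        PairClassification("r", pair, same) for pair in PAIR_LABELS for _ in range(3)
    ]
    table = tabulate(items)
    for pair in PAIR_LABELS:
        assert table[pair].sum() == 3
    assert (table.loc[Verdict.SAME.value] == 3).all()
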