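"""Wash / embed / minimize checkpoints and the end-to-end record workflow."""

import pytest

from stereofid.conversion import (
    ConversionPolicy,
    add_hydrogens,
    embed_3d,
    minimize,
    run_checkpoints,
)
from stereofid.fixtures import _compile_template
from stereofid.identifiers import count_undefined_chiral, gen_inchi
from stereofid.stereo_compare import Verdict


def test_add_hydrogens_methane():
    wash = add_hydrogens(_compile_template("methane", "C"))
    assert [a.element for a in wash.atoms].count("H") == 4
    assert len(wash.atoms) == 5


def test_add_hydrogens_preserves_defined_parity(fixture_records):
    record = fixture_records["single-l-alanine"]
    wash = add_hydrogens(record)
    assert gen_inchi(wash).t == gen_inchi(record).t
    assert gen_inchi(wash).m == gen_inchi(record).m


def test_preserve_undefined_keeps_question_mark(fixture_records):
    record = fixture_records["undef-partial-threonine"]
    wash = add_hydrogens(record, ConversionPolicy())
    assert count_undefined_chiral(gen_inchi(wash)) == 1


def test_random_assign_fills_undefined_centers(fixture_records):
    record = fixture_records["undef-partial-threonine"]
    policy = ConversionPolicy(undefined_center_policy="random_assign")
    wash = add_hydrogens(record, policy, seed=5)
    assert count_undefined_chiral(gen_inchi(wash)) == 0
    assert "random_chiral_assignments" in wash.properties
    # deterministic for a fixed seed
    again = add_hydrogens(record, policy, seed=5)
    assert gen_inchi(again).raw == gen_inchi(wash).raw


def test_random_assign_requires_seed(fixture_records):
    policy = ConversionPolicy(undefined_center_policy="random_assign")
    with pytest.raises(ValueError):
        add_hydrogens(fixture_records["undef-partial-threonine"], policy, seed=None)


def test_unknown_policy_rejected():
    with pytest.raises(ValueError):
        ConversionPolicy(undefined_center_policy="wing_it")


def test_embed_is_3d_and_seed_deterministic(fixture_records):
    wash = add_hydrogens(fixture_records["single-l-alanine"])
    first = embed_3d(wash, seed=13)
    second = embed_3d(wash, seed=13)
    assert first.dimensionality == "3D"
    assert [(a.x, a.y, a.z) for a in first.atoms] == [
        (a.x, a.y, a.z) for a in second.atoms
    ]


def test_embed_preserves_double_bond_geometry(fixture_records):
    wash = add_hydrogens(fixture_records["ez-crotonic-e"])
    embedded = embed_3d(wash, seed=13)
    # re-perceived from 3D coordinates, the b sublayer must be unchanged
    assert gen_inchi(embedded).b == gen_inchi(wash).b


def test_minimize_records_energy_and_reduces_it(fixture_records):
    wash = add_hydrogens(fixture_records["multi-l-threonine"])
    embedded = embed_3d(wash, seed=13)
    barely = minimize(embedded, ConversionPolicy(max_minimization_steps=1))
    fully = minimize(embedded, ConversionPolicy(max_minimization_steps=500))
    e_barely = float(barely.properties["mm_energy_kcal_mol"])
    e_fully = float(fully.properties["mm_energy_kcal_mol"])
    assert e_fully <= e_barely + 1e-6


def test_lower_energy_conformer_identified():
    """Two minimizations from different starting points: the energies the
    pipeline records order the conformers."""
    wash = add_hydrogens(_compile_template("diene", "C=CC=C"))
    energies = []
    for seed in (3, 17):
        mm = minimize(embed_3d(wash, seed=seed), ConversionPolicy())
        energies.append(float(mm.properties["mm_energy_kcal_mol"]))
    assert min(energies) == sorted(energies)[0]


def test_run_checkpoints_rigid_fixture_all_same(fixture_records):
    result = run_checkpoints(
        fixture_records["multi-l-threonine"], ConversionPolicy(), seed=42
    )
    assert result.checkpoints.failure_stage is None
    assert result.checkpoints.mm.dimensionality == "3D"
    for (pair, channel), outcome in result.verdicts.items():
        assert outcome.verdict == Verdict.SAME, (pair, channel)


def test_run_checkpoints_salt_strip_breaks_formula(fixture_records):
    policy = ConversionPolicy(strip_salts_at_wash=True)
    result = run_checkpoints(fixture_records["salt-acetate-na"], policy, seed=42)
    assert result.verdicts[("cpd – wash", "inchi")].verdict == Verdict.ELSE_UNMATCHED
    # the kept fragment is conserved from wash onward
    assert result.verdicts[("wash – mm", "inchi")].verdict == Verdict.SAME


def test_run_checkpoints_random_assign_reads_as_chiral_missing(fixture_records):
    policy = ConversionPolicy(undefined_center_policy="random_assign")
    result = run_checkpoints(
        fixture_records["undef-partial-threonine"], policy, seed=42
    )
    assert result.verdicts[("cpd – wash", "inchi")].verdict == Verdict.CHIRAL_MISSING


def test_heavy_atoms_conserved_wash_to_mm(fixture_records):
    result = run_checkpoints(fixture_records["polyene-sorbic"], ConversionPolicy(), seed=42)
    heavy = lambda r: sum(1 for a in r.atoms if a.element != "H")
    assert heavy(result.checkpoints.wash) == heavy(result.checkpoints.mm)


def test_pipeline_deterministic_across_runs(fixture_records):
    record = fixture_records["multi-l-isoleucine"]
    r1 = run_checkpoints(record, ConversionPolicy(), seed=99)
    r2 = run_checkpoints(record, ConversionPolicy(), seed=99)
    assert gen_inchi(r1.checkpoints.mm).raw == gen_inchi(r2.checkpoints.mm).raw
    assert [
        (k, v.verdict) for k, v in sorted(r1.verdicts.items())
    ] == [(k, v.verdict) for k, v in sorted(r2.verdicts.items())]


def test_policy_yaml_round_trip(tmp_path):
    path = tmp_path / "policy.yaml"
    path.write_text(
        "constrain_chirality: false\nstrip_salts_at_wash: false\n"
        "max_minimization_steps: 100\nforce_field_id: UFF\n"
    )
    policy = ConversionPolicy.from_yaml(path)
    assert policy.constrain_chirality is False
    assert policy.max_minimization_steps == 100
    assert policy.force_field_id == "UFF"
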