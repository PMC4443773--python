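"""The three-checkpoint 2D→3D conversion workflow.

Each record passes through three snapshots:

* ``cpd``  — the screened input 2D structure;
* ``wash`` — salts optionally stripped, hydrogens made explicit;
* ``mm``   — distance-geometry embedded 3D coordinates, energy-minimized
  with a molecular-mechanics force field.

The identifier comparison runs over the three checkpoint pairs
(cpd–wash, wash–mm, cpd–mm). The central design point is that the
chirality constraint is *not* trusted from any backend flag: after
minimization the stereo layers are re-perceived from the 3D coordinates and
verified against the wash snapshot; on a mismatch the embedding is retried
with a derived seed. Backends have historically inverted stereocenters
silently, so verification is post-hoc by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.rdchem import ChiralType

from ._rdkit_bridge import mol_to_record, record_to_mol
from .chem_io import StructureRecord
from .identifiers import BACKEND_ID
from .screening import component_count, strip_salts
from .stereo_compare import (
    PAIR_LABELS,
    ComparisonVerdict,
    UntranslatablePair,
    Verdict,
    classify_pair,
)

__all__ = [
    "ConversionPolicy",
    "CheckpointSet",
    "CheckpointResult",
    "ConversionFailure",
    "add_hydrogens",
    "embed_3d",
    "minimize",
    "run_checkpoints",
]

_SEED_MASK = 0x7FFFFFFF  # RDKit wants a positive 32-bit embedding seed


@dataclass
class ConversionPolicy:
    constrain_chirality: bool = True
    undefined_center_policy: str = "preserve_undefined"  # or "random_assign"
    strip_salts_at_wash: bool = True
    max_minimization_steps: int = 500
    force_field_id: str = "MMFF94"  # "UFF" also accepted; per-record fallback to UFF
    max_constraint_retries: int = 4

    def __post_init__(self) -> None:
        if self.undefined_center_policy not in ("preserve_undefined", "random_assign"):
            raise ValueError(
                f"unknown undefined_center_policy {self.undefined_center_policy!r}"
            )

    @classmethod
    def from_yaml(cls, path) -> "ConversionPolicy":
        data = yaml.safe_load(open(path)) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)


class ConversionFailure(RuntimeError):
    def __init__(self, stage: str, record_id: str, message: str):
        self.stage = stage
        self.record_id = record_id
        super().__init__(f"{stage} failed for {record_id!r}: {message}")


@dataclass
class CheckpointSet:
    cpd: StructureRecord
    wash: StructureRecord | None
    mm: StructureRecord | None
    seed: int
    policy: ConversionPolicy
    backend_id: str = BACKEND_ID
    mm_energy: float | None = None  # force-field energy, kcal/mol
    failure_stage: str | None = None


@dataclass
class CheckpointResult:
    checkpoints: CheckpointSet
    #: {(pair label, channel): verdict-or-untranslatable}
    verdicts: dict[tuple[str, str], ComparisonVerdict | UntranslatablePair] = field(
        default_factory=dict
    )


def add_hydrogens(
    record: StructureRecord,
    policy: ConversionPolicy | None = None,
    seed: int | None = None,
) -> StructureRecord:
    """Make hydrogens explicit; the "wash" transformation on one record.

    Defined stereo annotations are preserved. Undefined tetrahedral centers
    stay undefined under ``preserve_undefined``; under ``random_assign`` each
    gets a parity drawn from the seeded generator and the assignment is
    logged in the record properties — emulating converters that silently
    invent a tag where none was drawn.
    """
    policy = policy or ConversionPolicy()
    mol = record_to_mol(record, remove_hs=False)
    if mol is None:
        raise ConversionFailure("wash", record.source_id, "structure perception failed")
    properties = dict(record.properties)
    if policy.undefined_center_policy == "random_assign":
        if seed is None:
            raise ValueError("random_assign requires a seed")
        rng = np.random.default_rng(seed)
        assigned: list[str] = []
        centers = Chem.FindMolChiralCenters(
            mol, includeUnassigned=True, useLegacyImplementation=False
        )
        for idx, label in centers:
            if label == "?":
                tag = (
                    ChiralType.CHI_TETRAHEDRAL_CW
                    if rng.integers(2)
                    else ChiralType.CHI_TETRAHEDRAL_CCW
                )
                mol.GetAtomWithIdx(idx).SetChiralTag(tag)
                assigned.append(f"{idx}:{tag.name}")
        if assigned:
            properties["random_chiral_assignments"] = ";".join(assigned)
    try:
        mol_h = Chem.AddHs(mol, addCoords=True)
    except Exception as exc:
        raise ConversionFailure("wash", record.source_id, str(exc))
    if mol_h.GetNumConformers():
        pos = mol_h.GetConformer().GetPositions()
        if not np.isfinite(pos).all():
            # degenerate (e.g. collinear) layouts defeat geometric H placement
            from rdkit.Chem import rdDepictor

            rdDepictor.Compute2DCoords(mol_h)
    return mol_to_record(
        mol_h, source_id=record.source_id, name=record.name, properties=properties
    )


def embed_3d(record: StructureRecord, seed: int) -> StructureRecord:
    """Assign 3D coordinates by distance geometry; deterministic per seed."""
    mol = record_to_mol(record, remove_hs=False)
    if mol is None:
        raise ConversionFailure("embed", record.source_id, "structure perception failed")
    properties = dict(record.properties)
    embedded = False
    # ETKDGv3 first; the plain experimental-torsion set rescues tiny
    # cumulated systems (e.g. propadiene) that defeat the v3 knowledge terms
    for params_factory, label in ((AllChem.ETKDGv3, "ETKDGv3"), (AllChem.ETDG, "ETDG")):
        params = params_factory()
        params.randomSeed = int(seed) & _SEED_MASK or 1
        if AllChem.EmbedMolecule(mol, params) == 0:
            embedded = True
            if label != "ETKDGv3":
                properties["embedding_fallback"] = label
            break
    if not embedded:
        raise ConversionFailure("embed", record.source_id, "embedding did not converge")
    return mol_to_record(
        mol,
        source_id=record.source_id,
        name=record.name,
        properties=properties,
    )


def minimize(
    record: StructureRecord, policy: ConversionPolicy | None = None
) -> StructureRecord:
    """Energy-minimize a 3D record; the resulting energy lands in properties.

    MMFF94 by default, with automatic per-record UFF fallback (flagged in the
    properties) when MMFF parameters are missing for an atom type.
    Non-convergence within the step budget is flagged, the last geometry kept.
    """
    policy = policy or ConversionPolicy()
    mol = record_to_mol(record, remove_hs=False)
    if mol is None:
        raise ConversionFailure("minimize", record.source_id, "structure perception failed")
    properties = dict(record.properties)
    ff = None
    ff_used = policy.force_field_id
    if policy.force_field_id.upper().startswith("MMFF"):
        props = AllChem.MMFFGetMoleculeProperties(mol, mmffVariant="MMFF94")
        if props is not None:
            ff = AllChem.MMFFGetMoleculeForceField(mol, props)
        if ff is None:
            ff_used = "UFF"
            properties["force_field_fallback"] = "UFF"
    if ff is None:
        ff = AllChem.UFFGetMoleculeForceField(mol)
        ff_used = "UFF" if not ff_used else ff_used
    if ff is None:
        raise ConversionFailure("minimize", record.source_id, "no force field applicable")
    ff.Initialize()
    not_converged = ff.Minimize(maxIts=policy.max_minimization_steps)
    if not_converged:
        properties["minimization_converged"] = "false"
    properties["mm_energy_kcal_mol"] = f"{ff.CalcEnergy():.6f}"
    properties["force_field_used"] = ff_used
    return mol_to_record(
        mol, source_id=record.source_id, name=record.name, properties=properties
    )


def _stereo_preserved(
    wash: StructureRecord, mm: StructureRecord, mode: str
) -> bool:
    outcome = classify_pair(wash, mm, channel="inchi", mode=mode)
    return (
        isinstance(outcome, ComparisonVerdict) and outcome.verdict == Verdict.SAME
    )


def run_checkpoints(
    record: StructureRecord,
    policy: ConversionPolicy | None = None,
    seed: int = 0,
    channels: tuple[str, ...] = ("inchi", "smiles"),
    mode: str = "extended",
) -> CheckpointResult:
    """Run one record through cpd → wash → mm and classify all three pairs.

    A failure at any stage yields a partial :class:`CheckpointSet` with the
    failure stage recorded; verdicts are only produced for snapshots that
    exist. With ``constrain_chirality`` the wash→mm stereo correspondence is
    verified on the InChI channel and the embedding retried with derived
    seeds until it holds or the retry budget is spent.
    """
    policy = policy or ConversionPolicy()
    cpd = record.copy()
    checkpoints = CheckpointSet(cpd=cpd, wash=None, mm=None, seed=seed, policy=policy)
    result = CheckpointResult(checkpoints=checkpoints)

    try:
        wash_input = cpd
        if policy.strip_salts_at_wash and component_count(cpd) > 1:
            wash_input = strip_salts(cpd)
        wash = add_hydrogens(wash_input, policy, seed)
        checkpoints.wash = wash
    except ConversionFailure:
        checkpoints.failure_stage = "wash"
        return result

    mm: StructureRecord | None = None
    attempts = 1 + (policy.max_constraint_retries if policy.constrain_chirality else 0)
    last_failure = None
    for attempt in range(attempts):
        attempt_seed = seed + 7919 * attempt
        try:
            embedded = embed_3d(wash, attempt_seed)
            candidate = minimize(embedded, policy)
        except ConversionFailure as exc:
            last_failure = exc
            continue
        mm = candidate
        if not policy.constrain_chirality or _stereo_preserved(wash, mm, mode):
            break
    if mm is None:
        checkpoints.failure_stage = last_failure.stage if last_failure else "embed"
        return result
    checkpoints.mm = mm
    energy = mm.properties.get("mm_energy_kcal_mol")
    checkpoints.mm_energy = float(energy) if energy else None

    snapshots = {"cpd": cpd, "wash": wash, "mm": mm}
    for pair_label in PAIR_LABELS:
        left, right = [s.strip() for s in pair_label.split("–")]
        for channel in channels:
            result.verdicts[(pair_label, channel)] = classify_pair(
                snapshots[left], snapshots[right], channel=channel, mode=mode
            )
    return result
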