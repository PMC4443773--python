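"""Synthetic structure set and corruption oracle.

The packaged fixtures emulate the stereochemical diversity of a natural-
product compound collection — chiral metabolites, E/Z alkenes, conjugated
polyenes, allenes, chiral phosphates, salts, partially annotated
stereocenters and generic-residue placeholder entries — so that every
verdict class, census count and geometry flag is exercised without any
external download.

Fixtures are defined as annotated SMILES templates compiled to 2D V2000
records at build time (ideal 1.5 Å bond lengths from the depiction engine),
which keeps them human-auditable and backend-checkable. Placeholder entries
are compiled from a dummy-atom template and the token is renamed afterwards,
since line notations cannot spell "R" or "X".

The corruption oracle applies exactly one known lesion to a record
(stereocenter inversion, annotation loss, E/Z flip, topology edits) and
carries the verdict the comparison machinery is expected to return — the
ground truth for the classification suite.

Undefined-center fixtures are deliberately *partial* (at least one defined
plus one undefined center): a standard InChI only prints the "?" marker for
an undefined center when a defined sibling forces the t sublayer to exist,
so a fully unannotated molecule would be invisible to the "?" census.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdDepictor
from rdkit.Chem.rdchem import BondStereo, ChiralType

from ._rdkit_bridge import mol_to_record
from .chem_io import Atom, Bond, BondOrder, StructureRecord
from .screening import screen_record
from .stereo_compare import UntranslatablePair, Verdict, classify_pair

__all__ = [
    "FixtureSpec",
    "CorruptionResult",
    "CORRUPTION_MODES",
    "EXPECTED_VERDICT",
    "build_fixture_set",
    "corrupt",
    "oracle_suite",
    "known_limits_suite",
    "build_planar_polyene",
    "build_twisted_polyene",
    "build_allene",
    "build_scaled_chain",
    "manifest",
]


@dataclass(frozen=True)
class FixtureSpec:
    fixture_id: str
    template: str  # annotated SMILES the record was compiled from
    expected_stereocenters: int  # defined tetrahedral centers visible to InChI
    expected_ez_bonds: int  # defined stereo double bonds
    expected_undefined: int  # unannotated potential stereocenters
    expected_p_tags: int  # phosphorus SMILES descriptors (InChI-invisible)
    tags: frozenset[str]


# fixture_id, template, stereocenters, ez, undefined, p_tags, tags
_TEMPLATES: list[tuple[str, str, int, int, int, int, set[str]]] = [
    ("achiral-ethanol", "CCO", 0, 0, 0, 0, {"achiral"}),
    ("achiral-acetone", "CC(C)=O", 0, 0, 0, 0, {"achiral"}),
    ("achiral-benzene", "c1ccccc1", 0, 0, 0, 0, {"achiral"}),
    ("achiral-pyridine", "c1ccncc1", 0, 0, 0, 0, {"achiral"}),
    ("achiral-cyclohexane", "C1CCCCC1", 0, 0, 0, 0, {"achiral"}),
    ("single-l-alanine", "C[C@H](N)C(=O)O", 1, 0, 0, 0, {"single_center"}),
    ("single-d-alanine", "C[C@@H](N)C(=O)O", 1, 0, 0, 0, {"single_center"}),
    ("single-l-lactic", "C[C@H](O)C(=O)O", 1, 0, 0, 0, {"single_center"}),
    ("single-glyceraldehyde", "OC[C@@H](O)C=O", 1, 0, 0, 0, {"single_center"}),
    ("single-proline", "OC(=O)[C@@H]1CCCN1", 1, 0, 0, 0, {"single_center"}),
    ("multi-l-threonine", "C[C@@H](O)[C@H](N)C(=O)O", 2, 0, 0, 0, {"multi_center"}),
    ("multi-l-isoleucine", "CC[C@H](C)[C@H](N)C(=O)O", 2, 0, 0, 0, {"multi_center"}),
    ("multi-ribose-chain", "OC[C@@H](O)[C@@H](O)[C@@H](O)C=O", 3, 0, 0, 0, {"multi_center"}),
    ("multi-tartaric-rr", "OC(=O)[C@H](O)[C@H](O)C(=O)O", 2, 0, 0, 0, {"multi_center"}),
    ("ez-crotonic-e", "C/C=C/C(=O)O", 0, 1, 0, 0, {"ez"}),
    ("ez-crotonic-z", "C/C=C\\C(=O)O", 0, 1, 0, 0, {"ez"}),
    ("ez-pentenol", "CC/C=C/CO", 0, 1, 0, 0, {"ez"}),
    ("ez-fumaric", "OC(=O)/C=C/C(=O)O", 0, 1, 0, 0, {"ez"}),
    ("ez-chiral-pentenoate", "C/C=C/[C@H](N)C(=O)O", 1, 1, 0, 0, {"ez", "single_center"}),
    ("polyene-sorbic", "C/C=C/C=C/C(=O)O", 0, 2, 0, 0, {"polyene", "ez"}),
    ("polyene-octatriene", "C/C=C/C=C/C=C/C", 0, 3, 0, 0, {"polyene", "ez"}),
    ("polyene-octatetraenoate", "C/C=C/C=C/C=C/C(=O)O", 0, 3, 0, 0, {"polyene", "ez"}),
    ("allene-propadiene", "C=C=C", 0, 0, 0, 0, {"allene", "achiral"}),
    ("allene-butadiene", "CC=C=C", 0, 0, 0, 0, {"allene"}),
    ("allene-tetramethyl", "CC(C)=C=C(C)C", 0, 0, 0, 0, {"allene"}),
    ("phosphate-methyl-ethyl", "CO[P@](=O)(O)OCC", 0, 0, 0, 1, {"phosphate"}),
    ("phosphate-ethyl-isopropyl", "CCO[P@@](=O)(O)OC(C)C", 0, 0, 0, 1, {"phosphate"}),
    ("salt-acetate-na", "CC(=O)[O-].[Na+]", 0, 0, 0, 0, {"salt", "achiral"}),
    ("salt-alaninium-cl", "C[C@@H]([NH3+])C(=O)O.[Cl-]", 1, 0, 0, 0, {"salt", "single_center"}),
    ("salt-oxalate-2na", "[O-]C(=O)C(=O)[O-].[Na+].[Na+]", 0, 0, 0, 0, {"salt"}),
    ("undef-partial-threonine", "C[C@@H](O)C(N)C(=O)O", 1, 0, 1, 0, {"undefined_center"}),
    ("undef-partial-isoleucine", "CC[C@H](C)C(N)C(=O)O", 1, 0, 1, 0, {"undefined_center"}),
]

#: placeholder entries: (fixture_id, dummy template, token to install)
_PLACEHOLDER_TEMPLATES = [
    ("placeholder-r-glycine", "*C(N)C(=O)O", "R"),
    ("placeholder-rhash-acid", "*CC(=O)O", "R#"),
    ("placeholder-x-ketone", "*CC(C)=O", "X"),
]


def _compile_template(fixture_id: str, smiles: str) -> StructureRecord:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"fixture template does not parse: {smiles!r}")
    rdDepictor.Compute2DCoords(mol)
    return mol_to_record(mol, source_id=fixture_id)


def build_fixture_set(seed: int = 0) -> list[tuple[StructureRecord, FixtureSpec]]:
    """Compile the full fixture set; deterministic (the seed is recorded only).

    Every record is 2D at ideal depiction bond lengths; stereo is fully
    annotated except the deliberate ``undefined_center`` fixtures, and the
    ``placeholder`` fixtures are built to fail screening.
    """
    out: list[tuple[StructureRecord, FixtureSpec]] = []
    for fid, template, n_tet, n_ez, n_undef, n_p, tags in _TEMPLATES:
        record = _compile_template(fid, template)
        record.properties["fixture_seed"] = str(seed)
        out.append(
            (
                record,
                FixtureSpec(fid, template, n_tet, n_ez, n_undef, n_p, frozenset(tags)),
            )
        )
    for fid, template, token in _PLACEHOLDER_TEMPLATES:
        record = _compile_template(fid, template)
        for atom in record.atoms:
            if atom.element == "*":
                atom.element = token
        record.properties["fixture_seed"] = str(seed)
        out.append(
            (record, FixtureSpec(fid, template, 0, 0, 0, 0, frozenset({"placeholder"})))
        )
    return out


def manifest(fixtures: list[tuple[StructureRecord, FixtureSpec]]) -> pd.DataFrame:
    rows = [
        {
            "fixture_id": spec.fixture_id,
            "template": spec.template,
            "expected_stereocenters": spec.expected_stereocenters,
            "expected_ez_bonds": spec.expected_ez_bonds,
            "expected_undefined": spec.expected_undefined,
            "expected_p_tags": spec.expected_p_tags,
            "tags": ",".join(sorted(spec.tags)),
        }
        for _, spec in fixtures
    ]
    return pd.DataFrame(rows)


# --- corruption oracle -------------------------------------------------------

CORRUPTION_MODES = (
    "identity",
    "invert_one_stereocenter",
    "remove_stereo_annotation",
    "flip_double_bond_ez",
    "remove_ez_annotation",
    "delete_terminal_atom",
    "add_methyl",
    "drop_fragment",
)

EXPECTED_VERDICT: dict[str, Verdict] = {
    "identity": Verdict.SAME,
    "invert_one_stereocenter": Verdict.CHIRAL_INVERSION,
    "remove_stereo_annotation": Verdict.CHIRAL_MISSING,
    "flip_double_bond_ez": Verdict.CIS_TRANS_INVERSION,
    "remove_ez_annotation": Verdict.CIS_TRANS_MISSING,
    "delete_terminal_atom": Verdict.ELSE_UNMATCHED,
    "add_methyl": Verdict.ELSE_UNMATCHED,
    "drop_fragment": Verdict.ELSE_UNMATCHED,
}

_DEFINED_TAGS = (ChiralType.CHI_TETRAHEDRAL_CW, ChiralType.CHI_TETRAHEDRAL_CCW)


@dataclass
class CorruptionResult:
    mode: str
    applicable: bool
    record: StructureRecord | None = None
    site: str = ""  # where the lesion was applied
    expected_verdict: Verdict | None = None


def _finish(
    mol: Chem.Mol,
    record: StructureRecord,
    mode: str,
    site: str,
    reassign: bool = False,
) -> CorruptionResult:
    Chem.SanitizeMol(mol)
    if reassign:
        # topology edits can leave stale stereo tags on atoms that are no
        # longer stereocenters; stereo edits must NOT be reassigned or the
        # stale bond-direction marks would undo the lesion
        Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    rdDepictor.Compute2DCoords(mol)
    out = mol_to_record(
        mol,
        source_id=record.source_id,
        name=record.name,
        properties=dict(record.properties),
    )
    out.properties["corruption"] = f"{mode}@{site}"
    return CorruptionResult(mode, True, out, site, EXPECTED_VERDICT[mode])


def _not_applicable(mode: str) -> CorruptionResult:
    return CorruptionResult(mode, False, expected_verdict=EXPECTED_VERDICT[mode])


def corrupt(record: StructureRecord, mode: str, seed: int = 0) -> CorruptionResult:
    """Apply exactly one lesion of the requested kind; seed-deterministic.

    Returns a typed not-applicable result when the record lacks the feature
    the mode targets, so suites can filter the (fixture x mode) cross.
    """
    if mode not in CORRUPTION_MODES:
        raise ValueError(f"unknown corruption mode {mode!r}")
    if mode == "identity":
        out = record.copy()
        return CorruptionResult(mode, True, out, "-", EXPECTED_VERDICT[mode])

    from ._rdkit_bridge import record_to_mol  # local import avoids cycle at init

    rng = np.random.default_rng(seed)
    mol = record_to_mol(record)
    if mol is None:
        return _not_applicable(mode)
    mol = Chem.RWMol(mol)

    if mode in ("invert_one_stereocenter", "remove_stereo_annotation"):
        centers = [a.GetIdx() for a in mol.GetAtoms() if a.GetChiralTag() in _DEFINED_TAGS]
        if not centers:
            return _not_applicable(mode)
        idx = int(rng.choice(centers))
        atom = mol.GetAtomWithIdx(idx)
        if mode == "invert_one_stereocenter":
            atom.InvertChirality()
        else:
            atom.SetChiralTag(ChiralType.CHI_UNSPECIFIED)
        return _finish(mol, record, mode, f"atom{idx}")

    if mode in ("flip_double_bond_ez", "remove_ez_annotation"):
        stereo_bonds = [
            b.GetIdx()
            for b in mol.GetBonds()
            if b.GetStereo() in (BondStereo.STEREOE, BondStereo.STEREOZ)
        ]
        if not stereo_bonds:
            return _not_applicable(mode)
        bidx = int(rng.choice(stereo_bonds))
        bond = mol.GetBondWithIdx(bidx)
        if mode == "flip_double_bond_ez":
            flipped = (
                BondStereo.STEREOZ
                if bond.GetStereo() == BondStereo.STEREOE
                else BondStereo.STEREOE
            )
            bond.SetStereo(flipped)
        else:
            for nb in list(bond.GetBeginAtom().GetBonds()) + list(bond.GetEndAtom().GetBonds()):
                nb.SetBondDir(Chem.BondDir.NONE)
            bond.SetStereo(BondStereo.STEREOANY)
        return _finish(mol, record, mode, f"bond{bidx}")

    if mode == "delete_terminal_atom":
        terminals = [
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetDegree() == 1 and a.GetSymbol() != "H" and mol.GetNumAtoms() > 2
        ]
        if not terminals:
            return _not_applicable(mode)
        idx = int(rng.choice(terminals))
        mol.RemoveAtom(idx)
        for atom in mol.GetAtoms():
            atom.SetNoImplicit(False)
            atom.SetNumExplicitHs(0)
        return _finish(mol, record, mode, f"atom{idx}", reassign=True)

    if mode == "add_methyl":
        hosts = [
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1
        ]
        if not hosts:
            return _not_applicable(mode)
        idx = int(rng.choice(hosts))
        host = mol.GetAtomWithIdx(idx)
        new_idx = mol.AddAtom(Chem.Atom(6))
        mol.AddBond(idx, new_idx, Chem.BondType.SINGLE)
        # the methyl replaces one hydrogen; explicit H counts do not
        # auto-decrement when a bond is added
        if host.GetNumExplicitHs() > 0:
            host.SetNumExplicitHs(host.GetNumExplicitHs() - 1)
        return _finish(mol, record, mode, f"atom{idx}", reassign=True)

    if mode == "drop_fragment":
        frags = Chem.GetMolFrags(mol)
        if len(frags) < 2:
            return _not_applicable(mode)
        smallest = min(frags, key=lambda f: (len(f), min(f)))
        for idx in sorted(smallest, reverse=True):
            mol.RemoveAtom(idx)
        return _finish(mol, record, mode, f"fragment{len(smallest)}atoms", reassign=True)

    raise AssertionError(mode)


# --- oracle suites -----------------------------------------------------------


def _pair_seed(base_seed: int, fixture_id: str, mode: str) -> int:
    return (int(base_seed) ^ zlib.crc32(f"{fixture_id}:{mode}".encode())) & 0x7FFFFFFF


def oracle_suite(seed: int = 0, mode_filter: tuple[str, ...] = CORRUPTION_MODES) -> pd.DataFrame:
    """Classify the full applicable (fixture x mode) cross on both channels.

    Main suite only: placeholder fixtures never reach the comparators and
    phosphate fixtures are quarantined in :func:`known_limits_suite`, because
    a phosphorus stereo-tag lesion is *designed* to be invisible there.
    """
    rows = []
    for record, spec in build_fixture_set(seed):
        if "placeholder" in spec.tags or "phosphate" in spec.tags:
            continue
        if screen_record(record).rejected:
            continue
        for mode in mode_filter:
            result = corrupt(record, mode, _pair_seed(seed, spec.fixture_id, mode))
            if not result.applicable:
                continue
            for channel in ("inchi", "smiles"):
                outcome = classify_pair(record, result.record, channel=channel)
                observed = (
                    "untranslatable"
                    if isinstance(outcome, UntranslatablePair)
                    else outcome.verdict.value
                )
                rows.append(
                    {
                        "fixture_id": spec.fixture_id,
                        "mode": mode,
                        "channel": channel,
                        "observed": observed,
                        "expected": result.expected_verdict.value,
                        "passed": observed == result.expected_verdict.value,
                    }
                )
    return pd.DataFrame(rows)


def known_limits_suite(seed: int = 0) -> pd.DataFrame:
    """Documented identifier blind spots, asserted as such.

    A phosphorus tetrahedral descriptor is invisible by construction: the
    phosphate normalization strips it from SMILES and a P(=O)(OH) center
    never reaches the InChI t sublayer. Inverting or deleting it must
    therefore read back as SAME on both channels.
    """
    rows = []
    for record, spec in build_fixture_set(seed):
        if "phosphate" not in spec.tags:
            continue
        for mode in ("invert_one_stereocenter", "remove_stereo_annotation"):
            result = corrupt(record, mode, _pair_seed(seed, spec.fixture_id, mode))
            if not result.applicable:
                continue
            for channel in ("inchi", "smiles"):
                outcome = classify_pair(record, result.record, channel=channel)
                observed = (
                    "untranslatable"
                    if isinstance(outcome, UntranslatablePair)
                    else outcome.verdict.value
                )
                rows.append(
                    {
                        "fixture_id": spec.fixture_id,
                        "mode": mode,
                        "channel": channel,
                        "observed": observed,
                        "expected": Verdict.SAME.value,  # the documented divergence
                        "passed": observed == Verdict.SAME.value,
                    }
                )
    return pd.DataFrame(rows)


# --- constructed geometry fixtures ------------------------------------------

_TILT_DEG = 25.0  # fixed out-of-plane tilt so planar chains register as 3D records


def _tilt(coords: np.ndarray, deg: float = _TILT_DEG) -> np.ndarray:
    t = np.radians(deg)
    rot = np.array(
        [[1, 0, 0], [0, np.cos(t), -np.sin(t)], [0, np.sin(t), np.cos(t)]]
    )
    return coords @ rot.T


def _chain_record(
    source_id: str, coords: np.ndarray, orders: list[BondOrder]
) -> StructureRecord:
    atoms = [
        Atom(i, "C", float(x), float(y), float(z)) for i, (x, y, z) in enumerate(coords)
    ]
    bonds = [Bond(i, i + 1, order) for i, order in enumerate(orders)]
    return StructureRecord(source_id, source_id, atoms, bonds)


def _polyene_coords(n_carbons: int, bond_length: float) -> np.ndarray:
    """All-trans zig-zag in the xy-plane (120° internal angles)."""
    coords = np.zeros((n_carbons, 3))
    step = bond_length * np.cos(np.radians(30.0))
    rise = bond_length * np.sin(np.radians(30.0))
    for i in range(n_carbons):
        coords[i] = (i * step, (i % 2) * rise, 0.0)
    return coords


def build_planar_polyene(n_carbons: int = 12, bond_length: float = 1.42) -> StructureRecord:
    """Ideal all-trans conjugated polyene C=C-C=C-…, planar by construction.

    Mimics a carotenoid backbone at reduced size; every conjugated single
    bond sits at a 180° torsion, so the planarity check must stay silent.
    """
    if n_carbons < 4 or n_carbons % 2:
        raise ValueError("polyene needs an even n_carbons >= 4")
    coords = _tilt(_polyene_coords(n_carbons, bond_length))
    orders = [
        BondOrder.DOUBLE if i % 2 == 0 else BondOrder.SINGLE
        for i in range(n_carbons - 1)
    ]
    return _chain_record("planar-polyene", coords, orders)


def build_twisted_polyene(
    n_carbons: int = 12, torsion_deg: float = 60.0, bond_length: float = 1.42
) -> StructureRecord:
    """Planar polyene twisted about its central conjugated single bond.

    The far half of the chain is rotated about the bond axis so the
    C=C–C=C torsion lands at ``torsion_deg`` — the lesion the planarity
    check must flag exactly once.
    """
    coords = _polyene_coords(n_carbons, bond_length)
    # central single bond: single bonds are (1,2), (3,4), ...
    singles = [i for i in range(n_carbons - 1) if i % 2 == 1]
    j = singles[len(singles) // 2]
    axis_origin = coords[j]
    axis = coords[j + 1] - coords[j]
    axis = axis / np.linalg.norm(axis)
    angle = np.radians(180.0 - torsion_deg)
    k = axis
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    rot = np.eye(3) + np.sin(angle) * kx + (1 - np.cos(angle)) * (kx @ kx)
    for i in range(j + 1, n_carbons):
        coords[i] = axis_origin + rot @ (coords[i] - axis_origin)
    coords = _tilt(coords)
    orders = [
        BondOrder.DOUBLE if i % 2 == 0 else BondOrder.SINGLE
        for i in range(n_carbons - 1)
    ]
    return _chain_record("twisted-polyene", coords, orders)


def build_allene(twist_deg: float = 90.0) -> StructureRecord:
    """Propadiene H2C=C=CH2 with a chosen terminal-plane twist.

    90° is the physically correct perpendicular arrangement; 0/180° is the
    flattened geometry molecular mechanics often produces.
    """
    cc = 1.31
    ch = 1.09
    # H–C=C angle of 120°: offset along the axis and within the plane
    ax = ch * np.cos(np.radians(60.0))
    perp = ch * np.sin(np.radians(60.0))
    atoms = [
        Atom(0, "C", -cc, 0.0, 0.0),
        Atom(1, "C", 0.0, 0.0, 0.0),
        Atom(2, "C", cc, 0.0, 0.0),
        # substituents on C0 in the xy-plane
        Atom(3, "H", -cc - ax, perp, 0.0),
        Atom(4, "H", -cc - ax, -perp, 0.0),
    ]
    # substituents on C2 in a plane twisted by twist_deg about the C=C=C axis
    t = np.radians(twist_deg)
    atoms.append(Atom(5, "H", cc + ax, perp * np.cos(t), perp * np.sin(t)))
    atoms.append(Atom(6, "H", cc + ax, -perp * np.cos(t), -perp * np.sin(t)))
    bonds = [
        Bond(0, 1, BondOrder.DOUBLE),
        Bond(1, 2, BondOrder.DOUBLE),
        Bond(0, 3, BondOrder.SINGLE),
        Bond(0, 4, BondOrder.SINGLE),
        Bond(2, 5, BondOrder.SINGLE),
        Bond(2, 6, BondOrder.SINGLE),
    ]
    return StructureRecord("allene", "allene", atoms, bonds)


def build_scaled_chain(bond_length: float = 1.5, n_carbons: int = 6) -> StructureRecord:
    """Flat 2D zig-zag carbon chain at a chosen drawing scale.

    At ~0.95 Å per bond it reproduces the coordinate scale of optically
    scanned drawings; at 1.5 Å it is an ordinary clean 2D layout.
    """
    coords = _polyene_coords(n_carbons, bond_length)
    orders = [BondOrder.SINGLE] * (n_carbons - 1)
    return _chain_record(f"chain-{bond_length:.2f}A", coords, orders)
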