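"""Geometric sanity checks for converted 3D structures.

Three symptoms of a chemically implausible geometry are flagged:

* a conjugated polyene whose C=C–C=C torsions are neither s-cis nor s-trans
  (conjugation keeps such systems planar; a force field fed a badly scaled
  2D drawing routinely twists them);
* an allene whose terminal substituent planes are not perpendicular — the
  two pi systems of a cumulated diene sit at 90°, yet molecular-mechanics
  minimization often flattens them to ~180°;
* heavy-atom bonds far below a plausible bond length, the signature of
  optically-scanned 2D drawings whose coordinate scale (0.90–0.98 Å per
  bond rather than ~1.5 Å) derails the 2D→3D conversion downstream.

Conjugation detection is pattern-based (double–single–double); aromatic
rings are exempt since backends keep them planar.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .chem_io import Bond, BondOrder, StructureRecord

__all__ = [
    "GeometryFlag",
    "dihedral",
    "find_conjugated_single_bonds",
    "flag_nonplanar_conjugation",
    "check_allenes",
    "check_bond_lengths",
    "run_geometry_qc",
    "PLANARITY_TOLERANCE_DEG",
    "ALLENE_TOLERANCE_DEG",
    "SHORT_BOND_LOWER_A",
]

PLANARITY_TOLERANCE_DEG = 20.0
ALLENE_TOLERANCE_DEG = 20.0
SHORT_BOND_LOWER_A = 1.05


@dataclass
class GeometryFlag:
    kind: str  # nonplanar_conjugation | allene_deviation | short_bond
    atom_indices: tuple[int, ...]
    measured: float  # degrees or Å
    threshold: float


def _coords(record: StructureRecord) -> np.ndarray:
    return np.array([[a.x, a.y, a.z] for a in record.atoms], dtype=float)


def dihedral(record: StructureRecord, a: int, b: int, c: int, d: int) -> float:
    """Signed torsion a-b-c-d in degrees, (−180, 180], right-hand convention."""
    if len({a, b, c, d}) != 4:
        raise ValueError("dihedral needs four distinct atoms")
    xyz = _coords(record)
    b1 = xyz[b] - xyz[a]
    b2 = xyz[c] - xyz[b]
    b3 = xyz[d] - xyz[c]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("undefined torsion: collinear a-b-c or b-c-d")
    angle = np.degrees(
        np.arctan2(
            np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2)), np.dot(n1, n2)
        )
    )
    return 180.0 if np.isclose(angle, -180.0) else float(angle)


def _adjacency(record: StructureRecord) -> dict[int, list[Bond]]:
    adj: dict[int, list[Bond]] = {a.index: [] for a in record.atoms}
    for bond in record.bonds:
        adj[bond.begin].append(bond)
        adj[bond.end].append(bond)
    return adj


def _double_partner(adj: dict[int, list[Bond]], atom: int, exclude: int) -> int | None:
    for bond in adj[atom]:
        if bond.order == BondOrder.DOUBLE:
            other = bond.end if bond.begin == atom else bond.begin
            if other != exclude:
                return other
    return None


def _ring_bonds(record: StructureRecord) -> set[frozenset[int]]:
    g = nx.Graph()
    g.add_nodes_from(a.index for a in record.atoms)
    g.add_edges_from((b.begin, b.end) for b in record.bonds)
    bridges = set(frozenset(e) for e in nx.bridges(g))
    return {
        frozenset((b.begin, b.end))
        for b in record.bonds
        if frozenset((b.begin, b.end)) not in bridges
    }


def find_conjugated_single_bonds(record: StructureRecord) -> list[Bond]:
    """Non-ring single bonds whose both end atoms carry a double bond."""
    adj = _adjacency(record)
    rings = _ring_bonds(record)
    out = []
    for bond in record.bonds:
        if bond.order != BondOrder.SINGLE:
            continue
        if frozenset((bond.begin, bond.end)) in rings:
            continue
        if (
            _double_partner(adj, bond.begin, bond.end) is not None
            and _double_partner(adj, bond.end, bond.begin) is not None
        ):
            out.append(bond)
    return out


def flag_nonplanar_conjugation(
    record: StructureRecord, tolerance_deg: float = PLANARITY_TOLERANCE_DEG
) -> list[GeometryFlag]:
    """Flag conjugated single bonds twisted away from both 0° and 180°."""
    adj = _adjacency(record)
    flags = []
    for bond in find_conjugated_single_bonds(record):
        a = _double_partner(adj, bond.begin, bond.end)
        d = _double_partner(adj, bond.end, bond.begin)
        try:
            torsion = dihedral(record, a, bond.begin, bond.end, d)
        except ValueError:
            continue
        deviation = min(abs(torsion), 180.0 - abs(torsion))
        if deviation > tolerance_deg:
            flags.append(
                GeometryFlag(
                    kind="nonplanar_conjugation",
                    atom_indices=(a, bond.begin, bond.end, d),
                    measured=torsion,
                    threshold=tolerance_deg,
                )
            )
    return flags


def _substituents(adj: dict[int, list[Bond]], atom: int, exclude: int) -> list[int]:
    subs = []
    for bond in adj[atom]:
        other = bond.end if bond.begin == atom else bond.begin
        if other != exclude:
            subs.append(other)
    return sorted(subs)


def check_allenes(
    record: StructureRecord, tolerance_deg: float = ALLENE_TOLERANCE_DEG
) -> list[GeometryFlag]:
    """Flag cumulated C=C=C units whose substituent-plane twist is not ~90°.

    The twist is the torsion from one terminal substituent to the other
    across the allene axis; a terminus with a single substituent uses that
    lone substituent, a terminus with none is skipped.
    """
    adj = _adjacency(record)
    flags = []
    for atom in record.atoms:
        doubles = [b for b in adj[atom.index] if b.order == BondOrder.DOUBLE]
        if len(doubles) != 2:
            continue
        t1 = doubles[0].end if doubles[0].begin == atom.index else doubles[0].begin
        t2 = doubles[1].end if doubles[1].begin == atom.index else doubles[1].begin
        s1 = _substituents(adj, t1, atom.index)
        s2 = _substituents(adj, t2, atom.index)
        if not s1 or not s2:
            continue  # bare terminus: twist undefined, skipped
        try:
            twist = dihedral(record, s1[0], t1, t2, s2[0])
        except ValueError:
            continue
        deviation = abs(abs(twist) - 90.0)
        if deviation > tolerance_deg:
            flags.append(
                GeometryFlag(
                    kind="allene_deviation",
                    atom_indices=(s1[0], t1, atom.index, t2, s2[0]),
                    measured=twist,
                    threshold=tolerance_deg,
                )
            )
    return flags


def check_bond_lengths(
    record: StructureRecord, lower: float = SHORT_BOND_LOWER_A
) -> list[GeometryFlag]:
    """Flag heavy-heavy bonds shorter than the plausibility bound (Å).

    Works on 2D records too (in-plane distances), which is where the
    OCR-scaling symptom actually lives.
    """
    xyz = _coords(record)
    flags = []
    for bond in record.bonds:
        if record.atoms[bond.begin].element == "H" or record.atoms[bond.end].element == "H":
            continue
        length = float(np.linalg.norm(xyz[bond.begin] - xyz[bond.end]))
        if length < lower:
            flags.append(
                GeometryFlag(
                    kind="short_bond",
                    atom_indices=(bond.begin, bond.end),
                    measured=length,
                    threshold=lower,
                )
            )
    return flags


def run_geometry_qc(
    record: StructureRecord,
    planarity_tolerance_deg: float = PLANARITY_TOLERANCE_DEG,
    allene_tolerance_deg: float = ALLENE_TOLERANCE_DEG,
    short_bond_lower: float = SHORT_BOND_LOWER_A,
) -> list[GeometryFlag]:
    """All geometry checks for one record; a nonzero count means "needs curation"."""
    return (
        flag_nonplanar_conjugation(record, planarity_tolerance_deg)
        + check_allenes(record, allene_tolerance_deg)
        + check_bond_lengths(record, short_bond_lower)
    )
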