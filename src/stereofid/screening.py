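"""Pre-filtering of structure records before identifier generation.

Public compound collections carry entries that do not denote a single,
fully defined compound: generic residues drawn as "R" (an amino-acid side
chain stands for twenty different molecules), "X" for an unspecified halogen,
and "n"-fold repeat units of polymers. Such records cannot be canonicalized
meaningfully and are rejected here; multi-component (salt) entries are
detected and optionally reduced to their largest fragment, the conventional
"wash" behavior of structure-preparation tools.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import networkx as nx

from ._rdkit_bridge import atomic_mass
from .chem_io import StructureRecord

__all__ = [
    "ScreenReport",
    "screen_record",
    "component_count",
    "strip_salts",
    "RESIDUE_TOKENS",
    "HALOGEN_TOKENS",
]

#: atom symbols denoting an undefined residue / query atom
RESIDUE_TOKENS = frozenset({"R", "R#", "*", "A", "Q"})
#: atom symbols denoting an unspecified halogen ("X" only as a full token,
#: so real elements such as Xe are untouched)
HALOGEN_TOKENS = frozenset({"X"})

_FORMULA_REPEAT_RE = re.compile(r"\)\s*n\b")


@dataclass
class ScreenReport:
    record_id: str
    rejected: bool
    reasons: list[str] = field(default_factory=list)
    component_count: int = 1
    kept_fragment_atoms: int = 0


def _bond_graph(record: StructureRecord) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(a.index for a in record.atoms)
    g.add_edges_from((b.begin, b.end) for b in record.bonds)
    return g


def component_count(record: StructureRecord) -> int:
    """Connected components of the atom-bond graph; isolated atoms count."""
    if not record.atoms:
        return 0
    return nx.number_connected_components(_bond_graph(record))


def screen_record(record: StructureRecord) -> ScreenReport:
    """Total screening: every matched rejection condition is listed."""
    reasons: list[str] = []
    if not record.atoms:
        reasons.append("empty")
    if any(a.element in RESIDUE_TOKENS for a in record.atoms):
        reasons.append("undefined_residue")
    if any(a.element in HALOGEN_TOKENS for a in record.atoms):
        reasons.append("undefined_halogen")
    repeat = any(t.upper() == "SRU" for t in record.sgroup_types)
    if not repeat:
        for key, value in record.properties.items():
            if "formula" in key.lower() and _FORMULA_REPEAT_RE.search(value):
                repeat = True
                break
    if repeat:
        reasons.append("repeat_unit")
    n_comp = component_count(record)
    largest = 0
    if record.atoms:
        g = _bond_graph(record)
        heavy = {a.index for a in record.atoms if a.element != "H"}
        largest = max(len(comp & heavy) for comp in nx.connected_components(g))
    return ScreenReport(
        record_id=record.source_id,
        rejected=bool(reasons),
        reasons=reasons,
        component_count=n_comp,
        kept_fragment_atoms=largest,
    )


def strip_salts(record: StructureRecord) -> StructureRecord:
    """Keep the largest fragment of a multi-component record.

    Selection: most heavy atoms, then largest total atomic mass, then the
    fragment containing the lowest original atom index. Atom indices are
    renumbered contiguously; the original component count is recorded in the
    properties. Single-component records are returned as an identical copy.
    """
    if not record.atoms:
        raise ValueError("cannot strip salts from an empty molecule")
    g = _bond_graph(record)
    components = [sorted(c) for c in nx.connected_components(g)]
    if len(components) == 1:
        return record.copy()
    by_index = {a.index: a for a in record.atoms}

    def rank(comp: list[int]) -> tuple[int, float, int]:
        heavy = sum(1 for i in comp if by_index[i].element != "H")
        mass = sum(atomic_mass(by_index[i].element) for i in comp)
        return (heavy, mass, -min(comp))

    keep = max(components, key=rank)
    keep_set = set(keep)
    mapping = {old: new for new, old in enumerate(keep)}
    out = record.copy()
    out.atoms = [
        replace(by_index[i], index=mapping[i]) for i in keep
    ]
    out.bonds = [
        replace(b, begin=mapping[b.begin], end=mapping[b.end])
        for b in record.bonds
        if b.begin in keep_set and b.end in keep_set
    ]
    out.properties = dict(record.properties)
    out.properties["original_component_count"] = str(len(components))
    return out
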