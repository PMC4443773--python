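"""Bridge between the neutral :class:`StructureRecord` and RDKit molecules.

All chemistry (perception, canonicalization, depiction, embedding) happens on
RDKit molecules; everything that crosses a module boundary is a
``StructureRecord``. The bridge goes through V2000 molblock text in both
directions so that stereo perception follows the file-format semantics
(wedges for 2D, coordinates for 3D) rather than any in-memory shortcuts.
"""

from __future__ import annotations

from rdkit import Chem, rdBase
from rdkit.Chem import AllChem  # noqa: F401  (registers depictor/forcefield code)

from .chem_io import StructureRecord, format_molblock, parse_molblock

rdBase.DisableLog("rdApp.warning")
rdBase.DisableLog("rdApp.error")

_PT = Chem.GetPeriodicTable()

#: tokens that are not chemical elements and must never reach the backend
PLACEHOLDER_TOKENS = frozenset({"R", "R#", "*", "A", "Q", "X"})


def is_real_element(symbol: str) -> bool:
    if symbol in PLACEHOLDER_TOKENS:
        return False
    try:
        return _PT.GetAtomicNumber(symbol) > 0
    except Exception:
        return False


def atomic_mass(symbol: str) -> float:
    """Standard atomic weight; 0.0 for placeholder/unknown tokens."""
    try:
        return float(_PT.GetAtomicWeight(symbol))
    except Exception:
        return 0.0


def has_placeholder(record: StructureRecord) -> bool:
    return any(not is_real_element(a.element) for a in record.atoms)


def record_to_mol(
    record: StructureRecord, *, remove_hs: bool = True, sanitize: bool = True
) -> Chem.Mol | None:
    """Build an RDKit Mol; returns None when RDKit cannot perceive the record."""
    if has_placeholder(record):
        raise ValueError(
            f"record {record.source_id!r} contains placeholder atoms; "
            "screen before handing it to the chemistry backend"
        )
    return Chem.MolFromMolBlock(
        format_molblock(record), sanitize=sanitize, removeHs=remove_hs
    )


def mol_to_record(
    mol: Chem.Mol,
    *,
    source_id: str,
    name: str | None = None,
    properties: dict[str, str] | None = None,
) -> StructureRecord:
    """Serialize a Mol (using its current conformer) back into a record."""
    block = Chem.MolToMolBlock(mol, kekulize=True)
    record = parse_molblock(block.splitlines())
    record.source_id = source_id
    record.name = name if name is not None else source_id
    if properties:
        record.properties = dict(properties)
    return record
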