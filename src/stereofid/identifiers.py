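"""InChI and canonical-SMILES generation, layer parsing, and stereo-tag inventory.

The quality-control methodology reduces "are these two structures the same
molecule?" to a comparison of line notations: InChI is split into its named
sublayers (formula, c connectivity, h hydrogens, b double-bond stereo,
t tetrahedral stereo, m parity, s stereo provenance) and canonical SMILES is
summarized as an inventory of tetrahedral (``@``/``@@``) and directional
(``/``, ``\\``) stereo descriptors.

One normalization rule is chemistry-specific: tetrahedral descriptors on
phosphorus are dropped before comparison, because the oxygens of a phosphate
group are rendered inequivalent only by the line notation's artificial bond
assignment (protonation/tautomer choice), not by the actual chemistry, so a
"flipped" phosphorus tag does not indicate a corrupted structure.

A single canonicalization backend (RDKit) is used for every string produced
in a run, so both sides of any comparison share the same SMILES flavor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from rdkit import Chem
from rdkit.Chem.rdchem import BondStereo, ChiralType

from ._rdkit_bridge import has_placeholder, record_to_mol
from .chem_io import StructureRecord

__all__ = [
    "InChILayers",
    "SmilesStereoProfile",
    "Untranslatable",
    "BACKEND_ID",
    "gen_inchi",
    "parse_inchi_layers",
    "reassemble_inchi",
    "count_undefined_chiral",
    "gen_canonical_smiles",
    "normalize_phosphate_tags",
]

BACKEND_ID = "rdkit-" + Chem.rdBase.rdkitVersion


@dataclass(frozen=True)
class Untranslatable:
    """Typed failure marker: the structure defeated the canonicalizer.

    Such records are a first-class count in reports, never a crash.
    """

    record_id: str
    channel: str  # "inchi" | "smiles"
    reason: str


#: main-layer prefixes exposed as named fields, in canonical order
_NAMED_PREFIXES = ("c", "h", "b", "t", "m", "s")
#: prefixes that open a non-main layer block (isotopic, fixed-H, reconnected)
_BLOCK_PREFIXES = ("i", "f", "r")


@dataclass(frozen=True)
class InChILayers:
    raw: str
    version_prefix: str
    formula: str
    segments: tuple[str, ...]  # every "/"-separated segment after the version, verbatim
    c: str | None = None
    h: str | None = None
    b: str | None = None
    t: str | None = None
    m: str | None = None
    s: str | None = None

    @property
    def undefined_chiral_count(self) -> int:
        return count_undefined_chiral(self)


def parse_inchi_layers(inchi: str) -> InChILayers:
    """Split an InChI string into named sublayers.

    The first segment after the version is the formula; subsequent main-layer
    segments are assigned by their one-letter prefixes. Segments belonging to
    auxiliary blocks (``/i``, ``/f``, ``/r``) and charge layers (``/q``,
    ``/p``) are preserved verbatim in ``segments`` for byte-exact reassembly
    but are not named. An absent layer is ``None``, never an empty string.
    """
    if not inchi.startswith("InChI="):
        raise ValueError(f"not an InChI string: {inchi!r}")
    parts = inchi.split("/")
    version = parts[0][len("InChI=") :]
    if len(parts) < 2:
        raise ValueError(f"InChI without formula segment: {inchi!r}")
    segments = tuple(parts[1:])
    formula = segments[0]
    named: dict[str, str] = {}
    in_main = True
    for seg in segments[1:]:
        if not seg:
            continue
        prefix = seg[0]
        if prefix in _BLOCK_PREFIXES:
            in_main = False
        if in_main and prefix in _NAMED_PREFIXES and prefix not in named:
            named[prefix] = seg[1:]
    return InChILayers(
        raw=inchi,
        version_prefix=version,
        formula=formula,
        segments=segments,
        **{k: named.get(k) for k in _NAMED_PREFIXES},
    )


def reassemble_inchi(layers: InChILayers) -> str:
    """Rebuild the InChI string; byte-exact inverse of :func:`parse_inchi_layers`."""
    return "InChI=" + layers.version_prefix + "/" + "/".join(layers.segments)


def count_undefined_chiral(layers: InChILayers) -> int:
    """Number of ``?`` (undefined stereocenter) markers in the t sublayer."""
    return layers.t.count("?") if layers.t is not None else 0


def gen_inchi(record: StructureRecord) -> InChILayers | Untranslatable:
    """Standard InChI with stereo perception, parsed into sublayers."""
    if has_placeholder(record):
        raise ValueError(
            f"record {record.source_id!r} has placeholder atoms; screen first"
        )
    mol = record_to_mol(record)
    if mol is None:
        return Untranslatable(record.source_id, "inchi", "structure perception failed")
    inchi = Chem.MolToInchi(mol, treatWarningAsError=False)
    if not inchi:
        return Untranslatable(record.source_id, "inchi", "InChI generation failed")
    return parse_inchi_layers(inchi)


# --- canonical SMILES --------------------------------------------------------

_TAG_RE = re.compile(r"@@|@")
#: bracket atom with a tetrahedral descriptor on phosphorus:
#: optional isotope, P, @/@@, optional explicit H count, optional charge
_P_TAG_RE = re.compile(r"\[(\d*)P(?:@@|@)((?:H\d*)?(?:[+-]\d*)?)\]")


@dataclass(frozen=True)
class SmilesStereoProfile:
    canonical: str
    tetrahedral_tags: int  # count of @/@@ descriptor groups ("@@" counts once)
    ez_tags: int  # count of "/" and "\" directional-bond characters
    phosphorus_tags_removed: int
    normalized: str  # canonical after phosphate normalization
    skeleton: str  # canonical with all stereo dropped (constitution only)
    tet_signature: str  # canonical with double-bond stereo cleared, P-normalized
    ez_signature: str  # canonical with tetrahedral stereo cleared

    @property
    def effective_tetrahedral_tags(self) -> int:
        """Tetrahedral descriptors that survive phosphate normalization."""
        return self.tetrahedral_tags - self.phosphorus_tags_removed


def _strip_phosphorus_tags(smiles: str) -> tuple[str, int]:
    # once the descriptor is gone a bare [P] bracket is redundant; drop it to
    # match what the canonicalizer itself prints for an untagged phosphorus
    def repl(m: re.Match) -> str:
        if not m.group(1) and not m.group(2):
            return "P"
        return f"[{m.group(1)}P{m.group(2)}]"

    return _P_TAG_RE.subn(repl, smiles)


def _canonical_no_bond_stereo(mol: Chem.Mol) -> str:
    m = Chem.Mol(mol)
    for bond in m.GetBonds():
        bond.SetStereo(BondStereo.STEREONONE)
        bond.SetBondDir(Chem.BondDir.NONE)
    return Chem.MolToSmiles(m)


def _canonical_no_atom_stereo(mol: Chem.Mol) -> str:
    m = Chem.Mol(mol)
    for atom in m.GetAtoms():
        atom.SetChiralTag(ChiralType.CHI_UNSPECIFIED)
    return Chem.MolToSmiles(m)


def gen_canonical_smiles(record: StructureRecord) -> SmilesStereoProfile | Untranslatable:
    """Canonical isomeric SMILES plus its stereo-descriptor inventory."""
    if has_placeholder(record):
        raise ValueError(
            f"record {record.source_id!r} has placeholder atoms; screen first"
        )
    mol = record_to_mol(record)
    if mol is None:
        return Untranslatable(record.source_id, "smiles", "structure perception failed")
    try:
        canonical = Chem.MolToSmiles(mol)
    except Exception as exc:  # canonicalization failure is a counted outcome
        return Untranslatable(record.source_id, "smiles", f"canonicalization failed: {exc}")
    if not canonical:
        return Untranslatable(record.source_id, "smiles", "canonicalization failed")
    normalized, n_removed = _strip_phosphorus_tags(canonical)
    tet_sig, _ = _strip_phosphorus_tags(_canonical_no_bond_stereo(mol))
    return SmilesStereoProfile(
        canonical=canonical,
        tetrahedral_tags=len(_TAG_RE.findall(canonical)),
        ez_tags=canonical.count("/") + canonical.count("\\"),
        phosphorus_tags_removed=n_removed,
        normalized=normalized,
        skeleton=Chem.MolToSmiles(mol, isomericSmiles=False),
        tet_signature=tet_sig,
        ez_signature=_canonical_no_atom_stereo(mol),
    )


def normalize_phosphate_tags(profile: SmilesStereoProfile) -> SmilesStereoProfile:
    """Drop tetrahedral descriptors on phosphorus; idempotent.

    ``normalized`` differs from ``canonical`` only at phosphorus stereo
    descriptors; non-phosphorus descriptors are untouched.
    """
    normalized, n_removed = _strip_phosphorus_tags(profile.canonical)
    tet_sig, _ = _strip_phosphorus_tags(profile.tet_signature)
    return replace(
        profile,
        normalized=normalized,
        phosphorus_tags_removed=n_removed,
        tet_signature=tet_sig,
    )
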