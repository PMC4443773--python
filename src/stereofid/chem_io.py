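"""Reading and writing MDL MOL / SD (V2000) structure files.

The reader is deliberately conservative: atoms keep their file order, element
tokens (including placeholder symbols such as ``R``, ``R#``, ``X``, ``*``) are
preserved verbatim, and records that fail to parse are collected in a report
instead of aborting the run, so dataset-composition statistics can still be
reported for dirty inputs.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from math import isfinite as _isfinite
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Atom",
    "Bond",
    "StructureRecord",
    "BondOrder",
    "Wedge",
    "EZ",
    "TetrahedralParity",
    "SdfParseError",
    "UnsupportedFormatError",
    "SdfReadResult",
    "read_sdf",
    "read_sdf_with_report",
    "write_sdf",
    "format_molblock",
    "parse_molblock",
    "detect_dimensionality",
]

#: |z| below this is treated as "zero" when deciding 2D vs 3D (Å).
Z_2D_TOLERANCE = 1e-4


class TetrahedralParity(enum.Enum):
    UNDEFINED = "undefined"
    CLOCKWISE = "clockwise"
    COUNTERCLOCKWISE = "counterclockwise"


class BondOrder(enum.IntEnum):
    SINGLE = 1
    DOUBLE = 2
    TRIPLE = 3
    AROMATIC = 4


class Wedge(enum.IntEnum):
    """MOL bond-stereo codes meaningful on single bonds."""

    NONE = 0
    UP = 1
    EITHER = 4
    DOWN = 6


class EZ(enum.Enum):
    """Double-bond stereo as encoded in a MOL file.

    In V2000 the geometry of a defined double bond lives in the 2D/3D
    coordinates; the only explicit annotation is the "crossed" flag (code 3)
    marking the stereochemistry as deliberately unspecified.
    """

    UNDEFINED = "undefined"
    E = "E"
    Z = "Z"
    CROSSED = "unspecified-crossed"


@dataclass
class Atom:
    index: int
    element: str
    x: float
    y: float
    z: float
    formal_charge: int = 0
    tetrahedral_parity: TetrahedralParity = TetrahedralParity.UNDEFINED


@dataclass
class Bond:
    begin: int
    end: int
    order: BondOrder
    wedge: Wedge = Wedge.NONE
    ez: EZ = EZ.UNDEFINED


@dataclass
class StructureRecord:
    source_id: str
    name: str
    atoms: list[Atom]
    bonds: list[Bond]
    properties: dict[str, str] = field(default_factory=dict)
    sgroup_types: list[str] = field(default_factory=list)

    @property
    def dimensionality(self) -> str:
        return detect_dimensionality(self)

    def copy(self) -> "StructureRecord":
        return StructureRecord(
            source_id=self.source_id,
            name=self.name,
            atoms=[replace(a) for a in self.atoms],
            bonds=[replace(b) for b in self.bonds],
            properties=dict(self.properties),
            sgroup_types=list(self.sgroup_types),
        )


class SdfParseError(ValueError):
    """A single record could not be parsed."""

    def __init__(self, record_index: int, source_id: str, message: str):
        self.record_index = record_index
        self.source_id = source_id
        super().__init__(f"record {record_index} ({source_id or '?'}): {message}")


class UnsupportedFormatError(ValueError):
    """Input uses a connection-table flavor this reader does not support."""


@dataclass
class SdfReadResult:
    records: list[StructureRecord]
    errors: list[SdfParseError]


def detect_dimensionality(record: StructureRecord) -> str:
    """``2D`` iff every atom has |z| below the flat-file tolerance."""
    if not record.atoms:
        raise ValueError("empty molecule has no dimensionality")
    if all(abs(a.z) < Z_2D_TOLERANCE for a in record.atoms):
        return "2D"
    return "3D"


# --- parsing -----------------------------------------------------------------

_LEGACY_CHARGE = {0: 0, 1: 3, 2: 2, 3: 1, 4: 0, 5: -1, 6: -2, 7: -3}
_PARITY = {
    1: TetrahedralParity.CLOCKWISE,
    2: TetrahedralParity.COUNTERCLOCKWISE,
}
_SD_KEY_RE = re.compile(r">\s*<(.*?)>")


def _int_at(line: str, start: int, end: int, default: int = 0) -> int:
    tok = line[start:end].strip()
    return int(tok) if tok else default


def parse_molblock(lines: Sequence[str], source_id: str = "") -> StructureRecord:
    """Parse the connection-table part of one record (header through M END)."""
    if len(lines) < 4:
        raise ValueError("truncated molblock: fewer than 4 lines")
    name = lines[0].strip()
    counts = lines[3]
    if "V3000" in counts:
        raise UnsupportedFormatError("V3000 connection tables are not supported")
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except ValueError as exc:
        raise ValueError(f"bad counts line: {counts!r}") from exc
    if len(lines) < 4 + n_atoms + n_bonds:
        raise ValueError("truncated molblock: atom/bond block incomplete")

    atoms: list[Atom] = []
    for i in range(n_atoms):
        line = lines[4 + i]
        try:
            x, y, z = float(line[0:10]), float(line[10:20]), float(line[20:30])
            element = line[31:34].strip()
        except (ValueError, IndexError):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"bad atom line: {line!r}")
            x, y, z = float(parts[0]), float(parts[1]), float(parts[2])
            element = parts[3]
        if not element:
            raise ValueError(f"empty element token on atom line: {line!r}")
        charge = _LEGACY_CHARGE.get(_int_at(line, 36, 39), 0)
        parity = _PARITY.get(_int_at(line, 39, 42), TetrahedralParity.UNDEFINED)
        atoms.append(Atom(i, element, x, y, z, charge, parity))

    bonds: list[Bond] = []
    for i in range(n_bonds):
        line = lines[4 + n_atoms + i]
        try:
            begin = int(line[0:3]) - 1
            end = int(line[3:6]) - 1
            order_code = int(line[6:9])
        except (ValueError, IndexError):
            parts = line.split()
            begin, end, order_code = int(parts[0]) - 1, int(parts[1]) - 1, int(parts[2])
            line = ""
        stereo = _int_at(line, 9, 12) if line else 0
        if begin == end:
            raise ValueError(f"self-bond on line: {line!r}")
        if not (0 <= begin < n_atoms and 0 <= end < n_atoms):
            raise ValueError(f"bond references missing atom: {begin + 1}-{end + 1}")
        try:
            order = BondOrder(order_code)
        except ValueError:
            raise ValueError(f"unsupported bond order {order_code}")
        wedge = Wedge.NONE
        ez = EZ.UNDEFINED
        if order == BondOrder.SINGLE and stereo in (1, 4, 6):
            wedge = Wedge(stereo)
        elif order == BondOrder.DOUBLE and stereo == 3:
            ez = EZ.CROSSED
        bonds.append(Bond(begin, end, order, wedge, ez))

    record = StructureRecord(source_id or name, name, atoms, bonds)

    for line in lines[4 + n_atoms + n_bonds :]:
        if line.startswith("M  END"):
            break
        if line.startswith("M  CHG"):
            parts = line.split()
            n = int(parts[2])
            for k in range(n):
                idx = int(parts[3 + 2 * k]) - 1
                record.atoms[idx].formal_charge = int(parts[4 + 2 * k])
        elif line.startswith("M  STY"):
            parts = line.split()
            n = int(parts[2])
            for k in range(n):
                record.sgroup_types.append(parts[4 + 2 * k])
    return record


def _split_records(text: str) -> list[list[str]]:
    blocks: list[list[str]] = []
    current: list[str] = []
    for line in text.splitlines():
        if line.strip() == "$$$$":
            blocks.append(current)
            current = []
        else:
            current.append(line)
    if any(ln.strip() for ln in current):
        blocks.append(current)
    return blocks


def _parse_record(block: list[str], index: int) -> StructureRecord:
    try:
        m_end = next(i for i, ln in enumerate(block) if ln.startswith("M  END"))
    except StopIteration:
        # single-record MOL files may legally omit M END; take the whole block
        m_end = len(block) - 1
    record = parse_molblock(block[: m_end + 1])
    # SD data fields
    i = m_end + 1
    while i < len(block):
        m = _SD_KEY_RE.match(block[i])
        if m:
            key = m.group(1)
            values: list[str] = []
            i += 1
            while i < len(block) and block[i].strip() != "":
                values.append(block[i])
                i += 1
            record.properties[key] = "\n".join(values)
        i += 1
    if not record.source_id:
        record.source_id = f"record_{index}"
    return record


def read_sdf_with_report(path: str | Path) -> SdfReadResult:
    """Read a multi-record SD (or single-record MOL) file.

    Records that fail block-level parsing are skipped and reported in
    ``errors``; an unreadable file raises.
    """
    text = Path(path).read_text()
    records: list[StructureRecord] = []
    errors: list[SdfParseError] = []
    for i, block in enumerate(_split_records(text)):
        header = block[0].strip() if block else ""
        try:
            records.append(_parse_record(block, i))
        except UnsupportedFormatError:
            raise
        except (ValueError, IndexError) as exc:
            errors.append(SdfParseError(i, header, str(exc)))
    return SdfReadResult(records, errors)


def read_sdf(path: str | Path) -> list[StructureRecord]:
    return read_sdf_with_report(path).records


# --- writing -----------------------------------------------------------------

_WRITE_CHARGE = {3: 1, 2: 2, 1: 3, -1: 5, -2: 6, -3: 7}
_WRITE_PARITY = {
    TetrahedralParity.CLOCKWISE: 1,
    TetrahedralParity.COUNTERCLOCKWISE: 2,
}


def format_molblock(record: StructureRecord) -> str:
    dim = "2D" if all(abs(a.z) < Z_2D_TOLERANCE for a in record.atoms) else "3D"
    lines = [
        record.name,
        f"  stereofd          {dim}",
        "",
        f"{len(record.atoms):3d}{len(record.bonds):3d}  0  0  0  0  0  0  0  0999 V2000",
    ]
    charged: list[tuple[int, int]] = []
    for a in record.atoms:
        if not all(map(_isfinite, (a.x, a.y, a.z))):
            raise ValueError(
                f"non-finite coordinates on atom {a.index} of {record.source_id!r}"
            )
        parity = _WRITE_PARITY.get(a.tetrahedral_parity, 0)
        lines.append(
            f"{a.x:10.4f}{a.y:10.4f}{a.z:10.4f} {a.element:<3}"
            f" 0{_WRITE_CHARGE.get(a.formal_charge, 0):3d}{parity:3d}"
            + "  0" * 9
        )
        if a.formal_charge != 0:
            charged.append((a.index + 1, a.formal_charge))
    for b in record.bonds:
        stereo = 0
        if b.order == BondOrder.SINGLE and b.wedge != Wedge.NONE:
            stereo = int(b.wedge)
        elif b.order == BondOrder.DOUBLE and b.ez == EZ.CROSSED:
            stereo = 3
        lines.append(f"{b.begin + 1:3d}{b.end + 1:3d}{int(b.order):3d}{stereo:3d}")
    for start in range(0, len(charged), 8):
        chunk = charged[start : start + 8]
        lines.append(
            f"M  CHG{len(chunk):3d}"
            + "".join(f"{idx:4d}{chg:4d}" for idx, chg in chunk)
        )
    lines.append("M  END")
    return "\n".join(lines) + "\n"


def format_sd_record(record: StructureRecord) -> str:
    out = format_molblock(record)
    for key, value in record.properties.items():
        out += f">  <{key}>\n{value}\n\n"
    out += "$$$$\n"
    return out


def write_sdf(records: Iterable[StructureRecord], path: str | Path) -> None:
    """Write records as a $$$$-delimited V2000 SD file (4-decimal coordinates)."""
    Path(path).write_text("".join(format_sd_record(r) for r in records))
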