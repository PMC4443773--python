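"""Six-way classification of structure pairs and the aggregate stereo reports.

A pair of snapshots of the same record (before/after a conversion step) is
classified as one of:

* ``SAME`` — every compared layer matches: a correct conversion;
* ``CHIRAL_INVERSION`` — a tetrahedral center flipped configuration;
* ``CHIRAL_MISSING`` — stereochemistry is undefined on one side
  ("?" in the InChI t sublayer, or @-descriptors lost from one SMILES);
* ``CIS_TRANS_INVERSION`` — a double bond flipped E/Z;
* ``CIS_TRANS_MISSING`` — double-bond stereo undefined on one side;
* ``ELSE_UNMATCHED`` — the constitution itself changed (formula/connectivity).

Chirality outranks cis/trans in the precedence ladder because chiral
inversion is the most serious and most frequent corruption mode in practice;
all coexisting differences are kept in the evidence string.

Pairs where either side defeated the canonicalizer are *withheld* from the
taxonomy and counted in a separate "Untranslatable" bucket, keeping the
frequency table a clean partition.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

from .chem_io import StructureRecord
from .identifiers import (
    InChILayers,
    SmilesStereoProfile,
    Untranslatable,
    count_undefined_chiral,
    gen_canonical_smiles,
    gen_inchi,
)

__all__ = [
    "Verdict",
    "ComparisonVerdict",
    "UntranslatablePair",
    "CensusRow",
    "PairClassification",
    "compare_inchi",
    "compare_smiles",
    "classify_pair",
    "census",
    "tabulate",
    "PAIR_LABELS",
    "STAGE_LABELS",
    "UNTRANSLATABLE_ROW",
]

#: checkpoint-pair column labels, as conventionally printed
PAIR_LABELS = ("cpd – wash", "wash – mm", "cpd – mm")
#: census stage row labels
STAGE_LABELS = {
    "initial_2d": "Initial 2D structures",
    "after_wash": "After wash",
    "after_minimization": "After minimization",
}
UNTRANSLATABLE_ROW = "Untranslatable"


class Verdict(str, enum.Enum):
    SAME = "Same"
    CHIRAL_INVERSION = "Chiral inversion"
    CHIRAL_MISSING = "Chiral missing"
    CIS_TRANS_INVERSION = "Cis/trans inversion"
    CIS_TRANS_MISSING = "Cis/trans missing"
    ELSE_UNMATCHED = "Else unmatched"


@dataclass
class ComparisonVerdict:
    verdict: Verdict
    channel: str  # "inchi" | "smiles"
    layer_match: dict[str, bool] = field(default_factory=dict)
    undefined_before: int = 0
    undefined_after: int = 0
    evidence: str = ""


@dataclass
class UntranslatablePair:
    """Verdict withheld: one (or both) sides has no identifier."""

    channel: str
    reason_before: str | None = None
    reason_after: str | None = None


def _parse_stereo_entries(layer: str | None) -> dict[str, str]:
    """Split a t/b sublayer into {center-or-bond key: sign} entries.

    ``"2-,3?"`` -> ``{"2": "-", "3": "?"}``; ``"4-3+"`` -> ``{"4-3": "+"}``.
    Standard InChI *omits* an undefined element from the layer entirely when
    no defined sibling forces a "?" placeholder, so a key present on one side
    only also means "annotation lost", not "annotation flipped".
    """
    if not layer:
        return {}
    entries: dict[str, str] = {}
    for item in layer.split(","):
        item = item.strip()
        if not item:
            continue
        if item[-1] in "+-?":
            entries[item[:-1]] = item[-1]
        else:
            entries[item] = ""
    return entries


def _stereo_layer_difference(before: str | None, after: str | None) -> str:
    """'' (no difference), 'missing', or 'inverted' for a t/b sublayer pair."""
    if before == after:
        return ""
    eb, ea = _parse_stereo_entries(before), _parse_stereo_entries(after)
    if "?" in (before or "") or "?" in (after or ""):
        return "missing"
    if set(eb) != set(ea):
        return "missing"
    return "inverted"


def compare_inchi(
    before: InChILayers, after: InChILayers, mode: str = "extended"
) -> ComparisonVerdict:
    """Classify a pair by sublayer correspondence (formula, c, h, b, t).

    ``mode="strict-paper"`` compares chirality on the t sublayer only;
    ``mode="extended"`` (default) also consults the m parity sublayer, which
    catches a whole-molecule mirror inversion that leaves t unchanged.
    """
    layers = ["formula", "c", "h", "b", "t"]
    if mode == "extended":
        layers.append("m")
    match = {
        name: getattr(before, name if name != "formula" else "formula")
        == getattr(after, name if name != "formula" else "formula")
        for name in layers
    }
    evidence_parts = [
        f"{name}: {getattr(before, name)!r} != {getattr(after, name)!r}"
        for name in layers
        if not match[name]
    ]
    ub, ua = count_undefined_chiral(before), count_undefined_chiral(after)

    t_diff = _stereo_layer_difference(before.t, after.t)
    m_diff = mode == "extended" and before.m != after.m
    b_diff = _stereo_layer_difference(before.b, after.b)

    if not match["formula"] or not match["c"] or not match["h"]:
        verdict = Verdict.ELSE_UNMATCHED
    elif t_diff == "missing":
        verdict = Verdict.CHIRAL_MISSING
    elif t_diff == "inverted" or m_diff:
        verdict = Verdict.CHIRAL_INVERSION
    elif b_diff == "missing":
        verdict = Verdict.CIS_TRANS_MISSING
    elif b_diff == "inverted":
        verdict = Verdict.CIS_TRANS_INVERSION
    else:
        verdict = Verdict.SAME
    return ComparisonVerdict(
        verdict=verdict,
        channel="inchi",
        layer_match=match,
        undefined_before=ub,
        undefined_after=ua,
        evidence="; ".join(evidence_parts),
    )


def compare_smiles(
    before: SmilesStereoProfile, after: SmilesStereoProfile
) -> ComparisonVerdict:
    """Classify a pair by canonical-SMILES text comparison.

    The phosphate-normalized strings are the primary comparison; when they
    differ the stereo-stripped skeletons decide constitution vs stereo, and
    the descriptor inventory decides missing vs inverted. No atom mapping is
    attempted — detection is string- and count-based by design.
    """
    evidence = ""
    if before.normalized == after.normalized:
        verdict = Verdict.SAME
    elif before.skeleton != after.skeleton:
        verdict = Verdict.ELSE_UNMATCHED
        evidence = f"skeleton: {before.skeleton!r} != {after.skeleton!r}"
    elif before.effective_tetrahedral_tags != after.effective_tetrahedral_tags:
        verdict = Verdict.CHIRAL_MISSING
        evidence = (
            f"tetrahedral tags {before.effective_tetrahedral_tags} -> "
            f"{after.effective_tetrahedral_tags}"
        )
    elif before.tet_signature != after.tet_signature:
        verdict = Verdict.CHIRAL_INVERSION
        evidence = f"{before.tet_signature!r} != {after.tet_signature!r}"
    elif before.ez_tags != after.ez_tags:
        verdict = Verdict.CIS_TRANS_MISSING
        evidence = f"directional chars {before.ez_tags} -> {after.ez_tags}"
    elif before.ez_signature != after.ez_signature:
        verdict = Verdict.CIS_TRANS_INVERSION
        evidence = f"{before.ez_signature!r} != {after.ez_signature!r}"
    else:
        # differs only at phosphorus descriptors pre-normalization
        verdict = Verdict.SAME
    return ComparisonVerdict(
        verdict=verdict,
        channel="smiles",
        layer_match={"normalized": before.normalized == after.normalized},
        evidence=evidence or (f"{before.normalized!r} != {after.normalized!r}"
                              if verdict != Verdict.SAME else ""),
    )


def classify_pair(
    before: StructureRecord,
    after: StructureRecord,
    channel: str = "inchi",
    mode: str = "extended",
) -> ComparisonVerdict | UntranslatablePair:
    """Generate identifiers on both sides and dispatch to the comparator."""
    if channel == "inchi":
        lb, la = gen_inchi(before), gen_inchi(after)
        if isinstance(lb, Untranslatable) or isinstance(la, Untranslatable):
            return UntranslatablePair(
                channel="inchi",
                reason_before=lb.reason if isinstance(lb, Untranslatable) else None,
                reason_after=la.reason if isinstance(la, Untranslatable) else None,
            )
        return compare_inchi(lb, la, mode=mode)
    if channel == "smiles":
        pb, pa = gen_canonical_smiles(before), gen_canonical_smiles(after)
        if isinstance(pb, Untranslatable) or isinstance(pa, Untranslatable):
            return UntranslatablePair(
                channel="smiles",
                reason_before=pb.reason if isinstance(pb, Untranslatable) else None,
                reason_after=pa.reason if isinstance(pa, Untranslatable) else None,
            )
        return compare_smiles(pb, pa)
    raise ValueError(f"unknown channel {channel!r}")


# --- census ------------------------------------------------------------------


@dataclass
class CensusRow:
    stage: str
    total: int
    chiral_tag_count_inchi: int  # entries with a t sublayer
    chiral_tag_count_smiles: int  # entries with >=1 tetrahedral descriptor
    cis_trans_count_inchi: int  # entries with a b sublayer
    cis_trans_count_smiles: int  # entries with "/" or "\"
    undefined_chiral_entries: int  # entries with >=1 "?" in t
    untranslatable_inchi: int = 0
    untranslatable_smiles: int = 0


def census(records: list[StructureRecord], stage: str) -> CensusRow:
    """Count stereo-annotation presence across a record set at one stage."""
    if stage not in STAGE_LABELS:
        raise ValueError(f"unknown stage {stage!r}")
    row = CensusRow(stage, len(records), 0, 0, 0, 0, 0)
    for record in records:
        layers = gen_inchi(record)
        if isinstance(layers, Untranslatable):
            row.untranslatable_inchi += 1
        else:
            row.chiral_tag_count_inchi += int(layers.t is not None)
            row.cis_trans_count_inchi += int(layers.b is not None)
            row.undefined_chiral_entries += int(count_undefined_chiral(layers) > 0)
        profile = gen_canonical_smiles(record)
        if isinstance(profile, Untranslatable):
            row.untranslatable_smiles += 1
        else:
            row.chiral_tag_count_smiles += int(profile.tetrahedral_tags > 0)
            row.cis_trans_count_smiles += int(profile.ez_tags > 0)
    return row


# --- frequency table ---------------------------------------------------------


@dataclass
class PairClassification:
    record_id: str
    pair: str  # one of PAIR_LABELS
    outcome: ComparisonVerdict | UntranslatablePair


def tabulate(classifications: list[PairClassification]) -> pd.DataFrame:
    """Frequency table: verdict rows x checkpoint-pair columns.

    Untranslatable pairs occupy their own row so that every column sums to
    the number of record pairs handed in for that checkpoint pair.
    """
    rows = [v.value for v in Verdict] + [UNTRANSLATABLE_ROW]
    table = pd.DataFrame(0, index=rows, columns=list(PAIR_LABELS), dtype=int)
    for item in classifications:
        if item.pair not in PAIR_LABELS:
            raise ValueError(f"unknown checkpoint pair {item.pair!r}")
        if isinstance(item.outcome, UntranslatablePair):
            table.loc[UNTRANSLATABLE_ROW, item.pair] += 1
        else:
            table.loc[item.outcome.verdict.value, item.pair] += 1
    return table
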