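"""Run orchestration and aggregation into machine-readable reports.

``run_dataset`` drives a whole record set through screening, the
three-checkpoint conversion and geometry QC; ``build_report`` condenses the
artifacts into a :class:`RunReport` whose JSON form is canonical (sorted
keys, no timestamps) so that two runs with identical input, policy and seed
produce byte-identical files. Timestamps and per-record narration go to the
run log instead. CSV tables are derived views carrying the conventional
row/column labels for side-by-side reading.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .chem_io import StructureRecord, write_sdf
from .conversion import CheckpointResult, ConversionPolicy, run_checkpoints
from .geometry_qc import GeometryFlag, run_geometry_qc
from .identifiers import BACKEND_ID
from .screening import ScreenReport, screen_record
from .stereo_compare import (
    PAIR_LABELS,
    STAGE_LABELS,
    CensusRow,
    ComparisonVerdict,
    PairClassification,
    UntranslatablePair,
    census,
    tabulate,
)

__all__ = ["RunArtifacts", "RunReport", "run_dataset", "build_report", "write_report"]


@dataclass
class RunArtifacts:
    policy: ConversionPolicy
    seed: int
    mode: str
    channels: tuple[str, ...]
    input_count: int = 0
    screen_reports: list[ScreenReport] = field(default_factory=list)
    rejected: list[StructureRecord] = field(default_factory=list)
    results: list[CheckpointResult] = field(default_factory=list)
    geometry_flags: dict[str, list[GeometryFlag]] = field(default_factory=dict)
    log_lines: list[str] = field(default_factory=list)


def run_dataset(
    records: list[StructureRecord],
    policy: ConversionPolicy | None = None,
    seed: int = 0,
    mode: str = "extended",
    channels: tuple[str, ...] = ("inchi", "smiles"),
) -> RunArtifacts:
    """Screen, convert and flag every record; rejected records are kept in
    the bookkeeping but excluded from conversion."""
    policy = policy or ConversionPolicy()
    artifacts = RunArtifacts(
        policy=policy, seed=seed, mode=mode, channels=channels, input_count=len(records)
    )
    for i, record in enumerate(records):
        screen = screen_record(record)
        artifacts.screen_reports.append(screen)
        if screen.rejected:
            artifacts.rejected.append(record)
            artifacts.log_lines.append(
                f"{record.source_id}\trejected\t{','.join(screen.reasons)}"
            )
            continue
        result = run_checkpoints(
            record, policy, seed=seed + i, channels=channels, mode=mode
        )
        artifacts.results.append(result)
        if result.checkpoints.failure_stage:
            artifacts.log_lines.append(
                f"{record.source_id}\tfailed\t{result.checkpoints.failure_stage}"
            )
            continue
        flags = run_geometry_qc(result.checkpoints.mm)
        if flags:
            artifacts.geometry_flags[record.source_id] = flags
        for (pair, channel), outcome in sorted(result.verdicts.items()):
            label = (
                "untranslatable"
                if isinstance(outcome, UntranslatablePair)
                else outcome.verdict.value
            )
            artifacts.log_lines.append(
                f"{record.source_id}\t{pair}\t{channel}\t{label}"
            )
    return artifacts


@dataclass
class RunReport:
    header: dict
    screening_summary: dict
    frequency_tables: dict[str, dict]  # channel -> {verdict row -> {pair -> count}}
    layer_correspondence: dict[str, dict[str, int]]  # pair -> layer -> match count
    census: list[dict]
    geometry_flags: dict[str, list[dict]]
    untranslatable: dict[str, int]
    accounting: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"


def _classifications(
    artifacts: RunArtifacts, channel: str
) -> list[PairClassification]:
    out = []
    for result in artifacts.results:
        if result.checkpoints.failure_stage:
            continue
        for (pair, chan), outcome in result.verdicts.items():
            if chan == channel:
                out.append(
                    PairClassification(result.checkpoints.cpd.source_id, pair, outcome)
                )
    return out


def build_report(artifacts: RunArtifacts) -> RunReport:
    """Condense run artifacts into the aggregate report.

    The accounting partition (rejected + classified + untranslatable +
    failed == input count) is computed on the InChI channel over the cpd–mm
    checkpoint pair; the frequency tables keep untranslatable pairs in their
    own row so columns still sum to the number of converted records.
    """
    reasons: dict[str, int] = {}
    for screen in artifacts.screen_reports:
        for reason in screen.reasons:
            reasons[reason] = reasons.get(reason, 0) + 1
    multi_component = sum(
        1 for s in artifacts.screen_reports if s.component_count > 1
    )

    frequency_tables: dict[str, dict] = {}
    for channel in artifacts.channels:
        table = tabulate(_classifications(artifacts, channel))
        frequency_tables[channel] = {
            row: {col: int(table.loc[row, col]) for col in table.columns}
            for row in table.index
        }

    layer_names = ["formula", "c", "h", "b", "t"]
    layer_correspondence = {
        pair: {name: 0 for name in layer_names} for pair in PAIR_LABELS
    }
    for item in _classifications(artifacts, "inchi"):
        if isinstance(item.outcome, ComparisonVerdict):
            for name in layer_names:
                layer_correspondence[item.pair][name] += int(
                    item.outcome.layer_match.get(name, False)
                )

    converted = [r for r in artifacts.results if not r.checkpoints.failure_stage]
    census_rows: list[CensusRow] = [
        census([r.checkpoints.cpd for r in converted], "initial_2d"),
        census([r.checkpoints.wash for r in converted], "after_wash"),
        census([r.checkpoints.mm for r in converted], "after_minimization"),
    ]

    failed = sum(1 for r in artifacts.results if r.checkpoints.failure_stage)
    untranslatable_ids = set()
    classified_ids = set()
    for result in converted:
        outcomes = [
            o for (pair, chan), o in result.verdicts.items() if chan == "inchi"
        ]
        if any(isinstance(o, UntranslatablePair) for o in outcomes):
            untranslatable_ids.add(result.checkpoints.cpd.source_id)
        else:
            classified_ids.add(result.checkpoints.cpd.source_id)

    accounting = {
        "input": artifacts.input_count,
        "rejected": len(artifacts.rejected),
        "classified": len(classified_ids),
        "untranslatable": len(untranslatable_ids),
        "failed": failed,
    }

    untranslatable_pairs = {
        channel: sum(
            1
            for item in _classifications(artifacts, channel)
            if isinstance(item.outcome, UntranslatablePair)
        )
        for channel in artifacts.channels
    }

    return RunReport(
        header={
            "backend_id": BACKEND_ID,
            "policy": asdict(artifacts.policy),
            "seed": artifacts.seed,
            "mode": artifacts.mode,
            "channels": list(artifacts.channels),
        },
        screening_summary={
            "total": artifacts.input_count,
            "rejected": len(artifacts.rejected),
            "rejection_reasons": reasons,
            "multi_component_entries": multi_component,
        },
        frequency_tables=frequency_tables,
        layer_correspondence=layer_correspondence,
        census=[asdict(row) for row in census_rows],
        geometry_flags={
            rid: [asdict(f) for f in flags]
            for rid, flags in artifacts.geometry_flags.items()
        },
        untranslatable=untranslatable_pairs,
        accounting=accounting,
    )


_LAYER_ROW_LABELS = {
    "formula": "Formula",
    "c": "c (Connection)",
    "h": "h (Hydration)",
    "b": "b (Cis/trans stereochemistry)",
    "t": "t (Chirality)",
}


def write_report(artifacts: RunArtifacts, out_dir: str | Path) -> RunReport:
    """Emit report.json (canonical), the CSV table views, run.log and the
    checkpoint SDF snapshots."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = build_report(artifacts)
    (out / "report.json").write_text(report.to_json())

    freq_frames = []
    for channel, table in report.frequency_tables.items():
        frame = pd.DataFrame(table).T
        frame.index.name = "verdict"
        frame.insert(0, "channel", channel)
        freq_frames.append(frame.reset_index())
    pd.concat(freq_frames).to_csv(out / "frequency.csv", index=False)

    census_frame = pd.DataFrame(report.census)
    census_frame["stage"] = census_frame["stage"].map(STAGE_LABELS)
    census_frame.to_csv(out / "census.csv", index=False)

    layers_frame = pd.DataFrame(report.layer_correspondence)
    layers_frame.index = [_LAYER_ROW_LABELS[i] for i in layers_frame.index]
    layers_frame.index.name = "layer"
    layers_frame.to_csv(out / "layers.csv")

    flag_rows = [
        {
            "record_id": rid,
            "kind": f["kind"],
            "atom_indices": ";".join(map(str, f["atom_indices"])),
            "measured": f["measured"],
            "threshold": f["threshold"],
        }
        for rid, flags in report.geometry_flags.items()
        for f in flags
    ]
    pd.DataFrame(
        flag_rows, columns=["record_id", "kind", "atom_indices", "measured", "threshold"]
    ).to_csv(out / "geometry_flags.csv", index=False)

    (out / "run.log").write_text("\n".join(artifacts.log_lines) + "\n")

    converted = [r for r in artifacts.results if not r.checkpoints.failure_stage]
    for stage in ("cpd", "wash", "mm"):
        write_sdf(
            [getattr(r.checkpoints, stage) for r in converted],
            out / f"checkpoint_{stage}.sdf",
        )
    return report
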