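"""Plain-text readers and writers for the pipeline's standard formats.

Formats: DE tables as TSV (gene, log2fc, pvalue, padj); gene sets as GMT;
annotation tables as TSV (gene, go_id, go_name, ontology); traces as
long-format CSV (well, time_s, signal); injection schedules and truth
records as YAML.
"""

from __future__ import annotations

from collections.abc import Iterable
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assays import InjectionSchedule, PlateTrace
from .enrichment import GeneSet, GeneSetCollection

DE_COLUMNS = ("gene", "log2fc", "pvalue", "padj")
TRACE_COLUMNS = ("well", "time_s", "signal")

__all__ = [
    "read_de_table",
    "write_de_table",
    "read_gmt",
    "write_gmt",
    "read_annotation_table",
    "read_traces_csv",
    "write_traces_csv",
    "read_schedule_yaml",
    "write_schedule_yaml",
    "read_yaml",
    "write_yaml",
]


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene", "log2fc") if c not in df.columns]
    if missing:
        raise ValueError(f"DE table {path} missing columns: {missing}")
    return df


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in DE_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols, float_format="%.10g")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read tab-separated gene sets: name, description, members..."""
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
            name, _desc, *members = fields
            collection.add(GeneSet(name=name, members=frozenset(m for m in members if m)))
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for gs in collection:
            desc = descriptions.get(gs.name, "na")
            fh.write("\t".join([gs.name, desc, *sorted(gs.members)]) + "\n")


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    from .annotations import validate_annotation_table

    return validate_annotation_table(pd.read_csv(path, sep="\t", dtype=str))


def read_traces_csv(path: str | Path, kind: str = "OCR_coupling") -> list[PlateTrace]:
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV {path} missing columns: {missing}")
    traces = []
    for well, sub in df.groupby("well", sort=True):
        sub = sub.sort_values("time_s", kind="mergesort")
        traces.append(
            PlateTrace(
                well=str(well),
                times=tuple(float(t) for t in sub["time_s"]),
                signal=tuple(float(s) for s in sub["signal"]),
                kind=kind,
            )
        )
    return traces


def write_traces_csv(traces: Iterable[PlateTrace], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"well": t.well, "time_s": t.times, "signal": t.signal}) for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def read_schedule_yaml(path: str | Path) -> InjectionSchedule:
    payload = read_yaml(path)
    events = tuple((str(e["label"]), float(e["time_s"])) for e in payload["events"])
    return InjectionSchedule(events=events, kind=payload.get("kind", "OCR_coupling"))


def write_schedule_yaml(schedule: InjectionSchedule, path: str | Path) -> None:
    payload = {
        "kind": schedule.kind,
        "events": [{"label": lab, "time_s": float(t)} for lab, t in schedule.events],
    }
    write_yaml(payload, path)


def _plain(obj):
    """Convert numpy scalars/containers so YAML stays human-readable."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_yaml(payload, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(payload), fh, sort_keys=False)


def read_yaml(path: str | Path):
    with open(path) as fh:
        return yaml.safe_load(fh)
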