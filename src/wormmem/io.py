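"""Reading and writing the pipeline's tidy tables.

Canonical interchange is long-format CSV (header row, UTF-8, '.' decimal):
one row per (neuron, animal, paradigm, treatment, time) sample for traces,
one row per (animal, frame) position for tracks.  Results objects round-trip
through :func:`save_results` / ``pandas.read_csv`` at full precision.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import Paradigm, StimulusSchedule, TraceRecord, Treatment

logger = logging.getLogger(__name__)

TRACE_COLUMNS = (
    "neuron_id",
    "animal_id",
    "paradigm",
    "treatment",
    "trial",
    "time",
    "intensity",
    "frame_rate",
)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


def load_trace_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> list[TraceRecord]:
    """Read a tidy trace table into :class:`TraceRecord` objects.

    ``schema`` optionally maps canonical column names to the file's column
    names.  Rows are grouped by (neuron, animal, paradigm, treatment) and
    sorted by time within a group; a non-monotone time vector inside a group
    is a validation error naming the record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("trace table %s is empty", path)
        return []
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    required = ("neuron_id", "animal_id", "paradigm", "treatment", "time", "intensity")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"trace table missing required column {col!r}")
    if df.empty:
        logger.warning("trace table %s has a header but no rows", path)
        return []
    if "frame_rate" not in df.columns:
        raise SchemaError("trace table missing required column 'frame_rate'")

    records: list[TraceRecord] = []
    keys = ["neuron_id", "animal_id", "paradigm", "treatment"]
    for (neuron, animal, paradigm, treatment), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("time")
        records.append(
            TraceRecord(
                neuron_id=str(neuron),
                animal_id=str(animal),
                paradigm=Paradigm(paradigm),
                treatment=Treatment(treatment),
                time=grp["time"].to_numpy(float),
                intensity=grp["intensity"].to_numpy(float),
                frame_rate=float(grp["frame_rate"].iloc[0]),
            )
        )
    return records


def traces_to_frame(records: Iterable[TraceRecord]) -> pd.DataFrame:
    """Flatten TraceRecords to the canonical long-format table."""
    parts = []
    for r in records:
        parts.append(
            pd.DataFrame(
                {
                    "neuron_id": r.neuron_id,
                    "animal_id": r.animal_id,
                    "paradigm": r.paradigm.value,
                    "treatment": r.treatment.value,
                    "time": r.time,
                    "intensity": r.intensity,
                    "frame_rate": r.frame_rate,
                }
            )
        )
    if not parts:
        return pd.DataFrame(
            columns=[c for c in TRACE_COLUMNS if c != "trial"]
        )
    return pd.concat(parts, ignore_index=True)


def save_trace_table(records: Iterable[TraceRecord], path: str | Path) -> Path:
    path = Path(path)
    traces_to_frame(records).to_csv(path, index=False)
    return path


def save_results(results, path: str | Path) -> Path:
    """Write a stage output to disk, re-loadably and at full precision.

    DataFrames go to CSV (NaN preserved as empty fields, restored as NaN on
    reload); mappings and dataclass-like objects go to JSON; numpy arrays to
    a single-column CSV.
    """
    import dataclasses
    import json

    path = Path(path)
    if isinstance(results, pd.DataFrame):
        results.to_csv(path, index=False)
    elif isinstance(results, np.ndarray):
        pd.DataFrame({"value": np.ravel(results)}).to_csv(path, index=False)
    else:
        if dataclasses.is_dataclass(results) and not isinstance(results, type):
            payload = dataclasses.asdict(results)
        else:
            payload = results

        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if hasattr(o, "value"):
                return o.value
            raise TypeError(f"cannot serialize {type(o)}")

        path.write_text(json.dumps(payload, indent=1, default=_default))
    return path


def save_schedule(schedule: StimulusSchedule, path: str | Path) -> Path:
    df = pd.DataFrame(
        [(a, b, s) for a, b, s in schedule.epochs],
        columns=["start_s", "end_s", "stimulus"],
    )
    df.to_csv(path, index=False)
    return path


def load_schedule(path: str | Path) -> StimulusSchedule:
    df = pd.read_csv(path)
    return StimulusSchedule(
        tuple(
            (float(r.start_s), float(r.end_s), str(r.stimulus))
            for r in df.itertuples()
        )
    )


TRACK_COLUMNS = ("animal_id", "group", "frame", "x", "y", "frame_rate")


def save_track_table(tracks: Sequence, path: str | Path) -> Path:
    """Write locomotion tracks (see :mod:`wormmem.locomotion`) to tidy CSV."""
    parts = []
    for tr in tracks:
        n = tr.positions.shape[0]
        parts.append(
            pd.DataFrame(
                {
                    "animal_id": tr.animal_id,
                    "group": tr.group,
                    "frame": np.arange(n),
                    "x": tr.positions[:, 0],
                    "y": tr.positions[:, 1],
                    "frame_rate": tr.frame_rate,
                }
            )
        )
    df = (
        pd.concat(parts, ignore_index=True)
        if parts
        else pd.DataFrame(columns=TRACK_COLUMNS)
    )
    df.to_csv(Path(path), index=False)
    return Path(path)


def load_track_table(path: str | Path, arena=None) -> list:
    from .locomotion import Track

    df = pd.read_csv(path)
    for col in ("animal_id", "x", "y", "frame_rate"):
        if col not in df.columns:
            raise SchemaError(f"track table missing required column {col!r}")
    tracks = []
    for (animal, group), grp in df.groupby(
        ["animal_id", "group"] if "group" in df.columns else ["animal_id"], sort=True
    ):
        grp = grp.sort_values("frame") if "frame" in grp.columns else grp
        tracks.append(
            Track(
                animal_id=str(animal),
                positions=np.column_stack(
                    [grp["x"].to_numpy(float), grp["y"].to_numpy(float)]
                ),
                frame_rate=float(grp["frame_rate"].iloc[0]),
                arena=arena,
                group=str(group),
            )
        )
    return tracks
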