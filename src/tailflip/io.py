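"""Plain-text I/O: traces (CSV + JSON sidecar), event logs, series and summaries.

All tables are CSV with stable column order and formatting so reruns are
byte-identical.  Times follow the package convention: event times in seconds
within a phase, series minutes relative to injection.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .types import ActivitySeries, FlipTrain, NormalizedSeries, Trace

__all__ = [
    "write_trace",
    "read_trace",
    "write_events",
    "read_events",
    "write_counts",
    "write_normalized",
    "read_normalized",
]

_FLOAT_FMT = "%.10g"


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write samples to ``<path>`` (one column CSV) and metadata to ``<path>.json``."""
    path = Path(path)
    pd.DataFrame({"sample": trace.samples}).to_csv(path, index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "sample_rate": trace.sample_rate,
        "t0": trace.t0,
        "phase": trace.phase,
        "fish_id": trace.fish_id,
        "units": "arbitrary impedance units",
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    samples = pd.read_csv(path)["sample"].to_numpy()
    meta = json.loads(Path(str(path) + ".json").read_text())
    return Trace(
        samples,
        sample_rate=meta["sample_rate"],
        t0=meta.get("t0", 0.0),
        phase=meta.get("phase", "pre"),
        fish_id=meta.get("fish_id", "fish"),
    )


def write_events(trains: Iterable[FlipTrain], path: str | Path) -> None:
    rows = []
    for train in trains:
        for t in train.event_times:
            rows.append({"fish_id": train.fish_id, "phase": train.phase, "time_s": t})
    pd.DataFrame(rows, columns=["fish_id", "phase", "time_s"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_events(path: str | Path, duration_min: float) -> list[FlipTrain]:
    df = pd.read_csv(path)
    trains = []
    for (fish_id, phase), sub in df.groupby(["fish_id", "phase"], sort=True):
        trains.append(
            FlipTrain(
                np.sort(sub["time_s"].to_numpy()),
                duration_min,
                fish_id=str(fish_id),
                phase=phase,
                source="detected",
            )
        )
    return trains


def write_counts(series: Iterable[ActivitySeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for m, v in zip(s.minute_index, s.values):
            rows.append(
                {"fish_id": s.fish_id, "phase": s.phase, "minute_index": m, "count": v}
            )
    pd.DataFrame(rows, columns=["fish_id", "phase", "minute_index", "count"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def write_normalized(series: Iterable[NormalizedSeries], path: str | Path) -> None:
    rows = []
    for ns in series:
        for t, v in zip(ns.time_min, ns.values):
            rows.append(
                {
                    "fish_id": ns.fish_id,
                    "group": ns.group,
                    "bin_start_min": t,
                    "bin_width_min": ns.bin_width_min,
                    "value_pct": v,
                }
            )
    pd.DataFrame(
        rows, columns=["fish_id", "group", "bin_start_min", "bin_width_min", "value_pct"]
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_normalized(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
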