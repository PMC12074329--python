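"""Plain-text persistence for traces, cohorts and window sets.

Traces are CSV files with columns ``index, fhr, toco`` (missing samples
hold the ``-1`` sentinel); a cohort is a directory of trace files plus one
``cohort.csv`` metadata table.  Preprocessed windows are stored as a
compressed ``.npz`` array container alongside a ``manifest.csv`` mapping
each window to its source trace.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CTGTrace, CTGWindow, windows_to_arrays

__all__ = [
    "write_trace",
    "read_trace",
    "write_cohort",
    "read_cohort",
    "write_windows",
    "read_windows",
]

COHORT_TABLE = "cohort.csv"


def write_trace(trace: CTGTrace, path) -> None:
    pd.DataFrame(
        {"index": np.arange(len(trace)), "fhr": trace.fhr, "toco": trace.toco}
    ).to_csv(path, index=False, float_format="%.17g")  # round-trip exact


def read_trace(path, trace_id=None, label: int = 0, days_to_delivery: int = 0,
               covariates: dict | None = None) -> CTGTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    return CTGTrace(
        trace_id=trace_id or Path(path).stem,
        fhr=df["fhr"].to_numpy(dtype=float),
        toco=df["toco"].to_numpy(dtype=float),
        label=label,
        days_to_delivery=days_to_delivery,
        covariates=covariates or {},
    )


def write_cohort(traces: list[CTGTrace], metadata: pd.DataFrame, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for trace in traces:
        write_trace(trace, out_dir / f"{trace.trace_id}.csv")
    metadata.to_csv(out_dir / COHORT_TABLE, index=False)


def read_cohort(in_dir) -> tuple[list[CTGTrace], pd.DataFrame]:
    in_dir = Path(in_dir)
    metadata = pd.read_csv(in_dir / COHORT_TABLE)
    covariate_cols = [
        c for c in metadata.columns
        if c not in ("trace_id", "label", "days_to_delivery")
    ]
    traces = []
    for row in metadata.itertuples(index=False):
        traces.append(
            read_trace(
                in_dir / f"{row.trace_id}.csv",
                trace_id=str(row.trace_id),
                label=int(row.label),
                days_to_delivery=int(row.days_to_delivery),
                covariates={c: float(getattr(row, c)) for c in covariate_cols},
            )
        )
    return traces, metadata


def write_windows(windows: list[CTGWindow], out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    X, y, days = windows_to_arrays(windows)
    np.savez_compressed(out_dir / "windows.npz", X=X, y=y, days=days)
    pd.DataFrame(
        {
            "window_id": np.arange(len(windows)),
            "trace_id": [w.trace_id for w in windows],
            "window_index": [w.window_index for w in windows],
            "label": y,
            "days_to_delivery": days,
        }
    ).to_csv(out_dir / "manifest.csv", index=False)


def read_windows(in_dir):
    in_dir = Path(in_dir)
    arrays = np.load(in_dir / "windows.npz")
    manifest = pd.read_csv(in_dir / "manifest.csv")
    return arrays["X"], arrays["y"], arrays["days"], manifest
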