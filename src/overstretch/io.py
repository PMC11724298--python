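"""Trace, event and manifest I/O plus half-cycle segmentation.

Traces live on disk as tab-separated text (columns ``time_s``,
``trap_position_nm``, ``force_pN``, ``cycle_id``, ``direction`` and
optionally ``truth_state``) with a JSON sidecar ``<trace>.json`` holding the
acquisition metadata.  Event tables are plain CSV.  Numeric columns round-trip
losslessly at 9 significant digits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import Trace, EVENT_COLUMNS

__all__ = [
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "segment_cycles",
    "HalfCycle",
    "DatasetManifest",
]

#: Sidecar fields required to interpret a trace.
REQUIRED_META = [
    "construct",
    "K_trap_pN_per_nm",
    "velocity_nm_per_s",
    "F_min_pN",
    "F_max_pN",
    "sample_rate_Hz",
    "cycle_count",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_trace(trace: Trace, path: str | Path) -> Path:
    """Write a trace as TSV plus its JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trace.to_frame().to_csv(path, sep="\t", index=False, float_format="%.9g")
    with open(_sidecar_path(path), "w") as fh:
        json.dump(trace.meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def read_trace(path: str | Path) -> Trace:
    """Read a TSV trace; validates the sidecar and time monotonicity."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    missing = [k for k in REQUIRED_META if k not in meta]
    if missing:
        raise ValueError(f"sidecar {sidecar} missing field(s): {', '.join(missing)}")
    df = pd.read_csv(path, sep="\t")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("non-monotone time")
    return Trace(
        time=t,
        trap_position=df["trap_position_nm"].to_numpy(dtype=float),
        force=df["force_pN"].to_numpy(dtype=float),
        cycle_id=df["cycle_id"].to_numpy(dtype=np.int64),
        direction=df["direction"].to_numpy(dtype=np.int8),
        truth_state=(
            df["truth_state"].to_numpy(dtype=np.int8)
            if "truth_state" in df.columns
            else None
        ),
        meta=meta,
    )


def write_events(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events.to_csv(path, index=False, float_format="%.9g")
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing column(s): {', '.join(missing)}")
    return df


@dataclass
class HalfCycle:
    """One monotone stretch or release ramp cut from a trace.

    ``sl`` is the slice of the parent trace; array views are provided for
    convenience.  ``direction`` is +1 for stretch, -1 for release.
    """

    time: np.ndarray
    trap_position: np.ndarray
    force: np.ndarray
    cycle_id: int
    direction: int
    sl: slice
    meta: dict
    truth_state: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.time)


def segment_cycles(trace: Trace) -> list[HalfCycle]:
    """Cut a trace into alternating stretch/release half-cycles.

    Turning points are located on the trap-position command signal (which is
    noise-free), never on the force, whose transition jumps would confound
    them.  A turning-point sample closes the preceding half-cycle (half-open
    intervals), so concatenating the segments reproduces the trace
    sample-for-sample.  Cycle-id boundaries also terminate segments.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    lam = trace.trap_position
    d = np.diff(lam)
    sgn = np.sign(d)
    # a jump between cycles is not a ramp turning point
    cyc_edge = np.nonzero(np.diff(trace.cycle_id) != 0)[0]
    sgn[cyc_edge] = 0
    # carry forward the sign over flat spots and cycle edges
    for i in range(1, len(sgn)):
        if sgn[i] == 0:
            sgn[i] = sgn[i - 1]
    if np.all(sgn == 0):
        raise ValueError("no ramp: trap position is constant")
    turn = np.nonzero(sgn[1:] != sgn[:-1])[0] + 1  # first index of new ramp
    cyc_break = np.nonzero(np.diff(trace.cycle_id) != 0)[0] + 1
    starts = np.unique(np.concatenate([[0], turn + 1, cyc_break]))
    # a cycle break immediately followed by a turn is one boundary, not two
    merged = [int(starts[0])]
    for s in starts[1:]:
        if s - merged[-1] >= 2:
            merged.append(int(s))
    starts = np.asarray(merged)
    bounds = list(starts) + [len(trace)]
    out: list[HalfCycle] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 1:
            continue
        sl = slice(a, b)
        direction = int(np.sign(lam[min(a + 1, b - 1)] - lam[a])) or 1
        out.append(
            HalfCycle(
                time=trace.time[sl],
                trap_position=lam[sl],
                force=trace.force[sl],
                cycle_id=int(trace.cycle_id[a]),
                direction=direction,
                sl=sl,
                meta=trace.meta,
                truth_state=None
                if trace.truth_state is None
                else trace.truth_state[sl],
            )
        )
    return out


@dataclass
class DatasetManifest:
    """Listing of trace files and their construct grouping."""

    traces: list[dict]
    protocol: dict

    def to_json(self) -> str:
        return json.dumps({"traces": self.traces, "protocol": self.protocol}, indent=1)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json() + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        d = json.loads(Path(path).read_text())
        return cls(traces=d["traces"], protocol=d["protocol"])
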