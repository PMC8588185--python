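"""Echogram container, event schedules and result tables.

The on-disk echogram container ("EGRAM") is a plain-text format: ``#``-prefixed
``key: value`` header lines carrying transducer metadata, followed by one
whitespace-separated row of dB values per ping.  Values are printed with two
decimals, so write/read round-trips are bit-exact at that precision.

The canonical vertical coordinate throughout the package is *range from the
transducer face*; depth below the surface is a reporting conversion only
(:func:`range_to_depth`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING_DB",
    "SOURCE_TYPES",
    "Echogram",
    "EventSchedule",
    "EchogramFormatError",
    "ScheduleError",
    "read_echogram",
    "write_echogram",
    "range_to_depth",
    "depth_to_range",
    "read_schedule",
    "write_table",
]

#: Sentinel for missing / below-floor samples; all metrics ignore it.
MISSING_DB = -999.0

#: Stimulus source types accepted in event schedules.
SOURCE_TYPES = frozenset(
    {
        "tone",
        "two-tone",
        "chirp",
        "white",
        "mls",
        "tsp",
        "sweep",
        "windmill",
        "ship",
        "lupara",
        "background",
    }
)

_HEADER_KEYS = (
    "ping_epoch_s0",
    "ping_interval_s",
    "range_start_m",
    "range_step_m",
    "transducer_depth_m",
    "orientation",
    "beam_width_3db_deg",
    "frequency_khz",
    "dynamic_range_max_db",
)


class EchogramFormatError(ValueError):
    """Raised for malformed EGRAM files."""


class ScheduleError(ValueError):
    """Raised for invalid event schedules."""


@dataclass
class Echogram:
    """Ping x range matrix of backscatter in dB with transducer metadata.

    Attributes
    ----------
    ping_times : ndarray, shape (n_pings,)
        Seconds since epoch, strictly increasing (uniform for file round-trip).
    range_bins : ndarray, shape (n_bins,)
        Bin-center ranges in metres from the transducer face, uniformly
        spaced and increasing away from the transducer.
    values : ndarray, shape (n_pings, n_bins)
        Backscatter in dB; ``MISSING_DB`` marks invalid samples.
    """

    ping_times: np.ndarray
    range_bins: np.ndarray
    values: np.ndarray
    transducer_depth: float
    orientation: str = "up"
    beam_width_3db: float = 25.0
    frequency: float = 200.0
    dynamic_range_max: float | None = None

    def __post_init__(self) -> None:
        self.ping_times = np.asarray(self.ping_times, dtype=float)
        self.range_bins = np.asarray(self.range_bins, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.ping_times.size, self.range_bins.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({self.ping_times.size}, {self.range_bins.size})"
            )
        if self.ping_times.size > 1 and not np.all(np.diff(self.ping_times) > 0):
            raise ValueError("ping_times must be strictly increasing")
        if np.any(self.range_bins < 0):
            raise ValueError("range_bins must be nonnegative")
        if self.range_bins.size > 1:
            steps = np.diff(self.range_bins)
            if not np.all(steps > 0):
                raise ValueError("range_bins must be increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("range_bins must be uniformly spaced")
        if self.orientation not in ("up", "down"):
            raise ValueError(f"orientation must be 'up' or 'down', got {self.orientation!r}")

    @property
    def n_pings(self) -> int:
        return self.ping_times.size

    @property
    def n_bins(self) -> int:
        return self.range_bins.size

    @property
    def range_step(self) -> float:
        if self.range_bins.size < 2:
            raise ValueError("range_step undefined for a single bin")
        return float(self.range_bins[1] - self.range_bins[0])

    @property
    def ping_interval(self) -> float:
        if self.ping_times.size < 2:
            raise ValueError("ping_interval undefined for a single ping")
        return float(self.ping_times[1] - self.ping_times[0])

    def copy(self) -> "Echogram":
        return replace(
            self,
            ping_times=self.ping_times.copy(),
            range_bins=self.range_bins.copy(),
            values=self.values.copy(),
        )


@dataclass
class EventSchedule:
    """Table of stimulus emissions with half-open windows [start, start+duration)."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = (
        "event_id",
        "start_time",
        "duration_s",
        "source_type",
        "nominal_frequency_hz",
        "spl_db",
    )

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.rows, columns=list(self.COLUMNS))
        df["start_time"] = df["start_time"].astype(float)
        df["duration_s"] = df["duration_s"].astype(float)
        df["spl_db"] = df["spl_db"].astype(float)
        df["nominal_frequency_hz"] = pd.to_numeric(df["nominal_frequency_hz"], errors="coerce")
        df["event_id"] = df["event_id"].astype(str)
        self.rows = df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.rows
        if df["event_id"].duplicated().any():
            dups = df.loc[df["event_id"].duplicated(), "event_id"].tolist()
            raise ScheduleError(f"duplicate event_id(s): {dups}")
        bad = set(df["source_type"]) - SOURCE_TYPES
        if bad:
            raise ScheduleError(f"unknown source_type(s): {sorted(bad)}")
        if not np.all(np.isfinite(df["spl_db"].to_numpy())):
            raise ScheduleError("spl_db must be finite")
        if np.any(df["duration_s"].to_numpy() <= 0):
            raise ScheduleError("duration_s must be positive")
        # Overlap check on half-open windows.
        order = np.argsort(df["start_time"].to_numpy(), kind="stable")
        starts = df["start_time"].to_numpy()[order]
        ends = starts + df["duration_s"].to_numpy()[order]
        ids = df["event_id"].to_numpy()[order]
        overlaps = [
            (ids[i], ids[i + 1])
            for i in range(len(ids) - 1)
            if starts[i + 1] < ends[i]
        ]
        if overlaps:
            raise ScheduleError(f"overlapping event windows: {overlaps}")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return (row for _, row in self.rows.iterrows())

    def windows(self) -> list[tuple[str, float, float]]:
        """Return (event_id, start, end) tuples, half-open."""
        return [
            (r.event_id, float(r.start_time), float(r.start_time + r.duration_s))
            for r in self.rows.itertuples()
        ]


# ---------------------------------------------------------------------------
# EGRAM container I/O


def write_echogram(e: Echogram, path: str | Path) -> Path:
    """Write an :class:`Echogram` to the EGRAM text container.

    Requires uniform ping spacing (the simulator guarantees it).  Values are
    printed with two decimals; the read side parses them back bit-exactly.
    """
    path = Path(path)
    if e.n_pings < 1 or e.n_bins < 1:
        raise ValueError("cannot write an empty echogram")
    if e.n_pings > 1:
        dts = np.diff(e.ping_times)
        if not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-9):
            raise ValueError("EGRAM container requires uniform ping intervals")
        interval = float(dts[0])
    else:
        interval = 0.0
    step = float(e.range_bins[1] - e.range_bins[0]) if e.n_bins > 1 else 0.0
    dmax = "nan" if e.dynamic_range_max is None else repr(float(e.dynamic_range_max))
    header = {
        "ping_epoch_s0": repr(float(e.ping_times[0])),
        "ping_interval_s": repr(interval),
        "range_start_m": repr(float(e.range_bins[0])),
        "range_step_m": repr(step),
        "transducer_depth_m": repr(float(e.transducer_depth)),
        "orientation": e.orientation,
        "beam_width_3db_deg": repr(float(e.beam_width_3db)),
        "frequency_khz": repr(float(e.frequency)),
        "dynamic_range_max_db": dmax,
    }
    with open(path, "w", encoding="utf-8") as fh:
        for key in _HEADER_KEYS:
            fh.write(f"# {key}: {header[key]}\n")
        np.savetxt(fh, e.values, fmt="%.2f", delimiter=" ")
    return path


def read_echogram(path: str | Path) -> Echogram:
    """Read an EGRAM container file.  See module docstring for the layout."""
    path = Path(path)
    meta: dict[str, str] = {}
    data_lines: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" not in body:
                    raise EchogramFormatError(
                        f"{path}:{lineno}: malformed header line {line!r}"
                    )
                key, _, val = body.partition(":")
                key = key.strip()
                if key not in _HEADER_KEYS:
                    raise EchogramFormatError(
                        f"{path}:{lineno}: unknown header key {key!r}"
                    )
                meta[key] = val.strip()
            else:
                data_lines.append(line)
    missing = [k for k in _HEADER_KEYS if k not in meta]
    if missing:
        raise EchogramFormatError(f"{path}: missing header key(s): {missing}")
    if not data_lines:
        raise EchogramFormatError(f"{path}: no data rows")
    try:
        values = np.array([[float(v) for v in ln.split()] for ln in data_lines])
    except ValueError as exc:
        raise EchogramFormatError(f"{path}: bad data value: {exc}") from exc
    if values.ndim != 2:
        raise EchogramFormatError(f"{path}: ragged data rows")
    n_pings, n_bins = values.shape
    t0 = float(meta["ping_epoch_s0"])
    dt = float(meta["ping_interval_s"])
    r0 = float(meta["range_start_m"])
    dr = float(meta["range_step_m"])
    if n_pings > 1 and dt <= 0:
        raise EchogramFormatError(f"{path}: nonpositive ping_interval_s with >1 ping")
    if n_bins > 1 and dr <= 0:
        raise EchogramFormatError(f"{path}: non-uniform or nonpositive range_step_m")
    dmax_s = meta["dynamic_range_max_db"]
    dmax = None if dmax_s.lower() in ("nan", "none", "") else float(dmax_s)
    return Echogram(
        ping_times=t0 + dt * np.arange(n_pings),
        range_bins=r0 + dr * np.arange(n_bins),
        values=values,
        transducer_depth=float(meta["transducer_depth_m"]),
        orientation=meta["orientation"],
        beam_width_3db=float(meta["beam_width_3db_deg"]),
        frequency=float(meta["frequency_khz"]),
        dynamic_range_max=dmax,
    )


# ---------------------------------------------------------------------------
# Coordinate conversion


def range_to_depth(e: Echogram, range_m):
    """Convert range-from-transducer to depth-below-surface (up-looking only).

    depth = transducer_depth - range, clamped at 0 m (surface).
    """
    if e.orientation != "up":
        raise ValueError("range_to_depth supports orientation='up' only")
    r = np.asarray(range_m, dtype=float)
    depth = np.clip(e.transducer_depth - r, 0.0, None)
    return float(depth) if np.isscalar(range_m) else depth


def depth_to_range(e: Echogram, depth_m):
    """Inverse of :func:`range_to_depth` on [0, transducer_depth]."""
    if e.orientation != "up":
        raise ValueError("depth_to_range supports orientation='up' only")
    d = np.asarray(depth_m, dtype=float)
    if np.any(d < 0) or np.any(d > e.transducer_depth):
        raise ValueError("depth outside [0, transducer_depth]")
    r = e.transducer_depth - d
    return float(r) if np.isscalar(depth_m) else r


# ---------------------------------------------------------------------------
# Schedules and result tables


def read_schedule(path: str | Path) -> EventSchedule:
    """Read a comma-separated event schedule with a header row."""
    df = pd.read_csv(path)
    missing = set(EventSchedule.COLUMNS) - set(df.columns)
    if missing:
        raise ScheduleError(f"{path}: missing column(s): {sorted(missing)}")
    return EventSchedule(df[list(EventSchedule.COLUMNS)])


def write_table(rows, path: str | Path) -> Path:
    """Write a table (DataFrame, EventSchedule, or records) as CSV with header."""
    path = Path(path)
    if isinstance(rows, EventSchedule):
        df = rows.rows
    elif isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return path
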