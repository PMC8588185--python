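"""Small deterministic fixtures used by the test-suite and the CLI.

Each fixture is a tiny in-memory object (echogram, mask, or schedule) with a
documented expected property; :func:`make_fixtures` also writes them to disk
as plain-text files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .io import Echogram, EventSchedule, MISSING_DB, write_echogram, write_table

__all__ = ["uniform_ping", "ramp_trace", "three_blobs", "toy_schedule", "make_fixtures"]


def _egram(values: np.ndarray, r0: float = 0.0, dr: float = 1.0) -> Echogram:
    n_pings, n_bins = values.shape
    return Echogram(
        ping_times=np.arange(n_pings, dtype=float),
        range_bins=r0 + dr * np.arange(n_bins),
        values=np.asarray(values, dtype=float),
        transducer_depth=24.0,
    )


def uniform_ping() -> Echogram:
    """One ping, uniform values over bins at 5..10 m: center of mass 7.5 m."""
    values = np.full((1, 6), -50.0)
    return _egram(values, r0=5.0, dr=1.0)


def ramp_trace() -> Echogram:
    """A 4-ping trace whose per-ping max range rises 10, 11, 12, 13 m:
    tilt slope +1.0 m/ping.  Background sits at the missing sentinel."""
    values = np.full((4, 20), MISSING_DB)
    for p, r in enumerate((10, 11, 12, 13)):
        values[p, r - 2 : r + 3] = -55.0
        values[p, r] = -40.0  # per-ping max at the nominal range
    return _egram(values, r0=0.0, dr=1.0)


def three_blobs() -> np.ndarray:
    """A 10x10 binary mask with exactly three 4-connected regions."""
    mask = np.zeros((10, 10), dtype=bool)
    mask[1:3, 1:4] = True
    mask[5:8, 5:7] = True
    mask[8:10, 0:2] = True
    return mask


def toy_schedule() -> EventSchedule:
    """Three non-overlapping events: a 50 Hz tone, a long windmill emission,
    and a background reference window."""
    return EventSchedule(
        pd.DataFrame(
            {
                "event_id": ["e1", "e2", "e3"],
                "start_time": [0.0, 100.0, 1100.0],
                "duration_s": [15.0, 900.0, 60.0],
                "source_type": ["tone", "windmill", "background"],
                "nominal_frequency_hz": [50.0, np.nan, np.nan],
                "spl_db": [165.0, 182.0, 93.0],
            }
        )
    )


def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write all fixtures under ``out_dir`` and return name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "uniform_ping": write_echogram(uniform_ping(), out / "uniform_ping.egram"),
        "ramp_trace": write_echogram(ramp_trace(), out / "ramp_trace.egram"),
        "toy_schedule": write_table(toy_schedule(), out / "toy_schedule.csv"),
    }
    mask_path = out / "three_blobs.txt"
    np.savetxt(mask_path, three_blobs().astype(int), fmt="%d")
    paths["three_blobs"] = mask_path
    rng = np.random.default_rng(seed)
    noise = rng.normal(-85.0, 2.0, (20, 30))
    paths["noise_only"] = write_echogram(_egram(noise, r0=0.5, dr=0.5),
                                         out / "noise_only.egram")
    return paths
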