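"""Per-ping school envelope: backscatter center of mass and school limits.

The center of mass weights bin ranges by linear power ``10^(dB/10)`` over
bins at or above the threshold.  Limits are the min/max range of the
thresholded mask after removing above-threshold runs shorter than
``min_run_bins`` (despeckle), which stabilizes the upper/lower dashed-line
envelope against isolated noise bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Echogram, MISSING_DB

__all__ = [
    "SchoolEnvelope",
    "center_of_mass_range",
    "school_limits",
    "compute_envelope",
    "aggregate_envelope",
    "DEFAULT_THRESHOLD_DB",
]

DEFAULT_THRESHOLD_DB = -70.0
MIN_RUN_BINS = 2


@dataclass
class SchoolEnvelope:
    """Per-ping envelope series (ranges in m from the transducer face)."""

    ping_times: np.ndarray
    center_of_mass: np.ndarray  # NaN where invalid
    upper_limit: np.ndarray  # shallow edge = larger range for 'up'
    lower_limit: np.ndarray  # near edge = smaller range
    valid: np.ndarray
    threshold_db: float
    saturated_fraction: np.ndarray | None = None


def _valid_mask(e: Echogram, threshold_db: float) -> np.ndarray:
    v = e.values
    return (v >= threshold_db) & (v > MISSING_DB)


def _com_from_mask(e: Echogram, mask: np.ndarray) -> np.ndarray:
    w = np.where(mask, 10.0 ** (e.values / 10.0), 0.0)
    wsum = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        com = (w * e.range_bins[None, :]).sum(axis=1) / wsum
    com[wsum == 0] = np.nan
    return com


def center_of_mass_range(e: Echogram, threshold_db: float = DEFAULT_THRESHOLD_DB):
    """Per-ping center of mass of linear backscatter power over the
    above-threshold bins; NaN for pings with no qualifying bin."""
    if e.n_pings == 0 or e.n_bins == 0:
        raise ValueError("empty echogram")
    return _com_from_mask(e, _valid_mask(e, threshold_db))


def _despeckle_runs(mask: np.ndarray, min_run_bins: int) -> np.ndarray:
    """Zero out along-range runs of True shorter than min_run_bins, per ping."""
    if min_run_bins <= 1:
        return mask
    out = mask.copy()
    padded = np.zeros((mask.shape[0], mask.shape[1] + 2), dtype=int)
    padded[:, 1:-1] = mask
    d = np.diff(padded, axis=1)
    for i in range(mask.shape[0]):
        starts = np.nonzero(d[i] == 1)[0]
        ends = np.nonzero(d[i] == -1)[0]
        for s, t in zip(starts, ends):
            if t - s < min_run_bins:
                out[i, s:t] = False
    return out


def school_limits(
    e: Echogram,
    threshold_db: float = DEFAULT_THRESHOLD_DB,
    min_run_bins: int = MIN_RUN_BINS,
):
    """Per-ping (lower_range, upper_range): min and max above-threshold bin
    range after despeckling; NaN where no bin qualifies."""
    if e.n_pings == 0 or e.n_bins == 0:
        raise ValueError("empty echogram")
    mask = _despeckle_runs(_valid_mask(e, threshold_db), min_run_bins)
    any_bin = mask.any(axis=1)
    first = mask.argmax(axis=1)
    last = e.n_bins - 1 - mask[:, ::-1].argmax(axis=1)
    lower = np.where(any_bin, e.range_bins[first], np.nan)
    upper = np.where(any_bin, e.range_bins[last], np.nan)
    return lower, upper


def compute_envelope(
    e: Echogram,
    threshold_db: float = DEFAULT_THRESHOLD_DB,
    min_run_bins: int = MIN_RUN_BINS,
) -> SchoolEnvelope:
    """Full per-ping envelope: center of mass, limits, validity, saturation.

    Both the center of mass and the limits use the despeckled mask here, so
    the limits always bracket the center of mass.
    """
    if e.n_pings == 0 or e.n_bins == 0:
        raise ValueError("empty echogram")
    mask = _despeckle_runs(_valid_mask(e, threshold_db), min_run_bins)
    com = _com_from_mask(e, mask)
    lower, upper = school_limits(e, threshold_db, min_run_bins)
    sat = None
    if e.dynamic_range_max is not None:
        sat = (e.values >= e.dynamic_range_max).mean(axis=1)
    return SchoolEnvelope(
        ping_times=e.ping_times,
        center_of_mass=com,
        upper_limit=upper,
        lower_limit=lower,
        valid=~np.isnan(com),
        threshold_db=threshold_db,
        saturated_fraction=sat,
    )


def aggregate_envelope(env: SchoolEnvelope, windows) -> pd.DataFrame:
    """Mean envelope per time window.

    ``windows`` is an iterable of (t0, t1) or (label, t0, t1); half-open.
    Windows without valid pings get NaN means rather than raising.  A window
    whose saturated-sample fraction exceeds 0.2 triggers a warning.
    """
    rows = []
    for win in windows:
        if len(win) == 3:
            label, t0, t1 = win
        else:
            t0, t1 = win
            label = f"{t0:g}-{t1:g}"
        sel = (env.ping_times >= t0) & (env.ping_times < t1)
        ok = sel & env.valid
        n_sel = int(sel.sum())
        row = {
            "window": label,
            "t_start": t0,
            "t_end": t1,
            "n_pings": n_sel,
            "valid_fraction": ok.sum() / n_sel if n_sel else np.nan,
            "com": np.nanmean(env.center_of_mass[ok]) if ok.any() else np.nan,
            "upper_limit": np.nanmean(env.upper_limit[ok]) if ok.any() else np.nan,
            "lower_limit": np.nanmean(env.lower_limit[ok]) if ok.any() else np.nan,
        }
        if env.saturated_fraction is not None and n_sel:
            sat = float(env.saturated_fraction[sel].mean())
            row["saturated_fraction"] = sat
            if sat > 0.2:
                warnings.warn(
                    f"window {label}: {sat:.0%} of samples saturated", stacklevel=2
                )
        rows.append(row)
    return pd.DataFrame(rows)
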