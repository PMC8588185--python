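"""Fish-trace extraction: binarization, morphological cleaning, 4-connected
segmentation, size/level filtering, and length/tilt indicators.

Conventions (stated once, pinned by tests): 4-connectivity and a 3x3 cross
structuring element throughout; per-ping maximum ties break toward the
nearest-to-transducer bin; tilt is the OLS slope of the per-ping
maximum-backscatter range on ping index, in m/ping, so a positive slope means
range increasing away from the transducer — swimming upward for an up-looking
beam.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import Echogram, MISSING_DB

__all__ = [
    "Trace",
    "binarize",
    "clean_mask",
    "thicken",
    "segment",
    "filter_regions",
    "trace_tilt",
    "extract_traces",
    "summarize_traces",
    "DEFAULT_BIN_THRESHOLD_DB",
    "DEFAULT_MIN_SIZE_PX",
    "DEFAULT_MIN_LEVEL_DB",
]

DEFAULT_BIN_THRESHOLD_DB = -70.0
DEFAULT_MIN_SIZE_PX = 6
DEFAULT_MIN_LEVEL_DB = -60.0

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class Trace:
    """One fish crossing the beam: a 4-connected echogram region."""

    pixels: np.ndarray  # (n, 2) array of (ping index, bin index)
    length_pings: int
    max_ranges: np.ndarray  # per distinct ping, range of the max-value pixel (m)
    ping_indices: np.ndarray  # the distinct ping indices, sorted
    tilt_slope: float | None  # m/ping; None when length_pings < 3
    mean_level_db: float
    start_time: float
    mean_range: float

    @property
    def upward(self) -> bool | None:
        if self.tilt_slope is None:
            return None
        return self.tilt_slope > 0


def binarize(e: Echogram, threshold_db: float = DEFAULT_BIN_THRESHOLD_DB) -> np.ndarray:
    """mask[i, j] = True iff value >= threshold; missing samples are False."""
    if not np.isfinite(threshold_db):
        raise ValueError("threshold must be finite")
    return (e.values >= threshold_db) & (e.values > MISSING_DB)


def thicken(mask: np.ndarray) -> np.ndarray:
    """One thickening iteration: add background pixels with at least two
    foreground 4-neighbours.  Fills single-pixel concavities and gaps so
    regions become more compact, while leaving isolated pixels untouched."""
    mask = np.asarray(mask, dtype=bool)
    kernel = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.uint8)
    nb = ndimage.convolve(mask.astype(np.uint8), kernel, mode="constant")
    return mask | (nb >= 2)


def clean_mask(mask: np.ndarray) -> np.ndarray:
    """Morphological cleanup: thickening (1 iteration), opening, closing,
    all with the 3x3 cross element.  Output is binary with the same shape."""
    m = thicken(np.asarray(mask, dtype=bool))
    m = ndimage.binary_opening(m, structure=_CROSS)
    # pad so the closing stays extensive at the image border
    p = np.pad(m, 1)
    p = ndimage.binary_dilation(p, structure=_CROSS)
    p = ndimage.binary_erosion(p, structure=_CROSS)
    return p[1:-1, 1:-1]


def segment(mask: np.ndarray) -> list[np.ndarray]:
    """4-connected components as (n, 2) pixel-index arrays, ordered by
    (first ping, first bin) of each region."""
    labels, n = ndimage.label(mask, structure=_CROSS)
    regions = []
    for lab in range(1, n + 1):
        pi, bi = np.nonzero(labels == lab)
        order = np.lexsort((bi, pi))
        regions.append(np.column_stack([pi[order], bi[order]]))
    regions.sort(key=lambda r: (int(r[0, 0]), int(r[0, 1])))
    return regions


def _region_mean_level(region: np.ndarray, e: Echogram) -> float:
    """Region mean echo level as dB of the mean linear power, so that
    below-floor pixels swallowed by the morphology do not dominate."""
    levels = e.values[region[:, 0], region[:, 1]]
    return float(10.0 * np.log10(np.mean(10.0 ** (levels / 10.0))))


def _region_to_trace(region: np.ndarray, e: Echogram) -> Trace:
    pi = region[:, 0]
    bi = region[:, 1]
    levels = e.values[pi, bi]
    pings = np.unique(pi)
    max_ranges = np.empty(pings.size)
    for k, p in enumerate(pings):
        sel = pi == p
        b = bi[sel]
        lv = levels[sel]
        # tie-break toward the nearest-to-transducer (smallest-range) bin
        best = b[lv == lv.max()].min()
        max_ranges[k] = e.range_bins[best]
    tilt = None
    if pings.size >= 3:
        tilt = float(np.polyfit(pings.astype(float), max_ranges, 1)[0])
    return Trace(
        pixels=region,
        length_pings=int(pings.size),
        max_ranges=max_ranges,
        ping_indices=pings,
        tilt_slope=tilt,
        mean_level_db=_region_mean_level(region, e),
        start_time=float(e.ping_times[pings[0]]),
        mean_range=float(e.range_bins[bi].mean()),
    )


def filter_regions(
    regions: list[np.ndarray],
    e: Echogram,
    min_size_px: int = DEFAULT_MIN_SIZE_PX,
    min_level_db: float = DEFAULT_MIN_LEVEL_DB,
) -> list[Trace]:
    """Keep regions with pixel count >= min_size_px and mean level over the
    region's pixels >= min_level_db; survivors become Traces."""
    out = []
    for region in regions:
        if len(region) < min_size_px:
            continue
        if _region_mean_level(region, e) < min_level_db:
            continue
        out.append(_region_to_trace(region, e))
    return out


def trace_tilt(t: Trace) -> float:
    """OLS slope of per-ping max-backscatter range on ping index (m/ping)."""
    if t.length_pings < 3:
        raise ValueError("tilt undefined for traces shorter than 3 pings")
    return float(np.polyfit(t.ping_indices.astype(float), t.max_ranges, 1)[0])


def extract_traces(
    e: Echogram,
    threshold_db: float = DEFAULT_BIN_THRESHOLD_DB,
    min_size_px: int = DEFAULT_MIN_SIZE_PX,
    min_level_db: float = DEFAULT_MIN_LEVEL_DB,
) -> list[Trace]:
    """Full pipeline: binarize -> clean -> segment -> filter."""
    mask = clean_mask(binarize(e, threshold_db))
    return filter_regions(segment(mask), e, min_size_px, min_level_db)


def trace_table(traces: list[Trace]) -> pd.DataFrame:
    """One row per trace with its summary columns."""
    return pd.DataFrame(
        {
            "start_time": [t.start_time for t in traces],
            "length_pings": [t.length_pings for t in traces],
            "tilt_slope": [t.tilt_slope if t.tilt_slope is not None else np.nan
                           for t in traces],
            "mean_level_db": [t.mean_level_db for t in traces],
            "mean_range": [t.mean_range for t in traces],
        }
    )


def summarize_traces(traces: list[Trace], windows) -> pd.DataFrame:
    """Per-window trace summary: mean length, mean tilt, count, fraction
    swimming upward (slope > 0).  Windows are (t0, t1) or (label, t0, t1),
    half-open on trace start time; empty windows yield NaN rows."""
    df = trace_table(traces)
    rows = []
    for win in windows:
        if len(win) == 3:
            label, t0, t1 = win
        else:
            t0, t1 = win
            label = f"{t0:g}-{t1:g}"
        sel = df[(df.start_time >= t0) & (df.start_time < t1)]
        tilts = sel["tilt_slope"].dropna()
        rows.append(
            {
                "window": label,
                "t_start": t0,
                "t_end": t1,
                "n_traces": len(sel),
                "mean_length_pings": sel["length_pings"].mean() if len(sel) else np.nan,
                "mean_tilt": tilts.mean() if len(tilts) else np.nan,
                "fraction_upward": (tilts > 0).mean() if len(tilts) else np.nan,
            }
        )
    return pd.DataFrame(rows)
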