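"""Calibrated hydrophone levels and spectra.

All levels are dB re 1 uPa (RMS) unless stated otherwise.  WAV input uses
``scipy.io.wavfile``; a sidecar calibration (hydrophone sensitivity in
dB re 1 V/uPa, chain gain in dB, and full-scale volts for integer PCM)
converts samples to pressure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "PressureSeries",
    "BandSpectrum",
    "calibrate",
    "read_wav_calibrated",
    "spl_rms",
    "peak_spl",
    "third_octave_levels",
    "narrowband_spectrum",
    "harmonic_distortion",
]

MISSING_LEVEL = -np.inf


@dataclass
class PressureSeries:
    """Calibrated pressure samples in micropascals."""

    samples: np.ndarray
    sample_rate: float
    source: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")


@dataclass
class BandSpectrum:
    """Third-octave band levels; NaN marks missing/silent bands."""

    centers: np.ndarray  # Hz, strictly increasing
    levels: np.ndarray  # dB re 1 uPa RMS

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("band centers must be strictly increasing")


def calibrate(
    volts: np.ndarray,
    sensitivity_db_re_1v_per_upa: float,
    gain_db: float = 0.0,
    sample_rate: float = 1.0,
    source: str = "",
) -> PressureSeries:
    """Convert a voltage series to pressure:
    p = v * 10^(-(sensitivity + gain) / 20) uPa."""
    volts = np.asarray(volts, dtype=float)
    if volts.size == 0:
        raise ValueError("empty input")
    scale = 10.0 ** (-(sensitivity_db_re_1v_per_upa + gain_db) / 20.0)
    return PressureSeries(volts * scale, sample_rate, source)


def read_wav_calibrated(wav_path: str | Path, cal_path: str | Path) -> PressureSeries:
    """Read a WAV file plus a YAML sidecar with sensitivity_db, gain_db and
    full_scale_volts, returning calibrated pressure."""
    rate, data = wavfile.read(wav_path)
    if data.ndim > 1:
        data = data[:, 0]
    with open(cal_path, "r", encoding="utf-8") as fh:
        cal = yaml.safe_load(fh)
    full_scale = float(cal.get("full_scale_volts", 1.0))
    if np.issubdtype(data.dtype, np.integer):
        volts = data.astype(float) / float(np.iinfo(data.dtype).max) * full_scale
    else:
        volts = data.astype(float) * full_scale
    return calibrate(
        volts,
        float(cal["sensitivity_db"]),
        float(cal.get("gain_db", 0.0)),
        sample_rate=float(rate),
        source=str(wav_path),
    )


def spl_rms(p: PressureSeries, time_constant_s: float = 1.0):
    """Exponentially averaged SPL series plus the overall (whole-series) SPL.

    The running mean square uses a one-pole exponential filter with the given
    time constant.  Overall SPL is 10*log10 of the plain mean square.  An
    all-zero signal yields -inf for both.
    """
    if time_constant_s <= 0:
        raise ValueError("time_constant_s must be positive")
    x2 = p.samples**2
    alpha = 1.0 - np.exp(-1.0 / (p.sample_rate * time_constant_s))
    ms = signal.lfilter([alpha], [1.0, -(1.0 - alpha)], x2, zi=[(1 - alpha) * x2[0]])[0]
    with np.errstate(divide="ignore"):
        series = 10.0 * np.log10(ms)
        mean_sq = float(x2.mean())
        overall = 10.0 * np.log10(mean_sq) if mean_sq > 0 else MISSING_LEVEL
    return series, overall


def peak_spl(p: PressureSeries) -> float:
    """20*log10(max |p| / 1 uPa); -inf for an all-zero signal."""
    if p.samples.size == 0:
        raise ValueError("empty input")
    peak = float(np.abs(p.samples).max())
    return 20.0 * np.log10(peak) if peak > 0 else MISSING_LEVEL


def _third_octave_centers(f_min: float, f_max: float) -> np.ndarray:
    """Base-10 exact third-octave centers 10^(n/10) kHz within [f_min, f_max]."""
    n_lo = int(np.ceil(10 * np.log10(f_min / 1000.0)))
    n_hi = int(np.floor(10 * np.log10(f_max / 1000.0)))
    return 1000.0 * 10.0 ** (np.arange(n_lo, n_hi + 1) / 10.0)


def third_octave_levels(
    p: PressureSeries, f_min: float = 20.0, f_max: float | None = None, order: int = 6
) -> BandSpectrum:
    """Third-octave band levels via bandpass filtering and per-band RMS.

    Base-10 band definition: edges at fc * 10^(+-1/20).  Bands whose upper
    edge reaches Nyquist are omitted with a warning.  Silent bands are NaN.
    """
    nyq = p.sample_rate / 2.0
    if f_max is None:
        f_max = nyq * 0.9
    if f_max >= nyq:
        raise ValueError("f_max must be below Nyquist")
    centers = _third_octave_centers(f_min, f_max)
    out_c, out_l = [], []
    for fc in centers:
        lo, hi = fc * 10 ** (-1 / 20), fc * 10 ** (1 / 20)
        if hi >= nyq:
            warnings.warn(f"band {fc:.4g} Hz above Nyquist; omitted", stacklevel=2)
            continue
        sos = signal.butter(order // 2, [lo, hi], btype="bandpass", fs=p.sample_rate,
                            output="sos")
        y = signal.sosfiltfilt(sos, p.samples)
        ms = float(np.mean(y**2))
        out_c.append(fc)
        out_l.append(10.0 * np.log10(ms) if ms > 0 else np.nan)
    return BandSpectrum(np.array(out_c), np.array(out_l))


def narrowband_spectrum(p: PressureSeries, nperseg: int | None = None):
    """Averaged periodogram (Hann window, 50% overlap); returns
    (frequencies Hz, level dB re 1 uPa^2 per bin, scaling='spectrum')."""
    if nperseg is None:
        nperseg = min(p.samples.size, 4096)
    f, pxx = signal.welch(
        p.samples,
        fs=p.sample_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        scaling="spectrum",
    )
    with np.errstate(divide="ignore"):
        level = 10.0 * np.log10(pxx)
    return f, level


def harmonic_distortion(
    p: PressureSeries, f0: float, n_harmonics: int = 5, nperseg: int | None = None
) -> float:
    """Super-harmonic distortion: 10*log10(sum of harmonic powers at
    2*f0..(n+1)*f0 over the fundamental power), from the averaged
    periodogram.  Each component's power is summed over a small neighbourhood
    of its bin."""
    if f0 * (n_harmonics + 1) >= p.sample_rate / 2:
        raise ValueError("highest harmonic above Nyquist")
    if nperseg is None:
        nperseg = min(p.samples.size, 8192)
    f, pxx = signal.welch(
        p.samples,
        fs=p.sample_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        scaling="spectrum",
    )

    def comp_power(freq: float) -> float:
        idx = int(np.argmin(np.abs(f - freq)))
        lo, hi = max(idx - 2, 0), min(idx + 3, f.size)
        return float(pxx[lo:hi].sum())

    fund = comp_power(f0)
    if fund <= 0:
        raise ValueError("no power at the fundamental frequency")
    harm = sum(comp_power((k + 2) * f0) for k in range(n_harmonics))
    return 10.0 * np.log10(harm / fund) if harm > 0 else MISSING_LEVEL
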