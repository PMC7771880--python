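"""Time-frequency analysis and population-burst detection.

Spectrograms follow the convention used throughout the figures: short-time
Fourier transform with 95% window overlap, power normalized to its maximum,
log10 scale, floored at 1e-2.  Band powers integrate the periodogram over
the standard working-memory bands (theta 3-11 Hz, beta 11-25 Hz,
gamma 25-100 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "Spectrogram",
    "BurstTrain",
    "spectrogram",
    "band_power",
    "detect_bursts",
    "dominant_frequency",
    "THETA_BAND",
    "BETA_BAND",
    "GAMMA_BAND",
]

THETA_BAND = (3.0, 11.0)
BETA_BAND = (11.0, 25.0)
GAMMA_BAND = (25.0, 100.0)

POWER_FLOOR = 1e-2


@dataclass
class Spectrogram:
    """Normalized log-power STFT.  times in s, frequencies in Hz."""

    times: np.ndarray
    frequencies: np.ndarray
    log_power: np.ndarray  # (n_freq, n_time), log10 of normalized power, >= -2

    def dominant_trace(self, f_min: float = 0.5) -> np.ndarray:
        """Frequency of maximal power at each time."""
        sel = self.frequencies >= f_min
        return self.frequencies[sel][np.argmax(self.log_power[sel], axis=0)]


def spectrogram(
    x: np.ndarray,
    fs: float,
    window_s: float = 0.2,
    overlap: float = 0.95,
) -> Spectrogram:
    """STFT spectrogram of a uniformly sampled signal.

    Parameters
    ----------
    x : signal samples
    fs : sampling rate in Hz
    window_s : STFT window length in seconds (0.2 s for short protocols,
        1 s for the multi-item runs, trading time for frequency resolution)
    overlap : fractional window overlap
    """
    nper = int(round(window_s * fs))
    if nper >= x.size:
        raise ValueError(
            f"window of {nper} samples does not fit signal of {x.size} samples"
        )
    f, t, Z = sps.stft(
        x - np.mean(x), fs=fs, nperseg=nper, noverlap=int(nper * overlap)
    )
    P = np.abs(Z) ** 2
    P /= P.max()
    P = np.maximum(P, POWER_FLOOR)
    return Spectrogram(times=t, frequencies=f, log_power=np.log10(P))


def band_power(
    x: np.ndarray, fs: float, band: tuple[float, float]
) -> float:
    """Integral of the periodogram power spectral density over ``band`` (Hz)."""
    lo, hi = band
    if hi > fs / 2:
        raise ValueError(f"band {band} exceeds the Nyquist frequency {fs / 2}")
    f, P = sps.periodogram(x - np.mean(x), fs=fs)
    sel = (f >= lo) & (f <= hi)
    return float(np.trapezoid(P[sel], f[sel]))


@dataclass
class BurstTrain:
    """Population-burst peak times (ms) and the inter-burst intervals."""

    times: np.ndarray  # ms, strictly increasing
    heights: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("burst times must be strictly increasing")

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.times)

    @property
    def rate_hz(self) -> float:
        """Inverse mean inter-burst interval (Hz); nan for < 2 bursts."""
        if self.times.size < 2:
            return float("nan")
        return 1e3 / float(self.intervals.mean())

    def restrict(self, t_min: float, t_max: float) -> "BurstTrain":
        sel = (self.times >= t_min) & (self.times < t_max)
        return BurstTrain(self.times[sel], self.heights[sel])


def detect_bursts(
    rate: np.ndarray,
    t: np.ndarray,
    baseline: float | None = None,
    threshold_factor: float = 5.0,
    min_separation: float = 20.0,
) -> BurstTrain:
    """Detect population bursts as prominent local maxima of a rate trace.

    A burst is a local maximum exceeding ``threshold_factor`` times the
    baseline rate, at least ``min_separation`` ms from the previous one.  The
    baseline defaults to the median of the trace (robust against the bursts
    themselves); detection is invariant under uniform rescaling of the trace
    because the threshold is relative.
    """
    rate = np.asarray(rate, dtype=float)
    t = np.asarray(t, dtype=float)
    dt = float(t[1] - t[0])
    if baseline is None:
        baseline = float(np.median(rate))
    height = threshold_factor * baseline
    peaks, props = sps.find_peaks(
        rate, height=height, distance=max(1, int(round(min_separation / dt)))
    )
    return BurstTrain(times=t[peaks], heights=rate[peaks])


def dominant_frequency(
    x: np.ndarray,
    fs: float,
    f_min: float = 0.5,
    interpolate: bool = True,
) -> float:
    """Frequency (Hz) of the periodogram maximum above ``f_min``.

    A parabolic fit through the peak bin and its neighbours refines the
    estimate beyond the raw bin resolution.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("signal too short for a frequency estimate")
    f, P = sps.periodogram(x - np.mean(x), fs=fs)
    sel = f >= f_min
    if not np.any(sel):
        raise ValueError(f"no spectral bins above f_min={f_min} Hz")
    f, P = f[sel], P[sel]
    i = int(np.argmax(P))
    if not interpolate or i == 0 or i == P.size - 1:
        return float(f[i])
    # log-parabolic interpolation around the peak
    a, b, c = np.log(P[i - 1] + 1e-300), np.log(P[i] + 1e-300), np.log(P[i + 1] + 1e-300)
    denom = a - 2 * b + c
    shift = 0.0 if denom == 0 else 0.5 * (a - c) / denom
    shift = float(np.clip(shift, -0.5, 0.5))
    return float(f[i] + shift * (f[1] - f[0]))
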