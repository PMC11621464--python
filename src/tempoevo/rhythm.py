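"""Wavelet rhythm metrics: dominant period and the coherence factor beta.

Each activity series is processed in a fixed order — rescale to [0, 1],
Gaussian smoothing (15-point window), continuous wavelet transform — and the
periodogram obtained by summing coefficient magnitudes over time at each
period yields two scalars per recording:

- the *dominant period*, the period at the periodogram's global maximum
  (the typical interval between activity bursts), and
- the *rhythmicity* (coherence factor) beta = Hdp / Wm, the tallest-peak
  height over the mean periodogram magnitude — a signal-to-noise-style
  measure of how regular the oscillation is. beta >= 1 always, with
  equality only for a flat periodogram.

The transform uses an analytic mother wavelet (Morlet with omega0 = 6 by
default, or a generalized Morse wavelet with gamma = 3, beta = 20) on a
logarithmic period grid, L1-normalized so a sinusoid contributes equal
magnitude at every scale. Both metrics are ratio- or argmax-based, which
makes them robust to the wavelet family; the two families are compared in
the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.fft

from .series import ActivityTimeSeries

__all__ = [
    "WaveletPeriodogram",
    "RhythmMetrics",
    "ConstantSeriesError",
    "SeriesTooShortError",
    "rescale_unit",
    "smooth_series",
    "wavelet_periodogram",
    "dominant_period",
    "rhythmicity",
    "truncate_to_match",
    "series_metrics",
]

MORLET_OMEGA0 = 6.0
MORSE_GAMMA = 3.0
MORSE_BETA = 20.0


class ConstantSeriesError(ValueError):
    """Raised when an operation is undefined on a constant series."""


class SeriesTooShortError(ValueError):
    """Raised when a series is too short for the wavelet transform."""


@dataclass(frozen=True)
class WaveletPeriodogram:
    """Summed wavelet magnitude on a strictly increasing period grid."""

    periods_min: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.periods_min, dtype=float)
        w = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "periods_min", p)
        object.__setattr__(self, "power", w)
        if p.ndim != 1 or p.shape != w.shape or p.size == 0:
            raise ValueError("periods and power must be equal-length 1-D arrays")
        if np.any(np.diff(p) <= 0):
            raise ValueError("period grid must be strictly increasing")
        if np.any(w < 0):
            raise ValueError("power must be >= 0")


@dataclass(frozen=True)
class RhythmMetrics:
    """Per-series tempo traits derived from the wavelet periodogram."""

    dominant_period_min: float
    rhythmicity_beta: float
    peak_height: float
    mean_power: float


def rescale_unit(series: ActivityTimeSeries) -> ActivityTimeSeries:
    """Affinely rescale to minimum 0, maximum 1."""
    lo, hi = float(series.values.min()), float(series.values.max())
    if hi == lo:
        raise ConstantSeriesError(
            f"series {series.series_id!r} is constant; unit rescaling undefined"
        )
    return series.with_values((series.values - lo) / (hi - lo))


def _gaussian_kernel(window: int) -> np.ndarray:
    # MATLAB-style gausswin convention: alpha = 2.5, std = (window-1)/(2*alpha)
    half = (window - 1) / 2
    if half == 0:
        return np.ones(1)
    sd = (window - 1) / 5.0
    k = np.arange(-half, half + 1)
    return np.exp(-0.5 * (k / sd) ** 2)


def smooth_series(series: ActivityTimeSeries, window: int = 15) -> ActivityTimeSeries:
    """Gaussian-weighted moving average with a centered odd window.

    Near the edges the kernel is truncated and renormalized, so the output
    has the same length as the input and a constant series is unchanged.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window < 1 or window > len(series):
        raise ValueError("window must be in [1, len(series)]")
    kernel = _gaussian_kernel(window)
    num = np.convolve(series.values, kernel, mode="same")
    den = np.convolve(np.ones(len(series)), kernel, mode="same")
    return series.with_values(num / den)


def _period_grid(n: int, dt_min: float, voices_per_octave: int) -> np.ndarray:
    p_min = 2.0 * dt_min
    p_max = n * dt_min / 2.0
    n_octaves = math.log2(p_max / p_min)
    if n_octaves < 2:
        raise SeriesTooShortError(
            f"series of {n} points spans fewer than two octaves of period"
        )
    n_steps = int(math.floor(n_octaves * voices_per_octave))
    return p_min * 2.0 ** (np.arange(n_steps + 1) / voices_per_octave)


def _wavelet_fourier(omega: np.ndarray, family: str) -> np.ndarray:
    """Fourier transform of the analytic mother wavelet, peak-normalized to 2.

    ``omega`` is scale times angular frequency; support is omega > 0 only
    (analytic wavelet), and the peak response sits at the wavelet's center
    frequency so an amplitude-A sinusoid yields coefficient magnitude ~A.
    """
    psi = np.zeros_like(omega)
    pos = omega > 0
    if family == "morlet":
        psi[pos] = 2.0 * np.exp(-0.5 * (omega[pos] - MORLET_OMEGA0) ** 2)
    elif family == "morse":
        b, g = MORSE_BETA, MORSE_GAMMA
        wp = (b / g) ** (1.0 / g)  # peak frequency
        log_peak = b * math.log(wp) - wp**g
        psi[pos] = 2.0 * np.exp(b * np.log(omega[pos]) - omega[pos] ** g - log_peak)
    else:
        raise ValueError(f"unknown wavelet family {family!r}")
    return psi


def _center_period_factor(family: str) -> float:
    """Ratio (Fourier period) / scale for the chosen wavelet."""
    if family == "morlet":
        # Torrence & Compo: lambda = 4 pi s / (w0 + sqrt(2 + w0^2))
        return 4 * math.pi / (MORLET_OMEGA0 + math.sqrt(2 + MORLET_OMEGA0**2))
    if family == "morse":
        return 2 * math.pi / (MORSE_BETA / MORSE_GAMMA) ** (1.0 / MORSE_GAMMA)
    raise ValueError(f"unknown wavelet family {family!r}")


def wavelet_periodogram(
    series: ActivityTimeSeries,
    family: str = "morlet",
    voices_per_octave: int = 12,
) -> WaveletPeriodogram:
    """Continuous wavelet transform summed over time at each period.

    The input is mirror-padded on both sides to mitigate edge effects, the
    analytic transform is evaluated by FFT at logarithmically spaced periods
    covering [2 x sample interval, record length / 2], and at each period the
    absolute coefficient magnitudes are summed across all (unpadded) time
    points. Callers should rescale and smooth first; :func:`series_metrics`
    enforces that order.
    """
    x = np.asarray(series.values, dtype=float)
    n = x.size
    if n < 64:
        raise SeriesTooShortError(f"need >= 64 points, got {n}")
    dt_min = series.sample_interval_s / 60.0
    periods = _period_grid(n, dt_min, voices_per_octave)
    scales = periods / dt_min / _center_period_factor(family)  # in samples

    x = x - x.mean()
    xp = np.concatenate([x[::-1], x, x[::-1]])  # mirror padding
    m = scipy.fft.next_fast_len(xp.size)
    xhat = scipy.fft.fft(xp, m)
    omega_k = 2 * math.pi * scipy.fft.fftfreq(m)  # radians per sample

    power = np.empty(periods.size)
    lo = n  # central (unpadded) block within xp
    for i, s in enumerate(scales):
        psi = _wavelet_fourier(s * omega_k, family)
        coeff = scipy.fft.ifft(xhat * psi)[lo : lo + n]
        power[i] = np.abs(coeff).sum()
    return WaveletPeriodogram(periods_min=periods, power=power)


def dominant_period(pg: WaveletPeriodogram) -> float:
    """Period (minutes) at the periodogram's global maximum.

    Ties are broken toward the shorter period (the grid is ascending and the
    first maximum wins), deterministically.
    """
    return float(pg.periods_min[int(np.argmax(pg.power))])


def rhythmicity(pg: WaveletPeriodogram) -> RhythmMetrics:
    """Coherence factor beta = (tallest peak) / (mean magnitude)."""
    hdp = float(pg.power.max())
    wm = float(pg.power.mean())
    if wm == 0:
        raise ValueError("mean wavelet power is zero (identically zero series)")
    return RhythmMetrics(
        dominant_period_min=dominant_period(pg),
        rhythmicity_beta=hdp / wm,
        peak_height=hdp,
        mean_power=wm,
    )


def truncate_to_match(series: ActivityTimeSeries, target_len: int) -> ActivityTimeSeries:
    """Keep the first ``target_len`` frames (recordings started each morning,
    so the head of the series is the comparable segment)."""
    if target_len > len(series):
        raise ValueError(
            f"target_len {target_len} exceeds series length {len(series)}"
        )
    if target_len == len(series):
        return series
    return series.with_values(series.values[:target_len])


def series_metrics(
    series: ActivityTimeSeries,
    smooth_window: int = 15,
    family: str = "morlet",
    voices_per_octave: int = 12,
    truncate_to: int | None = None,
) -> RhythmMetrics:
    """Full per-series pipeline: (truncate) -> rescale -> smooth -> CWT -> metrics."""
    if truncate_to is not None and truncate_to < len(series):
        series = truncate_to_match(series, truncate_to)
    series = rescale_unit(series)
    series = smooth_series(series, smooth_window)
    pg = wavelet_periodogram(series, family=family, voices_per_octave=voices_per_octave)
    return rhythmicity(pg)
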