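"""Sensor-level spectral feature mathematics.

Implements the electrophysiological aging markers computed at the sensor
level: peak evoked-response latency, alpha-band peak frequency (after
polynomial 1/f detrending), 1/f spectral slope topographies, and Hilbert
power envelopes.  Degenerate inputs (no discernible alpha peak, flat evoked
responses) are flagged explicitly rather than returning a silent number;
flagged features propagate downstream as missing values, consistent with
the opportunistic design of the stacking model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .simulate import MultichannelSignal


@dataclass
class PowerSpectrum:
    """Per-channel power spectral density on a common frequency grid."""

    freqs: np.ndarray  # Hz, strictly increasing
    power: np.ndarray  # channels x freqs, >= 0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.power.shape[1] != len(self.freqs):
            raise ValueError("power/freqs shape mismatch")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass
class EvokedResponse:
    times: np.ndarray  # s, strictly increasing
    data: np.ndarray   # channels x times

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.data.shape[1] != len(self.times):
            raise ValueError("data/times shape mismatch")


@dataclass
class AlphaPeak:
    """Alpha-peak estimate; ``found=False`` flags a degenerate residual."""

    frequency_hz: float
    found: bool
    residual_height: float  # log10-power residual at the peak bin

    def __float__(self) -> float:
        return self.frequency_hz if self.found else math.nan


@dataclass
class EvokedLatency:
    latency_s: float
    found: bool

    def __float__(self) -> float:
        return self.latency_s if self.found else math.nan


def welch_psd(signal: MultichannelSignal, window_s: float = 2.0,
              overlap: float = 0.5) -> PowerSpectrum:
    """Welch average-periodogram PSD (Hann taper, density scaling).

    Defaults give at worst 0.5 Hz resolution. Raises if the signal is
    shorter than one window.
    """
    nperseg = int(round(window_s * signal.fs))
    if nperseg > signal.n_samples:
        raise ValueError("window longer than signal")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    freqs, power = scipy.signal.welch(
        signal.data, fs=signal.fs, window="hann", nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)), detrend=False,
        scaling="density", axis=-1)
    return PowerSpectrum(freqs, power)


def alpha_peak(spectrum: PowerSpectrum, band: tuple = (6.0, 15.0),
               detrend_degree: int = 15,
               min_height: float = 0.1) -> AlphaPeak:
    """Alpha-band peak frequency after polynomial removal of the 1/f trend.

    Fits a degree-``detrend_degree`` polynomial to log10 power versus
    frequency per channel over the full available range (0 Hz excluded),
    subtracts it, takes the per-bin maximum of the residual across channels
    and returns the frequency of the band-restricted argmax. A residual
    peak lower than ``min_height`` (log10 units) flags "no peak".
    """
    lo, hi = band
    valid = spectrum.freqs > 0
    freqs = spectrum.freqs[valid]
    if lo < freqs[0] or hi > freqs[-1]:
        raise ValueError("band outside spectrum support")
    if len(freqs) <= detrend_degree + 1:
        raise ValueError("not enough frequency bins for the polynomial fit")
    power = spectrum.power[:, valid]
    floor = np.finfo(float).tiny
    logp = np.log10(np.clip(power, floor, None))
    residual = np.empty_like(logp)
    for ch in range(logp.shape[0]):
        # Polynomial.fit rescales the domain internally; degree 15 is
        # ill-conditioned on a raw Hz axis otherwise.
        poly = np.polynomial.Polynomial.fit(freqs, logp[ch], deg=detrend_degree)
        residual[ch] = logp[ch] - poly(freqs)
    peak_profile = residual.max(axis=0)
    in_band = (freqs >= lo) & (freqs <= hi)
    band_profile = peak_profile[in_band]
    idx = int(np.argmax(band_profile))
    height = float(band_profile[idx])
    freq = float(freqs[in_band][idx])
    return AlphaPeak(freq, found=height >= min_height, residual_height=height)


def one_over_f_slope(spectrum: PowerSpectrum,
                     fit_range: tuple = (0.1, 40.0)) -> np.ndarray:
    """OLS slope of log10 power on log10 frequency, one per channel.

    Non-positive power bins are excluded per channel; a channel with fewer
    than 3 usable bins raises. A pure ``c * f**(-k)`` spectrum yields
    exactly ``-k``.
    """
    lo, hi = fit_range
    if lo <= 0:
        raise ValueError("fit_range must exclude 0 Hz")
    sel = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
    if sel.sum() < 3:
        raise ValueError("need at least 3 bins in fit_range")
    logf = np.log10(spectrum.freqs[sel])
    slopes = np.empty(spectrum.power.shape[0])
    for ch in range(spectrum.power.shape[0]):
        p = spectrum.power[ch, sel]
        ok = p > 0
        if ok.sum() < 3:
            raise ValueError(f"channel {ch}: fewer than 3 positive-power bins")
        slope, _ = np.polyfit(logf[ok], np.log10(p[ok]), deg=1)
        slopes[ch] = slope
    return slopes


def evoked_latency(evoked: EvokedResponse,
                   search_window: tuple) -> EvokedLatency:
    """Latency of the maximum across-channel RMS within a time window.

    A constant RMS trace (e.g. all-zero data) is flagged rather than
    returning an arbitrary argmax.
    """
    lo, hi = search_window
    if lo < evoked.times[0] or hi > evoked.times[-1]:
        raise ValueError("search window outside evoked time range")
    sel = (evoked.times >= lo) & (evoked.times <= hi)
    rms = np.sqrt(np.mean(evoked.data[:, sel] ** 2, axis=0))
    if np.ptp(rms) < 1e-300:
        return EvokedLatency(math.nan, found=False)
    return EvokedLatency(float(evoked.times[sel][np.argmax(rms)]), found=True)


def hilbert_envelope(signal: MultichannelSignal) -> MultichannelSignal:
    """Per-channel magnitude of the analytic signal (Hilbert transform)."""
    if not np.all(np.isfinite(signal.data)):
        raise ValueError("signal contains non-finite values")
    analytic = scipy.signal.hilbert(signal.data, axis=-1)
    return MultichannelSignal(np.abs(analytic), signal.fs)
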