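"""Comparator HRV metrics: RMSSD and FFT band powers from a sliding window.

Spectral analysis runs on 256-s windows of the 8 Hz signal: mean-centre,
Bartlett (triangular) taper, FFT, one-sided power spectrum normalized by the
taper energy so that band powers stay in ms^2 regardless of the taper.
Bands: VLF [0, 0.04), LF [0.04, 0.15), HF [0.15, hf_upper) Hz, with the DC
bin excluded; nHF = HF / (HF + LF).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beats import BeatSeries, UniformSeries
from .fsi import IndexTrace

__all__ = ["VLF_BAND", "LF_BAND", "HF_LOW", "SPECTRAL_WINDOW_S",
           "SpectralBands", "SpectralTrace", "rmssd", "band_spectrum",
           "spectral_trace"]

VLF_BAND = (0.0, 0.04)
LF_BAND = (0.04, 0.15)
HF_LOW = 0.15
SPECTRAL_WINDOW_S = 256.0
_RATE = 8.0


@dataclass
class SpectralBands:
    """One window's band powers (ms^2) and normalized HF."""

    vlf: float
    lf: float
    hf: float
    nhf: float  # NaN when hf + lf == 0


@dataclass
class SpectralTrace:
    """1 Hz traces of the band powers, timestamped at window centres."""

    times: np.ndarray
    vlf: np.ndarray
    lf: np.ndarray
    hf: np.ndarray
    nhf: np.ndarray

    def trace(self, band: str) -> IndexTrace:
        return IndexTrace(times=self.times, values=getattr(self, band), name=band)

    def __len__(self) -> int:
        return int(self.times.size)


def rmssd(series: BeatSeries, t0: float | None = None,
          t1: float | None = None) -> float:
    """Root mean square of successive R-R differences over ``[t0, t1)``.

    Computed on the beat-to-beat series, never on resampled data.  Needs at
    least 3 beats in the interval.
    """
    if t0 is None:
        t0 = -np.inf
    if t1 is None:
        t1 = np.inf
    sel = (series.beat_time >= t0) & (series.beat_time < t1)
    rr = series.rr[sel]
    if rr.size < 3:
        raise ValueError(f"need >= 3 beats in [{t0}, {t1}), found {rr.size}")
    d = np.diff(rr)
    return float(np.sqrt(np.mean(d * d)))


def _one_sided_power(window: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Frequencies and taper-normalized one-sided power of one window."""
    n = window.size
    x = window - window.mean()
    taper = np.bartlett(n)
    xw = x * taper
    spec = np.fft.rfft(xw)
    power = np.abs(spec) ** 2 / (n * np.sum(taper * taper))
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0  # Nyquist bin is not mirrored
    return np.fft.rfftfreq(n, 1.0 / rate), power


def band_spectrum(window: np.ndarray, rate: float = _RATE,
                  hf_upper: float | None = None) -> SpectralBands:
    """Band powers of one mean-centred, Bartlett-tapered window.

    ``hf_upper`` defaults to the Nyquist frequency (HF is "above 0.15 Hz").
    Band bins are assigned by half-open intervals; DC is excluded.
    """
    window = np.asarray(window, dtype=float)
    if hf_upper is None:
        hf_upper = rate / 2.0
    freqs, power = _one_sided_power(window, rate)
    nonzero = freqs > 0
    vlf = float(power[nonzero & (freqs < VLF_BAND[1])].sum())
    lf = float(power[(freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])].sum())
    # include the Nyquist bin when hf_upper is exactly Nyquist
    at_nyquist = (freqs == rate / 2.0) & (hf_upper == rate / 2.0)
    in_hf = (freqs >= HF_LOW) & ((freqs < hf_upper) | at_nyquist)
    hf = float(power[in_hf].sum())
    nhf = hf / (hf + lf) if hf + lf > 0 else float("nan")
    return SpectralBands(vlf=vlf, lf=lf, hf=hf, nhf=nhf)


def spectral_trace(signal: UniformSeries, hf_upper: float | None = None,
                   step_s: float = 1.0) -> SpectralTrace:
    """Sliding-window band powers at a 1-s step (vectorized over windows)."""
    if signal.rate != _RATE:
        raise ValueError(f"expected a {_RATE:g} Hz signal, got {signal.rate:g} Hz")
    rate = signal.rate
    nwin = int(SPECTRAL_WINDOW_S * rate)
    duration = signal.duration
    n_tr = int(np.floor(duration - SPECTRAL_WINDOW_S)) + 1
    if n_tr < 1:
        raise ValueError(f"signal spans {duration:.1f} s; "
                         f"need >= {SPECTRAL_WINDOW_S:.0f} s")
    if hf_upper is None:
        hf_upper = rate / 2.0
    starts = (np.arange(n_tr) * step_s * rate).astype(int)
    wins = np.lib.stride_tricks.sliding_window_view(signal.values, nwin)[starts]
    x = wins - wins.mean(axis=1, keepdims=True)
    taper = np.bartlett(nwin)
    spec = np.fft.rfft(x * taper, axis=1)
    power = np.abs(spec) ** 2 / (nwin * np.sum(taper * taper))
    power[:, 1:] *= 2.0
    if nwin % 2 == 0:
        power[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(nwin, 1.0 / rate)
    vlf = power[:, (freqs > 0) & (freqs < VLF_BAND[1])].sum(axis=1)
    lf = power[:, (freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])].sum(axis=1)
    at_nyquist = (freqs == rate / 2.0) & (hf_upper == rate / 2.0)
    in_hf = (freqs >= HF_LOW) & ((freqs < hf_upper) | at_nyquist)
    hf = power[:, in_hf].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nhf = np.where(hf + lf > 0, hf / (hf + lf), np.nan)
    times = signal.start_time + SPECTRAL_WINDOW_S / 2.0 + np.arange(n_tr) * step_s
    return SpectralTrace(times=times, vlf=vlf, lf=lf, hf=hf, nhf=nhf)
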