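"""Fetal stress index: envelope-area analysis of the normalized, high-passed
R-R signal over a sliding 64-s window.

Pipeline per window (512 samples at 8 Hz):

1. mean-centre (removes basal heart rate), divide by the Euclidean norm of
   the deviations (removes variability magnitude);
2. dyadic wavelet high-pass above ~0.125 Hz (4-tap Daubechies, 5 levels);
3. upper/lower envelopes through the local extrema of the filtered signal;
4. envelope area over four 16-s quarters; the minimum quarter area maps
   linearly to an index clipped to [0, 100].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .beats import UniformSeries
from .wavelet import highpass, highpass_operator

__all__ = [
    "FSI_A", "FSI_B", "FSI_DENOM", "WINDOW_S", "RATE_HZ", "LEVELS",
    "FsiWindowResult", "IndexTrace",
    "center_and_normalize", "highpass_wavelet", "envelopes", "subareas",
    "fsi_from_auc", "fsi_window", "fsi_trace", "period_mean",
]

# index mapping constants, empirically calibrated upstream; taken as given
FSI_A = 5.1
FSI_B = 1.2
FSI_DENOM = 12.8

WINDOW_S = 64.0
RATE_HZ = 8.0
LEVELS = 5
_NORM_EPS = 1e-6


@dataclass
class FsiWindowResult:
    """Every intermediate of one analysis window."""

    m: float
    s: float
    rr_norm: np.ndarray | None = None
    filtered: np.ndarray | None = None
    upper_env: np.ndarray | None = None
    lower_env: np.ndarray | None = None
    areas: tuple[float, float, float, float] | None = None
    auc_min: float | None = None
    fsi: float | None = None
    valid: bool = False
    reason: str = ""


@dataclass
class IndexTrace:
    """A 1 Hz series of an index, timestamped at window centres.

    Invalid windows hold NaN in ``values`` and False in ``valid``.
    """

    times: np.ndarray
    values: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    name: str = "index"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = ~np.isnan(self.values)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.times.shape == self.values.shape == self.valid.shape):
            raise ValueError("times/values/valid shape mismatch")

    def __len__(self) -> int:
        return int(self.times.size)


def center_and_normalize(window: np.ndarray,
                         norm_eps: float = _NORM_EPS) -> tuple[float, float, np.ndarray | None]:
    """Return ``(M, S, rr_norm)``: mean, Euclidean norm of deviations, and the
    unit-norm deviation vector (None when the window is effectively constant).
    """
    window = np.asarray(window, dtype=float)
    m = float(window.mean())
    dev = window - m
    s = float(np.sqrt(np.sum(dev * dev)))
    if s < norm_eps:
        return m, s, None
    return m, s, dev / s


def highpass_wavelet(rr_norm: np.ndarray, levels: int = LEVELS,
                     extension: str = "symmetric") -> np.ndarray:
    """Wavelet high-pass of a power-of-two-length window (see :mod:`.wavelet`)."""
    return highpass(rr_norm, levels=levels, extension=extension)


def envelopes(filtered: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    """Upper/lower envelopes through local maxima/minima.

    Extrema are samples strictly greater (smaller) than both neighbours;
    plateaus contribute their midpoint.  Envelopes interpolate linearly
    between extrema, hold flat to the window edges, and are clamped so that
    ``upper >= filtered >= lower`` pointwise.  Returns None with fewer than
    two maxima or two minima.
    """
    filtered = np.asarray(filtered, dtype=float)
    maxima, _ = find_peaks(filtered)
    minima, _ = find_peaks(-filtered)
    if maxima.size < 2 or minima.size < 2:
        return None
    idx = np.arange(filtered.size)
    upper = np.interp(idx, maxima, filtered[maxima])
    lower = np.interp(idx, minima, filtered[minima])
    upper = np.maximum(upper, filtered)
    lower = np.minimum(lower, filtered)
    return upper, lower


def subareas(upper_env: np.ndarray, lower_env: np.ndarray,
             rate: float = RATE_HZ) -> tuple[float, float, float, float, float]:
    """Envelope-gap area over four equal quarters, in normalized-unit seconds.

    Each quarter area is the sum of ``upper - lower`` over its samples divided
    by the sampling rate (so a constant gap ``c`` over a 16-s quarter gives
    ``16 c``).  Returns ``(A1, A2, A3, A4, auc_min)``.
    """
    gap = np.asarray(upper_env, dtype=float) - np.asarray(lower_env, dtype=float)
    if gap.size % 4:
        raise ValueError("envelope length must split into four equal quarters")
    if np.any(gap < -1e-12):
        raise ValueError("upper envelope below lower envelope")
    areas = gap.reshape(4, -1).sum(axis=1) / rate
    a1, a2, a3, a4 = (float(a) for a in areas)
    return a1, a2, a3, a4, float(min(a1, a2, a3, a4))


def fsi_from_auc(auc_min: float) -> float:
    """Linear index map, clipped to [0, 100]: ``100 (5.1 AUC + 1.2) / 12.8``."""
    if auc_min < 0:
        raise ValueError("auc_min must be non-negative")
    raw = 100.0 * (FSI_A * auc_min + FSI_B) / FSI_DENOM
    return float(np.clip(raw, 0.0, 100.0))


def fsi_window(window: np.ndarray, rate: float = RATE_HZ, levels: int = LEVELS,
               extension: str = "symmetric") -> FsiWindowResult:
    """Run the full per-window pipeline, keeping every intermediate."""
    window = np.asarray(window, dtype=float)
    m, s, rr_norm = center_and_normalize(window)
    if rr_norm is None:
        return FsiWindowResult(m=m, s=s, reason="constant window")
    filt = highpass_wavelet(rr_norm, levels=levels, extension=extension)
    env = envelopes(filt)
    if env is None:
        return FsiWindowResult(m=m, s=s, rr_norm=rr_norm, filtered=filt,
                               reason="too few extrema")
    upper, lower = env
    a1, a2, a3, a4, auc_min = subareas(upper, lower, rate=rate)
    return FsiWindowResult(
        m=m, s=s, rr_norm=rr_norm, filtered=filt,
        upper_env=upper, lower_env=lower,
        areas=(a1, a2, a3, a4), auc_min=auc_min,
        fsi=fsi_from_auc(auc_min), valid=True,
    )


def _sliding_starts(n_samples: int, rate: float, window_s: float,
                    step_s: float = 1.0) -> np.ndarray:
    duration = (n_samples - 1) / rate
    n_win = int(np.floor(duration - window_s)) + 1
    if n_win < 1:
        raise ValueError(
            f"signal spans {duration:.1f} s; need >= {window_s:.0f} s")
    return (np.arange(n_win) * step_s * rate).astype(int)


def fsi_trace(signal: UniformSeries, levels: int = LEVELS,
              extension: str = "symmetric",
              keep_windows: bool = False) -> IndexTrace | tuple[IndexTrace, list[FsiWindowResult]]:
    """Slide the 64-s window at a 1-s step over an 8 Hz signal.

    Filtering is batched through the cached high-pass operator; envelope
    detection runs per window.  Invalid windows are NaN.
    """
    if signal.rate != RATE_HZ:
        raise ValueError(f"expected a {RATE_HZ:g} Hz signal, got {signal.rate:g} Hz")
    nwin = int(WINDOW_S * RATE_HZ)
    starts = _sliding_starts(len(signal), signal.rate, WINDOW_S)
    wins = np.lib.stride_tricks.sliding_window_view(signal.values, nwin)[starts]
    means = wins.mean(axis=1, keepdims=True)
    dev = wins - means
    s = np.sqrt(np.sum(dev * dev, axis=1))
    ok = s > _NORM_EPS
    rr_norm = np.where(ok[:, None], dev / np.where(ok, s, 1.0)[:, None], np.nan)
    hp = highpass_operator(nwin, levels=levels, extension=extension)
    filtered = rr_norm @ hp.T

    values = np.full(starts.size, np.nan)
    results: list[FsiWindowResult] = []
    for k in range(starts.size):
        if not ok[k]:
            res = FsiWindowResult(m=float(means[k, 0]), s=float(s[k]),
                                  reason="constant window")
        else:
            env = envelopes(filtered[k])
            if env is None:
                res = FsiWindowResult(m=float(means[k, 0]), s=float(s[k]),
                                      rr_norm=rr_norm[k], filtered=filtered[k],
                                      reason="too few extrema")
            else:
                upper, lower = env
                a1, a2, a3, a4, auc_min = subareas(upper, lower, rate=signal.rate)
                res = FsiWindowResult(m=float(means[k, 0]), s=float(s[k]),
                                      rr_norm=rr_norm[k], filtered=filtered[k],
                                      upper_env=upper, lower_env=lower,
                                      areas=(a1, a2, a3, a4), auc_min=auc_min,
                                      fsi=fsi_from_auc(auc_min), valid=True)
                values[k] = res.fsi
        if keep_windows:
            results.append(res)

    times = signal.start_time + WINDOW_S / 2.0 + np.arange(starts.size) * 1.0
    trace = IndexTrace(times=times, values=values, name="fsi")
    return (trace, results) if keep_windows else trace


def period_mean(trace: IndexTrace, t0: float, t1: float,
                min_valid_frac: float = 0.5) -> float:
    """Mean of valid trace values whose window centre lies in ``[t0, t1)``.

    Raises when the interval misses the trace span entirely; returns NaN
    (with a warning) when fewer than ``min_valid_frac`` of the covered
    windows are valid.
    """
    if t1 <= t0:
        raise ValueError("need t1 > t0")
    if t1 <= trace.times[0] or t0 > trace.times[-1]:
        raise ValueError(f"interval [{t0}, {t1}) outside trace span "
                         f"[{trace.times[0]}, {trace.times[-1]}]")
    sel = (trace.times >= t0) & (trace.times < t1)
    n_sel = int(sel.sum())
    if n_sel == 0:
        raise ValueError(f"no window centres in [{t0}, {t1})")
    good = sel & trace.valid
    if good.sum() < min_valid_frac * n_sel:
        warnings.warn(f"only {int(good.sum())}/{n_sel} valid windows in "
                      f"[{t0}, {t1}); returning NaN", stacklevel=2)
        return float("nan")
    return float(trace.values[good].mean())
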