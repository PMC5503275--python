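"""Artifact handling and uniform resampling of beat-to-beat R-R series.

Artifact detection uses a running-median rule: a beat whose interval deviates
from the median of its 11 nearest reference beats by more than a relative
threshold (default 25%) is flagged.  Flagged beats are replaced by linear
interpolation between the nearest clean neighbours, and the cleaned series is
resampled by linear interpolation onto a uniform 8 Hz grid.
"""

from __future__ import annotations

import warnings

import numpy as np

from .beats import (
    ECTOPIC,
    FALSE_POSITIVE,
    INTERPOLATED,
    MISSED,
    RR_MAX_MS,
    RR_MIN_MS,
    VALID,
    BeatSeries,
    UniformSeries,
)

__all__ = ["flag_artifacts", "replace_artifacts", "resample_uniform", "clean"]

_MEDIAN_WINDOW = 11
_MIN_BEATS = 12


def _neighbor_median(i: int, reference_idx: np.ndarray, rr: np.ndarray,
                     window: int) -> float:
    """Median rr of the `window` reference beats nearest to beat i (excluding i)."""
    others = reference_idx[reference_idx != i]
    if others.size == 0:
        return np.nan
    order = np.argsort(np.abs(others - i), kind="stable")
    nearest = others[order[:window]]
    return float(np.median(rr[nearest]))


def flag_artifacts(series: BeatSeries, rel_threshold: float = 0.25,
                   window: int = _MEDIAN_WINDOW) -> BeatSeries:
    """Flag beats deviating from the local running median of clean beats.

    Runs to a fixed point so the operation is idempotent: beats already
    flagged are excluded from the reference set of later passes.  Beats
    outside the physiologic band (100-3000 ms) are always flagged.  A series
    shorter than 12 beats is returned unchanged with a warning.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    if not 0.0 < rel_threshold < 1.0:
        raise ValueError("rel_threshold must be in (0, 1)")
    if len(series) < _MIN_BEATS:
        warnings.warn(f"series has {len(series)} < {_MIN_BEATS} beats; "
                      "artifact flagging skipped", stacklevel=2)
        return series.copy()

    out = series.copy()
    flags = out.flag
    rr = out.rr
    changed = True
    while changed:
        changed = False
        # reference beats: clean originals plus previously repaired beats
        ref = np.flatnonzero((flags == VALID) | (flags == INTERPOLATED))
        for i in np.flatnonzero(flags == VALID):
            if not (RR_MIN_MS < rr[i] < RR_MAX_MS):
                flags[i] = MISSED if rr[i] >= RR_MAX_MS else FALSE_POSITIVE
                changed = True
                continue
            med = _neighbor_median(i, ref, rr, window)
            if np.isnan(med):
                continue
            if abs(rr[i] - med) > rel_threshold * med:
                flags[i] = MISSED if rr[i] > med else FALSE_POSITIVE
                changed = True
    return out


def replace_artifacts(series: BeatSeries) -> BeatSeries:
    """Replace non-valid intervals by linear interpolation over beat index.

    Interpolation runs in beat-index coordinates between the nearest valid
    neighbours; runs touching either end are held at the nearest valid value
    (with a warning).  Valid beats pass through bit-identical; replaced beats
    are re-flagged ``interpolated``.
    """
    out = series.copy()
    good = out.flag == VALID
    if good.all():
        return out
    if not good.any():
        raise ValueError("no valid beats to interpolate from")
    bad = np.flatnonzero(~good)
    good_idx = np.flatnonzero(good)
    if bad[0] < good_idx[0] or bad[-1] > good_idx[-1]:
        warnings.warn("artifact run touches series edge; holding nearest valid value",
                      stacklevel=2)
    # np.interp holds edges flat, matching the edge rule
    out.rr[bad] = np.interp(bad, good_idx, out.rr[good_idx])
    out.flag[bad] = INTERPOLATED
    low, high = out.rr.min(), out.rr.max()
    if low <= RR_MIN_MS or high >= RR_MAX_MS:
        raise ValueError(
            f"cleaned rr outside physiologic band ({RR_MIN_MS}, {RR_MAX_MS}) ms: "
            f"range [{low:.1f}, {high:.1f}]")
    return out


def resample_uniform(series: BeatSeries, rate: float = 8.0) -> UniformSeries:
    """Linear-interpolate (beat_time, rr) onto a uniform grid.

    The grid starts at the first beat time and has
    ``floor(duration * rate) + 1`` samples.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if series.duration < 1.0:
        raise ValueError(f"series spans {series.duration:.3f} s; "
                         "need >= 1 s to resample")
    t0 = float(series.beat_time[0])
    n = int(np.floor(series.duration * rate)) + 1
    grid = t0 + np.arange(n) / rate
    values = np.interp(grid, series.beat_time, series.rr)
    return UniformSeries(start_time=t0, rate=rate, values=values)


def clean(series: BeatSeries, rel_threshold: float = 0.25) -> BeatSeries:
    """Convenience: flag then replace."""
    return replace_artifacts(flag_artifacts(series, rel_threshold))
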