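"""Static plot helpers (matplotlib imported lazily; optional dependency)."""

from __future__ import annotations

from .fsi import FsiWindowResult, IndexTrace


def plot_window(result: FsiWindowResult, rate: float = 8.0, ax=None):
    """Filtered signal with its envelopes and quarter boundaries."""
    import matplotlib.pyplot as plt
    import numpy as np

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    if result.filtered is None:
        ax.set_title(f"invalid window ({result.reason})")
        return ax
    t = np.arange(result.filtered.size) / rate
    ax.plot(t, result.filtered, color="k", lw=0.8, label="filtered")
    if result.upper_env is not None:
        ax.fill_between(t, result.lower_env, result.upper_env,
                        color="0.8", label="envelope gap")
    for q in range(1, 4):
        ax.axvline(q * t[-1] / 4, color="0.5", ls=":")
    if result.fsi is not None:
        ax.set_title(f"FSI = {result.fsi:.1f} (AUCmin = {result.auc_min:.2f})")
    ax.set_xlabel("time in window (s)")
    ax.legend(loc="upper right", fontsize=8)
    return ax


def plot_trace(trace: IndexTrace, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(trace.times, trace.values, lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel(trace.name)
    return ax
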