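"""Paired before/after comparison statistics.

Implements the standard small-cohort battery: two-sided Wilcoxon signed-rank (exact by
sign-pattern enumeration for small n, normal approximation otherwise), the
paired Cohen's d variant (mean difference over the SD of the differences,
often written d_z), the coefficient of variation in percent, and
median (Q1-Q3) summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["WilcoxonResult", "PairedComparison", "wilcoxon_signed_rank",
           "cohens_d_paired", "cv_percent", "summarize", "compare_paired",
           "comparison_table", "comparison_markdown"]

_EXACT_N_MAX = 15


@dataclass
class WilcoxonResult:
    statistic: float          # W+ (sum of ranks of positive differences)
    n: int                    # non-zero differences used
    p_exact: float | None     # enumeration p, None when n > exact cutoff
    p_asymptotic: float       # normal approximation, no continuity correction
    n_zero: int = 0           # zero differences dropped

    @property
    def p_value(self) -> float:
        return self.p_exact if self.p_exact is not None else self.p_asymptotic


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Counts of 2*W+ over all sign assignments, by generating-function DP.

    ``ranks2`` are the midranks doubled so they are integers even with ties.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=np.uint64)
    counts[0] = 1
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:counts.size - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(before, after) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (classic convention).  For n <= 15 the exact
    two-sided p is computed over all 2^n sign assignments of the midranks as
    ``min(1, 2 * min(P(W+ <= w), P(W+ >= w)))``; the asymptotic p uses
    ``z = (W+ - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24 - tie correction)`` with no
    continuity correction and is always reported alongside.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after length mismatch")
    d = after - before
    n_zero = int(np.sum(d == 0))
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all differences are zero; p = 1", stacklevel=2)
        return WilcoxonResult(statistic=0.0, n=0, p_exact=1.0,
                              p_asymptotic=1.0, n_zero=n_zero)
    if n < 3:
        raise ValueError(f"need >= 3 non-zero differences, found {n}")
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())

    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_corr = np.sum(tie_counts**3 - tie_counts) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr)
    z = (w_pos - mu) / sigma
    p_asym = float(min(1.0, 2.0 * norm.sf(abs(z))))

    p_exact = None
    if n <= _EXACT_N_MAX:
        ranks2 = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_distribution(ranks2)
        total = float(2**n)
        w2 = int(round(2 * w_pos))
        p_lo = counts[: w2 + 1].sum() / total
        p_hi = counts[w2:].sum() / total
        p_exact = float(min(1.0, 2.0 * min(p_lo, p_hi)))
    return WilcoxonResult(statistic=w_pos, n=n, p_exact=p_exact,
                          p_asymptotic=p_asym, n_zero=n_zero)


def cohens_d_paired(before, after) -> tuple[float, bool]:
    """Paired effect size d = mean(diff) / sqrt(SS_D / (n - 1)).

    ``SS_D`` is the sum of squared deviations of the differences from their
    mean.  Returns ``(d, degenerate)``; ``degenerate`` marks a zero-variance
    difference vector with a non-zero mean (infinite effect).
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after length mismatch")
    d = after - before
    n = d.size
    if n < 2:
        raise ValueError("need >= 2 pairs")
    d_bar = d.mean()
    ss_d = float(np.sum((d - d_bar) ** 2))
    if ss_d == 0.0:
        if d_bar == 0.0:
            return 0.0, False
        return float(np.sign(d_bar) * np.inf), True
    return float(d_bar / np.sqrt(ss_d / (n - 1))), False


def cv_percent(values) -> float:
    """Coefficient of variation, 100 * sample SD / mean.

    Uses the n-1 denominator.  A negative mean is taken in magnitude with a
    warning; a zero mean is an error.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need >= 2 values")
    m = values.mean()
    if m == 0.0:
        raise ValueError("mean is zero; %CV undefined")
    if m < 0:
        warnings.warn("negative mean; using |mean| for %CV", stacklevel=2)
    sd = values.std(ddof=1)
    return float(100.0 * sd / abs(m))


def summarize(values) -> tuple[float, float, float]:
    """``(median, Q1, Q3)`` by linear interpolation of order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("need >= 1 value")
    q1, med, q3 = np.percentile(values, [25.0, 50.0, 75.0],
                                method="linear")
    return float(med), float(q1), float(q3)


@dataclass
class PairedComparison:
    """Per-index before/after comparison with its summary statistics."""

    name: str
    before: np.ndarray
    after: np.ndarray
    n: int
    n_dropped: int
    median_before: float
    q1_before: float
    q3_before: float
    median_after: float
    q1_after: float
    q3_after: float
    cv_before: float
    cv_after: float
    wilcoxon: WilcoxonResult
    cohens_d: float
    degenerate_d: bool = False
    d_bar: float = field(default=float("nan"))

    @property
    def p_value(self) -> float:
        return self.wilcoxon.p_value

    @property
    def effect_size(self) -> float:
        """Magnitude of d (the sign lives in d_bar)."""
        return abs(self.cohens_d)


def compare_paired(before, after, name: str = "index") -> PairedComparison:
    """Assemble a full paired comparison; pairs with a NaN side are dropped."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after length mismatch")
    keep = ~(np.isnan(before) | np.isnan(after))
    n_dropped = int(np.sum(~keep))
    b, a = before[keep], after[keep]
    if b.size < 3:
        raise ValueError(f"{name}: only {b.size} complete pairs; need >= 3")
    med_b, q1_b, q3_b = summarize(b)
    med_a, q1_a, q3_a = summarize(a)
    d, degen = cohens_d_paired(b, a)
    return PairedComparison(
        name=name, before=b, after=a, n=int(b.size), n_dropped=n_dropped,
        median_before=med_b, q1_before=q1_b, q3_before=q3_b,
        median_after=med_a, q1_after=q1_a, q3_after=q3_a,
        cv_before=cv_percent(b), cv_after=cv_percent(a),
        wilcoxon=wilcoxon_signed_rank(b, a),
        cohens_d=d, degenerate_d=degen, d_bar=float((a - b).mean()),
    )


def comparison_table(comparisons: list[PairedComparison]):
    """Comparisons as a DataFrame (Before, %CV, After, %CV, p, effect size)."""
    import pandas as pd

    rows = []
    for c in comparisons:
        rows.append({
            "index": c.name,
            "before": f"{c.median_before:.3g}({c.q1_before:.3g}-{c.q3_before:.3g})",
            "cv_before_pct": round(c.cv_before, 1),
            "after": f"{c.median_after:.3g}({c.q1_after:.3g}-{c.q3_after:.3g})",
            "cv_after_pct": round(c.cv_after, 1),
            "p_exact": c.wilcoxon.p_exact,
            "p_asymptotic": c.wilcoxon.p_asymptotic,
            "effect_size": round(c.effect_size, 2),
            "n": c.n,
        })
    return pd.DataFrame(rows)


def comparison_markdown(comparisons: list[PairedComparison]) -> str:
    """Markdown rendering of :func:`comparison_table`."""
    df = comparison_table(comparisons)
    header = "| " + " | ".join(df.columns) + " |"
    rule = "|" + "|".join("---" for _ in df.columns) + "|"
    lines = [header, rule]
    for _, row in df.iterrows():
        cells = []
        for v in row:
            if isinstance(v, float):
                cells.append("" if np.isnan(v) else f"{v:.4g}")
            else:
                cells.append(str(v))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)
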