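"""Seeded generator of fetal-like R-R series and an in-silico blockade harness.

A subject's instantaneous heart period is a basal level (from heart rate in
bpm) plus LF and HF sinusoidal modulations, slow per-subject amplitude
wander, and per-beat Gaussian jitter.  Beats are placed by direct iteration
on the instantaneous period.  Drug scenarios rescale the modulation
amplitudes and basal rate smoothly over a 30-s transition: atropine
suppresses HF and raises heart rate; propranolol suppresses LF and lowers
heart rate (default multipliers target heart-rate shifts of roughly
156->190 and 161->147 bpm).

All randomness flows from one master seed through ``numpy.random.SeedSequence``
spawning, so identical (config, seed) pairs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np

from .beats import ECTOPIC, MISSED, VALID, BeatSeries
from .fsi import fsi_trace, period_mean
from .preprocess import clean, resample_uniform
from .spectral import rmssd, spectral_trace
from .stats import PairedComparison, compare_paired

__all__ = ["DRUG_EFFECTS", "ScenarioConfig", "generate_subject",
           "run_experiment", "ExperimentResult", "adversarial_windows"]

# (hf-amplitude factor, lf-amplitude factor, basal-heart-rate factor)
DRUG_EFFECTS = {
    "none": (1.0, 1.0, 1.0),
    "atropine": (0.25, 1.0, 1.22),
    "propranolol": (1.0, 0.35, 0.91),
}

_TRANSITION_S = 30.0
_PERIOD_OFFSETS = (-600.0, -300.0, 300.0, 600.0)  # 5-min periods around drug


@dataclass
class ScenarioConfig:
    """Cohort scenario parameters.

    ``subject_sd`` is the relative between-subject spread applied
    multiplicatively to the basal heart rate and both modulation amplitudes.
    ``wander`` is the relative depth of slow (mHz) amplitude modulation that
    gives each subject non-stationary variability.
    """

    duration: float = 1500.0
    basal_hr: float = 156.0
    a_lf: float = 5.5
    a_hf: float = 11.0
    a_vlf: float = 7.0
    f_lf: float = 0.10
    f_hf: float = 0.50
    f_vlf: float = 0.02
    jitter_sd: float = 2.5
    artifact_rate: float = 0.005
    n_subjects: int = 7
    subject_sd: float = 0.07
    wander: float = 0.30
    drug: str = "none"
    drug_time: float = 750.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.duration <= 0:
            problems.append("duration must be positive")
        if not 60.0 <= self.basal_hr <= 300.0:
            problems.append("basal_hr outside plausible range [60, 300] bpm")
        if not 0.04 <= self.f_lf < 0.15:
            problems.append("f_lf must lie in [0.04, 0.15)")
        if self.f_hf < 0.15:
            problems.append("f_hf must be >= 0.15")
        if not 0.0 < self.f_vlf < 0.04:
            problems.append("f_vlf must lie in (0, 0.04)")
        if self.a_lf < 0 or self.a_hf < 0 or self.a_vlf < 0:
            problems.append("modulation amplitudes must be >= 0")
        if not 0.0 <= self.artifact_rate <= 0.05:
            problems.append("artifact_rate must lie in [0, 0.05]")
        if self.jitter_sd < 0:
            problems.append("jitter_sd must be >= 0")
        if self.n_subjects < 1:
            problems.append("n_subjects must be >= 1")
        if self.subject_sd < 0 or self.wander < 0:
            problems.append("subject_sd and wander must be >= 0")
        if self.drug not in DRUG_EFFECTS:
            problems.append(f"drug must be one of {sorted(DRUG_EFFECTS)}")
        if not 0.0 < self.drug_time < self.duration:
            problems.append("drug_time must fall inside the recording")
        if problems:
            raise ValueError("invalid scenario: " + "; ".join(problems))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown scenario fields: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _smoothstep(t: np.ndarray | float, t0: float, width: float):
    """0 before t0, 1 after t0 + width, C1-smooth ramp in between."""
    u = np.clip((np.asarray(t, dtype=float) - t0) / width, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def generate_subject(config: ScenarioConfig, subject_seed) -> BeatSeries:
    """Generate one subject's beat series.

    ``subject_seed`` is anything ``numpy.random.default_rng`` accepts
    (typically a spawned ``SeedSequence``).
    """
    config.validate()
    rng = np.random.default_rng(subject_seed)

    def factor(rel_sd: float) -> float:
        return float(max(0.2, 1.0 + rel_sd * rng.standard_normal()))

    hr0 = config.basal_hr * factor(config.subject_sd)
    alf0 = config.a_lf * factor(config.subject_sd)
    ahf0 = config.a_hf * factor(config.subject_sd)
    avlf0 = config.a_vlf * factor(config.subject_sd)
    phi_lf, phi_hf, phi_vlf = rng.uniform(0.0, 2 * np.pi, size=3)
    # independent slow amplitude wander per band (vlf wanders hardest, making
    # the normalization denominator non-stationary between analysis periods)
    # slow enough that the two 5-min analysis periods sit on different
    # amplitude states instead of averaging the wander away
    fw = rng.uniform(0.0005, 0.002, size=3)
    psi = rng.uniform(0.0, 2 * np.pi, size=3)
    depth = min(config.wander, 0.95)
    depth_vlf = min(2.0 * depth, 0.95)

    m_hf, m_lf, m_hr = DRUG_EFFECTS[config.drug]

    times: list[float] = []
    rrs: list[float] = []
    t = 0.0
    while t < config.duration:
        s = float(_smoothstep(t, config.drug_time, _TRANSITION_S)) \
            if config.drug != "none" else 0.0
        hr = hr0 * (1.0 + (m_hr - 1.0) * s)
        alf = alf0 * (1.0 + (m_lf - 1.0) * s) * (1.0 + depth * np.sin(2 * np.pi * fw[0] * t + psi[0]))
        ahf = ahf0 * (1.0 + (m_hf - 1.0) * s) * (1.0 + depth * np.sin(2 * np.pi * fw[1] * t + psi[1]))
        avlf = avlf0 * (1.0 + depth_vlf * np.sin(2 * np.pi * fw[2] * t + psi[2]))
        r = (60000.0 / hr
             + alf * np.sin(2 * np.pi * config.f_lf * t + phi_lf)
             + ahf * np.sin(2 * np.pi * config.f_hf * t + phi_hf)
             + avlf * np.sin(2 * np.pi * config.f_vlf * t + phi_vlf))
        if r <= 0:
            raise ValueError("instantaneous period <= 0; modulation amplitudes too large")
        r += float(rng.normal(0.0, config.jitter_sd)) if config.jitter_sd > 0 else 0.0
        r = max(r, 120.0)  # jitter guard, keeps rr physiologic
        t += r / 1000.0
        times.append(t)
        rrs.append(r)

    times_a = np.asarray(times)
    rrs_a = np.asarray(rrs)
    flags = np.full(rrs_a.size, VALID, dtype="<U14")

    if config.artifact_rate > 0:
        keep_t, keep_rr, keep_fl = [], [], []
        i = 0
        while i < rrs_a.size:
            if rng.random() < config.artifact_rate and 0 < i < rrs_a.size - 1:
                if rng.random() < 0.5:
                    # missed beat: this interval merges into the next
                    merged = rrs_a[i] + rrs_a[i + 1]
                    keep_t.append(times_a[i + 1])
                    keep_rr.append(merged)
                    keep_fl.append(MISSED)
                    i += 2
                    continue
                # ectopic: split the interval in two
                u = rng.uniform(0.3, 0.5)
                keep_t.append(times_a[i] - rrs_a[i] * (1 - u) / 1000.0)
                keep_rr.append(rrs_a[i] * u)
                keep_fl.append(ECTOPIC)
                keep_t.append(times_a[i])
                keep_rr.append(rrs_a[i] * (1 - u))
                keep_fl.append(ECTOPIC)
                i += 1
                continue
            keep_t.append(times_a[i])
            keep_rr.append(rrs_a[i])
            keep_fl.append(VALID)
            i += 1
        times_a = np.asarray(keep_t)
        rrs_a = np.asarray(keep_rr)
        flags = np.asarray(keep_fl, dtype="<U14")

    # the analyzer must rediscover artifacts: present everything as valid
    flags_out = np.full(rrs_a.size, VALID, dtype="<U14")
    return BeatSeries(beat_time=times_a, rr=rrs_a, flag=flags_out)


@dataclass
class ExperimentResult:
    config: ScenarioConfig
    comparisons: dict[str, PairedComparison]
    per_subject: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def table(self):
        from .stats import comparison_table
        return comparison_table(list(self.comparisons.values()))


def _subject_indices(series: BeatSeries, drug_time: float) -> dict[str, tuple[float, float]]:
    cleaned = clean(series)
    signal = resample_uniform(cleaned)
    fsi = fsi_trace(signal)
    spec = spectral_trace(signal)
    t_b0, t_b1 = drug_time + _PERIOD_OFFSETS[0], drug_time + _PERIOD_OFFSETS[1]
    t_a0, t_a1 = drug_time + _PERIOD_OFFSETS[2], drug_time + _PERIOD_OFFSETS[3]
    out: dict[str, tuple[float, float]] = {}
    out["FSI"] = (period_mean(fsi, t_b0, t_b1), period_mean(fsi, t_a0, t_a1))
    for band in ("hf", "lf", "nhf"):
        tr = spec.trace(band)
        out[band.upper() if band != "nhf" else "nHF"] = (
            period_mean(tr, t_b0, t_b1), period_mean(tr, t_a0, t_a1))
    out["RMSSD"] = (rmssd(cleaned, t_b0, t_b1), rmssd(cleaned, t_a0, t_a1))
    return out


def run_experiment(config: ScenarioConfig) -> ExperimentResult:
    """Generate a cohort, run the full pipeline, and compare periods.

    Analysis periods are 10-5 min before and 5-10 min after ``drug_time``
    (windows inside the +-5 min injection guard are never analyzed).
    """
    config.validate()
    if config.drug_time < 600.0 or config.duration - config.drug_time < 600.0:
        raise ValueError("need >= 10 min of recording on each side of drug_time")
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    per_index: dict[str, list[tuple[float, float]]] = {}
    n_failed = 0
    for ss in seeds:
        try:
            series = generate_subject(config, ss)
            vals = _subject_indices(series, config.drug_time)
        except (ValueError, RuntimeError):
            n_failed += 1
            continue
        for k, v in vals.items():
            per_index.setdefault(k, []).append(v)
    n_ok = config.n_subjects - n_failed
    if n_ok < 3:
        raise RuntimeError(f"only {n_ok} subjects completed; need >= 3")
    comparisons = {}
    per_subject = {}
    for k, pairs in per_index.items():
        arr = np.asarray(pairs)
        comparisons[k] = compare_paired(arr[:, 0], arr[:, 1], name=k)
        per_subject[k] = arr
    return ExperimentResult(config=config, comparisons=comparisons,
                            per_subject=per_subject)


def adversarial_windows(n: int, seed: int, n_samples: int = 512,
                        rate: float = 8.0) -> Iterator[np.ndarray]:
    """Yield `n` stress-test windows for the index's output-bound checks.

    Cycles through extreme sinusoids (amplitudes 0.1-200 ms, frequencies
    0.01-3.5 Hz), two-tone mixtures, pure noise, impulses on a constant
    baseline, and noisy sinusoids.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / rate
    base = 400.0
    for k in range(n):
        kind = k % 5
        if kind == 0:
            amp = float(np.exp(rng.uniform(np.log(0.1), np.log(200.0))))
            f = float(np.exp(rng.uniform(np.log(0.01), np.log(3.5))))
            w = base + amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        elif kind == 1:
            amps = np.exp(rng.uniform(np.log(0.1), np.log(200.0), size=2))
            fs = np.exp(rng.uniform(np.log(0.01), np.log(3.5), size=2))
            ph = rng.uniform(0, 2 * np.pi, size=2)
            w = base + sum(a * np.sin(2 * np.pi * f * t + p)
                           for a, f, p in zip(amps, fs, ph))
        elif kind == 2:
            sd = float(np.exp(rng.uniform(np.log(0.1), np.log(50.0))))
            w = base + rng.normal(0.0, sd, size=n_samples)
        elif kind == 3:
            w = np.full(n_samples, base)
            n_spikes = int(rng.integers(1, 6))
            pos = rng.integers(0, n_samples, size=n_spikes)
            w[pos] += rng.choice([-1.0, 1.0], size=n_spikes) * \
                np.exp(rng.uniform(np.log(0.1), np.log(200.0), size=n_spikes))
        else:
            amp = float(np.exp(rng.uniform(np.log(0.1), np.log(200.0))))
            f = float(np.exp(rng.uniform(np.log(0.01), np.log(3.5))))
            w = base + amp * np.sin(2 * np.pi * f * t) + \
                rng.normal(0.0, 0.3 * amp, size=n_samples)
        yield w
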