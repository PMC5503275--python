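# fetalhrv

Heart-rate-variability analysis of beat-to-beat R-R interval series, built
around a **fetal stress index (FSI)**: a 0–100 parasympathetic-tone index
computed by mean-centring and norm-normalizing a sliding 64-s window of the
8 Hz-resampled R-R signal, high-pass filtering it with a 4-tap Daubechies
dyadic wavelet filter, and measuring the minimum 16-s envelope area of the
result. The package also provides the classic comparators (RMSSD, FFT band
powers VLF/LF/HF and normalized HF from a 256-s Bartlett-tapered window),
paired before/after statistics (exact + asymptotic Wilcoxon signed-rank,
paired Cohen's d, %CV, median/quartile summaries), and a seeded synthetic
generator of fetal-like R-R series that emulates autonomic-blockade
(atropine / propranolol) experiments end to end.

## Layout

| module | contents |
|---|---|
| `fetalhrv.beats` | `BeatSeries` / `UniformSeries` containers |
| `fetalhrv.preprocess` | artifact flagging (running-median rule), interpolation repair, 8 Hz resampling |
| `fetalhrv.wavelet` | orthonormal periodized 4-tap Daubechies DWT and the dyadic high-pass filter |
| `fetalhrv.fsi` | per-window FSI pipeline, sliding 1 Hz trace, period means |
| `fetalhrv.spectral` | RMSSD, Bartlett-tapered band powers, sliding spectral trace |
| `fetalhrv.stats` | Wilcoxon (exact + asymptotic), Cohen's d_z, %CV, summaries, report tables |
| `fetalhrv.simulate` | scenario config, subject generator, in-silico experiment harness, adversarial window suite |
| `fetalhrv.io` / `fetalhrv.cli` | CSV/YAML round-tripping and the `fetalhrv` command |

## CLI

```sh
# analyze a recording (CSV with header time_s,rr_ms[,flag], or a bare rr column)
fetalhrv compute recording.csv --out results/ --period 100 400 --debug-window 300

# spectral trace only
fetalhrv spectrum recording.csv --out results/

# generate a synthetic cohort from a scenario YAML
fetalhrv simulate scenario.yaml --out cohort/

# full in-silico before/after experiment -> Table-style report (CSV + Markdown)
fetalhrv experiment scenario.yaml --out experiment/

# render a report CSV as Markdown
fetalhrv report experiment/report.csv
```

A scenario YAML sets any `ScenarioConfig` field, e.g.:

```yaml
drug: atropine       # none | atropine | propranolol
drug_time: 750.0     # s; experiment analyses 10-5 min before and 5-10 min after
n_subjects: 7
basal_hr: 156.0      # bpm
seed: 7
```

Every output directory contains `config.json` with the resolved settings and
package version.

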