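"""CSV/YAML round-tripping for beat series, traces, and scenarios.

Beat files are CSV or TSV with header ``time_s,rr_ms[,flag]``, or a
headerless single column of consecutive R-R intervals in ms (beat times then
come from the cumulative sum).  All errors carry 1-based line numbers.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import yaml

from .beats import FLAGS, VALID, BeatSeries
from .fsi import IndexTrace
from .simulate import ScenarioConfig
from .spectral import SpectralTrace

__all__ = ["read_beats", "write_beats", "write_trace", "read_trace",
           "write_spectral_trace", "read_spectral_trace",
           "load_scenario", "dump_scenario"]


class BeatFileError(ValueError):
    pass


def _sniff_delimiter(header: str) -> str:
    return "\t" if "\t" in header else ","


def read_beats(path) -> BeatSeries:
    path = Path(path)
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise BeatFileError(f"{path}: empty file")
        fh.seek(0)
        delim = _sniff_delimiter(first)
        if first.lower().lstrip().startswith("time_s"):
            return _read_beats_table(fh, path, delim)
        return _read_beats_column(fh, path)


def _read_beats_table(fh, path: Path, delim: str) -> BeatSeries:
    reader = csv.reader(fh, delimiter=delim)
    header = [c.strip().lower() for c in next(reader)]
    if header[:2] != ["time_s", "rr_ms"]:
        raise BeatFileError(f"{path}:1: expected header time_s,rr_ms[,flag]")
    has_flag = len(header) >= 3 and header[2] == "flag"
    times, rrs, flags = [], [], []
    for lineno, row in enumerate(reader, start=2):
        if not row or not "".join(row).strip():
            continue
        try:
            times.append(float(row[0]))
            rrs.append(float(row[1]))
        except (ValueError, IndexError) as exc:
            raise BeatFileError(f"{path}:{lineno}: bad row {row!r}") from exc
        if rrs[-1] <= 0:
            raise BeatFileError(f"{path}:{lineno}: non-positive rr_ms {rrs[-1]}")
        if has_flag and len(row) > 2 and row[2].strip():
            fl = row[2].strip().lower()
            if fl not in FLAGS:
                raise BeatFileError(f"{path}:{lineno}: unknown flag {fl!r}")
            flags.append(fl)
        else:
            flags.append(VALID)
    if not times:
        raise BeatFileError(f"{path}: no data rows")
    try:
        return BeatSeries(np.array(times), np.array(rrs), np.array(flags))
    except ValueError as exc:
        raise BeatFileError(f"{path}: {exc}") from exc


def _read_beats_column(fh, path: Path) -> BeatSeries:
    rrs = []
    for lineno, line in enumerate(fh, start=1):
        token = line.strip().split(",")[0].strip()
        if not token:
            continue
        try:
            rr = float(token)
        except ValueError as exc:
            raise BeatFileError(f"{path}:{lineno}: not a number: {token!r}") from exc
        if rr <= 0:
            raise BeatFileError(f"{path}:{lineno}: non-positive rr_ms {rr}")
        rrs.append(rr)
    if not rrs:
        raise BeatFileError(f"{path}: no data rows")
    return BeatSeries.from_rr(np.array(rrs))


def write_beats(series: BeatSeries, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "rr_ms", "flag"])
        for t, rr, fl in zip(series.beat_time, series.rr, series.flag):
            w.writerow([f"{t:.9f}", f"{rr:.9f}", fl])


def write_trace(trace: IndexTrace, path, name: str | None = None) -> None:
    name = name or trace.name
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", name, "valid"])
        for t, v, ok in zip(trace.times, trace.values, trace.valid):
            w.writerow([f"{t:.9f}", "" if np.isnan(v) else f"{v:.9f}", int(ok)])


def read_trace(path) -> IndexTrace:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        name = header[1]
        times, values, valid = [], [], []
        for row in reader:
            if not row:
                continue
            times.append(float(row[0]))
            values.append(float(row[1]) if row[1] != "" else np.nan)
            valid.append(bool(int(row[2])))
    return IndexTrace(np.array(times), np.array(values),
                      np.array(valid, dtype=bool), name=name)


def write_spectral_trace(trace: SpectralTrace, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "vlf", "lf", "hf", "nhf"])
        for i in range(len(trace)):
            row = [f"{trace.times[i]:.9f}"]
            for band in (trace.vlf, trace.lf, trace.hf, trace.nhf):
                row.append("" if np.isnan(band[i]) else f"{band[i]:.9f}")
            w.writerow(row)


def read_spectral_trace(path) -> SpectralTrace:
    data = np.genfromtxt(path, delimiter=",", skip_header=1)
    data = np.atleast_2d(data)
    return SpectralTrace(times=data[:, 0], vlf=data[:, 1], lf=data[:, 2],
                         hf=data[:, 3], nhf=data[:, 4])


def load_scenario(path) -> ScenarioConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: scenario file must be a YAML mapping")
    return ScenarioConfig.from_dict(raw)


def dump_scenario(config: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
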