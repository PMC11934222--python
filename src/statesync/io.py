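"""Readers and writers for the plain-text interchange formats.

Spikes: TSV ``unit_id<TAB>time_s`` (header optional); epochs: TSV
``start_s<TAB>end_s<TAB>label`` with half-open intervals; LFP: either a
flat little-endian int16 binary with a YAML sidecar header (rate_hz,
scale), or a two-column TSV (time_s, value).  Writers round-trip to full
float precision (``repr``-style formatting).
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import EpochSet, SpikeTrain
from .lfp import LFP


def _has_header(path, expect_numeric_col: int) -> bool:
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        return False
    tok = first.rstrip("\n").split("\t")
    try:
        float(tok[expect_numeric_col])
        return False
    except (ValueError, IndexError):
        return True


def _parse_float_column(series, path, colname, header):
    """Exact (correctly rounded) float parsing with line-number errors."""
    try:
        vals = series.to_numpy(dtype=float)
    except (TypeError, ValueError):
        vals = np.empty(len(series))
        for i, v in enumerate(series):
            try:
                vals[i] = float(v)
            except (TypeError, ValueError):
                line = i + (2 if header == 0 else 1)
                raise ValueError(
                    f"{path}: malformed {colname} on line {line}") from None
    if np.isnan(vals).any():
        line = int(np.flatnonzero(np.isnan(vals))[0]) + (2 if header == 0
                                                         else 1)
        raise ValueError(f"{path}: malformed {colname} on line {line}")
    return vals


def read_spikes(path, t_start: float = 0.0, t_end: float | None = None,
                strict: bool = False) -> list[SpikeTrain]:
    """Read per-unit spike trains from a unit/time TSV."""
    path = Path(path)
    if os.path.getsize(path) == 0:
        return []
    header = 0 if _has_header(path, 1) else None
    df = pd.read_csv(path, sep="\t", header=header,
                     names=["unit_id", "time_s"],
                     dtype={"unit_id": str, "time_s": object},
                     float_precision="round_trip")
    df["time_s"] = _parse_float_column(df["time_s"], path, "time", header)
    if t_end is None:
        t_end = float(df["time_s"].max()) if len(df) else t_start
    trains = []
    for uid, g in df.groupby("unit_id", sort=True):
        t = g["time_s"].to_numpy(float)
        if np.any(np.diff(t) < 0):
            if strict:
                raise ValueError(f"{path}: unsorted spike times for {uid}")
            warnings.warn(f"{path}: sorting spike times of unit {uid}",
                          stacklevel=2)
            t = np.sort(t)
        trains.append(SpikeTrain(uid, t, t_start, t_end))
    return trains


def write_spikes(path, trains) -> None:
    with open(path, "w") as fh:
        fh.write("unit_id\ttime_s\n")
        for tr in trains:
            for t in tr.times:
                fh.write(f"{tr.unit_id}\t{float(t)!r}\n")


def read_epochs(path, strict: bool = False) -> EpochSet:
    """Read a labeled epoch set from a start/end/label TSV."""
    path = Path(path)
    header = 0 if _has_header(path, 0) else None
    df = pd.read_csv(path, sep="\t", header=header,
                     names=["start_s", "end_s", "label"],
                     dtype={"start_s": object, "end_s": object},
                     float_precision="round_trip")
    for col in ("start_s", "end_s"):
        df[col] = _parse_float_column(df[col], path, col, header)
    try:
        return EpochSet(df["start_s"].to_numpy(float),
                        df["end_s"].to_numpy(float),
                        df["label"].to_numpy(object))
    except ValueError:
        if strict:
            raise
        # tolerate tiny within-label overlaps by clipping starts
        starts = df["start_s"].to_numpy(float)
        ends = df["end_s"].to_numpy(float)
        labels = df["label"].to_numpy(object)
        order = np.argsort(starts, kind="stable")
        starts, ends, labels = starts[order], ends[order], labels[order]
        for lab in set(labels.tolist()):
            m = np.flatnonzero(labels == lab)
            for i, j in zip(m[:-1], m[1:]):
                if starts[j] < ends[i]:
                    starts[j] = ends[i]
        keep = ends > starts
        warnings.warn(f"{path}: clipped overlapping epochs", stacklevel=2)
        return EpochSet(starts[keep], ends[keep], labels[keep])


def write_epochs(path, epochs: EpochSet) -> None:
    with open(path, "w") as fh:
        fh.write("start_s\tend_s\tlabel\n")
        for s, e, lab in epochs.to_tuples():
            fh.write(f"{float(s)!r}\t{float(e)!r}\t{lab}\n")


def write_lfp(path, lfp: LFP, scale: float | None = None) -> None:
    """Write LFP as little-endian int16 binary plus a YAML sidecar
    (``<path>.yaml``) carrying rate, scale and t_start."""
    path = Path(path)
    if scale is None:
        peak = float(np.max(np.abs(lfp.samples))) or 1.0
        scale = peak / 32000.0
    ints = np.clip(np.round(lfp.samples / scale), -32768, 32767)
    ints.astype("<i2").tofile(path)
    with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
        yaml.safe_dump({"rate_hz": float(lfp.rate), "scale": float(scale),
                        "t_start": float(lfp.t_start), "dtype": "int16_le"},
                       fh)


def read_lfp(path) -> LFP:
    """Read LFP from an int16 binary (+ YAML sidecar) or a 2-column TSV."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh)
        raw = np.fromfile(path, dtype="<i2")
        return LFP(raw.astype(np.float32) * float(meta["scale"]),
                   float(meta["rate_hz"]), float(meta.get("t_start", 0.0)))
    header = 0 if _has_header(path, 0) else None
    df = pd.read_csv(path, sep="\t", header=header,
                     names=["time_s", "value"],
                     float_precision="round_trip")
    t = df["time_s"].to_numpy(float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.ptp(dt) > 1e-6:
        raise ValueError(f"{path}: sample times must be evenly spaced")
    return LFP(df["value"].to_numpy(np.float32), 1.0 / dt.mean(), float(t[0]))


def write_dce_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_dce_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
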