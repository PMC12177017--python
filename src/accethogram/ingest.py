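"""Read logger and annotation CSVs, synchronise on UTC, and label samples.

Logger exports vary in delimiter; both comma and semicolon are accepted,
detected from the header line.  Behaviour labels are applied per sample
with the bout-trimming rule used when ground-truthing against video: the
first and last ``trim_s`` seconds of every bout are discarded to absorb
clock-synchronisation error.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .types import AccelTrace, AnnotationSet, LabeledSeries

__all__ = ["read_accel_csv", "read_annotation_csv", "align_labels"]

_ACCEL_COLUMNS = ["timestamp", "ax_g", "ay_g", "az_g"]
_ANN_COLUMNS = ["behaviour", "start_utc", "stop_utc"]


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return ";" if header.count(";") > header.count(",") else ","


def _parse_utc_seconds(values: pd.Series) -> np.ndarray:
    ts = pd.to_datetime(values, utc=True, format="ISO8601")
    return ts.astype("int64").to_numpy() / 1e9


def read_accel_csv(
    path: str | os.PathLike,
    individual_id: str | None = None,
    species: str = "",
    position: str | None = None,
    dynamic_range_g: float | None = None,
    resolution_bits: int = 8,
) -> AccelTrace:
    """Read a logger CSV (``timestamp,ax_g,ay_g,az_g``) into an AccelTrace.

    The sampling rate is inferred from the median timestep and recorded.
    Individual id and position default to parsing the ``<id>_<position>.csv``
    file-name convention.  The dynamic range defaults to the smallest of
    {2, 4} g that bounds the data.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    missing = [c for c in _ACCEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    t = _parse_utc_seconds(df["timestamp"])
    if len(t) >= 2:
        dt = np.diff(t)
        bad = np.where(dt <= 0)[0]
        if len(bad):
            # offending sample index bad[0]+1; +1 header +1 one-based
            raise ValueError(
                f"{path.name}: non-monotone timestamp at file row {bad[0] + 3} "
                f"(duplicate or out of order)"
            )
        rate = 1.0 / float(np.median(dt))
    else:
        rate = float("nan")
    if individual_id is None or position is None:
        stem = path.stem
        if "_" in stem:
            guess_id, _, guess_pos = stem.rpartition("_")
            individual_id = individual_id or guess_id
            position = position or guess_pos
    a = df[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float)
    if dynamic_range_g is None:
        amax = float(np.abs(a).max()) if len(a) else 0.0
        dynamic_range_g = 2.0 if amax <= 2.0 else 4.0 if amax <= 4.0 else float(np.ceil(amax))
    return AccelTrace(
        individual_id=individual_id or path.stem,
        species=species,
        position=position or "scute3",
        t=t,
        ax=a[:, 0],
        ay=a[:, 1],
        az=a[:, 2],
        sample_rate_hz=round(rate, 3) if np.isfinite(rate) else rate,
        dynamic_range_g=dynamic_range_g,
        resolution_bits=resolution_bits,
    )


def read_annotation_csv(path: str | os.PathLike, individual_id: str | None = None) -> AnnotationSet:
    """Read a behaviour annotation CSV (``behaviour,start_utc,stop_utc``)
    into a sorted, validated AnnotationSet (overlaps raise)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    missing = [c for c in _ANN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    if individual_id is None:
        individual_id = path.stem.removesuffix("_annotations")
    if len(df) == 0:
        return AnnotationSet(individual_id=individual_id, bouts=[])
    starts = _parse_utc_seconds(df["start_utc"])
    stops = _parse_utc_seconds(df["stop_utc"])
    bouts = [(str(b), float(s), float(e)) for b, s, e in zip(df["behaviour"], starts, stops)]
    return AnnotationSet(individual_id=individual_id, bouts=bouts)


def align_labels(trace: AccelTrace, ann: AnnotationSet, trim_s: float = 1.0) -> LabeledSeries:
    """Label each sample with its bout's behaviour, trimming ``trim_s``
    seconds from both ends of every bout.

    A sample at time t is labelled with bout (behaviour, start, end) iff
    t lies in the half-open interval [start + trim_s, end - trim_s); the
    half-open convention keeps adjacent bouts from sharing a sample.  Bouts
    shorter than ``2 * trim_s`` contribute no labels.  Unlabelled samples
    are retained with null labels.
    """
    if trace.individual_id != ann.individual_id:
        raise ValueError(
            f"trace individual '{trace.individual_id}' != annotation "
            f"individual '{ann.individual_id}'"
        )
    if trim_s < 0:
        raise ValueError("trim_s must be >= 0")
    n = len(trace)
    label = np.full(n, None, dtype=object)
    bout_id = np.full(n, -1, dtype=int)
    if n == 0:
        return LabeledSeries(trace=trace, label=label, bout_id=bout_id)
    t0 = trace.t[0]
    fs = trace.sample_rate_hz
    for idx, (behaviour, start, end) in enumerate(ann.bouts):
        a = start + trim_s
        b = end - trim_s
        if b <= a:
            continue
        # half-open [a, b) on the uniform grid t0 + k/fs
        i0 = int(np.ceil((a - t0) * fs - 1e-6))
        i1 = int(np.ceil((b - t0) * fs - 1e-6))
        i0 = max(i0, 0)
        i1 = min(i1, n)
        if i1 > i0:
            label[i0:i1] = behaviour
            bout_id[i0:i1] = idx
    return LabeledSeries(trace=trace, label=label, bout_id=bout_id)
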