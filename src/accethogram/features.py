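"""Per-window summary metrics: moments and extrema per axis, dynamic body
acceleration (ODBA, VeDBA) and posture (pitch/roll) statistics.

The canonical 18-metric set:

==============  =============================================================
mean_x/y/z      per-axis mean over the window (static acceleration), g
sd_x/y/z        per-axis sample SD (n-1 denominator), g
min_x/y/z       per-axis minimum, g
max_x/y/z       per-axis maximum, g
odba            mean over samples of |dx| + |dy| + |dz|, g
vedba           mean over samples of sqrt(dx^2 + dy^2 + dz^2), g
pitch_mean/sd   per-sample pitch = atan2(ax, hypot(ay, az)), degrees
roll_mean/sd    per-sample roll = atan2(ay, az), degrees
==============  =============================================================

where (dx, dy, dz) is the dynamic component: the sample minus the window
mean per axis.  VeDBA is the Euclidean-norm analogue of ODBA and the usual
energy-expenditure proxy.  By the L1/L2 norm inequalities in three
dimensions, vedba <= odba <= sqrt(3) * vedba holds for every window.

An alternative metric list can be registered under a name and selected via
``registry=``, so a different supplement-defined set can be swapped in
without touching the pipeline.
"""

from __future__ import annotations

from collections.abc import Callable, Sequence

import numpy as np
import pandas as pd

from .types import LabeledWindow

__all__ = [
    "FEATURE_NAMES",
    "static_dynamic_split",
    "compute_features",
    "build_feature_table",
    "register_metric_set",
    "METADATA_COLUMNS",
]

FEATURE_NAMES = (
    "mean_x", "mean_y", "mean_z",
    "sd_x", "sd_y", "sd_z",
    "min_x", "min_y", "min_z",
    "max_x", "max_y", "max_z",
    "odba", "vedba",
    "pitch_mean", "roll_mean", "pitch_sd", "roll_sd",
)

METADATA_COLUMNS = ("individual_id", "species", "position", "window_s", "freq_hz", "behaviour", "t0")


def static_dynamic_split(
    window: LabeledWindow,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Split each axis into static (window mean, constant array) and dynamic
    (sample minus static) components; static + dynamic reconstructs the
    input exactly."""
    if len(window) == 0:
        raise ValueError("empty window")
    static: dict[str, np.ndarray] = {}
    dynamic: dict[str, np.ndarray] = {}
    for name, arr in (("x", window.ax), ("y", window.ay), ("z", window.az)):
        m = float(np.mean(arr))
        static[name] = np.full_like(arr, m)
        dynamic[name] = arr - m
    return static, dynamic


def _canonical18(window: LabeledWindow) -> dict[str, float]:
    x, y, z = window.ax, window.ay, window.az
    _, dyn = static_dynamic_split(window)
    dx, dy, dz = dyn["x"], dyn["y"], dyn["z"]
    pitch = np.degrees(np.arctan2(x, np.hypot(y, z)))
    roll = np.degrees(np.arctan2(y, z))
    return {
        "mean_x": float(np.mean(x)), "mean_y": float(np.mean(y)), "mean_z": float(np.mean(z)),
        "sd_x": float(np.std(x, ddof=1)), "sd_y": float(np.std(y, ddof=1)),
        "sd_z": float(np.std(z, ddof=1)),
        "min_x": float(np.min(x)), "min_y": float(np.min(y)), "min_z": float(np.min(z)),
        "max_x": float(np.max(x)), "max_y": float(np.max(y)), "max_z": float(np.max(z)),
        "odba": float(np.mean(np.abs(dx) + np.abs(dy) + np.abs(dz))),
        "vedba": float(np.mean(np.sqrt(dx**2 + dy**2 + dz**2))),
        "pitch_mean": float(np.mean(pitch)), "roll_mean": float(np.mean(roll)),
        "pitch_sd": float(np.std(pitch, ddof=1)), "roll_sd": float(np.std(roll, ddof=1)),
    }


_REGISTRY: dict[str, Callable[[LabeledWindow], dict[str, float]]] = {
    "canonical18": _canonical18,
}


def register_metric_set(name: str, fn: Callable[[LabeledWindow], dict[str, float]]) -> None:
    """Register an alternative per-window metric function under ``name``."""
    _REGISTRY[name] = fn


def compute_features(window: LabeledWindow, registry: str = "canonical18") -> dict[str, float]:
    """Compute the per-window summary-metric vector.

    Requires at least two samples (the SD uses the unbiased n-1
    denominator).  All values are finite.
    """
    if len(window) < 2:
        raise ValueError("window needs >= 2 samples for SD metrics")
    feats = _REGISTRY[registry](window)
    if not all(np.isfinite(v) for v in feats.values()):
        raise ValueError("non-finite feature value")
    return feats


def build_feature_table(
    windows: Sequence[LabeledWindow], registry: str = "canonical18"
) -> pd.DataFrame:
    """One row per window: metadata columns then the metric columns, ordered
    by (individual_id, t0).  All windows must share window_s and freq_hz."""
    feature_names = FEATURE_NAMES if registry == "canonical18" else None
    if len(windows) == 0:
        cols = list(METADATA_COLUMNS) + list(feature_names or FEATURE_NAMES)
        return pd.DataFrame(columns=cols)
    if len({(w.window_s, w.freq_hz) for w in windows}) > 1:
        raise ValueError("mixed window_s / freq_hz in one feature table")
    rows = []
    for w in sorted(windows, key=lambda w: (w.individual_id, w.position, w.t0)):
        row = {
            "individual_id": w.individual_id,
            "species": w.species,
            "position": w.position,
            "window_s": w.window_s,
            "freq_hz": w.freq_hz,
            "behaviour": w.behaviour,
            "t0": w.t0,
        }
        row.update(compute_features(w, registry=registry))
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.isna().any().any():
        raise ValueError("missing metric values in feature table")
    return df.reset_index(drop=True)
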