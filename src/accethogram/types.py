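"""Core domain types for the accelerometer ethogram pipeline.

Axis convention (fixed package-wide): x = surge (anterior), y = sway
(left), z = heave (dorsal).  A motionless animal on a level surface reads
(0, 0, 1) g.  Pitch is the rotation of the surge axis out of the
horizontal plane, roll the rotation of the sway/heave pair about surge:

    pitch = atan2(ax, sqrt(ay^2 + az^2)),   roll = atan2(ay, az)

both in degrees downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

POSITIONS = ("scute1", "scute3")

#: sampling frequencies (Hz) supported by the windowing stage
SUPPORTED_FREQUENCIES = (100, 50, 25, 12, 10, 8, 4, 2)

#: supported window lengths (s)
SUPPORTED_WINDOWS = (1, 2)


@dataclass(frozen=True)
class BehaviourSpec:
    """One ethogram behaviour as a generative recipe.

    Parameters
    ----------
    name
        Behaviour label.
    pitch_deg, roll_deg
        Mean body posture while the behaviour is performed.
    osc_freq_hz
        Dominant limb-beat frequency; 0 for motionless behaviours.
    osc_amp_g
        Peak oscillation amplitude on the surge axis.
    noise_sd_g
        SD of i.i.d. Gaussian sensor/movement noise per axis.
    bout_mean_s, bout_min_s
        Mean and floor of the exponential bout-duration distribution.
    """

    name: str
    pitch_deg: float = 0.0
    roll_deg: float = 0.0
    osc_freq_hz: float = 0.0
    osc_amp_g: float = 0.0
    noise_sd_g: float = 0.0
    bout_mean_s: float = 20.0
    bout_min_s: float = 3.0

    def __post_init__(self) -> None:
        if self.osc_amp_g < 0:
            raise ValueError(f"{self.name}: osc_amp_g must be >= 0")
        if self.noise_sd_g < 0:
            raise ValueError(f"{self.name}: noise_sd_g must be >= 0")
        if self.osc_freq_hz < 0:
            raise ValueError(f"{self.name}: osc_freq_hz must be >= 0")
        if self.bout_min_s < 3:
            raise ValueError(
                f"{self.name}: bout_min_s must be >= 3 s so a bout survives "
                "the 1 s start/end trim and still yields a window"
            )
        if self.bout_mean_s < self.bout_min_s:
            raise ValueError(f"{self.name}: bout_mean_s < bout_min_s")


@dataclass(frozen=True)
class PositionEffect:
    """Per-position signal degradation: multiplicative gain on the dynamic
    (movement) component plus additive Gaussian noise."""

    gain: float = 1.0
    extra_noise_sd_g: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.extra_noise_sd_g < 0:
            raise ValueError("extra_noise_sd_g must be >= 0")


@dataclass
class CohortConfig:
    """Recording/generation settings for one synthetic cohort."""

    species: str
    n_individuals: int
    behaviours: list[BehaviourSpec]
    transition_weights: np.ndarray
    duration_s: float = 300.0
    sample_rate_hz: int = 100
    dynamic_range_g: float = 2.0
    resolution_bits: int = 8
    position_effect: dict[str, PositionEffect] = field(
        default_factory=lambda: {p: PositionEffect() for p in POSITIONS}
    )
    individual_sd: float = 0.0
    seed: int = 0
    start_utc: float = 0.0

    def __post_init__(self) -> None:
        self.transition_weights = np.asarray(self.transition_weights, dtype=float)
        k = len(self.behaviours)
        if self.transition_weights.shape != (k, k):
            raise ValueError(
                f"transition_weights must be {k}x{k} (square over behaviours), "
                f"got {self.transition_weights.shape}"
            )
        if np.any(self.transition_weights < 0):
            raise ValueError("transition_weights must be non-negative")
        if np.any(np.diag(self.transition_weights) != 0):
            raise ValueError("transition_weights diagonal must be zero")
        if k > 1 and np.any(self.transition_weights.sum(axis=1) <= 0):
            raise ValueError("every transition_weights row needs a positive sum")
        if self.n_individuals < 4:
            raise ValueError("n_individuals must be >= 4")
        if self.sample_rate_hz % 2 != 0:
            raise ValueError("sample_rate_hz must be divisible by 2")
        if self.dynamic_range_g <= 0:
            raise ValueError("dynamic_range_g must be > 0")
        names = [b.name for b in self.behaviours]
        if len(set(names)) != len(names):
            raise ValueError("behaviour names must be unique")

    @property
    def behaviour_names(self) -> list[str]:
        return [b.name for b in self.behaviours]


@dataclass
class AccelTrace:
    """Timestamped tri-axial acceleration for one individual and tag position.

    ``t`` holds UTC epoch seconds on a uniform grid of step
    ``1/sample_rate_hz``.  Uniformity is validated to the representable
    precision of float64 at the magnitude of the timestamps (absolute epoch
    seconds cannot hold a 10 ms grid to 1e-9 s; the check scales with eps).
    """

    individual_id: str
    species: str
    position: str
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    sample_rate_hz: float
    dynamic_range_g: float
    resolution_bits: int

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise ValueError(f"position must be one of {POSITIONS}")
        self.t = np.asarray(self.t, dtype=float)
        for name in ("ax", "ay", "az"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.t.shape:
                raise ValueError(f"{name} length != t length")
            if np.any(np.abs(arr) > self.dynamic_range_g + 1e-12):
                raise ValueError(f"{name} exceeds dynamic range ±{self.dynamic_range_g} g")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            step = 1.0 / self.sample_rate_hz
            tol = max(1e-9, 8 * np.finfo(float).eps * max(abs(self.t[0]), abs(self.t[-1])))
            if np.max(np.abs(dt - step)) > tol:
                raise ValueError("timestamps are not on a uniform grid")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class AnnotationSet:
    """Ground-truth behaviour bouts for one individual, sorted and
    non-overlapping.  Each bout is ``(behaviour, start_utc, end_utc)``."""

    individual_id: str
    bouts: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        for b, s, e in self.bouts:
            if e <= s:
                raise ValueError(f"bout '{b}' has end <= start ({s} .. {e})")
        self.bouts = sorted(self.bouts, key=lambda b: b[1])
        for (b1, s1, e1), (b2, s2, e2) in zip(self.bouts, self.bouts[1:]):
            if s2 < e1 - 1e-9:
                raise ValueError(
                    f"overlapping bouts: '{b1}' ({s1}..{e1}) and '{b2}' ({s2}..{e2})"
                )

    @property
    def total_duration_s(self) -> float:
        return float(sum(e - s for _, s, e in self.bouts))


@dataclass
class LabeledSeries:
    """An AccelTrace with per-sample behaviour labels after bout trimming.

    ``label[i]`` is the behaviour name or None; ``bout_id[i]`` indexes the
    originating bout or -1.  Trimmed margins and unannotated spans are
    unlabelled but retained so coverage can be reported.
    """

    trace: AccelTrace
    label: np.ndarray  # object array of str | None
    bout_id: np.ndarray  # int array, -1 for unlabelled

    def __post_init__(self) -> None:
        if len(self.label) != len(self.trace) or len(self.bout_id) != len(self.trace):
            raise ValueError("label/bout_id must match trace length")

    @property
    def n_labelled(self) -> int:
        return int(np.sum(self.bout_id >= 0))


@dataclass
class LabeledWindow:
    """A fixed-duration, single-behaviour segment: the unit of classification."""

    individual_id: str
    species: str
    position: str
    behaviour: str
    window_s: float
    freq_hz: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    t0: float

    def __post_init__(self) -> None:
        n = len(self.ax)
        if not (len(self.ay) == len(self.az) == n):
            raise ValueError("axis arrays must share a length")

    def __len__(self) -> int:
        return len(self.ax)
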