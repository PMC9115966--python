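"""Dynamic-scan frame schedules, measurement weights and curve containers.

A dynamic PET acquisition groups list-mode data into contiguous time
frames.  All times are kept in two conventions: frame *durations* in
seconds (as protocols quote them) and frame *mid-times* in minutes
post-injection (as kinetic models need them).  The tracer is typically
injected a short while after data collection starts, so the earliest
frame(s) may have negative mid-times; those frames are background and are
excluded from every fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: 18F decay constant, 1/min (half-life 109.77 min).
F18_DECAY_CONSTANT = np.log(2.0) / 109.77


@dataclass(frozen=True)
class FrameSchedule:
    """Frame durations and timing of a dynamic scan.

    Parameters
    ----------
    durations_s :
        Duration of each frame in seconds.
    injection_offset_s :
        Time from acquisition start to tracer injection, in seconds.
        Frame times are reported relative to injection.
    """

    durations_s: np.ndarray
    injection_offset_s: float = 0.0

    def __post_init__(self):
        d = np.asarray(self.durations_s, dtype=float)
        if d.ndim != 1 or d.size == 0:
            raise ValueError("durations_s must be a non-empty 1-D sequence")
        if np.any(d <= 0):
            raise ValueError("frame durations must be positive")
        object.__setattr__(self, "durations_s", d)

    @property
    def n_frames(self) -> int:
        return self.durations_s.size

    @property
    def start_times_min(self) -> np.ndarray:
        """Frame start times, minutes post-injection."""
        edges = np.concatenate([[0.0], np.cumsum(self.durations_s)])
        return (edges[:-1] - self.injection_offset_s) / 60.0

    @property
    def end_times_min(self) -> np.ndarray:
        edges = np.cumsum(self.durations_s)
        return (edges - self.injection_offset_s) / 60.0

    @property
    def mid_times_min(self) -> np.ndarray:
        """Frame mid-times, minutes post-injection."""
        return 0.5 * (self.start_times_min + self.end_times_min)

    @property
    def t_scan_min(self) -> float:
        """End of the last frame, minutes post-injection."""
        return float(self.end_times_min[-1])

    @property
    def post_injection(self) -> np.ndarray:
        """Boolean mask of frames that start at or after injection."""
        return self.start_times_min >= 0.0


def make_standard_schedule() -> FrameSchedule:
    """The 40-frame, 45-min dynamic breast protocol.

    Frames {1 x 30 s, 12 x 5 s, 6 x 10 s, 5 x 30 s, 10 x 60 s, 6 x 300 s}
    with injection 30 s after the start of data collection, so the single
    30 s frame is pre-injection background and the post-injection span is
    45 min (total acquisition 45.5 min).
    """
    durations = np.concatenate(
        [
            np.repeat(30.0, 1),
            np.repeat(5.0, 12),
            np.repeat(10.0, 6),
            np.repeat(30.0, 5),
            np.repeat(60.0, 10),
            np.repeat(300.0, 6),
        ]
    )
    return FrameSchedule(durations_s=durations, injection_offset_s=30.0)


@dataclass
class Curve:
    """Decay-corrected activity-concentration samples on a frame schedule."""

    schedule: FrameSchedule
    values: np.ndarray  # kBq/mL per frame

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.schedule.n_frames,):
            raise ValueError(
                f"expected {self.schedule.n_frames} values, got shape {v.shape}"
            )
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": np.arange(self.schedule.n_frames),
                "duration_s": self.schedule.durations_s,
                "mid_time_min": self.schedule.mid_times_min,
                "concentration_kBq_per_mL": self.values,
            }
        )


@dataclass
class FrameWeights:
    """Relative least-squares weights per frame.

    ``valid`` flags frames usable in fitting; excluded frames carry
    weight 0 so weighted sums can ignore the mask safely.
    """

    weights: np.ndarray
    valid: np.ndarray = field(default=None)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if self.valid is None:
            self.valid = w > 0
        self.valid = np.asarray(self.valid, dtype=bool)
        self.weights = np.where(self.valid, w, 0.0)


def compute_weights(
    schedule: FrameSchedule,
    activities,
    decay_constant: float = F18_DECAY_CONSTANT,
) -> FrameWeights:
    """Inverse-variance frame weights  w_i = (dT_i / A_i) * exp(-lambda t_i).

    dT_i is the frame duration (s), A_i the measured activity
    concentration and t_i the frame mid-time post-injection (min);
    lambda is the isotope decay constant (1/min).  Frames with
    non-positive activity, and pre-injection frames, are excluded
    (weight 0, flagged invalid).
    """
    a = np.asarray(activities, dtype=float)
    if a.shape != (schedule.n_frames,):
        raise ValueError("activities must align with the schedule")
    if decay_constant < 0:
        raise ValueError("decay_constant must be >= 0")
    valid = (a > 0) & schedule.post_injection
    if not np.any(valid):
        raise ValueError("no frame has positive activity after injection")
    w = np.zeros_like(a)
    t = schedule.mid_times_min
    w[valid] = (
        schedule.durations_s[valid] / a[valid] * np.exp(-decay_constant * t[valid])
    )
    return FrameWeights(weights=w, valid=valid)
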