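"""Dynamic-PET frame timing.

A dynamic FET acquisition is a contiguous sequence of emission frames of
increasing duration: short frames capture the tracer bolus, long late frames
give the statistics needed for quantification. All times are seconds
post-injection (p.i.) unless a function says minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameSchedule", "default_frame_schedule"]


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping frame timing for a dynamic acquisition.

    Parameters
    ----------
    frame_starts : tuple of float
        Frame start times, seconds p.i. The first frame starts at 0.
    frame_durations : tuple of float
        Frame durations in seconds, all strictly positive.
    """

    frame_starts: tuple[float, ...]
    frame_durations: tuple[float, ...]

    def __post_init__(self) -> None:
        starts = np.asarray(self.frame_starts, dtype=float)
        durs = np.asarray(self.frame_durations, dtype=float)
        if starts.size == 0 or starts.size != durs.size:
            raise ValueError("frame_starts and frame_durations must be equal, non-empty")
        if starts[0] != 0.0:
            raise ValueError("first frame must start at 0 s p.i.")
        if np.any(durs <= 0):
            raise ValueError("all frame durations must be > 0")
        if not np.allclose(starts[1:], starts[:-1] + durs[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")

    @property
    def n_frames(self) -> int:
        return len(self.frame_starts)

    @property
    def frame_ends_s(self) -> np.ndarray:
        return np.asarray(self.frame_starts) + np.asarray(self.frame_durations)

    @property
    def end_s(self) -> float:
        """End of the acquisition, seconds p.i."""
        return float(self.frame_ends_s[-1])

    @property
    def mid_times_s(self) -> np.ndarray:
        """Frame mid-times in seconds p.i."""
        return np.asarray(self.frame_starts) + 0.5 * np.asarray(self.frame_durations)

    @property
    def mid_times_min(self) -> np.ndarray:
        """Frame mid-times in minutes p.i. — the time axis of TTP images."""
        return self.mid_times_s / 60.0

    def to_dict(self) -> dict:
        return {
            "frame_starts_s": list(self.frame_starts),
            "frame_durations_s": list(self.frame_durations),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrameSchedule":
        return cls(tuple(d["frame_starts_s"]), tuple(d["frame_durations_s"]))


def default_frame_schedule() -> FrameSchedule:
    """The 16-frame clinical schedule: 7×10 s, 3×30 s, 1×2 min, 3×5 min, 2×10 min.

    Contiguous from 0 s; the final frame ends at 2380 s (39.67 min) p.i.
    """
    durations = [10.0] * 7 + [30.0] * 3 + [120.0] + [300.0] * 3 + [600.0] * 2
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(tuple(starts), tuple(durations))
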