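"""Freezing-bout detection from frame-difference motion signals.

Freezing (immobility except respiration) is operationalized on a per-frame
motion signal: candidate events are maximal runs of frames whose motion lies
strictly below an absolute threshold (the same value for all animals);
candidates separated by movement gaps strictly shorter than 200 ms are
merged; merged events lasting 2 s or less are discarded.  Merging runs
before the duration filter so that fragmented long freezes survive.

Bout boundaries are at frame resolution: a run of frames ``[i, j)`` becomes
the bout ``[i, j) / frame_rate_hz``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import FrameStack, MotionTrace

__all__ = [
    "FreezingBout",
    "FreezingSummary",
    "motion_from_frames",
    "detect_freezing",
    "merge_and_filter",
    "freezing_summary",
]

MERGE_GAP_S = 0.2
MIN_BOUT_S = 2.0


@dataclass(frozen=True)
class FreezingBout:
    """A single freezing episode, in seconds from session start."""

    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class FreezingSummary:
    """Session-level freezing score."""

    total_freezing_s: float
    session_duration_s: float
    percent_freezing: float
    bout_count: int


def motion_from_frames(stack: FrameStack) -> MotionTrace:
    """Per-frame motion as the mean absolute pixel change across frames.

    ``motion[t] = mean |frame[t+1] - frame[t]|`` for t = 0..T-2 (length T-1);
    the first motion value carries the second frame's timestamp.
    """
    frames = stack.frames
    motion = np.abs(np.diff(frames, axis=0)).mean(axis=(1, 2))
    return MotionTrace(frame_rate_hz=stack.frame_rate_hz, motion=motion)


def _below_runs(below: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index pairs [i, j)."""
    if not below.any():
        return []
    padded = np.concatenate(([False], below, [False])).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def merge_and_filter(candidates: list[tuple[float, float]],
                     merge_gap_s: float = MERGE_GAP_S,
                     min_bout_s: float = MIN_BOUT_S) -> list[FreezingBout]:
    """Merge candidate immobility events, then drop short ones.

    Gaps strictly shorter than ``merge_gap_s`` are merged; merged events with
    duration <= ``min_bout_s`` (strictly "longer than" survives) are dropped.
    Idempotent on already-valid bout lists.
    """
    merged: list[list[float]] = []
    for s, e in sorted(candidates):
        if merged and s - merged[-1][1] < merge_gap_s:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [FreezingBout(s, e) for s, e in merged if e - s > min_bout_s]


def detect_freezing(motion: MotionTrace, threshold: float,
                    merge_gap_s: float = MERGE_GAP_S,
                    min_bout_s: float = MIN_BOUT_S) -> list[FreezingBout]:
    """Call freezing bouts on a motion trace with an absolute threshold.

    Candidate events are maximal runs of frames with ``motion < threshold``;
    they are merged across gaps < ``merge_gap_s`` and filtered to durations
    > ``min_bout_s``.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if len(motion.motion) == 0:
        raise ValueError("motion trace is empty")
    fps = motion.frame_rate_hz
    candidates = [(i / fps, j / fps) for i, j in _below_runs(motion.motion < threshold)]
    return merge_and_filter(candidates, merge_gap_s=merge_gap_s, min_bout_s=min_bout_s)


def freezing_summary(bouts: list[FreezingBout],
                     session_duration_s: float) -> FreezingSummary:
    """Percent of the session spent freezing (100 x total bout time / duration)."""
    if session_duration_s <= 0:
        raise ValueError(f"session_duration_s must be > 0, got {session_duration_s}")
    for b in bouts:
        if b.start_s < -1e-9 or b.end_s > session_duration_s + 1e-9:
            raise ValueError(
                f"bout [{b.start_s}, {b.end_s}] lies outside the session "
                f"[0, {session_duration_s}]")
    total = float(sum(b.duration_s for b in bouts))
    return FreezingSummary(
        total_freezing_s=total,
        session_duration_s=float(session_duration_s),
        percent_freezing=100.0 * total / session_duration_s,
        bout_count=len(bouts),
    )
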