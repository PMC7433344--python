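"""Ethogram scoring: per-behavior time budgets over a session.

The five scored behaviors are grooming, freezing, rearing, stretch/attend
and lying on back.  Input is an interval annotation table (hand-scored or
simulator-produced); totals are reported in minutes, mirroring how such
time budgets are conventionally tabulated for an 1110 s startle session.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .freezing import FreezingBout
from .synth import BEHAVIOR_STATES, SimGroundTruth

__all__ = [
    "EthogramInterval",
    "BehaviorDurations",
    "score_ethogram",
    "merge_freezing_sources",
    "ethogram_from_states",
    "righting_times",
]


@dataclass(frozen=True)
class EthogramInterval:
    """One annotated behavior episode."""

    behavior: str
    start_s: float
    end_s: float

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValueError(
                f"interval end {self.end_s} must exceed start {self.start_s} "
                f"({self.behavior})")


@dataclass(frozen=True)
class BehaviorDurations:
    """Per-behavior totals in minutes over one session."""

    minutes: Mapping[str, float]
    session_duration_s: float

    def __getitem__(self, behavior: str) -> float:
        return self.minutes[behavior]


def score_ethogram(intervals: Sequence[EthogramInterval],
                   session_duration_s: float) -> BehaviorDurations:
    """Sum per-behavior interval time, clipped to ``[0, session_duration_s]``.

    Behaviors with no intervals report 0; an unknown behavior label raises.
    Scoring is invariant to the order of the input intervals.
    """
    totals = {b: 0.0 for b in BEHAVIOR_STATES}
    for iv in intervals:
        if iv.behavior not in totals:
            raise ValueError(
                f"unknown behavior label {iv.behavior!r}; expected one of "
                f"{BEHAVIOR_STATES}")
        start = max(0.0, iv.start_s)
        end = min(session_duration_s, iv.end_s)
        if end > start:
            totals[iv.behavior] += end - start
    return BehaviorDurations(
        minutes={b: t / 60.0 for b, t in totals.items()},
        session_duration_s=float(session_duration_s),
    )


def merge_freezing_sources(ethogram_freezing: Sequence[EthogramInterval],
                           detector_bouts: Sequence[FreezingBout]
                           ) -> list[EthogramInterval]:
    """Combine annotated and detector-called freezing into one interval list.

    Detector bouts are relabeled as freezing intervals; when both sources are
    present the union is taken and overlapping/touching episodes coalesced.
    """
    spans = [(iv.start_s, iv.end_s) for iv in ethogram_freezing]
    spans += [(b.start_s, b.end_s) for b in detector_bouts]
    merged: list[list[float]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [EthogramInterval("freezing", s, e) for s, e in merged]


def ethogram_from_states(states: SimGroundTruth) -> list[EthogramInterval]:
    """Simulator state intervals as scorable annotations (``move`` excluded)."""
    return [EthogramInterval(b, s, e) for b, s, e in states.true_state_intervals
            if b != "move" and e > s]


def righting_times(intervals: Iterable[EthogramInterval]) -> list[float]:
    """Per-episode righting time: the length of each on-back episode, seconds."""
    return [iv.end_s - iv.start_s for iv in intervals if iv.behavior == "on_back"]
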