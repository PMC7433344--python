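"""Timed stimulus schedules for startle and fear-conditioning sessions.

A behavioral session is a :class:`SessionProtocol`: an acclimation (baseline)
period of silence followed by a sorted, non-overlapping sequence of
:class:`StimulusEvent` objects.  Three session types are modelled:

* **startle** — 300 s acclimation, then 20 white-noise bursts (20 ms) in five
  blocks; each block presents the four intensities 70/80/90/100 dB SPL in a
  seeded pseudorandom order, with inter-stimulus intervals drawn uniformly
  from 30–50 s.  The session is scored over a fixed nominal 1110 s.
* **conditioning** — 180 s baseline, then three back-to-back CS–US pairings:
  a CS train of 20 tone beeps (7.5 kHz, 75 dB, 500 ms on / 500 ms off)
  immediately followed by a 1 s, 0.7 mA footshock; inter-pairing gaps >= 80 s.
* **retrieval** — 180 s baseline, then four CS-only trains in a new context.

Inter-stimulus intervals are measured stimulus-offset to next-stimulus-onset,
so silence intervals stay in range by construction (with 20 ms bursts the two
conventions differ negligibly).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "StimulusEvent",
    "SessionProtocol",
    "build_startle_protocol",
    "build_conditioning_protocol",
    "build_retrieval_protocol",
    "validate_protocol",
    "STARTLE_INTENSITIES_DB",
]

NOISE_BURST_DURATION_S = 0.02
TONE_BEEP_DURATION_S = 0.5
FOOTSHOCK_DURATION_S = 1.0
TONE_FREQUENCY_HZ = 7500.0
TONE_INTENSITY_DB = 75.0
FOOTSHOCK_CURRENT_MA = 0.7

STARTLE_INTENSITIES_DB = (70, 80, 90, 100)
STARTLE_ACCLIMATION_S = 300.0
STARTLE_N_BLOCKS = 5
STARTLE_ISI_RANGE_S = (30.0, 50.0)
STARTLE_NOMINAL_DURATION_S = 1110.0

CONDITIONING_BASELINE_S = 180.0
CS_N_BEEPS = 20
CS_BEEP_PERIOD_S = 1.0  # 0.5 s on + 0.5 s off
PAIRING_ISI_RANGE_S = (80.0, 120.0)

EVENT_KINDS = ("noise_burst", "tone_beep", "footshock")

_KIND_DURATIONS = {
    "noise_burst": NOISE_BURST_DURATION_S,
    "tone_beep": TONE_BEEP_DURATION_S,
    "footshock": FOOTSHOCK_DURATION_S,
}


@dataclass(frozen=True)
class StimulusEvent:
    """A single timed stimulus within a session."""

    onset_s: float
    kind: str
    duration_s: float
    intensity_db: float | None = None
    frequency_hz: float | None = None
    current_ma: float | None = None

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s

    def to_dict(self) -> dict:
        d = {"onset_s": self.onset_s, "kind": self.kind, "duration_s": self.duration_s}
        if self.intensity_db is not None:
            d["intensity_db"] = self.intensity_db
        if self.frequency_hz is not None:
            d["frequency_hz"] = self.frequency_hz
        if self.current_ma is not None:
            d["current_ma"] = self.current_ma
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusEvent":
        return cls(
            onset_s=float(d["onset_s"]),
            kind=str(d["kind"]),
            duration_s=float(d["duration_s"]),
            intensity_db=None if d.get("intensity_db") is None else float(d["intensity_db"]),
            frequency_hz=None if d.get("frequency_hz") is None else float(d["frequency_hz"]),
            current_ma=None if d.get("current_ma") is None else float(d["current_ma"]),
        )


def noise_burst(onset_s: float, intensity_db: float) -> StimulusEvent:
    return StimulusEvent(onset_s, "noise_burst", NOISE_BURST_DURATION_S,
                         intensity_db=float(intensity_db))


def tone_beep(onset_s: float) -> StimulusEvent:
    return StimulusEvent(onset_s, "tone_beep", TONE_BEEP_DURATION_S,
                         intensity_db=TONE_INTENSITY_DB, frequency_hz=TONE_FREQUENCY_HZ)


def footshock(onset_s: float) -> StimulusEvent:
    return StimulusEvent(onset_s, "footshock", FOOTSHOCK_DURATION_S,
                         current_ma=FOOTSHOCK_CURRENT_MA)


@dataclass(frozen=True)
class SessionProtocol:
    """An ordered, non-overlapping stimulus schedule for one session."""

    protocol_id: str
    acclimation_s: float
    events: tuple[StimulusEvent, ...]
    nominal_duration_s: float
    rng_seed: int

    def __post_init__(self):
        object.__setattr__(self, "events", tuple(self.events))

    def events_of_kind(self, kind: str) -> tuple[StimulusEvent, ...]:
        return tuple(e for e in self.events if e.kind == kind)

    @property
    def kind(self) -> str:
        """Session type inferred from the protocol id prefix."""
        return self.protocol_id.split(":", 1)[0]

    def to_dict(self) -> dict:
        return {
            "protocol_id": self.protocol_id,
            "acclimation_s": self.acclimation_s,
            "nominal_duration_s": self.nominal_duration_s,
            "rng_seed": self.rng_seed,
            "events": [e.to_dict() for e in self.events],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionProtocol":
        return cls(
            protocol_id=str(d["protocol_id"]),
            acclimation_s=float(d["acclimation_s"]),
            events=tuple(StimulusEvent.from_dict(e) for e in d["events"]),
            nominal_duration_s=float(d["nominal_duration_s"]),
            rng_seed=int(d["rng_seed"]),
        )


def build_startle_protocol(seed: int) -> SessionProtocol:
    """Build the 20-burst acoustic startle schedule.

    Five consecutive blocks; each block is a seeded random permutation of
    {70, 80, 90, 100} dB, so every intensity occurs exactly five times.
    Offset-to-onset ISIs are drawn uniformly from [30, 50] s.  The first
    burst starts when the 300 s acclimation ends.  Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    intensities: list[int] = []
    for _ in range(STARTLE_N_BLOCKS):
        intensities.extend(rng.permutation(STARTLE_INTENSITIES_DB).tolist())
    events = []
    onset = STARTLE_ACCLIMATION_S
    for i, db in enumerate(intensities):
        events.append(noise_burst(onset, db))
        if i < len(intensities) - 1:
            onset = events[-1].offset_s + rng.uniform(*STARTLE_ISI_RANGE_S)
    return SessionProtocol(
        protocol_id=f"startle:seed={seed}",
        acclimation_s=STARTLE_ACCLIMATION_S,
        events=tuple(events),
        nominal_duration_s=STARTLE_NOMINAL_DURATION_S,
        rng_seed=int(seed),
    )


def _cs_train(start_s: float) -> list[StimulusEvent]:
    """20 tone beeps at a 1 s period (0.5 s on / 0.5 s off), spanning 19.5 s."""
    return [tone_beep(start_s + k * CS_BEEP_PERIOD_S) for k in range(CS_N_BEEPS)]


def build_conditioning_protocol(seed: int) -> SessionProtocol:
    """Three back-to-back CS–US pairings after a 180 s baseline.

    Each pairing is a 20-beep CS train whose last beep's offset coincides with
    the footshock onset ("back-to-back").  Gaps between pairings (shock offset
    to next train onset) are drawn uniformly from [80, 120] s — the minimum is
    the stated 80 s, the upper bound a configurable modelling choice.
    """
    rng = np.random.default_rng(seed)
    events: list[StimulusEvent] = []
    start = CONDITIONING_BASELINE_S
    for pairing in range(3):
        train = _cs_train(start)
        events.extend(train)
        shock = footshock(train[-1].offset_s)
        events.append(shock)
        if pairing < 2:
            start = shock.offset_s + rng.uniform(*PAIRING_ISI_RANGE_S)
    return SessionProtocol(
        protocol_id=f"conditioning:seed={seed}",
        acclimation_s=CONDITIONING_BASELINE_S,
        events=tuple(events),
        nominal_duration_s=events[-1].offset_s + 60.0,
        rng_seed=int(seed),
    )


def build_retrieval_protocol(seed: int) -> SessionProtocol:
    """Four CS-only trains after a 180 s baseline (no footshocks)."""
    rng = np.random.default_rng(seed)
    events: list[StimulusEvent] = []
    start = CONDITIONING_BASELINE_S
    for train_idx in range(4):
        train = _cs_train(start)
        events.extend(train)
        if train_idx < 3:
            start = train[-1].offset_s + rng.uniform(*PAIRING_ISI_RANGE_S)
    return SessionProtocol(
        protocol_id=f"retrieval:seed={seed}",
        acclimation_s=CONDITIONING_BASELINE_S,
        events=tuple(events),
        nominal_duration_s=events[-1].offset_s + 60.0,
        rng_seed=int(seed),
    )


def validate_protocol(p: SessionProtocol) -> list[str]:
    """Check type invariants; return human-readable violations (empty if valid).

    Violations are data, not exceptions: each entry names the offending event
    index (where applicable) and the rule broken.
    """
    v: list[str] = []
    for i, e in enumerate(p.events):
        if e.kind not in EVENT_KINDS:
            v.append(f"event {i}: unknown kind {e.kind!r}")
            continue
        if e.onset_s < 0:
            v.append(f"event {i}: onset_s {e.onset_s} < 0")
        if e.duration_s <= 0:
            v.append(f"event {i}: duration_s {e.duration_s} <= 0")
        expected = _KIND_DURATIONS[e.kind]
        if abs(e.duration_s - expected) > 1e-9:
            v.append(f"event {i}: {e.kind} duration_s {e.duration_s} != {expected}")
        if e.kind == "noise_burst" and e.intensity_db not in STARTLE_INTENSITIES_DB:
            v.append(f"event {i}: noise_burst intensity {e.intensity_db} dB not in "
                     f"{STARTLE_INTENSITIES_DB}")
    for i in range(1, len(p.events)):
        if p.events[i].onset_s < p.events[i - 1].onset_s:
            v.append(f"events {i - 1},{i}: not sorted by onset")
        elif p.events[i].onset_s < p.events[i - 1].offset_s - 1e-9:
            v.append(f"events {i - 1},{i}: overlapping")
    if p.events and p.events[0].onset_s < p.acclimation_s - 1e-9:
        v.append(f"event 0: onset {p.events[0].onset_s} precedes acclimation "
                 f"({p.acclimation_s} s)")

    kind = p.kind
    n_bursts = len(p.events_of_kind("noise_burst"))
    n_shocks = len(p.events_of_kind("footshock"))
    n_beeps = len(p.events_of_kind("tone_beep"))
    if kind == "startle":
        if p.acclimation_s != STARTLE_ACCLIMATION_S:
            v.append(f"startle acclimation_s {p.acclimation_s} != {STARTLE_ACCLIMATION_S}")
        if n_bursts != 20:
            v.append(f"startle protocol has {n_bursts} noise_burst events, expected 20")
        if p.nominal_duration_s != STARTLE_NOMINAL_DURATION_S:
            v.append(f"startle nominal_duration_s {p.nominal_duration_s} != "
                     f"{STARTLE_NOMINAL_DURATION_S}")
    elif kind == "conditioning":
        if n_shocks != 3:
            v.append(f"conditioning protocol has {n_shocks} footshock events, expected 3")
        if n_beeps != 3 * CS_N_BEEPS:
            v.append(f"conditioning protocol has {n_beeps} tone_beep events, "
                     f"expected {3 * CS_N_BEEPS}")
    elif kind == "retrieval":
        if n_shocks != 0:
            v.append(f"retrieval protocol has {n_shocks} footshock events, expected 0")
        if n_beeps != 4 * CS_N_BEEPS:
            v.append(f"retrieval protocol has {n_beeps} tone_beep events, "
                     f"expected {4 * CS_N_BEEPS}")
    return v
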