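"""Startle-amplitude extraction from piezo platform traces.

The startle amplitude of a trial is the maximum rectified deviation
|v(t) - baseline mean| of the piezo voltage within a 100 ms window after
noise-burst onset; the trial counts as a response when that deviation exceeds
twice the standard deviation of a 500 ms pre-stimulus baseline.  Rectifying
before taking the maximum matters because piezo startle transients are
oscillatory — a signed maximum would miss negative-going peaks.

Windows are half-open ``[start, end)`` at sample resolution; a time ``t``
maps to sample index ``floor(t * rate)``.  Baseline statistics use the
population (1/n) standard deviation — at n = 2500 the 1/(n-1) difference is
negligible, and fixing the convention keeps results bit-reproducible.

Sub-threshold trials score 0 by default and still enter the per-intensity
mean (``nonresponse="zero"``); pass ``nonresponse="drop"`` to average over
responding trials only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .paradigm import SessionProtocol, StimulusEvent
from .synth import PiezoTrace

__all__ = [
    "BaselineStats",
    "StartleResponse",
    "IntensitySummary",
    "compute_baseline",
    "extract_startle",
    "summarize_session",
    "session_response_table",
]

BASELINE_WINDOW_S = 0.5
RESPONSE_WINDOW_S = 0.1
THRESHOLD_SD = 2.0


@dataclass(frozen=True)
class BaselineStats:
    """Mean and population SD of the pre-stimulus baseline window."""

    mean: float
    sd: float
    window_s: float
    n_samples: int


@dataclass(frozen=True)
class StartleResponse:
    """One burst's extracted response.

    ``peak_amplitude`` is always the maximum rectified deviation in the
    response window; ``scored_amplitude`` applies the non-response policy
    (0 for sub-threshold trials under the default "zero" policy).
    """

    burst_index: int
    intensity_db: float
    baseline: BaselineStats
    threshold: float
    peak_amplitude: float
    peak_latency_s: float
    is_response: bool

    @property
    def scored_amplitude(self) -> float:
        return self.peak_amplitude if self.is_response else 0.0


@dataclass(frozen=True)
class IntensitySummary:
    """Per-intensity aggregate over the session's trials at that level."""

    intensity_db: float
    mean_amplitude: float
    n_trials: int
    amplitudes: tuple[float, ...]


def compute_baseline(trace: PiezoTrace, onset_s: float,
                     window_s: float = BASELINE_WINDOW_S) -> BaselineStats:
    """Mean/SD of the half-open pre-stimulus window ``[onset - window, onset)``."""
    rate = trace.sampling_rate_hz
    start = int(np.floor((onset_s - window_s) * rate))
    stop = int(np.floor(onset_s * rate))
    if start < 0:
        raise ValueError(
            f"baseline window [{onset_s - window_s:.3f}, {onset_s:.3f}) s for burst at "
            f"{onset_s:.3f} s extends before trace start")
    seg = trace.samples[start:stop]
    return BaselineStats(mean=float(seg.mean()), sd=float(seg.std()),
                         window_s=window_s, n_samples=len(seg))


def extract_startle(trace: PiezoTrace, burst: StimulusEvent,
                    baseline_window_s: float = BASELINE_WINDOW_S,
                    response_window_s: float = RESPONSE_WINDOW_S,
                    threshold_sd: float = THRESHOLD_SD,
                    burst_index: int = 0) -> StartleResponse:
    """Extract the startle response to one noise burst.

    Peak = max of |v - baseline mean| over ``[onset, onset + 0.1)``; the trial
    is a response iff the peak exceeds ``threshold_sd`` baseline SDs (in either
    direction).  Latency is the argmax time relative to onset, ties broken by
    the earliest sample.
    """
    rate = trace.sampling_rate_hz
    onset = burst.onset_s
    start = int(np.floor(onset * rate))
    stop = int(np.floor((onset + response_window_s) * rate))
    if stop > len(trace.samples):
        raise ValueError(
            f"trace ends at {trace.duration_s:.3f} s, before the response window of the "
            f"burst at {onset:.3f} s")
    baseline = compute_baseline(trace, onset, baseline_window_s)
    dev = np.abs(trace.samples[start:stop] - baseline.mean)
    i_peak = int(np.argmax(dev))  # argmax returns the first maximum
    peak = float(dev[i_peak])
    threshold = threshold_sd * baseline.sd
    return StartleResponse(
        burst_index=burst_index,
        intensity_db=float(burst.intensity_db),
        baseline=baseline,
        threshold=float(threshold),
        peak_amplitude=peak,
        peak_latency_s=i_peak / rate,
        is_response=bool(peak > threshold),
    )


def _session_responses(trace: PiezoTrace, protocol: SessionProtocol,
                       **kwargs) -> list[StartleResponse]:
    bursts = protocol.events_of_kind("noise_burst")
    if not bursts:
        raise ValueError(f"protocol {protocol.protocol_id!r} has no noise_burst events")
    if bursts[-1].onset_s + RESPONSE_WINDOW_S > trace.duration_s + 1e-9:
        raise ValueError(
            f"trace ({trace.duration_s:.1f} s) does not cover the session "
            f"(last burst at {bursts[-1].onset_s:.1f} s)")
    return [extract_startle(trace, b, burst_index=i, **kwargs)
            for i, b in enumerate(bursts)]


def summarize_session(trace: PiezoTrace, protocol: SessionProtocol,
                      nonresponse: str = "zero",
                      **kwargs) -> list[IntensitySummary]:
    """Per-intensity mean scored amplitudes for one animal's session.

    Returns one :class:`IntensitySummary` per intensity present in the
    protocol (ascending dB).  Under ``nonresponse="zero"`` sub-threshold
    trials contribute 0 to the mean; under ``"drop"`` they are excluded
    (an intensity with no responses reports mean 0 over 0 trials).
    """
    if nonresponse not in ("zero", "drop"):
        raise ValueError(f"nonresponse must be 'zero' or 'drop', got {nonresponse!r}")
    responses = _session_responses(trace, protocol, **kwargs)
    out = []
    for db in sorted({r.intensity_db for r in responses}):
        at_db = [r for r in responses if r.intensity_db == db]
        if nonresponse == "zero":
            amps = [r.scored_amplitude for r in at_db]
        else:
            amps = [r.peak_amplitude for r in at_db if r.is_response]
        mean = float(np.mean(amps)) if amps else 0.0
        out.append(IntensitySummary(intensity_db=db, mean_amplitude=mean,
                                    n_trials=len(amps), amplitudes=tuple(amps)))
    return out


def session_response_table(trace: PiezoTrace, protocol: SessionProtocol,
                           **kwargs) -> pd.DataFrame:
    """Per-burst response table (one row per burst, in presentation order)."""
    rows = [{
        "burst_index": r.burst_index,
        "intensity_db": r.intensity_db,
        "peak_amplitude": r.peak_amplitude,
        "latency_s": r.peak_latency_s,
        "is_response": r.is_response,
        "scored_amplitude": r.scored_amplitude,
        "baseline_mean": r.baseline.mean,
        "baseline_sd": r.baseline.sd,
    } for r in _session_responses(trace, protocol, **kwargs)]
    return pd.DataFrame(rows)
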