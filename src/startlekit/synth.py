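"""Synthetic piezo traces, motion traces, frame stacks and behavioral states.

Every downstream stage of the pipeline (startle extraction, freezing
detection, ethogram scoring, group statistics) is testable against known
ground truth because the generators record exactly what they injected:

* :func:`simulate_piezo` — Gaussian baseline noise plus, for each noise burst
  that elicits a response, an exponentially damped sinusoid whose true peak
  amplitude is drawn around a genotype- and intensity-dependent gain.
* :func:`simulate_behavior_states` — a semi-Markov alternation between
  ``move`` and five discrete behaviors with exponential dwell times.
* :func:`simulate_motion` — a frame-rate motion signal that is
  ``motion_move_level`` plus noise outside freezing and |noise| inside it.
* :func:`simulate_frames` — a dark blob on a bright field that displaces
  during movement and is pixel-identical across frames during freezing.

All simulators are pure functions of (inputs, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .paradigm import SessionProtocol

__all__ = [
    "SimConfig",
    "SimGroundTruth",
    "PiezoTrace",
    "MotionTrace",
    "FrameStack",
    "simulate_piezo",
    "simulate_behavior_states",
    "simulate_motion",
    "simulate_frames",
    "BEHAVIOR_STATES",
]

PIEZO_SAMPLING_RATE_HZ = 5000.0

#: the five scored behaviors; ``move`` is the implicit background state
BEHAVIOR_STATES = ("grooming", "freezing", "rearing", "stretch_attend", "on_back")


@dataclass(frozen=True)
class PiezoTrace:
    """Continuous piezo platform voltage, sampled at a fixed rate from t = 0."""

    sampling_rate_hz: float
    samples: np.ndarray
    start_s: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate_hz

    def index_of(self, t_s: float) -> int:
        """Sample index covering time ``t_s`` (floor convention)."""
        return int(np.floor(t_s * self.sampling_rate_hz))


@dataclass(frozen=True)
class MotionTrace:
    """Per-frame motion signal (a.u., non-negative) at a fixed frame rate.

    Frame ``i`` covers the time interval ``[i, i+1) / frame_rate_hz``.
    """

    frame_rate_hz: float
    motion: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.motion, dtype=float)
        if self.frame_rate_hz <= 0:
            raise ValueError(f"frame_rate_hz must be > 0, got {self.frame_rate_hz}")
        if len(m) and m.min() < 0:
            raise ValueError("motion values must be non-negative")
        object.__setattr__(self, "motion", m)

    @property
    def duration_s(self) -> float:
        return len(self.motion) / self.frame_rate_hz


@dataclass(frozen=True)
class FrameStack:
    """T grayscale frames of identical H x W shape, values in [0, 255]."""

    frames: np.ndarray  # (T, H, W)
    frame_rate_hz: float = 30.0

    def __post_init__(self):
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3 or f.shape[0] < 2:
            raise ValueError(f"frames must be (T>=2, H, W), got shape {f.shape}")
        object.__setattr__(self, "frames", f)


@dataclass(frozen=True)
class SimGroundTruth:
    """What a simulator injected: per-burst true peaks and/or state intervals."""

    seed: int
    injected_peaks: np.ndarray = field(default_factory=lambda: np.empty(0))
    true_state_intervals: tuple[tuple[str, float, float], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "injected_peaks",
                           np.asarray(self.injected_peaks, dtype=float))
        object.__setattr__(self, "true_state_intervals",
                           tuple(tuple(iv) for iv in self.true_state_intervals))

    def total_time(self, behavior: str) -> float:
        return float(sum(e - s for b, s, e in self.true_state_intervals if b == behavior))


# wild-type-like defaults; genotype presets override these (see presets.py)
_DEFAULT_GAIN = {70: 50.0, 80: 125.0, 90: 280.0, 100: 450.0}
_DEFAULT_ENTRY = {"grooming": 1 / 150, "freezing": 1 / 350, "rearing": 1 / 80,
                  "stretch_attend": 1 / 200, "on_back": 0.0}
_DEFAULT_DWELL = {"grooming": 10.0, "freezing": 8.0, "rearing": 4.0,
                  "stretch_attend": 5.0, "on_back": 4.0}


@dataclass(frozen=True)
class SimConfig:
    """All tunables of the synthetic-data generators.

    ``startle_gain`` maps stimulus intensity (dB) to the expected transient
    peak (a.u.); ``state_entry_rates`` are per-second hazards of leaving
    ``move`` into each behavior (their sum fixes the mean move dwell) and
    ``state_dwell_s`` the mean exponential dwell of each behavior.
    ``genotype_overrides`` maps a genotype label to field replacements, so one
    config describes a whole cohort; :meth:`for_genotype` resolves it.
    """

    seed: int = 0
    baseline_noise_sd: float = 1.0
    startle_gain: Mapping[int, float] = field(default_factory=lambda: dict(_DEFAULT_GAIN))
    startle_latency_s: float = 0.02
    transient_decay_s: float = 0.05
    transient_freq_hz: float = 40.0
    peak_jitter_cv: float = 0.15
    response_prob: float = 1.0
    state_entry_rates: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_ENTRY))
    state_dwell_s: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_DWELL))
    motion_move_level: float = 10.0
    motion_noise_sd: float = 1.0
    frame_rate_hz: float = 30.0
    piezo_rate_hz: float = PIEZO_SAMPLING_RATE_HZ  # 5 kHz for faithful sessions
    genotype_overrides: Mapping[str, Mapping] = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.response_prob <= 1.0):
            raise ValueError(f"response_prob must be in [0,1], got {self.response_prob}")
        if self.baseline_noise_sd < 0 or self.motion_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not (0.0 <= self.startle_latency_s < 0.1):
            # injected peaks must fall inside the 100 ms detection window
            raise ValueError(f"startle_latency_s must be < 0.1 s, got {self.startle_latency_s}")
        if self.transient_decay_s <= 0 or self.frame_rate_hz <= 0 or self.piezo_rate_hz <= 0:
            raise ValueError("transient_decay_s, frame_rate_hz and piezo_rate_hz must be > 0")
        for name, rates in (("state_entry_rates", self.state_entry_rates),
                            ("state_dwell_s", self.state_dwell_s)):
            for k, val in rates.items():
                if k not in BEHAVIOR_STATES:
                    raise ValueError(f"{name}: unknown behavior {k!r}")
                if val < 0 or (name == "state_dwell_s" and val <= 0):
                    raise ValueError(f"{name}[{k}] out of range: {val}")

    @property
    def freeze_rate_per_s(self) -> float:
        return float(self.state_entry_rates.get("freezing", 0.0))

    @property
    def freeze_dwell_s(self) -> float:
        return float(self.state_dwell_s["freezing"])

    @property
    def move_dwell_s(self) -> float:
        """Mean move dwell implied by the total exit hazard (inf if no exits)."""
        total = sum(self.state_entry_rates.values())
        return float("inf") if total == 0 else 1.0 / total

    def for_genotype(self, genotype: str) -> "SimConfig":
        """Resolve per-genotype overrides into a flat config."""
        over = self.genotype_overrides.get(genotype, {})
        if not over:
            return self
        return dataclasses.replace(self, genotype_overrides={}, **dict(over))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["startle_gain"] = {str(k): v for k, v in self.startle_gain.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "startle_gain" in d:
            d["startle_gain"] = {int(k): float(v) for k, v in d["startle_gain"].items()}
        return cls(**d)


def _damped_sinusoid(n: int, rate_hz: float, freq_hz: float, tau_s: float) -> np.ndarray:
    """Unit-normalized damped sinusoid: exp(-t/tau) sin(2 pi f t), peak |.| = 1."""
    t = np.arange(n) / rate_hz
    w = np.exp(-t / tau_s) * np.sin(2 * np.pi * freq_hz * t)
    peak = np.abs(w).max()
    return w / peak if peak > 0 else w


def simulate_piezo(protocol: SessionProtocol, cfg: SimConfig,
                   genotype: str = "wt") -> tuple[PiezoTrace, SimGroundTruth]:
    """Simulate the piezo platform voltage for a startle session.

    For each noise burst, a Bernoulli(``response_prob``) draw decides whether
    the animal responds; if so a damped 40 Hz sinusoid is injected at
    onset + latency, scaled so its true peak equals the gain for that
    intensity times a lognormal jitter (CV ``peak_jitter_cv``; exactly the
    gain when the CV is 0).  Ground truth records the injected peak of every
    burst (0 for non-responses).
    """
    cfg = cfg.for_genotype(genotype)
    bursts = protocol.events_of_kind("noise_burst")
    if not bursts or len(bursts) != len(protocol.events):
        kinds = sorted({e.kind for e in protocol.events})
        raise ValueError(
            f"simulate_piezo requires a startle protocol (only noise_burst events); "
            f"got {protocol.protocol_id!r} with event kinds {kinds}")
    rng = np.random.default_rng(cfg.seed)
    rate = cfg.piezo_rate_hz
    duration = max(protocol.nominal_duration_s, bursts[-1].onset_s + 0.2)
    n = int(round(duration * rate))
    samples = (rng.normal(0.0, cfg.baseline_noise_sd, n)
               if cfg.baseline_noise_sd > 0 else np.zeros(n))

    wave_n = int(round(5 * cfg.transient_decay_s * rate))
    wave = _damped_sinusoid(wave_n, rate, cfg.transient_freq_hz, cfg.transient_decay_s)
    sigma = np.sqrt(np.log1p(cfg.peak_jitter_cv ** 2))

    peaks = np.zeros(len(bursts))
    for i, burst in enumerate(bursts):
        responds = rng.random() < cfg.response_prob
        gain = float(cfg.startle_gain[int(burst.intensity_db)])
        jitter = float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0
        if not responds:
            continue
        peak = gain * jitter
        start = int(np.floor((burst.onset_s + cfg.startle_latency_s) * rate))
        stop = min(start + wave_n, n)
        samples[start:stop] += peak * wave[: stop - start]
        peaks[i] = peak
    trace = PiezoTrace(sampling_rate_hz=rate, samples=samples)
    return trace, SimGroundTruth(seed=cfg.seed, injected_peaks=peaks)


def simulate_behavior_states(protocol: SessionProtocol, cfg: SimConfig,
                             genotype: str = "wt") -> SimGroundTruth:
    """Simulate a semi-Markov behavioral state sequence over the session.

    The animal alternates between ``move`` and the five scored behaviors:
    from ``move``, exit after an Exp(1/sum of entry rates) dwell into a
    behavior chosen proportionally to its entry rate; each behavior dwells
    Exp(mean ``state_dwell_s``) and returns to ``move``.  Intervals tile
    ``[0, nominal_duration_s]`` with no gaps or overlaps.
    """
    cfg = cfg.for_genotype(genotype)
    rng = np.random.default_rng(cfg.seed)
    duration = protocol.nominal_duration_s
    behaviors = [b for b in BEHAVIOR_STATES if cfg.state_entry_rates.get(b, 0.0) > 0]
    rates = np.array([cfg.state_entry_rates[b] for b in behaviors])
    total_rate = rates.sum()

    intervals: list[tuple[str, float, float]] = []
    t = 0.0
    while t < duration:
        if total_rate == 0:
            intervals.append(("move", t, duration))
            break
        dwell = rng.exponential(1.0 / total_rate)
        end = min(t + dwell, duration)
        intervals.append(("move", t, end))
        t = end
        if t >= duration:
            break
        b = behaviors[rng.choice(len(behaviors), p=rates / total_rate)]
        dwell = rng.exponential(cfg.state_dwell_s[b])
        end = min(t + dwell, duration)
        intervals.append((b, t, end))
        t = end
    return SimGroundTruth(seed=cfg.seed, true_state_intervals=tuple(intervals))


def _freezing_mask(states: SimGroundTruth, times: np.ndarray) -> np.ndarray:
    mask = np.zeros(len(times), dtype=bool)
    for b, s, e in states.true_state_intervals:
        if b == "freezing":
            mask |= (times >= s) & (times < e)
    return mask


def simulate_motion(states: SimGroundTruth, cfg: SimConfig) -> MotionTrace:
    """Render the state sequence as a frame-rate motion signal.

    Non-freezing frames carry ``motion_move_level`` plus Gaussian noise
    (clipped at 0); freezing frames carry |noise| only — residual pixel noise
    with no displacement component.
    """
    if not states.true_state_intervals:
        raise ValueError("states ground truth has no intervals")
    duration = max(e for _, _, e in states.true_state_intervals)
    n = int(round(duration * cfg.frame_rate_hz))
    rng = np.random.default_rng(cfg.seed)
    noise = (rng.normal(0.0, cfg.motion_noise_sd, n)
             if cfg.motion_noise_sd > 0 else np.zeros(n))
    times = np.arange(n) / cfg.frame_rate_hz
    freezing = _freezing_mask(states, times)
    motion = np.where(freezing, np.abs(noise),
                      np.clip(cfg.motion_move_level + noise, 0.0, None))
    return MotionTrace(frame_rate_hz=cfg.frame_rate_hz, motion=motion)


def simulate_frames(states: SimGroundTruth, cfg: SimConfig,
                    shape: tuple[int, int] = (48, 48), step_px: int = 2,
                    blob_radius_px: int | None = None,
                    pixel_noise_sd: float = 0.0) -> FrameStack:
    """Render a dark blob on a bright field from the state sequence.

    The blob centroid takes an integer random-walk step of ``step_px`` pixels
    per frame during non-freezing states (reflected at the walls) and is
    exactly stationary during freezing, so with zero pixel noise the
    frame-difference motion vanishes identically inside freezing bouts.
    """
    H, W = shape
    if H < 16 or W < 16:
        raise ValueError(f"frame shape must be at least 16x16, got {shape}")
    if not states.true_state_intervals:
        raise ValueError("states ground truth has no intervals")
    duration = max(e for _, _, e in states.true_state_intervals)
    n = max(2, int(round(duration * cfg.frame_rate_hz)))
    rng = np.random.default_rng(cfg.seed)
    times = np.arange(n) / cfg.frame_rate_hz
    freezing = _freezing_mask(states, times)

    r = blob_radius_px if blob_radius_px is not None else max(3, min(H, W) // 6)
    yy, xx = np.mgrid[0:H, 0:W]
    cy, cx = H // 2, W // 2
    frames = np.full((n, H, W), 200.0)
    for i in range(n):
        if i > 0:
            if not freezing[i]:
                cy = int(np.clip(cy + rng.choice((-step_px, step_px)), r, H - 1 - r))
                cx = int(np.clip(cx + rng.choice((-step_px, step_px)), r, W - 1 - r))
        blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        frames[i][blob] = 30.0
    if pixel_noise_sd > 0:
        frames += rng.normal(0.0, pixel_noise_sd, frames.shape)
        frames = np.clip(frames, 0.0, 255.0)
    return FrameStack(frames=frames, frame_rate_hz=cfg.frame_rate_hz)
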