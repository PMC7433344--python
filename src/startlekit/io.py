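"""File formats, run configuration and session manifests.

Everything on disk is plain text: traces are single-column CSV (``value``)
with a JSON sidecar manifest carrying the sampling rate and provenance;
behavior annotations are ``behavior,start_s,end_s`` CSV; protocols and
configs are JSON.  CSV dialect: comma-separated, '.' decimal, header row,
UTF-8, LF line endings, times in seconds as decimals.

Every report embeds the :class:`RunConfig` hash and seed so a run can be
reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ethogram import EthogramInterval
from .paradigm import SessionProtocol
from .synth import MotionTrace, PiezoTrace

__all__ = [
    "RunConfig",
    "SessionManifest",
    "read_protocol", "write_protocol",
    "read_trace", "write_trace",
    "read_motion", "write_motion",
    "read_intervals", "write_intervals",
    "read_manifest", "write_manifest",
]

GENOTYPES = ("wt", "het", "hom")
LINES = ("spastic", "spasmodic")


@dataclass(frozen=True)
class RunConfig:
    """All pipeline tunables, serialized into every output for provenance.

    Defaults: 500 ms pre-stimulus baseline, 100 ms response window, a
    mean +/- 2 SD response threshold, 200 ms freezing merge gap, 2 s minimum
    bout, 1110 s nominal startle session, alpha = 0.05.  The absolute
    freezing motion threshold has no published value; the default is the
    midpoint between the simulator's freezing level (0) and its moving level
    (10 a.u.).
    """

    baseline_window_s: float = 0.5
    response_window_s: float = 0.1
    threshold_sd: float = 2.0
    merge_gap_s: float = 0.2
    min_bout_s: float = 2.0
    freeze_threshold: float = 5.0
    nominal_duration_s: float = 1110.0
    alpha: float = 0.05
    nonresponse_policy: str = "zero"
    seed: int = 0

    def __post_init__(self):
        if self.nonresponse_policy not in ("zero", "drop"):
            raise ValueError(f"nonresponse_policy must be 'zero' or 'drop', "
                             f"got {self.nonresponse_policy!r}")
        for name in ("baseline_window_s", "response_window_s", "threshold_sd",
                     "min_bout_s", "freeze_threshold", "nominal_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class SessionManifest:
    """Pointers to one animal's session files plus its group labels."""

    animal_id: str
    genotype: str
    line: str
    protocol_path: str
    seed: int = 0
    trace_path: str | None = None
    motion_path: str | None = None
    intervals_path: str | None = None
    sampling_rate_hz: float = 5000.0
    frame_rate_hz: float = 30.0

    def __post_init__(self):
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype {self.genotype!r} not in {GENOTYPES}")
        if self.line not in LINES:
            raise ValueError(f"line {self.line!r} not in {LINES}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SessionManifest":
        return cls(**d)


# ---------------------------------------------------------------- protocols

def write_protocol(protocol: SessionProtocol, path: str | Path) -> None:
    Path(path).write_text(json.dumps(protocol.to_dict(), indent=1) + "\n")


def read_protocol(path: str | Path) -> SessionProtocol:
    return SessionProtocol.from_dict(json.loads(Path(path).read_text()))


# ------------------------------------------------------------------- traces

def write_trace(trace: PiezoTrace, path: str | Path, *,
                manifest: dict | None = None) -> None:
    """Write a piezo trace as CSV plus a JSON sidecar (``<path>.json``)."""
    path = Path(path)
    pd.DataFrame({"value": trace.samples}).to_csv(path, index=False, lineterminator="\n")
    meta = {"sampling_rate_hz": trace.sampling_rate_hz, "units": "a.u.",
            "start_s": trace.start_s}
    meta.update(manifest or {})
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1) + "\n")


def read_trace(path: str | Path) -> PiezoTrace:
    path = Path(path)
    df = _read_csv(path, ["value"])
    sidecar = path.with_suffix(path.suffix + ".json")
    rate = 5000.0
    if sidecar.exists():
        rate = float(json.loads(sidecar.read_text())["sampling_rate_hz"])
    return PiezoTrace(sampling_rate_hz=rate, samples=df["value"].to_numpy())


def write_motion(motion: MotionTrace, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"value": motion.motion}).to_csv(path, index=False, lineterminator="\n")
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"frame_rate_hz": motion.frame_rate_hz, "units": "a.u."}, indent=1) + "\n")


def read_motion(path: str | Path, frame_rate_hz: float | None = None) -> MotionTrace:
    path = Path(path)
    df = _read_csv(path, ["value"])
    if frame_rate_hz is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        frame_rate_hz = (float(json.loads(sidecar.read_text())["frame_rate_hz"])
                         if sidecar.exists() else 30.0)
    return MotionTrace(frame_rate_hz=frame_rate_hz, motion=df["value"].to_numpy())


def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV: surface the pandas diagnosis
        raise ValueError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


# ---------------------------------------------------------------- intervals

def write_intervals(intervals: list[EthogramInterval], path: str | Path) -> None:
    pd.DataFrame(
        [{"behavior": iv.behavior, "start_s": iv.start_s, "end_s": iv.end_s}
         for iv in intervals],
        columns=["behavior", "start_s", "end_s"],
    ).to_csv(path, index=False, lineterminator="\n")


def read_intervals(path: str | Path) -> list[EthogramInterval]:
    df = _read_csv(Path(path), ["behavior", "start_s", "end_s"])
    out = []
    for i, row in df.iterrows():
        try:
            out.append(EthogramInterval(str(row["behavior"]),
                                        float(row["start_s"]), float(row["end_s"])))
        except (ValueError, TypeError) as exc:
            # header is line 1, so data row i is file line i + 2
            raise ValueError(f"{path}, line {i + 2}: {exc}") from exc
    return out


# ---------------------------------------------------------------- manifests

def write_manifest(manifest: SessionManifest, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest.to_dict(), indent=1) + "\n")


def read_manifest(path: str | Path) -> SessionManifest:
    path = Path(path)
    m = SessionManifest.from_dict(json.loads(path.read_text()))
    for attr in ("protocol_path", "trace_path", "motion_path", "intervals_path"):
        ref = getattr(m, attr)
        if ref is not None and not (path.parent / ref).exists():
            raise FileNotFoundError(
                f"{path}: {attr} references missing file {ref!r}")
    return m


def resolve(manifest_path: str | Path, ref: str) -> Path:
    """Manifest file references are relative to the manifest's directory."""
    return Path(manifest_path).parent / ref
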