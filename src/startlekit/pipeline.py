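"""End-to-end orchestration: simulate cohorts, detect, score, test, report.

Two entry points:

* :func:`simulate_cohort` writes a full synthetic cohort to disk (per-animal
  protocol/trace/motion/interval files plus manifests) so the file-based CLI
  path can be exercised end to end.
* :func:`run_experiment` consumes manifests and a :class:`RunConfig` and
  emits the report bundle: a per-intensity startle table, an ethogram time
  budget, a freezing table, and the statistics battery (mixed ANOVA with
  Bonferroni post hoc on startle amplitudes; per-behavior and freezing
  Student t tests).  Detection outputs are always written; if the cohort
  cannot support statistics (fewer than two groups or fewer than two animals
  per group) the statistics stage records an error instead.

:func:`analyze_synthetic_cohort` does the same in memory (no files), which
is what the examples and the acceptance script use.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as skio
from .ethogram import BehaviorDurations, ethogram_from_states, score_ethogram
from .freezing import detect_freezing, freezing_summary
from .paradigm import SessionProtocol, build_startle_protocol
from .startle import summarize_session
from .stats import GroupSample, MixedAnovaResult, TTestResult, mixed_anova, student_t_test
from .synth import (BEHAVIOR_STATES, SimConfig, simulate_behavior_states,
                    simulate_motion, simulate_piezo)

__all__ = [
    "AnimalResult",
    "CohortReport",
    "analyze_animal",
    "analyze_synthetic_cohort",
    "simulate_cohort",
    "run_experiment",
]

log = logging.getLogger("startlekit")


@dataclass(frozen=True)
class AnimalResult:
    """One animal's per-session measurements."""

    animal_id: str
    genotype: str
    intensity_means: dict[float, float]      # dB -> mean scored amplitude
    ethogram_min: dict[str, float]           # behavior -> minutes
    percent_freezing: float
    bout_count: int


@dataclass
class CohortReport:
    """All tables of a cohort analysis plus the statistics battery."""

    config: skio.RunConfig
    intensity_table: pd.DataFrame            # animal x intensity (wide)
    genotype: pd.Series                      # per-animal labels
    ethogram_table: pd.DataFrame             # animal, genotype, behavior, minutes
    freezing_table: pd.DataFrame             # animal, genotype, percent, bouts
    anova: MixedAnovaResult | None = None
    behavior_tests: dict[str, TTestResult] = field(default_factory=dict)
    freezing_test: TTestResult | None = None
    errors: list[str] = field(default_factory=list)


def analyze_animal(animal_id: str, genotype: str, protocol: SessionProtocol,
                   trace, motion, intervals, config: skio.RunConfig) -> AnimalResult:
    """Run detection and scoring for one animal's startle session."""
    summaries = summarize_session(
        trace, protocol, nonresponse=config.nonresponse_policy,
        baseline_window_s=config.baseline_window_s,
        response_window_s=config.response_window_s,
        threshold_sd=config.threshold_sd)
    bouts = detect_freezing(motion, config.freeze_threshold,
                            merge_gap_s=config.merge_gap_s,
                            min_bout_s=config.min_bout_s)
    fs = freezing_summary(bouts, protocol.nominal_duration_s)
    durations = score_ethogram(intervals, protocol.nominal_duration_s)
    log.info("animal %s (%s): %d bursts, %d freezing bouts, %.1f%% freezing",
             animal_id, genotype, sum(s.n_trials for s in summaries),
             fs.bout_count, fs.percent_freezing)
    return AnimalResult(
        animal_id=animal_id,
        genotype=genotype,
        intensity_means={s.intensity_db: s.mean_amplitude for s in summaries},
        ethogram_min=dict(durations.minutes),
        percent_freezing=fs.percent_freezing,
        bout_count=fs.bout_count,
    )


def _build_report(results: list[AnimalResult], config: skio.RunConfig) -> CohortReport:
    idx = [r.animal_id for r in results]
    genotype = pd.Series([r.genotype for r in results], index=idx, name="genotype")
    intensity_table = pd.DataFrame([r.intensity_means for r in results], index=idx)
    intensity_table = intensity_table[sorted(intensity_table.columns)]
    ethogram_table = pd.DataFrame(
        [{"animal_id": r.animal_id, "genotype": r.genotype, "behavior": b,
          "minutes": r.ethogram_min.get(b, 0.0)}
         for r in results for b in BEHAVIOR_STATES])
    freezing_table = pd.DataFrame(
        [{"animal_id": r.animal_id, "genotype": r.genotype,
          "percent_freezing": r.percent_freezing, "bout_count": r.bout_count}
         for r in results])
    report = CohortReport(config=config, intensity_table=intensity_table,
                          genotype=genotype, ethogram_table=ethogram_table,
                          freezing_table=freezing_table)

    groups = list(pd.unique(genotype))
    counts = genotype.value_counts()
    if len(groups) != 2 or (counts < 2).any():
        report.errors.append(
            f"statistics stage skipped: need exactly 2 genotype groups with >= 2 "
            f"animals each, got {counts.to_dict()}")
        return report

    report.anova = mixed_anova(intensity_table, genotype)
    for behavior in BEHAVIOR_STATES:
        sub = ethogram_table[ethogram_table.behavior == behavior]
        a = GroupSample(groups[0], sub[sub.genotype == groups[0]].minutes.to_numpy())
        b = GroupSample(groups[1], sub[sub.genotype == groups[1]].minutes.to_numpy())
        report.behavior_tests[behavior] = student_t_test(a, b)
    fa = GroupSample(groups[0], freezing_table[freezing_table.genotype == groups[0]]
                     .percent_freezing.to_numpy())
    fb = GroupSample(groups[1], freezing_table[freezing_table.genotype == groups[1]]
                     .percent_freezing.to_numpy())
    report.freezing_test = student_t_test(fa, fb)
    log.info("stats: interaction F(%d,%d) = %.4g, p = %.4g",
             report.anova.df1, report.anova.df2,
             report.anova.F_interaction, report.anova.p_interaction)
    return report


def analyze_synthetic_cohort(cohort: dict[str, int], sim: SimConfig,
                             config: skio.RunConfig | None = None,
                             seed: int = 0) -> CohortReport:
    """Simulate and analyze a cohort entirely in memory.

    ``cohort`` maps genotype label to the number of animals.  Each animal gets
    its own startle protocol and simulator seeds derived from ``seed``.
    """
    config = config or skio.RunConfig(seed=seed)
    root = np.random.default_rng(seed)
    results = []
    for genotype in cohort:
        for j in range(cohort[genotype]):
            aseed = int(root.integers(2 ** 31 - 1))
            protocol = build_startle_protocol(aseed)
            asim = dataclasses.replace(sim, seed=aseed)
            trace, _ = simulate_piezo(protocol, asim, genotype)
            states = simulate_behavior_states(protocol, asim, genotype)
            motion = simulate_motion(states, asim.for_genotype(genotype))
            intervals = ethogram_from_states(states)
            results.append(analyze_animal(f"{genotype}-{j:02d}", genotype,
                                          protocol, trace, motion, intervals, config))
    return _build_report(results, config)


def simulate_cohort(outdir: str | Path, line: str, cohort: dict[str, int],
                    sim: SimConfig, seed: int = 0) -> list[Path]:
    """Write a synthetic cohort to disk; returns the manifest paths."""
    from .presets import preset_config  # noqa: F401  (callers may pass preset configs)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(seed)
    manifest_paths = []
    for genotype in cohort:
        for j in range(cohort[genotype]):
            aseed = int(root.integers(2 ** 31 - 1))
            aid = f"{line}-{genotype}-{j:02d}"
            protocol = build_startle_protocol(aseed)
            asim = dataclasses.replace(sim, seed=aseed)
            trace, gt = simulate_piezo(protocol, asim, genotype)
            states = simulate_behavior_states(protocol, asim, genotype)
            motion = simulate_motion(states, asim.for_genotype(genotype))
            skio.write_protocol(protocol, outdir / f"{aid}.protocol.json")
            skio.write_trace(trace, outdir / f"{aid}.trace.csv",
                             manifest={"seed": aseed, "protocol_id": protocol.protocol_id})
            skio.write_motion(motion, outdir / f"{aid}.motion.csv")
            skio.write_intervals(ethogram_from_states(states),
                                 outdir / f"{aid}.intervals.csv")
            pd.DataFrame({"burst_index": np.arange(len(gt.injected_peaks)),
                          "true_peak": gt.injected_peaks}).to_csv(
                outdir / f"{aid}.truth_peaks.csv", index=False, lineterminator="\n")
            m = skio.SessionManifest(
                animal_id=aid, genotype=genotype, line=line,
                protocol_path=f"{aid}.protocol.json", seed=aseed,
                trace_path=f"{aid}.trace.csv", motion_path=f"{aid}.motion.csv",
                intervals_path=f"{aid}.intervals.csv")
            mp = outdir / f"{aid}.manifest.json"
            skio.write_manifest(m, mp)
            manifest_paths.append(mp)
    return manifest_paths


def run_experiment(config: skio.RunConfig, manifest_paths: list[str | Path],
                   outdir: str | Path) -> CohortReport:
    """File-based pipeline: load manifests, analyze each animal, write reports."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = []
    for mp in manifest_paths:
        m = skio.read_manifest(mp)
        protocol = skio.read_protocol(skio.resolve(mp, m.protocol_path))
        trace = skio.read_trace(skio.resolve(mp, m.trace_path))
        motion = skio.read_motion(skio.resolve(mp, m.motion_path))
        intervals = (skio.read_intervals(skio.resolve(mp, m.intervals_path))
                     if m.intervals_path else [])
        results.append(analyze_animal(m.animal_id, m.genotype, protocol,
                                      trace, motion, intervals, config))
    report = _build_report(results, config)
    write_report(report, outdir)
    return report


def write_report(report: CohortReport, outdir: str | Path) -> None:
    """Serialize the report bundle as CSV/JSON with embedded provenance."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = {"config_hash": report.config.config_hash, "seed": report.config.seed,
            "config": report.config.to_dict()}
    fmt = "%.10g"

    wide = report.intensity_table.copy()
    wide.insert(0, "genotype", report.genotype)
    wide.to_csv(outdir / "per_intensity.csv", index_label="animal_id",
                lineterminator="\n", float_format=fmt)
    report.ethogram_table.to_csv(outdir / "ethogram.csv", index=False,
                                 lineterminator="\n", float_format=fmt)
    report.freezing_table.to_csv(outdir / "freezing.csv", index=False,
                                 lineterminator="\n", float_format=fmt)

    stats: dict = {"provenance": prov, "errors": report.errors}
    if report.anova is not None:
        a = report.anova
        stats["mixed_anova"] = {
            "F_interaction": a.F_interaction, "df1": a.df1, "df2": a.df2,
            "p_interaction": a.p_interaction,
            "F_between": a.F_between, "p_between": a.p_between,
            "F_within": a.F_within, "p_within": a.p_within,
            "posthoc": [dataclasses.asdict(c) for c in a.posthoc],
        }
    if report.behavior_tests:
        stats["behavior_t_tests"] = {
            b: dataclasses.asdict(t) for b, t in report.behavior_tests.items()}
    if report.freezing_test is not None:
        stats["freezing_t_test"] = dataclasses.asdict(report.freezing_test)
    (outdir / "stats.json").write_text(
        json.dumps(_jsonable(stats), indent=1) + "\n")


def _jsonable(x):
    """Strict-JSON sanitizer: numpy scalars to Python, non-finite to strings."""
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        x = x.item()
    if isinstance(x, float) and not np.isfinite(x):
        return repr(x)
    return x
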