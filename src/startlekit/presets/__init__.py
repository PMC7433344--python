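"""Genotype/line presets for the synthetic-data generators.

Presets ship as JSON files under ``startlekit/presets/`` and resolve to a
:class:`~startlekit.synth.SimConfig` whose ``genotype_overrides`` carry the
per-genotype gains and state-process parameters.  They are illustrative —
chosen to preserve the ordinal structure of the two mutant lines (homozygous
spasmodic: large intensity-increasing startle gains, frequent long freezing,
on-back episodes; heterozygous spastic: wild-type-like) — not fits to any
reported group mean.
"""

from __future__ import annotations

import json
from importlib import resources

from ..synth import SimConfig

__all__ = ["available_lines", "available_genotypes", "preset_config"]

_CACHE: dict[str, dict] = {}


def _load_line(line: str) -> dict:
    if line not in _CACHE:
        try:
            text = (resources.files("startlekit.presets") / f"{line}.json").read_text()
        except FileNotFoundError:
            raise KeyError(f"no preset for line {line!r}; available: {available_lines()}")
        _CACHE[line] = json.loads(text)
    return _CACHE[line]


def available_lines() -> list[str]:
    return sorted(p.name.removesuffix(".json")
                  for p in (resources.files("startlekit.presets")).iterdir()
                  if p.name.endswith(".json"))


def available_genotypes(line: str) -> list[str]:
    return sorted(_load_line(line)["genotypes"])


def preset_config(line: str, seed: int = 0) -> SimConfig:
    """Build a cohort SimConfig for a mouse line with per-genotype overrides."""
    spec = _load_line(line)
    overrides = {}
    for genotype, over in spec["genotypes"].items():
        over = dict(over)
        if "startle_gain" in over:
            over["startle_gain"] = {int(k): float(v) for k, v in over["startle_gain"].items()}
        overrides[genotype] = over
    base = dict(spec.get("base", {}))
    return SimConfig(seed=seed, genotype_overrides=overrides, **base)
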