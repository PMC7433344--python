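"""Score a session's behavior time budget (the ethogram).

The five scored behaviors are grooming, freezing, rearing, stretch/attend
and lying on back.  Here the intervals come from the semi-Markov state
simulator, so the scored minutes can be checked against the generator's
dwell-time ground truth; a hand-scored CSV would work identically.
"""

import dataclasses

from startlekit import build_startle_protocol, score_ethogram, simulate_behavior_states
from startlekit.ethogram import ethogram_from_states, righting_times
from startlekit.presets import preset_config

protocol = build_startle_protocol(seed=2)
sim = dataclasses.replace(preset_config("spasmodic"), seed=2)

for genotype in ("wt", "hom"):
    states = simulate_behavior_states(protocol, sim, genotype)
    durations = score_ethogram(ethogram_from_states(states), protocol.nominal_duration_s)
    budget = ", ".join(f"{b} {m:.2f}" for b, m in durations.minutes.items())
    print(f"{genotype}: {budget} (min)")
    rt = righting_times(ethogram_from_states(states))
    if rt:
        print(f"     {len(rt)} on-back episodes, righting times "
              + ", ".join(f"{t:.1f} s" for t in rt))
# The hom preset spends more time freezing and on its back, less time
# grooming and rearing — the ordinal pattern of the mutant phenotype.
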