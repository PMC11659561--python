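"""Demographic bias audit with the minimum-subgroup reporting rule.

Tests eye-level sensitivity and specificity differences across sex, race
(Black vs non-Black) and ethnicity (Hispanic vs non-Hispanic) with a
participant-clustered bootstrap; subgroups under 10 participants are
suppressed entirely.
"""

from drdtrial import (
    BootstrapSettings,
    SimulationConfig,
    SubgroupSpec,
    bias_test,
    generate_trial,
)

ds = generate_trial(SimulationConfig(n_participants=2000, seed=3))
settings = BootstrapSettings(n_replicates=2000, seed=3)

for attribute in ("sex", "race", "ethnicity"):
    for metric in ("sensitivity", "specificity"):
        print(bias_test(ds, SubgroupSpec(attribute), metric, settings=settings).render())
# The generator applies one operating point to everyone, so differences are
# Monte-Carlo noise and every p-value should be comfortably non-significant.
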