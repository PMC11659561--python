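"""Participant-clustered bootstrap non-inferiority test.

Resamples whole participants (both eyes together) with replacement, expands
the ETDRS >= 53 spectrum to 20% of positive eyes within each replicate, and
tests H0: sensitivity < 75% and H0: specificity < 77.5% one-sided at 2.5%.
"""

from drdtrial import (
    BootstrapSettings,
    NIHypothesis,
    SimulationConfig,
    bootstrap_metric,
    generate_trial,
    study_success,
)

ds = generate_trial(SimulationConfig(n_participants=567, seed=5))
settings = BootstrapSettings(n_replicates=2000, seed=5, expand_spectrum=True)
hypothesis = NIHypothesis()

results = {}
for metric in ("sensitivity", "specificity"):
    r = bootstrap_metric(ds, metric, "eye", "level1", settings, hypothesis)
    results[metric] = r
    print(
        f"{metric}: {100 * r.point_estimate:.1f}% "
        f"(one-sided 97.5% lower bound: {100 * r.lower_bound:.1f}%; "
        f"p = {r.ni_p_value:.4f} vs p0 = {100 * hypothesis.p0(metric):.1f}%)"
    )

print("study success:", study_success(results["sensitivity"], results["specificity"], hypothesis))
# Study success requires BOTH nulls rejected.  The specificity margin (77.5%
# vs a true 88.4%) is comfortably cleared; the sensitivity margin (75% vs a
# true 79.6%) is tight, so any single simulated trial may or may not reject —
# that borderline power is exactly why the trial design enriched severe cases.

from drdtrial import power_simulation  # noqa: E402

power = power_simulation(0.85, 0.90, n_trials=100, settings=BootstrapSettings(n_replicates=300, seed=0))
print(
    f"design power at a true operating point of (0.85, 0.90): "
    f"{power['power_study']:.2f} +/- {power['mc_se_study']:.2f}"
)
# At the enrollment design (200 positive / 140 negative eyes) and a stronger
# alternative, both endpoints reject in well over 80% of trials.
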