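"""End-to-end pipeline and report rendering.

``run_pipeline`` wires the stages together in the order a trial analysis
runs them: generate (or load) the participant–eye data, build disposition
and accuracy panels, run the clustered-bootstrap non-inferiority tests,
compute the screening-equity (PAS) comparison, and audit demographic
subgroups.  Every stochastic stage receives its own child seed spawned from
the single global seed, so identical configuration yields a byte-identical
machine-readable bundle and any stage can be re-run independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import accuracy_engine as acc
from .bias_audit import BiasReport, SubgroupSpec, bias_test
from .equity_pas import PASInputs, pas_break_even_ratio, pas_simplified
from .inference import BootstrapSettings, NIHypothesis, bootstrap_metric, study_success
from .synthetic_trial import SimulationConfig, generate_trial
from .trial_data import TrialDataset, TrialDataError, waterfall_summary

__all__ = ["RunConfig", "run_pipeline", "render_report"]

#: Predicate-system PAS operands: participant-level sensitivity from the
#: predicate device's pivotal trial.
PREDICATE_SENSITIVITY = 0.872


@dataclass
class RunConfig:
    """Configuration for the end-to-end pipeline."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    hypothesis: NIHypothesis = field(default_factory=NIHypothesis)
    n_replicates: int = 2000
    spectrum_target: float = 0.20
    expand_spectrum: bool = True
    seed: int = 0
    min_subgroup_n: int = 10
    verbosity: int = 0


def _stage_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


def _accuracy_dict(summary: acc.AccuracySummary) -> dict:
    return {
        "sensitivity": summary.sensitivity,
        "specificity": summary.specificity,
        "ppv": summary.ppv,
        "npv": summary.npv,
        "plr": summary.plr,
        "nlr": summary.nlr,
        "diagnosability": summary.diagnosability,
        "n_units": summary.n_units,
    }


def _bootstrap_dict(result) -> dict:
    return {
        "metric": result.metric,
        "point_estimate": result.point_estimate,
        "lower_bound": result.lower_bound,
        "ni_p_value": result.ni_p_value,
        "n_replicates": int(len(result.replicate_values)),
        "n_excluded": result.n_excluded,
    }


def _bias_dict(report: BiasReport) -> dict:
    if not report.reported:
        return {
            "attribute": report.attribute,
            "metric": report.metric,
            "reported": False,
            "reason": f"not reported (n<{report.suppression_reason})",
        }
    return {
        "attribute": report.attribute,
        "metric": report.metric,
        "reported": True,
        "groups": dict(zip(report.group_labels, report.group_estimates)),
        "group_ns": list(report.group_ns),
        "difference": report.difference,
        "p_value": report.p_value,
    }


def run_pipeline(config: RunConfig, dataset: Optional[TrialDataset] = None) -> dict:
    """Run generate → analyze → infer → equity → audit; return the bundle.

    A pre-loaded dataset may be supplied instead of the synthetic generator
    (its eyes must carry AI outputs).
    """
    seeds = _stage_seeds(config.seed, 4)

    if dataset is None:
        if config.simulation.n_participants == 0:
            raise TrialDataError("generation stage: n_participants must be >= 1")
        dataset = generate_trial(config.simulation.with_seed(seeds[0]))

    waterfall = waterfall_summary(dataset, dataset, dataset).to_dict("records")

    accuracy = {}
    for unit in ("eye", "participant"):
        accuracy[unit] = _accuracy_dict(acc.summarize(dataset, unit, "level1"))
    worst = acc.worst_case_impute(acc.build_table(dataset, "eye", "level1"))
    accuracy["eye_worst_case"] = {
        "sensitivity": acc.sensitivity(worst),
        "specificity": acc.specificity(worst),
    }

    settings = BootstrapSettings(
        n_replicates=config.n_replicates,
        seed=seeds[1],
        spectrum_target=config.spectrum_target,
        expand_spectrum=config.expand_spectrum,
    )
    sens = bootstrap_metric(dataset, "sensitivity", "eye", "level1", settings, config.hypothesis)
    spec = bootstrap_metric(dataset, "specificity", "eye", "level1", settings, config.hypothesis)
    inference = {
        "sensitivity": _bootstrap_dict(sens),
        "specificity": _bootstrap_dict(spec),
        "study_success": study_success(sens, spec, config.hypothesis),
    }

    part = acc.summarize(dataset, "participant", "level1")
    new_pas = pas_simplified(part.sensitivity, 1.0, part.diagnosability)
    equity = {
        "participant_sensitivity": part.sensitivity,
        "participant_diagnosability": part.diagnosability,
        "pas_new_system": new_pas,
        "pas_break_even_ratio": pas_break_even_ratio(
            PASInputs(s_c=PREDICATE_SENSITIVITY, d_c=part.diagnosability),
            PASInputs(s_c=part.sensitivity, d_c=part.diagnosability),
        ),
    }

    audit_settings = BootstrapSettings(n_replicates=min(config.n_replicates, 2000), seed=seeds[2])
    bias = []
    for attribute in ("sex", "race", "ethnicity"):
        for metric in ("sensitivity", "specificity"):
            bias.append(
                _bias_dict(
                    bias_test(
                        dataset,
                        SubgroupSpec(attribute, min_n=config.min_subgroup_n),
                        metric,
                        settings=audit_settings,
                    )
                )
            )

    return {
        "config": {
            "seed": config.seed,
            "n_participants": dataset.n_participants,
            "n_replicates": config.n_replicates,
            "spectrum_target": config.spectrum_target,
            "expand_spectrum": config.expand_spectrum,
        },
        "waterfall": waterfall,
        "accuracy": accuracy,
        "inference": inference,
        "equity": equity,
        "bias_audit": bias,
    }


_REQUIRED_SECTIONS = ("waterfall", "accuracy", "inference", "equity", "bias_audit")


def _pct(x: Optional[float]) -> str:
    return "n/a" if x is None else f"{100 * x:.1f}%"


def render_report(bundle: dict, format: str = "text") -> str:
    """Render a bundle as human-readable text or canonical JSON."""
    missing = [s for s in _REQUIRED_SECTIONS if s not in bundle]
    if missing:
        raise TrialDataError(f"incomplete bundle, missing sections: {missing}")
    if format == "json":
        return json.dumps(bundle, indent=2, sort_keys=True)
    if format != "text":
        raise TrialDataError(f"unknown format {format!r}")

    lines = ["== Disposition =="]
    for row in bundle["waterfall"]:
        lines.append(
            f"  {row['stage']}: {row['participants']} participants / {row['eyes']} eyes"
            f" (excluded: {row['participants_excluded']}/{row['eyes_excluded']})"
        )
    lines.append("== Accuracy (Level I standard) ==")
    for unit in ("eye", "participant"):
        a = bundle["accuracy"][unit]
        lines.append(
            f"  {unit}: sensitivity {_pct(a['sensitivity'])}, specificity {_pct(a['specificity'])}, "
            f"PPV {_pct(a['ppv'])}, NPV {_pct(a['npv'])}, diagnosability {_pct(a['diagnosability'])}"
        )
    w = bundle["accuracy"]["eye_worst_case"]
    lines.append(
        f"  worst-case (eye): sensitivity {_pct(w['sensitivity'])}, specificity {_pct(w['specificity'])}"
    )
    lines.append("== Non-inferiority (clustered bootstrap) ==")
    for metric in ("sensitivity", "specificity"):
        r = bundle["inference"][metric]
        lines.append(
            f"  {metric}: {_pct(r['point_estimate'])} "
            f"(one-sided 97.5% lower bound: {_pct(r['lower_bound'])}; p = {r['ni_p_value']:.3f})"
        )
    lines.append(f"  study success: {'yes' if bundle['inference']['study_success'] else 'no'}")
    e = bundle["equity"]
    lines.append("== Screening equity (PAS) ==")
    lines.append(
        f"  participant sensitivity {_pct(e['participant_sensitivity'])}, "
        f"diagnosability {_pct(e['participant_diagnosability'])}, "
        f"break-even adoption ratio {e['pas_break_even_ratio']:.2f}x"
    )
    lines.append("== Bias audit (unadjusted) ==")
    if not bundle["bias_audit"]:
        lines.append("  (no subgroup analyses)")
    for b in bundle["bias_audit"]:
        if not b["reported"]:
            lines.append(f"  {b['attribute']}/{b['metric']}: {b['reason']}")
        else:
            groups = ", ".join(f"{k} {_pct(v)}" for k, v in b["groups"].items())
            lines.append(
                f"  {b['attribute']}/{b['metric']}: {groups} "
                f"(diff {100 * b['difference']:+.1f} pp, p = {b['p_value']:.3f})"
            )
    return "\n".join(lines)
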