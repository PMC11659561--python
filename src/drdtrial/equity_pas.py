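"""Population Achieved Sensitivity (PAS) and screening-equity comparisons.

PAS measures how many people who truly have the disease a screening system
identifies at population scale.  It combines the system's sensitivity s_c and
diagnosability d_c in the subpopulation with access, the access fraction c,
and the disease prevalences with (p_c) and without (p̂_nc) access:

    PAS = s_c · c · p_c · d_c / (c · p_c + (1 − c) · p̂_nc)

Under the conservative assumption that prevalence is equal in both
subpopulations this collapses to s_c · c · d_c.  Comparing two systems with a
shared target population eliminates the hard-to-measure access fraction: the
*break-even ratio* PAS_ref / PAS_new is the adoption multiple above which the
lower-sensitivity but more adoptable system identifies more true cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .trial_data import TrialDataError

__all__ = [
    "PASInputs",
    "RiskProfile",
    "pas",
    "pas_simplified",
    "pas_break_even_ratio",
    "pas_ratio_interval",
    "risk_annotation",
]

#: Conservative default prevalence for both subpopulations.
DEFAULT_PREVALENCE = 0.2


@dataclass(frozen=True)
class PASInputs:
    """The PAS operands for one screening system."""

    s_c: float  # sensitivity in the subpopulation with access
    d_c: float = 1.0  # diagnosability
    c: float = 1.0  # access fraction
    p_c: float = DEFAULT_PREVALENCE  # prevalence with access
    p_nc_hat: float = DEFAULT_PREVALENCE  # estimated prevalence without access

    def __post_init__(self) -> None:
        for name in ("s_c", "d_c", "c", "p_c", "p_nc_hat"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise TrialDataError(f"{name} must be in [0, 1], got {v}")


def pas(inputs: PASInputs) -> float:
    """Exact PAS; equals ``s_c * c * d_c`` whenever p_c == p̂_nc."""
    denom = inputs.c * inputs.p_c + (1.0 - inputs.c) * inputs.p_nc_hat
    if denom <= 0.0:
        raise TrialDataError("PAS denominator c*p_c + (1-c)*p_nc_hat is zero")
    return inputs.s_c * inputs.c * inputs.p_c * inputs.d_c / denom


def pas_simplified(s_c: float, c: float, d_c: float) -> float:
    """The equal-prevalence simplification: s_c * c * d_c."""
    for name, v in (("s_c", s_c), ("c", c), ("d_c", d_c)):
        if not 0.0 <= v <= 1.0:
            raise TrialDataError(f"{name} must be in [0, 1], got {v}")
    return s_c * c * d_c


def pas_break_even_ratio(reference_system: PASInputs, new_system: PASInputs) -> float:
    """PAS(reference) / PAS(new) with the shared access fraction cancelled.

    Both systems must be specified at the same access fraction.  Adoption of
    the new system above this multiple identifies more true positives than
    the reference system does.
    """
    if reference_system.c != new_system.c:
        raise TrialDataError("break-even ratio requires a shared access fraction")
    ref = pas(reference_system)
    new = pas(new_system)
    if new <= 0.0:
        raise TrialDataError("new-system PAS is zero; break-even ratio undefined")
    return ref / new


def _se_from_ci(point: float, ci: tuple[float, float]) -> float:
    lo, hi = ci
    if not lo <= point <= hi:
        raise TrialDataError(f"point {point} outside its CI {ci}")
    if hi < lo:
        raise TrialDataError(f"degenerate CI {ci}")
    # A zero-width CI means no uncertainty: the draw collapses to the point.
    return (hi - lo) / (2.0 * 1.959963984540054)


def pas_ratio_interval(
    reference: tuple[float, tuple[float, float]],
    new: tuple[float, tuple[float, float]],
    n_draws: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo 95% interval for the PAS break-even ratio.

    Each argument is ``(sensitivity_point, (ci_low, ci_high))``.  Sensitivities
    are drawn independently from normals with standard error inferred from the
    CI half-width / 1.96, truncated to (0, 1); the 2.5th and 97.5th percentiles
    of the ratio are returned.  This is an uncertainty interpretation, not a
    reproduction of any particular published propagation scheme.
    """
    rng = np.random.default_rng(seed)
    draws = []
    for point, ci in (reference, new):
        se = _se_from_ci(point, ci)
        x = rng.normal(point, se, n_draws)
        draws.append(np.clip(x, 1e-9, 1.0 - 1e-9))
    ratio = draws[0] / draws[1]
    return float(np.quantile(ratio, 0.025)), float(np.quantile(ratio, 0.975))


@dataclass(frozen=True)
class RiskProfile:
    """Literature-derived clinical-outcome risks attached to an AI output."""

    label: str
    risk_pdr_3y: float
    risk_modvl_1y: float
    risk_modvl_3y: float
    icd10_category: str

    def __post_init__(self) -> None:
        for name in ("risk_pdr_3y", "risk_modvl_1y", "risk_modvl_3y"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise TrialDataError(f"{name} out of [0, 1]")


_RISK_LOOKUP = {
    # Disease present (ETDRS >= 35 or DME): 18.5% 3-year risk of proliferative
    # retinopathy; center-involved DME carries ~11%/1y and ~35%/3y risk of
    # moderate-or-worse vision loss.  Maps to ICD-10 E11.339x.
    "detected": RiskProfile("detected", 0.185, 0.11, 0.35, "E11.339x"),
    # Disease absent (ETDRS <= 20, no DME): risks at or below 1.8% (PDR) and
    # ~1.4% (vision loss).  Diabetes without ophthalmic complication.
    "not_detected": RiskProfile("not_detected", 0.018, 0.014, 0.014, "E11.9"),
}


def risk_annotation(ai_label: str) -> RiskProfile:
    """Fixed lookup from a disease-level AI output to clinical-outcome risk."""
    if ai_label not in _RISK_LOOKUP:
        raise TrialDataError(f"no risk annotation for label {ai_label!r}")
    return _RISK_LOOKUP[ai_label]
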