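"""Two-step mediation calculus on the product-of-coefficients scale.

Given three pairwise MR estimates — exposure->outcome (total effect),
exposure->mediator (beta1) and mediator->outcome (beta2) — the indirect
(mediated) effect is beta1*beta2, its standard error follows from the
delta method (Sobel), sqrt(beta1^2 se2^2 + beta2^2 se1^2), and the direct
effect is total - indirect. The mediated proportion is indirect/total,
reported as a percentage when the two share a sign and flagged as
"inconsistent mediation" otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .estimators import MREstimate, Z975


@dataclass
class MediationResult:
    exposure_id: str
    mediator_id: str
    outcome_id: str
    total_effect: float
    total_ci: tuple[float, float]
    beta1: float
    beta1_ci: tuple[float, float]
    beta2: float
    beta2_ci: tuple[float, float]
    mediation_effect: float          # beta1*beta2, unrounded
    mediation_effect_rounded: float  # display value, 5 decimals
    se_mediation: float
    ci_low: float
    ci_high: float
    pvalue: float
    direct_effect: float             # total - mediation, exact identity
    consistent: bool                 # mediation and total share sign
    proportion_mediated: float | None      # percent, 1-decimal display chain
    proportion_unrounded: float | None     # percent from unrounded product


def proportion_mediated(mediation: float, total: float,
                        ndigits: int | None = 5) -> float:
    """Mediated proportion as a percentage, 100 * mediation / total.

    ``ndigits`` rounds the mediation effect before dividing (the report
    chain uses 5 decimals, matching print precision); pass None for the
    unrounded value. Undefined for total == 0.
    """
    if total == 0:
        raise ValueError("proportion undefined: total effect is zero")
    m = round(mediation, ndigits) if ndigits is not None else mediation
    return 100.0 * m / total


def two_step_mediation(total: MREstimate, step1: MREstimate,
                       step2: MREstimate,
                       exposure_id: str = "exposure",
                       mediator_id: str = "mediator",
                       outcome_id: str = "outcome") -> MediationResult:
    """Combine the three pairwise MR fits into a mediation decomposition.

    All three estimates must be on the log/linear effect scale. The total
    effect is taken from the exposure->outcome fit as-is (not recomputed as
    direct + indirect); the decomposition identity direct + indirect = total
    then holds exactly by construction.
    """
    b1, se1 = step1.beta, step1.se
    b2, se2 = step2.beta, step2.se
    med = b1 * b2
    se_med = math.sqrt(b1 ** 2 * se2 ** 2 + b2 ** 2 * se1 ** 2)
    if se_med > 0:
        p = 2.0 * stats.norm.sf(abs(med) / se_med)
        ci = (med - Z975 * se_med, med + Z975 * se_med)
    else:
        p, ci = float("nan"), (med, med)
    tot = total.beta
    consistent = (med == 0) or (tot != 0 and (med > 0) == (tot > 0))
    prop = prop_raw = None
    if tot != 0 and consistent:
        prop = proportion_mediated(med, tot, ndigits=5)
        prop_raw = proportion_mediated(med, tot, ndigits=None)
    return MediationResult(
        exposure_id=exposure_id, mediator_id=mediator_id, outcome_id=outcome_id,
        total_effect=tot, total_ci=(total.ci_low, total.ci_high),
        beta1=b1, beta1_ci=(step1.ci_low, step1.ci_high),
        beta2=b2, beta2_ci=(step2.ci_low, step2.ci_high),
        mediation_effect=med, mediation_effect_rounded=round(med, 5),
        se_mediation=se_med, ci_low=ci[0], ci_high=ci[1], pvalue=p,
        direct_effect=tot - med, consistent=consistent,
        proportion_mediated=prop, proportion_unrounded=prop_raw,
    )
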