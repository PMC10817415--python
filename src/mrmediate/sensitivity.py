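"""Heterogeneity, pleiotropy and stability diagnostics for an MR analysis.

Cochran's Q tests whether per-SNP Wald ratios are mutually consistent
(df = k-1 around the IVW estimate, k-2 around the Egger fit); the Egger
intercept tests for directional horizontal pleiotropy; leave-one-out refits
flag individual instruments that drive the pooled estimate; and the reverse
direction re-runs the whole battery with exposure and outcome swapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import estimators
from .estimators import (EstimatorConfig, EstimationError, MREstimate,
                         WaldRatioSet, ivw, mr_egger, wald_ratios)
from .instruments import InstrumentSelectionConfig, LDTable, instrument_report, \
    selected_instruments
from .summary_io import HarmonizedInstrumentSet, SummaryDataset, harmonize, \
    HarmonizationError


@dataclass(frozen=True)
class HeterogeneityResult:
    method_context: str  # "ivw" | "egger"
    Q: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class PleiotropyResult:
    intercept: float
    se: float
    pvalue: float

    def present(self, alpha: float = 0.05) -> bool:
        return self.pvalue < alpha


def cochran_q(ratios: WaldRatioSet, center: float,
              method_context: str = "ivw") -> HeterogeneityResult:
    """Q = sum_j w_j (ratio_j - center)^2 against chi-square(k-1).

    For the Egger context use :func:`mr_egger`'s extras instead, where Q is
    computed from fit residuals on k-2 df.
    """
    k = len(ratios)
    if k < 2:
        raise EstimationError("Cochran's Q requires >=2 instruments")
    q = float(np.sum(ratios.weight * (ratios.ratio - center) ** 2))
    df = k - 1
    return HeterogeneityResult(method_context=method_context, Q=q, df=df,
                               pvalue=float(stats.chi2.sf(q, df)))


def heterogeneity(h: HarmonizedInstrumentSet) -> list[HeterogeneityResult]:
    """Q in both conventional contexts: around the IVW estimate (k-1 df)
    and around the Egger regression line (k-2 df, when k >= 3)."""
    w = wald_ratios(h)
    out = [cochran_q(w, ivw(h).beta, "ivw")]
    if h.n_snps >= 3:
        eg = mr_egger(h)
        out.append(HeterogeneityResult(
            method_context="egger", Q=eg.extras["Q"], df=eg.extras["Q_df"],
            pvalue=eg.extras["Q_pvalue"]))
    return out


def egger_intercept_test(h: HarmonizedInstrumentSet) -> PleiotropyResult:
    eg = mr_egger(h)
    return PleiotropyResult(intercept=eg.extras["intercept"],
                            se=eg.extras["intercept_se"],
                            pvalue=eg.extras["intercept_pvalue"])


def leave_one_out(h: HarmonizedInstrumentSet) -> pd.DataFrame:
    """IVW refits each omitting one SNP, plus the all-SNP row.

    ``flagged`` marks exclusions that change the sign of the estimate or
    move it outside the full-set 95% CI — a numeric surrogate for the usual
    visual leave-one-out inspection.
    """
    k = h.n_snps
    if k < 2:
        raise EstimationError("leave-one-out requires >=2 instruments")
    full = ivw(h)
    rows = []
    for i, snp in enumerate(h.table["snp_id"]):
        sub = HarmonizedInstrumentSet(
            exposure_id=h.exposure_id, outcome_id=h.outcome_id,
            table=h.table.drop(h.table.index[i]).reset_index(drop=True),
            log=h.log)
        est = ivw(sub)
        flagged = (np.sign(est.beta) != np.sign(full.beta)) or \
                  not (full.ci_low <= est.beta <= full.ci_high)
        rows.append({"excluded_snp": snp, "beta": est.beta, "se": est.se,
                     "ci_low": est.ci_low, "ci_high": est.ci_high,
                     "pvalue": est.pvalue, "n_snps": est.n_snps,
                     "flagged": bool(flagged)})
    rows.append({"excluded_snp": "<none>", "beta": full.beta, "se": full.se,
                 "ci_low": full.ci_low, "ci_high": full.ci_high,
                 "pvalue": full.pvalue, "n_snps": full.n_snps, "flagged": False})
    return pd.DataFrame(rows)


@dataclass
class ReverseResult:
    """Reverse-direction analysis outcome; ``estimable`` is False when the
    former outcome trait has no usable instruments."""

    exposure_id: str
    outcome_id: str
    estimable: bool
    reason: str | None = None
    estimates: list[MREstimate] | None = None
    harmonized: HarmonizedInstrumentSet | None = None
    no_causal_effect: bool | None = None


def reverse_direction(
    new_exposure: SummaryDataset,
    new_outcome: SummaryDataset,
    selection: InstrumentSelectionConfig = InstrumentSelectionConfig(),
    est_config: EstimatorConfig = EstimatorConfig(),
    ld: LDTable | None = None,
    r2_mode: str = "from-eaf",
    alpha: float = 0.05,
    palindrome_eaf_window: tuple[float, float] = (0.42, 0.58),
) -> ReverseResult:
    """Re-run the full battery with the trait roles swapped.

    Instruments are re-selected for the new exposure; if none pass, a
    structured not-estimable result is returned rather than raising. The
    report flags "no causal effect" when the reverse IVW p >= alpha.
    """
    base = ReverseResult(exposure_id=new_exposure.trait_id,
                         outcome_id=new_outcome.trait_id, estimable=False)
    try:
        rep = instrument_report(new_exposure, selection, ld, r2_mode=r2_mode)
        snps = selected_instruments(rep)
    except ValueError as exc:
        base.reason = f"instrument selection failed: {exc}"
        return base
    if not snps:
        base.reason = "no genome-wide-significant independent instruments"
        return base
    try:
        h = harmonize(new_exposure, new_outcome, snps,
                      palindrome_eaf_window=palindrome_eaf_window)
    except HarmonizationError as exc:
        base.reason = str(exc)
        return base
    if h.n_snps >= 3:
        ests = estimators.run_all_methods(h, est_config)
    else:
        ests = [ivw(h)]
    ivw_est = next(e for e in ests if e.method in ("ivw", "wald_ratio"))
    return ReverseResult(
        exposure_id=new_exposure.trait_id, outcome_id=new_outcome.trait_id,
        estimable=True, estimates=ests, harmonized=h,
        no_causal_effect=bool(ivw_est.pvalue >= alpha))
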