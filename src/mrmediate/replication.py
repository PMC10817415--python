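"""Monte-Carlo replication studies over the synthetic generator.

Used to check, under the generator's own ground truth, that the pipeline
recovers the chain coefficients without bias, that the IVW test holds its
nominal size under the null, and that the Egger intercept recovers a
directional pleiotropy mean. Each replicate runs the real analysis path:
instrument selection -> harmonization -> estimation.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .estimators import ivw
from .instruments import instrument_report, selected_instruments
from .mediation import two_step_mediation
from .sensitivity import egger_intercept_test
from .summary_io import SummaryDataset, harmonize
from .synthetic_data import SimulationConfig, simulate_chain, simulate_null

#: keep derived seeds under 2^31
_SEED_MOD = 2 ** 31 - 1


def _ivw_pair(exposure: SummaryDataset, outcome: SummaryDataset,
              exclude: set[str] | None = None):
    snps = selected_instruments(instrument_report(exposure, exclude=exclude))
    return ivw(harmonize(exposure, outcome, snps))


def recovery_study(n_reps: int = 50, seed: int = 0,
                   config: SimulationConfig = SimulationConfig()) -> dict:
    """Repeated end-to-end two-step analyses on freshly simulated chains.

    Returns per-quantity means, Monte-Carlo SEs and the generating truth
    for the total effect, both step effects and the mediated proportion.
    """
    out = {"beta1": [], "total": [], "beta2": [], "proportion_pct": []}
    for r in range(n_reps):
        cfg = dataclasses.replace(config, seed=(seed * 100_003 + r) % _SEED_MOD)
        study = simulate_chain(cfg)
        upstream = set(study.exposure.table.loc[
            study.exposure.table["pvalue"] < 5e-8, "snp_id"])
        step1 = _ivw_pair(study.exposure, study.mediator)
        total = _ivw_pair(study.exposure, study.outcome)
        step2 = _ivw_pair(study.mediator, study.outcome, exclude=upstream)
        med = two_step_mediation(total, step1, step2)
        out["beta1"].append(step1.beta)
        out["total"].append(total.beta)
        out["beta2"].append(step2.beta)
        out["proportion_pct"].append(med.proportion_unrounded)
    truth = {"beta1": config.theta_xm, "total": config.theta_total,
             "beta2": config.theta_my,
             "proportion_pct": 100.0 * config.theta_xm * config.theta_my
             / config.theta_total}
    summary = {}
    for key, vals in out.items():
        v = np.asarray(vals, float)
        summary[key] = {
            "mean": float(v.mean()),
            "mc_se": float(v.std(ddof=1) / np.sqrt(len(v))),
            "truth": truth[key],
        }
    summary["n_reps"] = n_reps
    return summary


def null_calibration(n_reps: int = 200, seed: int = 0, k_snps: int = 20,
                     alpha: float = 0.05,
                     config: SimulationConfig = SimulationConfig()) -> dict:
    """Type-I error of the exposure->outcome IVW test under the all-null
    generator (all causal paths off, no pleiotropy)."""
    base = dataclasses.replace(config, k_snps=k_snps, pleiotropy_mean=0.0,
                               pleiotropy_sd=0.0)
    rejections = 0
    for r in range(n_reps):
        cfg = dataclasses.replace(base, seed=(seed * 100_019 + r) % _SEED_MOD)
        study = simulate_null(cfg)
        est = _ivw_pair(study.exposure, study.outcome)
        rejections += est.pvalue < alpha
    rate = rejections / n_reps
    return {"type1_error_rate": rate, "n_reps": n_reps, "alpha": alpha,
            "binomial_se": float(np.sqrt(alpha * (1 - alpha) / n_reps))}


def pleiotropy_calibration(n_reps: int = 200, seed: int = 0, k_snps: int = 20,
                           pleiotropy_mean: float = 0.02,
                           pleiotropy_sd: float = 0.01,
                           config: SimulationConfig = SimulationConfig()) -> dict:
    """Mean Egger intercept across null replicates with directional
    pleiotropy; unbiasedness requires the intercept mean to track the
    generating pleiotropy mean."""
    base = dataclasses.replace(config, k_snps=k_snps,
                               pleiotropy_mean=pleiotropy_mean,
                               pleiotropy_sd=pleiotropy_sd)
    intercepts = []
    for r in range(n_reps):
        cfg = dataclasses.replace(base, seed=(seed * 100_043 + r) % _SEED_MOD)
        study = simulate_null(cfg)
        snps = selected_instruments(instrument_report(study.exposure))
        h = harmonize(study.exposure, study.outcome, snps)
        intercepts.append(egger_intercept_test(h).intercept)
    v = np.asarray(intercepts, float)
    return {"intercept_mean": float(v.mean()),
            "mc_se": float(v.std(ddof=1) / np.sqrt(len(v))),
            "truth": pleiotropy_mean, "n_reps": n_reps}
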