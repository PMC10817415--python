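"""The eight two-sample MR causal estimators.

All methods operate on per-SNP Wald ratios beta_out/beta_exp with
first-order standard errors se_out/|beta_exp| and inverse-variance weights,
except maximum likelihood, which models exposure-side measurement error
explicitly. The primary estimator is the multiplicative random-effects IVW;
MR-Egger adds an unconstrained intercept (directional pleiotropy); the
median-, mode- and likelihood-based methods trade efficiency for robustness
to invalid instruments.

Methods:
    ivw                         inverse-variance weighted (random effects)
    mr_egger                    weighted regression with free intercept
    simple_median               unweighted median of Wald ratios
    weighted_median             inverse-variance-weighted median
    penalized_weighted_median   heterogeneity-downweighted weighted median
    mode_estimate               simple / weighted mode (KDE argmax)
    maximum_likelihood          bivariate-normal profile likelihood
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .summary_io import HarmonizedInstrumentSet

Z975 = stats.norm.ppf(0.975)

METHOD_NAMES = (
    "ivw", "mr_egger", "simple_median", "weighted_median",
    "penalized_weighted_median", "simple_mode", "weighted_mode",
    "maximum_likelihood",
)


class EstimationError(ValueError):
    pass


@dataclass(frozen=True)
class EstimatorConfig:
    """Method settings shared across an analysis run."""
    n_boot: int = 1000
    seed: int = 0
    bandwidth_factor: float = 1.0
    penalty_k: float = 20.0


@dataclass
class MREstimate:
    """One method's causal estimate on the log/linear effect scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    or_: float = field(init=False)
    or_low: float = field(init=False)
    or_high: float = field(init=False)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.or_ = beta_to_or(self.beta)
        self.or_low = beta_to_or(self.ci_low)
        self.or_high = beta_to_or(self.ci_high)


@dataclass(frozen=True)
class WaldRatioSet:
    """Per-SNP ratio estimates beta_out/beta_exp with first-order SEs."""

    snp_ids: tuple
    ratio: np.ndarray
    se: np.ndarray

    @property
    def weight(self) -> np.ndarray:
        return 1.0 / self.se ** 2

    def __len__(self) -> int:
        return len(self.ratio)


def beta_to_or(beta: float) -> float:
    """Exponentiate a log-scale effect, rounded to 5 decimals for report."""
    return round(math.exp(beta), 5)


def wald_ratios(h: HarmonizedInstrumentSet) -> WaldRatioSet:
    bx = h.table["beta_exp"].to_numpy(float)
    by = h.table["beta_out"].to_numpy(float)
    sy = h.table["se_out"].to_numpy(float)
    zero = np.flatnonzero(bx == 0)
    if zero.size:
        bad = h.table["snp_id"].iloc[zero[0]]
        raise EstimationError(f"zero exposure effect for {bad}; Wald ratio undefined")
    return WaldRatioSet(snp_ids=tuple(h.table["snp_id"]),
                        ratio=by / bx, se=sy / np.abs(bx))


def _estimate(method: str, beta: float, se: float, k: int,
              pvalue: float | None = None, extras: dict | None = None) -> MREstimate:
    p = pvalue if pvalue is not None else 2.0 * stats.norm.sf(abs(beta) / se)
    return MREstimate(method=method, beta=float(beta), se=float(se),
                      ci_low=float(beta - Z975 * se), ci_high=float(beta + Z975 * se),
                      pvalue=float(p), n_snps=k, extras=extras or {})


def _q_statistic(ratio: np.ndarray, weight: np.ndarray, center: float) -> float:
    return float(np.sum(weight * (ratio - center) ** 2))


def ivw(h: HarmonizedInstrumentSet) -> MREstimate:
    """Multiplicative random-effects IVW (the primary estimator).

    Point estimate is the inverse-variance-weighted mean of Wald ratios;
    the fixed-effect SE is inflated by max(1, sqrt(Q/(k-1))) so it never
    shrinks below the fixed-effect value. p-value from a two-sided normal.
    """
    w = wald_ratios(h)
    k = len(w)
    if k == 0:
        raise EstimationError("no instruments")
    if k == 1:
        return _estimate("wald_ratio", w.ratio[0], w.se[0], 1)
    wt = w.weight
    beta = float(np.sum(wt * w.ratio) / np.sum(wt))
    se_fixed = float(np.sum(wt) ** -0.5)
    q = _q_statistic(w.ratio, wt, beta)
    infl = max(1.0, math.sqrt(q / (k - 1)))
    se = se_fixed * infl
    return _estimate("ivw", beta, se, k, extras={
        "se_fixed": se_fixed, "Q": q, "Q_df": k - 1,
        "Q_pvalue": float(stats.chi2.sf(q, k - 1)),
    })


def mr_egger(h: HarmonizedInstrumentSet) -> MREstimate:
    """MR-Egger: WLS of beta_out on beta_exp with an unconstrained intercept.

    SNPs are oriented so beta_exp >= 0 before fitting. The slope is the
    causal estimate; a nonzero intercept indicates directional pleiotropy.
    Standard errors use the multiplicative model with inflation floored at 1;
    p-values use a t distribution on k-2 df.
    """
    k = h.n_snps
    if k < 3:
        raise EstimationError("Egger requires >=3 instruments")
    bx = h.table["beta_exp"].to_numpy(float).copy()
    by = h.table["beta_out"].to_numpy(float).copy()
    sy = h.table["se_out"].to_numpy(float)
    flip = bx < 0
    bx[flip] *= -1
    by[flip] *= -1
    w = 1.0 / sy ** 2

    sw, swx = w.sum(), (w * bx).sum()
    swx2, swy, swxy = (w * bx * bx).sum(), (w * by).sum(), (w * bx * by).sum()
    det = sw * swx2 - swx ** 2
    if det <= 1e-12 * sw * swx2 or not np.isfinite(det):
        raise EstimationError("singular design: exposure effects carry no spread")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swx2 * swy - swx * swxy) / det
    resid = by - intercept - slope * bx
    q = float(np.sum(w * resid ** 2))
    scale2 = max(1.0, q / (k - 2))
    se_slope = math.sqrt(sw / det * scale2)
    se_int = math.sqrt(swx2 / det * scale2)
    df = k - 2
    p_slope = 2.0 * stats.t.sf(abs(slope) / se_slope, df)
    p_int = 2.0 * stats.t.sf(abs(intercept) / se_int, df)
    tq = stats.t.ppf(0.975, df)
    est = _estimate("mr_egger", slope, se_slope, k, pvalue=p_slope, extras={
        "intercept": float(intercept), "intercept_se": float(se_int),
        "intercept_pvalue": float(p_int), "Q": q, "Q_df": df,
        "Q_pvalue": float(stats.chi2.sf(q, df)),
    })
    # t-based CI overrides the normal-theory default
    est.ci_low, est.ci_high = slope - tq * se_slope, slope + tq * se_slope
    est.or_low, est.or_high = beta_to_or(est.ci_low), beta_to_or(est.ci_high)
    return est


def _weighted_median_point(ratio: np.ndarray, weight: np.ndarray) -> float:
    """Interpolated weighted median of ``ratio`` under ``weight``."""
    order = np.argsort(ratio, kind="mergesort")
    r, w = ratio[order], weight[order]
    s = np.cumsum(w)
    p = (s - w / 2.0) / s[-1]
    return float(np.interp(0.5, p, r))


def _parametric_bootstrap_se(h: HarmonizedInstrumentSet, point_fn, n_boot: int,
                             seed: int) -> float:
    """SE of a ratio-based statistic via parametric resampling of the
    per-SNP effects from normal(beta, se) on both sides."""
    rng = np.random.default_rng(seed)
    bx = h.table["beta_exp"].to_numpy(float)
    sx = h.table["se_exp"].to_numpy(float)
    by = h.table["beta_out"].to_numpy(float)
    sy = h.table["se_out"].to_numpy(float)
    w0 = 1.0 / (sy / np.abs(bx)) ** 2  # weights held at observed precision
    vals = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs[bxs == 0] = 1e-300
        ratios = bys / bxs
        vals[b] = point_fn(ratios, w0)
    return float(np.std(vals, ddof=1))


def simple_median(h: HarmonizedInstrumentSet,
                  config: EstimatorConfig = EstimatorConfig()) -> MREstimate:
    """Unweighted median of Wald ratios with parametric-bootstrap SE."""
    if h.n_snps < 3:
        raise EstimationError("median methods require >=3 instruments")
    w = wald_ratios(h)
    beta = float(np.median(w.ratio))
    se = _parametric_bootstrap_se(h, lambda r, _w: np.median(r),
                                  config.n_boot, config.seed)
    return _estimate("simple_median", beta, se, len(w))


def weighted_median(h: HarmonizedInstrumentSet,
                    config: EstimatorConfig = EstimatorConfig()) -> MREstimate:
    """Inverse-variance weighted median (consistent if >=50% of weight is
    on valid instruments)."""
    if h.n_snps < 3:
        raise EstimationError("median methods require >=3 instruments")
    w = wald_ratios(h)
    beta = _weighted_median_point(w.ratio, w.weight)
    se = _parametric_bootstrap_se(h, _weighted_median_point,
                                  config.n_boot, config.seed)
    return _estimate("weighted_median", beta, se, len(w))


def _penalized_point(ratio: np.ndarray, weight: np.ndarray,
                     penalty_k: float) -> float:
    beta0 = _weighted_median_point(ratio, weight)
    qj = weight * (ratio - beta0) ** 2
    pen = np.minimum(1.0, penalty_k * stats.chi2.sf(qj, 1))
    w2 = weight * pen
    if not np.any(w2 > 0):
        raise EstimationError("penalized weights all zero (penalty_k too small?)")
    return _weighted_median_point(ratio, w2)


def penalized_weighted_median(h: HarmonizedInstrumentSet,
                              config: EstimatorConfig = EstimatorConfig()) -> MREstimate:
    """Weighted median after downweighting SNPs with outlying per-SNP
    heterogeneity contributions (chi-square(1) tail penalty)."""
    if h.n_snps < 3:
        raise EstimationError("median methods require >=3 instruments")
    w = wald_ratios(h)
    beta = _penalized_point(w.ratio, w.weight, config.penalty_k)
    se = _parametric_bootstrap_se(
        h, lambda r, wt: _penalized_point(r, wt, config.penalty_k),
        config.n_boot, config.seed)
    return _estimate("penalized_weighted_median", beta, se, len(w))


def _mode_point(ratio: np.ndarray, weight: np.ndarray,
                bandwidth_factor: float) -> float:
    k = len(ratio)
    sd = float(np.std(ratio, ddof=1)) if k > 1 else 0.0
    mad = float(np.median(np.abs(ratio - np.median(ratio)))) / 0.6745
    cands = [c for c in (sd, mad) if c > 0]
    if not cands:  # all ratios identical
        return float(ratio[0])
    h_bw = bandwidth_factor * 0.9 * min(cands) * k ** (-1 / 5)
    grid = np.linspace(ratio.min() - 3 * h_bw, ratio.max() + 3 * h_bw, 512)
    dens = (weight[None, :] *
            stats.norm.pdf((grid[:, None] - ratio[None, :]) / h_bw)).sum(axis=1)
    # ties at the max break toward the smaller ratio value: argmax takes the
    # first index of the (ascending) grid
    return float(grid[int(np.argmax(dens))])


def mode_estimate(h: HarmonizedInstrumentSet, weighted: bool = False,
                  config: EstimatorConfig = EstimatorConfig()) -> MREstimate:
    """Mode-based estimate: argmax of a normal-kernel density over Wald
    ratios (unit weights for the simple mode, inverse-variance weights for
    the weighted mode), evaluated on a 512-point grid."""
    if h.n_snps < 3:
        raise EstimationError("mode methods require >=3 instruments")
    w = wald_ratios(h)
    wt = w.weight if weighted else np.ones(len(w))
    beta = _mode_point(w.ratio, wt, config.bandwidth_factor)
    se = _parametric_bootstrap_se(
        h,
        (lambda r, ww: _mode_point(r, ww, config.bandwidth_factor)) if weighted
        else (lambda r, _ww: _mode_point(r, np.ones(len(r)), config.bandwidth_factor)),
        config.n_boot, config.seed)
    name = "weighted_mode" if weighted else "simple_mode"
    return _estimate(name, beta, se, len(w))


def _profile_negloglik(theta: float, bx, sx, by, sy) -> float:
    # per-SNP true exposure effects profiled out in closed form; the
    # variance log-terms do not involve theta and drop from the profile
    return float(0.5 * np.sum((by - theta * bx) ** 2
                              / (sy ** 2 + theta ** 2 * sx ** 2)))


def maximum_likelihood(h: HarmonizedInstrumentSet) -> MREstimate:
    """Profile-likelihood estimate under the bivariate measurement-error
    model beta_exp_j ~ N(xi_j, se_exp^2), beta_out_j ~ N(theta*xi_j, se_out^2),
    the one estimator that models exposure-side sampling error. SE from the
    numerical observed information."""
    if h.n_snps < 1:
        raise EstimationError("no instruments")
    bx = h.table["beta_exp"].to_numpy(float)
    sx = h.table["se_exp"].to_numpy(float)
    by = h.table["beta_out"].to_numpy(float)
    sy = h.table["se_out"].to_numpy(float)
    if np.any(bx == 0):
        raise EstimationError("zero exposure effect; ratio model undefined")
    start = ivw(h).beta if h.n_snps > 1 else by[0] / bx[0]
    span = 10.0 * (abs(start) + np.max(sy / np.abs(bx)))
    res = optimize.minimize_scalar(
        _profile_negloglik, bounds=(start - span, start + span),
        args=(bx, sx, by, sy), method="bounded",
        options={"xatol": 1e-10, "maxiter": 500})
    if not res.success:
        raise EstimationError(f"ML optimization did not converge: {res.message}")
    theta = float(res.x)
    step = 1e-4 * max(1.0, abs(theta))
    d2 = (_profile_negloglik(theta + step, bx, sx, by, sy)
          - 2.0 * _profile_negloglik(theta, bx, sx, by, sy)
          + _profile_negloglik(theta - step, bx, sx, by, sy)) / step ** 2
    if d2 <= 0 or not np.isfinite(d2):
        raise EstimationError("non-positive observed information at the optimum")
    se = math.sqrt(1.0 / d2)
    return _estimate("maximum_likelihood", theta, se, h.n_snps)


def run_all_methods(h: HarmonizedInstrumentSet,
                    config: EstimatorConfig = EstimatorConfig()
                    ) -> list[MREstimate]:
    """The paper-battery of eight methods on one exposure-outcome pair.

    With a single instrument every ratio-based method degenerates to the
    Wald ratio; methods whose minimum instrument count is not met are
    reported as not-estimable rows by the pipeline rather than raising here.
    """
    out = [ivw(h)]
    seeds = {m: config.seed + i for i, m in enumerate(METHOD_NAMES)}
    out.append(mr_egger(h))
    out.append(simple_median(h, replace(config, seed=seeds["simple_median"])))
    out.append(weighted_median(h, replace(config, seed=seeds["weighted_median"])))
    out.append(penalized_weighted_median(
        h, replace(config, seed=seeds["penalized_weighted_median"])))
    out.append(mode_estimate(h, weighted=False,
                             config=replace(config, seed=seeds["simple_mode"])))
    out.append(mode_estimate(h, weighted=True,
                             config=replace(config, seed=seeds["weighted_mode"])))
    out.append(maximum_likelihood(h))
    return out


def estimates_to_frame(estimates: list[MREstimate]) -> pd.DataFrame:
    rows = [{
        "method": e.method, "n_snps": e.n_snps, "beta": e.beta, "se": e.se,
        "ci_low": e.ci_low, "ci_high": e.ci_high, "pvalue": e.pvalue,
        "or": e.or_, "or_low": e.or_low, "or_high": e.or_high,
    } for e in estimates]
    return pd.DataFrame(rows)
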