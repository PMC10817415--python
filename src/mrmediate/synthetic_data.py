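"""Synthetic GWAS summary statistics for a three-trait mediation chain.

Emulates the exposure -> mediator -> outcome design on which the analysis
runs: k independent SNPs act on the exposure with effects gamma_j, the
exposure acts on the mediator (theta_xm), and the outcome receives a direct
exposure path (theta_direct), the mediated path (theta_xm * theta_my), and
optional per-SNP horizontal pleiotropy alpha_j. A further k SNPs act on the
mediator alone (effects delta_j, zero on the exposure, theta_my * delta_j
on the outcome), mirroring the two-protein design in which each trait is
instrumented by its own distinct loci; exposure SNPs still show their
transmitted effects theta_xm * gamma_j in the mediator GWAS, as a causal
chain requires. Summary statistics are
generated directly at the summary level: per-trait standard errors follow
the standardized-trait approximation se = (2 MAF (1-MAF) n)^(-1/2) and
observed betas are normal around their expectations. Effect alleles are
coded as the exposure-increasing allele (gamma_j >= 0 by convention), which
makes directional pleiotropy well-defined relative to the oriented
instruments. Instrument usability is guaranteed by rejection-sampling
gamma_j until its expected exposure-GWAS p-value is genome-wide significant.

Optional LD proxies are built from a small latent-genotype construction
(haplotype copying with probability sqrt(r2)) so that emitted pairwise r^2
values are empirical, not nominal.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import LDTable
from .summary_io import COMPLEMENT, SummaryDataset, dataset_from_frame

#: z threshold for two-sided p < 5e-8
Z_GWS = float(stats.norm.isf(2.5e-8))

_MAX_REJECTION_ATTEMPTS = 1000


class InstrumentStrengthError(RuntimeError):
    """gamma_sd is too small for the exposure sample size: rejection
    sampling cannot reach genome-wide significance."""


@dataclass(frozen=True)
class SimulationConfig:
    """Causal-graph and noise parameters of the generator.

    Defaults describe a well-powered three-GWAS design: 50 instruments,
    50,000 samples per GWAS, pQTL-scale per-allele effects (SD 0.35 of a
    standardized trait), a mediation chain with theta_xm = 0.4,
    theta_my = 0.5 and a direct effect of 0.2, i.e. a total effect of 0.4
    of which 50% is mediated, and no pleiotropy.
    """

    k_snps: int = 50
    n_exp: int = 50_000
    n_med: int = 50_000
    n_out: int = 50_000
    maf_range: tuple[float, float] = (0.1, 0.5)
    gamma_sd: float = 0.35
    theta_xm: float = 0.4
    theta_my: float = 0.5
    theta_direct: float = 0.2
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    ld_proxy_count: int = 0
    ld_proxy_r2: float = 0.8
    n_ref: int = 10_000  # reference individuals for the proxy construction
    window_kb: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if min(self.n_exp, self.n_med, self.n_out) < 10:
            raise ValueError("sample sizes must be >= 10")
        if self.k_snps < 1:
            raise ValueError("k_snps must be >= 1")
        if not (0 <= self.ld_proxy_r2 < 1):
            raise ValueError("ld_proxy_r2 must be in [0,1)")

    @property
    def theta_total(self) -> float:
        return self.theta_direct + self.theta_xm * self.theta_my


@dataclass
class SimulatedStudy:
    exposure: SummaryDataset
    mediator: SummaryDataset
    outcome: SummaryDataset
    truth: dict
    ld: LDTable | None


def _se(maf: np.ndarray | float, n: int) -> np.ndarray | float:
    return (2.0 * maf * (1.0 - maf) * n) ** -0.5


_NONPALINDROMIC = [(a, b) for a in "ACGT" for b in "ACGT"
                   if b != a and b != COMPLEMENT[a]]


def _draw_gamma(rng: np.random.Generator, gamma_sd: float, se_x: float,
                maf: float) -> float:
    # half-normal, resampled until the expected exposure z-score clears
    # genome-wide significance; a single SNP cannot explain more variance
    # of a standardized trait than the trait has, so 2p(1-p)g^2 < 1
    g_max = (2.0 * maf * (1.0 - maf)) ** -0.5
    for _ in range(_MAX_REJECTION_ATTEMPTS):
        g = abs(rng.normal(0.0, gamma_sd))
        if g / se_x > Z_GWS and g < 0.99 * g_max:
            return g
    raise InstrumentStrengthError(
        f"no genome-wide-significant effect in {_MAX_REJECTION_ATTEMPTS} draws "
        f"(gamma_sd={gamma_sd}, se_exposure={se_x:.4g})")


def simulate_chain(config: SimulationConfig) -> SimulatedStudy:
    """Generate the three linked summary datasets plus a ground-truth record.

    Causal SNPs are spaced farther apart than the clumping window (cycling
    over chromosomes), so only planted LD proxies ever co-occur within a
    window. Reproducible: the same config (including seed) yields identical
    datasets.
    """
    rng = np.random.default_rng(config.seed)
    k = config.k_snps
    spacing = int(config.window_kb * 1000 * 2) + 1

    rows_exp, rows_med, rows_out = [], [], []
    truth_snps = []
    dosages: dict[str, np.ndarray] = {}
    need_ld = config.ld_proxy_count > 0
    cluster_ids: list[list[str]] = []

    # 2k loci: exposure instruments first, then mediator-specific instruments
    for locus in range(2 * k):
        role = "exposure_instrument" if locus < k else "mediator_instrument"
        maf = float(rng.uniform(*config.maf_range))
        se_x = float(_se(maf, config.n_exp))
        se_m = float(_se(maf, config.n_med))
        se_y = float(_se(maf, config.n_out))
        if role == "exposure_instrument":
            effect = _draw_gamma(rng, config.gamma_sd, se_x, maf)  # gamma_j
        else:
            effect = _draw_gamma(rng, config.gamma_sd, se_m, maf)  # delta_j
        alpha = float(rng.normal(config.pleiotropy_mean, config.pleiotropy_sd)) \
            if (config.pleiotropy_mean or config.pleiotropy_sd) else 0.0
        ea, oa = _NONPALINDROMIC[int(rng.integers(len(_NONPALINDROMIC)))]
        chrom = str(locus % 22 + 1)
        pos = (locus // 22 + 1) * spacing
        base_id = 100000 + 100 * locus
        snp = f"rs{base_id}"

        members = [(snp, pos, 1.0)]  # (id, position, dosage-correlation with parent)
        if need_ld:
            q = float(np.sqrt(config.ld_proxy_r2))
            hap = (rng.random((config.n_ref, 2)) < maf).astype(np.int8)
            dosages[snp] = hap.sum(axis=1)
            for i in range(config.ld_proxy_count):
                copy = rng.random((config.n_ref, 2)) < q
                fresh = (rng.random((config.n_ref, 2)) < maf).astype(np.int8)
                phap = np.where(copy, hap, fresh)
                pid = f"rs{base_id + i + 1}"
                dosages[pid] = phap.sum(axis=1)
                r = float(np.corrcoef(dosages[snp], dosages[pid])[0, 1])
                members.append((pid, pos + (i + 1) * 1000, r))
            cluster_ids.append([m[0] for m in members])

        for sid, sp_pos, r in members:
            a_eff = r * alpha
            if role == "exposure_instrument":
                g_eff = r * effect
                mu_x = g_eff
                mu_m = config.theta_xm * g_eff
                mu_y = config.theta_total * g_eff + a_eff
            else:
                d_eff = r * effect
                mu_x = 0.0
                mu_m = d_eff
                mu_y = config.theta_my * d_eff + a_eff
            bx = float(rng.normal(mu_x, se_x))
            bm = float(rng.normal(mu_m, se_m))
            by = float(rng.normal(mu_y, se_y))

            def _p(beta, se):
                # clamp underflow so files round-trip through the reader
                return max(2 * stats.norm.sf(abs(beta) / se), 1e-300)
            base = dict(chrom=chrom, pos=sp_pos, effect_allele=ea,
                        other_allele=oa, eaf=maf)
            rows_exp.append(dict(snp_id=sid, **base, beta=bx, se=se_x,
                                 pvalue=_p(bx, se_x),
                                 n=config.n_exp))
            rows_med.append(dict(snp_id=sid, **base, beta=bm, se=se_m,
                                 pvalue=_p(bm, se_m),
                                 n=config.n_med))
            rows_out.append(dict(snp_id=sid, **base, beta=by, se=se_y,
                                 pvalue=_p(by, se_y),
                                 n=config.n_out))
            truth_snps.append(dict(snp_id=sid, role=role,
                                   effect=r * effect, alpha=a_eff, maf=maf,
                                   is_proxy=sid != snp, parent=snp))

    ld = None
    if need_ld:
        # pairwise empirical r^2 within each proxy cluster
        pairs = {}
        for ids in cluster_ids:
            for a in range(len(ids)):
                for b in range(a + 1, len(ids)):
                    r = np.corrcoef(dosages[ids[a]], dosages[ids[b]])[0, 1]
                    pairs[frozenset((ids[a], ids[b]))] = float(r ** 2)
        ld = LDTable(pairs)

    cols = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pvalue", "n"]
    truth = {
        "theta_xm": config.theta_xm, "theta_my": config.theta_my,
        "theta_direct": config.theta_direct, "theta_total": config.theta_total,
        "mediated_proportion_pct": (
            100.0 * config.theta_xm * config.theta_my / config.theta_total
            if config.theta_total != 0 else None),
        "pleiotropy_mean": config.pleiotropy_mean,
        "pleiotropy_sd": config.pleiotropy_sd,
        "snps": truth_snps,
        "config": dataclasses.asdict(config),
    }
    return SimulatedStudy(
        exposure=dataset_from_frame(pd.DataFrame(rows_exp, columns=cols),
                                    "sim_exposure", n_default=config.n_exp),
        mediator=dataset_from_frame(pd.DataFrame(rows_med, columns=cols),
                                    "sim_mediator", n_default=config.n_med),
        outcome=dataset_from_frame(pd.DataFrame(rows_out, columns=cols),
                                   "sim_outcome", trait_type="binary",
                                   n_default=config.n_out),
        truth=truth, ld=ld)


def simulate_null(config: SimulationConfig) -> SimulatedStudy:
    """The same generator with every causal path switched off (theta = 0);
    pleiotropy settings are kept, so it also serves the directional-
    pleiotropy calibration."""
    null_cfg = dataclasses.replace(config, theta_xm=0.0, theta_my=0.0,
                                   theta_direct=0.0)
    return simulate_chain(null_cfg)


def write_study(study: SimulatedStudy, outdir) -> dict[str, str]:
    """Serialize datasets (conventional TSV dialect), ground truth (JSON)
    and, when present, the r^2 table. Returns {section: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, ds in (("exposure", study.exposure), ("mediator", study.mediator),
                     ("outcome", study.outcome)):
        p = outdir / f"{name}.tsv"
        ds.to_tsv(p)
        paths[name] = str(p)
    tp = outdir / "truth.json"
    tp.write_text(json.dumps(study.truth, indent=1, sort_keys=True))
    paths["truth"] = str(tp)
    if study.ld is not None:
        lp = outdir / "ld_r2.tsv"
        study.ld.to_tsv(lp)
        paths["ld"] = str(lp)
    return paths
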