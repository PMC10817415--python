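"""End-to-end two-step MR study orchestration.

Runs, for each of the three forward trait pairs (exposure->mediator,
exposure->outcome, mediator->outcome): instrument selection, harmonization,
the eight-method estimator battery, and sensitivity diagnostics; then the
reverse-direction checks and the mediation decomposition; and serializes
everything as TSV tables plus a JSON manifest. Partial failures (e.g. a
reverse direction with no instruments) degrade to annotated report sections.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import estimators
from .estimators import EstimatorConfig, MREstimate, ivw, wald_ratios
from .instruments import (InstrumentSelectionConfig, LDTable,
                          instrument_report, load_exclusion_list,
                          select_by_pvalue, selected_instruments)
from .mediation import MediationResult, two_step_mediation
from .sensitivity import (ReverseResult, egger_intercept_test, heterogeneity,
                          leave_one_out, reverse_direction)
from .summary_io import (ConfigurationError, HarmonizationError,
                         SummaryDataset, harmonize, read_summary_stats)

logger = logging.getLogger(__name__)

FORWARD_PAIRS = (("exposure", "mediator"), ("exposure", "outcome"),
                 ("mediator", "outcome"))
REVERSE_PAIRS = (("outcome", "exposure"), ("outcome", "mediator"),
                 ("mediator", "exposure"))


@dataclass(frozen=True)
class TraitSpec:
    path: str
    trait_id: str
    trait_type: str = "quantitative"
    n_default: float | None = None
    column_map: dict | None = None


@dataclass(frozen=True)
class AnalysisConfig:
    exposure: TraitSpec
    mediator: TraitSpec
    outcome: TraitSpec
    outdir: str = "mr_report"
    selection: InstrumentSelectionConfig = InstrumentSelectionConfig()
    estimator: EstimatorConfig = EstimatorConfig()
    ld_path: str | None = None
    exclusion_path: str | None = None
    r2_mode: str = "from-eaf"
    palindrome_eaf_window: tuple[float, float] = (0.42, 0.58)
    run_reverse: bool = True
    run_mediation: bool = True
    #: drop, from the mediator->outcome instrument set, SNPs genome-wide
    #: significant for the exposure: an upstream exposure with a direct
    #: outcome path otherwise contaminates the step-2 Wald ratios
    filter_mediator_instruments: bool = True
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        kwargs = dict(raw)
        for trait in ("exposure", "mediator", "outcome"):
            kwargs[trait] = TraitSpec(**raw[trait])
        if "selection" in raw:
            kwargs["selection"] = InstrumentSelectionConfig(**raw["selection"])
        if "estimator" in raw:
            kwargs["estimator"] = EstimatorConfig(**raw["estimator"])
        if "palindrome_eaf_window" in raw:
            kwargs["palindrome_eaf_window"] = tuple(raw["palindrome_eaf_window"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["palindrome_eaf_window"] = list(self.palindrome_eaf_window)
        return d


@dataclass
class PairResult:
    name: str
    exposure_id: str
    outcome_id: str
    estimable: bool
    reason: str | None = None
    instrument_report: pd.DataFrame | None = None
    harmonization_log: pd.DataFrame | None = None
    estimates: list[MREstimate] = field(default_factory=list)
    heterogeneity: list = field(default_factory=list)
    pleiotropy: object = None
    leave_one_out: pd.DataFrame | None = None
    scatter: pd.DataFrame | None = None
    forest: pd.DataFrame | None = None


@dataclass
class StudyReport:
    config: AnalysisConfig
    pairs: dict[str, PairResult]
    reverse: dict[str, ReverseResult]
    mediation: MediationResult | None
    mediation_skip_reason: str | None = None


def _analyze_pair(name: str, exposure: SummaryDataset, outcome: SummaryDataset,
                  config: AnalysisConfig, ld: LDTable | None,
                  exclude: set[str]) -> PairResult:
    res = PairResult(name=name, exposure_id=exposure.trait_id,
                     outcome_id=outcome.trait_id, estimable=False)
    try:
        rep = instrument_report(exposure, config.selection, ld,
                                r2_mode=config.r2_mode, exclude=exclude)
        res.instrument_report = rep
        snps = selected_instruments(rep)
        if not snps:
            res.reason = "no instruments passed selection"
            return res
        h = harmonize(exposure, outcome, snps,
                      palindrome_eaf_window=config.palindrome_eaf_window)
    except (ValueError, HarmonizationError) as exc:
        res.reason = str(exc)
        return res
    res.harmonization_log = h.log
    if h.n_snps >= 3:
        res.estimates = estimators.run_all_methods(h, config.estimator)
    else:
        res.estimates = [ivw(h)]
    res.heterogeneity = heterogeneity(h)
    if h.n_snps >= 3:
        res.pleiotropy = egger_intercept_test(h)
    if h.n_snps >= 2:
        res.leave_one_out = leave_one_out(h)
    res.scatter = h.table[["snp_id", "beta_exp", "se_exp",
                           "beta_out", "se_out"]].copy()
    w = wald_ratios(h)
    res.forest = pd.DataFrame({
        "snp_id": list(w.snp_ids), "ratio": w.ratio, "se": w.se,
        "ci_low": w.ratio - 1.959963984540054 * w.se,
        "ci_high": w.ratio + 1.959963984540054 * w.se,
    })
    res.estimable = True
    return res


def run_two_step_datasets(
    exposure: SummaryDataset, mediator: SummaryDataset,
    outcome: SummaryDataset, config: AnalysisConfig,
    ld: LDTable | None = None,
) -> StudyReport:
    """The full study on already-loaded datasets (the CLI wrapper loads
    files first). Deterministic given config (all bootstrap seeds derive
    from ``config.estimator.seed``)."""
    exclude = set()
    if config.exclusion_path:
        exclude = load_exclusion_list(config.exclusion_path)
    if ld is None and config.ld_path:
        ld = LDTable.from_tsv(config.ld_path)

    traits = {"exposure": exposure, "mediator": mediator, "outcome": outcome}
    upstream: set[str] = set()
    if config.filter_mediator_instruments:
        try:
            upstream = set(select_by_pvalue(exposure, config.selection.p_threshold))
        except ValueError:
            upstream = set()
    pairs = {}
    for a, b in FORWARD_PAIRS:
        name = f"{a}_{b}"
        pair_exclude = exclude | (upstream if a == "mediator" else set())
        pairs[name] = _analyze_pair(name, traits[a], traits[b], config, ld,
                                    pair_exclude)
        logger.info("pair %s: %s", name,
                    "ok" if pairs[name].estimable else pairs[name].reason)

    reverse = {}
    if config.run_reverse:
        for a, b in REVERSE_PAIRS:
            name = f"{a}_{b}"
            reverse[name] = reverse_direction(
                traits[a], traits[b], config.selection, config.estimator,
                ld=ld, r2_mode=config.r2_mode, alpha=config.alpha,
                palindrome_eaf_window=config.palindrome_eaf_window)

    med = None
    med_skip = None
    if config.run_mediation:
        fw = [pairs["exposure_outcome"], pairs["exposure_mediator"],
              pairs["mediator_outcome"]]
        if all(p.estimable for p in fw):
            def _ivw_of(p: PairResult) -> MREstimate:
                return next(e for e in p.estimates
                            if e.method in ("ivw", "wald_ratio"))
            med = two_step_mediation(
                _ivw_of(fw[0]), _ivw_of(fw[1]), _ivw_of(fw[2]),
                exposure_id=exposure.trait_id, mediator_id=mediator.trait_id,
                outcome_id=outcome.trait_id)
        else:
            med_skip = "; ".join(f"{p.name}: {p.reason}" for p in fw
                                 if not p.estimable)
    else:
        med_skip = "run_mediation disabled"
    return StudyReport(config=config, pairs=pairs, reverse=reverse,
                       mediation=med, mediation_skip_reason=med_skip)


def run_two_step(config: AnalysisConfig) -> StudyReport:
    """Load the three summary-statistic files named in ``config`` and run
    the study. Unreadable inputs raise before any computation starts."""
    datasets = {}
    for role in ("exposure", "mediator", "outcome"):
        spec: TraitSpec = getattr(config, role)
        if not Path(spec.path).exists():
            raise ConfigurationError(f"{role} file not found: {spec.path}")
        datasets[role] = read_summary_stats(
            spec.path, column_map=spec.column_map, trait_type=spec.trait_type,
            n_default=spec.n_default, trait_id=spec.trait_id)
    return run_two_step_datasets(datasets["exposure"], datasets["mediator"],
                                 datasets["outcome"], config)


# ---------------------------------------------------------------- reporting

def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    """Paper-precision display: effects/ORs to 5 decimals, p to 4 sig figs."""
    out = df.copy()
    for col in out.columns:
        if col in ("pvalue", "Q_pvalue", "intercept_pvalue"):
            out[col] = out[col].map(lambda v: f"{v:.4g}" if pd.notna(v) else "")
        elif out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: f"{v:.5f}" if pd.notna(v) else "")
    return out


def _write(df: pd.DataFrame, path: Path) -> None:
    _fmt(df).to_csv(path, sep="\t", index=False)


def _estimates_frame(pairs: dict, which: str = "pair") -> pd.DataFrame:
    rows = []
    for name, p in pairs.items():
        ests = p.estimates if getattr(p, "estimable", False) else []
        if not ests:
            rows.append({which: name, "method": "<none>", "n_snps": 0,
                         "note": getattr(p, "reason", None)})
        for e in ests:
            rows.append({which: name, "method": e.method, "n_snps": e.n_snps,
                         "beta": e.beta, "se": e.se, "ci_low": e.ci_low,
                         "ci_high": e.ci_high, "pvalue": e.pvalue, "or": e.or_,
                         "or_low": e.or_low, "or_high": e.or_high, "note": None})
    return pd.DataFrame(rows)


def mediation_frame(med: MediationResult) -> pd.DataFrame:
    return pd.DataFrame([{
        "total_effect": med.total_effect,
        "total_ci_low": med.total_ci[0], "total_ci_high": med.total_ci[1],
        "beta1": med.beta1,
        "beta1_ci_low": med.beta1_ci[0], "beta1_ci_high": med.beta1_ci[1],
        "beta2": med.beta2,
        "beta2_ci_low": med.beta2_ci[0], "beta2_ci_high": med.beta2_ci[1],
        "mediation_effect": med.mediation_effect_rounded,
        "mediation_ci_low": med.ci_low, "mediation_ci_high": med.ci_high,
        "proportion_mediated_pct": med.proportion_mediated,
        "se_mediation": med.se_mediation,
        "mediation_effect_unrounded": med.mediation_effect,
        "direct_effect": med.direct_effect,
        "pvalue": med.pvalue,
        "consistent": med.consistent,
    }])


def render_report(report: StudyReport, outdir=None) -> dict:
    """Write every table plus ``manifest.json`` (file checksums + resolved
    config); returns the manifest dict."""
    outdir = Path(outdir if outdir is not None else report.config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        _write(df, path)
        written.append(path)

    emit(_estimates_frame(report.pairs), "estimates.tsv")
    het_rows, plei_rows = [], []
    for name, p in report.pairs.items():
        if p.instrument_report is not None:
            emit(p.instrument_report, f"instruments_{name}.tsv")
        if p.harmonization_log is not None:
            emit(p.harmonization_log, f"harmonization_{name}.tsv")
        if p.leave_one_out is not None:
            emit(p.leave_one_out, f"leave_one_out_{name}.tsv")
        if p.scatter is not None:
            emit(p.scatter, f"scatter_{name}.tsv")
        if p.forest is not None:
            emit(p.forest, f"forest_{name}.tsv")
        for hres in p.heterogeneity:
            het_rows.append({"pair": name, "context": hres.method_context,
                             "Q": hres.Q, "df": hres.df, "pvalue": hres.pvalue,
                             "heterogeneity_present": hres.pvalue < report.config.alpha})
        if p.pleiotropy is not None:
            plei_rows.append({"pair": name, "intercept": p.pleiotropy.intercept,
                              "se": p.pleiotropy.se, "pvalue": p.pleiotropy.pvalue,
                              "pleiotropy_present": p.pleiotropy.present(report.config.alpha)})
    if het_rows:
        emit(pd.DataFrame(het_rows), "heterogeneity.tsv")
    if plei_rows:
        emit(pd.DataFrame(plei_rows), "pleiotropy.tsv")

    skipped = {}
    if report.reverse:
        rev_pairs = {}
        for name, r in report.reverse.items():
            if r.estimable:
                rev_pairs[name] = type("X", (), {
                    "estimable": True, "estimates": r.estimates, "reason": None})()
            else:
                rev_pairs[name] = type("X", (), {
                    "estimable": False, "estimates": [], "reason": r.reason})()
        df = _estimates_frame(rev_pairs)
        df["no_causal_effect"] = df["pair"].map(
            {n: r.no_causal_effect for n, r in report.reverse.items()})
        emit(df, "reverse_estimates.tsv")
    for name, p in report.pairs.items():
        if not p.estimable:
            skipped[name] = p.reason
    if report.mediation is not None:
        emit(mediation_frame(report.mediation), "mediation.tsv")
    else:
        skipped["mediation"] = report.mediation_skip_reason

    manifest = {
        "files": {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                  for p in sorted(written)},
        "config": report.config.to_dict(),
        "sections_skipped": skipped,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    return manifest
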