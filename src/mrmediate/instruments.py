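"""Instrument selection and strength validation.

Instruments are SNPs passing genome-wide significance (p < 5e-8 by default,
strict inequality), pruned to mutual independence by greedy LD clumping
(r^2 < 0.001 within a 10,000 kb window by default), and screened for weak
instrument bias via the first-stage F-statistic (F < 10 flags a weak
instrument). Per-SNP variance explained R^2 is computed either from the
effect-allele frequency on a standardized trait, R^2 = 2p(1-p)b^2, or from
the t-statistic, R^2 = t^2/(t^2 + n - 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .summary_io import SummaryDataset


class LDError(ValueError):
    """An in-window pair has no r^2 entry; independence may not be assumed."""


@dataclass(frozen=True)
class InstrumentSelectionConfig:
    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    window_kb: float = 10_000.0
    f_threshold: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0,1)")
        if not (0 <= self.r2_threshold <= 1):
            raise ValueError("r2_threshold must be in [0,1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")
        if self.f_threshold < 0:
            raise ValueError("f_threshold must be >= 0")


class LDTable:
    """Symmetric pairwise r^2 lookup keyed by rsID pairs."""

    def __init__(self, pairs: dict[frozenset, float] | None = None):
        self._pairs = dict(pairs or {})

    @classmethod
    def from_pairs(cls, df: pd.DataFrame) -> "LDTable":
        """Build from a 3-column frame/TSV layout (snp_a, snp_b, r2)."""
        a, b, r = df.columns[:3]
        pairs = {frozenset((row[a], row[b])): float(row[r]) for _, row in df.iterrows()}
        return cls(pairs)

    @classmethod
    def from_tsv(cls, path) -> "LDTable":
        return cls.from_pairs(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_matrix(cls, df: pd.DataFrame) -> "LDTable":
        """Build from a square r^2 matrix with an rsID index and columns."""
        pairs = {}
        for i, a in enumerate(df.index):
            for b in df.columns[i + 1:]:
                pairs[frozenset((a, b))] = float(df.loc[a, b])
        return cls(pairs)

    @classmethod
    def from_dosages(cls, dosages: pd.DataFrame) -> "LDTable":
        """Squared Pearson correlation of genotype dosage columns (one SNP
        per column, individuals in rows, values in {0,1,2})."""
        corr = dosages.corr().to_numpy() ** 2
        pairs = {}
        snps = list(dosages.columns)
        for i in range(len(snps)):
            for j in range(i + 1, len(snps)):
                pairs[frozenset((snps[i], snps[j]))] = float(corr[i, j])
        return cls(pairs)

    def r2(self, a: str, b: str) -> float | None:
        return self._pairs.get(frozenset((a, b)))

    def to_tsv(self, path) -> None:
        rows = [(*sorted(k), v) for k, v in sorted(self._pairs.items(),
                                                   key=lambda kv: sorted(kv[0]))]
        pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).to_csv(
            path, sep="\t", index=False, float_format="%.6g")


def select_by_pvalue(dataset: SummaryDataset, p_threshold: float = 5e-8) -> list[str]:
    """SNPs with p strictly below threshold, ascending p (ties by rsID)."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    hits = dataset.table.loc[dataset.table["pvalue"] < p_threshold,
                             ["snp_id", "pvalue"]]
    hits = hits.sort_values(["pvalue", "snp_id"], kind="mergesort")
    return hits["snp_id"].tolist()


def ld_clump(
    candidates: pd.DataFrame,
    ld: LDTable | None,
    config: InstrumentSelectionConfig = InstrumentSelectionConfig(),
) -> list[str]:
    """Greedy LD clumping by ascending p-value.

    ``candidates`` needs columns ``snp_id, chrom, pos, pvalue``. Repeatedly
    keep the lowest-p remaining SNP and discard remaining SNPs on the same
    chromosome within ``window_kb`` whose r^2 with it is >= ``r2_threshold``.
    A missing r^2 for an in-window pair raises :class:`LDError` — pairwise
    independence is never silently assumed inside the window.
    """
    ld = ld or LDTable()
    df = candidates.sort_values(["pvalue", "snp_id"], kind="mergesort")
    remaining = list(df.itertuples(index=False))
    window_bp = config.window_kb * 1000.0
    retained: list[str] = []
    while remaining:
        top = remaining.pop(0)
        retained.append(top.snp_id)
        survivors = []
        for cand in remaining:
            if str(cand.chrom) == str(top.chrom) and abs(cand.pos - top.pos) <= window_bp:
                r2 = ld.r2(top.snp_id, cand.snp_id)
                if r2 is None:
                    raise LDError(
                        f"no r2 for in-window pair ({top.snp_id}, {cand.snp_id})"
                    )
                if r2 >= config.r2_threshold:
                    continue
            survivors.append(cand)
        remaining = survivors
    return retained


def compute_r2(beta: float, se: float | None = None, eaf: float | None = None,
               n: float | None = None, mode: str = "from-eaf") -> float:
    """Per-SNP proportion of phenotypic variance explained.

    ``from-eaf``: R^2 = 2*eaf*(1-eaf)*beta^2 (standardized quantitative
    trait). ``from-f``: R^2 = t^2/(t^2 + n - 2) with t = beta/se.
    """
    if mode == "from-eaf":
        if eaf is None or np.isnan(eaf):
            raise ValueError("from-eaf mode requires an effect-allele frequency")
        return float(2.0 * eaf * (1.0 - eaf) * beta ** 2)
    if mode == "from-f":
        if se is None or n is None:
            raise ValueError("from-f mode requires se and n")
        t2 = (beta / se) ** 2
        return float(t2 / (t2 + n - 2.0))
    raise ValueError(f"unknown mode {mode!r}")


def f_statistic(r2: float, n: float) -> float:
    """First-stage F-statistic, F = (n-2) * R^2 / (1 - R^2)."""
    if n <= 2:
        raise ValueError("sample size must exceed 2")
    if not (0 <= r2 < 1):
        raise ValueError("r2 must be in [0,1)")
    return float((n - 2.0) * r2 / (1.0 - r2))


def instrument_report(
    dataset: SummaryDataset,
    config: InstrumentSelectionConfig = InstrumentSelectionConfig(),
    ld: LDTable | None = None,
    r2_mode: str = "from-eaf",
    exclude: set[str] | None = None,
) -> pd.DataFrame:
    """Run the full selection cascade and report per-SNP outcomes.

    Stages: genome-wide significance filter, greedy LD clump, optional
    confounder exclusion list, weak-instrument F screen. The returned frame
    has one row per input SNP with ``selected`` and ``rejection_reason``.
    """
    exclude = exclude or set()
    sig = set(select_by_pvalue(dataset, config.p_threshold))
    cand = dataset.table.loc[dataset.table["snp_id"].isin(sig),
                             ["snp_id", "chrom", "pos", "pvalue"]]
    clumped = set(ld_clump(cand, ld, config)) if len(cand) else set()

    rows = []
    for rec in dataset.table.itertuples(index=False):
        n = rec.n if not np.isnan(rec.n) else (dataset.n_default or np.nan)
        try:
            if r2_mode == "from-eaf":
                r2 = compute_r2(rec.beta, eaf=rec.eaf, mode="from-eaf")
            else:
                r2 = compute_r2(rec.beta, se=rec.se, n=n, mode="from-f")
        except ValueError:
            r2 = np.nan
        f = (f_statistic(r2, n) if np.isfinite(r2) and 0 <= r2 < 1 and n > 2
             else np.nan)

        reason = None
        if rec.snp_id not in sig:
            reason = "not-significant"
        elif rec.snp_id not in clumped:
            reason = "ld-clumped"
        elif rec.snp_id in exclude:
            reason = "excluded-confounder"
        elif np.isfinite(f) and f < config.f_threshold:
            reason = "weak-instrument"
        rows.append({
            "snp_id": rec.snp_id, "pvalue": rec.pvalue, "r2_explained": r2,
            "f_stat": f, "selected": reason is None, "rejection_reason": reason,
        })
    rep = pd.DataFrame(rows)
    return rep


def selected_instruments(report: pd.DataFrame) -> list[str]:
    """rsIDs flagged selected, in ascending-p order (ties by rsID)."""
    sel = report.loc[report["selected"]].sort_values(
        ["pvalue", "snp_id"], kind="mergesort")
    return sel["snp_id"].tolist()


def load_exclusion_list(path) -> set[str]:
    """One rsID per line; '#' comments and blank lines ignored."""
    ids = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.add(line.split()[0])
    return ids
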