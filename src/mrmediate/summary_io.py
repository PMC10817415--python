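"""Reading, validation and harmonization of GWAS summary statistics.

Two-sample MR pairs per-SNP effects from two different GWAS. Before any
estimator can run, the outcome effects must refer to the same effect allele
as the exposure effects: alleles reported in swapped order need a sign flip,
strand-flipped records need complement relabelling, and palindromic (A/T,
C/G) variants — where allele labels cannot distinguish strands — are aligned
by effect-allele frequency or dropped when the frequency is too close to 0.5
to decide.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
VALID_ALLELES = frozenset(COMPLEMENT)

#: canonical internal column names -> default header names in input files
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
}

MANDATORY = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pvalue")


class ConfigurationError(ValueError):
    """Input file or column map does not meet the reader's contract."""


class HarmonizationError(ValueError):
    """No SNP survived harmonization; message carries per-reason counts."""


@dataclass(frozen=True)
class VariantAssociation:
    """One GWAS association record for a single variant and trait.

    ``beta`` is the per-effect-allele effect on the trait (log-odds for a
    binary trait), ``se`` its standard error, ``eaf`` the effect-allele
    frequency (NaN when unreported).
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: float


@dataclass
class SummaryDataset:
    """A validated set of per-variant summary statistics for one trait."""

    trait_id: str
    trait_type: str  # "quantitative" | "binary"
    n_default: float | None
    table: pd.DataFrame
    drop_reasons: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ConfigurationError(
                f"trait_type must be quantitative|binary, got {self.trait_type!r}"
            )
        if self.table["snp_id"].duplicated().any():
            dups = self.table.loc[self.table["snp_id"].duplicated(), "snp_id"]
            raise ConfigurationError(f"duplicate snp_id in {self.trait_id}: {list(dups[:5])}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def records(self) -> Iterator[VariantAssociation]:
        for row in self.table.itertuples(index=False):
            yield VariantAssociation(
                snp_id=row.snp_id, chrom=str(row.chrom), pos=int(row.pos),
                effect_allele=row.effect_allele, other_allele=row.other_allele,
                eaf=float(row.eaf), beta=float(row.beta), se=float(row.se),
                pvalue=float(row.pvalue), n=float(row.n),
            )

    def lookup(self, snp_id: str) -> pd.Series:
        sub = self.table.loc[self.table["snp_id"] == snp_id]
        if sub.empty:
            raise KeyError(snp_id)
        return sub.iloc[0]

    def to_tsv(self, path, column_map: Mapping[str, str] | None = None) -> None:
        cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
        out = self.table.rename(columns=cmap)
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _detect_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ConfigurationError(f"{path}: empty file")
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return r"\s+"


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "quantitative",
    n_default: float | None = None,
    trait_id: str | None = None,
) -> SummaryDataset:
    """Read delimited summary statistics into a validated :class:`SummaryDataset`.

    ``column_map`` maps canonical field names (``snp_id``, ``beta``, ...) to
    the header names used in the file; unmapped fields fall back to the
    conventional ``SNP/CHR/BP/A1/A2/EAF/BETA/SE/P/N`` headers. Rows violating
    hard invariants (non-positive SE, invalid alleles, p outside (0,1]) are
    dropped and counted in ``drop_reasons``; a p-value inconsistent with
    |beta/se| by more than a factor of 10 only logs a warning.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=_detect_sep(path), engine="python")
    if raw.empty:
        raise ConfigurationError(f"{path}: no data rows")

    missing = [cmap[k] for k in MANDATORY if cmap[k] not in raw.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing mandatory columns {missing}")

    df = pd.DataFrame(index=raw.index)
    for canon, name in cmap.items():
        if name in raw.columns:
            df[canon] = raw[name]
    for optional, default in (("chrom", "0"), ("pos", 0), ("eaf", np.nan), ("n", np.nan)):
        if optional not in df.columns:
            df[optional] = default

    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for col in ("pos", "eaf", "beta", "se", "pvalue", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    drops: Counter = Counter()

    def _drop(mask: pd.Series, reason: str) -> pd.Series:
        n = int(mask.sum())
        if n:
            drops[reason] += n
        return ~mask

    keep = pd.Series(True, index=df.index)
    keep &= _drop(df["beta"].isna() | df["se"].isna() | df["pvalue"].isna(),
                  "missing-beta-se-p")
    keep &= _drop(keep & ~(df["se"] > 0), "nonpositive-se")
    # p = 0 in a summary file is floating-point underflow of an extreme
    # association, not an invalid record: clamp rather than drop
    underflow = df["pvalue"] == 0
    if underflow.any():
        logger.warning("%s: %d underflowed p-values clamped to 1e-300",
                       path, int(underflow.sum()))
        df.loc[underflow, "pvalue"] = 1e-300
    keep &= _drop(keep & ((df["pvalue"] < 0) | (df["pvalue"] > 1)),
                  "pvalue-out-of-range")
    allele_ok = (
        df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
    )
    keep &= _drop(keep & ~allele_ok, "invalid-alleles")

    df = df.loc[keep].copy()
    # out-of-range EAF is recoverable: treat as unreported
    bad_eaf = ~df["eaf"].between(0, 1) & df["eaf"].notna()
    if bad_eaf.any():
        logger.warning("%s: %d EAF values outside [0,1] set to missing", path, bad_eaf.sum())
        df.loc[bad_eaf, "eaf"] = np.nan

    if n_default is not None:
        df["n"] = df["n"].fillna(n_default)

    # soft check: p should match a two-sided normal test on beta/se within 10x
    with np.errstate(divide="ignore"):
        implied = 2.0 * stats.norm.sf(np.abs(df["beta"] / df["se"]))
    implied = np.maximum(implied, 1e-300)  # same underflow floor as above
    ratio = df["pvalue"] / implied
    inconsistent = (ratio > 10) | (ratio < 0.1)
    if inconsistent.any():
        logger.warning(
            "%s: %d p-values differ from the normal-test value by >10x",
            path, int(inconsistent.sum()),
        )

    if df.empty:
        raise ConfigurationError(f"{path}: all rows dropped ({dict(drops)})")

    df = df[list(DEFAULT_COLUMN_MAP)].reset_index(drop=True)
    ds = SummaryDataset(
        trait_id=trait_id or str(path),
        trait_type=trait_type,
        n_default=n_default,
        table=df,
        drop_reasons=drops,
    )
    if drops:
        logger.info("%s: dropped %d rows (%s)", path, sum(drops.values()), dict(drops))
    return ds


def dataset_from_frame(
    table: pd.DataFrame,
    trait_id: str,
    trait_type: str = "quantitative",
    n_default: float | None = None,
) -> SummaryDataset:
    """Wrap an in-memory canonical-column frame as a :class:`SummaryDataset`."""
    df = table.copy()
    if n_default is not None and "n" in df:
        df["n"] = df["n"].fillna(n_default)
    return SummaryDataset(trait_id=trait_id, trait_type=trait_type,
                          n_default=n_default, table=df.reset_index(drop=True))


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT[a1] == a2


@dataclass
class HarmonizedInstrumentSet:
    """Per-SNP exposure/outcome effects on a common effect allele.

    ``table`` holds retained SNPs only (columns ``snp_id, beta_exp, se_exp,
    beta_out, se_out, eaf_exp, eaf_out, action``); ``log`` additionally
    records dropped SNPs with their drop reason in ``action``.
    """

    exposure_id: str
    outcome_id: str
    table: pd.DataFrame
    log: pd.DataFrame

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def to_datasets_like(self, exposure: SummaryDataset, outcome: SummaryDataset
                         ) -> tuple[SummaryDataset, SummaryDataset]:
        """Re-express the harmonized pair as two summary datasets (for
        idempotence checks and reverse analyses)."""
        exp_rows = exposure.table.set_index("snp_id").loc[self.table["snp_id"]]
        base = exp_rows.reset_index()[["snp_id", "chrom", "pos", "effect_allele",
                                       "other_allele"]]
        exp_df = base.assign(
            eaf=self.table["eaf_exp"].to_numpy(), beta=self.table["beta_exp"].to_numpy(),
            se=self.table["se_exp"].to_numpy(),
            pvalue=2 * stats.norm.sf(np.abs(self.table["beta_exp"] / self.table["se_exp"])),
            n=exp_rows["n"].to_numpy(),
        )
        out_n = outcome.table.set_index("snp_id").loc[self.table["snp_id"], "n"].to_numpy()
        out_df = base.assign(
            eaf=self.table["eaf_out"].to_numpy(), beta=self.table["beta_out"].to_numpy(),
            se=self.table["se_out"].to_numpy(),
            pvalue=2 * stats.norm.sf(np.abs(self.table["beta_out"] / self.table["se_out"])),
            n=out_n,
        )
        return (
            dataset_from_frame(exp_df, exposure.trait_id, exposure.trait_type),
            dataset_from_frame(out_df, outcome.trait_id, outcome.trait_type),
        )


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    snp_ids: Sequence[str] | None = None,
    palindrome_eaf_window: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedInstrumentSet:
    """Align outcome effects to the exposure's effect allele, SNP by SNP.

    Resolution order per SNP: identical allele pair -> kept; swapped pair ->
    sign/frequency flip; complementary pair -> strand relabel then the same
    two checks; palindromic pair -> EAF-side comparison unless either EAF
    falls inside ``palindrome_eaf_window`` (then dropped); absent from the
    outcome -> dropped-missing.
    """
    lo, hi = palindrome_eaf_window
    if not (0 <= lo < 0.5 < hi <= 1) or abs((0.5 - lo) - (hi - 0.5)) > 1e-12:
        raise ConfigurationError(
            f"palindrome window must be symmetric around 0.5 inside [0,1]: {palindrome_eaf_window}"
        )

    exp_idx = exposure.table.set_index("snp_id")
    out_idx = outcome.table.set_index("snp_id")
    if snp_ids is None:
        snp_ids = list(exposure.table["snp_id"])
    else:
        unknown = [s for s in snp_ids if s not in exp_idx.index]
        if unknown:
            raise ConfigurationError(f"snp_ids not in exposure dataset: {unknown[:5]}")

    rows = []
    for snp in snp_ids:
        e = exp_idx.loc[snp]
        rec = {
            "snp_id": snp, "beta_exp": float(e.beta), "se_exp": float(e.se),
            "eaf_exp": float(e.eaf), "beta_out": np.nan, "se_out": np.nan,
            "eaf_out": np.nan, "action": None,
        }
        if snp not in out_idx.index:
            rec["action"] = "dropped-missing"
            rows.append(rec)
            continue
        o = out_idx.loc[snp]
        ea_e, oa_e = e.effect_allele, e.other_allele
        ea_o, oa_o = o.effect_allele, o.other_allele
        b_out, se_out, eaf_out = float(o.beta), float(o.se), float(o.eaf)

        if _is_palindromic(ea_e, oa_e):
            if not {ea_o, oa_o} == {ea_e, oa_e}:
                rec["action"] = "dropped-mismatch"
                rows.append(rec)
                continue
            # allele labels cannot identify the strand; decide by allele frequency
            if ea_o != ea_e:  # nominally swapped labels
                b_out, eaf_out = -b_out, 1.0 - eaf_out
            eaf_e = float(e.eaf)
            if (np.isnan(eaf_e) or np.isnan(eaf_out)
                    or lo < eaf_e < hi or lo < eaf_out < hi):
                rec["action"] = "dropped-palindromic"
                rows.append(rec)
                continue
            if (eaf_e < 0.5) != (eaf_out < 0.5):
                b_out, eaf_out = -b_out, 1.0 - eaf_out
                rec["action"] = "flipped"
            else:
                rec["action"] = "flipped" if ea_o != ea_e else "kept"
        else:
            strand = False
            if {ea_o, oa_o} == {COMPLEMENT[ea_e], COMPLEMENT[oa_e]} and \
                    {ea_o, oa_o} != {ea_e, oa_e}:
                ea_o, oa_o = COMPLEMENT[ea_o], COMPLEMENT[oa_o]
                strand = True
            if (ea_o, oa_o) == (ea_e, oa_e):
                rec["action"] = "strand-corrected" if strand else "kept"
            elif (ea_o, oa_o) == (oa_e, ea_e):
                b_out, eaf_out = -b_out, 1.0 - eaf_out
                rec["action"] = "strand-corrected" if strand else "flipped"
            else:
                rec["action"] = "dropped-mismatch"
                rows.append(rec)
                continue
        rec.update(beta_out=b_out, se_out=se_out, eaf_out=eaf_out)
        rows.append(rec)

    log = pd.DataFrame(rows, columns=["snp_id", "beta_exp", "se_exp", "eaf_exp",
                                      "beta_out", "se_out", "eaf_out", "action"])
    retained = log.loc[~log["action"].str.startswith("dropped")].reset_index(drop=True)
    if retained.empty:
        counts = log["action"].value_counts().to_dict()
        raise HarmonizationError(
            f"no SNP retained harmonizing {exposure.trait_id} vs {outcome.trait_id}: {counts}"
        )
    return HarmonizedInstrumentSet(
        exposure_id=exposure.trait_id, outcome_id=outcome.trait_id,
        table=retained, log=log,
    )
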