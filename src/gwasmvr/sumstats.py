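"""Reading, validation, writing and allele harmonization of GWAS summary statistics.

A summary-statistics table holds one row per variant: identifier, genomic
coordinates, the two alleles, effect-allele frequency, an effect estimate with
its standard error and P-value, imputation quality and sample size. Disorder
effects are kept on the log-odds scale (odds ratios are converted at read
time); quantitative outcomes such as years of schooling stay in outcome units.

Harmonization expresses every trait's effect for the same effect allele as a
chosen reference trait. Swapped allele pairs flip the effect sign and the
allele frequency; strand-complement codings (A/G reported as T/C) are matched
after complementing. Palindromic variants (A/T, C/G), where swap and strand
flip are indistinguishable from the alleles alone, are resolved by allele
frequency when both frequencies are informative, otherwise dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LOG_ODDS = "log-odds"
OUTCOME_UNITS = "outcome-units"

_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical internal column name -> recognized (lower-cased) header synonyms
COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "snp": ("snp", "rsid", "markername", "id", "variant_id"),
    "chrom": ("chr", "chrom", "chromosome"),
    "pos": ("bp", "pos", "position"),
    "effect_allele": ("a1", "ea", "effect_allele"),
    "other_allele": ("a2", "oa", "nea", "other_allele"),
    "eaf": ("eaf", "frq", "freq", "eaf_a1", "frq_a1"),
    "beta": ("beta", "b"),
    "odds_ratio": ("or", "oddsratio"),
    "se": ("se", "stderr", "standard_error"),
    "pvalue": ("p", "pval", "pvalue", "p_value"),
    "info": ("info", "imputation_quality"),
    "n": ("n", "nobs", "sample_size"),
}

_REQUIRED = ("snp", "chrom", "pos", "effect_allele", "other_allele", "se", "pvalue")
_OUTPUT_HEADER = ["SNP", "CHR", "BP", "A1", "A2", "EAF", "BETA", "SE", "P", "INFO", "N"]
_CANONICAL = ["snp", "chrom", "pos", "effect_allele", "other_allele",
              "eaf", "beta", "se", "pvalue", "info", "n"]


class SumstatsError(ValueError):
    """Malformed or unusable summary-statistics input."""


@dataclass
class SummaryStats:
    """Validated per-variant association records for one trait.

    ``table`` uses canonical columns: snp, chrom, pos, effect_allele,
    other_allele, eaf, beta, se, pvalue, info, n (optional columns may hold
    NaN). ``effect_unit`` is ``"log-odds"`` for case-control disorder traits
    and ``"outcome-units"`` for quantitative outcomes.
    """

    trait_name: str
    effect_unit: str
    table: pd.DataFrame
    n_total: int | None = None
    n_cases: int | None = None
    n_controls: int | None = None
    audit: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.effect_unit not in (LOG_ODDS, OUTCOME_UNITS):
            raise SumstatsError(
                f"effect_unit must be {LOG_ODDS!r} or {OUTCOME_UNITS!r}, "
                f"got {self.effect_unit!r}")
        missing = [c for c in _CANONICAL if c not in self.table.columns]
        if missing:
            raise SumstatsError(f"summary table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.table)

    def zscores(self) -> pd.Series:
        return self.table["beta"] / self.table["se"]


def or_to_logodds(odds_ratio):
    """Natural log of an odds ratio; accepts scalars or arrays.

    Raises ValueError for non-positive input.
    """
    arr = np.asarray(odds_ratio, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("odds ratios must be finite and > 0")
    out = np.log(arr)
    return float(out) if np.isscalar(odds_ratio) or out.ndim == 0 else out


def _resolve_columns(header: list[str], column_map: dict[str, str] | None) -> dict[str, str]:
    """Map canonical names to actual file headers, honouring user overrides."""
    lower = {h.lower(): h for h in header}
    resolved: dict[str, str] = {}
    column_map = column_map or {}
    for canon, synonyms in COLUMN_SYNONYMS.items():
        if canon in column_map:
            if column_map[canon] not in header:
                raise SumstatsError(
                    f"column_map maps {canon!r} to {column_map[canon]!r}, "
                    f"absent from header {header}")
            resolved[canon] = column_map[canon]
            continue
        for syn in synonyms:
            if syn in lower:
                resolved[canon] = lower[syn]
                break
    for canon in _REQUIRED:
        if canon not in resolved:
            raise SumstatsError(f"required column {canon!r} not found in header {header}")
    if "beta" not in resolved and "odds_ratio" not in resolved:
        raise SumstatsError("neither a BETA nor an OR column found")
    return resolved


def validate_table(df: pd.DataFrame) -> tuple[pd.DataFrame, Counter]:
    """Drop rows violating per-variant invariants; count drops by reason.

    Reasons: nonfinite_beta, nonpositive_se, pvalue_out_of_range,
    invalid_alleles, identical_alleles, nonpositive_pos, invalid_eaf,
    invalid_info, duplicate_snp_id. Missing eaf/info/n are tolerated.
    """
    audit: Counter = Counter()
    keep = pd.Series(True, index=df.index)

    def flag(bad: pd.Series, reason: str) -> None:
        bad = bad & keep
        n = int(bad.sum())
        if n:
            audit[reason] += n
            keep[bad] = False

    flag(~np.isfinite(df["beta"]), "nonfinite_beta")
    flag(~(df["se"] > 0) | ~np.isfinite(df["se"]), "nonpositive_se")
    flag(~((df["pvalue"] > 0) & (df["pvalue"] <= 1)), "pvalue_out_of_range")
    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    flag(~(ea.isin(_BASES) & oa.isin(_BASES)), "invalid_alleles")
    flag(ea == oa, "identical_alleles")
    flag(~(df["pos"] >= 1), "nonpositive_pos")
    has_eaf = df["eaf"].notna()
    flag(has_eaf & ~((df["eaf"] > 0) & (df["eaf"] < 1)), "invalid_eaf")
    has_info = df["info"].notna()
    flag(has_info & ~((df["info"] >= 0) & (df["info"] <= 1)), "invalid_info")
    dup = df["snp"].duplicated(keep="first")
    flag(dup, "duplicate_snp_id")

    clean = df.loc[keep].copy()
    clean["effect_allele"] = ea.loc[keep]
    clean["other_allele"] = oa.loc[keep]
    return clean.reset_index(drop=True), audit


def read_sumstats(path, column_map: dict[str, str] | None = None,
                  effect_unit: str = OUTCOME_UNITS,
                  trait_name: str | None = None,
                  n_total: int | None = None,
                  n_cases: int | None = None,
                  n_controls: int | None = None) -> SummaryStats:
    """Read a tab- or whitespace-delimited summary-statistics file.

    Column headers are matched case-insensitively against
    :data:`COLUMN_SYNONYMS`; ``column_map`` overrides individual mappings
    (canonical name -> file header). An OR column is converted to log-odds.
    Rows violating invariants are dropped and counted in ``.audit``.
    """
    raw = pd.read_csv(path, sep=r"\s+")
    if raw.empty:
        raise SumstatsError(f"no data rows in {path}")
    resolved = _resolve_columns(list(raw.columns), column_map)

    df = pd.DataFrame()
    for canon in _CANONICAL:
        if canon in resolved:
            df[canon] = raw[resolved[canon]]
        elif canon != "beta":
            df[canon] = np.nan
    if "beta" not in df.columns:
        ors = pd.to_numeric(raw[resolved["odds_ratio"]], errors="coerce")
        with np.errstate(invalid="ignore", divide="ignore"):
            df["beta"] = np.where(ors > 0, np.log(ors), np.nan)
    for col in ("pos", "eaf", "beta", "se", "pvalue", "info", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["snp"] = df["snp"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df = df[_CANONICAL]

    clean, audit = validate_table(df)
    if clean.empty:
        raise SumstatsError(f"no valid rows left after validation of {path}: {dict(audit)}")
    return SummaryStats(
        trait_name=trait_name or str(path),
        effect_unit=effect_unit,
        table=clean,
        n_total=n_total, n_cases=n_cases, n_controls=n_controls,
        audit={"dropped": dict(audit), "n_read": len(df), "n_valid": len(clean)},
    )


def write_sumstats(stats: SummaryStats, path) -> None:
    """Write in the fixed output dialect: SNP CHR BP A1 A2 EAF BETA SE P INFO N."""
    out = stats.table[_CANONICAL].copy()
    out.columns = _OUTPUT_HEADER
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def _classify_orientation(ea_r, oa_r, ea_o, oa_o, eaf_r, eaf_o,
                          palindrome_policy: str):
    """Vectorized allele-pair orientation: +1 keep, -1 flip, 0 drop.

    Returns (sign array, drop-reason array of object dtype or None).
    """
    comp = np.vectorize(_COMPLEMENT.get)
    cea_o, coa_o = comp(ea_o), comp(oa_o)

    same = (ea_o == ea_r) & (oa_o == oa_r)
    swap = (ea_o == oa_r) & (oa_o == ea_r)
    csame = (cea_o == ea_r) & (coa_o == oa_r)
    cswap = (cea_o == oa_r) & (coa_o == ea_r)
    pal_r = ea_r == comp(oa_r)
    pal_o = ea_o == coa_o
    palindromic = pal_r | pal_o
    compatible = same | swap | csame | cswap

    sign = np.zeros(len(ea_r), dtype=int)
    reason = np.full(len(ea_r), None, dtype=object)
    reason[~compatible] = "allele_mismatch"

    plain = compatible & ~palindromic
    sign[plain & (same | csame)] = 1
    sign[plain & ~(same | csame) & (swap | cswap)] = -1

    pal = compatible & palindromic
    if palindrome_policy == "drop":
        reason[pal] = "palindromic_dropped"
    elif palindrome_policy == "eaf":
        informative = (pal
                       & np.isfinite(eaf_r) & np.isfinite(eaf_o)
                       & (np.abs(eaf_r - 0.5) > 0.1) & (np.abs(eaf_o - 0.5) > 0.1))
        agree = (eaf_r < 0.5) == (eaf_o < 0.5)
        sign[informative & agree] = 1
        sign[informative & ~agree] = -1
        reason[pal & ~informative] = "palindromic_ambiguous"
    else:
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    return sign, reason


def harmonize(reference: SummaryStats, others: list[SummaryStats],
              palindrome_policy: str = "eaf") -> tuple[pd.DataFrame, dict]:
    """Align every trait's effects onto the reference trait's effect allele.

    Returns ``(table, audit)``. The table holds one row per variant present
    and reconcilable in all inputs, with columns ``snp, chrom, pos,
    effect_allele, other_allele, eaf`` (reference orientation) and
    ``beta_<trait>, se_<trait>, p_<trait>`` for the reference and each other
    trait. ``audit`` counts drops per trait and reason, so that
    ``|input SNPs| = |aligned| + |dropped|`` per trait.

    palindrome_policy: ``"eaf"`` resolves A/T and C/G variants by frequency
    agreement when both frequencies lie outside [0.4, 0.6], otherwise drops;
    ``"drop"`` drops all palindromic variants.
    """
    names = [reference.trait_name] + [o.trait_name for o in others]
    if len(set(names)) != len(names):
        raise SumstatsError(f"trait names must be distinct, got {names}")

    ref = reference.table.rename(columns={
        "beta": f"beta_{reference.trait_name}",
        "se": f"se_{reference.trait_name}",
        "pvalue": f"p_{reference.trait_name}",
    }).drop(columns=["info", "n"])

    audit: dict = {"palindrome_policy": palindrome_policy, "traits": {}}
    merged = ref
    for other in others:
        t = other.trait_name
        o = other.table[["snp", "effect_allele", "other_allele", "eaf",
                         "beta", "se", "pvalue"]].rename(columns={
            "effect_allele": "_ea_o", "other_allele": "_oa_o", "eaf": "_eaf_o",
            "beta": f"beta_{t}", "se": f"se_{t}", "pvalue": f"p_{t}"})
        n_before = len(merged)
        merged = merged.merge(o, on="snp", how="inner")
        n_common = len(merged)

        sign, reason = _classify_orientation(
            merged["effect_allele"].to_numpy(), merged["other_allele"].to_numpy(),
            merged["_ea_o"].to_numpy(), merged["_oa_o"].to_numpy(),
            merged["eaf"].to_numpy(dtype=float), merged["_eaf_o"].to_numpy(dtype=float),
            palindrome_policy)
        drops = Counter(r for r, s in zip(reason, sign) if s == 0 and r is not None)
        merged[f"beta_{t}"] = merged[f"beta_{t}"] * sign
        keep = sign != 0
        merged = merged.loc[keep].drop(columns=["_ea_o", "_oa_o", "_eaf_o"])
        audit["traits"][t] = {
            "n_not_in_intersection": n_before - n_common,
            "dropped": dict(drops),
            "n_aligned": len(merged),
        }
    if merged.empty:
        raise SumstatsError("no variants shared across all inputs after harmonization")
    return merged.reset_index(drop=True), audit
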