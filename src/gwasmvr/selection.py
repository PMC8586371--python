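"""Variant-set construction: thresholded discovery sets, risk-allele
orientation, concordant subsets and conditional P-value thresholding.

Discovery sets keep common (MAF > 0.01), well-imputed (INFO > 0.7),
LD-independent (greedy clumping at r2 < 0.25 within +/-500 kb) variants below
each P-value threshold of a grid. Conditional subsets restrict one disorder's
set to members that are also associated with the other disorder — directly or
through an LD proxy (r2 >= 0.6 within +/-500 kb) — below each of six
conditional thresholds; subsets are nested across increasing thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ld import LDReference, clump, find_proxies
from .sumstats import SummaryStats

DISCOVERY_THRESHOLDS = (5e-8, 5e-7, 5e-6, 5e-5, 5e-4, 0.0015, 0.005, 0.05, 0.1, 0.3, 0.5)
CONDITIONAL_THRESHOLDS = (0.0015, 0.005, 0.05, 0.1, 0.3, 0.5)


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds and filters for variant-set construction."""

    p_thresholds: tuple[float, ...] = DISCOVERY_THRESHOLDS
    conditional_thresholds: tuple[float, ...] = CONDITIONAL_THRESHOLDS
    maf_min: float | None = 0.01
    info_min: float | None = 0.7
    r2_clump: float = 0.25
    window_kb: int = 500
    proxy_r2: float = 0.6

    def __post_init__(self) -> None:
        for name in ("p_thresholds", "conditional_thresholds"):
            ts = getattr(self, name)
            if not ts or any(not (0 < t <= 1) for t in ts):
                raise ValueError(f"{name} must be non-empty with values in (0, 1]")
            if any(a >= b for a, b in zip(ts, ts[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if self.maf_min is not None and not (0 < self.maf_min < 0.5):
            raise ValueError("maf_min must lie in (0, 0.5)")
        if self.info_min is not None and not (0 <= self.info_min <= 1):
            raise ValueError("info_min must lie in [0, 1]")
        if not (0 < self.r2_clump <= 1):
            raise ValueError("r2_clump must lie in (0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")
        if not (0 < self.proxy_r2 <= 1):
            raise ValueError("proxy_r2 must lie in (0, 1]")


@dataclass
class VariantSet:
    """LD-independent variants of one trait below one P-value threshold."""

    source_trait: str
    p_threshold: float
    members: tuple[str, ...]
    audit: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp": self.members,
            "source": self.source_trait,
            "p_threshold": self.p_threshold,
        })


@dataclass
class ConditionalSet:
    """Members of a primary set that also meet a conditional threshold in the
    other disorder's statistics, directly ('identical') or via a proxy.

    ``table`` columns: snp, overlap_mode, proxy_id, proxy_r2.
    """

    primary_trait: str
    primary_threshold: float
    conditional_trait: str
    conditional_threshold: float
    table: pd.DataFrame

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(self.table["snp"])

    @property
    def size(self) -> int:
        return len(self.table)

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(1, "source", self.primary_trait)
        out.insert(2, "primary_threshold", self.primary_threshold)
        out.insert(3, "conditional_trait", self.conditional_trait)
        out.insert(4, "conditional_threshold", self.conditional_threshold)
        return out


def _filter_mask(table: pd.DataFrame, cfg: SelectionConfig, p_thr: float) -> tuple[pd.Series, dict]:
    """Strict-inequality filters; missing eaf/info fail an enabled filter."""
    audit = {"n_input": len(table)}
    mask = table["pvalue"] < p_thr
    audit["fail_p"] = int((~mask).sum())
    if cfg.maf_min is not None:
        maf = np.minimum(table["eaf"], 1.0 - table["eaf"])
        ok = maf > cfg.maf_min
        ok &= table["eaf"].notna()
        audit["fail_maf"] = int((mask & ~ok).sum())
        mask &= ok
    if cfg.info_min is not None:
        ok = (table["info"] > cfg.info_min) & table["info"].notna()
        audit["fail_info"] = int((mask & ~ok).sum())
        mask &= ok
    return mask, audit


def select_variants(stats: SummaryStats, cfg: SelectionConfig, p_thr: float,
                    ld: LDReference) -> VariantSet:
    """Build one discovery variant set: P < p_thr, MAF/INFO filters, clumping.

    An empty result is returned (size 0), not raised.
    """
    mask, audit = _filter_mask(stats.table, cfg, p_thr)
    candidates = stats.table.loc[mask, ["snp", "pos", "pvalue"]]
    if candidates.empty:
        audit.update(n_candidates=0, clumped_out=0, retained=0)
        return VariantSet(stats.trait_name, p_thr, (), audit)
    retained = clump(candidates, ld, r2_max=cfg.r2_clump, window_kb=cfg.window_kb)
    audit.update(n_candidates=len(candidates),
                 clumped_out=len(candidates) - len(retained),
                 retained=len(retained))
    return VariantSet(stats.trait_name, p_thr, tuple(retained), audit)


def align_to_risk(table: pd.DataFrame, primary: str) -> pd.DataFrame:
    """Orient every row so the primary trait's effect is risk-increasing.

    Rows with a negative primary beta have their effect/other alleles swapped,
    eaf complemented, and all beta columns negated; rows with beta exactly 0
    are unchanged. Idempotent, and slope estimates downstream are invariant to
    the original reported allele.
    """
    col = f"beta_{primary}"
    if col not in table.columns:
        raise KeyError(f"no column {col} in aligned table")
    out = table.copy()
    flip = out[col].to_numpy(dtype=float) < 0
    beta_cols = [c for c in out.columns if c.startswith("beta_")]
    out.loc[flip, beta_cols] = -out.loc[flip, beta_cols]
    if {"effect_allele", "other_allele"} <= set(out.columns):
        ea = out["effect_allele"].to_numpy(copy=True)
        oa = out["other_allele"].to_numpy(copy=True)
        out.loc[flip, "effect_allele"] = oa[flip]
        out.loc[flip, "other_allele"] = ea[flip]
    if "eaf" in out.columns:
        out.loc[flip, "eaf"] = 1.0 - out.loc[flip, "eaf"]
    return out


def concordant_subset(table: pd.DataFrame, exposures: Sequence[str]) -> pd.DataFrame:
    """Keep rows where both exposures' effects share a sign.

    Rows with either beta exactly 0 are dropped (a zero effect has no
    risk-increasing allele). Idempotent.
    """
    if len(exposures) != 2:
        raise ValueError("concordant_subset expects exactly two exposures")
    a = table[f"beta_{exposures[0]}"].to_numpy(dtype=float)
    b = table[f"beta_{exposures[1]}"].to_numpy(dtype=float)
    keep = ((a > 0) & (b > 0)) | ((a < 0) & (b < 0))
    return table.loc[keep].reset_index(drop=True)


def conditional_grid(primary_set: VariantSet, other_stats: SummaryStats,
                     cfg: SelectionConfig, ld: LDReference) -> list[ConditionalSet]:
    """One conditional subset per conditional threshold (nested, ascending).

    A primary member qualifies at threshold t if it, or its best proxy
    (r2 >= cfg.proxy_r2 within +/-cfg.window_kb) among the other trait's
    variants passing MAF/INFO filters with P < t, exists. The subset row keeps
    the primary SNP itself; the proxy only establishes qualification.
    """
    if primary_set.size == 0:
        raise ValueError("primary variant set is empty")
    out: list[ConditionalSet] = []
    for t in cfg.conditional_thresholds:
        mask, _ = _filter_mask(other_stats.table, cfg, t)
        candidates = set(other_stats.table.loc[mask, "snp"])
        rows = []
        if candidates:
            matches = find_proxies(primary_set.members, candidates, ld,
                                   r2_min=cfg.proxy_r2, window_kb=cfg.window_kb)
            for sid in primary_set.members:
                m = matches[sid]
                if m is None:
                    continue
                rows.append((sid, "identical" if m.identical else "proxy",
                             m.partner_id, m.r2))
        out.append(ConditionalSet(
            primary_trait=primary_set.source_trait,
            primary_threshold=primary_set.p_threshold,
            conditional_trait=other_stats.trait_name,
            conditional_threshold=t,
            table=pd.DataFrame(rows, columns=["snp", "overlap_mode",
                                              "proxy_id", "proxy_r2"])))
    return out
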