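"""Sample-overlap-aware meta-analysis and a simplified cross-trait LD-score
genetic correlation.

The meta-analysis combines two traits' per-variant estimates by generalized
least squares under a per-variant covariance matrix
``[[s1^2, c*s1*s2], [c*s1*s2, s2^2]]`` whose correlation ``c`` captures the
score covariance induced by shared samples (Lin–Sullivan-style). ``c`` is
estimated from the correlation of z-scores over variants that are null in
both traits.

The genetic-correlation estimator regresses z1*z2 on the LD score for the
genetic covariance, z^2 on the LD score per trait for the heritability
slopes, and forms rg = cov-slope / sqrt(h1-slope * h2-slope); intercepts are
unconstrained. Because both slopes and the covariance slope carry the same
per-trait sample-size scaling in their z-scores, the ratio is scale-free.
Standard errors come from a delete-one block jackknife over contiguous
variant blocks. This is a deliberately simplified two-step estimator, not a
re-implementation of the reference LDSC software's iterative weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sumstats import SummaryStats, harmonize


class OverlapEstimationError(ValueError):
    """Too little data to estimate the overlap-induced correlation."""


@dataclass
class RgResult:
    """Cross-trait genetic correlation from LD-score regression."""

    trait_1: str
    trait_2: str
    cov_slope: float
    h2_slope_1: float
    h2_slope_2: float
    rg: float                 # NaN when a heritability slope is non-positive
    rg_se: float
    intercept_cov: float
    intercept_1: float
    intercept_2: float
    n_blocks: int
    n_snps: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.rg)

    def to_json_dict(self) -> dict:
        return {k: (None if isinstance(v, float) and not np.isfinite(v) else v)
                for k, v in self.__dict__.items()}


def _paired_z(s1: SummaryStats, s2: SummaryStats) -> pd.DataFrame:
    table, _ = harmonize(s1, [s2])
    t1, t2 = s1.trait_name, s2.trait_name
    out = table[["snp", "chrom", "pos"]].copy()
    out["z1"] = table[f"beta_{t1}"] / table[f"se_{t1}"]
    out["z2"] = table[f"beta_{t2}"] / table[f"se_{t2}"]
    return out


def estimate_overlap_correlation(s1: SummaryStats, s2: SummaryStats,
                                 z_cut: float = 1.96) -> float:
    """Correlation of z-scores over variants null in both traits.

    Under shared samples (or shared controls) the association scores of two
    traits are correlated even at null variants; that correlation is what the
    covariance-adjusted meta-analysis needs. Requires >= 100 jointly null
    variants (|z| < z_cut in both traits).
    """
    z = _paired_z(s1, s2)
    null = (z["z1"].abs() < z_cut) & (z["z2"].abs() < z_cut)
    m = int(null.sum())
    if m < 100:
        raise OverlapEstimationError(
            f"only {m} jointly null variants (need >= 100)")
    return float(np.corrcoef(z.loc[null, "z1"], z.loc[null, "z2"])[0, 1])


def covariance_adjusted_meta(s1: SummaryStats, s2: SummaryStats,
                             c: float) -> SummaryStats:
    """Minimum-variance combination of two traits' estimates allowing overlap.

    Per variant, with standard errors s1, s2 and overlap correlation c, the
    combined estimate is the GLS solution under covariance
    [[s1^2, c s1 s2], [c s1 s2, s2^2]]; P-values use the normal
    approximation. Variants whose per-variant matrix is not positive definite
    are dropped and audited. |c| is capped at 0.999 with a warning.
    """
    if abs(c) >= 1:
        warnings.warn("overlap correlation |c| >= 1; capping at 0.999")
        c = float(np.sign(c)) * 0.999
    table, _ = harmonize(s1, [s2])
    t1, t2 = s1.trait_name, s2.trait_name
    b1 = table[f"beta_{t1}"].to_numpy(dtype=float)
    b2 = table[f"beta_{t2}"].to_numpy(dtype=float)
    e1 = table[f"se_{t1}"].to_numpy(dtype=float)
    e2 = table[f"se_{t2}"].to_numpy(dtype=float)

    cov = c * e1 * e2
    det = e1 ** 2 * e2 ** 2 - cov ** 2
    denom = e1 ** 2 + e2 ** 2 - 2 * cov      # = det * 1' Sigma^-1 1
    ok = (det > 0) & (denom > 0)
    n_dropped = int((~ok).sum())

    with np.errstate(divide="ignore", invalid="ignore"):
        w1 = (e2 ** 2 - cov) / denom
        w2 = (e1 ** 2 - cov) / denom
        beta = w1 * b1 + w2 * b2
        var = det / denom
    se = np.sqrt(var)
    z = beta / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    p = np.where(p > 0, p, np.finfo(float).tiny)

    out = table.loc[ok, ["snp", "chrom", "pos", "effect_allele",
                         "other_allele", "eaf"]].copy()
    out["beta"] = beta[ok]
    out["se"] = se[ok]
    out["pvalue"] = p[ok]
    out["info"] = np.nan
    out["n"] = np.nan
    n_total = (s1.n_total or 0) + (s2.n_total or 0) or None
    return SummaryStats(
        trait_name=f"meta({t1},{t2})", effect_unit=s1.effect_unit,
        table=out.reset_index(drop=True), n_total=n_total,
        audit={"overlap_correlation": c, "dropped_not_positive_definite": n_dropped})


def _ols_slope(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least-squares slope and intercept of y on x."""
    sw = np.sum(w)
    xb = np.sum(w * x) / sw
    yb = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xb) ** 2)
    if sxx <= 0:
        raise ValueError("degenerate LD-score spread")
    slope = float(np.sum(w * (x - xb) * (y - yb)) / sxx)
    return slope, float(yb - slope * xb)


def _rg_from(z1, z2, ell, w) -> tuple[float, float, float, float, float, float]:
    cov_slope, i_cov = _ols_slope(ell, z1 * z2, w)
    h1, i1 = _ols_slope(ell, z1 ** 2, w)
    h2, i2 = _ols_slope(ell, z2 ** 2, w)
    rg = cov_slope / np.sqrt(h1 * h2) if (h1 > 0 and h2 > 0) else np.nan
    return cov_slope, h1, h2, rg, i_cov, (i1, i2)


def cross_trait_ldsc(s1: SummaryStats, s2: SummaryStats, ld_scores,
                     n_blocks: int = 20, weighting: str = "none") -> RgResult:
    """Unconstrained cross-trait LD-score regression with block jackknife.

    ``ld_scores``: mapping/Series snp id -> LD score, or a DataFrame/path
    with columns SNP, L2. ``weighting``: "none" (ordinary least squares) or
    "inv_ell" (1/LD-score weights). Jackknife blocks are contiguous in the
    harmonized variant order.
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if isinstance(ld_scores, (str, bytes)) or hasattr(ld_scores, "read"):
        ld_scores = pd.read_csv(ld_scores, sep=r"\s+")
    if isinstance(ld_scores, pd.DataFrame):
        cols = {c.upper(): c for c in ld_scores.columns}
        ld_scores = ld_scores.set_index(ld_scores[cols["SNP"]].astype(str))[cols["L2"]]
    z = _paired_z(s1, s2)
    z = z[z["snp"].isin(ld_scores.index)]
    if len(z) < n_blocks:
        raise ValueError("fewer variants with LD scores than jackknife blocks")
    ell = ld_scores.loc[z["snp"]].to_numpy(dtype=float)
    z1 = z["z1"].to_numpy()
    z2 = z["z2"].to_numpy()
    if weighting == "none":
        w = np.ones_like(ell)
    elif weighting == "inv_ell":
        w = 1.0 / np.maximum(ell, 1.0)
    else:
        raise ValueError("weighting must be 'none' or 'inv_ell'")

    cov_slope, h1, h2, rg, i_cov, (i1, i2) = _rg_from(z1, z2, ell, w)

    bounds = np.linspace(0, len(z), n_blocks + 1, dtype=int)
    pseudo = []
    for b in range(n_blocks):
        keep = np.ones(len(z), dtype=bool)
        keep[bounds[b]:bounds[b + 1]] = False
        try:
            _, _, _, rg_b, _, _ = _rg_from(z1[keep], z2[keep], ell[keep], w[keep])
        except ValueError:
            rg_b = np.nan
        pseudo.append(rg_b)
    pseudo_arr = np.asarray(pseudo, dtype=float)
    valid = np.isfinite(pseudo_arr)
    if np.isfinite(rg) and valid.sum() >= 2:
        nb = int(valid.sum())
        rg_se = float(np.sqrt((nb - 1) / nb * np.sum(
            (pseudo_arr[valid] - np.mean(pseudo_arr[valid])) ** 2)))
    else:
        rg_se = np.nan

    return RgResult(
        trait_1=s1.trait_name, trait_2=s2.trait_name,
        cov_slope=cov_slope, h2_slope_1=h1, h2_slope_2=h2,
        rg=float(rg), rg_se=rg_se, intercept_cov=i_cov,
        intercept_1=i1, intercept_2=i2,
        n_blocks=n_blocks, n_snps=len(z))
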