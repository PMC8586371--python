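"""Synthetic three-trait GWAS summary statistics with block LD and ground truth.

The generator emulates two case-control disorder GWAS (effects on the
log-odds scale) and one quantitative-outcome GWAS over the same markers.
Markers live in AR1-correlated LD blocks placed far apart (> 1 Mb), so
cross-block LD is exactly zero. Each scenario encodes a candidate mechanism
for discordant polygenic association of the two disorders with the outcome:

* ``I-a`` / ``I-b``  — disjoint disorder causal variants, in low-LD regions of
  the same block or in different blocks (independent markers).
* ``III-d`` — a shared causal variant whose alleles confer opposite-signed
  disorder effects; ``III-e`` / ``III-f`` — co-localised distinct causal
  variants in high LD with opposite marker-level signs (same-gene /
  different-gene flags are metadata only).
* ``IV-g`` / ``IV-h`` — identical marker alleles tag two distinct, same-signed
  causal variants in high LD, one per disorder.
* ``V-i`` — a single causal allele raises risk for both disorders (same sign)
  with correlated but different magnitudes (biological pleiotropy).
* ``mixture`` — blocks cycle through V-i, I-a, III-d, IV-g.

Outcome causal effects follow the generative identity
``b_out = theta_asd * b_asd + theta_adhd * b_adhd + Normal(0, sigma_e^2)``,
so true marginal (LD-convolved) effects satisfy the same identity and a
weighted regression of outcome marginals on disorder marginals recovers
``(theta_asd, theta_adhd)`` exactly in the noise-free limit.

Effects are on the standardized-genotype scale, so the per-trait sampling
error of an estimate is ``1/sqrt(N)``. Each marker's reported allele is
flipped with probability 0.5 per trait (allele pairs are never palindromic),
forcing downstream harmonization to be exercised end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ld import LDReference
from .sumstats import LOG_ODDS, OUTCOME_UNITS, SummaryStats

SCENARIOS = ("I-a", "I-b", "III-d", "III-e", "III-f", "IV-g", "IV-h", "V-i", "mixture")
_MIXTURE_CYCLE = ("V-i", "I-a", "III-d", "IV-g")
# ordered, non-palindromic allele pairs
_ALLELE_PAIRS = (("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                 ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"))


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one simulated three-trait GWAS."""

    seed: int
    scenario: str = "V-i"
    n_blocks: int = 200
    block_size: int = 100
    rho_ld: float = 0.8               # AR1 parameter of within-block signed r
    causal_fraction: float = 0.05     # causal variants per block, per disorder
    causal_scale: float = 0.4         # sd of causal effect sizes
    n_asd: int = 50_000
    n_adhd: int = 50_000
    n_out: int = 50_000
    theta_asd: float = 0.1            # outcome units per log-odds
    theta_adhd: float = -0.1
    rho_disorders: float = 0.6
    sigma_e: float = 0.0005           # residual sd of outcome causal effects
    emit_replicate: bool = False      # independent disorder draws for selection
    noise_free: bool = False          # infinite-N switch: emit true marginals
    trait_names: tuple[str, str, str] = ("ASD", "ADHD", "EA")

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if min(self.n_blocks, self.block_size, self.n_asd, self.n_adhd, self.n_out) <= 0:
            raise ValueError("all sizes must be positive")
        if not (0 <= self.rho_ld < 1):
            raise ValueError("rho_ld must lie in [0, 1)")
        if not (0 <= self.causal_fraction <= 1):
            raise ValueError("causal_fraction must lie in [0, 1]")
        if abs(self.rho_disorders) >= 1:
            raise ValueError("|rho_disorders| must be < 1")
        if self.sigma_e < 0 or self.causal_scale < 0:
            raise ValueError("scales must be non-negative")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is mandatory and must be an integer")

    @classmethod
    def consortium_scale(cls, seed: int, **overrides) -> "ScenarioConfig":
        """Preset with realistically small polygenic effects and large N,
        matching the scale of real consortium estimates."""
        base = cls(seed=seed, theta_asd=0.009, theta_adhd=-0.029,
                   n_asd=500_000, n_adhd=500_000, n_out=500_000)
        return replace(base, **overrides) if overrides else base

    @classmethod
    def infinitesimal(cls, seed: int, **overrides) -> "ScenarioConfig":
        """Every marker causal with small effects: the polygenic regime that
        LD-score-based genetic-correlation estimation assumes."""
        base = cls(seed=seed, causal_fraction=1.0, causal_scale=0.04,
                   sigma_e=1.5e-4)
        return replace(base, **overrides) if overrides else base


@dataclass
class ScenarioTruth:
    """Ground truth of one simulated study."""

    scenario: str
    theta: dict[str, float]
    causal: pd.DataFrame           # snp, b_asd, b_adhd, b_out (causal rows only)
    marginals: pd.DataFrame        # snp, m_asd, m_adhd, m_out for every marker
    ld_scores: pd.Series
    block_of: pd.Series
    flips: dict[str, np.ndarray]   # trait -> reported-allele flip mask
    rg_true: dict[str, float]      # correlations of true marginal vectors
    gene_flag: str | None = None   # same_gene / different_gene (metadata)


@dataclass
class SimulatedStudy:
    asd: SummaryStats
    adhd: SummaryStats
    outcome: SummaryStats
    truth: ScenarioTruth
    ld: LDReference
    ld_scores: pd.Series
    asd_replicate: SummaryStats | None = None
    adhd_replicate: SummaryStats | None = None

    @property
    def stats(self) -> tuple[SummaryStats, SummaryStats, SummaryStats]:
        return self.asd, self.adhd, self.outcome


def _block_ids(cfg: ScenarioConfig, b: int) -> list[str]:
    return [f"rs{b * cfg.block_size + i + 1}" for i in range(cfg.block_size)]


def build_ld(cfg: ScenarioConfig) -> tuple[LDReference, pd.Series]:
    """AR1 LD blocks (r_ij = rho_ld^|i-j|) spaced > 1 Mb apart.

    Returns the LD reference and per-variant LD scores
    (sum of r^2 within the block, including the variant itself).
    """
    blocks = []
    scores: dict[str, float] = {}
    offsets = np.arange(cfg.block_size)
    r = cfg.rho_ld ** np.abs(offsets[:, None] - offsets[None, :])
    score_row = (r ** 2).sum(axis=1)
    for b in range(cfg.n_blocks):
        chrom = str(b // 50 + 1)
        base = 1 + (b % 50) * 2_000_000
        pos = base + offsets * 1_000
        ids = _block_ids(cfg, b)
        blocks.append((chrom, ids, pos, r))
        for sid, s in zip(ids, score_row):
            scores[sid] = float(s)
    return LDReference(blocks), pd.Series(scores, name="L2")


def _bvn(rng, n: int, scale: float, rho: float) -> np.ndarray:
    cov = scale ** 2 * np.array([[1.0, rho], [rho, 1.0]])
    return rng.multivariate_normal(np.zeros(2), cov, size=n, method="cholesky")


def _shared_sign_corr(rho_m: float) -> float:
    """Realized corr of (s|x1|, s|x2|) for BVN(rho_m) magnitudes, shared sign s."""
    return (2.0 / np.pi) * (np.sqrt(1.0 - rho_m ** 2) + rho_m * np.arcsin(rho_m))


def _magnitude_rho(target: float) -> float:
    """Magnitude correlation so that shared-sign effects realize ``target``.

    Sharing a risk-allele sign alone induces an effect correlation of
    2/pi ~ 0.64; targets below that floor realize the floor (independent
    magnitudes).
    """
    lo = _shared_sign_corr(0.0)
    if target <= lo:
        return 0.0
    from scipy.optimize import brentq
    return float(brentq(lambda r: _shared_sign_corr(r) - target, 0.0, 1.0 - 1e-9))


def _block_causal(cfg: ScenarioConfig, rng, scenario: str, b: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Per-block causal disorder effect vectors (b_asd, b_adhd)."""
    bs = cfg.block_size
    nc = max(1, round(cfg.causal_fraction * bs)) if cfg.causal_fraction > 0 else 0
    b_a = np.zeros(bs)
    b_d = np.zeros(bs)
    if nc == 0:
        return b_a, b_d

    if scenario == "V-i":
        idx = np.sort(rng.choice(bs, nc, replace=False))
        # identical risk alleles: shared sign per causal variant; magnitude
        # correlation chosen so realized effect correlation ~ rho_disorders
        x = _bvn(rng, nc, cfg.causal_scale, _magnitude_rho(cfg.rho_disorders))
        s = rng.choice([-1.0, 1.0], nc)
        b_a[idx] = s * np.abs(x[:, 0])
        b_d[idx] = s * np.abs(x[:, 1])
    elif scenario == "I-a":
        third = max(1, bs // 3)
        idx_a = rng.choice(third, min(nc, third), replace=False)
        idx_d = bs - 1 - rng.choice(third, min(nc, third), replace=False)
        b_a[idx_a] = rng.normal(0, cfg.causal_scale, len(idx_a))
        b_d[idx_d] = rng.normal(0, cfg.causal_scale, len(idx_d))
    elif scenario == "I-b":
        if b % 2 == 0:
            idx = rng.choice(bs, nc, replace=False)
            b_a[idx] = rng.normal(0, cfg.causal_scale, nc)
        else:
            idx = rng.choice(bs, nc, replace=False)
            b_d[idx] = rng.normal(0, cfg.causal_scale, nc)
    elif scenario == "III-d":
        idx = np.sort(rng.choice(bs, nc, replace=False))
        x = _bvn(rng, nc, cfg.causal_scale, abs(cfg.rho_disorders))
        sign = np.where(x[:, 0] == 0, 1.0, np.sign(x[:, 0]))
        b_a[idx] = x[:, 0]
        b_d[idx] = -sign * np.abs(x[:, 1])      # opposite sign at every shared variant
    elif scenario in ("III-e", "III-f", "IV-g", "IV-h"):
        # co-localised pairs: disorder causal variants at adjacent markers
        starts = np.sort(rng.choice(np.arange(0, bs - 1, 4), min(nc, (bs - 1) // 4),
                                    replace=False))
        x = _bvn(rng, len(starts), cfg.causal_scale, abs(cfg.rho_disorders))
        sign_a = np.where(x[:, 0] == 0, 1.0, np.sign(x[:, 0]))
        flip = -1.0 if scenario.startswith("III") else 1.0
        b_a[starts] = x[:, 0]
        b_d[starts + 1] = flip * sign_a * np.abs(x[:, 1])
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(scenario)
    return b_a, b_d


def _emit(cfg: ScenarioConfig, rng, trait: str, unit: str, n_samples: int,
          marginal: np.ndarray, chrom: np.ndarray, pos: np.ndarray,
          ids: list[str], eaf_base: np.ndarray, ea: np.ndarray, oa: np.ndarray
          ) -> tuple[SummaryStats, np.ndarray]:
    """Observed statistics for one trait: sampling noise, then allele flips."""
    se = np.full(len(ids), 1.0 / np.sqrt(n_samples))
    if cfg.noise_free:
        beta = marginal.copy()
    else:
        beta = marginal + rng.normal(0.0, 1.0 / np.sqrt(n_samples), len(ids))
    flip = rng.random(len(ids)) < 0.5
    sgn = np.where(flip, -1.0, 1.0)
    z = beta / se
    p = np.maximum(2.0 * sps.norm.sf(np.abs(z)), np.finfo(float).tiny)
    table = pd.DataFrame({
        "snp": ids,
        "chrom": chrom,
        "pos": pos,
        "effect_allele": np.where(flip, oa, ea),
        "other_allele": np.where(flip, ea, oa),
        "eaf": np.where(flip, 1.0 - eaf_base, eaf_base),
        "beta": sgn * beta,
        "se": se,
        "pvalue": p,
        "info": 1.0,
        "n": float(n_samples),
    })
    stats = SummaryStats(trait_name=trait, effect_unit=unit, table=table,
                         n_total=n_samples)
    return stats, flip


def simulate_triple_gwas(cfg: ScenarioConfig) -> SimulatedStudy:
    """Generate the three-trait study for ``cfg.scenario`` with ground truth.

    Deterministic given ``cfg.seed``: identical configurations produce
    bit-identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    ld, ld_scores = build_ld(cfg)
    t_asd, t_adhd, t_out = cfg.trait_names

    all_ids: list[str] = []
    chrom_parts, pos_parts = [], []
    m_a_parts, m_d_parts, m_o_parts = [], [], []
    b_a_parts, b_d_parts, b_o_parts = [], [], []
    block_idx_parts = []
    for b, blk in enumerate(ld.blocks):
        scen = _MIXTURE_CYCLE[b % len(_MIXTURE_CYCLE)] if cfg.scenario == "mixture" \
            else cfg.scenario
        b_a, b_d = _block_causal(cfg, rng, scen, b)
        causal_any = (b_a != 0) | (b_d != 0)
        b_o = cfg.theta_asd * b_a + cfg.theta_adhd * b_d
        if cfg.sigma_e > 0:
            b_o = b_o + np.where(causal_any,
                                 rng.normal(0.0, cfg.sigma_e, cfg.block_size), 0.0)
        r = blk.r
        m_a_parts.append(r @ b_a)
        m_d_parts.append(r @ b_d)
        m_o_parts.append(r @ b_o)
        b_a_parts.append(b_a)
        b_d_parts.append(b_d)
        b_o_parts.append(b_o)
        all_ids.extend(blk.ids)
        chrom_parts.append(np.full(cfg.block_size, blk.chrom, dtype=object))
        pos_parts.append(blk.pos)
        block_idx_parts.append(np.full(cfg.block_size, b))

    chrom = np.concatenate(chrom_parts)
    pos = np.concatenate(pos_parts)
    m_a = np.concatenate(m_a_parts)
    m_d = np.concatenate(m_d_parts)
    m_o = np.concatenate(m_o_parts)
    b_a = np.concatenate(b_a_parts)
    b_d = np.concatenate(b_d_parts)
    b_o = np.concatenate(b_o_parts)
    block_of = pd.Series(np.concatenate(block_idx_parts), index=all_ids,
                         name="block")

    eaf_base = rng.uniform(0.05, 0.5, len(all_ids))
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), len(all_ids))
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    asd, flip_a = _emit(cfg, rng, t_asd, LOG_ODDS, cfg.n_asd, m_a,
                        chrom, pos, all_ids, eaf_base, ea, oa)
    adhd, flip_d = _emit(cfg, rng, t_adhd, LOG_ODDS, cfg.n_adhd, m_d,
                         chrom, pos, all_ids, eaf_base, ea, oa)
    out, flip_o = _emit(cfg, rng, t_out, OUTCOME_UNITS, cfg.n_out, m_o,
                        chrom, pos, all_ids, eaf_base, ea, oa)

    asd_rep = adhd_rep = None
    flips = {t_asd: flip_a, t_adhd: flip_d, t_out: flip_o}
    if cfg.emit_replicate:
        asd_rep, flip_ar = _emit(cfg, rng, f"{t_asd}_replicate", LOG_ODDS,
                                 cfg.n_asd, m_a, chrom, pos, all_ids,
                                 eaf_base, ea, oa)
        adhd_rep, flip_dr = _emit(cfg, rng, f"{t_adhd}_replicate", LOG_ODDS,
                                  cfg.n_adhd, m_d, chrom, pos, all_ids,
                                  eaf_base, ea, oa)
        flips[f"{t_asd}_replicate"] = flip_ar
        flips[f"{t_adhd}_replicate"] = flip_dr

    causal_mask = (b_a != 0) | (b_d != 0) | (b_o != 0)
    causal = pd.DataFrame({
        "snp": np.asarray(all_ids)[causal_mask],
        "b_asd": b_a[causal_mask],
        "b_adhd": b_d[causal_mask],
        "b_out": b_o[causal_mask],
    })
    marginals = pd.DataFrame({"snp": all_ids, "m_asd": m_a, "m_adhd": m_d,
                              "m_out": m_o})

    def _corr(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1])

    truth = ScenarioTruth(
        scenario=cfg.scenario,
        theta={t_asd: cfg.theta_asd, t_adhd: cfg.theta_adhd},
        causal=causal,
        marginals=marginals,
        ld_scores=ld_scores,
        block_of=block_of,
        flips=flips,
        rg_true={
            f"{t_asd},{t_adhd}": _corr(m_a, m_d),
            f"{t_asd},{t_out}": _corr(m_a, m_o),
            f"{t_adhd},{t_out}": _corr(m_d, m_o),
        },
        gene_flag={"III-e": "same_gene", "III-f": "different_gene",
                   "IV-g": "same_gene", "IV-h": "different_gene"}.get(cfg.scenario),
    )
    return SimulatedStudy(asd=asd, adhd=adhd, outcome=out, truth=truth,
                          ld=ld, ld_scores=ld_scores,
                          asd_replicate=asd_rep, adhd_replicate=adhd_rep)
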