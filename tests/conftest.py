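"""Shared fixtures and independently coded oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gwasmvr.ld import LDReference
from gwasmvr.simulate import ScenarioConfig, simulate_triple_gwas


def random_correlation(rng: np.random.Generator, n: int) -> np.ndarray:
    """Symmetric unit-diagonal matrix with entries in [-1, 1] (rank-2 factor)."""
    f = rng.normal(size=(n, 2))
    f /= np.linalg.norm(f, axis=1, keepdims=True)
    r = f @ f.T
    np.fill_diagonal(r, 1.0)
    return r


def random_ld_toy(rng: np.random.Generator, n_snps: int, n_blocks: int = 2,
                  span_kb: int = 800) -> tuple[LDReference, pd.DataFrame]:
    """Random block LD reference plus a record table (snp, pos, pvalue)."""
    sizes = np.maximum(1, rng.multinomial(n_snps, np.ones(n_blocks) / n_blocks))
    blocks, rows = [], []
    sid = 0
    for b, size in enumerate(sizes):
        pos = np.sort(rng.choice(span_kb * 1000, size=size, replace=False)) + 1
        ids = [f"s{sid + i}" for i in range(size)]
        sid += size
        blocks.append(("1" if b == 0 else str(b + 1), ids, pos,
                       random_correlation(rng, size)))
        for i, p in zip(ids, pos):
            rows.append((i, int(p), float(rng.uniform())))
    return LDReference(blocks), pd.DataFrame(rows, columns=["snp", "pos", "pvalue"])


def clump_oracle(records: pd.DataFrame, ld: LDReference, r2_max: float,
                 window_kb: int) -> list[str]:
    """Brute-force greedy clumping straight from the definition."""
    order = records.sort_values(["pvalue", "pos", "snp"], kind="mergesort")
    kept: list[tuple[str, int, str]] = []  # (id, pos, chrom)
    for sid, pos in zip(order["snp"], order["pos"]):
        chrom = ld.chrom_of(sid)
        excluded = any(
            kchrom == chrom and abs(int(pos) - kpos) <= window_kb * 1000
            and ld.r2(sid, kid) >= r2_max
            for kid, kpos, kchrom in kept)
        if not excluded:
            kept.append((sid, int(pos), chrom))
    return [k[0] for k in kept]


def proxy_oracle(index_ids, candidate_ids, ld: LDReference, r2_min: float,
                 window_kb: int) -> dict[str, tuple[str, float] | None]:
    """Exhaustive best-proxy search over all candidate pairs."""
    out = {}
    for idx in index_ids:
        if idx in set(candidate_ids):
            out[idx] = (idx, 1.0)
            continue
        best = None
        for cand in sorted(candidate_ids):
            if ld.chrom_of(cand) != ld.chrom_of(idx):
                continue
            dist = abs(ld.pos_of(cand) - ld.pos_of(idx))
            if dist > window_kb * 1000:
                continue
            r2 = ld.r2(idx, cand)
            if r2 < r2_min:
                continue
            key = (-r2, dist, cand)
            if best is None or key < best:
                best = key
        out[idx] = None if best is None else (best[2], -best[0])
    return out


def wls_oracle(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> dict:
    """Normal-equations weighted least squares with explicit inversion."""
    from scipy import stats as sps

    n = len(y)
    D = np.column_stack([np.ones(n), X])
    p = D.shape[1]
    A = D.T @ np.diag(w) @ D
    Ainv = np.linalg.inv(A)
    b = Ainv @ D.T @ np.diag(w) @ y
    resid = y - D @ b
    rss_w = float(resid @ np.diag(w) @ resid)
    scale = rss_w / (n - p)
    se = np.sqrt(np.diag(scale * Ainv))
    t = b / se
    pvals = 2 * sps.t.sf(np.abs(t), n - p)
    sigma2 = rss_w / n
    loglik = (-n / 2 * (np.log(2 * np.pi * sigma2) + 1)
              + 0.5 * float(np.sum(np.log(w))))
    return {"params": b, "se": se, "t": t, "p": pvals, "loglik": loglik,
            "df": n - p}


def make_triplet(rng: np.random.Generator, n: int,
                 theta=(0.3, -0.2), intercept: float = 0.0,
                 noise: float = 0.05, rho: float = 0.5) -> pd.DataFrame:
    """Random aligned three-trait table with heterogeneous outcome SEs."""
    x1 = rng.normal(0, 1, n)
    x2 = rho * x1 + np.sqrt(1 - rho ** 2) * rng.normal(0, 1, n)
    se_out = rng.uniform(0.5, 2.0, n)
    y = intercept + theta[0] * x1 + theta[1] * x2 + noise * se_out * rng.normal(size=n)
    return pd.DataFrame({
        "snp": [f"s{i}" for i in range(n)],
        "chrom": "1", "pos": np.arange(1, n + 1) * 1000,
        "effect_allele": "A", "other_allele": "G", "eaf": 0.3,
        "beta_E1": x1, "se_E1": 0.1, "p_E1": 0.5,
        "beta_E2": x2, "se_E2": 0.1, "p_E2": 0.5,
        "beta_OUT": y, "se_OUT": se_out, "p_OUT": 0.5,
    })


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study reused by read-only tests."""
    return simulate_triple_gwas(ScenarioConfig(seed=20_260_101, n_blocks=30,
                                               block_size=50,
                                               emit_replicate=True))


@pytest.fixture()
def rng():
    return np.random.default_rng(97)
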