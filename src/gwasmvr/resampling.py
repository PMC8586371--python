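"""Permutation null for locus subsets.

Does a designated k-variant subset's multivariable association with the
outcome exceed what chance draws of k variants from its parent set produce?
The permuted statistic is the absolute slope t-value per exposure; the
empirical P uses the plus-one estimator (r + 1) / (B + 1), so it is never 0
and never below 1 / (B + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .regression import fit_weighted_mvr


@dataclass
class PermutationResult:
    exposures: tuple[str, ...]
    observed_t: dict[str, float]
    B: int
    seed: int
    exceed: dict[str, int]
    empirical_p: dict[str, float]
    n_singular: int
    k: int

    def to_json_dict(self) -> dict:
        return {
            "exposures": list(self.exposures),
            "observed_abs_t": self.observed_t,
            "B": self.B,
            "seed": self.seed,
            "exceed_count": self.exceed,
            "empirical_p": self.empirical_p,
            "n_singular_permutations": self.n_singular,
            "k": self.k,
        }


def _abs_slope_t(D: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray | None:
    """|t| of the non-intercept terms of a weighted fit; None when singular."""
    n, p = D.shape
    A = D.T @ (w[:, None] * D)
    d = np.sqrt(np.diag(A))
    if np.any(d <= 0):
        return None
    C = A / np.outer(d, d)
    if 1.0 / np.linalg.cond(C) < 1e-12:
        return None
    b = np.linalg.solve(A, D.T @ (w * y))
    resid = y - D @ b
    scale = float(np.sum(w * resid ** 2)) / (n - p)
    if scale <= 0:
        return None
    se = np.sqrt(scale * np.diag(np.linalg.inv(A)))
    return np.abs(b[1:] / se[1:])


def permutation_null(parent_table: pd.DataFrame, subset_ids: Sequence[str],
                     exposures: Sequence[str], outcome: str,
                     B: int = 10_000, seed: int = 0) -> PermutationResult:
    """Empirical P for the subset's slopes against random k-subsets.

    ``parent_table`` is an aligned table (``beta_<trait>`` columns) whose rows
    form the parent variant set; ``subset_ids`` designates the tested k-SNP
    subset (must be drawn from the parent). For each of B permutations, k rows
    are sampled uniformly without replacement, refitted, and the absolute
    slope t recorded; empirical_p = (#{|t_perm| >= |t_obs|} + 1) / (B + 1).
    Singular permuted fits count as non-exceeding and are audited. Fully
    reproducible given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    ids = parent_table["snp"].astype(str)
    subset_ids = [str(s) for s in subset_ids]
    member = ids.isin(subset_ids)
    k = len(subset_ids)
    if member.sum() != k:
        raise ValueError("subset_ids must all be distinct rows of parent_table")
    if k > len(parent_table):
        raise ValueError("subset larger than parent set")

    observed = fit_weighted_mvr(parent_table.loc[member.to_numpy()],
                                exposures, outcome)
    obs_t = {e: float(abs(observed.slope(e)["t"])) for e in exposures}

    n = len(parent_table)
    X = np.column_stack([np.ones(n)] +
                        [parent_table[f"beta_{e}"].to_numpy(dtype=float)
                         for e in exposures])
    y = parent_table[f"beta_{outcome}"].to_numpy(dtype=float)
    w = parent_table[f"se_{outcome}"].to_numpy(dtype=float) ** -2.0

    rng = np.random.default_rng(seed)
    exceed = {e: 0 for e in exposures}
    n_singular = 0
    obs_vec = np.array([obs_t[e] for e in exposures])
    # tolerance so refitting the observed subset itself (row order permuted)
    # counts as a tie despite floating-point jitter
    cut = np.where(np.isfinite(obs_vec), obs_vec * (1.0 - 1e-9), obs_vec)
    for _ in range(B):
        idx = rng.choice(n, size=k, replace=False)
        t_abs = _abs_slope_t(X[idx], y[idx], w[idx])
        if t_abs is None:
            n_singular += 1
            continue
        for e, hit in zip(exposures, t_abs >= cut):
            if hit:
                exceed[e] += 1
    empirical_p = {e: (exceed[e] + 1) / (B + 1) for e in exposures}
    return PermutationResult(
        exposures=tuple(exposures), observed_t=obs_t, B=B, seed=seed,
        exceed=exceed, empirical_p=empirical_p, n_singular=n_singular, k=k)
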