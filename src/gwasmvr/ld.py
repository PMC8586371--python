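"""Block-structured linkage-disequilibrium reference: pairwise lookup, greedy
clumping and proxy search.

LD is stored as signed correlation ``r`` within blocks; variants in different
blocks are unlinked (r = 0). Windows are measured center-to-center in base
pairs and are inclusive at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class UnknownVariantError(KeyError):
    """Variant id not present in the LD reference."""


@dataclass(frozen=True)
class Block:
    chrom: str
    ids: tuple[str, ...]
    pos: np.ndarray          # int64, 1-based
    r: np.ndarray            # signed correlation, symmetric, unit diagonal


@dataclass(frozen=True)
class ProxyMatch:
    index_id: str
    partner_id: str
    r2: float
    distance_bp: int

    @property
    def identical(self) -> bool:
        return self.index_id == self.partner_id


class LDReference:
    """Pairwise signed-r lookup over LD blocks.

    Parameters
    ----------
    blocks:
        iterable of ``(chrom, ids, pos, r)`` tuples or :class:`Block`; each
        ``r`` must be symmetric with unit diagonal and entries in [-1, 1].
    """

    def __init__(self, blocks: Iterable):
        self.blocks: list[Block] = []
        self._where: dict[str, tuple[int, int]] = {}
        for b in blocks:
            blk = b if isinstance(b, Block) else Block(
                chrom=str(b[0]), ids=tuple(b[1]),
                pos=np.asarray(b[2], dtype=np.int64),
                r=np.asarray(b[3], dtype=float))
            m = blk.r
            if m.shape != (len(blk.ids), len(blk.ids)):
                raise ValueError("LD matrix shape does not match member count")
            if not np.allclose(m, m.T, atol=1e-12):
                raise ValueError("LD matrix must be symmetric")
            if not np.allclose(np.diag(m), 1.0, atol=1e-12):
                raise ValueError("LD matrix must have unit diagonal")
            if np.any(np.abs(m) > 1 + 1e-12):
                raise ValueError("LD entries must lie in [-1, 1]")
            bi = len(self.blocks)
            self.blocks.append(blk)
            for i, sid in enumerate(blk.ids):
                if sid in self._where:
                    raise ValueError(f"duplicate variant id {sid!r} across blocks")
                self._where[sid] = (bi, i)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._where

    def __len__(self) -> int:
        return len(self._where)

    def _locate(self, snp_id: str) -> tuple[int, int]:
        try:
            return self._where[snp_id]
        except KeyError:
            raise UnknownVariantError(snp_id) from None

    def r(self, a: str, b: str) -> float:
        """Signed correlation; 0 across blocks."""
        bi, i = self._locate(a)
        bj, j = self._locate(b)
        return float(self.blocks[bi].r[i, j]) if bi == bj else 0.0

    def r2(self, a: str, b: str) -> float:
        return self.r(a, b) ** 2

    def chrom_of(self, snp_id: str) -> str:
        bi, _ = self._locate(snp_id)
        return self.blocks[bi].chrom

    def pos_of(self, snp_id: str) -> int:
        bi, i = self._locate(snp_id)
        return int(self.blocks[bi].pos[i])

    # ---------------------------------------------------------------- IO ---
    @classmethod
    def from_pair_list(cls, pairs, sites) -> "LDReference":
        """Build from a long pair list and a site table.

        ``pairs``: path or DataFrame with columns SNP_A, SNP_B, R
        (tab-delimited file). ``sites``: path or DataFrame with columns
        SNP, CHR, BP giving every variant's location (singletons allowed).
        Connected components of the pair graph become blocks; unlisted pairs
        within a component have r = 0.
        """
        if not isinstance(pairs, pd.DataFrame):
            pairs = pd.read_csv(pairs, sep=r"\s+")
        if not isinstance(sites, pd.DataFrame):
            sites = pd.read_csv(sites, sep=r"\s+")
        pairs = pairs.rename(columns=str.upper)
        sites = sites.rename(columns=str.upper)
        loc = sites.set_index(sites["SNP"].astype(str))

        # union-find over the pair graph
        parent: dict[str, str] = {str(s): str(s) for s in sites["SNP"]}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in zip(pairs["SNP_A"].astype(str), pairs["SNP_B"].astype(str)):
            if a not in parent or b not in parent:
                raise ValueError(f"pair ({a}, {b}) references variant absent from sites table")
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
        comps: dict[str, list[str]] = {}
        for s in parent:
            comps.setdefault(find(s), []).append(s)

        blocks = []
        for members in comps.values():
            members = sorted(members, key=lambda s: (int(loc.at[s, "BP"]), s))
            idx = {s: i for i, s in enumerate(members)}
            m = np.eye(len(members))
            sub = pairs[pairs["SNP_A"].astype(str).isin(idx) & pairs["SNP_B"].astype(str).isin(idx)]
            for a, b, r in zip(sub["SNP_A"].astype(str), sub["SNP_B"].astype(str), sub["R"]):
                m[idx[a], idx[b]] = m[idx[b], idx[a]] = float(r)
            chroms = {str(loc.at[s, "CHR"]) for s in members}
            if len(chroms) != 1:
                raise ValueError("an LD block may not span chromosomes")
            blocks.append((chroms.pop(), members,
                           [int(loc.at[s, "BP"]) for s in members], m))
        return cls(blocks)

    def to_pair_list(self, path) -> None:
        """Write nonzero off-diagonal entries as SNP_A SNP_B R (tab-delimited)."""
        rows = []
        for blk in self.blocks:
            iu, ju = np.triu_indices(len(blk.ids), k=1)
            for i, j in zip(iu, ju):
                if blk.r[i, j] != 0.0:
                    rows.append((blk.ids[i], blk.ids[j], blk.r[i, j]))
        pd.DataFrame(rows, columns=["SNP_A", "SNP_B", "R"]).to_csv(
            path, sep="\t", index=False)


def clump(records, ld: LDReference, r2_max: float = 0.25,
          window_kb: int = 500) -> list[str]:
    """Greedy LD clumping: keep the most significant variant of every clump.

    ``records`` is a DataFrame with columns ``snp, pos, pvalue`` (or an
    iterable of such triples). Variants are visited by ascending P-value
    (ties: ascending position, then id) and retained iff no already-retained
    variant on the same chromosome within +/- ``window_kb`` has
    r2 >= ``r2_max`` with them. Returns retained ids in visitation order.
    """
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must be in (0, 1]")
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(records, columns=["snp", "pos", "pvalue"])
    if records.empty:
        raise ValueError("no records to clump")

    order = records.sort_values(["pvalue", "pos", "snp"], kind="mergesort")
    window = window_kb * 1000
    retained: list[str] = []
    # cross-block r is 0, so only same-block retained variants can exclude
    by_block: dict[int, list[tuple[int, int]]] = {}
    for sid, pos in zip(order["snp"].astype(str), order["pos"].astype(np.int64)):
        bi, i = ld._locate(sid)
        m = ld.blocks[bi].r
        ok = True
        for j, jpos in by_block.get(bi, ()):
            if abs(int(pos) - jpos) <= window and m[i, j] ** 2 >= r2_max:
                ok = False
                break
        if ok:
            retained.append(sid)
            by_block.setdefault(bi, []).append((i, int(pos)))
    return retained


def find_proxies(index_ids, candidate_ids, ld: LDReference,
                 r2_min: float = 0.6, window_kb: int = 500
                 ) -> dict[str, ProxyMatch | None]:
    """Best-proxy lookup: map each index variant to itself, or to the
    candidate within +/- ``window_kb`` with maximal r2 >= ``r2_min``.

    Ties break by smaller base-pair distance, then lexicographic id.
    Unmatched indices map to None.
    """
    index_ids = list(dict.fromkeys(str(s) for s in index_ids))
    candidates = set(str(s) for s in candidate_ids)
    if not index_ids or not candidates:
        raise ValueError("index and candidate sets must be non-empty")
    window = window_kb * 1000

    cand_by_block: dict[int, list[tuple[int, int, str]]] = {}
    for sid in candidates:
        bi, i = ld._locate(sid)
        cand_by_block.setdefault(bi, []).append((i, ld.pos_of(sid), sid))

    out: dict[str, ProxyMatch | None] = {}
    for sid in index_ids:
        if sid in candidates:
            out[sid] = ProxyMatch(sid, sid, 1.0, 0)
            continue
        bi, i = ld._locate(sid)
        pos = ld.pos_of(sid)
        m = ld.blocks[bi].r
        best: tuple[float, int, str] | None = None  # (-r2, dist, id) minimised
        for j, jpos, cid in cand_by_block.get(bi, ()):
            dist = abs(jpos - pos)
            if dist > window:
                continue
            r2 = m[i, j] ** 2
            if r2 < r2_min:
                continue
            key = (-r2, dist, cid)
            if best is None or key < best:
                best = key
        out[sid] = None if best is None else ProxyMatch(sid, best[2], -best[0], best[1])
    return out
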