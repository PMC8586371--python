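"""End-to-end orchestration: discovery MVR grid, concordant sensitivity,
conditional grid with permutation, and overlap-aware meta + genetic
correlation, on any harmonizable trio of summary statistics.

The outcome trait and both exposures are parameters, so specificity analyses
(a different outcome, or a different second exposure) reuse the same code
path with different inputs. Reports are plain dataclasses serializable to a
consolidated JSON plus TSV tables; they carry per-cell variant counts and
audit information and contain no timestamps, so identical inputs and seeds
give byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ld import LDReference
from .overlap import RgResult, covariance_adjusted_meta, cross_trait_ldsc, \
    estimate_overlap_correlation
from .regression import (InsufficientDataError, MvrResult, SingularDesignError,
                         bonferroni_threshold, fit_weighted_mvr, fit_weighted_uvr,
                         likelihood_ratio_test)
from .resampling import PermutationResult, permutation_null
from .selection import (ConditionalSet, SelectionConfig, align_to_risk,
                        concordant_subset, conditional_grid, select_variants)
from .simulate import ScenarioConfig, simulate_triple_gwas
from .sumstats import SummaryStats, harmonize, read_sumstats


def _maybe(result: MvrResult | None):
    return None if result is None else result.to_json_dict()


@dataclass
class CellResult:
    """One (direction, threshold) cell of the discovery grid."""

    direction: str            # trait the set was selected from and oriented to
    p_threshold: float
    n_selected: int
    n_snps: int
    mvr: MvrResult | None = None
    uvr: dict[str, MvrResult] = field(default_factory=dict)
    lrt: dict[str, tuple[float, float]] = field(default_factory=dict)
    concordant: MvrResult | None = None
    n_concordant: int = 0
    empty: bool = False
    error: str | None = None

    def to_json_dict(self) -> dict:
        return {
            "direction": self.direction,
            "p_threshold": self.p_threshold,
            "n_selected": self.n_selected,
            "n_snps": self.n_snps,
            "empty": self.empty,
            "error": self.error,
            "mvr": _maybe(self.mvr),
            "uvr": {k: v.to_json_dict() for k, v in self.uvr.items()},
            "lrt": {k: {"statistic": s, "p": p} for k, (s, p) in self.lrt.items()},
            "n_concordant": self.n_concordant,
            "concordant_mvr": _maybe(self.concordant),
        }


@dataclass
class DiscoveryReport:
    exposures: tuple[str, str]
    outcome: str
    thresholds: tuple[float, ...]
    bonferroni_exact: float
    bonferroni_rounded: float
    cells: list[CellResult]
    harmonization_audit: dict

    def cell(self, direction: str, p_threshold: float) -> CellResult:
        for c in self.cells:
            if c.direction == direction and c.p_threshold == p_threshold:
                return c
        raise KeyError((direction, p_threshold))

    def to_json_dict(self) -> dict:
        return {
            "analysis": "discovery",
            "exposures": list(self.exposures),
            "outcome": self.outcome,
            "thresholds": list(self.thresholds),
            "n_tests": 2 * len(self.thresholds),
            "bonferroni_exact": self.bonferroni_exact,
            "bonferroni_rounded": self.bonferroni_rounded,
            "harmonization_audit": self.harmonization_audit,
            "cells": [c.to_json_dict() for c in self.cells],
        }


def _fit_cell(triplet: pd.DataFrame, members, primary: str, other: str,
              outcome: str) -> tuple[pd.DataFrame, MvrResult, dict, dict]:
    sub = triplet[triplet["snp"].isin(set(members))]
    oriented = align_to_risk(sub, primary)
    mvr = fit_weighted_mvr(oriented, (primary, other), outcome,
                           orientation_trait=primary)
    uvr, lrt = {}, {}
    for expo in (primary, other):
        try:
            u = fit_weighted_uvr(oriented, expo, outcome, orientation_trait=primary)
            uvr[expo] = u
            lrt[expo] = likelihood_ratio_test(u, mvr)
        except (InsufficientDataError, SingularDesignError):
            pass
    return oriented, mvr, uvr, lrt


def run_discovery(stats_1: SummaryStats, stats_2: SummaryStats,
                  stats_out: SummaryStats, ld: LDReference,
                  cfg: SelectionConfig = SelectionConfig(),
                  selection_stats: dict[str, SummaryStats] | None = None,
                  palindrome_policy: str = "eaf") -> DiscoveryReport:
    """Bidirectional MVR grid over the discovery thresholds.

    For each direction (variant sets from ``stats_1`` oriented to its risk
    allele, then from ``stats_2``) and each threshold: select, orient, fit the
    MVR, both univariable fits with likelihood-ratio comparisons, and the
    concordant-subset MVR. ``selection_stats`` optionally maps a trait name to
    an independent statistics set used for selection only (winner's-curse
    control). Cell-level failures are recorded without aborting other cells.
    """
    t1, t2, tout = stats_1.trait_name, stats_2.trait_name, stats_out.trait_name
    triplet, audit = harmonize(stats_1, [stats_2, stats_out],
                               palindrome_policy=palindrome_policy)
    selection_stats = selection_stats or {}
    bonf = bonferroni_threshold(0.05, 2 * len(cfg.p_thresholds))

    cells: list[CellResult] = []
    for primary, other, stats in ((t1, t2, stats_1), (t2, t1, stats_2)):
        sel_source = selection_stats.get(primary, stats)
        for thr in cfg.p_thresholds:
            vs = select_variants(sel_source, cfg, thr, ld)
            cell = CellResult(direction=primary, p_threshold=thr,
                              n_selected=vs.size, n_snps=0)
            try:
                if vs.size < 4:
                    cell.empty = True
                else:
                    oriented, mvr, uvr, lrt = _fit_cell(
                        triplet, vs.members, primary, other, tout)
                    cell.n_snps = mvr.n_snps
                    cell.mvr, cell.uvr, cell.lrt = mvr, uvr, lrt
                    conc = concordant_subset(oriented, (t1, t2))
                    cell.n_concordant = len(conc)
                    if len(conc) >= 4:
                        cell.concordant = fit_weighted_mvr(
                            conc, (primary, other), tout, orientation_trait=primary)
            except (InsufficientDataError, SingularDesignError, ValueError) as exc:
                cell.error = f"{type(exc).__name__}: {exc}"
            cells.append(cell)

    return DiscoveryReport(
        exposures=(t1, t2), outcome=tout, thresholds=tuple(cfg.p_thresholds),
        bonferroni_exact=bonf.exact, bonferroni_rounded=bonf.rounded,
        cells=cells, harmonization_audit=audit)


@dataclass
class ConditionalDirectionReport:
    direction: str
    primary_threshold: float
    parent_size: int
    subsets: list[ConditionalSet]
    fits: dict[float, MvrResult | None]
    permutation: PermutationResult | None

    def to_json_dict(self) -> dict:
        return {
            "direction": self.direction,
            "primary_threshold": self.primary_threshold,
            "parent_size": self.parent_size,
            "subsets": [
                {"conditional_threshold": s.conditional_threshold,
                 "size": s.size,
                 "n_identical": int((s.table["overlap_mode"] == "identical").sum()),
                 "n_proxy": int((s.table["overlap_mode"] == "proxy").sum())}
                for s in self.subsets],
            "fits": {str(t): _maybe(f) for t, f in self.fits.items()},
            "permutation": None if self.permutation is None
            else self.permutation.to_json_dict(),
        }


@dataclass
class ConditionalReport:
    exposures: tuple[str, str]
    outcome: str
    bonferroni_rounded: float
    directions: list[ConditionalDirectionReport]

    def to_json_dict(self) -> dict:
        return {
            "analysis": "conditional",
            "exposures": list(self.exposures),
            "outcome": self.outcome,
            "bonferroni_rounded": self.bonferroni_rounded,
            "directions": [d.to_json_dict() for d in self.directions],
        }


def run_conditional(stats_1: SummaryStats, stats_2: SummaryStats,
                    stats_out: SummaryStats, ld: LDReference,
                    cfg: SelectionConfig = SelectionConfig(),
                    primary_threshold: float = 0.0015,
                    permutation_B: int = 1000, seed: int = 0,
                    palindrome_policy: str = "eaf") -> ConditionalReport:
    """Conditional P-value thresholding both ways, with a permutation null.

    Builds the conditional subsets of each disorder's variant set at
    ``primary_threshold``, fits the MVR per subset, and tests the most
    stringent subset against random equal-size draws from its parent set.
    """
    t1, t2, tout = stats_1.trait_name, stats_2.trait_name, stats_out.trait_name
    triplet, _ = harmonize(stats_1, [stats_2, stats_out],
                           palindrome_policy=palindrome_policy)
    bonf = bonferroni_threshold(0.05, 2 * len(SelectionConfig().p_thresholds))

    directions = []
    for primary, other, p_stats, o_stats in ((t1, t2, stats_1, stats_2),
                                             (t2, t1, stats_2, stats_1)):
        parent = select_variants(p_stats, cfg, primary_threshold, ld)
        subsets = conditional_grid(parent, o_stats, cfg, ld)
        fits: dict[float, MvrResult | None] = {}
        parent_rows = align_to_risk(
            triplet[triplet["snp"].isin(set(parent.members))], primary)
        for cs in subsets:
            rows = parent_rows[parent_rows["snp"].isin(set(cs.members))]
            try:
                fits[cs.conditional_threshold] = fit_weighted_mvr(
                    rows, (primary, other), tout, orientation_trait=primary)
            except (InsufficientDataError, SingularDesignError):
                fits[cs.conditional_threshold] = None
        stringent = subsets[0]
        perm = None
        members_in_table = [s for s in stringent.members
                            if s in set(parent_rows["snp"])]
        if len(members_in_table) >= 4 and len(parent_rows) > len(members_in_table):
            perm = permutation_null(parent_rows, members_in_table,
                                    (primary, other), tout,
                                    B=permutation_B, seed=seed)
        directions.append(ConditionalDirectionReport(
            direction=primary, primary_threshold=primary_threshold,
            parent_size=parent.size, subsets=subsets, fits=fits,
            permutation=perm))
    return ConditionalReport(exposures=(t1, t2), outcome=tout,
                             bonferroni_rounded=bonf.rounded,
                             directions=directions)


@dataclass
class MetaRgReport:
    """Genetic correlations with the outcome before and after meta-analysis."""

    overlap_correlation: float
    rg_1: RgResult
    rg_2: RgResult
    rg_meta: RgResult
    attenuated: bool

    def to_json_dict(self) -> dict:
        return {
            "analysis": "meta_rg",
            "overlap_correlation": self.overlap_correlation,
            "rg_trait1_outcome": self.rg_1.to_json_dict(),
            "rg_trait2_outcome": self.rg_2.to_json_dict(),
            "rg_meta_outcome": self.rg_meta.to_json_dict(),
            "attenuated": self.attenuated,
        }


def run_meta_rg(stats_1: SummaryStats, stats_2: SummaryStats,
                stats_out: SummaryStats, ld_scores,
                n_blocks: int = 20, z_cut: float = 1.96,
                overlap_correlation: float | None = None) -> MetaRgReport:
    """Effect-cancellation check: meta-analyse the two disorders allowing
    sample overlap and compare each trait's genetic correlation with the
    outcome to the meta-analysis's."""
    c = (estimate_overlap_correlation(stats_1, stats_2, z_cut=z_cut)
         if overlap_correlation is None else overlap_correlation)
    meta = covariance_adjusted_meta(stats_1, stats_2, c)
    rg_1 = cross_trait_ldsc(stats_1, stats_out, ld_scores, n_blocks=n_blocks)
    rg_2 = cross_trait_ldsc(stats_2, stats_out, ld_scores, n_blocks=n_blocks)
    rg_m = cross_trait_ldsc(meta, stats_out, ld_scores, n_blocks=n_blocks)
    attenuated = bool(abs(rg_m.rg) < min(abs(rg_1.rg), abs(rg_2.rg))) \
        if all(np.isfinite([rg_m.rg, rg_1.rg, rg_2.rg])) else False
    return MetaRgReport(overlap_correlation=c, rg_1=rg_1, rg_2=rg_2,
                        rg_meta=rg_m, attenuated=attenuated)


def replicate_seeds(base_seed: int, n: int) -> list[int]:
    """Deterministic per-replicate seeds below 2^31 derived from one seed."""
    return [int(s) % (2 ** 31) for s in
            np.random.SeedSequence(base_seed).generate_state(n)]


def replicate_recovery(n_replicates: int, base_seed: int,
                       p_thr: float = 0.0015,
                       sel_cfg: SelectionConfig = SelectionConfig(),
                       **scenario_overrides) -> pd.DataFrame:
    """Repeated end-to-end slope recovery on freshly simulated studies.

    Each replicate simulates a study (replicate disorder statistics are used
    for variant selection, the main draws for estimation — winner's-curse
    control), harmonizes, selects at ``p_thr``, orients to the first
    disorder's risk allele and fits the MVR. Returns one row per replicate
    with estimate/se/p per exposure and the variant count.
    """
    rows = []
    for seed in replicate_seeds(base_seed, n_replicates):
        cfg = ScenarioConfig(seed=seed, emit_replicate=True, **scenario_overrides)
        sim = simulate_triple_gwas(cfg)
        t_asd, t_adhd, t_out = cfg.trait_names
        vs = select_variants(sim.asd_replicate, sel_cfg, p_thr, sim.ld)
        triplet, _ = harmonize(sim.asd, [sim.adhd, sim.outcome])
        oriented = align_to_risk(
            triplet[triplet["snp"].isin(set(vs.members))], t_asd)
        res = fit_weighted_mvr(oriented, (t_asd, t_adhd), t_out,
                               orientation_trait=t_asd)
        row = {"seed": seed, "n_snps": res.n_snps}
        for expo, key in ((t_asd, "asd"), (t_adhd, "adhd")):
            s = res.slope(expo)
            row[f"theta_{key}"] = float(s["estimate"])
            row[f"se_{key}"] = float(s["se"])
            row[f"p_{key}"] = float(s["p"])
        rows.append(row)
    return pd.DataFrame(rows)


def cancellation_study(n_replicates: int, base_seed: int,
                       n_blocks: int = 600, **scenario_overrides) -> pd.DataFrame:
    """Repeated effect-cancellation experiment on symmetric polygenic studies.

    Each replicate simulates an infinitesimal-architecture study with
    discordant symmetric slopes, meta-analyses the two disorders allowing
    sample overlap, and records the three genetic correlations with the
    outcome plus whether the meta-analysis attenuated below both traits.
    """
    rows = []
    for seed in replicate_seeds(base_seed, n_replicates):
        cfg = ScenarioConfig.infinitesimal(seed, n_blocks=n_blocks,
                                           **scenario_overrides)
        sim = simulate_triple_gwas(cfg)
        rep = run_meta_rg(sim.asd, sim.adhd, sim.outcome, sim.ld_scores)
        rows.append({"seed": seed, "rg_1": rep.rg_1.rg, "rg_2": rep.rg_2.rg,
                     "rg_meta": rep.rg_meta.rg,
                     "overlap_c": rep.overlap_correlation,
                     "attenuated": rep.attenuated})
    return pd.DataFrame(rows)


def permutation_calibration(n_repeats: int, base_seed: int, B: int = 999,
                            parent_rows: int = 300, k: int = 50,
                            n_blocks: int = 20, block_size: int = 50
                            ) -> np.ndarray:
    """Empirical permutation P-values when the tested subset is itself an
    exchangeable random draw from its parent set (the null).

    Returns one empirical P per repeat (first-exposure slope); under the null
    these are approximately Uniform(0, 1).
    """
    ps = []
    for seed in replicate_seeds(base_seed, n_repeats):
        cfg = ScenarioConfig(seed=seed, n_blocks=n_blocks, block_size=block_size)
        sim = simulate_triple_gwas(cfg)
        t_asd, t_adhd, t_out = cfg.trait_names
        triplet, _ = harmonize(sim.asd, [sim.adhd, sim.outcome])
        rng = np.random.default_rng(seed + 1)
        idx = rng.choice(len(triplet), size=parent_rows, replace=False)
        parent = triplet.iloc[np.sort(idx)].reset_index(drop=True)
        subset = list(rng.choice(parent["snp"], size=k, replace=False))
        res = permutation_null(parent, subset, (t_asd, t_adhd), t_out,
                               B=B, seed=seed + 2)
        ps.append(res.empirical_p[t_asd])
    return np.asarray(ps)


# ------------------------------------------------------------------ config --

_LD_KEYS = {"pairs", "sites"}


def load_config(path) -> dict:
    """Load and validate the YAML run configuration.

    Top-level sections: ``inputs`` (either ``simulate: {scenario config}`` or
    file paths ``trait1/trait2/outcome`` plus ``ld: {pairs, sites}`` and
    optional ``ld_scores``), optional ``selection``, ``conditional``,
    ``permutation`` and ``meta`` overrides.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "inputs" not in cfg:
        raise ValueError("config must be a mapping with an 'inputs' section")
    inputs = cfg["inputs"]
    if "simulate" in inputs:
        if "seed" not in inputs["simulate"]:
            raise ValueError("inputs.simulate requires an explicit seed")
    else:
        missing = {"trait1", "trait2", "outcome", "ld"} - set(inputs)
        if missing:
            raise ValueError(f"inputs missing keys: {sorted(missing)}")
        if not _LD_KEYS <= set(inputs["ld"]):
            raise ValueError("inputs.ld requires 'pairs' and 'sites' paths")
    if "selection" in cfg:
        SelectionConfig(**cfg["selection"])  # validates eagerly
    return cfg


def _load_inputs(cfg: dict):
    inputs = cfg["inputs"]
    if "simulate" in inputs:
        sim = simulate_triple_gwas(ScenarioConfig(**inputs["simulate"]))
        return sim.asd, sim.adhd, sim.outcome, sim.ld, sim.ld_scores
    s1 = read_sumstats(inputs["trait1"]["path"], effect_unit="log-odds",
                       trait_name=inputs["trait1"].get("name", "trait1"))
    s2 = read_sumstats(inputs["trait2"]["path"], effect_unit="log-odds",
                       trait_name=inputs["trait2"].get("name", "trait2"))
    out = read_sumstats(inputs["outcome"]["path"], effect_unit="outcome-units",
                        trait_name=inputs["outcome"].get("name", "outcome"))
    ld = LDReference.from_pair_list(inputs["ld"]["pairs"], inputs["ld"]["sites"])
    scores = None
    if "ld_scores" in inputs:
        df = pd.read_csv(inputs["ld_scores"], sep=r"\s+")
        cols = {c.upper(): c for c in df.columns}
        scores = df.set_index(df[cols["SNP"]].astype(str))[cols["L2"]]
    return s1, s2, out, ld, scores


def run_all(config: dict, outdir) -> dict:
    """Run discovery, conditional and meta/rg stages; write consolidated
    JSON and per-stage TSVs under ``outdir``. Returns the consolidated dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s1, s2, out, ld, ld_scores = _load_inputs(config)
    sel = SelectionConfig(**config.get("selection", {}))
    perm_cfg = config.get("permutation", {})

    discovery = run_discovery(s1, s2, out, ld, sel)
    conditional = run_conditional(
        s1, s2, out, ld, sel,
        primary_threshold=config.get("conditional", {}).get("primary_threshold", 0.0015),
        permutation_B=perm_cfg.get("B", 1000),
        seed=perm_cfg.get("seed", 0))
    consolidated = {
        "discovery": discovery.to_json_dict(),
        "conditional": conditional.to_json_dict(),
    }
    if ld_scores is not None:
        try:
            meta_rg = run_meta_rg(s1, s2, out, ld_scores,
                                  n_blocks=config.get("meta", {}).get("n_blocks", 20))
            consolidated["meta_rg"] = meta_rg.to_json_dict()
        except ValueError as exc:  # stage failure must not void other stages
            consolidated["meta_rg"] = {"error": f"{type(exc).__name__}: {exc}"}

    with open(outdir / "report.json", "w") as fh:
        json.dump(consolidated, fh, indent=2, allow_nan=True)
    rows = []
    for cell in discovery.cells:
        for res in filter(None, [cell.mvr, *cell.uvr.values(), cell.concordant]):
            frame = res.to_frame()
            frame.insert(0, "direction", cell.direction)
            frame.insert(1, "p_threshold", cell.p_threshold)
            rows.append(frame)
    if rows:
        pd.concat(rows, ignore_index=True).to_csv(
            outdir / "discovery_estimates.tsv", sep="\t", index=False)
    return consolidated


def scatter_triplet(table: pd.DataFrame, exposures, outcome, path) -> None:
    """Minimal per-cell diagnostic: outcome effects against each exposure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(exposures), figsize=(4 * len(exposures), 3.5))
    axes = np.atleast_1d(axes)
    for ax, expo in zip(axes, exposures):
        ax.scatter(table[f"beta_{expo}"], table[f"beta_{outcome}"], s=6, alpha=0.5)
        ax.set_xlabel(f"beta {expo}")
        ax.set_ylabel(f"beta {outcome}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
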