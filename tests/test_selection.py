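"""Variant-set construction: filters, clumped discovery sets, risk-allele
orientation, concordant subsets and conditional thresholding."""

import numpy as np
import pandas as pd
import pytest

from conftest import clump_oracle, make_triplet
from gwasmvr.ld import LDReference
from gwasmvr.selection import (SelectionConfig, align_to_risk,
                               concordant_subset, conditional_grid,
                               select_variants, VariantSet)
from gwasmvr.sumstats import LOG_ODDS, SummaryStats


def _stats(df, name="D"):
    return SummaryStats(trait_name=name, effect_unit=LOG_ODDS, table=df)


def _table(snps, pos, pvalue, eaf=None, info=None, beta=None):
    n = len(snps)
    return pd.DataFrame({
        "snp": snps, "chrom": "1", "pos": pos,
        "effect_allele": "A", "other_allele": "G",
        "eaf": eaf if eaf is not None else [0.3] * n,
        "beta": beta if beta is not None else [0.1] * n,
        "se": [0.05] * n, "pvalue": pvalue,
        "info": info if info is not None else [1.0] * n,
        "n": [1000] * n})


class TestSelectionConfig:
    def test_defaults_match_study_design(self):
        cfg = SelectionConfig()
        assert len(cfg.p_thresholds) == 11
        assert cfg.p_thresholds[0] == 5e-8 and cfg.p_thresholds[-1] == 0.5
        assert len(cfg.conditional_thresholds) == 6
        assert (cfg.maf_min, cfg.info_min) == (0.01, 0.7)
        assert (cfg.r2_clump, cfg.window_kb, cfg.proxy_r2) == (0.25, 500, 0.6)

    @pytest.mark.parametrize("kw", [
        {"p_thresholds": (0.5, 0.05)},           # not increasing
        {"p_thresholds": (0.0, 0.5)},            # out of range
        {"maf_min": 0.6},
        {"info_min": 1.5},
        {"r2_clump": 0.0},
        {"proxy_r2": 0.0},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SelectionConfig(**kw)


class TestSelectVariants:
    @pytest.fixture()
    def toy(self):
        # 6 SNPs, mutually unlinked: 2 fail MAF, 1 fails INFO
        df = _table([f"s{i}" for i in range(6)],
                    pos=[int(1e6 * i) + 1 for i in range(6)],
                    pvalue=[0.01] * 6,
                    eaf=[0.3, 0.005, 0.995, 0.3, 0.3, 0.3],
                    info=[1.0, 1.0, 1.0, 0.5, 1.0, 1.0])
        ld = LDReference([("1", [f"s{i}"], [int(1e6 * i) + 1], np.eye(1))
                          for i in range(6)])
        return _stats(df), ld

    def test_filter_bookkeeping(self, toy):
        stats, ld = toy
        vs = select_variants(stats, SelectionConfig(), 0.05, ld)
        assert set(vs.members) == {"s0", "s4", "s5"}
        assert vs.audit["fail_maf"] == 2
        assert vs.audit["fail_info"] == 1

    def test_degenerate_threshold_gives_empty_set(self, toy):
        stats, ld = toy
        vs = select_variants(stats, SelectionConfig(), 1e-30, ld)
        assert vs.size == 0 and vs.members == ()

    def test_missing_eaf_fails_enabled_filter_only(self, toy):
        stats, ld = toy
        stats.table.loc[0, "eaf"] = np.nan
        assert "s0" not in select_variants(stats, SelectionConfig(), 0.05, ld).members
        relaxed = SelectionConfig(maf_min=None)
        assert "s0" in select_variants(stats, relaxed, 0.05, ld).members

    def test_equals_sequential_filter_plus_clump_oracle(self, rng):
        n = 50
        pos = np.sort(rng.choice(900_000, n, replace=False)) + 1
        f = rng.normal(size=(n, 2))
        f /= np.linalg.norm(f, axis=1, keepdims=True)
        r = f @ f.T
        np.fill_diagonal(r, 1.0)
        ids = [f"s{i}" for i in range(n)]
        ld = LDReference([("1", ids, pos, r)])
        df = _table(ids, pos, rng.uniform(size=n),
                    eaf=rng.uniform(0.001, 0.5, n),
                    info=rng.uniform(0.5, 1.0, n))
        cfg = SelectionConfig()
        vs = select_variants(_stats(df), cfg, 0.3, ld)
        ok = df[(df["pvalue"] < 0.3)
                & (np.minimum(df["eaf"], 1 - df["eaf"]) > cfg.maf_min)
                & (df["info"] > cfg.info_min)]
        want = clump_oracle(ok[["snp", "pos", "pvalue"]], ld,
                            cfg.r2_clump, cfg.window_kb)
        assert list(vs.members) == want

    def test_nesting_across_thresholds(self, small_study):
        cfg = SelectionConfig()
        sets = [select_variants(small_study.asd, cfg, t, small_study.ld)
                for t in (0.0015, 0.05, 0.5)]
        for tighter, looser in zip(sets, sets[1:]):
            assert set(tighter.members) <= set(looser.members)


class TestAlignToRisk:
    def test_negative_primary_row_fully_negated(self):
        t = make_triplet(np.random.default_rng(0), 5)
        t.loc[0, ["beta_E1", "beta_E2", "beta_OUT"]] = [-0.1, 0.05, 0.02]
        out = align_to_risk(t, "E1")
        assert list(out.loc[0, ["beta_E1", "beta_E2", "beta_OUT"]]) == \
            [0.1, -0.05, -0.02]
        assert out.loc[0, "effect_allele"] == "G"
        assert out.loc[0, "eaf"] == pytest.approx(0.7)

    def test_nonnegative_rows_unchanged(self):
        t = make_triplet(np.random.default_rng(1), 5)
        t["beta_E1"] = np.abs(t["beta_E1"])
        pd.testing.assert_frame_equal(align_to_risk(t, "E1"), t)

    def test_idempotent_on_random_table(self, rng):
        t = make_triplet(rng, 100)
        once = align_to_risk(t, "E1")
        assert (once["beta_E1"] >= 0).all()
        pd.testing.assert_frame_equal(align_to_risk(once, "E1"), once)


class TestConcordantSubset:
    def test_keeps_shared_sign_drops_mixed_and_zero(self):
        t = make_triplet(np.random.default_rng(2), 4)
        t["beta_E1"] = [0.1, 0.1, -0.2, 0.0]
        t["beta_E2"] = [0.2, -0.2, -0.1, 0.3]
        out = concordant_subset(t, ("E1", "E2"))
        assert list(out["snp"]) == ["s0", "s2"]

    def test_idempotent(self, rng):
        t = make_triplet(rng, 200)
        once = concordant_subset(t, ("E1", "E2"))
        pd.testing.assert_frame_equal(concordant_subset(once, ("E1", "E2")), once)

    def test_retained_fraction_matches_orthant_probability(self):
        """Bivariate-normal betas with correlation rho share signs with
        probability 1/2 + arcsin(rho)/pi."""
        rho = 0.5
        rng = np.random.default_rng(33)
        n = 40_000
        t = make_triplet(rng, n, rho=rho)
        frac = len(concordant_subset(t, ("E1", "E2"))) / n
        expected = 0.5 + np.arcsin(rho) / np.pi
        assert frac == pytest.approx(expected, abs=3 * np.sqrt(0.25 / n))


class TestConditionalGrid:
    @pytest.fixture()
    def setup(self, small_study):
        cfg = SelectionConfig()
        parent = select_variants(small_study.asd, cfg, 0.0015, small_study.ld)
        return small_study, cfg, parent

    def test_six_subsets_nested(self, setup):
        study, cfg, parent = setup
        grids = conditional_grid(parent, study.adhd, cfg, study.ld)
        assert len(grids) == 6
        assert [g.conditional_threshold for g in grids] == \
            list(cfg.conditional_thresholds)
        for tight, loose in zip(grids, grids[1:]):
            assert set(tight.members) <= set(loose.members)
        for g in grids:
            assert set(g.members) <= set(parent.members)

    def test_all_null_other_stats_gives_empty_subsets(self, setup):
        study, cfg, parent = setup
        null = study.adhd.table.copy()
        null["pvalue"] = 0.9
        grids = conditional_grid(parent, _stats(null, "N"), cfg, study.ld)
        assert all(g.size == 0 for g in grids)

    def test_membership_matches_qualification_rule(self, setup):
        """Brute-force re-check: member iff itself or a window-limited proxy
        with r2 >= 0.6 passes the conditional threshold in the other trait."""
        study, cfg, parent = setup
        other = study.adhd
        grids = conditional_grid(parent, other, cfg, study.ld)
        tbl = other.table.set_index("snp")
        for g in grids[:2]:
            passing = set(tbl.index[
                (tbl["pvalue"] < g.conditional_threshold)
                & (np.minimum(tbl["eaf"], 1 - tbl["eaf"]) > cfg.maf_min)
                & (tbl["info"] > cfg.info_min)])
            for sid in parent.members:
                qualifies = sid in passing or any(
                    study.ld.chrom_of(c) == study.ld.chrom_of(sid)
                    and abs(study.ld.pos_of(c) - study.ld.pos_of(sid))
                    <= cfg.window_kb * 1000
                    and study.ld.r2(sid, c) >= cfg.proxy_r2
                    for c in passing)
                assert (sid in set(g.members)) == qualifies

    def test_proxy_rows_record_partner(self, setup):
        study, cfg, parent = setup
        grids = conditional_grid(parent, study.adhd, cfg, study.ld)
        any_proxy = pd.concat([g.table for g in grids])
        proxies = any_proxy[any_proxy["overlap_mode"] == "proxy"]
        if len(proxies):
            assert (proxies["proxy_r2"] >= cfg.proxy_r2).all()
        identical = any_proxy[any_proxy["overlap_mode"] == "identical"]
        assert (identical["proxy_id"] == identical["snp"]).all()

    def test_empty_parent_rejected(self, setup):
        study, cfg, _ = setup
        empty = VariantSet("D", 0.0015, ())
        with pytest.raises(ValueError):
            conditional_grid(empty, study.adhd, cfg, study.ld)
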