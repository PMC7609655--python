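"""Synthetic-data generator: determinism, design counts, variance
bookkeeping and the cell-level round trip."""

import math

import numpy as np
import pandas as pd
import pytest

from xyloherit import (
    PopulationConfig,
    VarianceConfig,
    count_locus_mismatches,
    default_trait_panel,
    simulate_cell_data,
    simulate_genotypes,
    simulate_population,
    simulate_trait_panel,
)
from xyloherit.anatomy import cells_to_traits
from xyloherit.synthio import (ConfigError, InfeasibleRingError,
                               _all_clonal_population)


class TestPopulation:
    def test_default_design_counts(self, default_stand):
        assert len(default_stand) == 47
        assert len({t.spatial_group for t in default_stand}) == 11
        clones = {t.clonal_group for t in default_stand if t.clonal_group}
        assert len(clones) == 9
        assert sum(t.clonal_group is None for t in default_stand) == 12

    def test_seeded_determinism(self):
        a = simulate_population(PopulationConfig(seed=5))
        b = simulate_population(PopulationConfig(seed=5))
        assert a == b

    def test_all_clonal_config(self):
        trees = simulate_population(_all_clonal_population(2, 3, seed=0))
        assert len(trees) == 6
        mates = {}
        for t in trees:
            mates.setdefault(t.clonal_group, []).append(t)
        assert all(len(v) == 3 for v in mates.values())

    def test_within_group_distances_respect_clustering_rule(
            self, default_stand):
        by_group = {}
        for t in default_stand:
            by_group.setdefault(t.spatial_group, []).append(t)
        for members in by_group.values():
            for a in members:
                for b in members:
                    assert math.hypot(a.x - b.x, a.y - b.y) <= 3.0

    def test_cdbh_nondecreasing(self, default_stand):
        for t in default_stand:
            vals = [t.cdbh_by_year[y] for y in sorted(t.cdbh_by_year)]
            assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ConfigError):
            simulate_population(PopulationConfig(
                n_spatial_groups=2, n_clone_only_groups=2,
                n_nonclonal_only_groups=2, seed=0))


class TestGenotypes:
    def test_clone_mates_identical_without_errors(self, default_stand):
        gs = simulate_genotypes(default_stand, error_rate=0.0, null_rate=0.0,
                                seed=0)
        by_tree = {g.tree_id: g for g in gs}
        for t in default_stand:
            for u in default_stand:
                if t.clonal_group and t.clonal_group == u.clonal_group:
                    assert count_locus_mismatches(by_tree[t.tree_id],
                                                  by_tree[u.tree_id]) == 0

    def test_full_error_rate_perturbs_every_locus(self, default_stand):
        gs = simulate_genotypes(default_stand, error_rate=1.0, seed=1)
        by_tree = {g.tree_id: g for g in gs}
        mates = [(t, u) for t in default_stand for u in default_stand
                 if t.tree_id < u.tree_id
                 and t.clonal_group and t.clonal_group == u.clonal_group]
        mm = np.mean([count_locus_mismatches(by_tree[a.tree_id],
                                             by_tree[b.tree_id])
                      for a, b in mates])
        assert mm > 10.0  # every locus perturbed; rare coincidences only

    def test_mismatch_rate_matches_binomial_expectation(self):
        """Clone-mate mismatch count ~ 11 * (1 - (1-e)^2) at e = 0.05."""
        e, n_loci = 0.05, 11
        counts = []
        for rep in range(250):
            trees = simulate_population(_all_clonal_population(
                20, 2, seed=rep))
            gs = simulate_genotypes(trees, error_rate=e, seed=5000 + rep)
            by_tree = {g.tree_id: g for g in gs}
            groups = {}
            for t in trees:
                groups.setdefault(t.clonal_group, []).append(t.tree_id)
            for pair in groups.values():
                counts.append(count_locus_mismatches(by_tree[pair[0]],
                                                     by_tree[pair[1]]))
        counts = np.asarray(counts, float)   # 5000 clone pairs
        p = 1 - (1 - e) ** 2
        expected = n_loci * p
        se = math.sqrt(n_loci * p * (1 - p) / len(counts))
        assert abs(counts.mean() - expected) < 3 * se + 0.02

    def test_null_rate_flags_loci(self, default_stand):
        gs = simulate_genotypes(default_stand, null_rate=1.0, seed=2)
        assert all(g.n_null_loci() == 11 for g in gs)

    def test_empty_allele_pool_raises(self, default_stand):
        with pytest.raises(ConfigError):
            simulate_genotypes(default_stand, allele_freqs=[{}] * 11)


class TestTraitPanel:
    def test_degenerate_config_returns_constant(self, default_stand):
        vc = VarianceConfig(mu=5.0, sigma2_R=0.0)
        panel = simulate_trait_panel(default_stand, vc, seed=0, trait="y")
        assert np.allclose(panel["y"], 5.0)

    def test_seeded_determinism(self, default_stand):
        vc = VarianceConfig(sigma2_G=0.3, sigma2_R=0.7)
        a = simulate_trait_panel(default_stand, vc, seed=9, trait="y")
        b = simulate_trait_panel(default_stand, vc, seed=9, trait="y")
        pd.testing.assert_frame_equal(a, b)

    def test_clone_variance_bookkeeping(self):
        """Among-clone variance of clone means ~ sigma2_G at 500 clones."""
        trees = simulate_population(_all_clonal_population(
            500, 2, seed=3, years=(2007, 2007)))
        vc = VarianceConfig(sigma2_G=1.0, sigma2_R=0.0)
        panel = simulate_trait_panel(trees, vc, seed=4, trait="y")
        clone_means = panel.groupby("genetic_group")["y"].mean()
        se = math.sqrt(2 / 499)  # var of sample variance of N(0,1)
        assert abs(clone_means.var(ddof=1) - 1.0) < 3 * se

    def test_ar1_autocorrelation(self):
        """Lag-1 autocorrelation of the residual series ~ rho."""
        trees = simulate_population(_all_clonal_population(
            2, 2, seed=5, years=(2000, 2199)))
        vc = VarianceConfig(sigma2_R=1.0, rho=0.8)
        panel = simulate_trait_panel(trees, vc, seed=6, trait="y")
        acfs = []
        for _, grp in panel.groupby("tree_id"):
            y = grp.sort_values("year")["y"].to_numpy()
            y = y - y.mean()
            acfs.append((y[1:] * y[:-1]).sum() / (y ** 2).sum())
        # AR(1) lag-1 ACF standard error ~ sqrt((1-rho^2)/T)
        se = math.sqrt((1 - 0.8 ** 2) / 200 / len(acfs))
        assert abs(np.mean(acfs) - 0.8) < 3 * se + 0.02

    def test_group_multipliers_scale_residual_sd(self):
        trees = simulate_population(_all_clonal_population(
            2, 2, seed=7, years=(2000, 2499)))
        groups = sorted({t.spatial_group for t in trees})
        vc = VarianceConfig(sigma2_R=1.0,
                            group_var_multipliers={groups[1]: 3.0})
        panel = simulate_trait_panel(trees, vc, seed=8, trait="y")
        sds = panel.groupby("spatial_group")["y"].std()
        assert sds[groups[1]] / sds[groups[0]] == pytest.approx(3.0, rel=0.2)


class TestCellData:
    def test_round_trip_recovers_panel_traits(self, default_stand):
        panel = default_trait_panel(default_stand, seed=11).head(40)
        cells = simulate_cell_data(panel, cells_per_ring=30, seed=12)
        rec = cells_to_traits(cells)
        merged = panel.merge(rec, on=["tree_id", "year"],
                             suffixes=("_want", "_got"))
        assert len(merged) == 40
        for trait, tol in [("EWW", 1e-6), ("LWW", 1e-6),
                           ("CWT.ew", 1e-6), ("CWT.lw", 1e-6),
                           ("DH.ew", 1e-6), ("DH.lw", 1e-6),
                           ("DEN.ew", 0.02), ("DEN.lw", 0.02)]:
            err = (merged[f"{trait}_want"] - merged[f"{trait}_got"]).abs()
            assert err.max() < tol, trait

    def test_explicit_density_target(self):
        """A ring asking for DEN.ew = 0.30 is reproduced within 0.02."""
        panel = pd.DataFrame([{
            "tree_id": "t1", "year": 2010,
            "EWW": 400.0, "LWW": 120.0,
            "CWT.ew": 2.2, "CWT.lw": 3.5,
            "DEN.ew": 0.30, "DEN.lw": 0.75,
            "DH.ew": 30.0, "DH.lw": 9.0,
        }])
        rec = cells_to_traits(simulate_cell_data(panel, seed=1))
        assert abs(rec["DEN.ew"].iloc[0] - 0.30) < 0.02

    def test_noise_free_profile_gives_contiguous_zones(self):
        panel = pd.DataFrame([{
            "tree_id": "t1", "year": 2010, "EWW": 300.0, "LWW": 100.0,
            "CWT.ew": 2.5, "CWT.lw": 3.5, "DEN.ew": 0.33, "DEN.lw": 0.76,
            "DH.ew": 30.0, "DH.lw": 9.0,
        }])
        cells = simulate_cell_data(panel, cells_per_ring=20, seed=0,
                                   noise=0.0)
        d = 2 * np.sqrt(cells["lumen_area_um2"] / math.pi)
        lw = (4 * cells["cwt_um"] / d >= 1.0).to_numpy()
        switch = np.flatnonzero(np.diff(lw.astype(int)))
        assert len(switch) == 1 and lw[-1] and not lw[0]

    def test_minimum_cells_per_ring(self):
        panel = pd.DataFrame([{
            "tree_id": "t1", "year": 2010, "EWW": 300.0, "LWW": 100.0,
            "CWT.ew": 2.5, "CWT.lw": 3.5, "DEN.ew": 0.33, "DEN.lw": 0.76,
            "DH.ew": 30.0, "DH.lw": 9.0,
        }])
        cells = simulate_cell_data(panel, cells_per_ring=4, seed=0)
        d = 2 * np.sqrt(cells["lumen_area_um2"] / math.pi)
        lw = (4 * cells["cwt_um"] / d >= 1.0)
        assert 0 < lw.sum() < len(cells)
        with pytest.raises(ConfigError):
            simulate_cell_data(panel, cells_per_ring=3, seed=0)

    def test_infeasible_density_target_raises(self):
        panel = pd.DataFrame([{
            "tree_id": "t1", "year": 2010, "EWW": 300.0, "LWW": 100.0,
            "CWT.ew": 2.5, "CWT.lw": 3.5, "DEN.ew": 0.95, "DEN.lw": 0.76,
            "DH.ew": 30.0, "DH.lw": 9.0,
        }])
        with pytest.raises(InfeasibleRingError, match="achievable range"):
            simulate_cell_data(panel, seed=0)

    def test_seeded_determinism(self, default_stand):
        panel = default_trait_panel(default_stand, seed=1).head(5)
        a = simulate_cell_data(panel, seed=2)
        b = simulate_cell_data(panel, seed=2)
        pd.testing.assert_frame_equal(a, b)
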