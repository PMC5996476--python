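"""Percentile-criteria region calling and gene annotation."""

import numpy as np
import pandas as pd
import pytest

from pearpop.sweeps import (BalancingCriteria, SweepCriteria, annotate_regions,
                            call_balancing_regions, call_selective_sweeps,
                            merge_windows, quantile_threshold)


class TestQuantileThreshold:
    def test_top_five_percent_of_hundred(self):
        values = np.arange(1, 101, dtype=float)
        cut = quantile_threshold(values, 0.05, "top")
        assert cut == 96
        assert set(values[values >= cut]) == {96, 97, 98, 99, 100}

    def test_bottom_decile_of_ten(self):
        values = np.arange(1, 11, dtype=float)
        cut = quantile_threshold(values, 0.10, "bottom")
        assert set(values[values <= cut]) == {1}

    def test_constant_vector_all_qualify(self):
        values = np.full(20, 3.5)
        cut = quantile_threshold(values, 0.05, "top")
        assert np.all(values >= cut)

    def test_missing_excluded_from_n(self):
        values = np.array([np.nan] * 90 + list(range(1, 11)), dtype=float)
        assert quantile_threshold(values, 0.10, "bottom") == 1

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            quantile_threshold([np.nan, np.nan], 0.05, "top")


def _grid(n, chrom="chr1"):
    return pd.DataFrame({
        "chrom": chrom, "start": np.arange(n) * 10_000, "end": (np.arange(n) + 1) * 10_000,
    })


def _tables(n, fst, rod, tajd, pi=None):
    grid = _grid(n)
    fst_df = grid.assign(fst=fst)
    rod_df = grid.assign(rod=rod)
    div_df = grid.assign(tajima_d=tajd, theta_pi=pi if pi is not None else 1e-3)
    return fst_df, rod_df, div_df


class TestCallSelectiveSweeps:
    def test_empty_when_nothing_passes_all(self):
        fst, rod, div = _tables(100, np.linspace(0, 1, 100), 0.0,
                                np.linspace(-2, 2, 100))
        assert len(call_selective_sweeps(fst, rod, div).regions) == 0

    def test_criteria_are_conjunctive(self):
        """99th-percentile F_ST with high ROD but median D is not called."""
        n = 100
        fst_v = np.linspace(0, 1, n)
        rod_v = np.full(n, 0.1)
        tajd_v = np.linspace(-2, 2, n)
        rod_v[99] = 0.8          # top F_ST window gets a qualifying ROD...
        tajd_v[99] = 0.0         # ...but D sits at the median
        fst, rod, div = _tables(n, fst_v, rod_v, tajd_v)
        assert len(call_selective_sweeps(fst, rod, div).regions) == 0

    def test_qualifying_run_merges(self):
        n = 50
        fst_v = np.zeros(n)
        rod_v = np.zeros(n)
        tajd_v = np.zeros(n)
        fst_v[10:13] = 1.0
        rod_v[10:13] = 0.9
        tajd_v[10:13] = -3.0
        fst, rod, div = _tables(n, fst_v, rod_v, tajd_v)
        result = call_selective_sweeps(fst, rod, div,
                                       SweepCriteria(0.06, 0.5, 0.10))
        assert len(result.regions) == 1
        region = result.regions.iloc[0]
        assert (region["start"], region["end"], region["n_windows"]) == (100_000, 130_000, 3)

    def test_missing_value_disqualifies(self):
        n = 40
        fst_v = np.zeros(n); fst_v[5] = 1.0
        rod_v = np.zeros(n); rod_v[5] = 0.9
        tajd_v = np.zeros(n); tajd_v[5] = np.nan
        fst, rod, div = _tables(n, fst_v, rod_v, tajd_v)
        assert not call_selective_sweeps(fst, rod, div).window_mask[5]

    def test_tightening_quantiles_never_adds_windows(self):
        rng = np.random.default_rng(3)
        n = 200
        fst, rod, div = _tables(n, rng.random(n), rng.random(n), rng.normal(size=n))
        loose = call_selective_sweeps(fst, rod, div, SweepCriteria(0.20, 0.2, 0.30))
        tight = call_selective_sweeps(fst, rod, div, SweepCriteria(0.05, 0.5, 0.10))
        assert np.all(loose.window_mask | ~tight.window_mask)

    def test_grid_mismatch_raises(self):
        fst, rod, div = _tables(10, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            call_selective_sweeps(fst, rod.iloc[:5], div)


class TestCallBalancingRegions:
    def test_neutral_called_fraction_bounded(self):
        """On exchangeable inputs the conjunction calls at most the strictest quantile."""
        rng = np.random.default_rng(11)
        n = 1000
        grid = _grid(n)
        fst = grid.assign(fst=rng.random(n))
        div = grid.assign(tajima_d=rng.normal(size=n), theta_pi=rng.random(n))
        result = call_balancing_regions(fst, div, div, BalancingCriteria())
        assert result.window_mask.sum() <= np.ceil(0.05 * n)

    def test_missing_pi_never_qualifies(self):
        n = 20
        grid = _grid(n)
        fst = grid.assign(fst=0.0)
        div = grid.assign(tajima_d=3.0, theta_pi=np.where(np.arange(n) == 3, np.nan, 1.0))
        result = call_balancing_regions(fst, div, div)
        assert not result.window_mask[3]


class TestMergeWindows:
    def test_merging_is_idempotent(self):
        grid = _grid(30)
        mask = np.zeros(30, dtype=bool)
        mask[[2, 3, 4, 10, 20, 21]] = True
        merged = merge_windows(grid, mask)
        grid2 = merged[["chrom", "start", "end"]]
        mask2 = np.ones(len(grid2), dtype=bool)
        again = merge_windows(grid2, mask2)
        pd.testing.assert_frame_equal(
            again[["chrom", "start", "end"]], grid2.reset_index(drop=True))

    def test_region_lengths_sum_member_windows(self):
        grid = _grid(30)
        mask = np.zeros(30, dtype=bool)
        mask[[4, 5, 6, 9]] = True
        merged = merge_windows(grid, mask)
        assert ((merged["end"] - merged["start"]) == merged["n_windows"] * 10_000).all()

    def test_chromosome_boundary_not_merged(self):
        grid = pd.concat([_grid(2, "chr1"), _grid(2, "chr2")], ignore_index=True)
        merged = merge_windows(grid, np.array([False, True, True, False]))
        assert len(merged) == 2


class TestAnnotateRegions:
    GFF = pd.DataFrame({
        "chrom": "chr1", "type": "gene",
        "start": [1_001, 5_001, 9_001, 20_001],   # 1-based inclusive
        "end": [2_000, 6_000, 10_000, 21_000],
        "feature_id": ["g1", "g2", "g3", "g4"],
    })

    def test_contained_gene_listed(self):
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [3_000]})
        out = annotate_regions(regions, self.GFF)
        assert out["gene_ids"].iloc[0] == ["g1"]

    def test_abutting_gene_excluded(self):
        """A gene starting exactly at the region end (half-open) is not listed."""
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [5_000]})
        out = annotate_regions(regions, self.GFF)
        assert out["gene_ids"].iloc[0] == ["g1"]  # g2 starts at half-open 5000

    def test_exact_sets_against_brute_force(self):
        rng = np.random.default_rng(5)
        genes = pd.DataFrame({
            "chrom": "chr1", "type": "gene",
            "start": rng.integers(1, 90_000, 10),
        })
        genes["end"] = genes["start"] + rng.integers(500, 5_000, 10)
        genes["feature_id"] = [f"g{i}" for i in range(10)]
        regions = pd.DataFrame({
            "chrom": "chr1", "start": [0, 30_000, 60_000],
            "end": [10_000, 45_000, 95_000],
        })
        out = annotate_regions(regions, genes)
        for k, row in regions.iterrows():
            expected = [
                g.feature_id for g in genes.itertuples()
                if g.start - 1 < row["end"] and g.end > row["start"]
            ]
            assert out["gene_ids"].iloc[k] == expected


class TestTruthRecovery:
    def test_sensitivity_nondecreasing_in_intensity(self):
        """Stronger planted sweeps are never recovered less completely."""
        import pearpop as pp
        from pearpop.diversity import SWEEP_WINDOWS, window_diversity, window_fst, window_rod
        from conftest import EXCLUDE_ADMIXED

        sens = []
        for intensity in (0.4, 1.0):
            cfg = pp.default_config(seed=9)
            cfg.sweep_specs = [
                pp.SweepSpec("chr1", 1_000_000, 1_100_000, "Asian_cultivated", intensity),
                pp.SweepSpec("chr1", 3_500_000, 3_600_000, "Asian_cultivated", intensity),
            ]
            m, truth = pp.simulate_cohort(cfg)
            dc = window_diversity(m, "Asian_cultivated", SWEEP_WINDOWS,
                                  exclude_species=EXCLUDE_ADMIXED)
            dw = window_diversity(m, "Asian_wild", SWEEP_WINDOWS,
                                  exclude_species=EXCLUDE_ADMIXED)
            fst = window_fst(m, "Asian_cultivated", "Asian_wild", SWEEP_WINDOWS,
                             exclude_species=EXCLUDE_ADMIXED)
            result = call_selective_sweeps(fst, window_rod(dc, dw), dc)
            grid, mask = result.grid, result.window_mask
            in_truth = np.zeros(len(grid), dtype=bool)
            for _, t in truth.planted_sweeps.iterrows():
                in_truth |= ((grid["chrom"] == t["chrom"]) & (grid["start"] >= t["start"])
                             & (grid["end"] <= t["end"])).to_numpy()
            sens.append((mask & in_truth).sum() / in_truth.sum())
        assert sens[1] >= sens[0]
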