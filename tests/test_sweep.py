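"""Pooled-heterozygosity scan: downsampling, pooling, windowed Hp,
Z standardisation, sweep calling and differential loci."""

import numpy as np
import pandas as pd
import pytest

from sojasweep import (GeneModel, GenomeIndex, InvariantError, LineCounts,
                       Region, SimulationConfig, call_sweeps,
                       differential_loci, downsample_depth, genes_in_regions,
                       hp_windows, pool_counts, simulate_panel, z_transform)
from sojasweep.sweep import (SweepRegion, hp_brute_force, union_gene_count,
                             union_snp_sites)


def lc(name, pos, refc, altc, chrom="chr1"):
    n = len(pos)
    return LineCounts(name, np.array([chrom] * n, dtype=object),
                      np.asarray(pos), np.asarray(refc), np.asarray(altc))


def windows_df(rows, pool="cultivated", step=50_000):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "z"])
    df["n_sites"] = 50
    df["sum_major"] = 100
    df["sum_minor"] = 10
    df["hp"] = 0.1
    df.attrs["pool"] = pool
    df.attrs["step"] = step
    return df


class TestDownsample:
    def test_below_target_is_identity(self):
        counts = lc("A", [0, 10], [2, 1], [1, 2])  # mean depth 3
        out = downsample_depth(counts, 4.0, seed=0)
        assert out is counts

    def test_binomial_expectation(self):
        """Sites at (40,10), mean depth 50, target 5: mean total depth of
        the thinned counts lands within 1% of 5 over 10,000 sites."""
        n = 10_000
        counts = lc("A", np.arange(n), np.full(n, 40), np.full(n, 10))
        out = downsample_depth(counts, 5.0, seed=1)
        assert out.mean_depth == pytest.approx(5.0, rel=0.01)
        # major:minor ratio preserved in expectation
        assert out.ref_count.mean() == pytest.approx(4.0, rel=0.02)
        assert out.alt_count.mean() == pytest.approx(1.0, rel=0.05)

    def test_same_seed_reproduces(self):
        counts = lc("A", np.arange(100), np.full(100, 30), np.full(100, 10))
        a = downsample_depth(counts, 4.0, seed=7)
        b = downsample_depth(counts, 4.0, seed=7)
        assert np.array_equal(a.ref_count, b.ref_count)
        assert np.array_equal(a.alt_count, b.alt_count)

    def test_negative_counts_rejected(self):
        with pytest.raises(InvariantError):
            lc("A", [0], [-1], [2])


class TestPoolCounts:
    def test_hand_sum_and_threshold(self):
        pooled = pool_counts([lc("A", [0], [5], [1]),
                              lc("B", [0], [3], [1])])
        assert pooled.iloc[0][["n_major", "n_minor"]].tolist() == [8, 2]

    @pytest.mark.parametrize("refs,alts,kept", [
        ((5, 3), (1, 0), False),   # pooled depth 9 -> dropped
        ((5, 4), (1, 0), True),    # 10: inclusive lower bound
        ((300, 150), (30, 20), True),    # 500: inclusive upper bound
        ((300, 151), (30, 20), False),   # 501 -> dropped
    ])
    def test_coverage_gate_inclusive(self, refs, alts, kept):
        pooled = pool_counts([lc("A", [0], [refs[0]], [alts[0]]),
                              lc("B", [0], [refs[1]], [alts[1]])])
        assert (len(pooled) == 1) is kept

    def test_minor_majority_swapped(self):
        pooled = pool_counts([lc("A", [0], [4], [6])])
        assert pooled.iloc[0][["n_major", "n_minor"]].tolist() == [6, 4]

    def test_monomorphic_sites_retained(self):
        pooled = pool_counts([lc("A", [0], [12], [0])])
        assert pooled.iloc[0][["n_major", "n_minor"]].tolist() == [12, 0]

    def test_mismatched_site_lists_rejected(self):
        with pytest.raises(InvariantError):
            pool_counts([lc("A", [0], [5], [5]), lc("B", [1], [5], [5])])


class TestHpWindows:
    def small_genome(self):
        return GenomeIndex(("chr1",), {"chr1": 150_000})

    def make_pooled(self, pos, maj, mino):
        df = pd.DataFrame({"chrom": "chr1", "pos": pos,
                           "n_major": maj, "n_minor": mino})
        df.attrs["pool"] = "cultivated"
        return df

    @pytest.mark.parametrize("maj,mino,expected", [
        (200, 200, 0.5),     # balanced counts: the maximum
        (40, 0, 0.0),        # monomorphic window
        (30, 10, 0.375),     # 2*30*10/40^2
    ])
    def test_direct_formula(self, maj, mino, expected):
        pos = np.arange(10) * 100
        pooled = self.make_pooled(pos, [maj // 10] * 10, [mino // 10] * 10)
        win = hp_windows(pooled, self.small_genome(), 100_000, 50_000,
                         min_sites=10)
        assert win.iloc[0]["hp"] == pytest.approx(expected)

    def test_window_below_min_sites_is_nan(self):
        pooled = self.make_pooled([10, 20], [5, 5], [5, 5])
        win = hp_windows(pooled, self.small_genome(), min_sites=10)
        assert np.isnan(win["hp"]).all()
        assert (win["n_sites"] >= 0).all()

    def test_last_window_truncated(self):
        win = hp_windows(self.make_pooled([], [], []), self.small_genome())
        assert win.iloc[-1]["end"] - win.iloc[-1]["start"] == 50_000

    def test_step_larger_than_window_rejected(self):
        with pytest.raises(InvariantError):
            hp_windows(self.make_pooled([], [], []), self.small_genome(),
                       window=100, step=200)

    def test_matches_brute_force_recomputation(self):
        """Vectorised window sums equal an explicit per-site loop exactly."""
        rng = np.random.default_rng(5)
        genome = GenomeIndex(("chr1", "chr2"),
                             {"chr1": 400_000, "chr2": 300_000})
        frames = []
        for chrom in genome.names:
            pos = np.sort(rng.choice(genome.length(chrom), 500,
                                     replace=False))
            frames.append(pd.DataFrame({
                "chrom": chrom, "pos": pos,
                "n_major": rng.integers(5, 50, 500),
                "n_minor": rng.integers(0, 20, 500)}))
        pooled = pd.concat(frames, ignore_index=True)
        win = hp_windows(pooled, genome, min_sites=1)
        for _, row in win.iterrows():
            k, sm, sn, hp = hp_brute_force(pooled, row["chrom"],
                                           row["start"], row["end"])
            assert (row["n_sites"], row["sum_major"],
                    row["sum_minor"]) == (k, sm, sn)
            if k:
                assert row["hp"] == hp  # bitwise: same formula, same ints

    def test_hp_bounds_and_balance_condition(self):
        rng = np.random.default_rng(6)
        genome = self.small_genome()
        pooled = self.make_pooled(np.arange(100) * 1000,
                                  rng.integers(1, 30, 100),
                                  rng.integers(0, 30, 100))
        win = hp_windows(pooled, genome, min_sites=1)
        hp = win["hp"].dropna()
        assert ((hp >= 0) & (hp <= 0.5)).all()
        at_max = win[win["hp"] == 0.5]
        assert (at_max["sum_major"] == at_max["sum_minor"]).all()


class TestZTransform:
    def base_windows(self, hps):
        df = pd.DataFrame({
            "chrom": "chr1",
            "start": np.arange(len(hps)) * 50_000,
            "end": np.arange(len(hps)) * 50_000 + 100_000,
            "n_sites": 50, "sum_major": 1, "sum_minor": 1,
            "hp": hps, "z": np.nan})
        return df

    def test_two_point_example(self):
        win = z_transform(self.base_windows([0.0, 0.5]))
        assert win["z"].tolist() == [-1.0, 1.0]

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(InvariantError, match="degenerate"):
            z_transform(self.base_windows([0.3, 0.3, 0.3]))

    def test_standardisation_identity(self):
        rng = np.random.default_rng(8)
        hps = rng.uniform(0, 0.5, 200)
        hps[rng.choice(200, 20, replace=False)] = np.nan
        z = z_transform(self.base_windows(hps))["z"]
        z = z[~np.isnan(z)]
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=0) - 1) < 1e-12


class TestCallSweeps:
    def test_no_outliers_empty(self):
        win = windows_df([("chr1", 0, 100_000, -1.0)])
        assert call_sweeps(win) == []

    def test_consecutive_windows_merge_with_min_z(self):
        win = windows_df([
            ("chr1", 0, 100_000, -4.2),
            ("chr1", 50_000, 150_000, -5.0),
            ("chr1", 100_000, 200_000, -4.1),
            ("chr1", 300_000, 400_000, -1.0)])
        regions = call_sweeps(win)
        assert len(regions) == 1
        r = regions[0]
        assert (r.chrom, r.start, r.end) == ("chr1", 0, 200_000)
        assert r.z == -5.0 and r.n_windows == 3

    def test_boundary_is_strict(self):
        win = windows_df([("chr1", 0, 100_000, -4.0)])
        assert call_sweeps(win, z_cut=-4.0) == []

    def test_chromosomes_never_merge(self):
        win = windows_df([("chr1", 0, 100_000, -4.5),
                          ("chr2", 0, 100_000, -4.5)])
        assert len(call_sweeps(win)) == 2


class TestDifferentialLoci:
    def cult_region(self):
        return SweepRegion(Region("chr1", 0, 200_000, "sweep"), -4.5,
                           "cultivated", 3)

    def test_retained_when_other_pools_unremarkable(self):
        wild = windows_df([("chr1", 0, 100_000, -1.0)], "wild")
        semi = windows_df([("chr1", 0, 100_000, -1.5)], "semiwild")
        out = differential_loci([self.cult_region()], wild, semi)
        assert len(out) == 1

    def test_excluded_by_wild_signal(self):
        wild = windows_df([("chr1", 50_000, 150_000, -2.5)], "wild")
        semi = windows_df([("chr1", 0, 100_000, -1.0)], "semiwild")
        assert differential_loci([self.cult_region()], wild, semi) == []

    def test_non_overlapping_signal_ignored(self):
        wild = windows_df([("chr1", 400_000, 500_000, -6.0)], "wild")
        semi = windows_df([("chr1", 0, 100_000, -1.0)], "semiwild")
        assert len(differential_loci([self.cult_region()], wild, semi)) == 1

    def test_empty_input(self):
        wild = windows_df([("chr1", 0, 100_000, -1.0)], "wild")
        assert differential_loci([], wild, wild) == []

    def test_mismatched_grids_rejected(self):
        wild = windows_df([("chr1", 0, 100_000, -1.0)], "wild", step=50_000)
        semi = windows_df([("chr1", 0, 100_000, -1.0)], "semiwild",
                          step=25_000)
        with pytest.raises(InvariantError, match="steps"):
            differential_loci([self.cult_region()], wild, semi)


class TestGenesInRegions:
    def test_any_overlap_rule(self):
        genes = [GeneModel("inside", "chr1", 150, 250),
                 GeneModel("one_bp", "chr1", 299, 400),
                 GeneModel("disjoint", "chr1", 300, 400),
                 GeneModel("other_chrom", "chr2", 150, 250)]
        out = genes_in_regions([Region("chr1", 100, 300)], genes)
        assert out[0][1] == ["inside", "one_bp"]

    def test_union_counts_each_gene_once(self):
        genes = [GeneModel("g1", "chr1", 0, 1000)]
        out = genes_in_regions([Region("chr1", 0, 100),
                                Region("chr1", 500, 600)], genes)
        assert union_gene_count(out) == 1


@pytest.fixture(scope="module")
def scan():
    cfg = SimulationConfig(
        n_chromosomes=10, chromosome_length=2_000_000,
        n_wild=8, n_semiwild=6, n_cultivated=8,
        n_sweeps=2, sweep_length=300_000, n_shared_sweeps=1,
        snp_density=0.008, n_specific_segments=0, seed=11)
    panel = simulate_panel(cfg)
    rng = np.random.default_rng(12)
    wins = {}
    for pop in ("wild", "semiwild", "cultivated"):
        lines = [downsample_depth(l, 4.0, rng)
                 for l in panel.line_counts(pop)]
        wins[pop] = z_transform(
            hp_windows(pool_counts(lines, pool=pop), panel.genome))
    return panel, wins


def test_zhp_plot_written(scan, tmp_path):
    from sojasweep.sweep import plot_zhp
    panel, wins = scan
    out = tmp_path / "zhp.png"
    plot_zhp(wins["cultivated"], out, genome=panel.genome)
    assert out.stat().st_size > 0


class TestSweepRecovery:
    """Parameter recovery on a truth-tagged simulation.

    The sweep load is kept below the standardisation bound (a fraction f
    of depressed windows cannot fall below -sqrt((1-f)/f)): two 300 kb
    cultivated sweeps plus one shared sweep on a 20 Mb genome.
    """

    def test_every_injected_sweep_is_called(self, scan):
        panel, wins = scan
        called = call_sweeps(wins["cultivated"], z_cut=-4.0)
        truth = panel.truth.sweeps
        for spec in truth:
            assert any(c.chrom == spec.chrom and c.start < spec.end
                       and spec.start < c.end for c in called), spec
        # false-call load outside truth regions stays small
        extra = [c for c in called
                 if not any(c.chrom == s.chrom and c.start < s.end
                            and s.start < c.end for s in truth)]
        assert len(extra) <= 1

    def test_differential_keeps_only_cultivated_only_sweeps(self, scan):
        panel, wins = scan
        called = call_sweeps(wins["cultivated"], z_cut=-4.0)
        diff = differential_loci(called, wins["wild"], wins["semiwild"],
                                 exclusion_z=-2.0)
        truth_only = panel.truth.cultivated_only_sweeps
        shared = panel.truth.shared_sweeps
        for spec in truth_only:
            assert any(c.chrom == spec.chrom and c.start < spec.end
                       and spec.start < c.end for c in diff), spec
        for spec in shared:
            assert not any(c.chrom == spec.chrom and c.start < spec.end
                           and spec.start < c.end for c in diff), spec

    def test_sweep_windows_monomorphic_in_pool(self, scan):
        """Inside truth sweeps the cultivated pool's minor-allele fraction
        stays below twice the base-call error rate."""
        panel, wins = scan
        pooled = pool_counts([l for l in panel.line_counts("cultivated")],
                             pool="cultivated")
        e = panel.config.error_rate
        for spec in panel.truth.sweeps:
            m = ((pooled["chrom"] == spec.chrom)
                 & (pooled["pos"] >= spec.start)
                 & (pooled["pos"] < spec.end))
            sub = pooled[m]
            frac = sub["n_minor"].sum() / (sub["n_major"].sum()
                                           + sub["n_minor"].sum())
            assert frac < 2 * e
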