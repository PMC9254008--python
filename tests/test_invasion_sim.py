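import numpy as np
import pandas as pd
import pytest

from tetrap import invasion_sim as sim


class TestGenomeLayout:
    def test_standard_layout_totals(self, standard_layout):
        lay = standard_layout
        assert lay.genome_bp == 162_000_000
        assert lay.total_cluster_bp == 4_250_000
        assert lay.cluster_fraction == pytest.approx(0.02623, abs=1e-5)
        assert len(lay.cluster_intervals) == 5
        # one terminal cluster per arm
        for ivs, L in zip(lay.cluster_intervals, lay.arm_lengths):
            assert ivs == ((int(L) - 850_000, int(L)),)

    def test_no_cluster_fraction_zero(self):
        lay = sim.build_genome([1_000_000], 0, 4.0)
        assert lay.cluster_fraction == 0.0
        assert not lay.in_clusters(np.array([0, 999_999])).any()

    def test_fraction_by_construction(self):
        lay = sim.build_genome([1_000_000], 200_000, 4.0)
        assert lay.cluster_fraction == pytest.approx(0.2)

    def test_cluster_longer_than_arm_rejected(self):
        with pytest.raises(sim.InvalidLayoutError):
            sim.build_genome([100_000], 200_000, 4.0)

    def test_overlapping_clusters_rejected(self):
        with pytest.raises(sim.InvalidLayoutError):
            sim.GenomeLayout([1000], [[(0, 500), (400, 800)]], 1.0)

    def test_in_clusters_boundaries(self):
        lay = sim.build_genome([1000, 1000], 100, 1.0)
        # clusters are [900,1000) on each arm; arm 2 spans [1000,2000)
        pos = np.array([899, 900, 999, 1000, 1899, 1900])
        np.testing.assert_array_equal(
            lay.in_clusters(pos), [False, True, True, False, False, True]
        )

    def test_expected_crossovers_per_arm(self, standard_layout):
        # r = 4 cM/Mb over 32.4 Mb -> 1.296 Morgans
        np.testing.assert_allclose(standard_layout.morgans_per_arm, 1.296)


class TestInitializePopulation:
    def test_exact_founder_mean(self, standard_layout, rng):
        params = sim.SimParams(N=230, u=0.1, M=396, generations=1)
        pop = sim.initialize_population(standard_layout, params, rng)
        assert pop.total_insertions == 396
        assert pop.copies_per_haploid == pytest.approx(396 / 460)

    def test_empty_init(self, standard_layout, rng):
        params = sim.SimParams(N=10, u=0.1, M=0, generations=1)
        pop = sim.initialize_population(standard_layout, params, rng)
        assert pop.total_insertions == 0

    def test_every_founder_frequency_one_over_2n(self, small_layout, rng):
        params = sim.SimParams(N=20, u=0.1, M=200, generations=1)
        pop = sim.initialize_population(small_layout, params, rng)
        # each (haplotype, position) pair unique => allele count 1
        key = np.repeat(np.arange(2 * params.N), np.diff(pop.ptr)) * int(
            small_layout.genome_bp
        ) + pop.pos
        assert len(np.unique(key)) == 200
        assert len(np.unique(pop.pos)) == 200  # distinct sites


class TestFitness:
    def _diploid(self, pos0, pos1):
        return sim.Diploid(
            sim.Haplotype(np.asarray(pos0, np.int64)),
            sim.Haplotype(np.asarray(pos1, np.int64)),
        )

    def test_empty_genome(self, small_layout):
        assert sim.fitness(self._diploid([], []), sim.Selection(x=0.01), small_layout) == 1.0

    def test_linear_cost(self, small_layout):
        d = self._diploid([0, 10, 20, 30, 40], [100, 110, 120, 130, 140])
        assert sim.fitness(d, sim.Selection(x=0.01), small_layout) == pytest.approx(0.9)

    def test_floor_at_zero(self, small_layout):
        d = self._diploid(list(range(0, 150)), [])
        assert sim.fitness(d, sim.Selection(x=0.01), small_layout) == 0.0

    def test_cluster_insertions_neutral(self, small_layout):
        # arm 1 cluster is [900000, 1000000)
        d = self._diploid([950_000, 960_000], [10, 20])
        assert sim.fitness(d, sim.Selection(x=0.1), small_layout) == pytest.approx(0.8)

    def test_dfe_effects_summed(self, small_layout):
        d = sim.Diploid(
            sim.Haplotype(np.array([10, 20]), eff=np.array([0.05, 0.02])),
            sim.Haplotype(np.array([30]), eff=np.array([0.1])),
        )
        selm = sim.Selection(dfe_effects=(0.02, 0.05, 0.1))
        assert sim.fitness(d, selm, small_layout) == pytest.approx(1 - 0.17)


class TestMakeGamete:
    def test_no_recombination_returns_one_parent_arm(self, rng):
        lay = sim.build_genome([1_000_000], 0, 0.0)
        d = sim.Diploid(
            sim.Haplotype(np.array([1, 2, 3], np.int64)),
            sim.Haplotype(np.array([10, 20], np.int64)),
        )
        seen = set()
        for _ in range(50):
            g = sim.make_gamete(d, lay, rng)
            seen.add(tuple(g.pos))
        assert seen == {(1, 2, 3), (10, 20)}

    def test_mendelian_transmission(self, rng):
        lay = sim.build_genome([1_000_000], 0, 0.0)
        d = sim.Diploid(
            sim.Haplotype(np.array([500], np.int64)), sim.Haplotype(np.zeros(0, np.int64))
        )
        hits = sum(sim.make_gamete(d, lay, rng).pos.size for _ in range(10_000))
        assert hits / 10_000 == pytest.approx(0.5, abs=0.02)

    def test_recombinant_fraction_matches_haldane(self, rng):
        # two markers 1.296 Morgans apart: recombinant fraction
        # (1 - exp(-2d))/2 = 0.4628
        lay = sim.build_genome([32_400_000], 0, 4.0)
        d = sim.Diploid(
            sim.Haplotype(np.array([0, 32_399_999], np.int64)),
            sim.Haplotype(np.zeros(0, np.int64)),
        )
        rec = 0
        n = 4000
        for _ in range(n):
            g = sim.make_gamete(d, lay, rng)
            if g.pos.size == 1:
                rec += 1
        expected = (1 - np.exp(-2 * 1.296)) / 2
        assert rec / n == pytest.approx(expected, abs=0.03)


class TestTranspose:
    def _zygote(self, pos0, pos1=()):
        return sim.Diploid(
            sim.Haplotype(np.asarray(pos0, np.int64)),
            sim.Haplotype(np.asarray(pos1, np.int64)),
        )

    def test_silenced_zygote_no_new_insertions(self, small_layout, rng):
        params = sim.SimParams(N=10, u=0.9, u_r=0.0, M=0)
        z = self._zygote([950_000, 10, 20, 30])  # 950000 is in a cluster
        out = sim.transpose(z, params, small_layout, rng)
        assert out.hap0.pos.size + out.hap1.pos.size == 4

    def test_zero_rate_unchanged(self, small_layout, rng):
        params = sim.SimParams(N=10, u=0.0, M=0)
        z = self._zygote([10, 20, 30])
        out = sim.transpose(z, params, small_layout, rng)
        np.testing.assert_array_equal(
            np.sort(np.concatenate([out.hap0.pos, out.hap1.pos])), [10, 20, 30]
        )

    def test_expected_new_copies(self, rng):
        lay = sim.build_genome([10_000_000], 0, 0.0)
        params = sim.SimParams(N=10, u=0.1, M=0)
        base = list(range(0, 1000, 100))
        total_new = 0
        n = 5000
        for _ in range(n):
            z = self._zygote(base)
            out = sim.transpose(z, params, lay, rng)
            total_new += out.hap0.pos.size + out.hap1.pos.size - 10
        assert total_new / n == pytest.approx(1.0, abs=0.05)  # Binomial(10, 0.1)


class TestStepGeneration:
    def test_census_size_preserved(self, small_layout, rng):
        params = sim.SimParams(N=30, u=0.1, M=60, generations=5)
        pop = sim.initialize_population(small_layout, params, rng)
        for g in range(5):
            pop = sim.step_generation(pop, params, small_layout, rng, g)
            assert pop.N == 30
            assert pop.ptr.shape == (61,)
            assert pop.ptr[-1] == pop.total_insertions

    def test_positions_stay_in_bounds_and_sorted(self, small_layout, rng):
        params = sim.SimParams(N=30, u=0.2, M=100, generations=20)
        pop = sim.initialize_population(small_layout, params, rng)
        for g in range(20):
            pop = sim.step_generation(pop, params, small_layout, rng, g)
        assert pop.pos.min() >= 0
        assert pop.pos.max() < small_layout.genome_bp
        for h in range(2 * pop.N):
            seg = pop.pos[pop.ptr[h]:pop.ptr[h + 1]]
            assert np.all(np.diff(seg) > 0)  # sorted, no duplicate site

    def test_neutral_mean_copy_number_is_martingale(self):
        lay = sim.build_genome([1_000_000] * 5, 0, 4.0)
        params = sim.SimParams(N=50, u=0.0, M=100, generations=30)
        finals = []
        for s in range(150):
            df = sim.run_invasion(params, lay, rng=np.random.default_rng(s))
            finals.append(df["copies_per_haploid"].iloc[-1])
        assert np.mean(finals) == pytest.approx(1.0, abs=0.08)

    def test_strong_selection_drives_loss(self):
        # no clusters: every insertion is costly, so the TE must vanish
        lay = sim.build_genome([1_000_000, 500_000], 0, 4.0)
        params = sim.SimParams(
            N=50, u=0.0, selection=sim.Selection(x=0.5), M=100, generations=40
        )
        df = sim.run_invasion(params, lay, rng=np.random.default_rng(0))
        assert df["copies_per_haploid"].iloc[-1] < 0.1

    def test_population_collapse_raises(self):
        lay = sim.build_genome([1_000_000], 0, 0.0)
        params = sim.SimParams(
            N=5, u=0.0, selection=sim.Selection(x=1.0), M=500, generations=3
        )
        with pytest.raises(sim.PopulationCollapseError):
            sim.run_invasion(lay and params, lay, rng=np.random.default_rng(1))


class TestRunInvasion:
    def test_no_cluster_growth_matches_closed_form(self):
        """Mean growth factor approaches (1+u) without clusters (x=0)."""
        lay = sim.build_genome([32_400_000] * 5, 0, 4.0)
        params = sim.SimParams(N=1000, u=0.154, M=1000, generations=20)
        finals = [
            sim.run_invasion(params, lay, rng=np.random.default_rng(s))[
                "copies_per_haploid"
            ].iloc[-1]
            for s in range(50)
        ]
        factor = (np.mean(finals) / 0.5) ** (1 / 20)
        assert abs(factor - 1.154) / 1.154 < 0.05

    def test_seeded_runs_are_identical(self, standard_layout):
        params = sim.SimParams(
            N=50, u=0.1, M=100, generations=30, replicates=3, seed=99
        )
        a = sim.run_replicates(params, standard_layout)
        b = sim.run_replicates(params, standard_layout)
        pd.testing.assert_frame_equal(a, b)

    def test_loss_padding_is_all_zero(self):
        lay = sim.build_genome([1_000_000], 0, 1.0)
        params = sim.SimParams(N=20, u=0.0, M=1, generations=60)
        df = sim.run_invasion(params, lay, rng=np.random.default_rng(3))
        if df["lost"].any():
            lost_rows = df.loc[df["lost"]]
            assert (lost_rows["copies_per_haploid"] == 0).all()

    def test_larger_clusters_lower_plateau(self):
        small = sim.standard_layout()
        big = sim.standard_layout(cluster_bp_per_arm=6_480_000)
        params = sim.SimParams(N=230, u=0.154, M=396, generations=150, replicates=3)
        end_small = (
            sim.run_replicates(params, small, seed=4)
            .query("generation > 100")["copies_per_haploid"].mean()
        )
        end_big = (
            sim.run_replicates(params, big, seed=4)
            .query("generation > 100")["copies_per_haploid"].mean()
        )
        assert end_big < end_small

    def test_silencing_lag_slows_silencing(self, standard_layout):
        base = dict(N=100, u=0.2, M=200, generations=60, replicates=2)
        fast = sim.run_replicates(
            sim.SimParams(**base), standard_layout, seed=5
        )
        slow = sim.run_replicates(
            sim.SimParams(**base, silencing_lag=7), standard_layout, seed=5
        )
        end = lambda df: df.query("generation == 60")["copies_per_haploid"].mean()
        assert end(slow) > end(fast)

    def test_residual_activity_keeps_copies_growing(self, standard_layout):
        base = dict(N=100, u=0.2, M=200, generations=120, replicates=2)
        none = sim.run_replicates(sim.SimParams(**base), standard_layout, seed=6)
        some = sim.run_replicates(
            sim.SimParams(**base, u_r=0.05), standard_layout, seed=6
        )
        end = lambda df: df.query("generation == 120")["copies_per_haploid"].mean()
        assert end(some) > end(none)


class TestSelectionModel:
    def test_dfe_validation(self):
        with pytest.raises(ValueError):
            sim.Selection(dfe_effects=(0.01, -0.1))
        with pytest.raises(ValueError):
            sim.Selection(dfe_effects=(0.01,), dfe_probs=(0.5, 0.5))
        selm = sim.Selection(dfe_effects=(0.0, 0.005, 0.01, 0.015, 0.02))
        assert selm.is_dfe
        assert sum(selm.dfe_probs) == pytest.approx(1.0)

    def test_uniform_dfe_mean_matches_constant_x_dynamics(self, standard_layout):
        """A DFE with mean x behaves like constant x at the mean-copy level."""
        dfe = sim.Selection(dfe_effects=(0.0, 0.005, 0.01, 0.015, 0.02))
        const = sim.Selection(x=0.01)
        base = dict(N=100, u=0.12, M=200, generations=60, replicates=4)
        a = sim.run_replicates(
            sim.SimParams(**base, selection=dfe), standard_layout, seed=8
        )
        b = sim.run_replicates(
            sim.SimParams(**base, selection=const), standard_layout, seed=8
        )
        end = lambda df: df.query("generation == 60")["copies_per_haploid"].mean()
        assert end(a) == pytest.approx(end(b), rel=0.5)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            sim.SimParams(N=1, u=0.1)
        with pytest.raises(ValueError):
            sim.SimParams(N=10, u=0.1, u_r=0.2)
        with pytest.raises(ValueError):
            sim.SimParams(N=10, u=0.1, M=-1)
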