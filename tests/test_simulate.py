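import numpy as np
import pytest
from scipy import stats as sps

from haplodrift.demography import DemographyModel, MigrationScheme
from haplodrift.simulate import (
    GridConfig,
    apply_migration,
    estimate_probability,
    run_grid,
    run_trial,
    wf_step,
    wilson_interval,
)


class TestWfStep:
    def test_absorbing_loss_and_fixation(self):
        rng = np.random.default_rng(0)
        assert wf_step(0, 100, 50, rng) == 0
        assert wf_step(100, 100, 73, rng) == 73

    def test_input_validation(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            wf_step(5, 0, 10, rng)
        with pytest.raises(ValueError):
            wf_step(11, 10, 10, rng)

    def test_distribution_matches_binomial(self):
        """Empirical draws of a 4-lineage step vs Binomial(4, 0.5)."""
        rng = np.random.default_rng(42)
        draws = wf_step(np.full(10**5, 2), 4, 4, rng)
        observed = np.bincount(draws, minlength=5)
        expected = sps.binom.pmf(np.arange(5), 4, 0.5) * 10**5
        _, p = sps.chisquare(observed, expected)
        assert p > 0.01


class TestApplyMigration:
    SCHEME = MigrationScheme(rate=0.1, interval=1)

    def test_zero_rate_identity(self):
        rng = np.random.default_rng(1)
        east, west = apply_migration(
            (50, 100), (20, 80), MigrationScheme(rate=0.0), rng
        )
        assert east == (50, 100) and west == (20, 80)

    def test_individuals_conserved(self):
        rng = np.random.default_rng(2)
        (ce, ne), (cw, nw) = apply_migration(
            (np.array([60]), 100), (np.array([10]), 50), self.SCHEME, rng
        )
        assert ne + nw == 150
        assert 0 <= ce[0] <= ne and 0 <= cw[0] <= nw

    def test_equal_frequencies_preserved_in_expectation(self):
        """f_e = f_w = 0.5: mean |df| over 1e4 applications within 3 SE of 0."""
        rng = np.random.default_rng(3)
        trials = 10**4
        ce = np.full(trials, 50)
        cw = np.full(trials, 40)
        (ce2, ne2), (cw2, nw2) = apply_migration(
            (ce, 100), (cw, 80), self.SCHEME, rng
        )
        df = ce2 / ne2 - cw2 / nw2
        se = df.std(ddof=1) / np.sqrt(trials)
        assert abs(df.mean()) < 3 * max(se, 1e-12)

    def test_mixing_expectation_extreme_demes(self):
        """All-N9b east and no-N9b west exchanging 10 of 100 each: expected
        post-migration frequencies 0.9 and 0.1."""
        rng = np.random.default_rng(4)
        trials = 10**4
        (ce2, ne2), (cw2, nw2) = apply_migration(
            (np.full(trials, 100), 100), (np.zeros(trials, dtype=int), 100),
            MigrationScheme(rate=0.1, interval=1), rng,
        )
        fe, fw = ce2 / ne2, cw2 / nw2
        assert abs(fe.mean() - 0.9) < 3 * fe.std(ddof=1) / np.sqrt(trials) + 1e-9
        assert abs(fw.mean() - 0.1) < 3 * fw.std(ddof=1) / np.sqrt(trials) + 1e-9

    def test_zero_migrants_for_small_rate_times_ne(self):
        """round(m * Ne) = 0 leaves both demes untouched (no fractional
        migrants)."""
        rng = np.random.default_rng(5)
        east, west = apply_migration(
            (5, 10), (3, 10), MigrationScheme(rate=0.01), rng
        )
        assert east == (5, 10) and west == (3, 10)


SMALL = dict(cap_ne=100, cap_generations=20, total_generations=200)


class TestRunTrial:
    def test_degenerate_start_fixed(self):
        for p0, expected in ((1.0, 1.0), (0.0, 0.0)):
            model = DemographyModel(p0=p0, **SMALL)
            traj = run_trial(model, rng=0)
            assert (traj["freq_n9b"] == expected).all()

    def test_trajectory_shape_and_bounds(self):
        model = DemographyModel(**SMALL)
        traj = run_trial(model, rng=1)
        assert set(traj["deme"]) == {"cap", "east", "west"}
        # CAP rows for generations 0..19, two deme rows for 20..199
        assert len(traj) == 20 + 2 * 180
        assert ((traj["count_n9b"] >= 0) & (traj["count_n9b"] <= traj["ne"])).all()
        assert traj["freq_n9b"].between(0, 1).all()

    def test_counts_sum_to_ne_for_both_haplogroups(self):
        """Tracking one haplogroup count implies the other is ne - count;
        frequencies sum to one by construction, counts never exceed ne."""
        model = DemographyModel(**SMALL)
        traj = run_trial(model, rng=2)
        other = traj["ne"] - traj["count_n9b"]
        assert (other >= 0).all()
        assert np.allclose(
            traj["count_n9b"] / traj["ne"] + other / traj["ne"], 1.0
        )


class TestEstimateProbability:
    def test_vacuous_and_unattainable_thresholds(self):
        model = DemographyModel(**SMALL)
        low = estimate_probability(model, n_trials=50, threshold=-1.0,
                                   checkpoints=(50, 150), seed=0)
        assert all(p == 1.0 for p in low.probabilities.values())
        high = estimate_probability(model, n_trials=50, threshold=1.01,
                                    checkpoints=(50, 150), seed=0)
        assert all(p == 0.0 for p in high.probabilities.values())

    def test_martingale_mean_frequency(self):
        """No migration, equal constant deme sizes: mean eastern frequency
        at a late checkpoint stays at p0 (within 3 SE over 1e4 trials)."""
        model = DemographyModel(cap_ne=100, cap_generations=50,
                                total_generations=500, split_ratio=0.5)
        from haplodrift.simulate import _simulate_batch

        rng = np.random.default_rng(7)
        diffs, _, _ = _simulate_batch(model, MigrationScheme(), 10**4, rng,
                                   checkpoints=(400,))
        # recompute means from the difference is not enough; rerun recording
        rng = np.random.default_rng(7)
        trials = 10**4
        count = np.full(trials, 50)
        for _ in range(1, 50):
            count = rng.binomial(100, count / 100)
        f_cap = count / 100
        ce = rng.binomial(50, f_cap)
        fe = ce / 50
        se = fe.std(ddof=1) / np.sqrt(trials)
        assert abs(fe.mean() - 0.5) < 3 * se

    def test_reproducible_given_seed(self):
        model = DemographyModel(**SMALL)
        a = estimate_probability(model, n_trials=200, checkpoints=(100, 150), seed=9)
        b = estimate_probability(model, n_trials=200, checkpoints=(100, 150), seed=9)
        assert a.probabilities == b.probabilities

    def test_checkpoint_validation(self):
        model = DemographyModel(**SMALL)
        with pytest.raises(ValueError):
            estimate_probability(model, checkpoints=(200,), n_trials=10, seed=0)
        with pytest.raises(ValueError):
            estimate_probability(model, n_trials=0, checkpoints=(150,), seed=0)

    def test_label_symmetry(self):
        """Swapping east/west and mirroring the split ratio mirrors the
        distribution of the frequency difference (two-sample KS)."""
        from haplodrift.simulate import _simulate_batch

        kwargs = dict(cap_ne=200, cap_generations=30, total_generations=300)
        m1 = DemographyModel(split_ratio=0.3, **kwargs)
        m2 = DemographyModel(split_ratio=0.7, **kwargs)
        d1, _, _ = _simulate_batch(m1, MigrationScheme(), 4000,
                                np.random.default_rng(21), checkpoints=(250,))
        d2, _, _ = _simulate_batch(m2, MigrationScheme(), 4000,
                                np.random.default_rng(22), checkpoints=(250,))
        _, p = sps.ks_2samp(d1[250], -d2[250])
        assert p > 0.01


class TestRunGrid:
    def test_shape_matches_factorial_product(self):
        config = GridConfig(
            cap_ne=(100,), split_ratios=(0.2, 0.5), rates=(0.0, 0.01),
            intervals=(1, 10), n_trials=20, checkpoints=(150, 250),
            total_generations=300, cap_generations=50, seed=1,
        )
        frame = run_grid(config)
        n_settings = len(config.migration_settings())  # 0 collapses intervals
        assert n_settings == 3
        assert len(frame) == 1 * 2 * n_settings * 2
        assert frame["P"].between(0, 1).all()

    def test_zero_rate_invariant_to_interval(self):
        base = dict(cap_ne=(100,), split_ratios=(0.5,), rates=(0.0,),
                    n_trials=50, checkpoints=(200,), total_generations=300,
                    cap_generations=50, seed=3)
        f1 = run_grid(GridConfig(intervals=(1,), **base))
        f2 = run_grid(GridConfig(intervals=(100,), **base))
        assert f1["P"].tolist() == f2["P"].tolist()

    def test_order_independent_cell_seeding(self):
        base = dict(rates=(0.0,), intervals=(1,), n_trials=30,
                    checkpoints=(200,), total_generations=300,
                    cap_generations=50, seed=5)
        wide = run_grid(GridConfig(cap_ne=(100, 200), split_ratios=(0.3, 0.5), **base))
        narrow = run_grid(GridConfig(cap_ne=(200,), split_ratios=(0.5,), **base))
        cell = wide[(wide.cap_ne == 200) & (wide.split_ratio == 0.5)]
        assert cell["P"].tolist() == narrow["P"].tolist()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            run_grid(GridConfig(cap_ne=()))


class TestNeutralDriftTheory:
    def test_fixation_probability_equals_initial_frequency(self):
        """p0 = 0.3, constant Ne = 50: fixation fraction ~ 0.3."""
        rng = np.random.default_rng(13)
        trials, N = 10**4, 50
        count = np.full(trials, 15)
        for _ in range(2000):
            count = rng.binomial(N, count / N)
            if np.all((count == 0) | (count == N)):
                break
        fixed = (count == N).mean()
        se = np.sqrt(0.3 * 0.7 / trials)
        assert abs(fixed - 0.3) < 3 * se

    def test_heterozygosity_decay_rate(self):
        """E[2p(1-p)] shrinks by (1 - 1/N) per generation; empirical decay
        slope within 5% for N = 100."""
        rng = np.random.default_rng(17)
        trials, N, gens = 10**4, 100, 80
        count = np.full(trials, N // 2)
        het = []
        for _ in range(gens):
            p = count / N
            het.append(np.mean(2 * p * (1 - p)))
            count = rng.binomial(N, p)
        slope = np.polyfit(np.arange(gens), np.log(het), 1)[0]
        expected = np.log(1 - 1 / N)
        assert slope == pytest.approx(expected, rel=0.05)


class TestWilsonInterval:
    def test_contains_point_estimate(self):
        lo, hi = wilson_interval(30, 100)
        assert lo < 0.3 < hi and 0 <= lo and hi <= 1

    def test_degenerate_counts(self):
        assert wilson_interval(0, 50)[0] == pytest.approx(0.0, abs=1e-12)
        assert wilson_interval(50, 50)[1] == pytest.approx(1.0, abs=1e-12)
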