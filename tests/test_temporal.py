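"""ISI statistics, Lilliefors exponentiality, edge-corrected peri-seizure
histograms and partial autocorrelation."""

import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors
from statsmodels.tsa.stattools import pacf as sm_pacf

from szdiary.diary import Cohort
from szdiary.simulate import SimulatorConfig, simulate_cohort
from szdiary.temporal import (
    daily_counts,
    exponential_ks_statistic,
    isi,
    isi_set,
    lilliefors_exponential,
    pacf,
    peri_seizure_analysis,
    peri_seizure_histogram,
    uniform_expectation,
)
from conftest import make_diary


class TestIsi:
    def test_successive_differences_in_hours(self):
        d = make_diary([0.0, 3.0 / 24, 7.5 / 24])
        assert np.allclose(isi(d), [3.0, 4.5])

    def test_fewer_than_two_events_raises(self):
        with pytest.raises(ValueError):
            isi(make_diary([1.0]))

    def test_pooled_histogram_weights_animals_equally(self):
        a = make_diary(np.arange(0, 10, 0.125), animal_id="fast")   # 3 h ISIs
        b = make_diary(np.arange(0, 10, 1.0), animal_id="slow")     # 24 h ISIs
        iset = isi_set(Cohort([a, b]), bin_h=1.5, max_h=48.0)
        hist = iset.pooled_hist
        bin_3h = int(3.0 // 1.5)
        bin_24h = int(24.0 // 1.5)
        assert hist[bin_3h] == pytest.approx(0.5)
        assert hist[bin_24h] == pytest.approx(0.5)


class TestLilliefors:
    def test_statistic_matches_statsmodels(self):
        rng = np.random.default_rng(3)
        x = rng.exponential(2.0, 80)
        d_sm, _ = sm_lilliefors(x, dist="exp", pvalmethod="table")
        assert exponential_ks_statistic(x) == pytest.approx(d_sm, abs=1e-12)

    def test_degenerate_point_mass_strongly_rejected(self):
        _, p = lilliefors_exponential(np.full(50, 3.0), 2000, seed=0)
        assert p < 0.001

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            lilliefors_exponential([1.0, 0.0, 2.0, 3.0, 4.0])

    def test_reproducible_for_fixed_seed(self):
        x = np.random.default_rng(0).exponential(1.0, 30)
        assert lilliefors_exponential(x, 1000, seed=5) == \
            lilliefors_exponential(x, 1000, seed=5)

    def test_power_against_clustered_diaries(self):
        """Self-excited diaries (branching 0.5, 3 h kernel) with >= 100
        intervals are detected as non-exponential at alpha = 0.01 in the
        vast majority of replicates."""
        rejects, used = 0, 0
        for s in range(100):
            c = simulate_cohort(SimulatorConfig(
                n_animals=1, seed=50_000 + s, excitation_gain=0.5,
                excitation_timescale_h=3.0, suppression_gain=0.0,
                circadian_amplitude=0.0, weekly_shape=(1.0,) * 4,
                induction_success_p=1.0, log_rate_mean=np.log(4.0),
                log_rate_sd=0.0))
            iv = isi(c.diaries[0])
            if len(iv) < 100:
                continue
            used += 1
            _, p = lilliefors_exponential(iv, 1000, seed=s)
            rejects += p < 0.01
        assert used >= 50
        assert rejects / used >= 0.8


class TestPeriSeizure:
    def test_single_pair_half_day_apart(self):
        d = make_diary([0.0, 0.5], epoch="first_seizure")
        entry = peri_seizure_histogram(d, bin_days=1.0, T_days=30.0)
        assert entry.raw[0] == 1
        assert entry.corrected[0] == pytest.approx(1 / 29.5)

    def test_three_equally_spaced_events(self):
        d = make_diary([0.0, 10.0, 20.0], epoch="first_seizure")
        entry = peri_seizure_histogram(d, bin_days=1.0, T_days=30.0,
                                       max_lag_days=25.0)
        assert entry.raw[10] == 2 and entry.raw[20] == 1
        assert entry.corrected[10] == pytest.approx(2 / (30 - 10.5))
        assert entry.corrected[20] == pytest.approx(1 / (30 - 20.5))

    def test_consecutive_only_mode_drops_long_pairs(self):
        d = make_diary([0.0, 1.2, 2.4], epoch="first_seizure")
        all_pairs = peri_seizure_histogram(d)
        consec = peri_seizure_histogram(d, all_pairs=False)
        assert all_pairs.raw.sum() == 3 and consec.raw.sum() == 2

    def test_uniform_expectation_matches_resampling_oracle(self):
        """Closed-form baseline vs brute-force uniform resampling."""
        rng = np.random.default_rng(7)
        n, T, n_mc = 9, 30.0, 4000
        edges = np.arange(0.0, 8.0)
        centers = edges[:-1] + 0.5
        vals = np.empty((n_mc, len(centers)))
        for i in range(n_mc):
            t = np.sort(rng.uniform(0, T, n))
            lags = (t[None, :] - t[:, None])[np.triu_indices(n, 1)]
            raw, _ = np.histogram(lags, bins=edges)
            vals[i] = raw / (T - centers) / n
        mc_mean = vals.mean(axis=0)
        mc_se = vals.std(axis=0, ddof=1) / np.sqrt(n_mc)
        cf = uniform_expectation(n, 1.0, T, 7.0)
        # 3 s.e. per bin (7 simultaneous bins) plus 2 s.e. on the pooled mean
        assert np.all(np.abs(cf - mc_mean) < 3 * mc_se + 1e-12)
        pooled = vals.mean(axis=1)
        assert abs(cf.mean() - pooled.mean()) < \
            2 * pooled.std(ddof=1) / np.sqrt(n_mc) + 1e-12

    def test_uniform_baseline_is_flat_across_lags(self):
        base = uniform_expectation(12, 1.0, 30.0, 7.0)
        assert np.allclose(base, base[0])

    def test_baseline_vanishes_as_window_grows(self):
        assert uniform_expectation(10, 1.0, 1e9, 7.0).max() < 1e-15

    def test_null_poisson_cohorts_rarely_reject(self):
        """Per-bin t-tests against the uniform baseline stay near their
        nominal level on homogeneous-Poisson cohorts (30 animals)."""
        from szdiary.diary import AnimalDiary, SeizureEvent, DAY_S
        from szdiary.simulate import thinning_sampler
        clean, rej, runs = 0, [], 30
        for s in range(runs):
            rng = np.random.default_rng(40_000 + s)
            diaries = []
            for i in range(30):
                rate = float(np.exp(rng.normal(np.log(3.0), 0.8)))
                times = thinning_sampler(lambda t: rate, 30.0, rate, rng)
                while len(times) < 2:
                    times = thinning_sampler(lambda t: rate, 30.0, rate, rng)
                diaries.append(AnimalDiary(
                    animal_id=f"p{i}", epoch="first_seizure",
                    events=[SeizureEvent(t * DAY_S, 60.0) for t in times],
                    recording_start_s=0.0, recording_end_s=30 * DAY_S,
                    injection_s=None))
            res = peri_seizure_analysis(Cohort(diaries))
            rej.append(res.p_value < 0.01)
            clean += np.all(res.p_value >= 0.01)
        # family-wise: calibrated independent bins give 0.99^7 ~ 0.93
        assert clean / runs >= 0.8
        assert np.mean(rej) <= 0.03


class TestDailyCountsAndPacf:
    def test_daily_counts_examples(self):
        d = make_diary([0.1, 0.5, 0.9], epoch="first_seizure")
        counts = daily_counts(d)
        assert counts[0] == 3 and counts.sum() == 3

    def test_daily_counts_sum_matches_diary(self, small_cohort):
        for d in small_cohort.seizing(min_events=2):
            assert daily_counts(d).sum() <= d.n_events
            assert daily_counts(d).sum() >= 1

    def test_pacf_matches_toeplitz_solve_oracle(self):
        """Durbin-Levinson vs an independent direct solve of the
        Yule-Walker system at each order."""
        def oracle(x, K):
            x = np.asarray(x, float)
            n = len(x)
            xc = x - x.mean()
            g = [np.dot(xc[:n - k], xc[k:]) / n for k in range(K + 1)]
            out = []
            for k in range(1, K + 1):
                R = np.array([[g[abs(i - j)] for j in range(k)]
                              for i in range(k)])
                out.append(np.linalg.solve(R, g[1:k + 1])[-1])
            return np.array(out)

        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.normal(size=rng.integers(25, 60))
            assert np.allclose(pacf(x, 7), oracle(x, 7), atol=1e-6)

    def test_pacf_matches_statsmodels_yule_walker(self):
        x = np.random.default_rng(1).normal(size=400)
        assert np.allclose(pacf(x, 5), sm_pacf(x, nlags=5, method="ywm")[1:],
                           atol=1e-10)

    def test_ar1_pacf_cuts_off_after_lag_one(self):
        rng = np.random.default_rng(8)
        n, phi = 100_000, 0.6
        e = rng.normal(size=n)
        x = np.empty(n)
        x[0] = e[0]
        for i in range(1, n):
            x[i] = phi * x[i - 1] + e[i]
        p = pacf(x, 3)
        assert p[0] == pytest.approx(0.6, abs=0.01)
        assert abs(p[1]) < 0.01 and abs(p[2]) < 0.01

    def test_white_noise_pacf_near_zero(self):
        x = np.random.default_rng(9).normal(size=100_000)
        assert np.all(np.abs(pacf(x, 7)) < 0.01)

    def test_ar2_sign_pattern_recovered(self):
        rng = np.random.default_rng(10)
        n, p1, p2 = 50_000, 0.5, -0.3
        e = rng.normal(size=n)
        x = np.zeros(n)
        for i in range(2, n):
            x[i] = p1 * x[i - 1] + p2 * x[i - 2] + e[i]
        p = pacf(x, 2)
        assert p[0] > 0 and p[1] == pytest.approx(p2, abs=0.02)

    def test_constant_series_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            pacf(np.zeros(50), 7)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            pacf(np.arange(20), 7)
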