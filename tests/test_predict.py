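"""Linear-kernel GP prediction: count splitting, the Bayesian-linear-
regression equivalence, interval probabilities and enrollment."""

import numpy as np
import pytest
from scipy import stats

from szdiary.diary import Cohort
from szdiary.predict import (
    enrollment_report,
    fit_gp_linear,
    interval_probability,
    split_counts,
    threshold_interval,
    training_pairs,
)
from szdiary.simulate import SimulatorConfig, simulate_cohort
from conftest import make_diary


def blr_predictive(x, y, xs, sb2, sv2, sn2):
    """Independent closed-form oracle: Bayesian linear regression with
    Gaussian priors N(0, sb2) on the intercept and N(0, sv2) on the slope."""
    Phi = np.c_[np.ones_like(x), x]
    A = np.diag([1 / sb2, 1 / sv2]) + Phi.T @ Phi / sn2
    Sw = np.linalg.inv(A)
    mw = Sw @ Phi.T @ y / sn2
    Ps = np.c_[np.ones_like(xs), xs]
    return Ps @ mw, np.sqrt(np.sum(Ps @ Sw * Ps, axis=1) + sn2)


class TestSplitCounts:
    def test_uniform_thirty_events(self):
        d = make_diary(np.arange(30) + 1e-6, epoch="first_seizure")
        sc = split_counts(d)
        assert (sc.first_week, sc.remaining) == (7, 23)

    def test_all_events_in_first_week(self):
        d = make_diary([0.0, 1.0, 2.0], epoch="first_seizure")
        sc = split_counts(d)
        assert (sc.first_week, sc.remaining) == (3, 0)

    def test_day_seven_event_counts_as_remaining(self):
        d = make_diary([0.0, 7.0], epoch="first_seizure")
        sc = split_counts(d)
        assert (sc.first_week, sc.remaining) == (1, 1)

    def test_short_window_flagged_but_counted(self):
        d = make_diary([0.0, 5.0, 10.0], epoch="first_seizure",
                       recording_days=20.0)
        with pytest.warns(UserWarning, match="shorter"):
            sc = split_counts(d)
        assert sc.truncated
        assert (sc.first_week, sc.remaining) == (2, 1)


class TestGpEqualsBlr:
    @pytest.mark.parametrize("sb2,sv2,sn2", [
        (1.0, 1.0, 0.1), (5.0, 0.5, 0.01), (0.3, 3.0, 1.0),
    ])
    def test_posterior_matches_closed_form(self, sb2, sv2, sn2):
        rng = np.random.default_rng(0)
        x = rng.normal(2, 1, 8)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.3, 8)
        model = fit_gp_linear(x, y, {"sigma_b2": sb2, "sigma_v2": sv2,
                                     "sigma_n2": sn2})
        xs = np.linspace(0, 5, 9)
        gm, gs = model.predict(xs)
        bm, bs = blr_predictive(x, y, xs, sb2, sv2, sn2)
        assert np.allclose(gm, bm, atol=1e-9)
        assert np.allclose(gs, bs, atol=1e-9)

    def test_collinear_data_interpolated(self):
        x = np.array([0.5, 1.0, 1.5, 2.0, 2.5])
        y = 2 * x + 1
        model = fit_gp_linear(x, y, {"sigma_b2": 10.0, "sigma_v2": 10.0,
                                     "sigma_n2": 1e-8})
        mu, _ = model.predict(np.array([0.75, 1.8, 3.0]))
        assert np.allclose(mu, 2 * np.array([0.75, 1.8, 3.0]) + 1, atol=1e-3)

    def test_loo_closed_form_matches_refit(self):
        rng = np.random.default_rng(5)
        x = rng.normal(2, 1, 9)
        y = 1 + 2 * x + rng.normal(0, 0.4, 9)
        hp = {"sigma_b2": 2.0, "sigma_v2": 1.0, "sigma_n2": 0.2}
        model = fit_gp_linear(x, y, hp)
        lm, ls = model.predict_loo()
        for i in range(len(x)):
            refit = fit_gp_linear(np.delete(x, i), np.delete(y, i), hp)
            bm, bs = refit.predict(x[i])
            assert lm[i] == pytest.approx(bm[0], abs=1e-9)
            assert ls[i] == pytest.approx(bs[0], abs=1e-9)


class TestMarginalLikelihoodFit:
    def test_simulated_cohort_recovers_positive_slope(self, default_cohort50):
        pairs = training_pairs(default_cohort50)
        model = fit_gp_linear(pairs["x"], pairs["y"])
        assert model.pearson_r > 0.5
        xs = np.array([pairs["x"].min(), pairs["x"].max()])
        mu, _ = model.predict(xs)
        slope = (mu[1] - mu[0]) / (xs[1] - xs[0])
        # multiplicative rate heterogeneity implies unit log-log slope
        assert abs(slope - 1.0) < 0.2


@pytest.fixture(scope="module")
def model(default_cohort50):
    pairs = training_pairs(default_cohort50)
    return fit_gp_linear(pairs["x"], pairs["y"])


class TestIntervalProbability:

    def test_total_interval_has_probability_one(self, model):
        assert interval_probability(model, 10, (1e-9, 1e12)) == \
            pytest.approx(1.0, abs=1e-9)

    def test_nested_intervals_are_monotone(self, model):
        for fw in (2, 5, 10, 20, 40):
            p_small = interval_probability(model, fw, (20, 100))
            p_big = interval_probability(model, fw, (20, 200))
            assert p_small <= p_big + 1e-12

    def test_vanishing_sd_concentrates_at_posterior_mean(self, model):
        x = 10.0
        m, _ = model.predict(np.log(x), include_noise=False)
        a, b = np.exp(m[0] - 0.01), np.exp(m[0] + 0.01)
        frozen = fit_gp_linear(model.x, model.y, {
            "sigma_b2": model.sigma_b2, "sigma_v2": model.sigma_v2,
            "sigma_n2": 1e-10})
        assert interval_probability(frozen, x, (a, b)) > 0.99

    def test_invalid_interval_rejected(self, model):
        with pytest.raises(ValueError):
            interval_probability(model, 10, (100, 20))

    def test_translation_consistency_under_refit(self, default_cohort50):
        pairs = training_pairs(default_cohort50)
        m1 = fit_gp_linear(pairs["x"], pairs["y"])
        m2 = fit_gp_linear(pairs["x"] + np.log(2), pairs["y"] + np.log(2))
        for fw in (5, 10, 20, 40):
            p1 = interval_probability(m1, fw, (20, 100))
            p2 = interval_probability(m2, 2 * fw, (40, 200))
            assert p1 == pytest.approx(p2, abs=0.02)


class TestThresholdInterval:
    def test_everywhere_below_threshold_is_empty(self):
        class Stub:
            def predict(self, xs, include_noise=True):
                xs = np.atleast_1d(xs)
                return np.full(xs.shape, 50.0), np.full(xs.shape, 1.0)
        ti = threshold_interval(Stub(), (20, 100),
                                x_grid=np.arange(1, 50))
        assert ti.empty and ti.as_range is None

    def test_constructed_window_12_to_17_returned(self):
        """A synthetic posterior whose predictive lands inside the target
        interval only for first-week counts 12-17."""
        target = (20.0, 100.0)
        centre = np.sqrt(target[0] * target[1])

        class Stub:
            def predict(self, xs, include_noise=True):
                xs = np.atleast_1d(np.asarray(xs, dtype=float))
                counts = np.exp(xs)
                inside = (counts >= 11.5) & (counts <= 17.5)
                mean = np.where(inside, np.log(centre), np.log(1000.0))
                return mean, np.full(xs.shape, 0.9)
        ti = threshold_interval(Stub(), target, x_grid=np.arange(1, 60))
        assert ti.as_range == (12, 17)
        assert ti.contiguous

    def test_widening_target_never_shrinks_window(self, default_cohort50):
        pairs = training_pairs(default_cohort50)
        model = fit_gp_linear(pairs["x"], pairs["y"])
        narrow = threshold_interval(model, (20, 100))
        wide = threshold_interval(model, (20, 200))
        assert set(narrow.members).issubset(set(wide.members))


class TestEnrollment:
    def test_equal_first_week_counts_get_identical_predictions(self):
        d1 = make_diary(np.linspace(0, 25, 12), animal_id="e1",
                        epoch="first_seizure")
        d2 = make_diary(np.linspace(0, 25, 12) + 0.01, animal_id="e2",
                        epoch="first_seizure")
        d3 = make_diary(np.linspace(0, 29, 40), animal_id="e3",
                        epoch="first_seizure")
        pairs = training_pairs(Cohort([d1, d2, d3]))
        model = fit_gp_linear(pairs["x"], pairs["y"],
                              {"sigma_b2": 1, "sigma_v2": 1, "sigma_n2": .1})
        rep = enrollment_report(model, pairs, [(20, 100)])
        r1 = rep[rep.animal_id == "e1"].iloc[0]
        r2 = rep[rep.animal_id == "e2"].iloc[0]
        assert r1.pred_median == pytest.approx(r2.pred_median)

    def test_alternating_assignment_balances_arms(self, default_cohort50):
        pairs = training_pairs(default_cohort50)
        model = fit_gp_linear(pairs["x"], pairs["y"])
        rep = enrollment_report(model, pairs, [(20, 100)])
        top2 = rep.sort_values("pred_median", ascending=False).head(2)
        assert set(top2["arm"]) == {"A", "B"}
        # counts are lognormal across animals, so balance is assessed on
        # the geometric mean (arithmetic means are dominated by the one
        # or two extreme animals whichever arm they land in)
        gmeans = rep.groupby("arm")["pred_median"].apply(
            lambda v: np.exp(np.mean(np.log(v))))
        assert abs(np.log(gmeans["A"] / gmeans["B"])) < np.log(1.1)
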