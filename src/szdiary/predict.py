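"""First-week seizure-count prediction via a linear-kernel Gaussian process.

Across animals the log count of seizures in the first week after seizure
onset predicts the log count over the remaining recording days.  A GP
with kernel ``k(x, x') = sigma_b^2 + sigma_v^2 x x'`` plus observation
noise ``sigma_n^2`` — mathematically identical to Bayesian linear
regression with Gaussian priors on intercept and slope — is fitted in
log-log space; the lognormal posterior predictive then yields, for any
first-week count, the probability that the remaining count falls in a
target interval, and hence enrollment windows in which that probability
exceeds 50%.

Hyperparameters maximise the log marginal likelihood (multi-start grid
plus local refinement) since the study protocol pins none; a
fixed-hyperparameter mode keeps tests reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .diary import DAY_S, AnimalDiary, Cohort, rebase_epoch

logger = logging.getLogger(__name__)

__all__ = [
    "split_counts",
    "SplitCounts",
    "training_pairs",
    "fit_gp_linear",
    "PredictionModel",
    "interval_probability",
    "threshold_interval",
    "ThresholdInterval",
    "enrollment_report",
]


@dataclass(frozen=True)
class SplitCounts:
    animal_id: str
    first_week: int
    remaining: int
    window_days: float
    truncated: bool   # recording shorter than the nominal 30-day window


def split_counts(
    diary: AnimalDiary, first_days: float = 7.0, total_days: float = 30.0
) -> SplitCounts:
    """Counts on [0, 7) and [7, 30) days since the first seizure.

    Both windows are half-open, so an event exactly at day 7.0 belongs to
    the remaining period.  If the recording ends before ``total_days`` the
    counts are still returned with ``truncated=True``.
    """
    d = diary if diary.epoch == "first_seizure" else rebase_epoch(
        diary, "first_seizure")
    t = d.onsets_s / DAY_S
    window = d.recording_end_s / DAY_S
    truncated = window < total_days - 1e-9
    if truncated:
        warnings.warn(
            f"{diary.animal_id}: recording window {window:.1f} d shorter "
            f"than {total_days:g} d; counts reflect the actual split",
            stacklevel=2)
    first = int(np.sum((t >= 0) & (t < first_days)))
    rest = int(np.sum((t >= first_days) & (t < total_days)))
    return SplitCounts(diary.animal_id, first, rest,
                       min(window, total_days), truncated)


def training_pairs(
    cohort: Cohort, first_days: float = 7.0, total_days: float = 30.0
) -> pd.DataFrame:
    """Per-animal (log first-week, log remaining) training pairs.

    Animals with a zero count in either window are excluded with a
    warning (their log is undefined).
    """
    rows = []
    for d in cohort.seizing():
        sc = split_counts(d, first_days, total_days)
        if sc.first_week == 0 or sc.remaining == 0:
            logger.warning(
                "%s excluded from prediction: zero count in a window "
                "(first=%d, remaining=%d)", d.animal_id, sc.first_week,
                sc.remaining)
            continue
        rows.append({
            "animal_id": sc.animal_id,
            "first_week": sc.first_week,
            "remaining": sc.remaining,
            "x": np.log(sc.first_week),
            "y": np.log(sc.remaining),
        })
    return pd.DataFrame(rows)


@dataclass
class PredictionModel:
    x: np.ndarray                 # log first-week counts
    y: np.ndarray                 # log remaining counts
    sigma_b2: float               # bias (intercept prior) variance
    sigma_v2: float               # slope prior variance
    sigma_n2: float               # observation noise variance
    pearson_r: float
    log_marginal_likelihood: float
    animal_ids: list[str] = field(default_factory=list)

    # cached Cholesky pieces
    _chol: np.ndarray | None = None
    _alpha: np.ndarray | None = None

    def _kernel(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return self.sigma_b2 + self.sigma_v2 * np.outer(a, b)

    def _factor(self) -> tuple[np.ndarray, np.ndarray]:
        if self._chol is None:
            K = self._kernel(self.x, self.x)
            K[np.diag_indices_from(K)] += self.sigma_n2 + 1e-12
            self._chol = np.linalg.cholesky(K)
            self._alpha = np.linalg.solve(
                self._chol.T, np.linalg.solve(self._chol, self.y))
        return self._chol, self._alpha

    def predict(
        self, x_star, include_noise: bool = True
    ) -> tuple[np.ndarray, np.ndarray]:
        """Posterior (predictive) mean and s.d. at log first-week counts."""
        xs = np.atleast_1d(np.asarray(x_star, dtype=float))
        L, alpha = self._factor()
        Ks = self._kernel(xs, self.x)
        mean = Ks @ alpha
        v = np.linalg.solve(L, Ks.T)
        var = (self.sigma_b2 + self.sigma_v2 * xs ** 2) - np.sum(v ** 2, axis=0)
        var = np.maximum(var, 0.0)
        if include_noise:
            var = var + self.sigma_n2
        return mean, np.sqrt(var)

    def predict_loo(self) -> tuple[np.ndarray, np.ndarray]:
        """Leave-one-out predictive mean and s.d. at each training point.

        Closed form from the inverse kernel matrix: removing point i and
        predicting y_i gives mean ``y_i - [K^-1 y]_i / [K^-1]_ii`` and
        variance ``1 / [K^-1]_ii`` (noise included).  Used for calibration
        checks of the predictive intervals.
        """
        K = self._kernel(self.x, self.x)
        K[np.diag_indices_from(K)] += self.sigma_n2 + 1e-12
        Ki = np.linalg.inv(K)
        diag = np.diag(Ki)
        mu = self.y - (Ki @ self.y) / diag
        return mu, np.sqrt(1.0 / diag)


def _log_marginal_likelihood(
    x: np.ndarray, y: np.ndarray, theta: np.ndarray
) -> float:
    sb2, sv2, sn2 = np.exp(theta)
    K = sb2 + sv2 * np.outer(x, x)
    K[np.diag_indices_from(K)] += sn2 + 1e-12
    try:
        L = np.linalg.cholesky(K)
    except np.linalg.LinAlgError:
        return -np.inf
    alpha = np.linalg.solve(L.T, np.linalg.solve(L, y))
    return float(-0.5 * y @ alpha - np.sum(np.log(np.diag(L)))
                 - 0.5 * len(y) * np.log(2 * np.pi))


def fit_gp_linear(
    x,
    y,
    hyperparameters: dict[str, float] | None = None,
    animal_ids: list[str] | None = None,
    noise_floor: float = 1e-8,
) -> PredictionModel:
    """Fit the linear-kernel GP to (log first-week, log remaining) pairs.

    With ``hyperparameters`` given (keys ``sigma_b2, sigma_v2, sigma_n2``)
    they are used as-is; otherwise each is optimised by maximising the log
    marginal likelihood from a log-spaced multi-start grid followed by
    Nelder–Mead refinement.  Also records the Pearson correlation of the
    training pairs.  Identical x values are legal — the slope variance
    simply stops being identifiable and the fit degenerates gracefully.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 (x, y) pairs of equal length")
    r = float(np.corrcoef(x, y)[0, 1]) if np.std(x) > 0 and np.std(y) > 0 \
        else np.nan
    if hyperparameters is not None:
        sb2 = float(hyperparameters["sigma_b2"])
        sv2 = float(hyperparameters["sigma_v2"])
        sn2 = max(float(hyperparameters["sigma_n2"]), noise_floor)
        lml = _log_marginal_likelihood(x, y, np.log([sb2, sv2, sn2]))
    else:
        vy = max(float(np.var(y)), 1e-6)
        vx = max(float(np.mean(x ** 2)), 1e-6)
        best, best_lml = None, -np.inf
        for fb in (0.1, 1.0, 10.0):
            for fv in (0.1, 1.0, 10.0):
                for fn in (0.01, 0.1, 1.0):
                    theta0 = np.log([fb * vy, fv * vy / vx, fn * vy])
                    res = optimize.minimize(
                        lambda th: -_log_marginal_likelihood(x, y, th),
                        theta0, method="Nelder-Mead",
                        options={"xatol": 1e-6, "fatol": 1e-9,
                                 "maxiter": 2000})
                    if -res.fun > best_lml:
                        best_lml, best = -res.fun, res.x
        sb2, sv2, sn2 = np.exp(best)
        sn2 = max(sn2, noise_floor)
        lml = best_lml
    return PredictionModel(
        x=x, y=y, sigma_b2=sb2, sigma_v2=sv2, sigma_n2=sn2,
        pearson_r=r, log_marginal_likelihood=lml,
        animal_ids=list(animal_ids) if animal_ids is not None else [],
    )


def interval_probability(
    model: PredictionModel, first_week_count: float,
    interval: tuple[float, float],
) -> float:
    """P(remaining count in [a, b] | first-week count).

    The posterior predictive on the log scale is Gaussian, so the
    probability is ``Phi((ln b - m)/s) - Phi((ln a - m)/s)`` evaluated at
    ``ln(first_week_count)``.
    """
    a, b = interval
    if not (0 < a < b):
        raise ValueError("interval must satisfy 0 < a < b")
    if first_week_count < 1:
        raise ValueError("first-week count must be >= 1")
    m, s = model.predict(np.log(first_week_count))
    m, s = float(m[0]), float(s[0])
    if s == 0:
        return float(np.log(a) <= m <= np.log(b))
    return float(stats.norm.cdf((np.log(b) - m) / s)
                 - stats.norm.cdf((np.log(a) - m) / s))


@dataclass
class ThresholdInterval:
    interval: tuple[float, float]
    p_threshold: float
    grid: np.ndarray
    probabilities: np.ndarray
    members: np.ndarray          # grid values with p > threshold

    @property
    def empty(self) -> bool:
        return self.members.size == 0

    @property
    def contiguous(self) -> bool:
        if self.members.size <= 1:
            return True
        return bool(np.all(np.diff(self.members) == np.diff(self.members)[0]))

    @property
    def as_range(self) -> tuple[int, int] | None:
        if self.empty:
            return None
        return int(self.members.min()), int(self.members.max())


def threshold_interval(
    model: PredictionModel,
    interval: tuple[float, float],
    p_threshold: float = 0.5,
    x_grid: np.ndarray | None = None,
) -> ThresholdInterval:
    """First-week counts for which P(remaining in interval) > threshold.

    Evaluated on an integer grid of first-week counts (counts are
    integers); an empty set is a legal answer and contiguity of the set is
    reported rather than assumed.
    """
    if x_grid is None:
        hi = int(np.ceil(2 * np.exp(model.x.max())))
        x_grid = np.arange(1, max(hi, 2) + 1)
    x_grid = np.asarray(x_grid)
    probs = np.array([
        interval_probability(model, float(xc), interval) for xc in x_grid
    ])
    return ThresholdInterval(
        interval=interval,
        p_threshold=p_threshold,
        grid=x_grid,
        probabilities=probs,
        members=x_grid[probs > p_threshold],
    )


def enrollment_report(
    model: PredictionModel,
    pairs: pd.DataFrame,
    intervals: list[tuple[float, float]],
) -> pd.DataFrame:
    """Per-animal predictions plus a stratified two-arm assignment.

    For each animal: predicted remaining-count median and central 50% and
    95% predictive ranges (lognormal predictive), the interval probability
    and in/out status for every target interval, and an arm assignment
    alternating down the prediction ranking so both arms have similar
    expected seizure burdens.
    """
    m, s = model.predict(pairs["x"].to_numpy())
    z50 = stats.norm.ppf(0.75)
    z95 = stats.norm.ppf(0.975)
    out = pairs[["animal_id", "first_week", "remaining"]].copy()
    out["pred_median"] = np.exp(m)
    out["pred_lo50"] = np.exp(m - z50 * s)
    out["pred_hi50"] = np.exp(m + z50 * s)
    out["pred_lo95"] = np.exp(m - z95 * s)
    out["pred_hi95"] = np.exp(m + z95 * s)
    for a, b in intervals:
        p = np.array([
            interval_probability(model, fw, (a, b))
            for fw in out["first_week"]
        ])
        out[f"p_in_{a:g}_{b:g}"] = p
        out[f"in_{a:g}_{b:g}"] = p > 0.5
    order = np.argsort(-out["pred_median"].to_numpy(), kind="stable")
    arms = np.empty(len(out), dtype=object)
    arms[order] = np.where(np.arange(len(out)) % 2 == 0, "A", "B")
    out["arm"] = arms
    return out
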