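"""Semiology tabulation and seizure-duration distributions.

Seizure types follow a five-class scheme (non-motor focal, unilateral
motor, bilateral motor, generalized tonic-clonic, unknown); labels arrive
pre-assigned from video review.  Duration histograms support per-animal
normalisation so the one or two animals with hundreds of seizures cannot
dominate the pooled distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .diary import SEMIOLOGY_CLASSES, Cohort, SeizureEvent

__all__ = [
    "SemiologyTable",
    "semiology_summary",
    "default_duration_bins",
    "duration_histogram",
    "duration_vs_isi",
]


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SemiologyTable:
    counts: dict[str, int]
    percentages: dict[str, float]
    durations: dict[str, np.ndarray]
    total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class": list(self.counts),
            "count": list(self.counts.values()),
            "pct": [self.percentages[c] for c in self.counts],
            "median_duration_s": [
                float(np.median(self.durations[c])) if len(self.durations[c])
                else np.nan
                for c in self.counts
            ],
        })


def semiology_summary(events) -> SemiologyTable:
    """Tabulate counts, percentages (1 decimal, half-up) and per-class
    durations for a set of labelled events.

    ``events`` may be a :class:`Cohort` or an iterable of
    :class:`SeizureEvent`.  Every event must carry a label; genuinely
    unobservable behaviour should be labelled ``"unknown"``.
    """
    if isinstance(events, Cohort):
        ev = [e for d in events for e in d]
    else:
        ev = list(events)
    if not ev:
        raise ValueError("no events to tabulate")
    for e in ev:
        if e.semiology is None:
            raise ValueError(
                "unlabelled event encountered; label unobservable seizures "
                "as 'unknown' instead of omitting the label"
            )
    counts = {c: 0 for c in SEMIOLOGY_CLASSES}
    durs: dict[str, list[float]] = {c: [] for c in SEMIOLOGY_CLASSES}
    for e in ev:
        counts[e.semiology] += 1
        durs[e.semiology].append(e.duration_s)
    total = len(ev)
    pct = {c: _round_half_up(100.0 * n / total) for c, n in counts.items()}
    return SemiologyTable(
        counts=counts,
        percentages=pct,
        durations={c: np.array(v) for c, v in durs.items()},
        total=total,
    )


def default_duration_bins(max_s: float = 500.0) -> np.ndarray:
    """5-s bins up to 150 s, then 25-s bins (durations beyond the last
    edge are clipped into the final bin)."""
    return np.concatenate([np.arange(0.0, 150.0, 5.0),
                           np.arange(150.0, max_s + 25.0, 25.0)])


def duration_histogram(
    cohort: Cohort,
    bin_edges: np.ndarray | None = None,
    per_animal_normalized: bool = True,
) -> pd.DataFrame:
    """Histogram of seizure durations, pooled or per-animal normalised.

    Unnormalised mode pools all events (raw counts plus a density).  The
    normalised mode weights each event by 1/(its animal's total) before
    pooling and divides by the number of contributing animals, so the
    density integrates to 1 regardless of how unequal the per-animal
    totals are.
    """
    edges = default_duration_bins() if bin_edges is None else np.asarray(
        bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    widths = np.diff(edges)
    seizing = [d for d in cohort if d.n_events > 0]
    if not seizing:
        raise ValueError("no events in cohort")
    counts = np.zeros(len(widths))
    weights = np.zeros(len(widths))
    for d in seizing:
        # clip so out-of-range durations land in the terminal bins and the
        # normalised density keeps unit mass
        durs = np.clip(d.durations_s, edges[0], edges[-1] - 1e-9)
        c, _ = np.histogram(durs, bins=edges)
        counts += c
        weights += c / d.n_events
    if per_animal_normalized:
        density = weights / (len(seizing) * widths)
    else:
        density = counts / (counts.sum() * widths)
    return pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "count": counts.astype(int),
        "density": density,
    })


@dataclass
class DurationIsiResult:
    pairs: pd.DataFrame           # columns: animal_id, isi_h, duration_s
    spearman_rho: float
    p_value: float
    n_permutations: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.spearman_rho)


def duration_vs_isi(
    cohort: Cohort, n_permutations: int = 5000, seed: int = 0
) -> DurationIsiResult:
    """Rank correlation between a seizure's duration and the interval
    since the preceding seizure, with a seeded permutation p-value.

    Each event after the first of a diary contributes one (preceding ISI,
    duration) pair.  With fewer than two pairs the correlation is flagged
    as undefined (NaN) rather than raising.
    """
    rows = []
    for d in cohort:
        if d.n_events < 2:
            continue
        onsets = d.onsets_s
        durs = d.durations_s
        isis_h = np.diff(onsets) / 3600.0
        for i, isi in enumerate(isis_h):
            rows.append((d.animal_id, isi, durs[i + 1]))
    pairs = pd.DataFrame(rows, columns=["animal_id", "isi_h", "duration_s"])
    if len(pairs) < 2:
        return DurationIsiResult(pairs, np.nan, np.nan, 0)
    x = pairs["isi_h"].to_numpy()
    y = pairs["duration_s"].to_numpy()
    # Spearman rho = Pearson correlation of midranks; permuting y and
    # re-ranking equals permuting y's ranks, so rank once and permute
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    rho = float(np.mean(rx * ry))
    rng = np.random.default_rng(seed)
    null = np.array([
        np.mean(rx * rng.permutation(ry)) for _ in range(n_permutations)
    ])
    p = (1 + int(np.sum(np.abs(null) >= abs(rho) - 1e-15))) / (n_permutations + 1)
    return DurationIsiResult(pairs, rho, p, n_permutations)
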