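"""Time-to-structured-diagnosis statistics: means and Kaplan-Meier curve.

The product-limit estimator is implemented directly (events before censorings
at tied times) so the pipeline carries no statistical dependency and can be
checked against an established implementation in the tests.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalInput:
    durations: np.ndarray  # days, int-like, >= 0
    events: np.ndarray  # bool; True = structured dx observed

    def __post_init__(self) -> None:
        d = np.asarray(self.durations, dtype=float)
        if d.size and (not np.all(np.isfinite(d)) or np.any(d < 0)):
            raise ValueError("durations must be finite and >= 0")
        if len(self.durations) != len(self.events):
            raise ValueError("durations and events must have equal length")

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[float, bool]]) -> "SurvivalInput":
        d = np.array([p[0] for p in pairs], dtype=float)
        e = np.array([p[1] for p in pairs], dtype=bool)
        return cls(d, e)


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier survival curve over distinct event times.

    ``survival[i]`` is S(t) for ``times[i] <= t < times[i+1]``; S = 1 before
    the first event time.  ``greenwood_var`` is the Greenwood variance
    estimate of S at each time.
    """

    times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray

    def __post_init__(self) -> None:
        s = self.survival
        assert np.all((s >= 0) & (s <= 1.0 + 1e-12))
        assert np.all(np.diff(s) <= 1e-12), "survival must be non-increasing"


def mean_delay(cohort: SurvivalInput) -> float | None:
    """Mean duration among event subjects only; None when there are none."""
    ev = np.asarray(cohort.events, dtype=bool)
    if not ev.any():
        logger.warning("mean_delay undefined: no event subjects")
        return None
    return float(np.mean(np.asarray(cohort.durations, dtype=float)[ev]))


def mean_censoring_time(cohort: SurvivalInput) -> float | None:
    """Mean duration among censored subjects only; None when there are none."""
    ev = np.asarray(cohort.events, dtype=bool)
    if ev.all():
        logger.warning("mean_censoring_time undefined: no censored subjects")
        return None
    return float(np.mean(np.asarray(cohort.durations, dtype=float)[~ev]))


def km_estimate(cohort: SurvivalInput) -> KMCurve:
    """Product-limit estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    At tied times events precede censorings (standard convention): a subject
    censored at t is still at risk for events at t.  An all-censored cohort
    yields an empty-step curve flat at 1.
    """
    durations = np.asarray(cohort.durations, dtype=float)
    events = np.asarray(cohort.events, dtype=bool)
    if durations.size == 0:
        raise ValueError("cohort is empty")

    event_times = np.unique(durations[events])
    n = durations.size
    times = []
    at_risk = []
    n_events = []
    survival = []
    gw = []
    # exact rational running product: with no censoring it telescopes to
    # (n - cum_events)/n, so S(t) equals the empirical survival bit-for-bit
    s = Fraction(1)
    gw_sum = 0.0
    for t in event_times:
        n_i = int(np.sum(durations >= t))  # censored at t still at risk
        d_i = int(np.sum(durations[events] == t))
        s *= Fraction(n_i - d_i, n_i)
        if n_i > d_i:
            gw_sum += d_i / (n_i * (n_i - d_i))
        else:
            gw_sum = np.inf  # S hits 0; variance term degenerate
        times.append(t)
        at_risk.append(n_i)
        n_events.append(d_i)
        s_f = float(s)
        survival.append(s_f)
        gw.append(s_f * s_f * gw_sum if np.isfinite(gw_sum) else 0.0)
    return KMCurve(
        np.asarray(times, dtype=float),
        np.asarray(at_risk, dtype=int),
        np.asarray(n_events, dtype=int),
        np.asarray(survival, dtype=float),
        np.asarray(gw, dtype=float),
    )


def probability_undiagnosed_at(curve: KMCurve, t: float) -> float:
    """Right-continuous step evaluation of S(t)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    idx = np.searchsorted(curve.times, t, side="right") - 1
    if idx < 0:
        return 1.0
    return float(curve.survival[idx])


def write_km_csv(curve: KMCurve, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["time_days", "at_risk", "events", "survival"])
        for t, n, d, s in zip(curve.times, curve.at_risk, curve.n_events, curve.survival):
            w.writerow([int(t), int(n), int(d), repr(float(s))])
    return path


def plot_km(curves: dict[str, KMCurve], path: str | Path) -> Path:
    """Optional step plot of the probability of remaining undiagnosed."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for label, curve in curves.items():
        xs = np.concatenate([[0.0], curve.times])
        ys = np.concatenate([[1.0], curve.survival])
        ax.step(xs, ys, where="post", label=label)
    ax.set_xlabel("days since computed diagnosis")
    ax.set_ylabel("probability of missing structured diagnosis")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
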