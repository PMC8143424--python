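"""Duration statistics for collective-state runs.

Kaplan–Meier survival of state durations per game phase, pairwise two-group
log-rank tests, and Gaussian-kernel density estimates of play-segment
durations.  State runs cut short by a phase-of-play change, a block boundary
or missing samples enter the analysis as right-censored observations —
treating them as complete events would bias durations downward.

The product-limit estimator and the log-rank statistic are delegated to
lifelines; this module owns the censoring bookkeeping that turns state runs
and phase segments into duration samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .tracking_io import PhaseSegment


@dataclass
class DurationSample:
    duration: float
    censored: bool
    state: str | None = None
    phase: str | None = None

    def __post_init__(self):
        if not self.duration > 0:
            raise ValueError("duration must be positive")


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate: S(0) = 1, non-increasing step function."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    n_samples: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


@dataclass
class LogrankResult:
    chi2: float
    df: int
    p: float
    n_a: int
    n_b: int

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p,
            "n_a": self.n_a,
            "n_b": self.n_b,
        }


# ---------------------------------------------------------------------------
# censoring bookkeeping


def state_duration_samples(runs: list, segments: list[PhaseSegment]) -> list:
    """Split state runs at phase boundaries into per-phase duration samples.

    Each run is intersected with the phase segments that overlap it.  A piece
    that ends before the run does (cut by a phase change) is right-censored at
    the cut; the final piece inherits the run's own censoring status (censored
    when the run was truncated by a block boundary or missing data, an event
    when it ended with an observed state change).
    """
    samples = []
    for run in runs:
        for seg in segments:
            lo = max(run.start, seg.start)
            hi = min(run.end, seg.end)
            if hi - lo <= 1e-12:
                continue
            cut = hi < run.end - 1e-12
            censored = True if cut else run.censored_end
            samples.append(DurationSample(hi - lo, censored, run.state, seg.phase))
    return samples


# ---------------------------------------------------------------------------
# estimators (lifelines-backed)


def km_estimate(samples: list) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimate of the duration survival function."""
    if not samples:
        raise ValueError("no duration samples")
    durations = np.array([s.duration for s in samples])
    observed = np.array([not s.censored for s in samples])
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    table = kmf.event_table
    mask = table["observed"].to_numpy() > 0
    times = table.index.to_numpy()[mask]
    surv = kmf.survival_function_["KM_estimate"].to_numpy()[mask]
    return SurvivalCurve(
        event_times=times,
        survival=surv,
        at_risk=table["at_risk"].to_numpy()[mask],
        events=table["observed"].to_numpy()[mask],
        n_samples=len(samples),
    )


def logrank(a: list, b: list) -> LogrankResult:
    """Two-group log-rank test (hypergeometric variance, df = 1)."""
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if not any(not s.censored for s in a) and not any(not s.censored for s in b):
        raise ValueError("no events in either group")
    res = logrank_test(
        np.array([s.duration for s in a]),
        np.array([s.duration for s in b]),
        event_observed_A=np.array([not s.censored for s in a]),
        event_observed_B=np.array([not s.censored for s in b]),
    )
    return LogrankResult(
        chi2=float(res.test_statistic), df=1, p=float(res.p_value),
        n_a=len(a), n_b=len(b),
    )


def duration_kde(
    durations: np.ndarray,
    bandwidth: float | None = None,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density estimate of durations on a covering grid.

    ``bandwidth`` is the absolute kernel standard deviation in seconds; the
    default is Silverman's rule of thumb.  Degenerate input (zero spread)
    with the automatic bandwidth is rejected.  Returns (grid, density); the
    density integrates to 1 over a grid covering the data ±4 bandwidths.
    """
    x = np.asarray(durations, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two durations")
    if bandwidth is None:
        sd = np.std(x, ddof=1)
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        bandwidth = 0.9 * spread * len(x) ** (-0.2)
        if not bandwidth > 0:
            raise ValueError(
                "degenerate durations: automatic bandwidth is zero, "
                "pass an explicit bandwidth"
            )
    if not bandwidth > 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        grid = np.linspace(x.min() - 4 * bandwidth, x.max() + 4 * bandwidth, 512)
    z = (grid[:, None] - x[None, :]) / bandwidth
    density = np.exp(-0.5 * z**2).sum(axis=1) / (
        len(x) * bandwidth * np.sqrt(2 * np.pi)
    )
    return grid, density
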