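"""Collective-state classification, state runs and transition segments.

States are regions of the (p_group, m_group) plane: high alignment with low
rotation is *polar*, low alignment with low rotation is *swarm*, low alignment
with high rotation is *milling*, and everything else — including any exact tie
with a threshold — is *transitional*.  The thresholds (0.65 / 0.35) follow the
standard fish-school classification scheme.  Classification uses the smoothed
parameter series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .order_params import OrderParameterSeries

STATES = ("polar", "swarm", "milling", "transitional")


@dataclass(frozen=True)
class StateThresholds:
    hi: float = 0.65
    lo: float = 0.35

    def __post_init__(self):
        if not (0.0 < self.lo < self.hi < 1.0):
            raise ValueError("thresholds must satisfy 0 < lo < hi < 1")


DEFAULT_THRESHOLDS = StateThresholds()


def classify(p: float, m: float, th: StateThresholds = DEFAULT_THRESHOLDS):
    """Collective state for one (p_group, m_group) pair; None if either is missing.

    Strict inequalities: (p > hi) & (m < lo) -> polar; (p < lo) & (m < lo) ->
    swarm; (p < lo) & (m > hi) -> milling; anything else (including equality
    with a threshold) -> transitional.
    """
    if p is None or m is None or not (np.isfinite(p) and np.isfinite(m)):
        return None
    if p > th.hi and m < th.lo:
        return "polar"
    if p < th.lo and m < th.lo:
        return "swarm"
    if p < th.lo and m > th.hi:
        return "milling"
    return "transitional"


def classify_series(
    ops: OrderParameterSeries, th: StateThresholds = DEFAULT_THRESHOLDS
) -> np.ndarray:
    """Per-timestep state labels from the smoothed p and m series (None = missing)."""
    return np.array([classify(p, m, th) for p, m in zip(ops.p, ops.m)], dtype=object)


@dataclass
class StateRun:
    """A maximal contiguous run of one collective state.

    ``censored_end`` marks runs that did not end with an observed state change
    (the run was truncated by a block boundary or by missing samples); such
    runs enter duration statistics as right-censored.
    """

    state: str
    start: float
    end: float
    start_idx: int
    end_idx: int  # exclusive
    censored_end: bool = False
    phase_context: list = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.start_idx


def extract_runs(
    labels: np.ndarray,
    timestamps: np.ndarray,
    sample_rate: float,
    blocks: list | None = None,
    phase_labels: np.ndarray | None = None,
) -> list:
    """Maximal constant-state runs; missing samples break runs.

    A run of n samples spans [t_first, t_first + n*dt) so that run durations
    tile each block (minus missing samples).  Runs ending at a block boundary
    or at a missing sample are flagged censored.
    """
    labels = np.asarray(labels, dtype=object)
    timestamps = np.asarray(timestamps, dtype=float)
    dt = 1.0 / sample_rate
    blocks = blocks if blocks is not None else [(0, len(labels))]
    runs = []
    for a, b in blocks:
        i = a
        while i < b:
            if labels[i] is None:
                i += 1
                continue
            j = i
            while j < b and labels[j] == labels[i]:
                j += 1
            censored = j == b or labels[j] is None
            run = StateRun(
                labels[i], timestamps[i], timestamps[i] + (j - i) * dt, i, j, censored
            )
            if phase_labels is not None:
                seen = []
                for ph in phase_labels[i:j]:
                    if not seen or seen[-1] != ph:
                        seen.append(ph)
                run.phase_context = seen
            runs.append(run)
            i = j
    return runs


@dataclass
class TransitionSegment:
    """A slice spanning one state-to-state transition.

    Covers the entirety of the departing run, any intervening transitional
    gap, and the entirety of the arriving run; re-entries (from_state ==
    to_state through a transitional period) are legitimate segments.
    """

    from_state: str
    to_state: str
    start: float
    end: float
    start_idx: int
    end_idx: int  # exclusive
    samples: np.ndarray | None = None  # ordered (p, m) pairs when attached

    @property
    def duration(self) -> float:
        return self.end - self.start


def extract_transitions(
    runs: list,
    kinds: set | None = None,
    include_reentries: bool = True,
) -> list:
    """Transition segments between successive non-transitional runs.

    For each ordered pair of non-transitional runs (X, Y) separated only by
    transitional runs (and by no block gap), a segment spans from the first
    sample of X to the last sample of Y.  ``kinds`` restricts output to given
    (from_state, to_state) pairs; re-entries (X == Y) are kept unless
    disabled.
    """
    segments = []
    runs = list(runs)
    for i, x in enumerate(runs):
        if x.state == "transitional":
            continue
        j = i + 1
        # walk over adjacent transitional runs only
        while (
            j < len(runs)
            and runs[j].state == "transitional"
            and runs[j].start_idx == runs[j - 1].end_idx
        ):
            j += 1
        if j >= len(runs) or runs[j].start_idx != runs[j - 1].end_idx:
            continue
        y = runs[j]
        if y.state == "transitional":
            continue
        if x.state == y.state and not include_reentries:
            continue
        if kinds is not None and (x.state, y.state) not in kinds:
            continue
        segments.append(
            TransitionSegment(x.state, y.state, x.start, y.end, x.start_idx, y.end_idx)
        )
    return segments


def attach_samples(segments: list, ops: OrderParameterSeries) -> list:
    """Fill each segment's ordered (p, m) sample array from the smoothed series."""
    for seg in segments:
        seg.samples = np.column_stack(
            [ops.p[seg.start_idx : seg.end_idx], ops.m[seg.start_idx : seg.end_idx]]
        )
    return segments


def runs_to_frame(runs: list) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "state": [r.state for r in runs],
            "start_s": [r.start for r in runs],
            "end_s": [r.end for r in runs],
            "duration_s": [r.duration for r in runs],
            "censored": [r.censored_end for r in runs],
            "phase": ["|".join(map(str, r.phase_context)) for r in runs],
        }
    )
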