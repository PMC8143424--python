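"""Reading, validation and time-alignment of player tracking and phase annotations.

The canonical tracking dialect is a long-format CSV with header
``time_s,player_id,x_m,y_m`` — one row per (sample, player), metres, origin at
the bottom-left corner of the pitch.  Other column layouts are accepted through
a :class:`DialectConfig` mapping.  Phase-of-play annotations are change events
``time_s,phase`` with phases ``attacking`` / ``defending`` / ``out_of_play``.

Samples where not all tracked players have a position (after short-gap
interpolation) are dropped and split the series into independent contiguous
*blocks*; no downstream statistic ever spans a block boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd

PHASES = ("attacking", "defending", "out_of_play")

_PHASE_ALIASES = {
    "attacking": "attacking",
    "attack": "attacking",
    "defending": "defending",
    "defence": "defending",
    "defense": "defending",
    "out_of_play": "out_of_play",
    "out-of-play": "out_of_play",
    "out of play": "out_of_play",
}


def normalise_phase(label: str) -> str:
    try:
        return _PHASE_ALIASES[str(label).strip().lower()]
    except KeyError:
        raise ValueError(f"unknown phase label: {label!r}") from None


@dataclass
class DialectConfig:
    """Column mapping for tracking CSV files in non-canonical layouts."""

    time: str = "time_s"
    player: str = "player_id"
    x: str = "x_m"
    y: str = "y_m"
    time_unit: float = 1.0  # multiplier to convert the time column to seconds
    position_unit: float = 1.0  # multiplier to convert positions to metres


@dataclass
class TrackingSeries:
    """Time-aligned positions of all tracked players on a fixed-rate grid.

    Attributes
    ----------
    timestamps : (T,) array of seconds, strictly increasing; spacing is
        uniform (1/sample_rate) *within* each block.
    positions : (T, N, 2) array of reported positions in metres.
    observed : (T, N) boolean mask; False marks values imputed by
        short-gap interpolation.
    blocks : list of (start, stop) index pairs delimiting contiguous
        analysis blocks.
    """

    timestamps: np.ndarray
    players: list
    positions: np.ndarray
    sample_rate: float
    observed: np.ndarray = None
    blocks: list = None
    pitch_length: float = 105.0
    pitch_width: float = 68.0
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (T, N, 2)")
        if self.positions.shape[0] != self.timestamps.shape[0]:
            raise ValueError("timestamps and positions disagree in length")
        if self.positions.shape[1] != len(self.players):
            raise ValueError("positions and players disagree in player count")
        if self.observed is None:
            self.observed = np.ones(self.positions.shape[:2], dtype=bool)
        if self.blocks is None:
            self.blocks = [(0, len(self.timestamps))] if len(self.timestamps) else []
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        oob = (
            (self.positions[..., 0] < 0)
            | (self.positions[..., 0] > self.pitch_length)
            | (self.positions[..., 1] < 0)
            | (self.positions[..., 1] > self.pitch_width)
        )
        # violations are flagged, never clamped
        self.flags["n_out_of_bounds"] = int(oob.sum())

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def n_players(self) -> int:
        return len(self.players)

    def __len__(self) -> int:
        return len(self.timestamps)

    def iter_blocks(self) -> Iterator[tuple]:
        """Yield (start, stop) index pairs for each contiguous block."""
        yield from self.blocks

    def centroids(self) -> np.ndarray:
        """Per-timestep arithmetic mean of player positions, shape (T, 2)."""
        return self.positions.mean(axis=1)


@dataclass
class PhaseAnnotation:
    """Step-function phase-of-play labelling given as ordered change events."""

    events: list  # list of (time_s, phase)

    def __post_init__(self):
        if not self.events:
            raise ValueError("annotation must contain at least one event")
        ev = [(float(t), normalise_phase(p)) for t, p in self.events]
        times = np.array([t for t, _ in ev])
        if np.any(np.diff(times) <= 0):
            raise ValueError("event timestamps must be strictly increasing")
        for (_, a), (_, b) in zip(ev, ev[1:]):
            if a == b:
                raise ValueError("consecutive events must change phase")
        self.events = ev

    def phase_at(self, t: float) -> str:
        """Phase of the most recent event at or before t; out_of_play before the first."""
        times = np.array([e[0] for e in self.events])
        i = int(np.searchsorted(times, t, side="right")) - 1
        return "out_of_play" if i < 0 else self.events[i][1]


@dataclass
class PhaseSegment:
    phase: str
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


# ---------------------------------------------------------------------------
# readers / writers


def write_tracking(series: TrackingSeries, path) -> None:
    """Write the canonical long-format tracking CSV (mm precision)."""
    T, N = series.positions.shape[:2]
    rows = {
        "time_s": np.repeat(series.timestamps, N),
        "player_id": np.tile(np.asarray(series.players, dtype=object), T),
        "x_m": series.positions[..., 0].ravel(),
        "y_m": series.positions[..., 1].ravel(),
    }
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.3f")


def read_tracking(
    path,
    dialect: DialectConfig | None = None,
    sample_rate: float = 20.0,
    expected_players: int | None = None,
    max_gap: float = 0.5,
    pitch_length: float = 105.0,
    pitch_width: float = 68.0,
) -> TrackingSeries:
    """Read, validate and grid-align a tracking file.

    Rows are regrouped per timestamp onto the fixed 1/sample_rate grid.
    Per-player gaps of at most ``max_gap`` seconds are linearly interpolated
    (marked unobserved); longer gaps, and samples missing for all players,
    split the series into independent blocks.
    """
    dialect = dialect or DialectConfig()
    df = pd.read_csv(path)
    for col in (dialect.time, dialect.player, dialect.x, dialect.y):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    t = df[dialect.time].to_numpy(dtype=float) * dialect.time_unit
    k = np.rint(t * sample_rate).astype(np.int64)
    if np.any(np.abs(t - k / sample_rate) > 0.25 / sample_rate):
        raise ValueError("timestamps do not lie on the sample-rate grid")
    players = sorted(df[dialect.player].astype(str).unique())
    pidx = {p: i for i, p in enumerate(players)}
    if df.duplicated(subset=[dialect.time, dialect.player]).any():
        raise ValueError("duplicate (timestamp, player) rows")

    k0, k1 = int(k.min()), int(k.max())
    T, N = k1 - k0 + 1, len(players)
    pos = np.full((T, N, 2), np.nan)
    rows_k = k - k0
    rows_p = df[dialect.player].astype(str).map(pidx).to_numpy()
    pos[rows_k, rows_p, 0] = df[dialect.x].to_numpy(dtype=float) * dialect.position_unit
    pos[rows_k, rows_p, 1] = df[dialect.y].to_numpy(dtype=float) * dialect.position_unit
    observed = np.isfinite(pos[..., 0])

    # interpolate short per-player gaps (both ends must be observed)
    max_gap_samples = int(round(max_gap * sample_rate))
    for j in range(N):
        pos[:, j] = _fill_short_gaps(pos[:, j], max_gap_samples)

    keep = np.all(np.isfinite(pos[..., 0]), axis=1)
    if not keep.any():
        raise ValueError("no timestamp has a full complement of players")
    timestamps = (np.arange(k0, k1 + 1)[keep]) / sample_rate
    pos, observed = pos[keep], observed[keep]
    blocks = _contiguous_blocks(np.flatnonzero(keep))

    if expected_players is not None and N != expected_players:
        raise ValueError(f"expected {expected_players} players, found {N}")
    n_imputed = int((~observed).sum())
    series = TrackingSeries(
        timestamps, players, pos, sample_rate, observed, blocks,
        pitch_length, pitch_width,
    )
    series.flags["n_imputed"] = n_imputed
    return series


def _fill_short_gaps(xy: np.ndarray, max_len: int) -> np.ndarray:
    """Linearly interpolate interior NaN runs of length <= max_len in (T, 2)."""
    xy = xy.copy()
    finite = np.isfinite(xy[:, 0])
    if finite.all() or not finite.any():
        return xy
    idx = np.arange(len(xy))
    gap_starts = np.flatnonzero(~finite[1:] & finite[:-1]) + 1
    for s in gap_starts:
        e = s
        while e < len(xy) and not finite[e]:
            e += 1
        if e == len(xy):  # trailing gap: leave missing
            continue
        if e - s <= max_len:
            for d in range(2):
                xy[s:e, d] = np.interp(idx[s:e], [s - 1, e], [xy[s - 1, d], xy[e, d]])
    return xy


def _contiguous_blocks(indices: np.ndarray) -> list:
    """(start, stop) pairs over the *retained* axis for runs of consecutive indices."""
    if len(indices) == 0:
        return []
    breaks = np.flatnonzero(np.diff(indices) > 1) + 1
    bounds = np.concatenate([[0], breaks, [len(indices)]])
    return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def write_annotation(annotation: PhaseAnnotation, path) -> None:
    pd.DataFrame(annotation.events, columns=["time_s", "phase"]).to_csv(
        path, index=False, float_format="%.3f"
    )


def read_annotation(path) -> PhaseAnnotation:
    df = pd.read_csv(path)
    for col in ("time_s", "phase"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    if df.empty:
        raise ValueError("empty annotation")
    return PhaseAnnotation(list(zip(df["time_s"], df["phase"])))


def read_vott_annotation(path) -> PhaseAnnotation:
    """Reduce a VoTT-style JSON export to phase change events.

    Accepts a JSON object whose ``events`` (or top-level list) entries carry a
    time in seconds and a phase tag; only changes of phase are retained.
    """
    import json

    with open(path) as fh:
        doc = json.load(fh)
    raw = doc.get("events", doc) if isinstance(doc, dict) else doc
    events = []
    for item in raw:
        t = float(item.get("time_s", item.get("time")))
        phase = normalise_phase(item.get("phase", item.get("tag")))
        if not events or events[-1][1] != phase:
            events.append((t, phase))
    return PhaseAnnotation(events)


# ---------------------------------------------------------------------------
# alignment and segmentation


def align(annotation: PhaseAnnotation, series: TrackingSeries) -> np.ndarray:
    """Per-timestep phase labels for the series grid.

    Each timestamp takes the phase of the most recent annotation event at or
    before it (an event between grid samples takes effect at the next sample);
    timestamps before the first event are out_of_play.
    """
    ev_times = np.array([t for t, _ in annotation.events])
    if ev_times[0] > series.timestamps[-1] or series.timestamps[0] > ev_times[-1]:
        if ev_times[0] > series.timestamps[-1]:
            raise ValueError("annotation does not overlap the tracking span")
    idx = np.searchsorted(ev_times, series.timestamps, side="right") - 1
    labels = np.empty(len(series.timestamps), dtype=object)
    labels[idx < 0] = "out_of_play"
    valid = idx >= 0
    phases = np.array([p for _, p in annotation.events], dtype=object)
    labels[valid] = phases[idx[valid]]
    return labels


def phase_segments(
    labels: Sequence,
    timestamps: np.ndarray,
    sample_rate: float,
    blocks: Iterable | None = None,
) -> list:
    """Maximal constant-phase runs; segments tile each block without overlap.

    A segment of n samples spans [t_first, t_first + n*dt), so per-block
    durations sum exactly to the block span (n_block * dt).
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) == 0:
        raise ValueError("empty labels")
    timestamps = np.asarray(timestamps, dtype=float)
    dt = 1.0 / sample_rate
    blocks = list(blocks) if blocks is not None else [(0, len(labels))]
    segments = []
    for a, b in blocks:
        i = a
        while i < b:
            j = i
            while j < b and labels[j] == labels[i]:
                j += 1
            segments.append(
                PhaseSegment(labels[i], timestamps[i], timestamps[i] + (j - i) * dt)
            )
            i = j
    return segments


def phase_transition_graph(segments: Sequence[PhaseSegment]) -> nx.DiGraph:
    """Directed phase-transition graph with edge weights as transition proportions.

    Nodes carry cumulative minutes per phase; each directed edge carries the
    raw transition count and its weight (count / total transitions).  Only
    temporally adjacent segments (no block gap between them) contribute a
    transition, so weights always sum to 1 when any transition exists.
    """
    if not segments:
        raise ValueError("no segments")
    g = nx.DiGraph()
    for seg in segments:
        if seg.phase not in g:
            g.add_node(seg.phase, minutes=0.0)
        g.nodes[seg.phase]["minutes"] += seg.duration / 60.0
    counts: dict = {}
    for s0, s1 in zip(segments, segments[1:]):
        if abs(s0.end - s1.start) < 1e-9:  # adjacency: no block gap
            counts[(s0.phase, s1.phase)] = counts.get((s0.phase, s1.phase), 0) + 1
    total = sum(counts.values())
    for (u, v), c in counts.items():
        g.add_edge(u, v, count=c, weight=c / total)
    return g
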