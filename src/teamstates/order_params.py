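"""Group order parameters for collective motion.

Five per-time-step descriptors of a tracked group:

* polarisation ``p_group`` — mean resultant length of the players' unit
  direction-of-motion vectors; 1 = perfectly aligned, 0 = fully scattered;
* angular momentum ``m_group`` — normalised magnitude of the summed 2-D cross
  products of centre-relative unit position vectors with direction-of-motion
  vectors; 1 = coherent rotation about the group centre;
* mean group speed ``v_group`` — backward-difference speed of the group
  centroid (m/s);
* movement entropy ``H_group`` — Shannon entropy (bits) of the binned
  distribution of per-step player velocity vectors pooled over a sliding
  2-second window;
* surface area ``A_group`` — area of the convex hull of the player
  positions (m²).

Directions of motion are derived from reported positions as backward
differences; players whose per-step displacement is below ``EPS_DISPLACEMENT``
have no defined direction and are excluded from the polarisation and angular
momentum sums (the divisor becomes the number of contributing players,
flagged whenever it is below the full complement).

p, m and v are smoothed with a Gaussian-weighted moving average (2-s window)
that never crosses block boundaries; H and A are reported raw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .tracking_io import TrackingSeries

#: displacements below this (metres) leave the direction of motion undefined
EPS_DISPLACEMENT = 1e-6

#: default Gaussian smoothing window (samples at 20 Hz = 2 s)
SMOOTH_WINDOW = 40


@dataclass
class EntropyGridConfig:
    """Square binning grid for movement-entropy velocity vectors.

    The domain is the square ``[-w, w] x [-w, w]`` (m/s) split into square
    bins of side ``bin_side``; defaults give a 32 x 32 grid of 1024 bins, and
    with a 2-s window at 20 Hz each window holds ``window * N`` vectors
    (400 for a 10-player team), capping the entropy at log2(400) ~ 8.64 bits.
    """

    domain_half_width: float = 8.0
    bin_side: float = 0.5
    window: int = 40

    def __post_init__(self):
        n = 2.0 * self.domain_half_width / self.bin_side
        if abs(n - round(n)) > 1e-9:
            raise ValueError("bin_side must divide the domain exactly")
        if self.window < 1:
            raise ValueError("window must be >= 1")

    @property
    def n_bins_per_axis(self) -> int:
        return int(round(2.0 * self.domain_half_width / self.bin_side))

    @property
    def n_bins(self) -> int:
        return self.n_bins_per_axis ** 2


@dataclass
class OrderParameterSeries:
    """Per-time-step group descriptors, raw and smoothed."""

    timestamps: np.ndarray
    p_raw: np.ndarray
    p: np.ndarray
    m_raw: np.ndarray
    m: np.ndarray
    v_raw: np.ndarray
    v: np.ndarray
    H: np.ndarray
    A: np.ndarray
    n_used: np.ndarray = None
    blocks: list = None
    flags: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.timestamps,
                "p_raw": self.p_raw,
                "p": self.p,
                "m_raw": self.m_raw,
                "m": self.m,
                "v_raw": self.v_raw,
                "v": self.v,
                "H": self.H,
                "A": self.A,
                "flags": self._step_flags(),
            }
        )

    def _step_flags(self) -> list:
        """Per-step degeneracy notes: reduced direction count, undefined p/m."""
        if self.n_used is None:
            return [""] * len(self.timestamps)
        n_full = int(self.n_used.max()) if len(self.n_used) else 0
        out = []
        for k in range(len(self.timestamps)):
            notes = []
            if 0 < self.n_used[k] < n_full:
                notes.append("reduced_n")
            if k > 0 and not np.isfinite(self.p_raw[k]):
                notes.append("undefined")
            out.append("|".join(notes))
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# elementary order parameters


def polarisation(directions: np.ndarray) -> float:
    """Mean resultant length of unit direction vectors (0 = scattered, 1 = aligned).

    ``directions`` holds only the players with a defined direction of motion;
    fewer than two leaves the parameter undefined (NaN).
    """
    directions = np.asarray(directions, dtype=float)
    n_used = len(directions)
    if n_used < 2:
        return np.nan
    return float(np.linalg.norm(directions.sum(axis=0)) / n_used)


def angular_momentum(positions: np.ndarray, directions: np.ndarray) -> float:
    """Normalised net rotation of the group about its centre.

    Scalar 2-D cross products ``r_hat x v = r_x v_y - r_y v_x`` of unit
    centre-relative position vectors with unit direction vectors, summed and
    normalised by the number of contributing players.  Players sitting exactly
    at the centroid have no defined bearing and are excluded.
    """
    positions = np.asarray(positions, dtype=float)
    directions = np.asarray(directions, dtype=float)
    if len(positions) < 2:
        return np.nan
    centroid = positions.mean(axis=0)
    r = positions - centroid
    dist = np.linalg.norm(r, axis=1)
    ok = dist > EPS_DISPLACEMENT
    if ok.sum() < 2:
        return np.nan
    r_hat = r[ok] / dist[ok, None]
    v = directions[ok]
    cross = r_hat[:, 0] * v[:, 1] - r_hat[:, 1] * v[:, 0]
    return float(abs(cross.sum()) / ok.sum())


def group_speed(centroids: np.ndarray, dt: float) -> np.ndarray:
    """Backward-difference speed of the centroid; the first sample is undefined."""
    centroids = np.asarray(centroids, dtype=float)
    if len(centroids) < 2:
        raise ValueError("need at least two centroid samples")
    if dt <= 0:
        raise ValueError("dt must be positive")
    speed = np.full(len(centroids), np.nan)
    speed[1:] = np.linalg.norm(np.diff(centroids, axis=0), axis=1) / dt
    return speed


def gaussian_kernel(window: int = SMOOTH_WINDOW, sigma: float | None = None) -> np.ndarray:
    """Symmetric Gaussian weights over offsets -window//2 .. window//2, summing to 1."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if sigma is None:
        sigma = window / 5.0
    half = window // 2
    x = np.arange(-half, half + 1, dtype=float)
    w = np.exp(-0.5 * (x / sigma) ** 2)
    return w / w.sum()


def smooth(
    series: np.ndarray,
    window: int = SMOOTH_WINDOW,
    sigma: float | None = None,
    blocks: list | None = None,
) -> np.ndarray:
    """Gaussian-weighted moving average, truncated and renormalised at edges.

    NaN samples receive no weight (and stay NaN only if the whole window is
    NaN); the filter is applied independently per block and never crosses
    block boundaries.
    """
    x = np.asarray(series, dtype=float)
    w = gaussian_kernel(window, sigma)
    out = np.full_like(x, np.nan)
    blocks = blocks if blocks is not None else [(0, len(x))]
    for a, b in blocks:
        seg = x[a:b]
        finite = np.isfinite(seg)
        filled = np.where(finite, seg, 0.0)
        num = np.convolve(filled, w, mode="same")
        den = np.convolve(finite.astype(float), w, mode="same")
        with np.errstate(invalid="ignore"):
            out[a:b] = np.where(den > 0, num / den, np.nan)
    return out


# ---------------------------------------------------------------------------
# movement entropy


def _bin_indices(vectors: np.ndarray, cfg: EntropyGridConfig) -> np.ndarray:
    """Flat grid-bin index per vector; -1 for vectors outside the domain.

    Bins are half-open [edge, edge + bin_side) except the topmost/rightmost
    edge, which is closed so that exactly +w is binnable.
    """
    w, side, nb = cfg.domain_half_width, cfg.bin_side, cfg.n_bins_per_axis
    ij = np.floor((vectors + w) / side).astype(np.int64)
    on_top = np.isclose(vectors, w)
    ij[on_top] = nb - 1
    inside = np.all((ij >= 0) & (ij < nb), axis=1)
    flat = np.where(inside, ij[:, 0] * nb + ij[:, 1], -1)
    return flat


def window_entropy(vectors: np.ndarray, cfg: EntropyGridConfig | None = None) -> float:
    """Shannon entropy (bits) of one window of movement vectors.

    Vectors are tails-at-origin velocity vectors (m/s); those outside the grid
    domain are discarded before normalisation.  With all vectors out of domain
    the entropy is undefined (NaN).
    """
    cfg = cfg or EntropyGridConfig()
    vectors = np.asarray(vectors, dtype=float)
    flat = _bin_indices(vectors, cfg)
    flat = flat[flat >= 0]
    if len(flat) == 0:
        return np.nan
    counts = np.bincount(flat, minlength=cfg.n_bins)
    p = counts[counts > 0] / len(flat)
    return float(-(p * np.log2(p)).sum())


def movement_entropy_series(
    series: TrackingSeries, cfg: EntropyGridConfig | None = None
) -> np.ndarray:
    """Windowed movement entropy H_group(t) for every timestamp of the series.

    Per-step velocity vectors (backward displacement / dt, m/s) from all
    players are pooled over a window of ``cfg.window`` steps centred on t and
    binned on the fixed grid.  Timestamps whose window is truncated by a block
    boundary are undefined (NaN).
    """
    cfg = cfg or EntropyGridConfig()
    H = np.full(len(series), np.nan)
    half_lo = cfg.window // 2 - 1  # velocities ending at t-half_lo .. t+half_hi
    half_hi = cfg.window - half_lo - 1
    for a, b in series.iter_blocks():
        vel = np.diff(series.positions[a:b], axis=0) / series.dt  # (n-1, N, 2)
        if len(vel) < cfg.window:
            continue
        flat = np.stack(
            [_bin_indices(vel[:, j], cfg) for j in range(series.n_players)], axis=1
        )  # (n-1, N)
        for t in range(half_lo + 1, (b - a) - half_hi):
            # velocity k (0-based) ends at local sample k+1
            win = flat[t - 1 - half_lo : t + half_hi].ravel()
            win = win[win >= 0]
            if len(win) == 0:
                continue
            counts = np.bincount(win)
            p = counts[counts > 0] / len(win)
            H[a + t] = -(p * np.log2(p)).sum()
    return H


# ---------------------------------------------------------------------------
# surface area


def surface_area(positions: np.ndarray) -> tuple[float, bool]:
    """Convex-hull area of the player positions; (area, degenerate_flag).

    Collinear or coincident configurations have a degenerate hull: the area
    is 0 and the flag is set.
    """
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 3:
        raise ValueError("need at least three players for a surface area")
    try:
        hull = ConvexHull(positions)
    except QhullError:
        return 0.0, True
    return float(hull.volume), False  # .volume is the area in 2-D


# ---------------------------------------------------------------------------
# full pipeline


def compute_order_parameters(
    series: TrackingSeries,
    entropy_cfg: EntropyGridConfig | None = None,
    smooth_window: int = SMOOTH_WINDOW,
    smooth_sigma: float | None = None,
) -> OrderParameterSeries:
    """All five order parameters for a tracking series, raw plus smoothed p, m, v."""
    entropy_cfg = entropy_cfg or EntropyGridConfig()
    T, N = series.positions.shape[:2]
    p_raw = np.full(T, np.nan)
    m_raw = np.full(T, np.nan)
    v_raw = np.full(T, np.nan)
    A = np.full(T, np.nan)
    n_used = np.zeros(T, dtype=int)
    n_degenerate = 0

    for a, b in series.iter_blocks():
        pos = series.positions[a:b]
        disp = np.diff(pos, axis=0)  # (n-1, N, 2)
        norms = np.linalg.norm(disp, axis=2)
        for t in range(1, b - a):
            moving = norms[t - 1] > EPS_DISPLACEMENT
            dirs = disp[t - 1][moving] / norms[t - 1][moving, None]
            n_used[a + t] = moving.sum()
            p_raw[a + t] = polarisation(dirs)
            m_raw[a + t] = angular_momentum(pos[t][moving], dirs)
        v_raw[a:b] = group_speed(pos.mean(axis=1), series.dt) if b - a >= 2 else np.nan
        for t in range(b - a):
            A[a + t], deg = surface_area(pos[t])
            n_degenerate += deg

    H = movement_entropy_series(series, entropy_cfg)
    p = smooth(p_raw, smooth_window, smooth_sigma, series.blocks)
    m = smooth(m_raw, smooth_window, smooth_sigma, series.blocks)
    v = smooth(v_raw, smooth_window, smooth_sigma, series.blocks)

    ops = OrderParameterSeries(
        series.timestamps, p_raw, p, m_raw, m, v_raw, v, H, A,
        n_used=n_used, blocks=list(series.blocks),
    )
    ops.flags["n_degenerate_hulls"] = n_degenerate
    ops.flags["n_reduced_direction_count"] = int(((n_used > 0) & (n_used < N)).sum())
    return ops
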