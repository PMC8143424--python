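"""Order-parameter unit and oracle tests: polarisation, angular momentum,
group speed, Gaussian smoothing, movement entropy, convex-hull surface area."""

import numpy as np
import pytest

from teamstates import (
    EntropyGridConfig,
    TrackingSeries,
    angular_momentum,
    compute_order_parameters,
    group_speed,
    movement_entropy_series,
    polarisation,
    smooth,
    surface_area,
    window_entropy,
)
from teamstates.order_params import gaussian_kernel

from conftest import unique_bin_window


# ---------------------------------------------------------------------------
# polarisation


@pytest.mark.parametrize(
    "directions, expected",
    [
        (np.tile([1.0, 0.0], (10, 1)), 1.0),  # perfect alignment
        ([[1, 0], [0, 1], [-1, 0], [0, -1]], 0.0),  # compass directions cancel
        ([[1, 0], [0, 1]], np.sqrt(2) / 2),  # |(1,1)| / 2
    ],
)
def test_polarisation_values(directions, expected):
    assert polarisation(np.asarray(directions, float)) == pytest.approx(expected)


def test_polarisation_undefined_below_two_directions():
    assert np.isnan(polarisation(np.array([[1.0, 0.0]])))


# ---------------------------------------------------------------------------
# angular momentum


def _ring():
    return np.array([[1.0, 0], [0, 1.0], [-1.0, 0], [0, -1.0]])


def _tangents_ccw():
    return np.array([[0, 1.0], [-1.0, 0], [0, -1.0], [1.0, 0]])


@pytest.mark.parametrize(
    "directions, expected",
    [
        (_tangents_ccw(), 1.0),  # coherent anticlockwise rotation
        (_ring(), 0.0),  # purely radial motion
        (np.array([[0, 1.0], [-1.0, 0], [0, 1.0], [-1.0, 0]]), 0.0),  # 2 CCW vs 2 CW
    ],
)
def test_angular_momentum_ring(directions, expected):
    assert angular_momentum(_ring(), directions) == pytest.approx(expected)


def test_angular_momentum_excludes_player_at_centroid():
    # five players: four on the ring plus one exactly at the centre; the
    # central player has no bearing and must not dilute the normalisation
    pos = np.vstack([_ring(), [0.0, 0.0]])
    dirs = np.vstack([_tangents_ccw(), [1.0, 0.0]])
    assert angular_momentum(pos, dirs) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# group speed


def test_group_speed_stationary_and_constant():
    c = np.tile([3.0, 4.0], (50, 1))
    v = group_speed(c, 0.05)
    assert np.isnan(v[0])
    assert np.allclose(v[1:], 0.0)
    c = np.cumsum(np.tile([0.2, 0.0], (50, 1)), axis=0)
    assert np.allclose(group_speed(c, 0.05)[1:], 4.0)


def test_group_speed_rejects_bad_input():
    with pytest.raises(ValueError):
        group_speed(np.array([[0.0, 0.0]]), 0.05)
    with pytest.raises(ValueError):
        group_speed(np.zeros((5, 2)), 0.0)


# ---------------------------------------------------------------------------
# smoothing


def test_smooth_preserves_constants_and_unit_mass():
    x = np.full(200, 0.7)
    assert np.allclose(smooth(x), 0.7)
    impulse = np.zeros(201)
    impulse[100] = 1.0
    assert smooth(impulse).sum() == pytest.approx(1.0)


def test_smooth_variance_reduction_matches_effective_weights():
    # white noise: var(smoothed) / var(raw) ~= sum(w^2) away from the edges
    rng = np.random.default_rng(42)
    x = rng.normal(size=100_000)
    w = gaussian_kernel(40)
    y = smooth(x)
    ratio = y[100:-100].var() / x.var()
    assert ratio == pytest.approx(np.sum(w**2), rel=0.05)


def test_smooth_never_crosses_block_boundaries():
    x = np.concatenate([np.zeros(100), np.ones(100)])
    y = smooth(x, blocks=[(0, 100), (100, 200)])
    assert np.allclose(y[:100], 0.0)
    assert np.allclose(y[100:], 1.0)


def test_smooth_skips_nan_and_renormalises():
    x = np.full(100, 2.0)
    x[50] = np.nan
    y = smooth(x)
    assert np.allclose(y, 2.0, atol=1e-12)


# ---------------------------------------------------------------------------
# movement entropy


def test_entropy_grid_defaults(entropy_cfg):
    assert entropy_cfg.n_bins_per_axis == 32
    assert entropy_cfg.n_bins == 1024
    assert entropy_cfg.window == 40


def test_entropy_single_bin_is_zero(entropy_cfg):
    vecs = np.tile([1.2, -0.7], (400, 1))
    assert window_entropy(vecs, entropy_cfg) == pytest.approx(0.0)


def test_entropy_all_distinct_bins_hits_ceiling(entropy_cfg):
    vecs = unique_bin_window(entropy_cfg)
    assert window_entropy(vecs, entropy_cfg) == pytest.approx(np.log2(400))


def test_entropy_two_equal_masses_is_one_bit(entropy_cfg):
    vecs = np.vstack([np.tile([0.2, 0.2], (200, 1)), np.tile([5.2, -3.3], (200, 1))])
    assert window_entropy(vecs, entropy_cfg) == pytest.approx(1.0)


def test_entropy_discards_out_of_domain(entropy_cfg):
    vecs = np.vstack([np.tile([0.2, 0.2], (100, 1)), np.tile([25.0, 0.0], (100, 1))])
    assert window_entropy(vecs, entropy_cfg) == pytest.approx(0.0)
    assert np.isnan(window_entropy(np.tile([25.0, 0.0], (10, 1)), entropy_cfg))


def _naive_entropy(vectors, cfg):
    """Independent two-pass histogram implementation of the window entropy."""
    edges = np.arange(-cfg.domain_half_width, cfg.domain_half_width + cfg.bin_side / 2,
                      cfg.bin_side)
    counts, _, _ = np.histogram2d(vectors[:, 0], vectors[:, 1], bins=[edges, edges])
    total = counts.sum()
    if total == 0:
        return np.nan
    h = 0.0
    for row in counts:
        for c in row:
            if c > 0:
                p = c / total
                h -= p * np.log2(p)
    return h


def test_entropy_equals_naive_histogram_oracle(entropy_cfg):
    rng = np.random.default_rng(7)
    for _ in range(100):
        vecs = rng.uniform(-9, 9, size=(400, 2))  # some vectors out of domain
        ours = window_entropy(vecs, entropy_cfg)
        inside = np.all(np.abs(vecs) <= 8, axis=1)
        theirs = _naive_entropy(vecs[inside], entropy_cfg)
        assert ours == pytest.approx(theirs, abs=1e-12)


def test_entropy_series_window_placement(entropy_cfg):
    # 41 samples -> velocities 0..39; only t=20 has a full centred window
    rng = np.random.default_rng(3)
    pos = np.cumsum(rng.uniform(-0.3, 0.3, size=(41, 10, 2)), axis=0) + 50.0
    series = TrackingSeries(np.arange(41) * 0.05, [f"p{i}" for i in range(10)],
                            pos, 20.0, pitch_length=1000, pitch_width=1000)
    H = movement_entropy_series(series, entropy_cfg)
    defined = np.flatnonzero(np.isfinite(H))
    assert list(defined) == [20]
    assert 0.0 <= H[20] <= np.log2(400)


# ---------------------------------------------------------------------------
# surface area


def _brute_force_hull_area(points):
    """Orientation-test hull: (i, j) is a hull edge iff all other points lie
    on one side; order the edges into a polygon and apply the shoelace formula."""
    n = len(points)
    edges = {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = points[j] - points[i]
            rel = points - points[i]
            cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
            others = np.ones(n, bool)
            others[[i, j]] = False
            if np.all(cross[others] > 1e-12):
                edges[i] = j
    if not edges:
        return 0.0
    start = next(iter(edges))
    order, cur = [start], edges[start]
    while cur != start:
        order.append(cur)
        cur = edges[cur]
    poly = points[order]
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def test_surface_area_interior_points_irrelevant():
    square = np.array([[0, 0], [1.0, 0], [1.0, 1.0], [0, 1.0]])
    interior = np.random.default_rng(0).uniform(0.2, 0.8, size=(6, 2))
    area, degenerate = surface_area(np.vstack([square, interior]))
    assert area == pytest.approx(1.0)
    assert not degenerate


def test_surface_area_collinear_flagged():
    pts = np.column_stack([np.linspace(0, 9, 10), np.linspace(0, 18, 10)])
    area, degenerate = surface_area(pts)
    assert area == 0.0
    assert degenerate


def test_surface_area_matches_brute_force_oracle():
    rng = np.random.default_rng(11)
    for _ in range(200):
        pts = rng.uniform(0, 50, size=(rng.integers(3, 13), 2))
        area, degenerate = surface_area(pts)
        if not degenerate:
            assert abs(area - _brute_force_hull_area(pts)) < 1e-9


# ---------------------------------------------------------------------------
# series-level invariants


def _random_series(rng, n=120, n_players=10):
    pos = np.cumsum(rng.uniform(-0.25, 0.25, size=(n, n_players, 2)), axis=0) + 60.0
    return TrackingSeries(np.arange(n) * 0.05, [f"p{i}" for i in range(n_players)],
                          pos, 20.0, pitch_length=1000, pitch_width=1000)


def test_ranges_on_computed_samples():
    ops = compute_order_parameters(_random_series(np.random.default_rng(5)))
    for arr, lo, hi in [(ops.p_raw, 0, 1), (ops.m_raw, 0, 1),
                        (ops.H, 0, np.log2(400))]:
        vals = arr[np.isfinite(arr)]
        assert len(vals) > 0
        assert np.all(vals >= lo - 1e-12) and np.all(vals <= hi + 1e-12)
    assert np.all(ops.A[np.isfinite(ops.A)] >= 0)
    assert np.all(ops.v_raw[np.isfinite(ops.v_raw)] >= 0)


def test_rigid_motion_invariance():
    # common rotation + translation (by whole bin widths, so H is bin-exact)
    rng = np.random.default_rng(9)
    series = _random_series(rng)
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    moved = TrackingSeries(series.timestamps, series.players,
                           series.positions @ R.T + np.array([40.0, 7.0]),
                           20.0, pitch_length=1000, pitch_width=1000)
    a = compute_order_parameters(series)
    b = compute_order_parameters(moved)
    for x, y in [(a.p_raw, b.p_raw), (a.m_raw, b.m_raw), (a.A, b.A)]:
        assert np.allclose(x[1:], y[1:], atol=1e-9, equal_nan=True)
    # axis-aligned translation by whole bin widths leaves H unchanged exactly
    shifted = TrackingSeries(series.timestamps, series.players,
                             series.positions + np.array([3.0, 1.5]),
                             20.0, pitch_length=1000, pitch_width=1000)
    c = compute_order_parameters(shifted)
    assert np.allclose(a.H, c.H, atol=1e-9, equal_nan=True)


def test_scale_law_speed_doubles_v_not_p():
    rng = np.random.default_rng(13)
    series = _random_series(rng)
    centre = series.positions.mean(axis=(0, 1))
    doubled = TrackingSeries(series.timestamps, series.players,
                             centre + 2.0 * (series.positions - centre),
                             20.0, pitch_length=1000, pitch_width=1000)
    a, b = compute_order_parameters(series), compute_order_parameters(doubled)
    assert np.allclose(b.v_raw[1:], 2.0 * a.v_raw[1:], rtol=1e-9)
    assert np.allclose(b.p_raw[1:], a.p_raw[1:], atol=1e-9, equal_nan=True)


def test_jitter_speed_filter_contract():
    # static true positions + reported jitter: raw speed is pure noise; the
    # Gaussian filter suppresses its fluctuations (variance), not its mean
    rng = np.random.default_rng(17)
    pos = np.tile(rng.uniform(20, 80, size=(1, 10, 2)), (800, 1, 1))
    pos += rng.normal(0, 0.1, size=pos.shape)
    series = TrackingSeries(np.arange(800) * 0.05, [f"p{i}" for i in range(10)],
                            pos, 20.0, pitch_length=1000, pitch_width=1000)
    ops = compute_order_parameters(series)
    raw, smoothed = ops.v_raw[1:], ops.v[1:]
    assert np.nanmean(raw) > 0
    # successive backward-difference speeds share a centroid sample, so the
    # raw series is autocorrelated and the reduction is below the white-noise
    # factor sum(w^2) ~ 0.03; an order of magnitude is still required
    assert np.nanvar(smoothed) < 0.1 * np.nanvar(raw)
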