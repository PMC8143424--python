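"""End-to-end match analysis: order parameters -> states -> transitions ->
survival statistics -> figures, plus a machine-readable summary report."""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import density_viz, order_params, states, survival_stats, tracking_io


@dataclass
class MatchAnalysis:
    """Everything the pipeline derives from one tracking series + annotation."""

    series: tracking_io.TrackingSeries
    annotation: tracking_io.PhaseAnnotation
    ops: order_params.OrderParameterSeries
    phase_labels: np.ndarray
    segments: list
    graph: object
    state_labels: np.ndarray
    runs: list
    transitions: list
    duration_samples: list
    km: dict = field(default_factory=dict)  # (phase, state) -> SurvivalCurve
    logrank: dict = field(default_factory=dict)  # (phase, state_a, state_b) -> result


def analyze_match(
    series: tracking_io.TrackingSeries,
    annotation: tracking_io.PhaseAnnotation,
    thresholds: states.StateThresholds = states.DEFAULT_THRESHOLDS,
    entropy_cfg: order_params.EntropyGridConfig | None = None,
) -> MatchAnalysis:
    """Run the full collective-state pipeline on one annotated tracking series."""
    ops = order_params.compute_order_parameters(series, entropy_cfg)
    phase_labels = tracking_io.align(annotation, series)
    segments = tracking_io.phase_segments(
        phase_labels, series.timestamps, series.sample_rate, series.blocks
    )
    graph = tracking_io.phase_transition_graph(segments)
    state_labels = states.classify_series(ops, thresholds)
    runs = states.extract_runs(
        state_labels, series.timestamps, series.sample_rate, series.blocks, phase_labels
    )
    transitions = states.attach_samples(states.extract_transitions(runs), ops)
    samples = survival_stats.state_duration_samples(runs, segments)

    analysis = MatchAnalysis(
        series, annotation, ops, phase_labels, segments, graph,
        state_labels, runs, transitions, samples,
    )
    by_group: dict = {}
    for s in samples:
        by_group.setdefault((s.phase, s.state), []).append(s)
    for key, group in by_group.items():
        if any(not s.censored for s in group):
            analysis.km[key] = survival_stats.km_estimate(group)
    for phase in tracking_io.PHASES:
        present = sorted({st for (ph, st) in by_group if ph == phase})
        for a, b in itertools.combinations(present, 2):
            ga, gb = by_group[(phase, a)], by_group[(phase, b)]
            if any(not s.censored for s in ga) and any(not s.censored for s in gb):
                analysis.logrank[(phase, a, b)] = survival_stats.logrank(ga, gb)
    return analysis


def summary_report(analysis: MatchAnalysis) -> dict:
    """Summary JSON: state time fractions per phase, transition counts, log-rank."""
    dt = analysis.series.dt
    time_by = {}
    for ph, st in zip(analysis.phase_labels, analysis.state_labels):
        if st is None:
            continue
        time_by.setdefault(ph, {}).setdefault(st, 0.0)
        time_by[ph][st] += dt
    fractions = {
        ph: {st: v / sum(d.values()) for st, v in d.items()}
        for ph, d in time_by.items()
    }
    trans_counts: dict = {}
    for seg in analysis.transitions:
        key = f"{seg.from_state}->{seg.to_state}"
        trans_counts[key] = trans_counts.get(key, 0) + 1
    phase_edges = {
        f"{u}->{v}": {
            "count": analysis.graph.edges[u, v]["count"],
            "weight": analysis.graph.edges[u, v]["weight"],
        }
        for u, v in analysis.graph.edges
    }
    return {
        "n_samples": len(analysis.series),
        "state_time_fractions_per_phase": fractions,
        "state_transition_counts": trans_counts,
        "phase_transition_edges": phase_edges,
        "logrank": {
            f"{ph}:{a}_vs_{b}": res.to_dict()
            for (ph, a, b), res in analysis.logrank.items()
        },
    }


def render_figures(analysis: MatchAnalysis, out_dir) -> list:
    """Write the standard figure set for one analysed match; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    ops = analysis.ops

    pm = np.column_stack([ops.p, ops.m])
    grid = density_viz.bin_density(pm, xlabel="p_group", ylabel="m_group")
    paths.append(density_viz.plot_density(grid, out / "density_pm.png",
                                          state_regions=True, title="all play"))
    grid.save(out / "density_pm")

    pv = np.column_stack([ops.p, ops.v])
    vmax = np.nanmax(ops.v) if np.isfinite(ops.v).any() else 1.0
    grid_pv = density_viz.bin_density(
        pv, nx=density_viz.BINS_PM, ny=density_viz.BINS_SPEED_AREA,
        domain=((0, 1), (0, max(vmax, 1e-6))), xlabel="p_group", ylabel="v_group (m/s)",
    )
    paths.append(density_viz.plot_density(grid_pv, out / "density_pv.png"))

    for phase in tracking_io.PHASES:
        sel = analysis.phase_labels == phase
        if sel.sum() < 2:
            continue
        g = density_viz.bin_density(pm[sel], xlabel="p_group", ylabel="m_group")
        paths.append(density_viz.plot_density(
            g, out / f"density_pm_{phase}.png", state_regions=True, title=phase))

    paths.append(density_viz.plot_phase_graph(analysis.graph, out / "phase_graph.png"))

    kde_curves = {}
    for phase in tracking_io.PHASES:
        durs = [s.duration for s in analysis.segments if s.phase == phase]
        if len(durs) >= 2 and np.std(durs) > 0:
            kde_curves[phase] = survival_stats.duration_kde(np.array(durs))
    if kde_curves:
        paths.append(density_viz.plot_duration_kde(kde_curves, out / "play_durations_kde.png"))

    for phase in tracking_io.PHASES:
        curves = {
            st: c for (ph, st), c in analysis.km.items() if ph == phase
        }
        if curves:
            paths.append(density_viz.plot_survival(
                curves, out / f"survival_{phase}.png", title=phase))

    # transition-kind densities with drift quivers
    by_kind: dict = {}
    for seg in analysis.transitions:
        by_kind.setdefault((seg.from_state, seg.to_state), []).append(seg.samples)
    for (a, b), segs in by_kind.items():
        pts = np.concatenate(segs, axis=0)
        g = density_viz.bin_density(pts, xlabel="p_group", ylabel="m_group")
        density_viz.mean_drift(segs, g)
        paths.append(density_viz.plot_density(
            g, out / f"transition_{a}_to_{b}.png", state_regions=True,
            quiver=True, title=f"{a} -> {b}"))

    if analysis.transitions:
        exemplar = max(analysis.transitions, key=lambda s: s.duration)
        paths.append(density_viz.plot_transition_exemplar(
            analysis.series, ops, analysis.state_labels, exemplar,
            out / "transition_exemplar.png"))
    return paths


def write_report(analysis: MatchAnalysis, path) -> dict:
    report = summary_report(analysis)
    Path(path).write_text(json.dumps(report, indent=2))
    return report
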