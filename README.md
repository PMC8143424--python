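# teamstates

Collective-state analysis of team player-tracking data.

Field-sport teams, like fish schools and bird flocks, move through
identifiable collective states: tightly aligned translation, unordered
aggregation, and (in principle) rotation about the group centre.
`teamstates` turns fixed-rate positional tracking of a team (e.g. 10 outfield
players at 20 Hz) plus a possession-based phase-of-play annotation into:

- **order parameters** per time step — polarisation
  `p_group(t) = (1/N) |Σᵢ v̂ᵢ(t)|`, angular momentum
  `m_group(t) = (1/N) |Σᵢ r̂ᵢc(t) × v̂ᵢ(t)|`, mean group speed
  `v̄_group(t) = |c_group(t) − c_group(t−Δt)|/Δt`, windowed movement entropy
  `H_group(t) = −Σᵢⱼ P_ij log₂ P_ij` (bits, velocity vectors binned on a
  fixed ±8 m/s grid of 0.5 m/s bins), and convex-hull surface area
  `A_group(t)`;
- **collective states** — polar (`p>0.65 ∧ m<0.35`), swarm
  (`p<0.35 ∧ m<0.35`), milling (`p<0.35 ∧ m>0.65`), else transitional —
  their maximal runs and the transition segments between them;
- **survival statistics** — Kaplan–Meier curves of state durations per game
  phase (runs cut by a phase change enter as right-censored), pairwise
  log-rank tests, and kernel-density estimates of play-segment durations;
- **state-space density figures** — 50×50 binned heat maps with 3×3
  neighbourhood smoothing, state-region overlays, and mean-drift quiver
  fields over transition segments;
- a **zonal agent simulator** (repulsion / orientation / attraction zones,
  constant speed, bounded pitch, reported-position jitter) with calibrated
  `polar` / `swarm` / `milling` / `out_of_play` presets and regime schedules,
  so the whole pipeline is testable without proprietary tracking data.

Audience: sports scientists and collective-behaviour researchers working
with positional tracking; everything is plain NumPy/pandas objects plus CSV
in, CSV/JSON/PNG out.

## Worked example

```python
from teamstates import (RegimeSegment, ZonalModelParams, simulate_match,
                        analyze_match, summary_report)

schedule = [
    RegimeSegment(30.0, "polar", "defending"),
    RegimeSegment(20.0, "swarm", "attacking"),
    RegimeSegment(10.0, "out_of_play", "out_of_play"),
    RegimeSegment(30.0, "polar", "defending"),
]
series, annotation = simulate_match(schedule, ZonalModelParams(seed=7))
report = summary_report(analyze_match(series, annotation))
print(report["state_time_fractions_per_phase"])
```

prints (seed 7, 1800 samples = 90 s at 20 Hz):

```
defending:   polar 0.99, transitional 0.01
attacking:   swarm 0.72, transitional 0.27, polar 0.01
out_of_play: swarm 0.92, transitional 0.09
```

i.e. the defending-phase segments (driven by the aligned `polar` regime) are
classified polar 99% of the time, while the attacking/out-of-play segments
(disordered regimes) sit in the swarm state with a transitional fringe — the
ordered-defence / disordered-attack contrast the state classification is
meant to expose.  The same analysis reports the median smoothed group speed
at 3.5 m/s while defending versus 0.6 m/s while attacking (aligned groups
move faster), the state-transition counts (`polar->swarm` 1,
`swarm->polar` 1, `swarm->swarm` re-entries 3), and phase-graph edge weights
(each of defending→attacking, attacking→out_of_play, out_of_play→defending
= 1/3 here).

From the shell:

```bash
teamstates simulate --preset polar --duration 60 --seed 1 --out sim/
teamstates analyze --tracking sim/tracking.csv --annotation sim/annotation.csv --out results/
teamstates report  --tracking sim/tracking.csv --annotation sim/annotation.csv --out report.json
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the analytic ceiling of the windowed movement entropy from
scratch: it constructs a 2-second, 20 Hz window for 10 players whose 400
per-step velocity vectors each land in a different bin of the default 32×32
grid, runs the package's windowed-entropy pipeline on it, cross-checks the
result against the closed-form entropy of a uniform occupancy, and writes
the value (bits) as JSON.
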