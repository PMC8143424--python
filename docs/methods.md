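# Methods

## Order parameters

All descriptors are computed per time step from the reported (possibly
jittered) positions of the N tracked players on a fixed 1/Δt grid
(default 20 Hz, Δt = 0.05 s).

**Direction of motion.** v̂ᵢ(t) is the backward difference
cᵢ(t) − cᵢ(t−Δt), normalised.  Any heading/speed columns a tracking export
may carry are ignored so that results depend only on positions.  When the
per-step displacement is below ε = 10⁻⁶ m the direction is undefined and the
player is excluded from the polarisation and angular-momentum sums at that
step; the divisor becomes n_used, the number of contributing players, and
steps with n_used < N are flagged.  Dividing by N instead would deflate both
parameters artefactually whenever a player is momentarily stationary.  With
fewer than two usable directions the parameter is missing at that step.

**Polarisation** p_group = (1/n_used)|Σ v̂ᵢ| ∈ [0, 1].
**Angular momentum** m_group = (1/n_used)|Σ r̂ᵢc × v̂ᵢ| with the 2-D cross
product taken as the scalar r̂ₓv_y − r̂_yv_x and r̂ᵢc the unit vector from
the centroid of the contributing players to player i; players exactly at the
centroid are excluded (no defined bearing).
**Group speed** v̄_group is the backward-difference speed of the all-player
centroid; the first sample of each block is missing.

**Smoothing.** p, m and v̄ are additionally reported after a
Gaussian-weighted moving average with a 2-s window (40 samples at 20 Hz) and
σ = window/5 = 8 samples — the default of the numerical environment this
family of filters is usually run in.  The kernel is truncated and
renormalised at block edges and at missing samples, and never crosses block
boundaries.  Note the filter removes temporal fluctuation, not bias: on a
pure-jitter speed series it shrinks the variance by roughly Σw² but
preserves the mean, which is why the smoothed speed of a static, jittered
group is small-variance, not zero.

**Movement entropy.** For each step t, the per-step velocity vectors
(displacement/Δt, m/s) of all players over a window of 40 steps centred on t
(±1 s) are placed tails-at-origin on a square grid covering ±8 m/s with
0.5 m/s bins (32 × 32 = 1024 bins, half-open bins with the top/right edge
closed), tallied into f_ij, normalised to P_ij, and
H_group = −Σ P_ij log₂ P_ij with 0·log 0 := 0.  A full window pools
40 × N = 400 vectors for a 10-player team, capping H at log₂ 400 ≈ 8.64
bits.  Vectors outside the domain are discarded before normalisation and
counted in the flags; a window truncated by a block boundary leaves H
missing.  The grid is defined on *velocities*, not raw per-step
displacements: the ±8 domain is motivated by maximal sprint speeds
(≈ 8–9 m/s), whereas raw 20 Hz displacements would occupy only the central
±0.5 m and waste the grid.  Window placement is symmetric about t; the
stride is 1 sample.

**Surface area** is the area of the convex hull of all player positions
(SciPy Qhull); collinear configurations return 0 with a degeneracy flag.

## State classification and transitions

Thresholds hi = 0.65, lo = 0.35 on the *smoothed* (p, m):
polar (p > hi ∧ m < lo), swarm (p < lo ∧ m < lo), milling
(p < lo ∧ m > hi), otherwise transitional.  Equality with a threshold is
transitional — the printed inequalities are strict and the tie must be
deterministic.  Milling is retained as a classifiable state even though real
football data essentially never visit it; the simulator produces it and the
code must handle it.  No debouncing or minimum run length is applied: the
upstream filter is the only hysteresis.

State runs are maximal constant-state sample runs; missing samples and block
boundaries break runs, and a run that ends for either reason is marked
censored.  A transition segment for (X → Y) spans the entirety of run X, the
intervening transitional runs (possibly none), and the entirety of run Y;
X = Y re-entries are legitimate segments.  Segments never span block gaps.

## Survival statistics

Runs are intersected with the phase segments.  A piece cut short by a phase
change is right-censored at the cut; the final piece inherits the run's own
censoring status.  Kaplan–Meier estimation and the two-group log-rank test
(hypergeometric variance, simultaneous-event tie convention, df = 1) are
delegated to lifelines; tests verify both against hand product-limit and
hand O/E/Var-table computations.  Play-segment duration densities use a
Gaussian KDE with Silverman's rule-of-thumb bandwidth by default; degenerate
(zero-spread) input requires an explicit bandwidth.

An aside on reported pairings of (χ², p) in the literature this package is
aimed at: a χ² of 2.86 on 1 df corresponds to p ≈ 0.09, not p ≈ 0; the
package computes the standard test and reports both numbers, making such
inconsistencies visible rather than reproducing them.

## Density representations

Order-parameter points are binned on equal-width grids — 50 × 50 for
(p, m); 60 bins for speed/area axes and 140 for the entropy axis —
half-open bins, top/right edge closed, out-of-domain points counted but
never binned.  Smoothing is the mean over the 3 × 3 neighbourhood,
restricted to existing cells at borders (6 cells on an edge, 4 at a
corner).  Heat maps display smoothed counts divided by the total point
count so panels with different sample sizes are comparable; raw counts are
always retained alongside.  For transition-segment plots the per-bin mean
drift is the average of (next sample − sample) over every sample falling in
the bin, pooled across all segments of that transition kind (pooling over
samples, not per-segment averages).  Colour maps are perceptually uniform
defaults; no attempt is made to pixel-match any particular publication
style.

## Zonal simulator

A minimal member of the behavioural-zones family: constant speed within a
regime, equal orientation/attraction weights, no blind zone.  Repulsion
(move away from neighbours closer than `zone_repulsion`) preempts the social
response; otherwise the desired direction is the normalised sum of the
normalised mean neighbour heading within `zone_orientation` and the
normalised attraction toward neighbours in the annulus between
`zone_orientation` and `zone_attraction`.  The annulus convention makes an
all-aligned group with a fully covering orientation zone an exact fixed
point of the update.  Gaussian angular noise (sd `noise_sd`) perturbs the
desired direction; the agent turns toward it by at most `max_turn` per step
and advances `speed·Δt`.  Boundaries reflect the heading specularly, which
preserves constant speed without modelling walls.  Reported positions add
independent Gaussian jitter (default sd 0.03 m) to the true positions;
this models only the high-frequency component of radio-tracking error —
real positioning error is temporally autocorrelated and larger in absolute
terms, which the generator does not emulate.  A green regime-recovery test
therefore establishes that the pipeline classifies clean, zone-generated
states correctly, not that it is robust to every real-world error process.

All randomness flows from one seed through three spawned substreams (initial
conditions, angular noise, jitter), so runs are bit-reproducible and jitter
can be disabled without changing the trajectory.

Preset parameters (frozen after one calibration pass against the
order-parameter pipeline):

| preset      | speed m/s | zor m | zoo m | zoa m | max_turn rad/step | noise_sd rad |
|-------------|-----------|-------|-------|-------|-------------------|--------------|
| polar       | 3.5       | 1.0   | 30    | 40    | 0.1               | 0.05         |
| swarm       | 1.5       | 2.0   | 2.0   | 12    | 0.3               | 0.4          |
| milling     | 3.0       | 0.5   | 0.5   | 30    | 0.025             | 0.02         |
| out_of_play | 0.7       | 1.5   | 1.5   | 15    | 0.3               | 0.5          |

Rationale for the load-bearing choices: the polar speed (3.5 m/s) sits in
the 3–4 m/s range characteristic of ordered defensive movement, and the
out-of-play speed below 1 m/s reflects collapsed formations between plays,
so the speed–alignment association emerges from regime composition rather
than from any fitted coupling.  Swarm sets `zone_orientation =
zone_repulsion` (no alignment band) with strong angular noise.  Milling
matches the turn limit to the 6 m ring initialisation
(`max_turn = speed·Δt/6 m`), making the attraction-limited orbit stable at
the ring; a looser turn limit lets agents spiral through the group centre
and the mill never forms.  Initialisations: polar starts aligned at a random
common heading, milling starts tangentially (anticlockwise) on the ring,
others start with independent random headings, all within ±10 m of the
pitch centre.  A 10-s burn-in is discarded before any regime-recovery
assertion.

Regime schedules concatenate presets while positions and headings continue
across boundaries — a switch changes interaction parameters, never state —
and emit the phase annotation as change events at segment starts
(consecutive identical phases merged; the out-of-play regime forces the
out-of-play label).

## Tracking I/O conventions

Canonical dialect `time_s,player_id,x_m,y_m`, metres, origin bottom-left,
default pitch 105 × 68 m; other layouts map through a column/unit config.
Timestamps snap to the nearest grid sample (tolerance Δt/4).  Per-player
gaps ≤ 0.5 s are linearly interpolated and marked imputed; longer gaps and
all-player holes (including half-time) split the series into independent
blocks, and no statistic spans a block boundary.  Annotation events take
effect at the next grid sample at or after the event time; samples before
the first event are out-of-play.  Out-of-pitch positions are flagged, never
clamped.  Phase segments are half-open [start, start + nΔt) so they tile
each block exactly; phase-transition edge weights are transition counts over
total transitions and sum to 1 whenever a transition exists.

## Numerical notes and limitations

- Tie-breaks: threshold equality → transitional; entropy bin edges
  half-open with closed outer edge; simultaneous log-rank events use the
  standard tie convention.
- Degenerate inputs: < 2 usable directions → missing p/m; < 3 players →
  surface area undefined (error); collinear hull → 0 m² flagged; all
  vectors out of the entropy domain → missing H; zero-spread KDE input →
  explicit bandwidth required.
- The simulator makes no attempt at tactical realism (no ball, no
  opponents, no formations); it exists to produce classifiable collective
  structure with known ground truth.
- Per-step displacement of a reflected agent is shorter than speed·Δt in a
  straight line (the path is folded); the constant-speed contract applies
  to path length, and tests assert it away from boundaries.
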