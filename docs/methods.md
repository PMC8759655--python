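# Methods

This note documents the models, conventions and numerical choices behind
`confinetrack`: what the synthetic-data generator simulates and why, how
the analyses define their quantities, and where the design was genuinely
open.

## The system being emulated

The package targets tracking data of fast-migrating amoeboid cells
confined to adhesive micropatterns on an otherwise non-adhesive substrate.
The canonical scenario is a 100-µm-diameter circular island imaged at 10-s
frame intervals; cells migrate at ≈3.9 ± 0.6 µm·min⁻¹, collide with each
other, cannot adhere beyond the pattern edge (so they either turn and
follow the boundary or migrate away), and divide with roughly Gaussian
doubling times of 9.3 ± 1.6 h. No public tracking data exist for this
system, so the generator is a first-class component: every analysis is
validated against synthetic tracks whose generating parameters are known.

## Geometry

Regions are closed subsets of the plane in continuous µm coordinates:
disks, axis-aligned rectangles, simple polygons (shapely-backed), and an
outer region minus a hole. Points on the boundary count as inside, because
boundary-following cells sit exactly on the edge. The boundary tangent is
oriented counter-clockwise with respect to the interior, and every boundary
point carries a curvature class — `linear`, `concave_arc` (centre of
curvature inside the region: the rim of a disk seen from inside) or
`convex_arc` (centre outside: the rim of a subtracted hole). Corners have
no tangent and raise an error so angle analyses can exclude them; the
simulator treats an exact-corner contact by aiming at the region's centre,
a measure-zero fallback.

## Agent-based simulation

Each cell carries a constant speed drawn once from a truncated normal
(mean 3.9, SD 0.6 µm·min⁻¹, ≥ 0) and a heading that diffuses with variance
2·dt/τ per step (τ = `persistence_time`, default 60 s — amoeboid
directional persistence on the minute scale). The time step equals the
frame interval (10 s), so emitted tracks are the simulated state with no
sub-sampling.

**Boundary interaction.** Within a sensing distance of the pattern edge
(default one cell radius), a cell whose heading lies within
`boundary_follow_angle` (default 30°) of the local tangent enters a
*following* state: it crawls along the boundary curve itself at full
speed, with turning noise scaled by `boundary_guidance_factor`
(default 0.4, a contact-guidance term), and it keeps crawling — including
when its noisy heading points outward, where no ground can be gained —
until a decisive inward turn beyond the follow angle releases it. Fresh
arrivals with steeper outward headings are specularly reflected. Two
points deserve emphasis:

* Following must be a *persistent state*, not a single-step correction. A
  rule that only redirects the individual offending step produces following
  episodes of ~2 frames and a steady-state radial distribution that is flat
  or rim-depleted (specular billiards preserve the uniform measure); the
  characteristic rim accumulation and the ability to classify 120-s
  following windows both require sustained crawling. The guidance factor is
  the one free parameter of this mechanism; 0.4 was fixed by requiring the
  generator to reproduce the qualitative phenotype it exists to emulate —
  sustained edge-following and outermost-ring dominance of the occupancy
  profile at 200 cells (32% area density) — and is not adjusted per
  analysis.
* Followers hold their course through cell–cell contacts (the episodes are
  still detected and recorded): edge guidance dominates the transient and
  highly dynamic cell–cell adhesion of these cells. Without this, at 32%
  density a follower is struck every few frames and rim accumulation
  vanishes, contrary to the observed behavior of the real system at that
  density.

**Collisions.** A contact episode opens when two centre points come within
2·`cell_radius`. The approaching cell samples an outcome from a
per-entering-angle-bin table — defaults (illustrative, not fitted):
shallow contacts mostly `reflect` (heading mirrored about the contact
tangent), intermediate mostly `pass` (heading kept, overlap tolerated),
steep contacts `push`/`pass` (target displaced along the contact normal).
Entering angles are measured against the tangent to the contacted cell's
perimeter at the contact point.

**Division.** Lifetimes are truncated-normal (default 9.3 ± 1.6 h, minimum
0.5 h); a cell becomes stationary ("rounded") for `rounding_duration`
(default 5 min) before abscission, then is replaced by two children at
± one radius along a random axis. Division depends only on age, never on
position, so `sample_lineage` — an event-driven sampler of the identical
lifetime law — is the exact temporal marginal of the spatial simulation
and is used when only division statistics are needed (e.g. hundred-seed
recovery studies).

Determinism: all randomness flows from one `numpy` generator seeded by
`SimConfig.seed`; identical configs give bit-identical tracks.

## Rigid-particle Monte-Carlo oracle

The closed-form rate Z = N(N−1)LV/(2(A−NS)) specifies no particle
kinetics. A literal ballistic hard-disk gas has a per-pair encounter rate
2L⟨v_rel⟩/A_free with ⟨v_rel⟩ = 4V/π, i.e. ≈2.5× the closed form, while a
fully diffusive walk yields far fewer distinct episodes — so *some*
episode-definition choice is unavoidable when cross-checking the formula
by simulation. The oracle used here: N hard disks of diameter L at constant
speed V in the circular arena, memoryless headings (redrawn every 5-s
step), specular wall reflection of disk centres at radius R − L/2, overlaps
resolved by symmetric separation along the pair axis (reproducing the
excluded-area effect of the A − NS denominator), and a collision counted
once per contact episode, an episode closing only after 8 consecutive
separated frames (40 s) so that the rapid re-contacts of diffusive relative
motion merge into single events. The closure window is the oracle's single
calibrated constant: it was set once against the analytic rate at N = 10
and then validated without adjustment at N = 5 and N = 20, where the
free-area correction differs; agreement is within one standard error at
all three occupancies (20 seeds × 1 h). The same episode logic is
implemented independently in `track_analysis.detect_collisions`, and the
two code paths are required to agree exactly on the oracle's emitted
tracks.

## Analyses

* **Velocity** — mean per-frame step displacement over the frame interval,
  reported in µm·min⁻¹. Invariant under rigid motions.
* **Collision events** — episodes with 2-frame closing hysteresis (default)
  against chatter at the threshold. The "A" cell of an event is the faster
  approacher along the centre line at opening. Entering angle: acute angle
  between A's 30-s incoming displacement and the tangent to B's perimeter
  at contact (0 = grazing, 90 = head-on). Exiting angle: signed angle of
  the outgoing displacement from the incoming tangential direction,
  positive toward A's side; `reflect` ≥ 0, `pass` in [−90, 0), `push`
  < −90. Retrograde exits steeper than the tangent fold back into [0, 90].
  30-s direction windows are used because single 10-s steps (~0.65 µm) are
  noise-dominated; events lacking a window are flagged unresolved and
  excluded from histograms, as are (by default) events whose contact point
  lies within a contact distance of the pattern boundary (mixed
  cell/boundary events).
* **Boundary encounters** — distance-based episodes: open below
  `near_distance` (default one cell radius), close beyond it plus a 1-µm
  hysteresis. Both angles are unsigned in [0, 90] since the cell cannot
  exit the region. `classify_following` demands the cell stay within the
  near distance for the whole 120-s window *and* move within 30° of the
  local tangent at every step after a 30-s settling allowance — captured
  cells show a few steep reorientation frames (pseudopod retraction)
  before travelling along the edge, and without the allowance essentially
  no real following event classifies as such.
* **Division statistics** — doubling time is birth (parent abscission) to
  own abscission; founders and cells alive at the end are excluded
  (right-censoring by exclusion). The Gaussian fit is maximum likelihood on
  the raw values; the histogram returned alongside is presentation only.
  Sibling asynchrony pairs the two children's doubling times. Under iid
  normal lifetimes E|X−Y| = 2σ/√π ≈ 1.81 h for σ = 1.6 — notably larger
  than the ≈1.0 h reported for real sibling pairs, which suggests positive
  sibling correlation in the real data; the generator deliberately keeps
  lifetimes independent, so this discrepancy is expected and documented
  rather than tuned away.
* **Occupancy** — a grid (default 0.5 µm; coarser grids are used in
  long-duration studies for speed, with the conservation invariant checked
  at ≤2%) marks points within one cell radius of any centroid per frame;
  the per-point time fraction is the analogue of an averaged fluorescence
  image. Ring summaries use four equal-radial-width rings by default
  (equal-area optional). The occupancy study protocol simulates 4 h and
  averages the final hour, because rim accumulation develops over a couple
  of hours from a uniform seeding — emulating imaging of an established
  culture.

## Selection protocols for division studies

Sampling "cells that divided before T" biases lifetimes short (deep
generations are only partially complete). Recovery studies therefore select
cells by *birth order* — the first 212 non-founders born, in runs long
enough (70 h from 8 founders) that all of them complete — which is
independent of each cell's own lifetime. Sibling studies likewise take the
first 48 pairs by parent birth order from 55-h runs. With these protocols
the fitted mean is unbiased (9.31 ± 0.02 over 40 seeds) and the
3σ/√n recovery criterion holds for at least 95% of seeds.

## Density conventions

Two per-cell footprints are supported deliberately: the model's particle
area S = 55.7 µm² (an 8.42-µm disk), and the effective footprint
≈12.57 µm² implied by the experimental correspondence of 200 cells to a
32% area density in the 7853-µm² arena (which makes 40% ≈ 250 cells). The
two are mutually inconsistent and the package resolves neither: every
conversion takes an explicit `DensityConvention`.

## Known limitations

* Cells are points with a nominal radius: no shapes, pseudopods,
  deformation or chemotaxis; collision outcomes are sampled from a table,
  not mechanics, and the default table is illustrative.
* The boundary-following mechanism is phenomenological contact guidance;
  its guidance factor is calibrated to the qualitative rim-accumulation
  phenotype, not measured.
* The rigid-particle oracle validates the closed form under a documented
  episode definition; it is not an independent derivation of the formula's
  constants.
* Passing the synthetic-data tests shows the analyses recover what the
  generator put in (angles, rates, lifetimes, occupancy ordering); it does
  not certify behavior on real segmentation/tracking artefacts such as
  identity switches, gaps, or positional noise beyond the simulated level.
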