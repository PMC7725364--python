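# Methods

`swarminfer` is a simulate-then-infer toolkit for collective motion in two
dimensions.  It generates trajectories with two standard individual-based
models, reconstructs interaction surfaces from those trajectories with an
averaging (force-matching) method, and measures how faithfully the surfaces
recover the rules that generated them.  This note records the models, the
estimators, every tunable that matters, and the design choices made where
the design was genuinely open.

## The zonal model

`ZonalParams` / `run_zonal` implement a discrete-time self-propelled
particle model.  Each of `N` individuals moves at constant speed `s`
(units/s) and steers according to three concentric zones:

* **repulsion** (distance in `(0, r_r]`): steer along the negated sum of
  unit vectors towards zone members — collision avoidance, overriding all
  other responses;
* **orientation** (`(r_r, r_o]`, `r_o = r_r + delta_r_o`): align with the
  sum of zone members' unit headings;
* **attraction** (`(r_o, r_a]`, `r_a = r_o + delta_r_a`): steer along the
  sum of unit vectors towards zone members.

When both the orientation and attraction zones are populated their *raw*
partner sums are added before normalising (`combine_mode="sum"`), so each
partner carries equal weight.  The alternative — normalising each zone's
resultant first so each *zone* carries equal weight
(`combine_mode="normalised"`) — is retained as an option; it produces
markedly more fragmentation-prone groups because a small aligned subgroup
can outvote the attraction of the distant main group.  With a single
partner per zone the two modes coincide.

A rear blind wedge of angular extent `omega_blind` (degrees, half-angle
each side of dead astern) hides neighbours; `blind_scope` selects whether
it applies in all zones, only in the orientation/attraction zones, or not
at all.  The preferred direction is perturbed by a Gaussian angle with
standard deviation `eta` radians (applied before the turning cap), and the
heading rotates towards the result by at most `theta_max * dt` degrees per
step.  An exactly antipodal preferred direction is resolved anticlockwise
(the `atan2` branch at +180°).  All agents update synchronously from the
same snapshot; positions advance `s * dt` along the new heading, so speed
is conserved exactly.  An agent with no visible neighbours (or a cancelled
resultant) steers towards its own noise-perturbed heading.

Defaults follow the standard parameterisation used throughout the package:
`theta_max = 40` deg/s, `s = 3` units/s, `dt = 0.1` s, `eta = 0.1` rad,
`N = 25`, 1000 steps.  Initial positions are uniform in a centred square of
side `init_box = 10` units with uniform random headings; the focal's own
heading is *not* added to the orientation sum (`include_self_heading`
switches this).  Both choices are conventions of this package — the
initial density and the self-heading term are not observable from the
emergent statistics we target, and the defaults are the common ones for
this model family.

## The Morse-potential swarm ODE

`ODEParams` / `run_ode` integrate

    dx_i/dt = v_i
    dv_i/dt = (alpha - beta |v_i|^2) v_i - (1/N) sum_{j != i} grad U(|x_i - x_j|)

with `U(r) = -C_A exp(-r/l_A) + C_R exp(-r/l_R)`.  Self-propulsion drives
speeds to `sqrt(alpha/beta)`; the pairwise force is attractive where
`U'(r) > 0` and repulsive below the zero crossing
`r* = ln(C_R l_A / (C_A l_R)) / (1/l_R - 1/l_A)`.  Integration is classical
fixed-step RK4 (`dt = 0.1` default); separations are clamped at 1e-9 to
keep near-coincident initial draws finite, and exactly coincident pairs
raise a named error.  Four presets (`MORSE_PRESETS["a"–"d"]`) span the
model's emergent states (double mill; mills/swarm; parallel/swarm; swarm).

Initial conditions: positions uniform in a 100-unit square, directions
uniform, initial speed `sqrt(alpha/beta)`.  A literal `alpha/beta` initial
speed is available via `init_speed_mode="ratio"`; the square-root form is
the default because it is the model's equilibrium speed, consistent with
groups stabilising within a few thousand steps, whereas the literal
quotient starts item-b groups at eight times equilibrium.

## Kinematics

All responses are forward differences of saved positions: velocity
`u = (x(t+dt) - x(t))/dt`; unit headings from velocities; unsigned heading
change by arccos of the clamped dot product (clamping guards |dot| > 1 by
rounding); rotation sense from the sign of the planar cross product, with
|cross| < 1e-12 treated as collinear, in which case the positive branch is
taken; the signed turn rate in deg/s is `(180/pi) * lambda * psi / dt`.
Speed change is the forward difference of speeds.  Zero-speed frames make
headings and turns undefined; undefined values are explicit `NaN`s and are
excluded from all downstream binning, never silently zeroed.

## The averaging (force-matching) method

For every ordered (focal, partner) pair at every time with defined focal
heading and responses, the partner position is rewritten in the focal frame
(focal at the origin, heading along +x; bearing positive to the left) and
the focal's turn rate and speed change are deposited into every overlapping
square bin containing the point.  Bins have side `w`, centre spacing `c`
and cover `[-L, L]^2`; membership is half-open per axis so a sample's bin
set is unambiguous.  Defaults: `w = 1`, `c = 0.5` (50 % overlap),
`L = 15` (covers attraction radii up to 14); a fine preset
(`w = 0.25`, `c = 0.125`, `L = 3`) resolves sub-unit repulsion zones.  A
bin is defined from one sample (empty bins are explicit `NaN`, rendered
white).  Surfaces store raw count/sum/sum-of-squares accumulators so
replicate pooling is exact, and can be conditioned on focal speed
(default: five equal-count quantile classes).  Time windows (`first_half`
/ `second_half`) split the response index range exactly, so the two half
windows always partition the full window.

## Order parameters, fragmentation and state labels

Polarisation `p = |sum_i h_i|/N` and angular momentum
`m = |sum_i rhat_ic x h_i|/N` (unit centroid-to-agent vectors crossed with
unit headings, scalar z-component; the signed mean retains the rotation
sense) are averaged over the second half of a run.  Groups that do not
fragment are labelled *parallel aligned* (`p > 0.65`, `m < 0.35`) or
*cohesion* — swarm (`p < 0.35`, `m < 0.35`) or mill (`p < 0.35`,
`m > 0.65`, sense from the signed mean).  Order parameters falling in the
threshold gaps leave a replicate *unclassified*; it is then not pooled.

Fragmentation is evaluated on the neighbour graph linking individuals
within `link_radius` (default: `r_a` for the zonal model, `2 r*` for the
ODE model — twice the equilibrium spacing, because members of an intact
Morse swarm sit *at* the equilibrium spacing and a link radius equal to it
disconnects intact mills).  A replicate is fragmented — overriding every
other label — when more than one component with at least two members is
present in over half of the window frames.  Counting only multi-member
components is deliberate: a lone straggler temporarily outside the
interaction range does not split a group, and treating it as a fragment
would discard the majority of otherwise cohesive replicates.

## Zone-geometry estimation

On a mean turn-rate surface, repulsion appears as near-field bins whose
mean turn is directed *away* from the partner (negative for partners on
the left, `y > 0`; positive on the right).  A bin is *sign-consistent*
when its away-signed mean exceeds 5 % of the surface's maximum absolute
mean; bins exactly on the x-axis carry no left/right information and are
never sign-consistent.  Group-level movement patterns can imprint
repulsion-signed patches at larger ranges (e.g. behind individuals in
polarised groups), so the estimators keep only the connected component of
sign-consistent bins nearest the origin on each side of the heading axis.

Before any geometry is measured, the turn-rate surface is
mirror-antisymmetrised by default: each bin is combined, count-weighted,
with the negated value of its reflection through the heading axis.  A
left/right-symmetric interaction rule implies `field(x, −y) = −field(x, y)`
exactly, so this leaves the true response untouched — but it cancels the
common-mode turn-rate offset contributed by pooled milling replicates whose
rotation senses do not balance, which otherwise distorts the rear wedge by
tens of degrees on unlucky ensembles.  Raw, non-symmetrised estimation
remains available (`symmetrise=False`), and is what the asymmetric-wedge
definition examples exercise.

* **Repulsion radius**: three rays at bearings +90°, +45°, −45° are walked
  outward in bin-centre steps; each contributes the outermost bin centre
  still inside the contiguous sign-consistent region, and the circle
  through the three points (perpendicular-bisector circumcircle) gives the
  apparent radius.  The point picking is deterministic, replacing
  by-inspection selection with an algorithm so estimates are reproducible.
* **Blind angle**: within the outer half of the fitted disc (annulus
  `[R/2, R]`, where repulsion is strongest and partner-position
  correlations distort the field least), bearings are scanned from dead
  astern towards dead ahead on each side; the first bearings showing a
  sign-consistent bin bound the rear wedge, and for edges `b1 > 0 > b2`
  the blind angle is `(180 - b1) + (180 + b2)`.  A wedge narrower than
  30° reports "no blind zone evident" — prescribed blind angles of
  interest (90°) and their absence (0°) are far from this threshold.

Bin geometry matters for the wedge: each edge carries a bearing-snap bias
of roughly `atan(c / (2 r_inner))`, so wedges should be measured on grids
whose spacing is small relative to the repulsion radius.  On the default
grid (`w = 1`) the wedge of a 1.5–2-unit repulsion zone is eaten by tens
of degrees; blind angles are therefore estimated on the fine grid.

## Analytic pairwise baselines

Closed-form single-partner response fields serve as comparison panels and
independent oracles.  For the zonal model (noise ignored): a visible
repulsion-zone partner at bearing `b` drives a turn of
`sign * min(|wrap(b + 180)|/dt, theta_max)` deg/s; an attraction-zone
partner likewise towards `b`; orientation-zone partners contribute zero by
convention, since their response depends on partner heading, which a
position-only field cannot express.  For the ODE model, the Morse force
resolves into a tangential component `(1/N) U'(d) cos(bearing)` (the speed
change, independent of focal speed) and a normal component giving a turn
rate of `(180/pi) U'(d) sin(bearing) / (N s)`.

When validating the averaging pipeline against these fields, the oracle is
evaluated *per sample* and pushed through the identical binning machinery,
rather than evaluated at bin centres: near-field Morse forces vary several-
fold across one bin, and the per-sample construction compares like with
like.  Two-agent simulations are used for these checks because with `N = 2`
the measured turning is exactly the pairwise normal force (self-propulsion
acts along the velocity), so any residual disagreement isolates
finite-difference and sampling error.  Agreement is asserted as full sign
agreement plus a 20 % relative-error bound on the bulk (90th percentile) of
well-populated bins, with the error denominator floored at 5 % of the field
maximum; per-bin bounds tighter than that are not statistically meaningful
at the 100-samples-per-bin threshold.

## Problem sizes and reproducibility

Zone-recovery estimates pool ten replicates of the required emergent state
(N = 25, 1000 steps each), simulating additional seeded replicates until
ten carry the label — the same collect-until-n practice used for the ODE
states, chosen because state frequencies vary strongly between parameter
rows and pooling one or two matching replicates yields ill-conditioned
surfaces.  The test suite runs reduced but representative sizes (e.g.
six 4000–6000-step ODE replicates for state statistics, 25 two-agent runs
of 2000 steps for oracle checks, roughly 1e5 pooled pair samples); these
sizes were chosen so the whole suite completes quickly while each check
retains a comfortable signal margin.  Every stochastic component draws
from `numpy` generators seeded as `[master_seed, replicate]`, so runs are
bit-reproducible and replicate streams are stable under changes to the
replicate count.

## Known limitations

* The synthetic trajectories are noise-free observations of the models
  themselves: no tracking error, missing frames, identity swaps, or
  arena boundaries.  Passing tests show the inference machinery recovers
  *prescribed* rules from clean data, not that it would from video
  tracking of real animals.
* The averaging method itself aggregates over group mates, so recovered
  zone sizes are biased by multi-partner geometry (larger groups shrink
  the apparent ODE repulsion region; emergent rotation imprints on turn
  surfaces).  These are properties of the method under study, not defects
  of the implementation.
* Orientation (alignment) interactions are not targeted by any estimator;
  the position-only surfaces cannot express them.
* The blind-angle wedge threshold (30°), sign threshold (5 % of maximum)
  and ray bearings are configurable conventions; estimates shift by a few
  percent with bin geometry, and the wedge is only resolvable on grids
  fine relative to the repulsion radius.
* Emergent-state frequencies are sensitive to the unobservable model
  details noted above (initial density, orientation weighting); the
  package exposes them as parameters rather than asserting one truth.
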