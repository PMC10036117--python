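# Methods

This note documents the models, conventions and numerical choices behind
`ymaze`, in the order data flow through the pipeline.

## Maze model

Both maze conditions are described parametrically (`ymaze.geometry`).
The frame is right-handed with the maze center at the origin, the floor
at z = 0 and azimuth counter-clockwise from +x; the goal arm C points
along 90° by default. The frame itself, and which arm pair carries the
50° separation in the geometry condition, are free conventions (nothing
in the experimental design pins them); they are the only things
`build_maze` overrides may change — the corridor dimensions, zone radii
and landmark parameters are design constants and attempts to override
them raise.

Derived geometry: each pair of azimuth-adjacent arms meets at an inner
corner at distance (w/2)/sin(γ/2) along the gap bisector (γ the gap,
w = 0.66 m the corridor width). The floor plan is the 9-vertex polygon
corner → outer-right → outer-left per arm; walls are the vertical
rectangles over its edges, closed at the arm ends, all at height
subject height + 0.10 m. The central area is the junction triangle (the
convex hull of the three corners) plus the inner third of each arm's
corridor quad, the third measured along the arm axis from the mouth
chord midpoint to the arm end — the design says "inner third" without
fixing the junction shape, so the hull construction is our documented
choice. Arm-end disks: goal/endpoint radius 0.4 m, departure radius
0.3 m, concentric at the arm ends. Because the departure circle lies
inside the endpoint disk, `point_zone`'s precedence order never returns
the departure label; `point_zones` and the disk predicates expose it.

Gaze rays are cast analytically against three surface families: wall
rectangles (either face — a ray that clears one wall can land on the
outer face of another), the floor plane z = 0 extended to the sky
sphere (a ray passing over a wall and descending hits "floor" outside
the corridor footprint), and the 6 m sky sphere about the maze center.
The nearest positive intersection wins; exact ties resolve wall < floor
< sky (a measure-zero convention). Sky hits in the landmark condition
carry a sector label: the landmark whose azimuth is nearest, boundaries
at the bisectors, exact-boundary ties to the counter-clockwise
neighbour. Landmark physical size is back-computed from the 10° design
subtense seen from the maze center at eye height (eye height defaults
to subject height − 0.10 m; the design does not state it, so it is a
configurable convention): diameter = 2·s·tan(5°) with s the slant
distance.

`ymaze.raymarch` re-derives hits by dense sampling (default step 1 mm;
wall crossings detected as flips of the even-odd footprint membership
between consecutive samples, smooth surfaces located by linear
interpolation). It shares only the maze description with the analytic
caster and serves as its cross-check; disagreements are re-marched 50×
finer and accepted only if the ray passes within tolerance of a
wall-panel edge, where surface labels genuinely meet.

## Synthetic cohorts

The simulator (`ymaze.simulate`) emulates the experimental protocol:
learning trials A → C until four consecutive successes (a failure is a
detour into arm B, drawn per trial from the profile's
`learning_error_rate`), then the six-trial test sequence B, A, A, B, A,
B. On B-start probes the agent goes to C with probability
`p_allocentric_choice`, else to A. Trajectories are waypoint polylines
resampled at constant per-trial speed (Gaussian per-trial draw) with a
quadratic-Bezier junction turn and smoothed Gaussian lateral jitter;
trials open with an orientation pause at the departure point and close
with a >5 s stop at the destination (the protocol's trial-end rule:
speed < 0.05 m/s inside an endpoint disk). View-matching agents insert
an extra stationary dwell (default 6 s) at the junction.

Gaze is generated by a state machine at 120 Hz. During orientation,
agents in the landmark condition fixate the sky sector of the landmark
facing their start arm (egocentric agents on probe trials keep
wall-level gaze instead); in the geometry condition they look down
toward the junction fork. While walking, gaze follows the heading at
wall level; view-matchers re-fixate the circle sector while inside the
central area. Per-state elevations are Gaussian (defaults: sky +25 ± 5°,
floor −30 ± 6°, walls −2 ± 4°) — values chosen once to reproduce the
qualitative dwell patterns (sky-dominant orientation in the landmark
condition, floor-dominant in the geometry condition, wall-dominant
navigation), not measured quantities. Gaze drop-out is i.i.d. Bernoulli
per sample at the study's rates (children 25 %, young 22 %, older 27 %
for both eyes at once, plus a 5 % single-eye drop that exercises the
monocular fallback). An optional `bursty` missing mode replaces the
i.i.d. draws with a two-state run-length process (mean burst ~12
samples, ~0.1 s) at the same stationary rate, since real blink losses
arrive in runs. Walking speeds (0.75–1.05 ± ~0.1 m/s by age group),
pauses (1.5–3.5 ± ~1 s) and heights are likewise documented free
parameters: the design gives no distributions for them.

Default cohort composition mirrors the study's immersive-VR cells
(n = 79 across three age groups × two conditions), with
majority-allocentric mixture weights set to the observed cell
proportions and the older landmark-condition allocentric group split
evenly between map-based and view-matching profiles. Everything flows
from one integer seed through `SeedSequence` spawning; identical
configurations are byte-identical. A `sparse` stream mode (coarser pose
sampling, no gaze, no terminal stop) exists for statistical
replication studies where only the trajectory → classification →
inference path matters; it runs the same code path through the same
classifiers. What the simulator does **not** model: biomechanical gait,
visually-driven gaze policies, vestibular disorientation, or any
rendering. Tests passing on
these cohorts therefore validate the pipeline's logic and statistics,
not the perceptual realism of the input streams.

## Trial metrics and classification

Orientation is the interval from stimulus onset until the first pose
sample outside the 0.3 m departure circle (it therefore includes the
fraction of a second needed to cross the circle at walking speed);
navigation is the remainder, ending at the first entry into the goal
disk (learning) or any endpoint disk (test), falling back to the last
sample. Escape latency is their sum by construction. Traveled distance
sums raw successive displacements over the navigation interval — no
filtering by default, since zone radii (0.3–0.4 m) are large relative
to 30 Hz steps at human walking speeds; an entry into an initially
occupied endpoint disk is only re-armed once the subject is 0.1 m
beyond its radius, so head sway at the disk boundary cannot register a
spurious re-entry. Average speed is distance over navigation duration;
normalized speed divides by subject height. Time in the central area
accumulates sample durations over the whole trial.

Per-probe strategy follows the first endpoint entered (C allocentric, A
egocentric, B or none unclassifiable); a subject is allocentric with ≥2
allocentric probes, egocentric with ≥2 egocentric probes, otherwise
unclassifiable — flagged, excluded from behavioral/gaze analyses, and
pooled with the egocentric group for the binary GLM outcome. A-start
test trials are computed but never enter strategy classification.
Sketch scoring treats the drawn landmark order as correct up to cyclic
rotation only (a mirrored order is wrong), placement as correct when
every landmark sits between arms, and the goal as correct when drawn in
the right arm relative to the landmark array.

## Gaze pipeline

Head position is linearly interpolated to the 120 Hz gaze clock and
yaw angularly interpolated on the unwrapped angle (equivalent to
spherical interpolation for a yaw-only head pose); the gaze origin is
the interpolated head position at eye height. The cyclopean direction
is the renormalized mean of the valid eyes, one eye when the other is
dropped, missing otherwise; upstream validity flags are trusted as
given, and fixations/saccades are deliberately not separated. Dwell
proportions exclude missing samples from the denominator, so
wall + floor + sky = 1 exactly whenever any usable sample exists, and
sector proportions sum exactly to the sky proportion. Time courses map
the orientation period onto 15 equal-duration bins and navigation onto
35 (time-normalized per period — bin counts are fixed by the analysis
convention, the mapping for variable-duration periods is ours), each
bin evaluated over a 1 s window centered on its midpoint and clipped at
the period edges. Heatmaps are max-normalized counts on a 2° azimuth ×
elevation grid (sky) or a 0.2 m x–y grid (floor); the grids are our
choices.

## Inference

The age × condition binomial GLM is saturated, so reported cell
probabilities are the observed proportions (identical to the ML fit
when it converges); with a perfectly separated cell the coefficient fit
falls back to a small-L2 (ridge) fit while the cell probabilities stay
the raw proportions. Second differences are computed on the probability
scale with delta-method standard errors, which for the saturated model
reduce to summed binomial cell variances; a subject-resampling
bootstrap is available as an alternative. Fisher tests use the exact
hypergeometric p and the conditional-MLE odds ratio, with one-sided
intervals [L, ∞) when a direction is stated by the caller (never
inferred from the data); φ is the binary Pearson correlation and
Cohen's w = |φ| for 2×2 tables. Rank tests report r = z/√N with z from
the tie-corrected normal approximation (no continuity correction), the
Wilcoxon z taken from the positive-rank sum; p-values come from exact
enumeration whenever scipy's exact path applies (small tie-free
samples). The power routine inverts the noncentral chi-square power
function to the smallest integer N with N·w² noncentrality reaching the
target; df defaults to 2 (three groups × binary outcome) and is an
explicit argument.

The altitude classifier is a one-predictor logistic regression with a
light L2 penalty (C = 10⁴) so perfectly separated training sets remain
well-defined while the boundary stays at the ML midpoint. Hold-out
validation stratifies the 25 % split by class by default, re-draws
splits that leave a class absent from training, and reports the
fraction of repetitions with below-half accuracy as the p-value.
A subtlety worth knowing when interpreting that p-value under null
(uninformative) features: within any one finite dataset, chance
feature–label associations are shared by the training and held-out
halves, so the per-dataset p-value is roughly uniform rather than
pinned at 0.5, and an accuracy atom at exactly ½ (even held-out counts)
biases it downward. Averaged over independent balanced datasets of a
few hundred subjects the p-value centers on 0.5, which is how the
chance-level checks are implemented.

## Problem sizes and checks

The test suite and `scripts/acceptance.py` use these sizes, chosen as a
balance between statistical resolution and a single-CPU run: 10⁵ random
interior rays (0.5 mm marching step) for the caster/oracle comparison;
200 subjects/cell × 100 replicate cohorts (sparse streams, three
B-probes each) for recovery of the generating cell probabilities and
the children-vs-young second difference — the recovery target is the
implied majority probability q = 3p²(1−p) + p³ of the per-trial choice
probability p, and the generating Δ₀ is computed on that scale; a
~50-subject full-stream cohort for the dwell/latency conservation laws;
500 subjects/class for the two-Gaussian classifier checks against the
closed-form Bayes accuracy Φ(d/2); and every 2×2 table with group sizes
≤ 8 plus tie-free rank-test samples up to 8 per group against
enumeration oracles.

## Known limitations

Cohort-scale empirical quantities (cell proportions, dwell
percentages, classifier accuracies on real recordings) depend on the
recorded data and are only emulated here at the qualitative level the
simulator encodes. Bayes-factor analyses and the visuo-cognitive
battery PCA are out of scope. The OSF-deposit reader is a schema-driven
adapter stub (`ymaze.io.read_trials` with a documented column
dictionary), not a tested ingestion path for the deposit's native
layout.
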