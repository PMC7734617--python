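# Methods

This note documents the models, conventions and numerical choices behind
`starmaze`. It is written for users who want to understand exactly what the
package computes, which parts are pinned conventions, and what the synthetic
cohorts do and do not establish about real recordings.

## The task and its geometry

The star maze is a regular pentagon with five corridors ("alleys") radiating
from its vertices. The navigator starts at the far end of one alley; a reward
sits at the far end of one or two alleys, invisible until reached, with a
2-minute limit per trial. Landmarks between adjacent alley ends support
allocentric (world-centred) navigation; removing them forces egocentric
(body-centred) navigation.

Coordinates are planar metres, origin at the pentagon centroid, alley 1
pointing along +y, alley *i* at heading 90° + (i−1)·72° counter-clockwise.
The source task never published its dimensions; the only calibration
constraint is that the ideal alley-1 → alley-3 route is 246 m long. The
default configuration therefore keeps a circumradius of 8 m, an alley width
of 4 m and a 2 m reward-capture radius, and solves the alley length
(≈ 115.39 m) from the 246 m constraint. All dimensions are configurable;
every derived quantity recomputes from the configured geometry.

**Ideal path convention.** The ideal path between two alley ends descends the
start alley along its axis, crosses the centre pentagon along the
vertex-to-vertex chord (inside the pentagon by convexity) and ascends the
goal alley: for 1 → 3 this is 115.39 + 15.22 + 115.39 = 246 m with a minimum
rotation of 36° (two 18° corner turns). With a corridor of nonzero width,
slightly shorter diagonal paths that cut corners inside the corridors exist
(≈ 1 m shorter at the default width); the ideal is pinned to the
corridor-axis route, which is what the published 246 m figure describes. The
turn-around path (start = goal, needed when a test trial returns to its own
alley) is the out-and-back stub with a 180° rotation.

## Trial metrics

Seven parameters per trial: success, time to reward, visited alleys, total
path length (TPL), duration, mean speed, distance error (DE) and rotation
angle (RA).

* **Capture.** The reward triggers at the capture radius. The crossing of
  the capture boundary is interpolated within the entering segment, so
  capture time and travelled distance are exact for piecewise-linear motion.
* **Capture completion.** On success the path is truncated at the crossing
  and completed with the straight stub from the crossing point to the reward
  coordinate. A perfect run then has TPL exactly 246 m and
  DE = 100·(travelled − ideal)/ideal exactly 0, and DE ≥ 0 holds for every
  successful run by minimality of the axis route. Without this convention a
  perfect run would read ~244 m and DE ≈ −0.8%. On failure the full recorded
  path is compared against the nearer reward's ideal path.
* **Mean speed** is distance actually walked over time actually walked
  (the completion stub, on which no time is spent, is excluded); an
  instantaneous-mean alternative is available via `speed_mode`. The source
  report's stable-trial medians (~10 m/s over 246 m in ~30 s) are mutually
  inconsistent as medians of ratios versus ratios of medians; no attempt is
  made to reproduce that inconsistency.
* **Visited alleys.** An alley counts as visited when a sample lies deeper
  than `depth_fraction` (default 0.10) of the alley length past the pentagon
  vertex, within the corridor; the start alley always counts; entry order is
  kept; samples after capture are ignored. The entry threshold is a
  convention — the original analysis never defines "entering" an alley.
* **Rotation.** Headings are taken between path points decimated to at least
  `min_step` = 0.05 m of travelled arc, which suppresses jitter-induced
  heading noise; the participant's rotation is the summed absolute heading
  change, and RA subtracts the ideal path's minimum rotation. RA of a
  sampled ideal route is zero to ~1e-8 degrees; decimation can wiggle a few
  degrees around tangent points of curved detours. RA can be slightly
  negative through discretisation and is reported as computed. Heading comes
  from positions, not body orientation — orientation traces are not part of
  the data model.

## Strategy classification

On test trials (start alley 4, rewards in alleys 1 and 3): AS = success at
alley 3 with exactly two visited alleys; ES = success at alley 1 with
exactly two visited alleys; otherwise no efficient strategy. Participant
labels from the five test trials, in precedence order: Allocentric
(≥ 4 consecutive AS, no ES), Egocentric (symmetric), Shifter (both AS and
ES appear), Lacking (≥ 4 NoEfficient); residual patterns fall back to
Lacking. "More than three consecutive" is read as ≥ 4 of 5, consistent with
the ≥ 4 reading of the Lacking rule; `consecutive_threshold=3` selects the
laxer reading. Compelled trials succeed only with a direct two-alley route.

Learning onset is the smallest training trial from which success never fails
again (missing trials count as failures). Default onset bins: trial 1; 2–3;
4–7; late (8–16); never stable. The source text is internally inconsistent
about the third bin's upper edge (4–6 by its methods, 8+ appears in its
results); the edges are configurable and the default follows the 4–7
reading.

## Stabilization ("knee") detection

The knee was originally found visually and then verified; here the search is
explicit so that it is reproducible. Over training trials 1..16 and the four
metrics (visited alleys, TPL, DE, RA), the knee is the smallest candidate
k ∈ 2..15 such that for **all four** metrics a Friedman test over trials
k..16 is non-significant (p > α_stable, default 0.05) and a paired Wilcoxon
signed-rank test between trials k−1 and k is significant (p < α_change,
default 0.05). Full per-candidate diagnostics are returned.

Conventions: Wilcoxon drops zero differences, exact null for small samples
without ties, normal approximation otherwise (scipy's defaults, pinned by
tests); complete-case deletion per test; identical repeated measures count
as perfectly stable (p = 1); at k = 15 only two post-knee trials remain, too
few for Friedman, so stability is assessed by the paired Wilcoxon between
trials 15 and 16.

Two properties of this rule are worth knowing. It never mislocalises a
sharp step (rank tests see the step at exactly one candidate), but the
four-fold conjunction is conservative: a chance Friedman rejection in any
metric vetoes a candidate, and smooth geometric learning curves — as
produced by the simulator's gradual error decay — may present no single
trial-to-trial drop large enough for the Wilcoxon, in which case no knee is
reported. That is a statement about the data, not a failure mode, and the
diagnostics make it inspectable.

## Group statistics

Pinned conventions (the original analyses ran in a commercial package whose
tie handling is undocumented): Mann-Whitney U exact when there are no ties
and min(n) ≤ 8, otherwise tie-corrected normal approximation without
continuity correction, two-sided; 2×2 gender tables by Pearson chi-square
without continuity correction (this reproduces the published p = 0.063;
the Yates-corrected value does not); continuous variables gated by a
Lilliefors normality test at α = 0.05 into an unpaired t-test or
Mann-Whitney; Spearman correlations between per-participant pre-knee metric
medians (trials 1..knee−1 of the participant's group) and the Corsi,
Labyrinth and Raven z-scores, pooled across groups with pairwise deletion;
no multiple-testing correction anywhere (none was applied originally).
Post-hoc power of the two-sample t-test uses the noncentral t distribution
with noncentrality d·√(n1·n2/(n1+n2)); the published 0.82 for 13 vs 15 at
d = 1, α = 0.05 is the one-tailed value, so one-tailed is the default.

## The simulator

The generator exists so that every pipeline stage is testable without
recordings. Agents steer between waypoints (alley end → vertex → chord →
vertex → alley end) at a per-trial lognormal speed (mean 8.5 m/s, sd
1.5 m/s — the task's virtual speeds are fast; a 246 m run takes ~30 s,
matching the stable-trial times) sampled at 120 Hz, with temporally
smoothed Gaussian positional jitter (pointwise sd 0.5 m, 1 s smoothing)
emulating sway and steering noise. The jitter tapers to zero over the final
two seconds: an agent homes onto the goal it steers at, so planned captures
are never lost to sway.

Strategies: the egocentric agent replays the trained start-relative offset
(+2 alleys), so it reaches alley 1 from the test start and misses from the
compelled-allocentric starts; the allocentric agent steers to the
landmark-defined alley 3 from any cued start and degrades to wandering in
the bare maze; the shifter alternates competences across test trials
(switch probability 1.0 by default, i.e. deterministic alternation, so a
noiseless shifter is recovered with certainty); the lost agent picks random
alleys with no reward memory, committing to the far end with probability
0.3 and otherwise peeking 30–80% in — children without a strategy explore
incompletely far more often than they walk a wrong alley to its end.

Learning is an error probability p(t) = p₀·(1−λ)^(t−1) over training trials
(defaults p₀ = 0.6, λ = 0.5). On an error the agent detours through one to
three wrong alleys, peeking 25–75% in (it knows they are not the goal),
before resuming; long detour chains run out the 120 s clock and fail
naturally. Per-agent learning rates vary with a latent aptitude
(λᵢ = λ₀ + 0.18·aᵢ, aᵢ ~ N(group mean, 1)), and the test z-scores are
generated with planted monotone links to that aptitude
(corsi_z = 0.2 + 0.55·a + ε(0.5); labyrinth_z = 0.3 + 0.5·a + ε(0.7);
raven_z = 0.15·a + ε(1.0)), giving the learning-phase correlations a
synthetic analogue with a known sign.

Two presets: `study_cohort_config` emulates the pilot cohort (13 TD vs
15 CP; strategy mixtures at the observed shares; the CP group half an
aptitude unit lower, hence slower learning); `recovery_cohort_config` is a
single 200-agent group (40% egocentric, 40% allocentric, 10% shifter, 10%
lost) for parameter-recovery experiments, with a noiseless variant (zero
jitter and error probability) that drops the lost class — "noiseless" is
meaningful only for agents executing a strategy, as the lost agent's
randomness is its behaviour, not noise.

What the simulator does **not** emulate: body/pelvis kinematics, platform
dynamics, visual rendering, fatigue, or any within-trial adaptation.
Passing recovery tests therefore show that the pipeline inverts its own
generative assumptions at realistic noise levels, not that it is calibrated
to real recordings; the deposited-data reproduction is a separate check
that requires downloading the original archive.

## Problem sizes and determinism

All randomness flows from explicit integer seeds (protocol counterbalancing,
cohort generation, test oracles), and simulated cohorts are byte-identical
across runs of the same configuration. The test suite uses desk-scale
problem sizes chosen to make the statistical assertions sharp but cheap:
200 agents for strategy recovery (binomial SE ≈ 1% at 95% accuracy), 1000
replicates for the type-I-error calibration (Monte-Carlo SE ≈ 0.7%), 10–12
participants for knee constructions, and 5–12 participants for end-to-end
pipeline runs.

## Known limitations

* The maze geometry is calibrated, not reconstructed; only ratios anchored
  to the 246 m ideal are meaningful in metres.
* The knee rule's four-fold conjunction is conservative (see above); use
  the diagnostics, and α thresholds, deliberately.
* Whether the original metrics were truncated at capture, and whether RA
  used pelvis orientation rather than path heading, is unknown; the
  conventions here are self-consistent and pinned by tests but may differ
  from the original Matlab computation in detail.
* The deposited archive's internal layout is not described in the source;
  `trajectory_io` reads a documented manifest layout and a column-mapping
  dialect is provided for converting foreign CSVs.
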