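# Methods

## Sleep scoring

A sleep bout is a maximal run of consecutive minutes with zero beam-break
counts whose length is at least `threshold_min` (default 5, the standard
*Drosophila* inactivity criterion; the threshold is a configuration knob).
Scoring depends only on the zero/nonzero pattern, so it is invariant to any
rescaling of counts. Conventions that matter at the edges:

- **Record edges.** A qualifying zero run touching the start or end of the
  record counts as a bout, truncated at the record limit; nothing is known
  beyond the record.
- **Window clipping.** Metrics over a window `[a, b)` clip bouts at the
  window edges: total sleep is the summed overlap, bout number counts bouts
  with nonzero overlap, and mean bout duration averages the *overlapped*
  portions. A bout spanning two adjacent windows contributes to both, and
  totals are conserved: per-window totals over a partition sum to the
  whole-record total. The same conservation ties sleep profiles (per-bin
  minutes asleep, default 30-min bins) to window totals.
- **No bouts.** Mean bout duration with zero bouts is reported as missing
  (`None`/blank), never 0: zero would conflate "no sleep" with "brief
  sleep" and bias downstream averages.

## Time bookkeeping

ZT (Zeitgeber time) is hours since lights-on; the design maps a wall-clock
lights-on time (default 06:30) to ZT0 and fixes the photoperiod
(`light_hours + dark_hours = 24`, default 12:12). Timestamps in monitor
files are naive local clock time; the design, not the file, defines the LD
cycle. Two design fields pin ST (starvation time) windows to series minute
coordinates: `recording_start_zt` (ZT of minute 0; recordings conventionally
start at lights-on, default 0) and `starvation_day` (which recorded cycle
food deprivation begins in, default 0).

The **first LD shift** after a starvation start at ZT *s* is the earliest
transition among {ZT0, ZT `light_hours`} *strictly* after *s*: a start
exactly at a transition points to the next one. In 12:12 this gives
starts ZT0/ZT6/ZT12/ZT18 → shifts ZT12/ZT12/ZT0/ZT0 at ST 12/6/12/6, and a
ZT12 start maps ST12–ST24 onto the ZT0–ZT12 light phase of the next cycle —
the windowing convention all default analyses use. Because shifts sit on
phase boundaries and each phase lasts 12 h in 12:12, the 12-h post-shift
window always spans a single phase.

## Starvation-induced sleep loss and statistics

`loss% = 100 × (fed_mean − starved_mean) / fed_mean` on cohort means of
total sleep over a common ST window (default ST12–ST24); negative values
are legal and meaningful (starved flies sleeping more). Loss is computed on
group means because fed and starved arms are independent cohorts; the only
well-defined unpaired per-fly variant (per-starved-fly loss against the fed
mean) has exactly the same mean, so it is not a separate estimator — but
those per-fly values are exposed (`per_fly_loss_values`) because they are
the sample that cross-genotype ANOVA on loss needs.

Two-sample comparisons default to Student's t (equal variance), with
Welch's t available; multi-group comparisons are one-way ANOVA with
Dunnett's test (each genotype vs a named control) or Tukey's HSD (all
pairs), delegated to scipy. Pinned degenerate conventions: identical
samples give t = 0, p = 1; zero variance in both samples with equal means
gives p = 1 (with unequal means, an infinite statistic and p = 0); a
dataset in which every observation is equal gives F = 0 and all adjusted
p = 1. Note that a Dunnett/Tukey adjusted p can be *smaller* than a plain
two-sample t-test p for the same contrast, because the post-hoc tests pool
variance across all groups with more degrees of freedom; adjustment is
guaranteed non-decreasing only against the unadjusted test built on the
same pooled error model, which is what the test suite checks.

A configurable dead-fly rule (exclude fed-arm flies with zero counts over
the final *N* hours, default 12) is provided but off by default; its
parameters are a pragmatic default, not a claim about any particular lab's
criterion.

## Defasciculation index

Rings are `k × ring_spacing_um` for k = 1..`n_rings` (defaults 15 rings,
10 µm — the spacing is micrometers; a centimetre-scale Sholl field is not
physically meaningful for a fly brain hemisphere, and typical s-LNv dorsal
projections span ~150 µm). The cone is parameterised by its *full* apex
angle (default 15°, i.e. ±7.5° about the centre line); both knobs are
configurable.

- **Crossing detection** solves the segment/circle quadratic exactly per
  polyline segment and ring. Tangential touches (double roots) and
  polyline vertices lying exactly on a ring (shared by two consecutive
  segments) count once: within a branch, a candidate within 1e-9 µm of an
  already-recorded crossing on the same ring is discarded. A chord crossing
  a ring twice, or an out-and-back excursion, counts twice, as it should.
- **Cone orientation** is found exactly via the anchor argument: an optimal
  cone can be rotated until one edge touches a crossing angle, so centres at
  `angle ± w/2` (plus the angles themselves) exhaust the optima. Membership
  on the cone boundary uses a 1e-9° tolerance. Ties in the maximal in-cone
  count are broken toward the smallest candidate centre in [0, 360) for
  determinism; ties never change DI, only the reported orientation.
- **DI = (total − in_cone) / total**, undefined (raised as an error) when
  total = 0; reporting 0 would claim perfect fasciculation from no
  evidence.
- **3-D input** (SWC with nonzero z) is projected by dropping z, matching
  tracing on maximum-intensity projections; `project_3d=False` rejects it
  instead.
- DI is computed per hemisphere (per input skeleton). Aggregation across
  hemispheres of a brain is left to the batch grouping, since the natural
  experimental unit is a reporting choice.

Invariants the implementation maintains (and the suite verifies):
conservation (`in_cone + outside = total`), rotation invariance of DI about
the root, covariance under joint scaling of skeleton and ring spacing, and
monotone non-increase of DI in cone width.

## Synthetic data

**Sleep/wake generator.** A two-state chain at 1-min resolution: awake →
asleep with per-minute probability `p_init(phase)`; asleep → awake with
probability `1/bout_len_mean(phase)`, so bout lengths are geometric
(memoryless — chosen for closed-form tractability; the recovery checks
depend only on stationary fractions, not dwell shape). Awake minutes emit
Poisson(`active_count_rate`) counts clamped to ≥ 1 so count noise can never
masquerade as sleep; asleep minutes emit 0. The initial state is drawn from
the minute-0 stationary distribution. Defaults
(`p_init` 0.05 light / 0.10 dark, mean bouts 20 / 40 min,
`active_count_rate` 2) give stationary sleep fractions of 0.5 (light) and
0.8 (dark) — a realistic wild-type LD pattern with consolidated night
sleep. Starvation multiplies `p_init` by `starvation_init_multiplier`
(default 0.5) from the first post-starvation LD shift onward, in the
starved arm only; a duration multiplier exists but defaults to 1 (off),
because the effect structure being modelled is "harder to fall asleep",
not "shorter sleep".

**Closed-form expected loss.** For geometric dwells the stationary fraction
of minutes inside *scored* (≥ T-min) bouts is
`E[L·1(L≥T)] / (E[L] + E[W])` with `E[L·1(L≥T)] = T x^(T−1) + x^T/q`,
`x = 1 − q`; `expected_sleep_loss` phase-weights this over the 12-h
post-shift window with and without the starvation multipliers. In a
single-phase window with no duration effect the truncation factor is common
to both arms and cancels, reducing to
`100 × (1 − [p′/(p′+q)] / [p/(p+q)])` (33.33% for the default multiplier
0.5 in the light phase). Neglected: bout clipping at window boundaries and
the relaxation from the fed stationary state during the first ~`1/(p′+q)`
minutes after the shift — both of order a couple of minutes against a
720-min window, well inside Monte-Carlo error at cohort sizes of 32.

**Arbors** are stars of `n_branches` polylines from the root: initial
direction trunk + Normal(0, `spread_sigma_deg`), per-1-µm-step heading
noise Normal(0, `wiggle_deg`), default length 170 µm so straight rays cross
all 15 default rings. Mean DI is strictly increasing in `spread_sigma_deg`
under common random numbers, which is the ground-truth ordering the DI
recovery checks use.

**Determinism.** All generators run on numpy's PCG64; cohorts derive
per-fly seeds via `SeedSequence((master_seed, arm_index, fly_index))`, so a
master seed reproduces a cohort exactly and arms are independent.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: circadian modulation within a phase (siesta
timing, evening anticipation), homeostatic rebound after deprivation,
starvation-induced locomotor hyperactivity, inter-fly parameter
heterogeneity, monitor artefacts (dead flies, status glitches, beam
misalignment), and in arbors: curvature trends, varicosities, true 3-D
structure, or day/night remodelling. The pipeline's correctness claims are
about its computations, not about any biological inference from real
recordings.

## Problem sizes

The test suite and acceptance script size their simulations for tight
statistical checks at interactive runtimes: 1,000 random days for the
scoring oracle, 200 arbors for DI oracle equivalence (dense resampling at
0.01 µm), 100 replicate cohorts of 32 flies/arm for effect-structure
recovery, 2,000 replicates for the type-I-error check, and 300 flies/arm
for the closed-form consistency check. The full default suite runs in well
under a minute of simulation time.

## Known limitations

- The DAM reader treats status codes only as valid/invalid; firmware
  semantics beyond that are out of scope, as are multibeam monitors.
- SWC output requires branches rooted at the arbor root (the generator's
  shape); arbitrary skeletons round-trip through the CSV polyline dialect.
- Non-12:12 photoperiods are supported by the windowing arithmetic, but the
  "post-shift window is one phase" simplification in `expected_sleep_loss`
  then no longer holds exactly; the function phase-weights correctly, while
  boundary effects grow with the number of phase changes in the window.
- No circadian period estimation, DD analysis, or survival analysis.
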