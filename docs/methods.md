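# Methods

This note documents the models, rules and numerical choices behind `ethodev`,
in the spirit of a methods appendix: what each stage assumes, which knobs
matter, and what the synthetic tests do and do not demonstrate.

## Data model

A recording session is a `TrackSet`: per-frame (x, y) centroids in cm for a
gerbil family (2 adults, up to 4 pups) in a 35.6 × 57.2 cm home cage, with a
wall-clock anchor, a postnatal-day label per frame, and per-day recording
coverage. Coordinates use a corner origin with x along the 57.2 cm axis.
Frame indices are 0-based; intervals are half-open `[start, end)`; postnatal
days change at wall-clock midnight (chosen for calendar consistency; the
recording protocol does not fix a convention). Missing positions are NaN —
in this paradigm an animal's open-field track lapses when it joins a huddle,
and that missingness is informative (see *Huddle time*).

Daily rates are rescaled by recorded coverage (`observed / coverage`) to
correct the ~10% downtime between recording chunks, making days comparable.
The light schedule defaults to lights-on 08:00–20:00 with the half-open
convention (08:00:00 is day; 20:00:00 is night).

## Track repair

**Identity switches.** The error mode is segment-level: a tracker exchanges
two animals' labels from some frame onward. The detector flags frame *f*
for pair (A, B) when A's one-frame displacement exceeds `jump_cm`
(default 10 cm/frame ≈ 2.5 m/s at 25 fps, beyond gerbil locomotion) while
B's position at *f* continues A's track within `refit_cm` (default 0.5 cm,
about 5 px at a typical overhead-camera scale), or symmetrically. Both
thresholds are configuration. Frames separated by recording downtime are
never compared. When displacements above `jump_cm` are *routine* at the
data's sampling interval (coarsely subsampled data), the jump criterion
cannot separate tracker errors from locomotion, and the pipeline skips
detection with a warning rather than emit noise.

**Correction semantics.** Segment-level swaps compose as transpositions
applied from their frame to the end of the session. The corrector therefore
applies detected events newest-first, each from its frame to the session
end — the exact algebraic inverse — so sessions with multiple switches
sharing an animal are restored exactly. A "swap only until the next event
involving either animal" scope is available (`scope="next_involving"`) but
is not an exact inverse when swap pairs overlap.

**Gap bridging.** A missing run for one animal is linearly interpolated iff
its flanking positions are < 3 cm apart — close enough that the animal
cannot have gone far — which also bounds every interpolated step below
3 cm. Huddle intervals less than 30 s apart are merged (same nest site,
momentary tracker dropout), with duration-weighted centroids.

**Cage-cleaning days.** A disturbed day's value is replaced per animal by
the mean of its two flanking days (e.g., P24 by the mean of P23 and P25).

## Behavior classification

All detectors run on per-frame **median centroids** (per-axis median over
the six skeleton nodes when poses are present), which damp single-node
errors.

- **ROI occupancy** — closed rectangles; food hopper 19.50 × 10.50 cm and
  waterspout 8.50 × 8.00 cm (sizes fixed by the apparatus; corner placement
  is configuration). Seeded random-placement control ROIs are provided.
- **Open exploration** — tracked frames outside the nest region. The nest
  region is inferred per dataset as the duration-weighted modal huddle
  centroid (snapped to a 1 cm grid) dilated to a 12 cm disc; a fixed-ROI
  override exists.
- **Distance traveled** — summed consecutive-frame displacements, skipping
  pairs that span missing data or downtime.
- **Pairwise proximity** — maximal runs strictly closer than 5 cm lasting
  strictly more than 200 ms.
- **Group membership** — connected components of the per-frame contact
  graph (pairs < 5 cm); reported as daily hours in groups of size 1, 2, 3+,
  and pup-only vs with-adult groups. Components are computed by boolean
  transitive closure, vectorized over frames.
- **Approaches** — rule-based implementation of the operational definition:
  a maximal movement bout of the initiator (5-frame-smoothed speed ≥ 2 cm/s,
  extended until it drops below 1 cm/s) that closes at least half the
  initial inter-animal distance and ends within one gerbil length (10 cm
  adult default; 6 cm is a sensible pup value) or in contact (2 cm). A
  trained classifier could substitute here; the rule-based detector
  implements the verbal definition directly and is deterministic.
- **Huddle time** — an animal is huddling when a huddle is active and its
  centroid lies within 6 cm of the huddle centroid *or* its track is
  missing (animals vanish from open-field tracking when huddled). The
  missing-track attribution is the default because it matches how the
  tracking pipeline behaves at the nest; proximity-only attribution is a
  flag.
- **Nest following** — a pup exit followed by an adult exit within 10 s;
  each adult exit matches at most one pup exit (earliest unmatched).

Every recorded frame falls in exactly one of {huddling, open, tracked in
nest, unattributed}, so the four daily totals close to 24 h after coverage
rescaling — a conservation law the tests assert to one second.

## Developmental statistics

**Adult normalization.** Pup values are divided by the mean of the two
adults at the P29 reference day (adults are stable by then), so 1.0 means
"at adult level".

**Rapid-development days.** For each day the cross-animal value distribution
is compared with the pooled previous two days by a two-sample
Kolmogorov–Smirnov test; p-values are Benjamini–Hochberg adjusted within
behavior, threshold 0.05. Pooling two previous days is a variance-robust
alternative to smoothing; K-S is distribution-free and conservative.
A variant additionally requiring a difference from the *following* day
(`comparison="both"`) exists, but note that under it a sustained step is
never flagged — the step day and its successor are identically distributed —
so the previous-days-only rule is the default. All pups are pooled across
cohorts before testing (12 pups at full design size).

**Convex-hull overlap.** Each animal's multi-day trajectory is one point;
a single PCA is fitted on the concatenation of the two behaviors being
compared (so both hulls share one coordinate frame) and the first 3
components are kept, falling back to 2 when either point set is degenerate.
Overlap = 100 × vol(A ∩ B) / vol(A ∪ B) (Jaccard — symmetric and bounded;
the denominator is configurable). Volumes are estimated by seeded uniform
rejection sampling (2 × 10⁵ points) over the joint bounding box, which is
dimension-agnostic and oracle-checkable; for half-shifted unit cubes it
reproduces the closed-form 33.3% within ±1.

**Identity shuffling / correlations.** The shuffle control permutes animal
labels independently per day, preserving daily marginals while destroying
individual trajectories. Pearson correlations over the day axis are grouped
within/between behavior, real/shuffled.

**Power utility.** Monte-Carlo power of a two-sided Welch test. Note that
at n = 3 the Satterthwaite approximation is conservative (measured null
rejection ≈ 0.032 at α = 0.05); with the planted effect (means 0 vs 1 on
the adult-relative scale, sds 0.10/0.20) power is ≈ 98%, comfortably above
the 80% planning threshold.

## Social-state networks

The floor is a 5 × 4 grid (5 columns along the 57.2 cm axis: 11.44 cm;
4 rows along the 35.6 cm axis: 8.9 cm — about 11 × 9 cm cells). Cell edges
are half-open with the wall-side row/column closed; a point exactly on an
interior boundary belongs to the higher-index cell. A frame's state is the
20-vector of subset-animal counts per cell; its sum equals the number of
tracked subset animals. Supported subset families: single pups, animal
pairs, all pups, all animals (14 networks per day at full family size).

The day's graph connects consecutive distinct states (consecutive identical
states collapse; repeated transitions deduplicate; downtime gaps create no
edge). Metrics: node count; **independent cycle count** = circuit rank
(edges − nodes + components) of the undirected simple projection —
deterministic and polynomial, matching an "unrepeated cycles" reading,
with exact directed simple-cycle enumeration available behind a flag for
small graphs; **transitivity** = 3 × triangles / connected triples (0 when
no triples); **mean path length** = average shortest-path length within the
largest connected component of the undirected projection.

## Circadian analysis

Behavior seconds accumulate into 24 wall-clock hour bins (bouts split
proportionally across bin edges), averaged over days, divided per bin by
recording coverage. Day/night fractions follow the light schedule.

Bhattacharyya distance between normalized profiles:
D = −ln Σᵢ √(pᵢ qᵢ); 0 iff identical, +∞ for disjoint supports (an
ε-regularized variant adds 10⁻¹² to the coefficient).

**Transition search.** Two postnatal-day breakpoints (t1, t2) split the
span into D1 = [first, t1], D2 = (t1, t2], D3 = (t2, last], each at least
2 days. The objective is the cumulative Bhattacharyya distance, summed over
animals, between each animal's mean daily normalized profile in
*successive* periods (D1 vs D2 plus D2 vs D3); the search is exhaustive and
ties break to the earliest (t1, t2), with a flat surface flagged
degenerate. Including the D1-vs-D3 pair (`pair_mode="all"`) is available
but biases t1 late: that term grows when D1 absorbs D2-like days, and on
planted three-regime data it misses the true first breakpoint. The
per-animal period profile is the mean of daily normalized profiles (equal
weight per day, robust to day-to-day volume differences). With a single
planted regime change and a three-period prior, one breakpoint lands on the
true change and the other is tie-broken — different priors give slightly
different windows, which is inherent to the method.

## Synthetic family simulator

The simulator generates the statistical structure the analysis consumes —
activity budgets, ROI dwell, huddle episodes, state occupancy — not
photorealistic kinematics.

- **Episodes.** Each animal alternates nest episodes (missing from
  open-field tracks; huddles form whenever ≥ 2 animals are nested) with
  active bouts (mean duration 6 min) placed without overlap at
  circadian-weighted times of day.
- **Movement.** A mean-reverting random walk toward per-frame goal points
  (cage center, or the food/water ROI during scripted dwells), with a hard
  per-frame step bound of 5 × speed-scale × dt and cage-bound clipping.
  Speed scale 6 cm/s.
- **Development.** Pup daily activity is flat at a baseline fraction of the
  adult level until a planted onset day, then rises as a saturating
  exponential (τ = 2 days) to a plateau fraction. The hinge form (rather
  than a symmetric logistic) gives the onset an unambiguous ground truth
  for recovery tests, and matches the biology: pups show essentially no
  independent behavior before nest emergence. Defaults: open-exploration
  baseline 0.16, plateau 0.96, onset P18; ROI ramps onset P19 from 0.10 to
  adult level. Adults are constant at 5.4 active h/day. Daily budgets get
  multiplicative lognormal noise (σ = 0.08).
- **Circadian structure.** Bout-start intensity is uniform for pups before
  the planted onset day (default P20) and day-biased with crepuscular
  Gaussian peaks (07:30 and 20:00, σ = 1.5 h) after it; adults are always
  rhythmic.
- **Downtime.** One contiguous ~6-min block is dropped per hour (10% of
  frames), and coverage records the kept fraction per day.
- **Corruption.** The swap injector plants Poisson-distributed identity
  swaps applied chronologically from their frame to session end (composing
  exactly like tracker errors). By default it plants them at frames bearing
  the detectable signature — both animals tracked, pair separation above
  the jump threshold, at least one quasi-stationary — because an undetectable
  planted swap tests nothing about the detector; `ensure_detectable=False`
  removes the filter.
- Light-weight planted-value generators (`planted_step_matrix`,
  `planted_circadian_profiles`) exercise the statistics modules directly.

**What the simulator does not emulate:** gait and pose-level kinematics,
social coordination beyond shared nest schedules, inter-individual
personality differences, sensor noise correlated with lighting, and the
slow drift of nest location across days. Passing recovery tests therefore
demonstrates that the analysis chain is a faithful inverse of this
generative structure, not that it reproduces any particular real dataset.

## Problem sizes and determinism

The full recording regime (25 fps, 15 days, 6 animals) is supported but
large; the package's own test and verification runs use reduced frame
rates (0.2–5 fps) and 2–15 simulated days, which is sound because every
behavioral threshold is expressed in seconds and centimeters, making the
classification results frame-rate-invariant. Ramp-onset recovery pools
12 pups from 3 simulated families, matching the full 3-cohort design.
All randomness flows from explicit seeds (`numpy.random.default_rng`);
pipeline stages derive independent seeds from the master seed via
`SeedSequence.spawn`, and a repeated run with the same config and seed
produces bit-identical artifacts (asserted by test).

## Known limitations

- The identity-switch detector needs a sampling interval at which real
  locomotion stays below the jump threshold; it is inapplicable to heavily
  subsampled data (the pipeline then skips it explicitly).
- Grooming, fighting, play and sexual behaviors are out of scope.
- Hull overlap is Monte-Carlo (seeded); values carry ~0.1–0.3 percentage
  points of sampling noise at the default 2 × 10⁵ samples.
- The three-period circadian prior is an assumption; data with one (or
  four) regime changes will still be forced into two breakpoints.
- Pixel-to-cm calibration cannot be inferred from pose-export files and
  must be supplied as metadata.
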