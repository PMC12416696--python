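# ethodev

Developmental ethograms from long-term multi-animal home-cage tracking.

`ethodev` is a downstream-analysis pipeline for continuous video tracking of
a rodent family — here, Mongolian gerbils: two adults and up to four pups in
a 35.6 × 57.2 cm home cage, recorded around the clock across postnatal days
P15–P30 under a 08:00–20:00 light cycle. It takes centroid (or 6-node pose)
trajectories and huddle intervals as input and produces, per animal and
postnatal day, a quantitative account of behavioral development:

- **track repair** — automatic detection and exact correction of identity
  switches between animals (jump-plus-refit criterion), bridging of short
  track gaps (< 3 cm), merging of fragmented huddles (< 30 s), and
  substitution of cage-cleaning days;
- **heuristic behavior classification** — ROI occupancy (food hopper,
  waterspout), open exploration, distance traveled, pairwise proximity
  (< 5 cm for > 200 ms), contact groups, rule-based approach detection,
  huddle time, and adults following pups out of the nest;
- **developmental statistics** — pup trajectories normalized to the adult
  mean at P29 (adult ≡ 1.0), rapid-development days via two-sample
  Kolmogorov–Smirnov tests against the pooled previous two days with
  Benjamini–Hochberg adjustment, convex-hull overlap of behaviors in a
  shared 3-PC space (Jaccard, Monte-Carlo volumes), identity-shuffle
  controls, and a Monte-Carlo power utility;
- **social-state networks** — the cage floor as a 5 × 4 grid yields a 20-D
  occupancy vector per frame; each day's directed transition graph is
  summarized by size, independent-cycle count (circuit rank), transitivity
  and mean path length;
- **circadian analysis** — hourly ethograms, day/night activity fractions,
  and an exhaustive two-breakpoint search maximizing the cumulative
  Bhattacharyya distance D = −ln Σ√(pᵢqᵢ) between each animal's mean hourly
  profiles in successive developmental periods;
- **a synthetic family simulator** with planted developmental ramps,
  circadian onsets, huddle schedules, recording downtime and injectable
  identity-swap corruption, so the whole chain is testable by parameter
  recovery without any external data.

See `docs/methods.md` for the full model and every default.

## Worked example

Simulate two days of a six-animal family at 5 fps, corrupt it with identity
swaps, repair it, and classify behavior:

```python
import pandas as pd
from ethodev import *
from ethodev.behavior_classify import infer_nest_region

tracks, huddles, truth = simulate_family(SimConfig(fps=5, days=(16, 17), seed=42))
corrupted, log = inject_id_swaps(tracks, rate_per_day=3.0, seed=7)
events = detect_id_switches(corrupted)
fixed = correct_id_switches(corrupted, events)
print("injected swaps:", len(log), "| detected:", len(events),
      "| identity accuracy after repair:", round(identity_accuracy(fixed, tracks), 4))

nest = infer_nest_region(huddles)
print(pd.DataFrame({n: open_exploration(fixed, n, nest)
                    for n in fixed.animal_names}).T.round(2))
```

prints

```
injected swaps: 6 | detected: 6 | identity accuracy after repair: 1.0
          16    17
female  5.67  5.39
male    5.81  4.88
pup1    0.84  1.00
pup2    0.96  0.85
pup3    0.90  0.94
pup4    0.84  0.77
```

Every planted swap is found at its exact frame and the repair restores the
uncorrupted tracks bit-for-bit. The daily open-exploration hours show the
expected developmental structure: adults spend ~5–6 h/day outside the nest
while P16–P17 pups manage under an hour (about 0.16 of the adult level),
the rest spent huddling. The same session yields ~18.5 huddle-h/day for
adults and ~23 h/day for pups.

The cohort-size planning utility reproduces the headline power calculation —
with 3 animals per group, group means 0 and 1 on the adult-relative scale
and standard deviations 0.10 and 0.20, a two-sided Welch test at α = 0.05
has Monte-Carlo power ≈ 98%, above the 80% planning threshold:

```python
from ethodev.development_stats import power_at_n
power_at_n(3, 0.0, 0.10, 1.0, 0.20, alpha=0.05, reps=10_000, seed=1)  # 0.983
```

A full run (`clean → classify → devstats → networks → circadian`) is one
call — `run_pipeline(PipelineConfig(simulate={"fps": 5}, seed=0))` — or one
shell command:

```sh
ethodev run --config config.yaml --seed 0
ethodev simulate --profile tiny --out fixtures/
```

All outputs are deterministic CSV/GraphML artifacts plus a `manifest.json`
with content hashes; the same config and seed reproduce identical bytes.

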