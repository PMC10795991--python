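# socialarena

Quantitative analysis of group social behavior from multi-animal arena
trajectories, for behavioral neuroscientists and computational ethologists
working with tracked pose data (e.g. groups of ~10 fruit flies in a
circular arena filmed at 30 fps).

From per-frame body-ellipse poses (center, heading θ, semi-axes a ≥ b) the
package computes:

* **Interaction networks.** A directed interaction condition per frame —
  the focal animal sees the other (occluded visual angle > 0) and its nose
  is within 8 mm of the other's body — symmetrized by union; true runs
  separated by < 120 gap frames are bridged, and candidates with ≥ 60
  condition-true frames become interaction events. Per recording of F
  frames, two symmetric weight matrices: duration weights
  W_ij = (interacting frames)/F, and count weights
  W_ij = (#events) / (((F − 60)/(60 + 120)) + 1). Metrics: density
  (mean weight over the n(n−1)/2 possible pairs), vertex strength
  s_v = Σ_u W_vu, walktrap community modularity
  Q = Σ_c [w_c/m − (d_c/2m)²], and weighted betweenness with edge length
  1/W (plus SDs across vertices).
* **Ethogram proxies.** Rule-based walk/stop/turn labels, directed chase
  bouts, the 5-min consolidated-inactivity sleep rule, and bout summaries
  (fraction of time, counts, durations, inter-bout intervals).
* **Behavioral signatures.** Per-feature z-scores pooled across cohorts;
  normality-gated group tests (ANOVA + Tukey or Kruskal–Wallis + Dunn)
  with Benjamini–Hochberg FDR across features.
* **Stress survival.** Kaplan–Meier curves, median survival, and pairwise
  log-rank tests with FDR.
* **Synthetic cohorts.** An agent-based simulator (correlated random walk
  with gamma speeds and social attraction/avoidance steering) with three
  presets emulating cohorts that differ in locomotor activity and social
  attraction — including a "rejected-like" avoidant cohort that yields
  sparser, more distant groups — so the whole pipeline runs at desk scale.

See `docs/methods.md` for the model details, parameter defaults and
limitations.

## Worked example

```python
from socialarena import ArenaSpec, cohort_preset, simulate_group, analyze_arena

arena = ArenaSpec()  # 25 mm radius, 30 fps, 27,000 frames (15 min)
table = simulate_group(arena, cohort_preset("rejected_like", seed=7))
res = analyze_arena(table)
print(f"events detected:        {int(res.summary['n_events'])}")
print(f"duration density:       {res.summary['density_duration']:.4f}")
print(f"count density:          {res.summary['density_count']:.4f}")
print(f"mean strength:          {res.summary['mean_strength_duration']:.4f}")
print(f"mean pair distance:     {res.mean_pair_distance:.2f} mm")
```

prints

```
events detected:        338
duration density:       0.0326
count density:          0.0499
mean strength:          0.2935
mean pair distance:     26.12 mm
```

The ten avoidant agents produced 338 pairwise interaction events in 15
simulated minutes, but the duration-weighted network is sparse (density
0.033: on average each of the 45 possible pairs spent ~3% of the recording
interacting) and individuals keep large distances (26 mm mean separation in
a 50 mm-diameter arena). An attractive preset (`naive_like`) under the same
seed gives densities around 0.3 and distances around 16 mm — the
sparser-network / larger-distance signature of the socially avoidant
cohort.

The same analyses are scriptable from the shell:

```sh
socialarena simulate --preset rejected_like --seed 7 --out traj.csv
socialarena network --traj traj.csv --out net.json
socialarena survival --records surv.csv --out survival.csv
```

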