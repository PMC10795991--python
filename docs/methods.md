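# Methods

## Scope and model

`socialarena` quantifies group social behavior of arena-housed animals
(designed around groups of ~10 male fruit flies in a circular arena filmed
at 30 fps) from tracked pose data: per frame, each individual is a body
ellipse with center (x, y), heading θ and semi-axes a ≥ b. From these poses
the package computes pairwise interaction events, two weighted social
networks per recording, rule-based behavior bouts, per-cohort behavioral
signatures, and stress-survival comparisons. An agent-based simulator
generates synthetic cohorts so the entire pipeline can be exercised and
validated at desk scale.

## Interaction definition and networks

A directed interaction condition holds on a frame when the focal animal can
see the other (the angle its body subtends in the focal field of view is
> 0) and the focal nose is within 8 mm (inclusive) of any point of the
other's body ellipse. The pair-level condition is the union of the two
directions (an `and` variant is available); the union reading follows the
phrasing "frames each pair of flies were interacting". Runs of
condition-true frames separated by fewer than 120 condition-false frames
(4 s at 30 fps) are bridged into one candidate event; a candidate qualifies
as an interaction event if it accumulates at least 60 condition-true frames
(2 s). The minimum applies to the condition-true total of the merged
candidate, not the envelope length; an envelope-based variant can be built
from the returned bouts since both boundaries and true counts are reported.

Two weight matrices summarize a recording of F frames:
* duration weights: W[i,j] = (condition-true frames over all events)/F ∈ [0,1];
* count weights: W[i,j] = (#events) / max_possible, with
  max_possible = ((F − 60)/(60 + 120)) + 1 evaluated as real arithmetic.

Network metrics: density is the mean weight over the n(n−1)/2 possible
undirected pairs, so a fully saturated unit-weight network has density 1
(a `literal` compatibility convention dividing by n(n−1) and multiplying by
0.5 — a constant factor 1/4 — is provided; it cannot affect between-group
comparisons). Strength is the per-vertex incident weight sum; communities
come from the walktrap algorithm (random-walk length 4, dendrogram cut at
maximum modularity, via igraph) and the reported modularity Q is always
recomputed from the explicit Newman–Girvan formula on the returned
partition; betweenness uses edge length 1/weight because weights are
affinities, not costs — most graph libraries default to weight-as-cost, so
this is set explicitly. SDs of strength and betweenness are sample SDs
across vertices. An edgeless network is a single community with Q = 0.

## Geometry

The nose is the front tip of the ellipse, (x + a cos θ, y + a sin θ).
Nose-to-ellipse distance is the Euclidean distance to the closest boundary
point, zero inside; it is computed by a 96-point parametric grid scan that
isolates the basin of the global minimum followed by 48 ternary-refinement
steps (parameter located to ~1e-9 rad; validated to 1e-4 mm against a
100,000-point boundary-sampling oracle). The occluded visual angle is exact:
mapping the other ellipse to the unit circle turns the two tangent lines
from the nose into circle tangents with closed-form tangency points; mapped
back, they bound the occluded arc, which is intersected with the
field-of-view arc (default fov = 2π, i.e. "visible" means any occlusion,
matching the use of "angle subtended > 0" as mere visibility; narrower
fields are supported). A nose inside the other body returns the full fov.
Validated against a 4,096-ray casting oracle to 2π/4096 rad.

The distance condition used by the pipeline exploits a sandwich bound: the
ellipse contains its b-disk and is contained in its a-disk, so the exact
distance is only needed when the nose-to-center distance falls in
(dist_max + b, dist_max + a]; a test asserts the fast path equals the exact
route.

Displacement-based features (speed, displacement direction φ) are assigned
to the earlier frame of each displacement; the last frame is missing. φ is
undefined below 0.1 mm/s to avoid jitter-driven angles, which propagates as
missing `absphidiff`.

## Synthetic cohorts

Agents perform a correlated random walk: per frame a speed is drawn from a
gamma distribution (shape 2, mean = cohort mean speed; gamma keeps speeds
nonnegative without clipping), the heading gets Gaussian noise
(SD 0.25 rad/frame) plus a social term s·clamp(Δ, ±0.5 rad) steering toward
(s > 0) or away from (s < 0) the centroid of other agents within 16 mm.
A step that would exit the 25 mm arena re-aims the heading at the arena
center first (specular reflection tends to produce wall-oscillation
artifacts). Orientation is the heading of the last nonzero displacement.
One seed per run; agent k's stream is `default_rng([seed, k])`, so adding
agents never changes existing trajectories.

Preset parameters (data, in `presets.cfg`): mated-like 3 mm/s, s = +0.05;
naive-like 6 mm/s, s = +0.05; rejected-like 6 mm/s, s = −0.10. The speed
ordering encodes the observation that males with recent mating experience
are the least active, and the negative social coefficient encodes active
social avoidance after repeated courtship rejection. These values were
chosen during simulator design by sweeping the social coefficient: at
s = +0.25 the group collapses into a single clump (duration density ≈ 0.98),
while the chosen values give unsaturated networks (duration densities
roughly 0.6 / 0.3 / 0.03 for mated / naive / rejected) with the required
directionality — rejected sparser and more distant than naive, mated most
stopped — by a wide margin. Because slower agents linger once together,
the mated-like cohort is the densest; only the rejected-vs-naive ordering
is a designed property. Arena radius (25 mm) and body semi-axes
(1.2 × 0.6 mm) are declared defaults, not measured values.

What the generator does not emulate: wall-following, grooming/resting
postures, identity swaps and tracking noise, courtship motifs, or any
learned behavior. Passing directionality checks on these synthetic cohorts
therefore shows that the pipeline recovers the orderings it is fed, not
that real cohorts would produce them.

## Ethogram proxies

The learned behavior classifiers of tracking rigs cannot be reconstructed
from thresholds, so locomotion, chase and sleep are simple declared rules:
stop ≤ 1 mm/s; turn ≥ π rad/s (precedence stop > turn > walk); walk
≥ 2 mm/s; chase (directed): nose within 6 mm, partner within π/4 of the
focal heading, both at walking speed, bouts via the shared run machinery
(min 15 frames, gap 15). Sleep is 5 min (9,000 frames at 30 fps, boundary
inclusive) of consolidated inactivity, with "no movement" given the numeric
floor of 0.1 mm/frame; no gap bridging. A stationary interval covering
frames [s, e] is delimited by the run of sub-threshold displacements
s..e−1, so a 9,000-frame stationary interval is exactly one bout. Bout
summaries report fraction of time, count, mean duration and mean inter-bout
interval (gap between consecutive bouts; missing with fewer than two).

## Signatures and statistics

Signatures are z-scores per feature over all replicates pooled across
groups (sample SD), matching standardization "according to all values
calculated ... for that feature"; constant features become zeros and are
flagged. Percent-difference normalization is 100·(x − mean)/mean per
experiment batch. Group comparisons per feature: Shapiro–Wilk at α = 0.05
on residuals (per-group means removed; raw-value gating available) routes
to one-way ANOVA + Tukey HSD or Kruskal–Wallis + Dunn (pooled-rank z tests
with tie correction). Benjamini–Hochberg runs across features within each
pairwise contrast (a global family variant is available); missing values
are dropped per feature, never imputed. Features with any group under 3
replicates are skipped with a warning.

## Survival

Kaplan–Meier product-limit curves (via lifelines) with the standard
convention that individuals censored at t leave the risk set after the
events at t; recorded death times are treated as exact. Median survival is
the smallest event time with S ≤ 0.5 (a 1e-12 tolerance absorbs product
round-off); log-rank is the (ΣO−E)²/V chi-square with 1 df, pairwise over
group pairs with BH adjustment. The chi-square reference is asymptotic: on
tiny groups (n ≈ 10) it is validated against an exact permutation
enumeration to 0.05 absolute on p. The supremum-type (Renyi) test is
reserved but not implemented.

## Validation scale and numerical choices

The test suite validates against independent oracles at these sizes: 1,000
random series (length 2,000) for event detection; 1,000 random pose pairs
per geometry oracle; 100 random graphs (n ≤ 7) for betweenness; 30
seed-matched arenas per preset (10 agents, 27,000 frames = 15 min) for
cohort directionality; 1,000/2,000-rep null simulations for test
calibration. `scripts/acceptance.py` uses 8 seed-matched arenas per preset
and 500/1,000-rep calibrations, sizes chosen to keep a full from-scratch
rerun convenient on a single CPU while leaving the medians stable.

Known limitations: the simulator is not a behavioral model of any real
cohort; ethogram thresholds are unvalidated proxies; the walktrap heuristic
can (rarely, on small graphs) return a sub-optimal partition — the reported
Q is always the exact modularity of the partition actually returned; no
interval-censoring model for survival times recorded every few hours.
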