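# Methods

## The model

Between two consecutive GPS fixes at times t₁ < t₂, an animal moving at most
at speed v_max can only have visited points p with
|p − x₁| + |p − x₂| ≤ v_max·(t₂ − t₁): an ellipse with the fixes at its foci,
semi-major axis a = v_max·Δt/2, half focal distance c = dist/2 and
semi-minor axis b = √(a² − c²). This potential path area (PPA) is the 2-D
projection of the space–time prism and treats every interior point as equally
reachable — the model is deterministic, not probabilistic; no visit-density
(Brownian-bridge) weighting is applied inside the prism.

Two individuals may have interacted wherever their PPAs intersect. The lag
between two intersecting ellipses is the absolute difference of their start
times; lags at or below the concurrency threshold (by default the data's
sampling interval) are concurrent interactions, larger lags are delayed
interactions — asynchronous reuse of the same place, e.g. scent-mark
response — binned by the largest boundary ≤ lag among {1 d, 1 w, 2 w, 3 w}
(closed lower bound; a delayed lag below 1 d reports bin 0). Which animal
moved first is recorded separately since the binning is direction-agnostic.

## Speed budget (EWMA)

The per-segment maximum speed is an exponentially weighted moving average of
observed speeds: s_i = Σ_{k=0}^{n−1} λ(1−λ)^k v_{i−k} (s_i = v_i when λ = 1),
scaled by an error term ε. Parameters, with defaults:

| parameter | default | meaning |
|---|---|---|
| λ | 0.5 | decay; weight of the k-th past speed is λ(1−λ)^k |
| n | 10 | window length (count of past segments) |
| ε | 1.25 | multiplicative headroom over the smoothed speed |

At the head of a track the sum is truncated to the available history and not
renormalized (a config flag enables renormalization as a variant). Because a
truncated weight sum is < 1, ε·s_i can fall below the observed speed v_i,
which would make the ellipse unable to contain its own chord; the budget is
therefore floored at v_i (`v_max = max(ε·s_i, v_i)`), and floored segments
are flagged. λ and n are analysis choices exposed in configuration and logs;
only ε has a canonical value.

## Numerical choices

- **Ellipse discretization.** Boundaries are polygons with V = 100 vertices
  at equal parametric angles; the inscribed-polygon area deficit is
  1 − sinc(2π/V) ≈ 0.07%, far below telemetry positional error. A degenerate
  budget (a = c) yields the chord as a zero-area line geometry, flagged, and
  still participates in intersection tests through its segment geometry.
- **Gap rule.** PPAs whose Δt exceeds mean + 3·SD of the individual's
  sampling intervals are removed before interaction analysis. The literal
  "3·SD" reading is selectable, but with near-constant sampling (SD ≈ 0) it
  would reject nearly everything or nothing, so the mean-anchored form is
  the default.
- **Candidate filtering.** Intersections are found by a k-d tree radius
  query on ellipse centroids with r = a_max(A) + a_max(B): two ellipses can
  only intersect if their centroid distance is at most the sum of their
  semi-major axes, so the candidate set is a guaranteed superset. Candidates
  then pass a per-pair centroid bound and the exact polygon test. On random
  instances the pipeline returns exactly the brute-force all-pairs set.
- **Continuity.** Successive events belong to one interaction segment when
  their PPA interval unions overlap or abut within one sampling interval;
  this tolerates interleaved fix times between the two animals. Segment
  duration is exactly max end − min start; monthly tables split durations at
  calendar-month boundaries (sum of splits equals the segment total) and
  count frequency in the starting month.
- **Months and timezones.** Timestamps are parsed as UTC unless configured
  otherwise; month binning follows the configured zone's wall clock.
- **Projection.** Geographic input is projected to the UTM zone of the data
  centroid using the standard WGS84 Transverse Mercator series (implemented
  in `timegeo.projection`); sub-kilometer distances are preserved to ≪0.1%.
- **Home ranges.** The 95% hull drops the ⌊0.05·n⌋ fixes farthest from the
  mean center (ties keep the earlier fix; median-center variant available),
  then takes the convex hull. Trimming is per window. Overlap is directional:
  area(x ∩ y)/area(y).
- **Ties at bin boundaries.** A lag exactly on a bin boundary is assigned to
  that bin; a lag exactly at the concurrency threshold is concurrent.

## Pattern signatures

At each event the generating segments' headings (degrees clockwise from
north) and speeds give the absolute circular heading difference ∈ [0°, 180°]
and absolute speed difference. Gaussian KDEs (Scott bandwidth) of these
summarize a dyad's interaction style. The four qualitative patterns are
operationalized as advisory labels with configurable thresholds — following:
concurrent, mean heading difference < 45°, duration ≥ 3 sampling intervals;
encounter: concurrent, shorter; latency: any delayed event; avoidance:
dyad-level, concurrent frequency below the 0.25 quantile of peer dyads. The
thresholds are explicitly heuristic: the quantitative signature is always
emitted alongside, and the labels carry a `label_is_heuristic` marker.

## Synthetic data

The simulator provides ground truth that real telemetry cannot. Each
individual follows a discrete-time correlated random walk: heading evolves
by wrapped-normal turns (SD 40° by default), step lengths are normal
(mean 500 m, SD 300 m per hour, floored at 0), and an
Ornstein–Uhlenbeck-style pull recovers 5% of the distance to a range center
per step, producing stable home ranges of a few tens of km² — magnitudes
typical of 1-h large-felid telemetry. Scripted regimes overwrite the base
motion and record truth intervals: co-movement (follower = leader +
Gaussian jitter, default 50 m), lagged revisit (follower retraces the
leader's path L hours later), avoidance (radial repulsion). After a regime
ends the follower's remaining path is rigidly translated to stay continuous,
which intentionally leaves one fast "rejoin" segment. The canned three-phase
scenario (30 d co-movement, then semi-independence with 24-h revisits, then
separation with a rare 1-week revisit) emulates a natal-dispersal design.
One integer seed determines all output bytes.

What the simulator does **not** emulate: positional error on fixes, habitat
or terrain constraints, behavioral-state switching beyond the scripted
regimes, and irregular (non-gap) sampling jitter. Passing recovery tests on
these data therefore demonstrates the correctness of the detection
machinery under the stated motion model, not field performance on real
collars.

## Problem sizes

Validation runs use dyads of 720–2160 hourly fixes (30–90 days), 500
random ellipse pairs against a 10⁵-sample Monte-Carlo membership oracle,
and 200-PPA-per-side brute-force equivalence checks — sizes at which exact
all-pairs oracles are feasible while exercising every code path of the
indexed pipeline.

## Known limitations

- The concurrency threshold equals the sampling interval by default; data
  with strongly heterogeneous intervals across individuals need an explicit
  choice.
- Delayed-interaction durations are not traced (delayed events are counted,
  per bin, optionally first-per-day), matching how delayed interactions are
  conventionally reported.
- No ≥3-way simultaneous intersection events; multi-animal structure is
  aggregated from dyads in the network module.
- Intersection *area* is reported as a diagnostic but not used to weight
  interaction strength; the whole intersecting PPA counts as potential
  interaction regardless of overlap size.
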