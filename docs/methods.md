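# Methods

## What the engine models

`snapp` re-implements, as a deterministic and testable library, the back
end of a tailored walking-coach intervention for adults. Three data streams
tailor the coaching: daily cumulative step counts, position fixes compared
against a database of green spaces, and each user's stated preferences for
ten behavior change techniques (BCTs). The engine selects and "delivers"
messages (to a JSONL log) under the protocol's selection rules, delivery
windows, and rate limits. The production transport (a messaging-app bot)
and mobile apps are out of scope; an abstract delivery sink and the
simulator stand in for them, so the whole rule set runs at desk scale.

## Selection procedures

All three channels use elimination: filter the library down to an eligible
pool, then randomize.

* **Step feedback (midday).** Pool = step-feedback templates whose stratum
  matches the day's latest count — LOW (≤ 2000), MID (2001–6000), HIGH
  (≥ 6001) — or is a wildcard; uniform choice; `<name>` and `<number>`
  substituted. When no count has arrived for the day the engine sends the
  LOW-stratum message with a count of 0 and flags the delivery
  `stale_steps=true`: the scheduled contact is never silently skipped and
  the fault stays observable in the log.
* **Green-space prompt (geofence-triggered).** Pool = prompt templates for
  the encountered space type (park / forest / walking trail) or wildcard;
  uniform choice; `<name>` and the type's display string substituted.
* **Preference-tailored coaching (morning and evening).** Pool = BCT
  templates legal for the weekday and slot. A subset of k = 4 is drawn
  without replacement with probability proportional to the user's score
  (1/5/10, from the −1/0/+1 survey) for each template's BCT, then one of
  the four is chosen uniformly. Sampling uses the exponential-race
  construction (item *i* gets key Exp(1)/w_i; the k smallest keys win in
  key order), which is distributionally identical to sequential
  proportional draws without replacement. Exact proportionality holds for
  the first draw; overall per-message selection probability tracks the
  weight ratio approximately — at 100 messages per weight class the
  measured 10-vs-1 frequency ratio is ≈ 9.7 rather than exactly 10,
  because without-replacement draws slightly deplete the heavy class.
  No subset-then-uniform scheme reproduces the factor exactly; the
  procedure, not the ratio, is the contract.

Empty pools are logged `NO_ELIGIBLE_MESSAGE` non-events, never exceptions.

## Scheduling and rate limits

The clock ticks in whole minutes; all windows are half-open `[start, end)`.
Per user-day the engine draws three send times uniformly over whole
minutes: morning 08:00–09:00, midday 11:30–12:30, evening 16:00–18:00
(times are drawn fresh each day). The geofence (default radius 300 m,
boundary inclusive, haversine on the mean Earth radius 6 371 008.8 m) is
polled every 2 minutes against the user's track; the step store syncs
hourly. Geolocation prompts pass a gate: inside 08:00–20:00, fewer than 3
sent that day, and at least 240 minutes since the previous geolocation
delivery (gap measured delivery-to-delivery; the daily counter resets at
local midnight, the gap clock does not — with this window it can never
bind across midnight). When a scheduled tick and a geofence tick share a
minute, the scheduled message goes first. One caller-seeded RNG governs
all randomness and users are processed in sorted id order, so a fixed seed
plus fixed inputs replays to a byte-identical delivery log.

Denied attempts (window / daily cap / minimum gap) and empty-pool events
are logged alongside deliveries; the production system would be silent,
but the log is the engine's test surface. Logged geolocation context
contains the timestamp, space id, and space type only — never user
coordinates.

## Configuration

Every numeric rule lives in `EngineConfig` (YAML-serializable): geofence
radius (m), poll and sync cadences (min), the four windows, daily cap,
minimum gap (min), subset size k, stratum bounds, the score map, and the
step goal. Defaults are the protocol values above; the goal defaults to
7000–8000 steps/day with only the lower bound evaluated (the upper bound
is descriptive). The protocol's daily goal (7000) and its top feedback
stratum (≥ 6001) genuinely disagree; both are implemented as stated.

## The simulator and what passing tests mean

The generators exist to drive every engine rule, not to emulate a
population:

* **Preferences** — 10 i.i.d. draws per user over {−1, 0, +1}, uniform by
  default.
* **Step accrual** — a compound process: Poisson(6) walking bouts per day
  at uniform times, lognormal bout sizes (log-space μ = 6.4, σ = 0.5,
  mean ≈ 680 steps), plus 100 background steps/hour, reported as 24 hourly
  cumulative records. Mean daily total = 6·exp(μ+σ²/2) + 2400 ≈ 6500
  steps — a realistic, mildly under-goal walker — with closed-form moments
  the tests check. The optional `stale_fault` stamps records with the
  previous date, reproducing a clock-rollover fault observed in piloting.
* **GPS tracks** — minute-resolution piecewise-linear walks between
  Gaussian waypoints (σ = 800 m) around a home location; with probability
  `dwell_near_green` (default 0.3) one waypoint is placed within 100 m of
  a green space. `constant_track` pins a user inside a geofence all day
  for rate-limit scenarios.

None of this models real human mobility, sensor noise, message fatigue, or
app attrition; passing tests demonstrate that the *rules* are implemented
faithfully and deterministically, not that the intervention changes
behavior.

## Numerical and design notes

* Distances: haversine with an asin clamp; errors versus an ellipsoid are
  ≪ 1 m at geofence scale. Proximity ties break on the smallest
  `space_id`. The small-input path and the vectorized path are checked
  against a pure-Python linear scan.
* Statistical tests use seeded RNGs and generous bands (chi-square
  p > 0.001; ±10% on the weight-ratio Monte Carlo) so they are stable
  across replays.
* Problem sizes in the test and acceptance runs (10⁵ selection draws,
  10 seeds × 20 users × 7 days of geofence dwell, 1000 proximity queries
  against 2000 spaces) were chosen as the smallest runs whose sampling
  error is comfortably inside those bands.
* Word counts outside the 20–30-word house style are lint warnings, not
  errors, since the style is approximate; missing pool coverage (a
  stratum, space type, or BCT with no template) is an error because that
  pool would be unselectable at run time.
* Day boundary is local midnight of the simulated clock; there is no
  time-zone or DST logic.

## Known limitations

* The BCT channel's weekday/slot restrictions are supported by the schema
  but the bundled fixture texts leave them unrestricted; which messages
  carry which restrictions is an authoring decision.
* No repeat-suppression across days: diversity comes only from the random
  choice among the subset of 4.
* No dynamic re-weighting of preferences from behavior (named future work
  for the original system).
* Geofences are circles around points; polygon spaces and map-matched
  movement are out of scope.
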