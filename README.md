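# snapp-engine

A testable re-implementation of the back end of a tailored walking-coach
intervention. Adults enrolled in such a program receive short coaching
text messages whose content is tailored from three data streams: daily
step counts, proximity to green spaces, and stated preferences for ten
behavior change techniques (BCTs — e.g. goal setting, self-monitoring,
social support). This package implements the full selection-and-delivery
rule set as a deterministic library with a simulator, so every rule can be
exercised, audited, and regression-tested at desk scale — no phones,
servers, or messaging bots required.

## The rules it implements

Each user-day delivers at least three messages, plus contextual prompts:

| Channel | When | Selection |
|---|---|---|
| BCT coaching | random minute in 08:00–09:00 and 16:00–18:00 | filter by weekday/slot; draw a subset of k=4 without replacement with P(draw) ∝ preference score w ∈ {1, 5, 10} (from the −1/0/+1 survey); uniform choice among the 4 |
| Step feedback | random minute in 11:30–12:30 | filter to the user's stratum — LOW ≤ 2000, MID 2001–6000, HIGH ≥ 6001 steps — then uniform choice; `<number>` and `<name>` substituted |
| Green-space prompt | geofence hit (300 m radius, polled every 2 min) | filter to the space type (park / forest / walking trail); uniform choice; gated to ≤ 3/day, ≥ 4 h apart, 08:00–20:00 |

A message whose BCT a user scored 10 is ~10× more likely to be delivered
than one scored 1. The engine logs every delivery *and* every skipped
attempt (empty pool, rate-limit denial, rejected step record) to a JSONL
delivery log; the log stores green-space ids and types but never user
coordinates. Identical seed and inputs replay to a byte-identical log.

The bundled simulator generates rosters, compound-process step
trajectories (Poisson bouts × lognormal sizes + background drift), and
waypoint GPS tracks, and can reproduce the stale-clock fault in which a
step feed stops rolling to the next date. See `docs/methods.md` for the
models and design choices.

## Worked example

```bash
snapp make-fixtures --out fixtures --users 3 --seed 42
snapp validate-library --messages fixtures/messages.csv
snapp simulate --messages fixtures/messages.csv \
    --green-spaces fixtures/green_spaces.csv \
    --preferences fixtures/preferences.csv \
    --days 2 --seed 42 --out run
```

prints

```
library OK: every selectable pool is covered
3 users x 2 day(s): 18 deliveries, 9 skips -> run
```

18 deliveries is exactly 3 users × 2 days × 3 scheduled contacts: none of
these tracks happened to dwell near a green space inside the 08:00–20:00
prompt window, and `run/summary.csv` shows the per-user-day breakdown
(1 STEP + 2 BCT each, the 9 skips being logged geofence denials):

```
user_id,date,STEP,GEO,BCT,SKIP,total
u001,2024-01-01,1,0,2,0,3
u001,2024-01-02,1,0,2,0,3
...
```

A delivery in `run/delivery_log.jsonl` carries its full selection context:

```json
{"channel": "STEP", "context": {"channel": "STEP", "pool_size": 3,
  "stale_steps": false, "steps": 5042, "stratum": "MID"},
 "kind": "DELIVERY", "message_id": "step_mid_002", "reason": "SELECTED",
 "text": "So far you have taken 5042 steps today, Anna. Well done! ...",
 "ts": "2024-01-01T12:16", "user_id": "u001"}
```

Point-in-radius queries work standalone:

```bash
$ snapp geofence-check --lat 52.3930 --lon 4.8878 --green-spaces fixtures/green_spaces.csv
within 300 m: g001 (Green space 1, park) at 14.0 m
```

The same functionality is available as a library (`snapp.run_simulation`,
`snapp.select_bct_message`, `snapp.check_proximity`, ...); the CLI is a
thin wrapper.

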