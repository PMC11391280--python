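# vocalmap

Spatiotemporal analysis of multi-individual vocal interactions in tracked
animal groups: does a call type work as an antiphonal **signal exchange**
(a call mobilizes a timed response from a nearby group member) or as a
context-driven **signal broadcast** (calling reflects the caller's own
state, with no contingency on others' calls)?

The package is written for bioacoustics and collective-behaviour
researchers working with synchronized animal-borne audio + GPS collars —
the motivating system is wild meerkat (*Suricata suricatta*) groups, where
every group member carries a recorder and a 1 Hz GPS unit, and where the
two dominant call types are foraging *close calls* (`cc`) and *short
notes* (`sn`). It works equally on its own simulator's ground-truth data,
so every statistic can be validated against known interaction parameters
without any field data.

## What it computes

Given a UTC-synchronized call table and cleaned 1 Hz planar trajectories:

1. **Call-sequence statistics** (`vocalmap.sequence_analysis`) — consecutive
   call pairs within an inter-call-interval threshold (the 90th percentile
   of onset-to-onset gaps, or a fixed override); multiple distinctive
   collocation analysis (MDCA) scoring each ordered category pair (a, b) by
   a signed log binomial tail,

   pbin(a,b) = ± −log₁₀ P(X ≷ k),  X ~ Binomial(n_a, p_b),

   with n_a the transitions initiating with a, p_b the global response
   margin, and k the observed a→b count (positive = over-represented);
   self- vs non-self-reply proportions per category with Pearson χ² and
   Bonferroni-corrected pairwise tests; and caller-identity patterns
   (A-A-stop, A-A-A, A-A-B, A-B-stop, A-B-A, A-B-B, A-B-C) of 2–3 call
   chains within 10 m of the initial caller, tested against permutation
   nulls (per-individual circular time shifts, or caller-label permutation
   over the pooled timeline).
2. **Peri-call response dynamics** (`vocalmap.response_dynamics`) —
   Gaussian-kernel responder calling-rate curves around each focal call
   (t = 0 at focal onset), stratified by caller–responder distance
   (0–2 / 2–5 / 5–10 / 10–50 m) or by (caller age, responder age), with a
   by-day bootstrap. Exchange shows symmetric peaks at ±latency; broadcast
   does not.
3. **Spatiotemporal clustering** (`vocalmap.spatial_clustering`) — for all
   call pairs, the statistic K(d, τ) = fraction of pairs at lag τ that are
   distance d apart, compared against an audio–GPS derangement null (each
   individual's call stream re-assigned to another's trajectory) as
   log K_obs/K̄_null: positive values mark persistent "vocal hotspots".
4. **Call rate vs context** (`vocalmap.rate_context`) — z-scored 10 s
   rolling call rates against movement speed (10 quantile bins) and number
   of neighbours within 5 m (0/1/2/3/4+), under eligibility filters
   (≥5 tracked individuals, ≥half the tracked group foraging, no alarm in
   the past minute).
5. **Plumbing** — CSV schemas and round-trip I/O, talking-clock drift
   correction, GPS quality filtering, note→call merging, hybrid-label
   collapsing (`vocalmap.events_io`, `vocalmap.preprocess`), and a
   ground-truth simulator of cohesive group movement with broadcast-mode
   (self-exciting) or exchange-mode (neighbour-triggered, 0.4 s latency,
   10 m radius) calling (`vocalmap.synthetic_data`).

## Worked example

```python
from vocalmap import synthetic_data as sd, sequence_analysis as sa, \
    response_dynamics as rd

cfg = sd.SimConfig(n_individuals=6, session_s=900.0, seed=3,
                   exchange=sd.ExchangeConfig(p_resp=0.7))
sim = sd.simulate_session(cfg, "exchange")

thr = sa.interval_threshold(sim.calls)          # 90th pct of call gaps
pairs = sa.build_pairs(sim.calls, thr)
print(f"threshold {thr:.2f} s, non-self share "
      f"{1 - pairs['same_caller'].mean():.2f}")

curves, _ = rd.peri_call_rate(sim.calls, sim.gps, "cc")
for c in curves:
    print(c.stratum, f"peak at {c.peak_lag((0.1, 2.0)):+.2f} s,",
          f"max {c.rate.max():.2f} calls/s")
```

prints

```
threshold 1.84 s, non-self share 0.88
0-2m peak at +0.35 s, max 1.34 calls/s
2-5m peak at +0.45 s, max 0.98 calls/s
5-10m peak at +0.35 s, max 1.11 calls/s
10-50m peak at +1.25 s, max 0.20 calls/s
```

88% of consecutive call pairs involve a caller change, and responders
within 10 m of a caller show a calling-rate peak ~0.4 s after the focal
call (the simulator's configured response latency), while the 10–50 m
stratum — beyond the 10 m response radius — shows no comparable structure.

## Analysis scripts and the CLI

The numbered drivers under `analysis/` run the full simulated study —
`01_simulate_sessions.py` (exchange-cc and broadcast-sn datasets with
per-device clock drift), `02_preprocess.py` (sync, clean, merge, context
mask), `03_sequence_statistics.py`, `04_response_dynamics.py`,
`05_spatial_clustering.py`, `06_rate_context.py` — each printing what it
found and writing summary tables under `results/`. Dataset-scale CSVs and
bootstrap replicates live under `scratch/`.

The same stages are exposed as a command line for user-supplied data:

```bash
vocalmap simulate --mode exchange --seed 7 --out-dir data/
vocalmap run-all --calls data/calls.csv --gps data/gps.csv \
    --pings data/pings.csv --seed 7 --out-dir out/
```

`run-all` chains preprocess → sequences → responses → clustering → rates
and writes every stage's tables, figure-style plots and a manifest.

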