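# Methods

This note documents the models, estimators and numerical choices behind
vocalmap, and what the simulator-based validation does and does not show.

## Data model and time

All analyses run on two tables: labelled call events (caller, category,
UTC onset/offset in floating-point seconds since the session's midnight, a
focal flag, age class, note count) and 1 Hz planar GPS fixes in metres.
Calendar dates are carried separately; every computation is within-session,
so no timezone machinery is needed. Sessions are (group, day) pairs;
multi-day inputs are always processed per session and pooled at the
accumulator level, never by concatenating timelines (seconds-since-midnight
would otherwise alias across days).

### Clock synchronization

Independently worn recorders drift. A periodic spoken-time ping (every
90 s) audible to all recorders gives paired (device time, true time)
anchors per device. Event times are mapped through the piecewise-linear
interpolant of those anchors, independently per device; outside the ping
span the nearest segment's slope extrapolates, and events more than 90 s
outside the span are logged. Linear interpolation between anchors is an
assumption: residual sub-ping drift is quadratically small for the
crystal-oscillator drift rates the simulator emulates (≤ a few hundred
ppm), for which recovery is better than 1 ms (tested).

### GPS cleaning

Three filters, applied per individual in order: (i) fixes with fewer than
5 satellites; (ii) all fixes within 60 s before or after a signal-loss gap
(any >1 s hole in the recorded 1 Hz timestamp stream — detection uses the
recorded stream, valid or not, so earlier filters cannot manufacture
gaps); (iii) a greedy forward scan dropping the later fix of any
consecutive pair >10 m apart and re-evaluating against the last kept fix
(the arriving fix is treated as the artefact). Fixes are flagged invalid
rather than deleted, which preserves the timestamp stream and makes the
operation idempotent. Counts per rule are reported.

### Note merging and label collapsing

Calls are often produced as bursts of notes. Runs of same-individual,
same-category notes with inter-note silence < 0.1 s merge into one call
(onset = first onset, offset = last offset, n_notes summed, so the total
note count is conserved). Only same-category runs merge; cross-category
merging would corrupt the transition statistics. Sequence analyses run on
the merged (call) level; response dynamics and clustering run on the note
level, where individual onsets carry the timing signal. Free-text hybrid
labels ("A/B") collapse to the more abundant of the mentioned categories
(dataset abundances supplied by the caller; ties break alphabetically and
are logged); unrecognizable labels become `ukn`.

## Sequence statistics

**Interval threshold.** Consecutive-pair analyses only consider a call and
the next call by anyone if the onset-to-onset gap is at or below a
threshold — by default the 90th percentile (type-7/linear quantile) of all
such gaps, computable from the data or overridden with a fixed value.
Onset-to-onset gaps are used because offsets are more sensitive to
labelling noise; the alternative (offset-to-onset) is a parameter away.
Ties in onset time are broken by (individual, event id) for determinism.

**MDCA.** For ordered category pair (a, b): n_a = pairs initiating with a,
p_b = global fraction of pairs ending with b, k = observed a→b count. The
score is the exact binomial tail probability — P(X ≥ k) when k is at or
above the expectation n_a·p_b, else P(X ≤ k), X ~ Bin(n_a, p_b) — reported
as a signed −log₁₀ (positive = over-represented). Conditioning trials on
the initiation margin and success probability on the global response
margin makes rows comparable across unevenly common initiating categories.
Degenerate cells: rows with n_a = 0 are NaN; a saturated margin (p_b = 1)
gives p = 1 hence a score of exactly 0. p is floored at 1e-300 before the
log. The same statistic runs on the self-reply and non-self-reply subsets.

**Self/non-self proportions.** For each category's homogeneous
(same-category) consecutive pairs, the share produced by a different
caller. The omnibus test is a Pearson χ² (no continuity correction) on the
categories × {self, nonself} table; pairwise 2×2 χ² tests are
Bonferroni-corrected (p × number of comparisons, capped at 1). The `mo`
and `ld` categories are excluded by default as too sparse for stable
proportions; the exclusion list is a parameter.

**Caller-sequence patterns.** Within one category, every call starts a
candidate chain; successive calls join while the gap stays at or below the
threshold *and* the caller is within 10 m of the initial caller, measured
at the initial call's time (nearest valid fix within ±1 s). An in-time but
out-of-radius caller *terminates* the chain rather than being skipped —
skipping would fabricate adjacency. Chains of length 2–3 are labelled by
caller identity (A-A-stop … A-B-C); length-1 chains are not counted.
Callers without usable GPS cannot start or extend chains (logged).

**Permutation nulls.** Two schemes, chosen deliberately because they test
different hypotheses:

- *circular*: each individual's call-onset series is shifted circularly by
  an independent uniform offset within the session window. Within-
  individual structure (burstiness, the inter-call interval multiset) is
  preserved exactly; only cross-individual timing is destroyed. This is
  the sharp null for antiphonal coupling — but independent stationary
  streams are *exchangeable* under it, so it cannot, even in principle,
  flag single-caller burst structure as deviant.
- *label*: the pooled onset multiset stays fixed and caller identities are
  permuted across calls (per-individual counts preserved). This breaks
  burst structure too, so same-caller repetition (broadcast-style A-A
  chains) appears as over-representation against it.

Exchange-style data are tested with the circular null, broadcast-style
repetition with the label null. Both schemes are exactly calibrated for
independent homogeneous callers (verified over 200 simulated datasets:
the fraction of two-tailed p < 0.05 stays in [0.01, 0.10]). p-values use
(1 + #{null ≥ obs}) / (1 + n_perm), both tails reported.

## Peri-call response dynamics

For every focal call of the target category and every other individual,
the responder's note onsets within ±5 s are accumulated as unit-mass
Gaussian kernels (σ = 0.1 s on a 0.05 s grid — σ resolves a ~0.4 s latency
while absorbing labelling jitter; both are parameters) and averaged over
contributing (focal, responder) pairs, giving a mean responder rate in
calls/s. Because all ordered pairs contribute, a one-directional
answering process still yields symmetric ±latency peaks: the +0.4 s peak
collects answers to the focal call, the −0.4 s peak collects focal calls
that were themselves answers. The curve integral times the pair count
equals the windowed event count (mass conservation, up to kernel mass
lost at the window edges), and homogeneous Poisson responders give flat
curves at the analytic rate — both are tested.

Distance strata (0–2, 2–5, 5–10, 10–50 m) use the caller–responder
distance at the focal onset, nearest valid fix within ±1 s per animal;
pairs without GPS are skipped and counted in a coverage report. The
age-class variant strata (caller age × responder age) drop the distance
requirement entirely so GPS-less juveniles participate. Uncertainty comes
from a day-level bootstrap: per replicate, each group's session-days are
resampled with replacement (observed per-group day count kept), resampled
days are relabelled as distinct pseudo-days, and all curves recomputed.

## Spatiotemporal clustering

For all unordered same-session call pairs of one category (not just
consecutive ones), binned by caller–caller distance at the earlier call's
onset and by lag |Δt|: K(d, τ) = pair count in (d, τ) normalized by the
total count at lag τ, so each populated lag column sums to 1. Default
bins: distance edges 0/2/5/10/20/50 m; lag edges log-spaced 1–3600 s
(12 bins) — the edges are parameters, and merging adjacent distance bins
commutes exactly with the normalization. Pair enumeration slides a
time-sorted window so only pairs within the maximum lag are touched.

The null re-assigns, per session and permutation, each GPS-bearing
individual's call stream to another individual's trajectory via a uniform
random derangement (no fixed points, rejection-sampled) — preserving the
group's spatial configuration and every calling sequence while severing
the link between them. The log-ratio log(K_obs/K̄_null) is NaN where
either surface is empty. One hundred permutations by default.

## Call rate versus context

Raw rate = call onsets in a trailing 10 s window, evaluated every second
(trailing keeps causality with the eligibility mask; centred alignment is
a parameter). Per individual, rates are z-scored over eligible seconds
(mean 0, SD 1; zero-variance series are flagged degenerate and dropped).
Eligibility requires ≥5 tracked individuals (valid fix within ±1 s),
≥half of the tracked individuals having given a close call in the
trailing minute (foraging proxy), and no alarm call in the trailing
minute; every ineligible second carries explicit reason flags. Speed is
net displacement over the same 10 s window in m/min (not path length);
neighbour count is tracked conspecifics with a valid fix within 5 m —
untracked animals are invisible to it. Profiles bin z-rates by pooled
speed quantiles (10 bins, near-equal occupancy) or neighbour count
(0/1/2/3/4+), average within individuals first, then across individuals
with equal weight (a pooled-observation mean is also returned as a
diagnostic); individuals contributing under 2 h of eligible data are
dropped by default (a parameter — the desk-scale analyses here lower it
in proportion to their shorter sessions).

## The simulator

`synthetic_data` generates the study conditions end to end and is
first-class, tested code; its defaults are the conditions the analyses
are validated under.

**Movement.** A correlated random walk per individual: persistent heading
(turn SD = (1 − persistence)·π), blended with a unit vector toward the
group centroid with weight a/(1+a) for attraction strength a, at a speed
set by a two-state forage/run Markov chain (defaults 5 and 25 m/min,
1 Hz). This produces a cohesive foraging group with realistic ~0–20 m/min
speeds; it does not model habitat structure, burrows, or leadership.

**Broadcast calling.** Per individual, a self-exciting cluster process:
Poisson immigrants (default 0.04 calls/s) each spawning Poisson(w)
offspring (w = 0.5 < 1) at exponential delays (mean 1 s) — single-caller
bursts with no cross-individual terms. The baseline can be gated up by a
factor when the individual's current speed exceeds a threshold
(fast-travel calling), implemented by thinning.

**Exchange calling.** Poisson baselines (default 0.1 calls/s ≈ the
foraging close-call rate) plus antiphonal responses: each emitted call
elicits, with probability p_resp·min(1, Σw), a reply from *one* in-range
neighbour drawn with weights w = decay(distance)·age-pair weight, after a
lognormal latency (mean 0.4 s, SD 0.15 s); the distance decay is a hard
10 m cut-off by default (exponential variant available). Replies can
themselves be answered. Recruiting at most one responder per call is a
deliberate design choice: it matches the call-and-response dyad that
defines an exchange, keeps the branching ratio exactly p_resp < 1 (always
subcritical — independent per-neighbour responses would go supercritical
in any cohesive group where everyone is within 10 m), and makes the
triggered fraction analytically p_resp, which the tests verify (±3%).
Every triggered call's parent and latency are recorded as ground truth.
When comparing across p_resp values, the baseline is scaled by
(1 − p_resp) so the *overall* call rate stays matched — otherwise total
volume grows as 1/(1 − p_resp) and overlapping response chains confound
the comparison with a pure density effect.

**Juveniles.** The last n_juveniles individuals call (optionally at a
multiplied rate) and move with the group but emit no GPS, exercising the
GPS-exclusion paths and the age-class analyses, mirroring audio-only
collars on animals too small for a GPS unit.

**Clock drift.** Device time = offset + (1 + ppm·10⁻⁶)·true time per
device, with a sync-ping table at 90 s cadence; composed with the drift
correction this recovers truth to < 1 ms.

All randomness flows from one integer seed; identical config + seed give
bit-identical output.

### What the simulation validates — and what it does not

Passing tests show the *estimators* do what they claim on data whose
generative truth is known: exact agreement with independent oracles for
the mechanical steps, calibrated nulls under independence, recovery of
the configured latency (peak lag within [0.3, 0.5] s for a 0.4 s latency)
and radius (elevation confined to ≤10 m strata), and the right
qualitative contrast between regimes. They do not show that real
field data meet the models' assumptions: real groups have habitat
structure, real GPS error is autocorrelated rather than absent, real call
streams mix categories and contexts, and real response latencies need not
be lognormal. Those are properties of data, not of the pipeline.

## Problem sizes and determinism

The bundled analyses and tests run on desk-scale configurations — 5–8
individuals, 600–1800 s sessions, 99–199 permutations, 30–100 bootstrap
replicates, 200 datasets for null-calibration sweeps — chosen as the
smallest sizes at which the statistics above are stable. Every stochastic
stage takes an explicit seed and is bit-reproducible; permutation and
bootstrap p-values therefore are too.

## Known limitations

- The pair-construction "next call" is global (any caller, any distance);
  the 10 m radius applies only to the caller-sequence chains. A radius on
  pair construction is a parameter away but not the default.
- The clustering surface treats same-caller pairs like any other pair;
  at distances below GPS error the 0–2 m bin mixes self- and
  cross-individual clustering.
- The day bootstrap resamples days, not individuals; individual-level
  uncertainty is only captured via the per-individual thin lines of the
  rate profiles.
- Fixed kernel bandwidth; no adaptive smoothing for rate curves.
- The context mask's foraging proxy (a close call in the past minute)
  is circular for close-call rate analyses at extreme parameter values —
  as in the field protocol it emulates, it is a pragmatic filter, not a
  behavioural classifier.
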