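# Methods

This note documents the models, conventions and numerical choices behind
the package; it is the reference for anyone extending the engine, the
simulator or the metrics.

## Event model and clocks

All components exchange tidy event streams: one record per RFID read,
nose-poke, reward delivery or cue onset, carrying `(t, kind, rfid_tag,
port, liquid, volume_ul)`.  Time is a single monotonic experiment clock
in seconds.  Every rule in the task is a relative interval, and circadian
analysis needs only a phase anchor, so the wall-clock mapping (experiment
start timestamp and lights-on hour) lives once in the log header, not in
each event.  By convention `t = 0` is lights-on of day 1, making the
light phase of day *d* the half-open interval `[(d-1)·86400,
(d-1)·86400 + 43200)`.  Pokes are modelled as instantaneous onsets; poke
duration plays no role in any schedule rule or metric here.

Logs serialize to CSV (fixed column order, `repr`-formatted floats) or
JSON lines with identical field names.  Both dialects round-trip
losslessly and byte-identically, which is what makes "strip the rewards
and replay" an exact-equality test rather than an approximate one.

## Trial engine

The engine is a per-cage state machine.  Semantics that the task
definition leaves implicit were fixed as follows:

* **Two windows, one default.**  The first-poke window and the
  inter-poke timeout are both 3 s but remain independently configurable;
  protocols that need asymmetric windows can set them separately.
* **Strict boundary.**  A poke qualifies iff its gap is strictly below
  the timeout; a gap of exactly 3.0 s ends the trial.
* **Cross-port pokes.**  Only time gaps end a trial.  A poke at the
  other port starts a fresh streak of 1 there and discards the previous
  port's progress — reward accumulation requires *consecutive same-port*
  pokes, but a port switch is not a termination cause.
* **Reward resets the streak**, so FR *n* pays on pokes *n*, 2*n*, 3*n*…
  of a same-port run; this is what produces the characteristic
  pokes-per-trial peaks at multiples of the ratio in entrained animals.
* **Displacement.**  Physically the tube admits one mouse, but the
  engine must be total over arbitrary logs: a repeated read of the
  current occupant is ignored; a read of a different mouse closes the
  open trial (`displaced`, ended at the read time) and opens a new one.
  Pokes with no open trial for their mouse are counted as orphans and
  never rewarded.
* **PR bookkeeping** is a persistent map (mouse, liquid) → requirement,
  initialized to 1 everywhere at session start, incremented by exactly
  one per same-liquid reward, with no within-session reset or timeout;
  session length is a protocol choice, not an engine rule.
* **Cues** (`cue_on`, default 500 ms on the fentanyl port) are emitted at
  reward time when configured; they never gate behavior in the engine.

Correctness is established against an independent brute-force oracle
that first segments the stream into visits and then re-derives rewards
from each visit's poke list with a from-scratch streak counter; the two
implementations agree exactly on 1000 fuzzed streams whose gaps straddle
the 3-s boundary.

## Protocol staging

The default staging encodes the standard choice experiment: days 1–2
single-port water FR1 (side flipped on day 2), days 3–4 single-port
fentanyl 0.1 mg/ml FR1 with the reward cue (side flipped on day 4), days
5–8 two-port choice FR1, days 9–12 FR3, day 13 onward FR5 with fentanyl
at 0.15 mg/ml, with the liquid/side assignment swapping daily throughout
the choice phase.  Drop volume is 10 µl everywhere.  Day numbering is
1-based with boundaries at lights-on, so a dark phase is never split
across days.  The FR1 and FR3 choice stages are fixed at four days each;
the FR5 stage is open-ended.  The cue is enabled for every
fentanyl-bearing stage by default (configurable off per stage); water
carries no cue.  A pre-experiment checklist entry records the two days of
0.1 mg/ml quinine habituation in the home cage, matching the reference
liquid's bitterness to the drug solution.

Per-mouse overrides replace the stage's schedule settings wholesale,
which is the mechanism for individually tailored contingencies.
Protocols serialize to TOML and re-parse to an equal configuration.

## Cohort simulator

The generative model per agent, chosen as the simplest family that
reproduces each qualitative pattern the assay is known for:

| parameter | default | meaning |
|---|---|---|
| `base_visit_rate` | 1.5 /h | light-phase visit rate |
| `dark_light_rate_ratio` | 3 | dark-phase rate multiplier (12-h square wave) |
| `intra_bout_revisit_rate` | 0.6 | P(immediate re-entry) after a visit |
| `bout_continuation_water/fentanyl` | 0.35 / 0.45 | geometric bout-size continuation |
| `fentanyl_choice_prob` | 0.55 | P(visit targets the fentanyl port) |
| `choice_escalation_per_day` | 0.02 | daily increment on the choice probability |
| `bout_escalation_per_day` | 0.01 | daily increment on fentanyl continuation |
| `poke_interval_mean_s` (± jitter) | 1.0 ± 0.35 | truncated-normal poke spacing, clipped to [0.15, 2.8] s |
| `entrainment_fidelity` (per port) | 0.85 | P(poke count stops exactly on a reward multiple) |
| `p_zero_poke_visit` | 0.05 | P(entry with no poke) |
| `pr_cap_fentanyl` / `pr_cap_water` | 8 / 3 | PR motivation caps |

Visits are a piecewise-homogeneous Poisson process (two rates, 12-h
square wave); with ratio 3 and equal phase lengths the expected dark
visit share is 3/4.  Revisit chains (geometric with continuation 0.6,
gaps of 0.2 s + Exp(4 s) past the trial end) produce the clustered ITI
distribution with a pooled median well under 20 s.  Bout targets are
geometric; a non-entrained visit (probability `1 − fidelity`, at ratios
> 1) undershoots its final reward, overshoots by a non-multiple
remainder, or disengages before the first reward (probabilities 0.4 /
0.4 / 0.2), which simultaneously lowers reward efficiency and the
entrainment score — the coupling observed in poorly entrained animals.
Escalation is linear-per-day on the choice probability and fentanyl
continuation, clipped to valid ranges; no functional form being
established, linear is the minimal choice.

The **inhibited phenotype** raises fentanyl bout continuation by 0.3
(capped at 0.9) and lowers fentanyl-port entrainment fidelity by 0.5
(floored at 0.1), leaving every water parameter untouched, so the
contrast reproduces: right-shifted fentanyl bout-size CDF, statistically
unchanged water CDF, lower reward efficiency at FR3/FR5, and a lower
entrainment score.

Single occupancy is enforced by serializing visit blocks through the
drinking zone: a visit that would begin while the zone is busy waits
0.05 s past the previous trial's end.  Visits are dropped rather than
truncated when queueing would push them across the lights-on day
boundary (a ≤ 30-s window per day), so a trial's contingency is always
that of a single day.  The simulator fabricates only RFID reads and
pokes; rewards and cues come from replaying that stream through the
engine, which makes simulator/engine consistency an exact identity.

Randomness: one root seed; each agent draws from a substream keyed by
(seed, SHA-256 of its tag), so adding an agent never perturbs the
others' draws (occupancy queueing may shift event times but never
removes entries).

The PR session uses a deterministic motivation-cap model: an agent keeps
completing the current requirement of a liquid exactly until the
requirement would exceed its cap, so the recovered breakpoint equals the
cap — which is what makes cap recovery an exact oracle rather than a
statistical one.

### What the simulator does and does not emulate

It reproduces circadian rate modulation, bout clustering, drug
preference and escalation, schedule entrainment and its failure modes,
individual visit-count/trial-length profiles, cage-level rate
multipliers, and single-occupancy queueing.  It does **not** model
spatial behavior, social hierarchy or dominance at the tube,
pharmacokinetics/satiety feedback, or sex and strain differences.
Passing tests therefore validate the pipeline's correctness and the
estimators' ability to recover known generative structure; they are not
evidence about any particular animal dataset.

## Metrics: conventions and numerics

* Zero-poke entries are visits: they count in visit totals and in the
  denominator of reward efficiency (an RFID entry is a visit by
  definition).  A mouse-day with no visits yields an explicit zero-intake
  row; its efficiency is NaN (flagged missing), never silently dropped.
* Fentanyl mass uses the concentration of the stage active on the
  reward's day, so the 0.1 → 0.15 mg/ml step is respected.
* The pokes-per-trial histogram is parameterized by *liquid*, not
  physical side, because the side swaps daily; the port is resolved per
  trial day.  The entrainment score is the fraction of poke-containing
  trials whose count at that port is an exact positive multiple of the
  active ratio (trivially 1 at FR1) — a scalar summary defined by this
  package for a pattern usually shown only as histograms.
* ITIs are next-trial start minus current-trial end, computed within
  mouse; both per-mouse and pooled modes are provided.  Histogram bins
  are logarithmic.
* Escalation slope is per-mouse OLS of daily mg on day (≥ 3 days), with
  a t-based 95% interval; group-level mixed-model inference is left to
  standard statistics software, to which the emitted tidy tables are
  directly consumable (this is deliberate scope, not a gap).
* The trial-length/visit-count profile is fit as `a·exp(−b·count)` with
  `a, b ≥ 0` by constrained nonlinear least squares (optional additive
  offset `c`).  R² is reported on the fitted scale and defined as 0 for
  zero-variance data; non-convergence raises an error carrying the data
  ranges rather than failing silently.
* PR breakpoints equal same-liquid reward counts (valid because the
  requirement starts at 1 and increments by one per reward); when the
  session's final PR state is supplied, the ledger is cross-checked
  against it and rejected on mismatch.  The paired fentanyl-vs-water
  comparison is a paired t-test; a constant nonzero paired difference is
  reported as an infinite statistic with p = 0 rather than a warning.
* Group comparisons: two-sample KS on poke-count distributions per FR
  stage with Bonferroni correction across stages; groups with fewer than
  two observations are rejected.

## Problem sizes

The test suite and the acceptance script run on deliberately moderate
cohorts — typically 4–16 mice for 2–14 days, 1000 fuzzed streams for the
oracle cross-check, and 10–20 seeds for directional recapitulation
checks — sizes at which every qualitative contrast is already decisive
while a full run stays in the tens of seconds.  All sizes are ordinary
function arguments, so larger studies are a parameter change.

## Known limitations

* The engine resolves a trial's contingency at trial start; a trial
  physically straddling lights-on would keep its opening day's settings
  (the simulator never generates one).
* The acquisition-side on-disk format of any particular hardware vendor
  is out of scope; external logs must be converted to the documented CSV
  or JSON-lines schema first.
* Simulated escalation is linear and unbounded short of its clips; it is
  a scaffold for estimator validation, not a pharmacological model.
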