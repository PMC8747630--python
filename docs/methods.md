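# Methods

This note documents the model implemented by `adlsim`, the parameters that
matter, how the per-stage presets were calibrated, the numerical choices,
and what the simulations do and do not say about real patients.

## Scope and assumptions

The simulator models the *cognitive* execution of three daily activities
(tea preparation, washing hands, dressing) by subjects at four Clinical
Dementia Rating stages: CDR-0.5 (MCI / questionable AD), CDR-1 (mild),
CDR-2 (moderate), CDR-3 (severe). It deliberately excludes perception and
motor control: the working hypothesis is that memory and executive errors
account for the bulk of functional failures across the AD spectrum, and
that is what functional tests such as the Kitchen Task Assessment (KTA) and
the Executive Function Performance Test score. Consequently:

- there is no base-level decay learning over time (memory is treated as
  already in decline; base levels are stable within a run, and caregiver
  boosts are the only within-episode modifier);
- object locations and the physical environment are not modelled; confusing
  the *locations* of items is not represented — item-to-item similarity is
  used instead and has the same observable effect;
- spreading activation is binary (a source is associated with a chunk or it
  is not); no fan effects or utility learning beyond the help-escalation
  bonuses.

## Error mechanics

**Omission and commission (organizational errors).** A retrieval step cues
a target chunk. The competition set is the target plus every chunk with an
explicit similarity entry to it — commission semantics stay auditable
because each activity file enumerates exactly which confusions exist
(teabag–water and mug–kettle for tea, soap–shampoo for handwashing, …).
Each candidate draws one activation; the argmax wins (ties to the target: a
deterministic, conservative choice), a sub-threshold winner is an omission,
a non-target winner a commission. A commission counts as "similar
confusion" when the winner is the target's designated partner (the entry
with the largest similarity), otherwise as "other confusion".

**Behaviour errors.** Every behaviour step is a {succeed, fail} production
pair with the same utility noise; the succeed production's noise-free
utility advantage (the *utility gap*) is the per-stage behaviour-difficulty
knob. Sequencing steps carry a `conflict_group` naming the steps they can
be swapped with; initiation, perseveration ("performs one step over and
over") and completion failures are carried by the category tag of the step
on which they occur, so failures route to KTA components structurally.

**Help escalation.** Retrieval: failure → boost (+`boost_increment` to the
target's base level) → retry, at most `max_attempts` (3) attempts; success
after 0/1/2 boosts = independent/verbal/physical, three failures = not
capable. Behaviour: failure → verbal-help production (extra utility
`help_extra_verbal`) → physical-help production (`help_extra_physical`) →
not capable. A not-capable step is skipped and later stages proceed — the
caregiver is assumed to complete it, and the functional test keeps scoring
through the task. Whether an initiation failure should instead abort the
whole activity is genuinely open; continuing with caregiver help was chosen
because it matches how the KTA is administered.

**Scoring.** A KTA component = the maximum help level over the events of
the steps tagged with it. Max rather than mean keeps component scores
integral (0–3, as the test sheet defines them) and matches the test's
"amount of help needed" semantics. Adding help events can therefore never
lower a score (a property the test suite checks).

## Noise

Both noise terms are zero-mean logistic with per-stage scales (Gaussian is
available via `noise_dist`). Logistic noise is the convention of the
ACT-R model family this simulator follows, and it gives closed-form
pairwise win probabilities, which the test suite uses as independent
oracles (computed by numerical quadrature over the logistic density, not by
the engine's own code path).

## Parameters and presets

Fixed by convention: `W_total = 1` for healthy attention, `S = 2`,
base levels 0. Per-stage structure (the progression "shape", not fitted):

| parameter            | cdr0.5 | cdr1 | cdr2 | cdr3 | meaning |
|----------------------|-------:|-----:|-----:|-----:|---------|
| `W_total`            | 1.00 | 0.85 | 0.70 | 0.55 | attentional weight, falls with severity |
| `noise_scale_act`    | 0.45 | 0.55 | 0.70 | 0.85 | activation noise scale |
| `noise_scale_util`   | 2.0  | 3.0  | 4.0  | 5.0  | utility noise scale |
| `help_extra_verbal`  | 29   | 27   | 24   | 21   | verbal-help utility bonus (kept in the effective 20–30 band; help is less effective late) |
| `help_extra_physical`| 37   | 35   | 32   | 29   | always 8 above verbal |
| `P` (matching scale) | 8.0  | 8.0  | 8.0  | 8.0  | see below |
| `boost_increment`    | 1.0  | 1.0  | 1.0  | 1.0  | base-level gain per help boost |

The matching scale was set so that the penalty of the closest similar item
(`P·|M| ≈ 2.4` for M = −0.3) sits a few noise scales below the target's
activation: commission errors then form a modest, severity-increasing share
of retrieval failures (≈1% of first attempts at CDR-0.5 up to ≈10% at
CDR-3) instead of swamping omissions. One preset per level is shared by
all three activities; per-activity presets would need per-activity
benchmark scores that do not exist.

**Calibrated per stage** (the shipped values in `data/profiles.yaml`):

- *retrieval threshold* τ — placed so the first-attempt retrieval success
  probability hits a structural anchor ladder 0.95 / 0.6^(1/4) / 0.70 /
  0.50. The CDR-1 anchor is chosen so that a four-retrieval organization
  component needs help with probability 1 − (0.6^(1/4))⁴ = 0.40 — the
  40-of-100 verbal-help / 60 independent split reported for mild AD on the
  kitchen task. τ is read off directly as a quantile of 20 000 simulated
  winning target activations (success = target wins *and* clears τ), which
  makes the fit deterministic and exact to Monte-Carlo resolution.
- *behaviour utility gap* — the only parameter fitted against the mean KTA
  targets, by coarse-to-fine grid search (25-point grid over [−80, 40], two
  refinement rounds) minimising |simulated mean − target| with a
  1000-subject evaluation cohort under common random numbers per level.

Calibration targets are the published reference mean KTA totals per stage —
1.73 / 4.6 / 9.67 / 13.36 on a kitchen task (Baum & Edwards' KTA provides
the clinical anchor; Serna et al.'s 2007 ACT-R cooking simulation is the
prior computational benchmark, means 1.69 / 4.52 / 9.87 / 13.84). Only
means are fitted; SDs are reported but not targeted (the simulated SDs,
≈1–2 points, are narrower than the clinical ones, as is typical for a model
without between-subject parameter heterogeneity). The shipped presets were
produced by `adlsim calibrate` with `--n-per-eval 1000 --seed 42` and
regenerate deterministically.

## What the simulations show — and what they do not

A cohort run draws n independent subjects from per-stage parameter
distributions that differ only through noise; it emulates the *average*
error and help profile of a stage, not individual heterogeneity,
comorbidity, day-to-day fluctuation, or environment effects. Matching the
benchmark means therefore validates the severity gradient and the help
ladder's bookkeeping, not patient-level prediction. The activity step
lists (10–14 steps each) are canonical occupational-therapy breakdowns;
the benchmark scores constrain score *distributions*, not step identity, so
editing the activity files changes flavour, not calibration targets —
except through the number of retrieval steps per category, which the
organization anchor depends on.

## Numerical and reproducibility choices

- Per-subject RNG substreams are spawned from one `SeedSequence`, so cohort
  results are bit-reproducible per seed and independent of cohort size
  ordering. All library entry points take either a seed or a Generator.
- Ties (equal activations, equal utilities) are broken deterministically:
  target first, list order first. With continuous noise they have measure
  zero; the rule matters only for noise-free configurations.
- Cohort SD uses the n−1 denominator and is defined as 0 for n = 1.
- Degenerate inputs: an empty context contributes no spreading activation
  (no division by zero); similarity scaling clips to [−1, 0]; calibration
  rejects infeasible bounds and any fitted set violating the monotone
  severity ordering (W nonincreasing, noise scales nondecreasing).
- Problem sizes: acceptance-style checks use 1000-subject cohorts (mean
  standard error ≈ 0.05 KTA points) and 100 000-episode Monte-Carlo oracle
  comparisons with 3σ margins; the calibration demo in `examples/` is
  scaled to 300-subject evaluations.

## Known limitations

Simulated SDs undershoot clinical SDs (no subject heterogeneity). The
"other confusion" channel is rare because far distractors carry large
similarity penalties. Latency is not modelled, so G and C are abstract
utility units rather than real time estimates. The five-category cohort
chart option hides (never merges) the performs-all-steps component; totals
always include all six.
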