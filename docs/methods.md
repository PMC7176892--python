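# Methods

This note documents the models and conventions behind `mhqtools`: the
branching-instrument semantics, the operational case definitions, the
synthetic-cohort generator, the tabulation conventions, and the numerical
and design choices that were genuinely open.

## 1. Instrument model and skip semantics

An instrument is an ordered list of coded items plus skip rules.  Each rule
has a single trigger item, a set of trigger codes, and a forward-pointing
list of skipped items; instrument order is therefore a topological order and
presentation resolves in one forward pass.

Gates that depend on *either* of two screens (the CIDI-SF depression and
mania flows) are encoded as rule chains that mirror the instrument's actual
flow: a positive first screen skips the second screen and opens the detail
block; a negative second screen skips out.  The net behaviour is "detail
presented iff either screen endorsed".

A rule fires when its trigger item was presented and either answered with a
trigger code or *declined* (including "do not know"): a respondent who
declines a screening question is conservatively routed past the items it
gates.  A rule whose trigger was itself rule-skipped never fires.  One known
corner: if a declined gate sits inside a chain, downstream chained rules
cannot fire (their trigger is rule-skipped), so the deepest detail items
default to presented.  This only affects records with declined screens,
whose classifications are unassessable regardless.

Response statuses are four-way — answered, declined, rule-skipped, absent —
and the distinction is load-bearing: rule-skipped is *information* (the
respondent screened out), declined/absent is missingness.  Declined and
"do not know" sentinels (−818 / −121 in delimited files) are both treated as
declined for analysis; the data dictionary preserves both codes.

Completion: a record is `complete` when every presented item is answered
**or declined** (declining is a response), `not_started` when nothing is
answered, else `partial`.

## 2. Case definitions and missing data

Classifiers are deterministic functions of one record and a versioned
ruleset; every threshold, required count, duration and item binding lives in
`data/ruleset_default.yaml`.  The bundled defaults encode DSM-IV
operationalisations of the named instruments (CIDI-SF lifetime depression
and GAD; a 1-week hypomania/mania duration rule; AUDIT ≥8; PCL-6 sum ≥14).
The ruleset is flagged `provisional`: the bundled instrument is a structural
skeleton with placeholder wording, and a deployed instrument's exact
criteria can be transcribed into the same file without code changes.

Missing data use Kleene three-valued logic.  Each atomic criterion
evaluates to true/false/unknown (symptom counts use known-true and
known-possible bounds); the conjunction decides the verdict whenever it can.
Hence a record that already fails a *known* criterion is `not_met` even with
other items missing, and `unassessable` is reserved for records whose
missing items could change the verdict.  Two deliberate exceptions: the
AUDIT and PCL sums are not prorated — any declined/absent bound item makes
those classifications unassessable, because a cut-off on a partial sum is
undefined.  Items skipped by a *declined* gate are treated as unknown, not
as "not endorsed" (tracked per record as `decline_skipped`).

Derived outputs:

* **Bipolar gating.** Likely bipolar affective disorder requires both
  lifetime mania and lifetime depression; mania without depression is never
  labelled bipolar.  If one input is unassessable and the other is not
  failed, the flag is unassessable.
* **Mood groups.** Precedence bipolar > recurrent depression (≥2 episodes)
  > single episode > subthreshold (screen endorsed, criteria unmet) > no
  depression.  The group is undefined (QC-counted, excluded from mood
  tables) when depression is unassessable, or when depression is met but
  the episode count is missing.  When depression is met and *mania* is
  unassessable, the record falls through to recurrent/single so that every
  record with assessable depression keeps a defined group; the bipolar
  group is assigned only on a met bipolar flag.

## 3. Synthetic cohort generator

The generator emulates a volunteer cohort of middle-aged and older adults
(ages 45–82, 53% ≥65, 57% female) completing the questionnaire online.  It
exists to validate the pipeline: defaults are chosen for realism of
structure, not to estimate any population.

**Latent joint model.**  Eight syndrome indicators (depression, mania, GAD,
unusual experiences, self-harm, hazardous alcohol use, current PTSD,
addiction) follow an Ising-style pairwise-tilted multivariate Bernoulli:
P(x) ∝ exp(Σᵢ αᵢxᵢ + Σᵢ<ⱼ βᵢⱼxᵢxⱼ).  Pairwise tilts βᵢⱼ (log-odds-ratio
scale) are the comorbidity dials; with eight nodes the 256-state
distribution is computed exactly, so sampling involves no MCMC.  Default
marginals: depression 0.24, alcohol 0.21, GAD 0.07, PTSD 0.06, unusual
experiences 0.05, self-harm 0.04, addiction 0.06, mania 0.02.  The default
depression–GAD tilt (1.7) was set from the exact joint so that
P(depression | GAD) ≈ 0.75, the strong anxiety–depression overlap typical
of such cohorts; other tilts encode directionally sensible positive
comorbidity (strongest around depression, self-harm and PTSD; weak between
alcohol and the rest).

**Covariates.**  Sex, age band, education, deprivation quintile, tenure,
long-standing illness, neuroticism (Binomial(12, 0.33)), childhood/adult
adversity, trauma exposure and loneliness are drawn independently at
configured rates.  Seven binary features (male, over-65, the four adversity
and loneliness flags, high neuroticism ≥7) shift the latent fields by
configured log-odds offsets — directions follow the established
epidemiology (depression/GAD commoner in women, alcohol and addiction in
men, everything rarer over 65, adversity and neuroticism raising risk);
magnitudes are this generator's defaults.

**Calibration.**  Because offsets shift the fields, the base αᵢ are
calibrated by coordinate-wise bisection (Brent's method per coordinate,
sweeps to convergence) so that the *mixture-averaged* marginals — exact
256-state marginals weighted by the analytic stratum probabilities of the
2⁷ feature combinations — equal the configured prevalences to within 10⁻⁴.
Unattainable targets (e.g. extreme prevalences under strong repulsive
tilts) raise a configuration error.  Depression splits into
single/recurrent by an independent `recurrent_share` coin (default 0.6
recurrent), making the two subtypes mutually exclusive by construction.

**Emission.**  For each scale, a classification-consistency coin is
flipped: a true positive yields a criteria-satisfying pattern with
probability `sensitivity`, a true negative a criteria-satisfying pattern
with probability `1 − specificity` (defaults 0.95/0.99).  The concrete
pattern is then drawn from the pre-enumerated set of skip-consistent
patterns whose classification — by the package's own classifiers — matches
the outcome.  Integer items are enumerated over small representative grids
spanning both sides of each threshold (e.g. depression duration
{1, 2, 4, 26} weeks; AUDIT items {0, 2, 4}), keeping each scale's pattern
space between 2 and ~4×10⁴ patterns; enumeration is cached per
(instrument, ruleset) version.

Within the negative class of a gated scale, sampling is uniform *within* an
engagement partition: with configured probability
(`screen_engage_given_negative`; defaults depression 0.15, mania 0.08, GAD
0.14, alcohol 0.93 — most adults drink) the true-negative engages the
screen and draws an engaged-but-unmet pattern (producing, e.g., subthreshold
depressive symptoms); otherwise it takes the screen-negative path.  Strictly
uniform sampling over the whole class would make engaged patterns dominate
combinatorially and leave essentially no screen-negative respondents.  The
partition never crosses a classification boundary, so truth recovery and
the attenuation identity are unaffected.

The adult-adversity and loneliness screens share the confiding-relationship
item, so their four items are emitted as one joint block conditioned on the
pair of latent flags.  Risk screens and demographic fields are exact
recodes of the latent profile (the fidelity coin applies to the eight
syndrome scales); self-reported diagnosis ticks and health behaviours are
drawn from simple configured conditional rates given the latent states.

**Censoring.**  Each answered item is declined independently with
`decline_rate` (default 0.01); with `partial_rate` (default 0.03) the
respondent abandons at a uniformly chosen presented item, and later items
become absent.  After censoring, skip marks are re-derived so every emitted
record passes structural validation with zero violations.  A consequence of
the declined-gate rule: with perfect parameters the attenuation identity
classified prevalence = p·se + (1 − p)(1 − sp) holds exactly only with
censoring off; the validation suite tests it under those conditions.

**Reproducibility.**  One global seed; the latent draw and each
respondent's emission use independent `SeedSequence([seed, stream, i])`
substreams, so output is byte-identical across runs and independent of
generation order.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: item-level psychometrics (no item-response
theory; patterns are uniform within consistency classes), nonresponse
driven by latent state (no selection-bias simulation; decline and
abandonment are independent of the truth), recall error structure, and any
population-representative joint distribution of covariates.  Classified
comorbidity conditionals are also attenuated relative to the latent ones
under imperfect fidelity (false positives dilute the conditioning set) —
e.g. a latent P(dep|GAD) of 0.75 surfaces as ≈0.62 at the default
fidelities.

## 4. Tabulation conventions

Cross-tabs are pairwise complete-case: cell (i, j) counts respondents
meeting row syndrome i among those assessable for both i and j, and its
denominator is reported explicitly.  Characteristics tables are per-cell
complete-case with explicit numerators and denominators; respondents may
belong to several syndrome strata, and the "none of the above" stratum
means criteria not met for depression, GAD, unusual experiences or
addiction.  Percentages render to one decimal and are always accompanied by
counts.  Confidence intervals are intentionally not produced (an optional
extension point); at the intended cohort sizes they add little, and the
explicit denominators support any external calculation.

## 5. Numerical and degenerate-input choices

* Calibration tolerance 10⁻⁴ on marginals; α bounded in [−30, 30]; failure
  to bracket or converge raises rather than warns.
* Empty strata/rows render as NaN ("undefined") with zero denominators,
  never as 0%.
* Ties at cut-offs: all cut-offs are "met at or above" (AUDIT 8, PCL 14,
  duration thresholds), matching the instruments' printed conventions.
* Multi-choice "none of the above" is an explicit code, so an empty tick
  set is distinguishable from a declined tick list.
* The pipeline manifest contains versions, seed and SHA-256 checksums but
  no timestamps; timings go to the log, keeping artifacts byte-identical
  under a fixed seed.

## 6. Validation strategy and problem sizes

The test suite validates each classifier against an independently coded
brute-force evaluation of the written rule over every enumerable response
pattern of its bound items (reduced value grids for integer items;
~2–8×10⁴ patterns per scale), checks exact truth recovery on a 5 000-person
perfect-fidelity cohort, the analytic attenuation at n = 20 000 and
fidelity (0.9, 0.95) within three standard errors, latent calibration at
n = 100 000 within the binomial sampling bound, cut-off boundary behaviour,
hand-enumerated toy tabulations with transpose symmetry and conservation on
simulated cohorts, and byte-identical artifacts across repeated pipeline
runs.  These sizes keep the full suite under a minute on one CPU while
leaving the stochastic checks' standard errors far below the tested
effects.

## 7. Known limitations

* The bundled instrument is a faithful structural skeleton, not the
  deployed item bank; prompts are placeholders and the ruleset is marked
  provisional pending transcription of exact criteria.
* The PCL-6 cut-off (14) and childhood-trauma per-item thresholds follow
  published short-form conventions but are configuration, not ground truth.
* Tri-state semantics are conservative: records can be unassessable that a
  human rater might adjudicate.
* The generator's associations are pairwise only; higher-order comorbidity
  structure is whatever the pairwise model implies.
* Prevalence outputs describe the synthetic configuration or the supplied
  cohort — never population estimates; volunteer cohorts of this kind are
  subject to healthy-volunteer selection that this package does not model.
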