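# mhqtools

Computable mental-health phenotyping from branching questionnaire data, with
a synthetic cohort simulator.

Large cohort studies increasingly assess lifetime mental-health phenotypes
with online self-report questionnaires built from validated screening
instruments — the UK Biobank "thoughts and feelings" mental health
questionnaire (MHQ) is the canonical example.  Such instruments have a
branching structure: screening questions and skip rules limit detailed
symptom items to respondents for whom they are relevant, and respondents may
decline any question.  Turning the resulting item-level data into *likely*
disorder phenotypes requires (a) faithful skip-rule semantics, (b) careful
missing-data handling, and (c) exact, auditable operational criteria.  The
real response data are access-restricted, so this package pairs the
phenotyping pipeline with a synthetic cohort generator with known latent
ground truth — every classifier and table can be validated end to end
without restricted data.

It is written for epidemiologists and psychiatric-genetics researchers who
derive categorical phenotypes from survey items and need the derivation to
be reproducible, configurable, and testable.

## What it computes

**Instrument model** (`mhqtools.instrument`) — items, codings, sections,
skip rules; the presented-item set for any response record; structural
validation; completion status.  Responses carry a four-way status:
answered / declined / rule-skipped / absent.

**Case definitions** (`mhqtools.phenotypes`) — deterministic tri-state
(met / not met / unassessable) classifiers:

- lifetime major depressive episode, CIDI-SF style (DSM-IV
  operationalisation): ≥1 core feature (depressed mood or anhedonia) most of
  the day nearly every day for ≥2 weeks, total symptom count ≥5, with
  impairment; episode count separates single from recurrent illness;
- lifetime hypomania/mania: elated or irritable period with the required
  associated symptoms lasting ≥1 week;
- lifetime generalised anxiety disorder: ≥6 months of excessive,
  hard-to-control worry with ≥3 associated symptoms;
- current hazardous/harmful alcohol use: AUDIT total score ≥8 (not
  prorated);
- current post-traumatic stress: 6-item PCL short-form sum at/above a
  configurable cut-off (default 14);
- lifetime unusual (psychotic-like) experiences, self-harm irrespective of
  intent, and self-reported addiction;
- the gated bipolar flag (mania **and** depression — mania alone is never
  labelled bipolar, because screening for rare disorders in the general
  population has poor positive predictive value) and the five-level mood
  grouping: bipolar > recurrent depression > single-episode depression >
  subthreshold symptoms > no depression.

All thresholds and item bindings live in a versioned YAML ruleset
(`mhqtools/data/ruleset_default.yaml`), so criteria can be transcribed or
amended without touching code.  Missing data follow three-valued logic: a
classification is `unassessable` only when the declined/absent items could
change the verdict.

**Risk factors** (`mhqtools.risk`) — childhood trauma screener, adult
adversity, trauma triggers, loneliness, social isolation, and demographic
recodes (age band, deprivation quintile, housing tenure, education, health
behaviours).

**Synthetic cohort** (`mhqtools.simulate`) — latent syndrome states drawn
from a pairwise-tilted multivariate Bernoulli (joint mass ∝
exp(Σ αᵢxᵢ + Σ βᵢⱼxᵢxⱼ)) with fields calibrated exactly to configured
prevalences; covariates shift the fields in the configured directions
(e.g. depression commoner in women, alcohol misuse in men, all syndromes
rarer over 65).  Item responses are emitted in two stages — a
sensitivity/specificity coin per scale, then a draw from the enumerated
skip-consistent patterns matching that outcome — followed by configurable
decline and abandonment censoring.

**Tabulation** (`mhqtools.tabulate`) — self-reported diagnosis prevalence,
row-conditional comorbidity cross-tabs, characteristics by syndrome or mood
group, sex stratification, and label-matched joins against user-supplied
external prevalence tables.  Every percentage is reported with its explicit
denominator.

## Worked example

```python
import mhqtools as m

spec = m.default_instrument()
rules = m.default_ruleset()
cfg = m.default_cohort_config(n=1000, seed=1)

records, truth = m.generate_cohort(cfg, spec, rules)
phen = m.classify_all(records, spec, rules)

n = len(phen)
for name in ("depression", "alcohol_hazardous"):
    k = sum(p.syndromes[name].met for p in phen)
    print(f"{name}: {k} ({100 * k / n:.1f}%)")
print("any syndrome:", sum(p.any_syndrome for p in phen))

from mhqtools.tabulate import comorbidity_crosstab
print(comorbidity_crosstab(phen).to_frame("pct").iloc[:3, :3])
```

prints

```
depression: 215 (21.5%)
alcohol_hazardous: 194 (19.4%)
any syndrome: 462
            depression  mania    gad
depression       100.0    7.6   24.5
mania             51.6  100.0   15.6
gad               62.7    6.0  100.0
```

At these default conditions (24% latent lifetime depression, 21% hazardous
alcohol use, positive pairwise comorbidity tilts, 95%/99% emission
sensitivity/specificity, 1% item decline, 3% abandonment) about 22% of
respondents are classified with likely lifetime depression and 46% with at
least one syndrome; each comorbidity cell is the share of the row syndrome's
cases who also meet the column syndrome among respondents assessable for
both — e.g. 62.7% of likely-GAD cases also meet depression criteria.

The same stages are available from a shell:

```sh
mhqtools simulate --out out/ --n 1000 --seed 1
mhqtools validate --in out/responses.tsv
mhqtools phenotype --in out/responses.tsv --out out/phenotypes.tsv --risks-out out/risks.tsv
mhqtools tabulate --phenotypes out/phenotypes.tsv --which table2 --out out/table2.tsv
mhqtools run --out out/ --n 1000 --seed 1      # full pipeline + manifest
mhqtools export-dictionary --out out/dict.tsv
```

## Caveats

Classifications are *likely* syndromes from self-report, not clinical
diagnoses, and the synthetic cohort is a modelling device: its prevalences
and associations are configured, not estimated, so outputs characterise the
pipeline, never a real population.  See `docs/methods.md` for the model,
its assumptions, and known limitations.
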