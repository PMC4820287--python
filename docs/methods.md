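# Methods

## The classification model

`aaapheno` treats case/control ascertainment as a deterministic rule
cascade over coded encounter data. The underlying clinical logic: an AAA
repair procedure is near-certain evidence of disease (Type 1); a
ruptured-AAA diagnosis assigned by the specialty service responsible for
AAA care is strong evidence (Type 2); repeated unruptured-AAA diagnoses at
such a service on separate visits indicate a confirmed diagnosis rather
than a working hypothesis (Type 3). Conversely, syndromic aortic disease
and dissection are phenocopies of the non-syndromic trait of interest, AAA
evidence at age ≤ 40 suggests trauma or an unrecognized syndrome, and a
lone `441.*` code is too likely to be a referral diagnosis or miscoding to
allow the subject into either group. Controls must additionally have been
seen recently, because AAA is late-onset and silent: a subject not under
observation cannot be asserted disease-free.

The cascade order is part of the model. Phenocopy and age exclusions
precede case typing (a Marfan patient with a repaired aorta is not a study
case); case types are tested in decreasing order of certainty, so a
subject satisfying several definitions gets the most certain one; the
residual-code and recency filters apply only to potential controls — an
operated case does not lose its label for lack of a recent visit. Each
label carries the triggering events as evidence, so every call is
auditable.

Two age rules coexist deliberately. Eligibility is assessed at the
reference date (inclusive bounds, default 40–89), while early onset is
assessed at the earliest AAA-evidence event (default ≤ 40). They answer
different questions — "is this person in the study's age range now?" vs
"did the disease appear implausibly early?" — and are configured
independently.

### Ages and dates

The input contract carries age-at-event, not birth dates (identifiers
aside, this keeps the extract minimally identifying). Age at the reference
date is therefore reconstructed as the age at the subject's most recent
event plus the whole years elapsed since; with multiple events on the
anchoring day the maximum recorded age is used. Subjects with no events
cannot be age-assessed and fall through to the no-recent-encounter
exclusion. Dates are compared at calendar-day granularity: two codes on
the same day are one "date" for the distinct-dates rule, since the rule's
purpose is to require separate visits. Years convert to days as 365.25 ×
years, so the recency boundary is leap-year-stable; an encounter exactly
at the boundary counts as recent.

### Reference date

"Within the past 5 years" needs an anchor. Production runs anchor on
execution time implicitly; a reproducible artifact cannot, so the engine
takes an explicit `reference_date`, or resolves `"auto"` to the latest
event date across both streams (and refuses to guess when there are no
events at all). The resolved value is echoed in the run manifest.

An alternative reading of the 5-year requirement — at least five years of
*record depth* rather than a recent encounter — appears in narrative
descriptions of this design. The encounter-recency reading is implemented
because it matches the control definition and the reported exclusion
counts; the record-depth variant would be a one-line predicate change and
is noted here as a known ambiguity rather than silently merged.

## Code sets

All rule predicates are set-membership tests over normalized codes.
Normalization maps every ICD-9 dialect to the dotted canonical form
("4414" → "441.4", left-padded numeric categories, upper-case V/E
prefixes) and is idempotent; matching is exact-string or explicit
trailing-wildcard (`441.*` matches `441`, `441.d`, `441.dd` and nothing
else — the bare category is included so a miscoded `441` can never reach
the control group; the conservative direction of error).

The registry enforces structural invariants at load time: all six roles
present, ruptured ∪ unruptured = AAA set, and every AAA diagnosis code
covered by the control-exclusion wildcard (otherwise controls could carry
AAA codes). The repair-CPT default list (EVAR 34800-series, open repair
35081/35082/35091/35092/35102/35103, post-EVAR open conversion
34830–34832) is a documented site-configurable default — the engine's
logic is independent of its contents — and the phenocopy list covers the
four named heritable disorders plus the non-abdominal 441.x family and
dissection codes. Production deployments should reconcile both lists with
the curated PheKB code list and local billing practice.

One vocabulary wrinkle: some descriptions of this phenotype print 444.3 as
the ruptured-AAA code. 444.x is the arterial embolism/thrombosis family,
not an aneurysm code; the default ruptured set is {441.3}, and a site that
disagrees can override it in one line of config.

## Validation statistics

PPV is estimated per stratum (predicted cases, predicted controls) as
confirmed/reviewed from blinded chart review. Intervals are exact
Clopper–Pearson, computed in the beta-quantile form; the printed bounds of
the pooled estimates (86.8–96.7 for 116/125; lower bound 97.0 for 122/122)
identify this as the method that reproduces the published figures, and the
test suite cross-checks the implementation against an independent
bisection inversion of the binomial tail sums and against
`statsmodels.proportion_confint(method="beta")`. The Wilson score interval
is available as an option for users who prefer a non-conservative
interval. Multi-site pooling sums counts per stratum; pooling means of
site PPVs would weight a 25-chart review equally with a 50-chart one and
does not reproduce the published pooled value. Percentages and CI bounds
are reported to one decimal.

Review samples are drawn uniformly without replacement per stratum from
the sorted subject-id lists with a seeded `numpy` generator, so a sample
is reproducible across runs and platforms; the exported review list is
shuffled and stripped of the predicted label (blinding), with a separate
sealed key file. When a stratum is smaller than requested the whole
stratum is taken with a warning, as happens at small sites.

Case-mix percentages are `100·count/total` rounded to one decimal. One
bundled example cell is worth flagging: the Mayo case-type counts
(72/0/106 of 178) give 40.4/0.0/59.6; a published rendering of the same
table prints 59.4 for the last cell, which is inconsistent with its own
counts, and this package reports the arithmetically correct value.

## The synthetic generator

The generator emulates the three extract streams with ten archetypes, each
constructed to trigger exactly one cascade rule under the default engine
configuration: the three case types; phenocopy; early-onset AAA;
single-code AAA; non-specialty-only AAA; stale record; and two control
flavours (sparse clean, code-heavy noisy). Per-subject ground truth
(expected label, case type or exclusion reason, and a separate
true-disease flag) is emitted alongside, so parameter-recovery tests can
demand 100% agreement rather than statistical similarity.

Defaults, chosen once for realism: a 10-year event window
(2004-01-01–2013-12-31), long enough to host both the early-onset recipe
(an AAA code 2–6 years before the reference date at age 36–39) and the
stale-record recipe (latest event pushed > 5 years before the window end);
case reference-ages 58–85, in line with the observed mean case ages of
71–80 in large AAA biobank cohorts (used as plausibility guidance, not a
fitted model); controls 50–85; Poisson noise of 2 extraneous benign codes
per subject drawn from a bundled list of common non-aortic ICD-9 codes.
Every subject has one latent birth date and all ages are derived from it,
so the engine's age reconstruction is exact; one benign anchor event is
always placed on the window's last day so `reference_date="auto"` resolves
to the window end the recipes are calibrated against (a mixture of only
stale records is rejected as unsatisfiable for this reason).

`perturb_to_false_positive` converts k clean controls into engine-level
Type 3 cases whose truth stays non-case — the synthetic analogue of
pre-aneurysmal aortic ectasia repeatedly coded at a vascular clinic, the
dominant false-positive mode for this phenotype, which a code-only
algorithm cannot see through. With n predicted cases after planting,
full-review PPV is analytically 100·(n−k)/n, giving the validation module
an exact end-to-end oracle.

What the generator does **not** model: code co-occurrence structure,
longitudinal disease progression, inter-site vocabulary drift, free-text
content, or data-entry pathologies beyond blank clinics. Passing the
synthetic round trip therefore demonstrates that the engine implements its
stated rules exactly — not that the rules achieve any particular PPV on a
real EMR, which is what blinded chart review is for.

## Numerical and design choices

- Clinic matching is exact string equality after trim + case-fold against
  a configured list; clinic vocabularies are site-specific, and fuzzy
  matching would make label changes un-auditable. A blank clinic is
  non-specialty (specialty attribution is a positive requirement).
- Events referencing subjects outside the identifier table are dropped
  with a logged count at load time, never classified.
- `case_type_distribution` with zero cases returns a zero-count table and
  performs no division.
- Tie-breaks: the early-onset rule uses the earliest AAA-evidence event by
  date; the age anchor uses the latest event (max recorded age on that
  day). Both are deterministic.
- Determinism: identical inputs and config produce byte-identical result
  tables; all stochastic components (generator, review sampling) are
  seeded `numpy` generators, and manifests record the seeds.
- Problem sizes used by the shipped checks — 1,000-subject recovery
  cohorts, 200 × 50-subject fuzz cohorts against the brute-force oracle,
  10,000-replicate coverage simulation — were chosen so the full suite
  completes in seconds while every archetype and predicate combination is
  exercised many times over.

## Known limitations

- The shipped repair-CPT and phenocopy lists are reconstructed defaults,
  not the curated production lists; sites must audit them (and PheKB)
  before use.
- Whether cases should also be subject to the recency filter is not
  resolvable from the published design; they are not, here, because the
  filter sits among the control rules. Flagged, configurable in effect by
  post-filtering results.
- ICD-9 only; mapping ICD-10-era extracts back to ICD-9 is out of scope.
- The adjudication of disagreeing duplicate chart reviews into one gold
  standard is not modelled; review outcomes are taken as single calls, and
  an "unsure" judgment on a predicted case counts against the algorithm
  (conservative).
- No NLP: aneurysm size is invisible to the algorithm, which is exactly
  why ectasia-driven false positives exist; the planted-false-positive
  machinery models their effect but nothing can remove them from coded
  data alone.
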