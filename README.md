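# aaapheno

Rule-based electronic-health-record phenotyping of **abdominal aortic
aneurysm (AAA)** cases and controls, with the chart-review validation
statistics used to certify such algorithms and a synthetic coded-EHR
generator that makes the whole pipeline testable without clinical data.

## The problem

Genetic and epidemiological studies of AAA need cohorts in which the cases
truly have a non-syndromic AAA and the controls are very unlikely to harbor
an occult one. Selecting them straight from diagnosis codes is unreliable:
a single ICD-9 441.4 is often a working or referral diagnosis, syndromic
aortic disease (Marfan, Ehlers-Danlos, dissection, thoracic aneurysm) is a
phenocopy of the trait under study, and AAA is a late-onset disease, so a
young "control" may simply not have developed one yet.

`aaapheno` implements a deterministic classification cascade over three
flat extract streams — subject identifiers, dated ICD-9 diagnosis events
and dated CPT procedure events, each carrying the assigning clinic and the
subject's age — and labels every subject exactly once:

| step | rule | outcome |
|---|---|---|
| 1 | any phenocopy diagnosis (759.82, 756.83, 437.5, 447.8, 441.0x/441.1/441.2/441.5–441.7/441.9, …) | excluded: phenocopy |
| 2 | age at the reference date < 40 or > 89 | excluded: age |
| 3 | earliest AAA evidence at age ≤ 40 | excluded: early onset |
| 4 | any AAA-repair CPT code | **case, Type 1** |
| 5 | ruptured-AAA code (441.3) at a specialty clinic | **case, Type 2** |
| 6 | AAA codes (441.3/441.4) at specialty clinics on ≥ 2 distinct dates | **case, Type 3** |
| 7 | any remaining `441.*` code | excluded: unconfirmed AAA code |
| 8 | no encounter within the last 5 years (or no events) | excluded: not recent |
| 9 | otherwise | **control** |

Case types are ordered by decreasing diagnostic certainty; the first
matching rule wins. Clinic lists, age bounds, the lookback window, the
reference date and every code set are configurable (`aaapheno show-config`
prints the complete defaults for site adaptation).

Validation follows the standard blinded-review design: equal random
samples of predicted cases and controls are reviewed by experts blinded to
the algorithm call, and per-stratum positive predictive value
`PPV = 100 · confirmed / reviewed` is reported with the exact
(Clopper–Pearson) binomial interval

```
lower = Beta⁻¹(α/2;  x,   n−x+1)      upper = Beta⁻¹(1−α/2;  x+1, n−x)
```

(with lower = 0 at x = 0 and upper = 1 at x = n). Multi-site results are
pooled by summing counts per stratum, i.e. the review-size-weighted
estimate. Sensitivity and NPV are not computable from this design and are
deliberately not reported.

> **Note on code lists.** The shipped code sets cover the ICD-9 codes that
> define the phenotype unambiguously; the AAA-repair CPT list and the tail
> of the phenocopy list are documented, site-configurable defaults. Before
> production use, confirm them against your site's billing practice and the
> curated code list published with the algorithm on PheKB.

## Worked example

Classify the bundled 60-subject synthetic fixture (6 subjects per
archetype; `examples/fixture_cohort/truth.csv` carries the ground truth):

```bash
aaapheno classify examples/fixture_cohort/subjects.csv \
                  examples/fixture_cohort/diagnoses.csv \
                  examples/fixture_cohort/procedures.csv --out out/
cat out/summary.json
```

```json
{
  "case_types": {"1": 6, "2": 6, "3": 6},
  "exclusion_reasons": {
    "aaa_onset_at_or_under_min_age": 6,
    "no_recent_encounter": 6,
    "phenocopy": 6,
    "unconfirmed_aaa_code": 12
  },
  "labels": {"case": 18, "control": 12, "excluded": 30},
  "n_subjects": 60,
  "reference_date": "2013-12-31"
}
```

All 18 case-archetype subjects are recovered with their intended types;
the 12 subjects with a single unconfirmed 441.4 or with AAA codes only at
non-specialty clinics are excluded rather than mislabeled, and the stale
records never reach the control group. `out/results.csv` holds the
per-subject labels and `out/manifest.json` the config echo and input
digests for reproducibility.

A PPV report from multi-site chart-review counts (here the bundled
example table; `--emerge-sites-only` pools the three network sites):

```bash
python -c "from aaapheno.datasets import example_chart_review_frame as f; \
           f().to_csv('counts.csv', index=False)"
aaapheno report counts.csv --sites GHS,Mayo,Marshfield
```

```
                             GHS              Mayo        Marshfield            Pooled
Case PPV            94.0 (47/50)      88.0 (44/50)     100.0 (25/25)    92.8 (116/125)
  95% CI               83.5-98.7         75.7-95.5        86.3-100.0         86.8-96.7
Control PPV        100.0 (50/50)     100.0 (50/50)     100.0 (22/22)   100.0 (122/122)
  95% CI              92.9-100.0        92.9-100.0        84.6-100.0        97.0-100.0
```

The pooled case PPV of 92.8% (116 of 125 reviewed case predictions
confirmed, exact 95% CI 86.8–96.7) and control PPV of 100% (122/122, CI
lower bound 97.0) are the headline performance figures of the algorithm;
per-site values show the spread across EMR systems.

Other commands: `aaapheno simulate` (synthetic cohorts from a YAML mixture
spec, see `examples/sim_config.yaml`), `aaapheno sample` (blinded review
samples with a sealed key file), `aaapheno show-config`.

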