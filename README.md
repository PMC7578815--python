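# fraudscreen

Rule-based screening of online survey cohorts for fraudulent and
low-quality responses.

When health-research participants are recruited through social media and
paid on completion, studies attract bots, coordinated "fraud farm"
respondents working through virtual private servers, and careless
(satisficing) respondents. `fraudscreen` implements a retrospective
screening pipeline for such cohorts: it reads a raw survey export, runs a
battery of indicator detectors, applies a fixed case-classification rule,
and reports cohort-level marginals. It is intended for survey
methodologists and research teams reviewing completed responses before
issuing remuneration or analyzing data.

## The indicator checklist and classification rule

Each completed case is checked against thirteen indicators in four
categories. Indicators that strongly suggest misrepresentation or
automation are designated **fraudulent**; those attributable to respondent
error or coincidence are **suspicious**:

| category | indicator | designation |
|---|---|---|
| inattention | completion time < 5 min | fraudulent |
| inattention | completion time < 10 min (but ≥ 5) | suspicious |
| inattention | straight-lining (identical answer to every closed item on a page) | suspicious |
| open text | exact response (> 2–3 words) shared by more than one respondent | fraudulent |
| open text | nonsensical/irrelevant response (human-annotated) | suspicious |
| open text | several responses follow the same phrasing pattern | suspicious |
| open text | verbatim duplicate of text in a reference corpus | suspicious |
| verifiable | reported location and zip-code prefix do not match | suspicious |
| verifiable | reported location and timestamp time zone do not match | suspicious |
| verifiable | reported treatment facility not a known cancer-care facility | suspicious |
| verifiable | timestamp time zone outside the United States | fraudulent |
| verifiable | referral names an organization not involved in recruitment | suspicious |
| automation | response to one or more hidden (honeypot) items | fraudulent |

The verdict is a pure function of the per-case counts
(*n<sub>F</sub>*, *n<sub>S</sub>*) of fraudulent and suspicious indicators:

* **fraudulent** iff *n<sub>F</sub>* ≥ 1 or *n<sub>S</sub>* ≥ 3
* **suspicious** iff *n<sub>F</sub>* = 0 and 1 ≤ *n<sub>S</sub>* ≤ 2
* **legitimate** iff *n<sub>F</sub>* = *n<sub>S</sub>* = 0

Hour of submission is summarized (share of surveys finished between
01:00–05:00 local; share of screenings submitted 00:00–04:00 Eastern) but
deliberately never enters the verdict.

## Worked example

Generate the packaged replication fixture — a deterministic 271-case
cohort (plus its 576-record screening funnel) whose indicator composition
matches a published fraud-compromised cohort — and screen it:

```bash
fraudscreen fixture --profile pozzar2020 --seed 1 --out fixture_out
fraudscreen screen \
    --responses fixture_out/responses.csv \
    --schema fixture_out/schema.json \
    --screening fixture_out/screening.csv \
    --out screen_out
```

The run log ends with:

```
... verdicts fraudulent=256 suspicious=15 legitimate=0
```

and `screen_out/summary.json` contains (excerpt):

```json
"verdict_pct": {"fraudulent": 94.5, "suspicious": 5.5, "legitimate": 0.0},
"category_pct": {"inattention": 49.1, "open_text": 50.9,
                 "verifiable": 86.7, "automation": 16.2},
"local_band_pct": 47.2,
"hidden_valid_ts_pct": 9.2,
"screening_est_band_pct": 82.5,
"screening_passed_pct": 47.0
```

Reading: 94.5% of the 271 cases classify fraudulent and 5.5% suspicious;
86.7% are inconsistent on at least one verifiable item pair; 16.2%
answered a honeypot item; 47.2% were submitted between 1 and 5 am in
their own reported time zone; 82.5% of eligibility screenings arrived
between midnight and 4 am Eastern. `screen_out/cases.csv` lists the
verdict, indicator counts and triggering codes per case.

A persona-mixture simulator is also available for stochastic testing:

```bash
fraudscreen simulate --n 200 --mix farm=0.5,legitimate=0.5 --seed 7 --out sim_out
```

It writes raw records plus a ground-truth persona sidecar; with the
shipped persona parameters roughly half of such a cohort ends up
classified fraudulent, tracking the planted farm share.

As a library:

```python
from fraudscreen import (generate_fixture, profile_cohort, classify_cohort,
                         summarize, packaged_zip_map, packaged_facilities,
                         packaged_channels)
fx = generate_fixture("pozzar2020", seed=1)
profiles = profile_cohort(fx.cohort, fx.schema, packaged_zip_map(),
                          packaged_facilities(), packaged_channels())
report = summarize(fx.cohort, profiles, classify_cohort(profiles), fx.screening)
print(report.verdict_pct)   # {'fraudulent': 94.5, 'suspicious': 5.5, 'legitimate': 0.0}
```

## Customization

The zip3→state table, state→time-zone table, facility registry and
recruitment-channel list ship as editable packaged fixtures and can be
overridden per run (`--zip-map`, `--state-zones`, `--facilities`,
`--channels`). Detector thresholds (duplicate token floor, pattern
similarity and cluster size, fuzzy name-match threshold, straight-lining
floor) are exposed as CLI flags and as `DetectorParams`.
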