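# Methods

## Screening model

`fraudscreen` operationalizes a retrospective case-review protocol for
online survey cohorts. Each completed case is evaluated against a fixed
checklist of thirteen indicators grouped into four categories —
inattention, open-text anomalies, verifiable-item inconsistencies, and
automation — and every indicator carries a fixed designation:
*fraudulent* (strongly suggests misrepresentation or automation) or
*suspicious* (attributable to respondent error or coincidence). The
verdict depends only on the per-case counts: fraudulent with ≥ 1
fraudulent indicator or ≥ 3 suspicious indicators; suspicious with no
fraudulent indicators and 1–2 suspicious; legitimate with none. Each
indicator code counts at most once per case, however many items trigger
it: the checklist is a case-level instrument and cohort statistics count
cases, not occurrences.

Key modeling assumptions:

* **Disjoint completion-time bands.** [0, 5) minutes is the fraudulent
  band and [5, 10) the suspicious band. Published counts from the cohort
  this package replicates (63 cases under 5 minutes plus 70 under
  10 minutes equalling the 133 inattention cases) are only arithmetically
  consistent with disjoint bands.
* **Unverifiable ≠ inconsistent.** A missing zip mapping, an unknown
  zip3, absent zone information or an empty registry yields *no* flag.
  The benefit of the doubt mirrors the protocol's treatment of
  hour-of-submission, which is summarized but never used as an indicator
  because legitimate night-time respondents exist.
* **Human-in-the-loop nonsense judgment.** Whether a response is
  nonsensical or irrelevant is a reviewer judgment supplied through an
  annotation CSV; the package does not attempt automated semantics.

## Detector parameters

| parameter | default | meaning |
|---|---|---|
| `min_tokens` | 3 | token floor for exact-duplicate flagging ("more than 2–3 words" made concrete; short generics like "none" are exempt) |
| `corpus_min_tokens` | 5 | token floor for reference-corpus matches |
| `similarity_threshold` | 0.6 | token-trigram Jaccard for pattern clustering |
| `min_cluster` | 3 | distinct cases required before a phrasing cluster flags |
| `fuzzy_threshold` | 0.85 | normalized `difflib` ratio for facility/referral name matching (tolerates spelling variants, rejects unrelated names) |
| `straightline_min_items` | 3 | answered closed items a page needs before constancy counts (a 1-item page trivially straight-lines) |

Text normalization is Unicode casefold, whitespace collapse and terminal
punctuation stripping, with no stemming — exactness is the criterion for
duplicates. Pattern detection clusters *distinct* normalized texts per
open item by single-linkage on trigram Jaccard; exact duplicates collapse
to one node first, so repetition alone never forms a "pattern" (that is
the exact-duplicate detector's job). The trigram metric is strict: two
9-token sentences differing in one interior word fall below 0.6, while a
final-word substitution stays above it, so the default threshold targets
fill-in-the-blank template reuse.

Zone consistency uses the export's IANA zone column when present;
otherwise the timestamp's UTC offset is compared against the offsets the
candidate zones observe at the submission instant. Hour bands are
half-open by convention ([00:00, 04:00) Eastern for screenings,
[01:00, 05:00) local for surveys; boundary handling is not specified by
the protocol, and the half-open choice is recorded here and in the report
metadata). "Eastern" is the America/New_York zone; the replication
fixture is dated mid-January, when that is EST.

Percentages round half-up to one decimal (via `decimal`, not float
banker's rounding), matching how screening reports conventionally print
shares such as 25/271 → 9.2.

## The replication fixture

The packaged composition profile `pozzar2020` pins a cohort of 271
completed surveys and 576 screening submissions to the marginals of a
published fraud-compromised recruitment episode: 256 fraudulent and 15
suspicious verdicts; 235 cases with ≥ 1 verifiable-item inconsistency; 44
honeypot responders, of whom exactly 25 have parseable timestamps (all
completing in under 2 minutes) and 19 carry zone-less timestamps; among
the fraudulent cases, 138 exact-duplicate texts, 63 sub-5-minute and 70
5-to-10-minute completions; 128 of 271 surveys submitted between 1 and
5 am local; 475 of 576 screenings between midnight and 4 am Eastern, with
271 passing and linking to survey cases.

The printed marginals under-determine the joint assignment of codes to
cases. The shipped profile uses one satisfying assignment, recorded per
case in the ground-truth sidecar: all 138 open-text flags are planted as
exact duplicates (the only fraudulent-designation route consistent with
the 256-case arithmetic); all 70 mid-band cases also carry a duplicate;
36 cases are fraudulent solely through a non-US time zone (which
necessarily also mismatches the reported state's zones); the 15
suspicious cases carry exactly one zip/state mismatch. Duplicate text is
planted as two published example sentences (one shared by 2 cases, one by
6) plus generated templates in clusters of two, each pinned to a single
open item; generated sentences are drawn from a domain vocabulary and
re-drawn until pairwise trigram similarity is below 0.3, so no unplanned
pattern cluster can form. Closed answers are guaranteed non-constant per
page, so no unplanned straight-lining occurs. The generator emits raw
records only — detectors must recover the planted codes, and the
round-trip is exercised at several seeds in the test suite.

Two published figures are intentionally **not** imposed. The cohort mean
completion time (12.8 min, SD 14.8) is not a fixture constraint: per-case
times were never printed, and imposing moments would fabricate data;
non-band completion times are drawn uniformly on [10.5, 40] minutes. The
share of cases with more than one indicator *category* (88.9% in the
source cohort) is likewise not pinned: it is jointly infeasible with the
constrained marginals above under this profile's assignment (the non-US
zone route and the timestamp-less honeypot cases are single-category by
construction), so the report computes it honestly (67.9% for the shipped
profile) without claiming to reproduce it.

Because the profile fixes the composition, every reported percentage is
seed-invariant; the seed varies only raw content (clock times within
bands, geography draws, template wording, case order).

## The persona simulator

`simulate_cohort` draws cases from a mixture of four behavioral personas,
whose parameters are stated constants in `data/personas.json`:

| persona | completion (log-normal, min) | hours (local) | key behaviors |
|---|---|---|---|
| legitimate | μ=ln 16, σ=0.28 | 08–22 | unique free text, consistent geography, no honeypot |
| satisficer | μ=ln 7, σ=0.35 | 08–22 | straight-lines with p=0.6, minimal text, truthful geography |
| farm | μ=ln 6, σ=0.5 | 00–04 | reuses a small shared template pool with p=0.8, zip mismatch p=0.4, non-US zone p=0.15 |
| bot | μ=ln 1.5, σ=0.3 | 00–04 | answers honeypot items with p=1, fast, random geography |

The legitimate σ is chosen so that sub-5-minute completions are
vanishingly rare (≈ 10⁻⁵), keeping an all-legitimate cohort free of
fraudulent verdicts while still allowing the occasional sub-10-minute
suspicious case, and mean completion times order bot < farm < legitimate.
The simulator emulates the behavioral signatures the screening protocol
targets — template exchange among coordinated respondents, night-hour
bursts, masked locations, honeypot hits — not the marketing funnel that
delivers them: advertisement targeting, share cascades and enrollment
dynamics over time are out of scope, and satisficers here never
misrepresent eligibility.

## What passing tests do and do not show

The fixture demonstrates that the detectors, rule and report reproduce a
known composition exactly from raw records; it does not validate the
thresholds against real-world text, which is messier than the generator's
vocabulary (real duplicate farms paraphrase, misspell and translate).
The fuzzy name threshold (0.85) was set for clean-to-moderately-misspelled
registry names; heavily abbreviated facility names will read as unknown.
Corpus matching requires a user-supplied reference corpus — there is no
live web search — and IP-based signals (VPS detection, geolocation) are
out of scope entirely because the screening design this package models
collected no IP addresses.

## Problem sizes

The shipped verification suite runs the 271-case fixture end-to-end at
three seeds, the 576-record screening funnel, simulated cohorts of up to
240 cases, and exhaustive enumeration of the classification rule over all
indicator-count pairs (n_F ∈ 0..4, n_S ∈ 0..9); the full suite completes
in well under a minute on one CPU.
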