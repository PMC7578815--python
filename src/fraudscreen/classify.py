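"""Case classification rule and cohort summary statistics.

The verdict is a pure function of the per-case indicator counts:

* ``fraudulent``  — >= 1 fraudulent indicator OR >= 3 suspicious indicators
* ``suspicious``  — no fraudulent indicators and 1–2 suspicious indicators
* ``legitimate``  — no indicators at all

Hour-of-submission bands are summarized for context but never enter the
verdict. All percentages round half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence
from zoneinfo import ZoneInfo

from .indicators import CATEGORIES, IndicatorProfile, completion_minutes
from .schema_io import ResponseRecord, ScreeningRecord

__all__ = [
    "VERDICTS",
    "CaseClassification",
    "SummaryReport",
    "classify",
    "classify_cohort",
    "round_pct",
    "summarize",
]

VERDICTS = ("fraudulent", "suspicious", "legitimate")

EASTERN = ZoneInfo("America/New_York")

# Half-open local-hour bands; see docs/methods.md for the boundary convention.
SCREENING_BAND = (0, 4)  # [00:00, 04:00) Eastern
SURVEY_LOCAL_BAND = (1, 5)  # [01:00, 05:00) in the case's own zone


@dataclass(frozen=True)
class CaseClassification:
    case_id: str
    verdict: str
    n_fraudulent: int
    n_suspicious: int
    codes: tuple[str, ...]


def classify(profile: IndicatorProfile) -> CaseClassification:
    """Apply the indicator-count rule to one case."""
    nf, ns = profile.n_fraudulent, profile.n_suspicious
    if nf >= 1 or ns >= 3:
        verdict = "fraudulent"
    elif ns >= 1:
        verdict = "suspicious"
    else:
        verdict = "legitimate"
    return CaseClassification(
        case_id=profile.case_id,
        verdict=verdict,
        n_fraudulent=nf,
        n_suspicious=ns,
        codes=tuple(sorted(profile.codes)),
    )


def classify_cohort(
    profiles: Mapping[str, IndicatorProfile],
) -> dict[str, CaseClassification]:
    return {cid: classify(p) for cid, p in profiles.items()}


def round_pct(num: int, den: int) -> float | None:
    """100*num/den rounded half-up to one decimal; None for an empty cohort."""
    if den == 0:
        return None
    frac = Decimal(num) * 100 / Decimal(den)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _in_band(hour: int, band: tuple[int, int]) -> bool:
    lo, hi = band
    return lo <= hour < hi


@dataclass
class SummaryReport:
    """Cohort-level marginals mirroring a screening report.

    Percentages are over ``n_cases`` unless stated; ``*_of_fraudulent`` are
    over the fraudulent-verdict count. ``None`` marks undefined values
    (empty denominators).
    """

    schema_version: int = 1
    n_cases: int = 0
    verdict_counts: dict[str, int] = field(default_factory=dict)
    verdict_pct: dict[str, float | None] = field(default_factory=dict)
    category_counts: dict[str, int] = field(default_factory=dict)
    category_pct: dict[str, float | None] = field(default_factory=dict)
    multi_category_count: int = 0
    multi_category_pct: float | None = None
    # inattention bands among fraudulent-verdict cases
    lt5_of_fraudulent_count: int = 0
    lt5_of_fraudulent_pct: float | None = None
    t5to10_of_fraudulent_count: int = 0
    t5to10_of_fraudulent_pct: float | None = None
    inattention_of_fraudulent_count: int = 0
    inattention_of_fraudulent_pct: float | None = None
    open_text_of_fraudulent_count: int = 0
    open_text_of_fraudulent_pct: float | None = None
    # submission-hour context (never an indicator)
    local_band_count: int = 0
    local_band_pct: float | None = None
    # bot/automation cross-checks
    hidden_valid_ts_count: int = 0
    hidden_valid_ts_pct: float | None = None
    hidden_valid_ts_max_minutes: float | None = None
    # completion-time stats over valid-timestamp cases
    completion_mean: float | None = None
    completion_sd: float | None = None
    n_valid_timestamps: int = 0
    # screening funnel
    screening_n: int = 0
    screening_est_band_count: int = 0
    screening_est_band_pct: float | None = None
    screening_passed_count: int = 0
    screening_passed_pct: float | None = None

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def _local_submission_hour(rec: ResponseRecord) -> int | None:
    """Hour of the end timestamp in the case's own zone, None if unknown."""
    if rec.end_ts is None or rec.end_ts.tzinfo is None:
        return None
    if rec.tzname:
        try:
            return rec.end_ts.astimezone(ZoneInfo(rec.tzname)).hour
        except Exception:
            return rec.end_ts.hour
    return rec.end_ts.hour  # offset-only: the stamp is already local wall time


def summarize(
    cohort: Sequence[ResponseRecord],
    profiles: Mapping[str, IndicatorProfile],
    classifications: Mapping[str, CaseClassification],
    screening: Sequence[ScreeningRecord] | None = None,
) -> SummaryReport:
    """Compute every cohort marginal in :class:`SummaryReport`."""
    import statistics

    rep = SummaryReport()
    n = rep.n_cases = len(cohort)

    rep.verdict_counts = {v: 0 for v in VERDICTS}
    for cls in classifications.values():
        rep.verdict_counts[cls.verdict] += 1
    rep.verdict_pct = {v: round_pct(c, n) for v, c in rep.verdict_counts.items()}

    rep.category_counts = {c: 0 for c in CATEGORIES}
    for prof in profiles.values():
        cats = prof.categories()
        for c in cats:
            rep.category_counts[c] += 1
        if len(cats) > 1:
            rep.multi_category_count += 1
    rep.category_pct = {c: round_pct(k, n) for c, k in rep.category_counts.items()}
    rep.multi_category_pct = round_pct(rep.multi_category_count, n)

    fraud_ids = [cid for cid, c in classifications.items() if c.verdict == "fraudulent"]
    nf = len(fraud_ids)
    for cid in fraud_ids:
        codes = profiles[cid].codes
        if "TIME_LT5" in codes:
            rep.lt5_of_fraudulent_count += 1
        if "TIME_5TO10" in codes:
            rep.t5to10_of_fraudulent_count += 1
        if "inattention" in profiles[cid].categories():
            rep.inattention_of_fraudulent_count += 1
        if "open_text" in profiles[cid].categories():
            rep.open_text_of_fraudulent_count += 1
    rep.lt5_of_fraudulent_pct = round_pct(rep.lt5_of_fraudulent_count, nf)
    rep.t5to10_of_fraudulent_pct = round_pct(rep.t5to10_of_fraudulent_count, nf)
    rep.inattention_of_fraudulent_pct = round_pct(rep.inattention_of_fraudulent_count, nf)
    rep.open_text_of_fraudulent_pct = round_pct(rep.open_text_of_fraudulent_count, nf)

    minutes: list[float] = []
    hidden_valid_minutes: list[float] = []
    for rec in cohort:
        hour = _local_submission_hour(rec)
        if hour is not None and _in_band(hour, SURVEY_LOCAL_BAND):
            rep.local_band_count += 1
        m = completion_minutes(rec)
        if m is not None:
            minutes.append(m)
            if "HIDDEN_RESPONSE" in profiles[rec.case_id].codes:
                hidden_valid_minutes.append(m)
    rep.local_band_pct = round_pct(rep.local_band_count, n)
    rep.n_valid_timestamps = len(minutes)
    if minutes:
        rep.completion_mean = statistics.fmean(minutes)
        rep.completion_sd = statistics.stdev(minutes) if len(minutes) > 1 else 0.0
    rep.hidden_valid_ts_count = len(hidden_valid_minutes)
    rep.hidden_valid_ts_pct = round_pct(rep.hidden_valid_ts_count, n)
    if hidden_valid_minutes:
        rep.hidden_valid_ts_max_minutes = max(hidden_valid_minutes)

    if screening:
        rep.screening_n = len(screening)
        for s in screening:
            if _in_band(s.submitted_ts.astimezone(EASTERN).hour, SCREENING_BAND):
                rep.screening_est_band_count += 1
            if s.passed:
                rep.screening_passed_count += 1
        rep.screening_est_band_pct = round_pct(rep.screening_est_band_count, rep.screening_n)
        rep.screening_passed_pct = round_pct(rep.screening_passed_count, rep.screening_n)

    return rep
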