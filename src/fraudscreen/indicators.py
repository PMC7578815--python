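"""Detectors for indicators of low-quality or fraudulent survey responses.

Each detector implements one row of the indicator checklist and emits
:class:`Indicator` objects with a fixed designation (``fraudulent`` or
``suspicious``) and category:

======================  ===========  ============  =======================================
code                    designation  category      trigger
======================  ===========  ============  =======================================
TIME_LT5                fraudulent   inattention   completion time in [0, 5) minutes
TIME_5TO10              suspicious   inattention   completion time in [5, 10) minutes
STRAIGHTLINE            suspicious   inattention   identical answer to every closed item
                                                   on a page with >=3 answered items
DUP_TEXT                fraudulent   open_text     exact open-text response (>= min_tokens
                                                   tokens) shared by >=2 cases
NONSENSE_TEXT           suspicious   open_text     human-annotated nonsensical/irrelevant
PATTERN_TEXT            suspicious   open_text     near-duplicate phrasing cluster
CORPUS_TEXT             suspicious   open_text     verbatim match to a reference corpus
ZIP_STATE_MISMATCH      suspicious   verifiable    zip3 maps to a different state
STATE_TZ_MISMATCH       suspicious   verifiable    timestamp zone implausible for state
FACILITY_UNKNOWN        suspicious   verifiable    facility not in the care registry
NONUS_TZ                fraudulent   verifiable    timestamp zone outside the US
REFERRAL_UNKNOWN        suspicious   verifiable    referral organization not a channel
HIDDEN_RESPONSE         fraudulent   automation    any non-empty honeypot-item response
======================  ===========  ============  =======================================

Hour of submission is deliberately NOT an indicator; it is summarized at
cohort level only (legitimate night-owl respondents exist).

Missing or unmappable inputs (unknown zip3, no zone information, empty zip
map) never generate flags: unverifiable is not the same as inconsistent.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from difflib import SequenceMatcher
from typing import Iterable, Mapping, Sequence
from zoneinfo import ZoneInfo

from .schema_io import ResponseRecord, SurveySchema, ZipRegionMap

__all__ = [
    "FRAUDULENT_CODES",
    "SUSPICIOUS_CODES",
    "CATEGORY",
    "DESIGNATION",
    "Indicator",
    "IndicatorProfile",
    "DetectorParams",
    "normalize_text",
    "tokens",
    "trigram_jaccard",
    "completion_minutes",
    "detect_inattention",
    "detect_duplicate_texts",
    "detect_pattern_texts",
    "detect_corpus_matches",
    "flag_nonsense",
    "check_verifiable",
    "detect_hidden_responses",
    "build_profile",
    "profile_cohort",
]

FRAUDULENT_CODES = frozenset({"TIME_LT5", "DUP_TEXT", "NONUS_TZ", "HIDDEN_RESPONSE"})
SUSPICIOUS_CODES = frozenset(
    {
        "TIME_5TO10",
        "STRAIGHTLINE",
        "NONSENSE_TEXT",
        "PATTERN_TEXT",
        "CORPUS_TEXT",
        "ZIP_STATE_MISMATCH",
        "STATE_TZ_MISMATCH",
        "FACILITY_UNKNOWN",
        "REFERRAL_UNKNOWN",
    }
)
ALL_CODES = FRAUDULENT_CODES | SUSPICIOUS_CODES

CATEGORY: dict[str, str] = {
    "TIME_LT5": "inattention",
    "TIME_5TO10": "inattention",
    "STRAIGHTLINE": "inattention",
    "DUP_TEXT": "open_text",
    "NONSENSE_TEXT": "open_text",
    "PATTERN_TEXT": "open_text",
    "CORPUS_TEXT": "open_text",
    "ZIP_STATE_MISMATCH": "verifiable",
    "STATE_TZ_MISMATCH": "verifiable",
    "FACILITY_UNKNOWN": "verifiable",
    "NONUS_TZ": "verifiable",
    "REFERRAL_UNKNOWN": "verifiable",
    "HIDDEN_RESPONSE": "automation",
}
DESIGNATION: dict[str, str] = {
    c: ("fraudulent" if c in FRAUDULENT_CODES else "suspicious") for c in ALL_CODES
}
CATEGORIES = ("inattention", "open_text", "verifiable", "automation")


@dataclass(frozen=True)
class Indicator:
    code: str
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.code not in ALL_CODES:
            raise ValueError(f"unknown indicator code {self.code!r}")

    @property
    def designation(self) -> str:
        return DESIGNATION[self.code]

    @property
    def category(self) -> str:
        return CATEGORY[self.code]


@dataclass
class IndicatorProfile:
    """Per-case union of detected indicators (each code at most once)."""

    case_id: str
    indicators: dict[str, Indicator] = field(default_factory=dict)
    completion_minutes: float | None = None  # None == invalid timestamp data

    def add(self, ind: Indicator) -> None:
        # first evidence string wins; a code counts once per case
        self.indicators.setdefault(ind.code, ind)

    @property
    def codes(self) -> frozenset[str]:
        return frozenset(self.indicators)

    @property
    def n_fraudulent(self) -> int:
        return sum(1 for c in self.indicators if c in FRAUDULENT_CODES)

    @property
    def n_suspicious(self) -> int:
        return sum(1 for c in self.indicators if c in SUSPICIOUS_CODES)

    def categories(self) -> frozenset[str]:
        return frozenset(CATEGORY[c] for c in self.indicators)


@dataclass(frozen=True)
class DetectorParams:
    """Tunable detector thresholds (defaults documented in docs/methods.md)."""

    min_tokens: int = 3  # "more than 2-3 words" for exact duplicates
    corpus_min_tokens: int = 5
    similarity_threshold: float = 0.6  # token-trigram Jaccard for pattern clusters
    min_cluster: int = 3
    fuzzy_threshold: float = 0.85  # facility/referral name matching
    straightline_min_items: int = 3

    def __post_init__(self) -> None:
        if self.min_tokens < 1:
            raise ValueError("min_tokens must be >= 1")
        if not 0 < self.similarity_threshold <= 1:
            raise ValueError("similarity_threshold must be in (0, 1]")


# ---------------------------------------------------------------------------
# text normalization

_WS = re.compile(r"\s+")
_TOKEN = re.compile(r"[0-9a-z']+")


def normalize_text(text: str) -> str:
    """Unicode casefold, collapse whitespace, strip terminal punctuation."""
    out = unicodedata.normalize("NFKC", text).casefold()
    out = _WS.sub(" ", out).strip()
    return out.strip(".,;:!?\"'()[]{}") .strip()


def tokens(text: str) -> list[str]:
    return _TOKEN.findall(normalize_text(text))


def _dup_key(text: str) -> str:
    return " ".join(tokens(text))


def trigram_jaccard(a: Sequence[str], b: Sequence[str]) -> float:
    """Jaccard similarity of token-trigram sets; 0 when either has none."""
    ta = {tuple(a[i : i + 3]) for i in range(len(a) - 2)}
    tb = {tuple(b[i : i + 3]) for i in range(len(b) - 2)}
    if not ta or not tb:
        return 0.0
    return len(ta & tb) / len(ta | tb)


def _name_similarity(a: str, b: str) -> float:
    return SequenceMatcher(None, _dup_key(a), _dup_key(b)).ratio()


# ---------------------------------------------------------------------------
# per-record detectors


def completion_minutes(record: ResponseRecord) -> float | None:
    """Survey completion time in minutes, or None for invalid timestamps."""
    if not record.valid_timestamps:
        return None
    delta = (record.end_ts - record.start_ts).total_seconds() / 60.0
    if delta < 0:
        return None
    return delta


def detect_inattention(
    record: ResponseRecord,
    schema: SurveySchema,
    params: DetectorParams = DetectorParams(),
) -> set[Indicator]:
    """Completion-time bands ([0,5) fraudulent, [5,10) suspicious — disjoint)
    and page-level straight-lining."""
    out: set[Indicator] = set()
    minutes = completion_minutes(record)
    if minutes is not None:
        if minutes < 5:
            out.add(Indicator("TIME_LT5", f"completed in {minutes:.1f} min"))
        elif minutes < 10:
            out.add(Indicator("TIME_5TO10", f"completed in {minutes:.1f} min"))
    for page_id, item_ids in schema.page_closed_items().items():
        answers = [record.closed[i] for i in item_ids if i in record.closed]
        if len(answers) >= params.straightline_min_items and len(set(answers)) == 1:
            out.add(
                Indicator(
                    "STRAIGHTLINE",
                    f"page {page_id}: {len(answers)} identical closed answers",
                )
            )
            break
    return out


def detect_hidden_responses(
    record: ResponseRecord, schema: SurveySchema
) -> set[Indicator]:
    """Honeypot check: any non-empty text in an item invisible to humans."""
    hit = [i for i in schema.hidden_items if record.hidden.get(i, "").strip()]
    if hit:
        return {Indicator("HIDDEN_RESPONSE", f"hidden item(s) answered: {hit}")}
    return set()


def flag_nonsense(
    record: ResponseRecord,
    annotations: Mapping[str, set[str]] | None,
) -> set[Indicator]:
    """Pass-through of human nonsense/irrelevance annotations; no automated
    semantic judgment is attempted."""
    if not annotations:
        return set()
    items = annotations.get(record.case_id)
    if items:
        return {Indicator("NONSENSE_TEXT", f"annotated item(s): {sorted(items)}")}
    return set()


def detect_corpus_matches(
    record: ResponseRecord,
    schema: SurveySchema,
    corpus: Sequence[str],
    params: DetectorParams = DetectorParams(),
) -> set[Indicator]:
    """Verbatim (normalized substring) match of an open response of at least
    ``corpus_min_tokens`` tokens inside any reference document."""
    if not corpus:
        return set()
    docs = [" " + _dup_key(doc) + " " for doc in corpus]
    for item_id, text in record.open.items():
        toks = tokens(text)
        if len(toks) < params.corpus_min_tokens:
            continue
        needle = " " + " ".join(toks) + " "
        if any(needle in doc for doc in docs):
            return {Indicator("CORPUS_TEXT", f"item {item_id} matches reference corpus")}
    return set()


# ---------------------------------------------------------------------------
# verifiable-item consistency


def _record_zone_matches(record: ResponseRecord, zones: frozenset[str]) -> bool | None:
    """Does the record's zone plausibly belong to ``zones``?

    Uses the named IANA zone when the export carries one; otherwise compares
    the timestamp's UTC offset against the offsets those zones observe at the
    submission instant. Returns None when unverifiable.
    """
    if not zones:
        return None
    if record.tzname:
        return record.tzname in zones
    if record.valid_timestamps:
        instant = record.end_ts
        offsets = {instant.astimezone(ZoneInfo(z)).utcoffset() for z in zones}
        return instant.utcoffset() in offsets
    return None


def _best_match(name: str, candidates: Sequence[str]) -> float:
    return max((_name_similarity(name, c) for c in candidates), default=0.0)


def check_verifiable(
    record: ResponseRecord,
    zipmap: ZipRegionMap,
    facilities: Sequence[str],
    channels: Sequence[str],
    params: DetectorParams = DetectorParams(),
) -> set[Indicator]:
    """Cross-check reported state vs zip prefix, state vs timestamp zone,
    zone vs the US, facility vs registry, referral vs recruitment channels."""
    out: set[Indicator] = set()
    state = (record.reported_state or "").strip().upper() or None

    if state and record.zip_prefix:
        mapped = zipmap.zip3_to_state.get(record.zip_prefix)
        if mapped is not None and mapped != state:
            out.add(
                Indicator(
                    "ZIP_STATE_MISMATCH",
                    f"zip3 {record.zip_prefix} maps to {mapped}, reported {state}",
                )
            )
    if state:
        state_zones = zipmap.state_to_zones.get(state, frozenset())
        match = _record_zone_matches(record, state_zones)
        if match is False:
            out.add(
                Indicator(
                    "STATE_TZ_MISMATCH",
                    f"zone {record.tzname or record.end_ts.utcoffset()} "
                    f"not plausible for {state}",
                )
            )
    us_match = _record_zone_matches(record, zipmap.us_zones)
    if us_match is False:
        out.add(
            Indicator(
                "NONUS_TZ",
                f"zone {record.tzname or record.end_ts.utcoffset()} outside the US",
            )
        )
    if record.facility and facilities:
        score = _best_match(record.facility, facilities)
        if score < params.fuzzy_threshold:
            out.add(
                Indicator(
                    "FACILITY_UNKNOWN",
                    f"facility {record.facility!r} best registry match {score:.2f}",
                )
            )
    if record.referral_source and channels:
        score = _best_match(record.referral_source, channels)
        if score < params.fuzzy_threshold:
            out.add(
                Indicator(
                    "REFERRAL_UNKNOWN",
                    f"referral {record.referral_source!r} best channel match {score:.2f}",
                )
            )
    return out


# ---------------------------------------------------------------------------
# cohort-level text detectors


def detect_duplicate_texts(
    cohort: Sequence[ResponseRecord],
    schema: SurveySchema,
    params: DetectorParams = DetectorParams(),
) -> dict[str, Indicator]:
    """Exact duplicate open-text responses shared across cases.

    Per open item, any normalized response of >= ``min_tokens`` tokens given
    by two or more distinct cases flags every sharing case. Symmetric and
    order-independent by construction.
    """
    by_key: dict[tuple[str, str], set[str]] = {}
    for rec in cohort:
        for item_id in schema.open_items:
            text = rec.open.get(item_id)
            if not text:
                continue
            toks = tokens(text)
            if len(toks) < params.min_tokens:
                continue
            by_key.setdefault((item_id, " ".join(toks)), set()).add(rec.case_id)
    flagged: dict[str, Indicator] = {}
    for (item_id, key), case_ids in sorted(by_key.items()):
        if len(case_ids) < 2:
            continue
        for cid in case_ids:
            if cid not in flagged:
                flagged[cid] = Indicator(
                    "DUP_TEXT",
                    f"item {item_id}: text {key!r} shared by {len(case_ids)} cases",
                )
    return flagged


def detect_pattern_texts(
    cohort: Sequence[ResponseRecord],
    schema: SurveySchema,
    params: DetectorParams = DetectorParams(),
) -> dict[str, Indicator]:
    """Near-duplicate phrasing clusters.

    Per open item, distinct normalized responses are single-linkage clustered
    by token-trigram Jaccard similarity >= ``similarity_threshold``; clusters
    spanning >= ``min_cluster`` distinct cases flag all their members. Exact
    duplicates (identical normalized text) are collapsed to one node first —
    exact repetition is DUP_TEXT's job, so a cluster must contain at least
    two *different* phrasings to flag anyone.
    """
    flagged: dict[str, Indicator] = {}
    for item_id in schema.open_items:
        texts: dict[str, set[str]] = {}  # normalized text -> case ids
        for rec in cohort:
            text = rec.open.get(item_id)
            if not text:
                continue
            toks = tokens(text)
            if len(toks) < 3:  # no trigrams, nothing to cluster
                continue
            texts.setdefault(" ".join(toks), set()).add(rec.case_id)
        keys = sorted(texts)
        if len(keys) < 2:
            continue
        tok_lists = [k.split() for k in keys]
        parent = list(range(len(keys)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        linked = [False] * len(keys)
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                if trigram_jaccard(tok_lists[i], tok_lists[j]) >= params.similarity_threshold:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[ri] = rj
                    linked[i] = linked[j] = True
        clusters: dict[int, list[int]] = {}
        for i in range(len(keys)):
            if linked[i]:
                clusters.setdefault(find(i), []).append(i)
        for members in clusters.values():
            if len(members) < 2:
                continue  # needs >=2 distinct phrasings
            case_ids = set().union(*(texts[keys[m]] for m in members))
            if len(case_ids) < params.min_cluster:
                continue
            for cid in case_ids:
                if cid not in flagged:
                    flagged[cid] = Indicator(
                        "PATTERN_TEXT",
                        f"item {item_id}: {len(members)} similar phrasings "
                        f"across {len(case_ids)} cases",
                    )
    return flagged


# ---------------------------------------------------------------------------
# assembly


def build_profile(
    case_id: str,
    detector_outputs: Iterable[Iterable[Indicator]],
    minutes: float | None,
) -> IndicatorProfile:
    """Union all detectors' indicators for one case (each code counted once)."""
    profile = IndicatorProfile(case_id=case_id, completion_minutes=minutes)
    for output in detector_outputs:
        for ind in output:
            profile.add(ind)
    return profile


def load_annotations(path, cohort_ids: set[str], schema: SurveySchema) -> dict[str, set[str]]:
    """Read a human-review nonsense annotation CSV (case_id, item_id)."""
    import csv as _csv
    from pathlib import Path as _Path

    out: dict[str, set[str]] = {}
    with _Path(path).open(newline="") as fh:
        for row in _csv.DictReader(fh):
            cid, item = row["case_id"].strip(), row["item_id"].strip()
            if cid not in cohort_ids:
                raise ValueError(f"annotation references unknown case {cid!r}")
            if item not in schema.items:
                raise ValueError(f"annotation references unknown item {item!r}")
            out.setdefault(cid, set()).add(item)
    return out


def profile_cohort(
    cohort: Sequence[ResponseRecord],
    schema: SurveySchema,
    zipmap: ZipRegionMap,
    facilities: Sequence[str] = (),
    channels: Sequence[str] = (),
    corpus: Sequence[str] = (),
    annotations: Mapping[str, set[str]] | None = None,
    params: DetectorParams = DetectorParams(),
) -> dict[str, IndicatorProfile]:
    """Run the full detector battery over a cohort.

    Returns case_id -> :class:`IndicatorProfile`, in cohort order.
    """
    dup = detect_duplicate_texts(cohort, schema, params)
    pattern = detect_pattern_texts(cohort, schema, params)
    profiles: dict[str, IndicatorProfile] = {}
    for rec in cohort:
        per_case: list[Iterable[Indicator]] = [
            detect_inattention(rec, schema, params),
            detect_hidden_responses(rec, schema),
            check_verifiable(rec, zipmap, facilities, channels, params),
            detect_corpus_matches(rec, schema, corpus, params),
            flag_nonsense(rec, annotations),
        ]
        if rec.case_id in dup:
            per_case.append([dup[rec.case_id]])
        if rec.case_id in pattern:
            per_case.append([pattern[rec.case_id]])
        profiles[rec.case_id] = build_profile(
            rec.case_id, per_case, completion_minutes(rec)
        )
    return profiles
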