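"""Synthetic survey cohorts: a replication fixture and a persona simulator.

Two generators share one synthetic survey instrument (124 closed, 14 open
and 2 hidden items over 8 pages — the shape of the study this package
screens for):

* :func:`generate_fixture` emits a deterministic cohort whose
  indicator-profile composition is pinned by a :class:`CompositionProfile`.
  The packaged ``pozzar2020`` profile encodes the printed marginals of the
  motivating cohort: 576 screening submissions (475 between midnight and
  4 am Eastern; 271 passing) and 271 completed surveys whose detected
  indicator sets, verdict counts and hour-band shares reproduce the
  published percentages. Records are RAW content — timestamps, open text
  with planted duplicate templates, zip/state/zone values, honeypot text —
  so the detectors must *recover* the planted codes; a ground-truth sidecar
  supports round-trip testing.

* :func:`simulate_cohort` draws cases from a mixture of behavioral
  personas (legitimate respondent, satisficer, fraud-farm worker, bot) for
  stochastic testing. Persona parameters are stated constants shipped in
  ``data/personas.json``, never hidden defaults.

Both are byte-deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from importlib import resources
from pathlib import Path
from random import Random
from typing import Mapping, Sequence
from zoneinfo import ZoneInfo

from .indicators import FRAUDULENT_CODES, ALL_CODES, tokens, trigram_jaccard
from .schema_io import (
    ResponseRecord,
    ScreeningRecord,
    SurveySchema,
    packaged_facilities,
    packaged_zip_map,
    schema_from_dict,
)

__all__ = [
    "InfeasibleProfileError",
    "DupSeed",
    "GroupSpec",
    "ScreeningSpec",
    "CompositionProfile",
    "PersonaParams",
    "FixtureResult",
    "SimulationResult",
    "replication_schema",
    "load_profile",
    "available_profiles",
    "default_personas",
    "generate_fixture",
    "simulate_cohort",
]

FIXTURE_DATE = datetime(2020, 1, 15)  # mid-January: Eastern observes EST
NON_US_ZONE = "Asia/Shanghai"

# (state, zone) pool for geographically consistent cases
_GEO_POOL = [
    ("MA", "America/New_York"),
    ("NY", "America/New_York"),
    ("PA", "America/New_York"),
    ("GA", "America/New_York"),
    ("FL", "America/New_York"),
    ("OH", "America/New_York"),
    ("IL", "America/Chicago"),
    ("TX", "America/Chicago"),
    ("CO", "America/Denver"),
    ("AZ", "America/Phoenix"),
    ("CA", "America/Los_Angeles"),
    ("WA", "America/Los_Angeles"),
]

_REFERRALS = ["Facebook", "Twitter", "Facebook advertisement", "Twitter advertisement"]
_SHORT_ANSWERS = ["none", "no", "nothing", "n/a", "ok", "good"]

# vocabulary for generated open-text sentences and duplicate templates
_VOCAB = (
    "doctor nurse clinic visit treatment surgery chemo radiation scan result "
    "question answer family support friend care team plan option side effect "
    "pain tired hope trust listen explain clear kind time wait call email "
    "appointment test blood week month follow local hospital center staff "
    "helpful honest open worry stress recover diagnosis stage medicine dose "
    "therapy group talk share decide choose understand information detail "
    "insurance cost travel drive home work rest sleep diet exercise walk"
).split()


class InfeasibleProfileError(ValueError):
    """A composition profile admits no satisfying cohort."""


# ---------------------------------------------------------------------------
# survey instrument


def replication_schema() -> SurveySchema:
    """The synthetic instrument: 124 closed, 14 open, 2 hidden items, 8 pages."""
    closed_per_page = [16, 16, 16, 16, 15, 15, 15, 15]
    open_per_page = [2, 2, 2, 2, 2, 2, 1, 1]
    pages = []
    items: dict[str, dict] = {}
    ci = oi = 0
    for p, (nc, no) in enumerate(zip(closed_per_page, open_per_page), start=1):
        ids = []
        if p == 1:
            ids.append("h01")
            items["h01"] = {"kind": "hidden"}
        if p == 5:
            ids.append("h02")
            items["h02"] = {"kind": "hidden"}
        for _ in range(nc):
            ci += 1
            iid = f"c{ci:03d}"
            ids.append(iid)
            items[iid] = {"kind": "closed", "domain": ["1", "2", "3", "4", "5"]}
        for _ in range(no):
            oi += 1
            iid = f"o{oi:02d}"
            ids.append(iid)
            items[iid] = {"kind": "open"}
        pages.append({"id": f"p{p}", "items": ids})
    return schema_from_dict(
        {
            "pages": pages,
            "items": items,
            "time_fields": ["start_ts", "end_ts"],
            "identity_fields": {
                "state": "reported_state",
                "zip_prefix": "zip_prefix",
                "facility": "facility",
                "referral": "referral_source",
                "email_hash": "email_hash",
                "tz": "tz",
            },
        }
    )


# ---------------------------------------------------------------------------
# composition profiles

TIMINGS = ("sub2", "lt5", "5to10", "normal", "invalid")
_TIMING_RANGE = {  # completion minutes drawn uniformly from these bands
    "sub2": (0.9, 1.9),
    "lt5": (2.3, 4.7),
    "5to10": (5.4, 9.5),
    "normal": (10.5, 40.0),
}


@dataclass(frozen=True)
class DupSeed:
    """A fixed duplicate template: exact text planted on `count` cases."""

    text: str
    count: int
    item: str


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n: int
    codes: frozenset[str]
    timing: str
    local_band_n: int = 0
    dup_pool: str | None = None


@dataclass(frozen=True)
class ScreeningSpec:
    n: int
    n_est_band: int
    n_passed: int


@dataclass(frozen=True)
class CompositionProfile:
    """Joint specification of a fixture cohort by indicator-code groups."""

    name: str
    n_cases: int
    screening: ScreeningSpec
    groups: tuple[GroupSpec, ...]
    dup_seeds: Mapping[str, tuple[DupSeed, ...]] = field(default_factory=dict)

    def validate(self) -> None:
        if sum(g.n for g in self.groups) != self.n_cases:
            raise InfeasibleProfileError(
                f"group sizes sum to {sum(g.n for g in self.groups)}, "
                f"profile declares n_cases={self.n_cases}"
            )
        s = self.screening
        if not (0 <= s.n_est_band <= s.n and 0 <= s.n_passed <= s.n):
            raise InfeasibleProfileError("screening band/pass counts exceed n")
        if s.n_passed != self.n_cases:
            raise InfeasibleProfileError(
                f"screening passes ({s.n_passed}) must equal survey cases "
                f"({self.n_cases}) for the funnel to link"
            )
        pools: dict[str, int] = {}
        for g in self.groups:
            unknown = g.codes - ALL_CODES
            if unknown:
                raise InfeasibleProfileError(f"{g.label}: unknown codes {sorted(unknown)}")
            if g.timing not in TIMINGS:
                raise InfeasibleProfileError(f"{g.label}: unknown timing {g.timing!r}")
            if not 0 <= g.local_band_n <= g.n:
                raise InfeasibleProfileError(f"{g.label}: local_band_n out of range")
            # timing and time-band codes must agree or detectors cannot
            # recover exactly the planted codes
            want = {"sub2": "TIME_LT5", "lt5": "TIME_LT5", "5to10": "TIME_5TO10"}.get(
                g.timing
            )
            bands = g.codes & {"TIME_LT5", "TIME_5TO10"}
            if want and bands != {want}:
                raise InfeasibleProfileError(
                    f"{g.label}: timing {g.timing} requires exactly {{{want}}}"
                )
            if not want and bands:
                raise InfeasibleProfileError(
                    f"{g.label}: band codes {sorted(bands)} need a matching timing"
                )
            if g.timing == "invalid":
                if g.local_band_n:
                    raise InfeasibleProfileError(
                        f"{g.label}: invalid timestamps cannot sit in a local band"
                    )
                if g.codes & {"STATE_TZ_MISMATCH", "NONUS_TZ"}:
                    raise InfeasibleProfileError(
                        f"{g.label}: zone codes are unverifiable without timestamps"
                    )
            if "NONUS_TZ" in g.codes and "STATE_TZ_MISMATCH" not in g.codes:
                raise InfeasibleProfileError(
                    f"{g.label}: a non-US zone also mismatches every state zone; "
                    "plant STATE_TZ_MISMATCH alongside NONUS_TZ"
                )
            if ("DUP_TEXT" in g.codes) != (g.dup_pool is not None):
                raise InfeasibleProfileError(
                    f"{g.label}: DUP_TEXT cases need a dup_pool (and only they may)"
                )
            if g.dup_pool:
                pools[g.dup_pool] = pools.get(g.dup_pool, 0) + g.n
        for pool, seeds in self.dup_seeds.items():
            size = pools.get(pool, 0)
            seeded = sum(sd.count for sd in seeds)
            if any(sd.count < 2 for sd in seeds):
                raise InfeasibleProfileError(
                    f"pool {pool!r}: a duplicate template needs >= 2 cases"
                )
            if seeded > size:
                raise InfeasibleProfileError(
                    f"pool {pool!r}: seeds demand {seeded} cases but only "
                    f"{size} records carry DUP_TEXT"
                )
            if size - seeded == 1:
                raise InfeasibleProfileError(
                    f"pool {pool!r}: one leftover case cannot share a duplicate"
                )
        for pool, size in pools.items():
            if size == 1:
                raise InfeasibleProfileError(
                    f"pool {pool!r}: a single case cannot duplicate itself"
                )


def profile_from_dict(cfg: Mapping) -> CompositionProfile:
    prof = CompositionProfile(
        name=cfg["name"],
        n_cases=cfg["n_cases"],
        screening=ScreeningSpec(**cfg["screening"]),
        groups=tuple(
            GroupSpec(
                label=g["label"],
                n=g["n"],
                codes=frozenset(g["codes"]),
                timing=g["timing"],
                local_band_n=g.get("local_band_n", 0),
                dup_pool=g.get("dup_pool"),
            )
            for g in cfg["groups"]
        ),
        dup_seeds={
            pool: tuple(DupSeed(**sd) for sd in seeds)
            for pool, seeds in cfg.get("dup_seeds", {}).items()
        },
    )
    prof.validate()
    return prof


def available_profiles() -> list[str]:
    out = []
    for entry in resources.files("fraudscreen.data").iterdir():
        name = entry.name
        if name.startswith("profile_") and name.endswith(".json"):
            out.append(name[len("profile_") : -len(".json")])
    return sorted(out)


def load_profile(name_or_path: str | Path) -> CompositionProfile:
    """Load a packaged profile by name (e.g. ``pozzar2020``) or a JSON path."""
    path = Path(str(name_or_path))
    if path.suffix == ".json" and path.exists():
        cfg = json.loads(path.read_text())
    else:
        res = resources.files("fraudscreen.data").joinpath(f"profile_{name_or_path}.json")
        if not res.is_file():
            raise KeyError(
                f"unknown profile {name_or_path!r}; available: {available_profiles()}"
            )
        cfg = json.loads(res.read_text())
    return profile_from_dict(cfg)


# ---------------------------------------------------------------------------
# shared content helpers


def _sentence(rng: Random, n_words: int) -> str:
    return " ".join(rng.choice(_VOCAB) for _ in range(n_words))


def _fresh_sentence(
    rng: Random, existing: list[list[str]], min_len: int = 6, max_len: int = 10
) -> str:
    """A sentence trigram-dissimilar (< 0.3) to every sentence in `existing`."""
    while True:
        cand = _sentence(rng, rng.randint(min_len, max_len))
        toks = tokens(cand)
        if all(trigram_jaccard(toks, other) < 0.3 for other in existing):
            existing.append(toks)
            return cand


def _closed_answers(rng: Random, schema: SurveySchema, straightline: bool) -> dict:
    """Answers to every closed item; constant on page 1 iff `straightline`,
    guaranteed non-constant on every other (and otherwise every) page."""
    out: dict[str, str] = {}
    for page_id, item_ids in schema.page_closed_items().items():
        if straightline and page_id == "p1":
            val = rng.choice("12345")
            for i in item_ids:
                out[i] = val
            continue
        vals = [rng.choice("12345") for _ in item_ids]
        if len(vals) >= 2 and len(set(vals)) == 1:
            vals[0] = next(v for v in "12345" if v != vals[0])
        for i, v in zip(item_ids, vals):
            out[i] = v
    return out


def _zone_aware(day: datetime, hour: int, minute: int, second: int, zone: str) -> datetime:
    return datetime(
        day.year, day.month, day.day, hour, minute, second, tzinfo=ZoneInfo(zone)
    )


# ---------------------------------------------------------------------------
# replication fixture


@dataclass
class FixtureResult:
    screening: list[ScreeningRecord]
    cohort: list[ResponseRecord]
    planted: dict[str, frozenset[str]]  # case_id -> intended indicator codes
    labels: dict[str, str]  # case_id -> group label
    schema: SurveySchema


def _state_zips(zipmap) -> dict[str, list[str]]:
    rev: dict[str, list[str]] = {}
    for z, s in sorted(zipmap.zip3_to_state.items()):
        rev.setdefault(s, []).append(z)
    return rev


def generate_fixture(
    profile: CompositionProfile | str, seed: int
) -> FixtureResult:
    """Generate raw screening + survey cohorts satisfying ``profile``.

    Detector round-trip holds by construction: running the full detector
    battery (with the packaged zip map, facility registry and channel list,
    no corpus, no annotations, default thresholds) over the emitted records
    recovers exactly the planted code set of every case.
    """
    if isinstance(profile, str):
        profile = load_profile(profile)
    profile.validate()
    rng = Random(seed)
    schema = replication_schema()
    zipmap = packaged_zip_map()
    state_zips = _state_zips(zipmap)
    facilities = packaged_facilities()
    open_items = schema.open_items

    # --- plan duplicate-template clusters per pool
    pool_cases: dict[str, int] = {}
    for g in profile.groups:
        if g.dup_pool:
            pool_cases[g.dup_pool] = pool_cases.get(g.dup_pool, 0) + g.n
    sentence_bank: list[list[str]] = [
        tokens(sd.text) for seeds in profile.dup_seeds.values() for sd in seeds
    ]
    pool_assignments: dict[str, list[tuple[str, str]]] = {}  # pool -> per-case (item, text)
    for pool in sorted(pool_cases):
        assignments: list[tuple[str, str]] = []
        for sd in profile.dup_seeds.get(pool, ()):
            assignments += [(sd.item, sd.text)] * sd.count
        remaining = pool_cases[pool] - len(assignments)
        sizes = [2] * (remaining // 2)
        if remaining % 2:
            sizes[-1] = 3
        for size in sizes:
            text = _fresh_sentence(rng, sentence_bank, 6, 10)
            item = rng.choice(open_items[1:-1])  # keep o01/o14 for generic + seeds
            assignments += [(item, text)] * size
        rng.shuffle(assignments)
        pool_assignments[pool] = assignments

    # --- per-case plan
    plan: list[dict] = []
    for g in profile.groups:
        for k in range(g.n):
            dup = pool_assignments[g.dup_pool].pop() if g.dup_pool else None
            plan.append(
                {
                    "label": g.label,
                    "codes": g.codes,
                    "timing": g.timing,
                    "band": k < g.local_band_n,
                    "dup": dup,
                }
            )
    rng.shuffle(plan)

    cohort: list[ResponseRecord] = []
    planted: dict[str, frozenset[str]] = {}
    labels: dict[str, str] = {}
    for idx, spec in enumerate(plan, start=1):
        case_id = f"C{idx:04d}"
        codes = spec["codes"]

        state, zone = rng.choice(_GEO_POOL)
        if "NONUS_TZ" in codes:
            zone = NON_US_ZONE
        if "ZIP_STATE_MISMATCH" in codes:
            other = rng.choice([s for s, _ in _GEO_POOL if s != state])
            zip3 = rng.choice(state_zips[other])
        else:
            zip3 = rng.choice(state_zips[state])

        if spec["timing"] == "invalid":
            # clock readings without zone information: parseable instants lost
            end = datetime(
                FIXTURE_DATE.year, FIXTURE_DATE.month, FIXTURE_DATE.day,
                rng.randint(0, 23), rng.randint(0, 59), rng.randint(0, 59),
            )
            start = end - timedelta(minutes=rng.uniform(1, 30))
            tzname = None
        else:
            hour = rng.randint(1, 4) if spec["band"] else rng.randint(6, 22)
            end = _zone_aware(
                FIXTURE_DATE, hour, rng.randint(0, 59), rng.randint(0, 59), zone
            )
            lo, hi = _TIMING_RANGE[spec["timing"]]
            start = end - timedelta(minutes=rng.uniform(lo, hi))
            tzname = zone

        open_answers = {"o01": rng.choice(_SHORT_ANSWERS)}
        if spec["dup"]:
            item, text = spec["dup"]
            open_answers[item] = text
        hidden = {"h01": rng.choice(["N/A", "ok", "good", "yes"])} if (
            "HIDDEN_RESPONSE" in codes
        ) else {}

        cohort.append(
            ResponseRecord(
                case_id=case_id,
                start_ts=start,
                end_ts=end,
                tzname=tzname,
                closed=_closed_answers(rng, schema, straightline="STRAIGHTLINE" in codes),
                open=open_answers,
                hidden=hidden,
                reported_state=state,
                zip_prefix=zip3,
                facility=rng.choice(facilities),
                referral_source=rng.choice(_REFERRALS),
                email_hash=f"eh{idx:04d}{rng.getrandbits(24):06x}",
                data_errors=[] if spec["timing"] != "invalid" else ["invalid timestamp data"],
            )
        )
        planted[case_id] = frozenset(codes)
        labels[case_id] = spec["label"]

    # --- screening funnel
    s = profile.screening
    flags = [True] * s.n_est_band + [False] * (s.n - s.n_est_band)
    rng.shuffle(flags)
    passed_idx = set(rng.sample(range(s.n), s.n_passed))
    screening: list[ScreeningRecord] = []
    case_iter = iter(rec.case_id for rec in cohort)
    for i in range(s.n):
        hour = rng.randint(0, 3) if flags[i] else rng.randint(4, 23)
        ts = _zone_aware(
            FIXTURE_DATE, hour, rng.randint(0, 59), rng.randint(0, 59),
            "America/New_York",
        )
        is_pass = i in passed_idx
        screening.append(
            ScreeningRecord(
                screening_id=f"S{i + 1:04d}",
                submitted_ts=ts,
                passed=is_pass,
                case_id=next(case_iter) if is_pass else None,
            )
        )
    return FixtureResult(screening, cohort, planted, labels, schema)


# ---------------------------------------------------------------------------
# persona simulator


@dataclass(frozen=True)
class PersonaParams:
    """Behavioral parameters for one respondent persona.

    Completion time is log-normal: ``exp(N(completion_mu_log,
    completion_sigma_log))`` minutes. Submission hour is uniform on the
    inclusive local-hour range. Probabilities are per-case Bernoulli draws.
    """

    completion_mu_log: float
    completion_sigma_log: float
    hour_low: int
    hour_high: int
    template_reuse_p: float
    hidden_p: float
    zip_mismatch_p: float
    nonus_zone_p: float
    straightline_p: float

    def __post_init__(self) -> None:
        for name in (
            "template_reuse_p",
            "hidden_p",
            "zip_mismatch_p",
            "nonus_zone_p",
            "straightline_p",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def default_personas() -> dict[str, PersonaParams]:
    cfg = json.loads(resources.files("fraudscreen.data").joinpath("personas.json").read_text())
    return {name: PersonaParams(**params) for name, params in cfg.items()}


@dataclass
class SimulationResult:
    cohort: list[ResponseRecord]
    personas: dict[str, str]  # case_id -> persona label
    schema: SurveySchema


def simulate_cohort(
    mix: Mapping[str, float],
    n: int,
    params: Mapping[str, PersonaParams] | None = None,
    seed: int = 0,
) -> SimulationResult:
    """Draw ``n`` cases from a persona mixture.

    ``mix`` maps persona name -> proportion (must sum to 1 within 1e-9);
    per-case persona labels are returned as ground truth.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixture proportions sum to {total!r}, expected 1")
    params = dict(params or default_personas())
    unknown = set(mix) - set(params)
    if unknown:
        raise ValueError(f"no parameters for personas: {sorted(unknown)}")

    rng = Random(seed)
    schema = replication_schema()
    zipmap = packaged_zip_map()
    state_zips = _state_zips(zipmap)
    facilities = packaged_facilities()
    names = sorted(mix)
    weights = [mix[p] for p in names]

    # farm workers trade a small pool of stock answers around
    shared_bank: list[list[str]] = []
    farm_templates = [_fresh_sentence(rng, shared_bank, 6, 9) for _ in range(5)]

    cohort: list[ResponseRecord] = []
    personas: dict[str, str] = {}
    for idx in range(1, n + 1):
        persona = rng.choices(names, weights=weights)[0]
        pp = params[persona]
        case_id = f"M{idx:04d}"
        personas[case_id] = persona

        state, zone = rng.choice(_GEO_POOL)
        zip3 = rng.choice(state_zips[state])
        if rng.random() < pp.zip_mismatch_p:
            other = rng.choice([s for s, _ in _GEO_POOL if s != state])
            zip3 = rng.choice(state_zips[other])
        if rng.random() < pp.nonus_zone_p:
            zone = NON_US_ZONE

        hour = rng.randint(pp.hour_low, pp.hour_high)
        end = _zone_aware(FIXTURE_DATE, hour, rng.randint(0, 59), rng.randint(0, 59), zone)
        minutes = rng.lognormvariate(pp.completion_mu_log, pp.completion_sigma_log)
        start = end - timedelta(minutes=minutes)

        open_answers = {"o01": rng.choice(_SHORT_ANSWERS)}
        if rng.random() < pp.template_reuse_p:
            open_answers["o03"] = rng.choice(farm_templates)
        elif persona == "legitimate":
            open_answers["o14"] = _fresh_sentence(rng, shared_bank, 7, 11)

        hidden = {"h01": "ok"} if rng.random() < pp.hidden_p else {}

        cohort.append(
            ResponseRecord(
                case_id=case_id,
                start_ts=start,
                end_ts=end,
                tzname=zone,
                closed=_closed_answers(
                    rng, schema, straightline=rng.random() < pp.straightline_p
                ),
                open=open_answers,
                hidden=hidden,
                reported_state=state,
                zip_prefix=zip3,
                facility=rng.choice(facilities),
                referral_source=rng.choice(_REFERRALS),
                email_hash=f"eh{idx:04d}{rng.getrandbits(24):06x}",
            )
        )
    return SimulationResult(cohort, personas, schema)
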