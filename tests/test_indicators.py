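from itertools import combinations

import pytest

from fraudscreen.indicators import (
    CATEGORY,
    DESIGNATION,
    FRAUDULENT_CODES,
    DetectorParams,
    Indicator,
    build_profile,
    check_verifiable,
    completion_minutes,
    detect_corpus_matches,
    detect_duplicate_texts,
    detect_hidden_responses,
    detect_inattention,
    detect_pattern_texts,
    flag_nonsense,
    tokens,
)

SENT_FILM = "professional and technical personnel carry out film packaging management"
SENT_SURGERY = "the first choice surgery excision treatment, surgery pathology"


def codes(indicators):
    return {i.code for i in indicators}


class TestDesignations:
    def test_table_designations_fixed(self):
        assert FRAUDULENT_CODES == {"TIME_LT5", "DUP_TEXT", "NONUS_TZ", "HIDDEN_RESPONSE"}
        assert all(
            DESIGNATION[c] == ("fraudulent" if c in FRAUDULENT_CODES else "suspicious")
            for c in DESIGNATION
        )
        assert CATEGORY["STRAIGHTLINE"] == "inattention"
        assert CATEGORY["CORPUS_TEXT"] == "open_text"
        assert CATEGORY["NONUS_TZ"] == "verifiable"
        assert CATEGORY["HIDDEN_RESPONSE"] == "automation"

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            Indicator("NOT_A_CODE")


class TestCompletionTime:
    def test_minutes_arithmetic(self, rec):
        assert completion_minutes(rec(minutes=12.8)) == pytest.approx(12.8)
        assert completion_minutes(rec(minutes=0.0)) == 0.0
        assert completion_minutes(rec(valid_ts=False)) is None

    @pytest.mark.parametrize(
        "minutes,expected",
        [
            (4.0, {"TIME_LT5"}),
            (0.0, {"TIME_LT5"}),
            (4.999, {"TIME_LT5"}),
            (5.0, {"TIME_5TO10"}),
            (7.5, {"TIME_5TO10"}),
            (9.999, {"TIME_5TO10"}),
            (10.0, set()),
            (12.8, set()),
        ],
    )
    def test_disjoint_bands(self, rec, small_schema, minutes, expected):
        got = codes(detect_inattention(rec(minutes=minutes), small_schema))
        assert got == expected
        assert not {"TIME_LT5", "TIME_5TO10"} <= got  # bands mutually exclusive

    def test_invalid_timestamps_emit_no_band(self, rec, small_schema):
        assert codes(detect_inattention(rec(valid_ts=False), small_schema)) == set()


class TestStraightlining:
    def test_constant_10_item_page_flagged(self, rec, small_schema):
        closed = {f"c{i:02d}": "3" for i in range(1, 11)}  # page 1
        closed |= {f"c{i:02d}": str(i % 5) for i in range(11, 16)}
        got = codes(detect_inattention(rec(minutes=12.8, closed=closed), small_schema))
        assert got == {"STRAIGHTLINE"}

    def test_short_page_exempt(self, rec, small_schema):
        # only 2 answered closed items on page 2: below the eligibility floor
        closed = {"c11": "4", "c12": "4"}
        got = codes(detect_inattention(rec(minutes=12.8, closed=closed), small_schema))
        assert got == set()

    def test_varied_page_not_flagged(self, rec, small_schema):
        got = codes(detect_inattention(rec(minutes=12.8), small_schema))
        assert got == set()


class TestDuplicateTexts:
    def test_worked_examples_flag_all_sharers(self, rec, small_schema):
        cohort = (
            [rec(f"F{i}", open_texts={"o1": SENT_FILM}) for i in range(2)]
            + [rec(f"S{i}", open_texts={"o2": SENT_SURGERY}) for i in range(6)]
            + [rec("CLEAN", open_texts={"o1": "very kind and helpful care team"})]
        )
        flagged = detect_duplicate_texts(cohort, small_schema)
        assert set(flagged) == {f"F{i}" for i in range(2)} | {f"S{i}" for i in range(6)}

    def test_short_generic_answers_exempt(self, rec, small_schema):
        cohort = [rec(f"C{i}", open_texts={"o1": "none"}) for i in range(40)]
        assert detect_duplicate_texts(cohort, small_schema) == {}

    def test_normalization_case_and_punctuation(self, rec, small_schema):
        a = rec("A", open_texts={"o1": "The Doctor Was  Very Kind."})
        b = rec("B", open_texts={"o1": "the doctor was very kind"})
        assert set(detect_duplicate_texts([a, b], small_schema)) == {"A", "B"}

    def test_same_text_different_items_not_duplicates(self, rec, small_schema):
        a = rec("A", open_texts={"o1": "surgery then chemo then radiation"})
        b = rec("B", open_texts={"o2": "surgery then chemo then radiation"})
        assert detect_duplicate_texts([a, b], small_schema) == {}

    def test_permutation_invariant(self, rec, small_schema):
        cohort = [rec(f"F{i}", open_texts={"o1": SENT_FILM}) for i in range(3)] + [
            rec("X", open_texts={"o1": "completely different words here"})
        ]
        fwd = detect_duplicate_texts(cohort, small_schema)
        rev = detect_duplicate_texts(list(reversed(cohort)), small_schema)
        assert set(fwd) == set(rev)


def _oracle_trigram_jaccard(a, b):
    ta = {tuple(a[i : i + 3]) for i in range(len(a) - 2)}
    tb = {tuple(b[i : i + 3]) for i in range(len(b) - 2)}
    return len(ta & tb) / len(ta | tb) if ta and tb else 0.0


class TestPatternTexts:
    TEMPLATES = [
        "the care team explained every treatment option clearly during visit one",
        "the care team explained every treatment option clearly during visit two",
        "the care team explained every treatment option clearly during visit three",
    ]

    def test_templates_exceed_default_threshold(self):
        # independent oracle: last-word substitution keeps >= 0.6 similarity
        for a, b in combinations(self.TEMPLATES, 2):
            assert _oracle_trigram_jaccard(tokens(a), tokens(b)) >= 0.6

    def test_template_cluster_flagged(self, rec, small_schema):
        cohort = [rec(f"T{i}", open_texts={"o1": t}) for i, t in enumerate(self.TEMPLATES)]
        assert set(detect_pattern_texts(cohort, small_schema)) == {"T0", "T1", "T2"}

    def test_dissimilar_sentences_unflagged(self, rec, small_schema):
        texts = [
            "my nurse answered every question with patience",
            "travel to the hospital takes two hours each way",
            "insurance paperwork remains the hardest part for us",
        ]
        cohort = [rec(f"D{i}", open_texts={"o1": t}) for i, t in enumerate(texts)]
        for a, b in combinations(texts, 2):
            assert _oracle_trigram_jaccard(tokens(a), tokens(b)) < 0.6
        assert detect_pattern_texts(cohort, small_schema) == {}

    def test_cluster_below_min_size_unflagged(self, rec, small_schema):
        cohort = [rec(f"P{i}", open_texts={"o1": t}) for i, t in enumerate(self.TEMPLATES[:2])]
        assert detect_pattern_texts(cohort, small_schema) == {}

    def test_exact_duplicates_are_not_a_pattern(self, rec, small_schema):
        text = self.TEMPLATES[0]
        cohort = [rec(f"E{i}", open_texts={"o1": text}) for i in range(4)]
        assert detect_pattern_texts(cohort, small_schema) == {}


class TestCorpus:
    DOC = "We recommend that professional and technical personnel carry out film packaging management at all times."

    def test_verbatim_sentence_flagged(self, rec, small_schema):
        got = detect_corpus_matches(
            rec(open_texts={"o1": SENT_FILM}), small_schema, [self.DOC]
        )
        assert codes(got) == {"CORPUS_TEXT"}

    def test_empty_corpus_never_flags(self, rec, small_schema):
        assert detect_corpus_matches(rec(open_texts={"o1": SENT_FILM}), small_schema, []) == set()

    def test_below_token_floor_exempt(self, rec, small_schema):
        got = detect_corpus_matches(
            rec(open_texts={"o1": "film packaging management"}), small_schema, [self.DOC]
        )
        assert got == set()


class TestNonsense:
    def test_annotation_passthrough(self, rec):
        got = flag_nonsense(rec("C7"), {"C7": {"o1"}})
        assert codes(got) == {"NONSENSE_TEXT"}
        assert flag_nonsense(rec("C8"), {"C7": {"o1"}}) == set()

    def test_empty_annotations_vacuous(self, rec):
        assert flag_nonsense(rec(), None) == set()
        assert flag_nonsense(rec(), {}) == set()

    def test_unknown_case_rejected_at_load(self, small_schema, tmp_path):
        from fraudscreen.indicators import load_annotations

        p = tmp_path / "ann.csv"
        p.write_text("case_id,item_id\nGHOST,o1\n")
        with pytest.raises(ValueError, match="GHOST"):
            load_annotations(p, {"C1"}, small_schema)


class TestVerifiable:
    def test_zip_state_mismatch(self, rec, zipmap):
        got = check_verifiable(rec(state="MA", zip3="900"), zipmap, [], [])
        assert codes(got) == {"ZIP_STATE_MISMATCH"}

    def test_non_us_zone_is_fraudulent_and_state_mismatch(self, rec, zipmap):
        got = check_verifiable(rec(zone="Asia/Shanghai"), zipmap, [], [])
        assert codes(got) == {"NONUS_TZ", "STATE_TZ_MISMATCH"}
        assert {i.designation for i in got} == {"fraudulent", "suspicious"}

    def test_state_zone_mismatch_within_us(self, rec, zipmap):
        got = check_verifiable(rec(state="MA", zip3="021", zone="America/Los_Angeles"), zipmap, [], [])
        assert codes(got) == {"STATE_TZ_MISMATCH"}

    def test_fully_consistent_case_clean(self, rec, zipmap):
        got = check_verifiable(
            rec(state="MA", zip3="021", zone="America/New_York"),
            zipmap,
            ["Dana-Farber Cancer Institute"],
            ["Facebook"],
        )
        assert got == set()

    def test_offset_only_timestamps_checked_by_offset(self, rec, zipmap):
        r = rec(state="MA", zip3="021", zone="America/New_York")
        r.tzname = None  # export without a zone-name column, offset -05:00 kept
        assert check_verifiable(r, zipmap, [], []) == set()
        bad = rec(state="MA", zip3="021", zone="Asia/Shanghai")
        bad.tzname = None
        assert "NONUS_TZ" in codes(check_verifiable(bad, zipmap, [], []))

    def test_unknown_zip3_unverifiable_not_flagged(self, rec, zipmap):
        got = check_verifiable(rec(state="MA", zip3="000"), zipmap, [], [])
        assert got == set()

    def test_facility_fuzzy_match_tolerates_variants(self, rec, zipmap):
        registry = ["Dana-Farber Cancer Institute"]
        ok = check_verifiable(rec(facility="Dana Farber Cancer institute"), zipmap, registry, [])
        assert "FACILITY_UNKNOWN" not in codes(ok)
        bad = check_verifiable(rec(facility="Totally Real Hospital"), zipmap, registry, [])
        assert "FACILITY_UNKNOWN" in codes(bad)

    def test_referral_unknown_org(self, rec, zipmap):
        got = check_verifiable(
            rec(referral="Global Survey Rewards Network"), zipmap, [], ["Facebook", "Twitter"]
        )
        assert "REFERRAL_UNKNOWN" in codes(got)


class TestHiddenItems:
    def test_any_nonempty_hidden_text_flagged(self, rec, small_schema):
        got = detect_hidden_responses(rec(hidden={"h1": "N/A"}), small_schema)
        assert codes(got) == {"HIDDEN_RESPONSE"}
        assert next(iter(got)).designation == "fraudulent"

    def test_empty_hidden_items_clean(self, rec, small_schema):
        assert detect_hidden_responses(rec(), small_schema) == set()
        assert detect_hidden_responses(rec(hidden={"h1": "   "}), small_schema) == set()

    def test_schema_without_hidden_items_never_flags(self, rec):
        from fraudscreen.schema_io import schema_from_dict

        schema = schema_from_dict(
            {
                "pages": [{"id": "p1", "items": ["c1"]}],
                "items": {"c1": {"kind": "closed"}},
                "time_fields": ["start_ts", "end_ts"],
                "identity_fields": {
                    "state": "reported_state",
                    "zip_prefix": "zip_prefix",
                    "facility": "facility",
                    "referral": "referral_source",
                    "email_hash": "email_hash",
                },
            }
        )
        assert detect_hidden_responses(rec(hidden={"h1": "text"}), schema) == set()


class TestBuildProfile:
    def test_counts_from_designations(self):
        p = build_profile(
            "C1",
            [[Indicator("TIME_LT5")], [Indicator("DUP_TEXT"), Indicator("HIDDEN_RESPONSE")]],
            4.0,
        )
        assert (p.n_fraudulent, p.n_suspicious) == (3, 0)

    def test_code_counted_once_per_case(self):
        p = build_profile(
            "C1",
            [[Indicator("DUP_TEXT", "item o1")], [Indicator("DUP_TEXT", "item o2")]],
            15.0,
        )
        assert (p.n_fraudulent, p.n_suspicious) == (1, 0)
        assert p.codes == {"DUP_TEXT"}

    def test_empty_profile(self):
        p = build_profile("C1", [], None)
        assert (p.n_fraudulent, p.n_suspicious) == (0, 0)
        assert p.completion_minutes is None

    def test_hidden_text_monotone(self, rec, small_schema, zipmap):
        from fraudscreen.indicators import profile_cohort

        base = rec("C1", minutes=4.0, state="MA", zip3="900")
        with_hidden = rec("C1", minutes=4.0, state="MA", zip3="900", hidden={"h1": "x"})
        before = profile_cohort([base], small_schema, zipmap)["C1"].codes
        after = profile_cohort([with_hidden], small_schema, zipmap)["C1"].codes
        assert before <= after
        assert after - before == {"HIDDEN_RESPONSE"}
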