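"""NP taxonomy cascade, counting, macro-types and Cohen's kappa."""

import pytest
from hypothesis import given, settings, strategies as st

from refcoh.annotation import (
    ManualFlags,
    NPCategory,
    NPSpan,
    aggregate_definiteness,
    annotate_transcript,
    classify_np,
    cohens_kappa,
    count_categories,
    macro_type,
)
from refcoh.datamodel import Transcript, ValidationError, make_tokens
from refcoh.examples import worked_examples


def _transcript(tokens):
    return Transcript(participant_id="t", group="NC", picture_id=1, tokens=tokens)


class TestClassifyCascade:
    @pytest.mark.parametrize("ex", worked_examples(), ids=lambda e: e.name)
    def test_worked_examples_classify_to_expected_categories(self, ex):
        ann = annotate_transcript(ex.transcript, list(ex.spans))
        assert tuple(s.category for s in ann.spans) == ex.expected

    def test_specificity_precedes_indefiniteness(self):
        # a span carrying case marking, plural and generic flags at once:
        # anaphoric > case > plural > generic > residual
        tokens = make_tokens(
            [("kitaplari", {"pos": "noun", "lemma": "kitap", "case": "accusative", "plural": True})]
        )
        span = NPSpan(start=0, end=1, head_lemma="kitap", manual_flags=ManualFlags(generic=True))
        assert classify_np(span, tokens) == NPCategory.BARE_SPECIFIC
        assert (
            classify_np(span, tokens, registry={"kitap"}) == NPCategory.BARE_ANAPHORIC
        )
        plural_only = make_tokens([("kitaplar", {"pos": "noun", "lemma": "kitap", "plural": True})])
        assert (
            classify_np(
                NPSpan(start=0, end=1, head_lemma="kitap", manual_flags=ManualFlags(generic=True)),
                plural_only,
            )
            == NPCategory.BARE_INDEFINITE
        )

    def test_pronoun_precedes_determiner_logic(self):
        tokens = make_tokens([("o", {"pos": "pronoun", "lemma": "o"})])
        span = NPSpan(start=0, end=1, head_lemma="o", is_pronoun=True)
        assert classify_np(span, tokens) == NPCategory.LEXICAL_PRONOUN

    def test_manual_anaphoric_false_overrides_registry(self):
        tokens = make_tokens([("adam", {"pos": "noun", "lemma": "adam"})])
        span = NPSpan(
            start=0, end=1, head_lemma="adam", manual_flags=ManualFlags(anaphoric=False)
        )
        assert classify_np(span, tokens, registry={"adam"}) == NPCategory.BARE_RESIDUAL

    def test_residual_is_total_fallback(self):
        tokens = make_tokens([("kedi", {"pos": "noun", "lemma": "kedi"})])
        span = NPSpan(start=0, end=1, head_lemma="kedi")
        assert classify_np(span, tokens) == NPCategory.BARE_RESIDUAL

    def test_null_subject_with_determiner_is_contradiction(self):
        tokens = make_tokens(
            [("bu", {"pos": "det", "determiner": "demonstrative", "agreement_subject": True})]
        )
        span = NPSpan(start=0, end=0, is_null_subject=True)
        with pytest.raises(ValidationError):
            # empty range anchored at a determiner-bearing token
            classify_np(NPSpan(start=0, end=1, is_null_subject=True), tokens)
        with pytest.raises(ValidationError):
            classify_np(span, tokens)


class TestAnnotateTranscript:
    def test_indefinite_then_bare_same_lemma_is_anaphoric(self):
        tokens = make_tokens(
            [
                ("bir", {"pos": "det", "determiner": "indefinite"}),
                ("adam", {"pos": "noun", "lemma": "adam"}),
                ("adam", {"pos": "noun", "lemma": "adam"}),
            ]
        )
        spans = [
            NPSpan(start=0, end=2, head_lemma="adam"),
            NPSpan(start=2, end=3, head_lemma="adam"),
        ]
        ann = annotate_transcript(_transcript(tokens), spans)
        assert [s.category for s in ann.spans] == [
            NPCategory.INDEFINITE_DP,
            NPCategory.BARE_ANAPHORIC,
        ]

    def test_empty_span_list(self):
        ann = annotate_transcript(_transcript(make_tokens(["a"])), [])
        assert ann.spans == [] and ann.anomaly_count == 0

    def test_registry_does_not_leak_across_narrations(self):
        tokens = make_tokens([("adam", {"pos": "noun", "lemma": "adam"})])
        spans = [NPSpan(start=0, end=1, head_lemma="adam")]
        first = annotate_transcript(_transcript(tokens), spans)
        second = annotate_transcript(_transcript(tokens), spans)
        assert first.spans[0].category == second.spans[0].category == NPCategory.BARE_RESIDUAL

    def test_overlapping_lexical_spans_rejected(self):
        tokens = make_tokens(
            [("a", {"pos": "noun", "lemma": "a"}), ("b", {"pos": "noun", "lemma": "b"})]
        )
        spans = [
            NPSpan(start=0, end=2, head_lemma="b"),
            NPSpan(start=1, end=2, head_lemma="b"),
        ]
        with pytest.raises(ValidationError, match="overlap"):
            annotate_transcript(_transcript(tokens), spans)


class TestCounts:
    def test_worked_example_counts_one_per_category(self):
        for ex in worked_examples():
            ann = annotate_transcript(ex.transcript, list(ex.spans))
            counts = count_categories(ann)
            for cat in ex.expected:
                assert counts[cat.value] >= 1

    def test_duplicate_transcript_doubles_counts(self):
        ex = worked_examples()[2]  # the two-span anaphora discourse
        ann = annotate_transcript(ex.transcript, list(ex.spans))
        single = count_categories(ann)
        doubled = {
            k: single[k] + count_categories(ann)[k]
            for k in single
            if k != "word_count"
        }
        assert all(doubled[k] == 2 * single[k] for k in doubled)

    def test_empty_set_all_zeros(self):
        ann = annotate_transcript(_transcript(make_tokens(["a"])), [])
        counts = count_categories(ann)
        assert all(counts[c.value] == 0 for c in NPCategory)
        assert counts["anomalies"] == 0

    def test_anomaly_flags_are_counted_not_detected(self):
        tokens = make_tokens([("kedi", {"pos": "noun", "lemma": "kedi"})])
        spans = [
            NPSpan(start=0, end=1, head_lemma="kedi", manual_flags=ManualFlags(anomaly=True))
        ]
        ann = annotate_transcript(_transcript(tokens), spans)
        assert ann.anomaly_count == 1


class TestMacroAndAggregation:
    @pytest.mark.parametrize(
        "cat,expected",
        [
            (NPCategory.DEFINITE_DP, "definite_dp"),
            (NPCategory.INDEFINITE_DP, "indefinite_dp"),
            (NPCategory.BARE_INDEFINITE, "bare_indefinite"),
            (NPCategory.BARE_RESIDUAL, "bare_residual"),
            (NPCategory.BARE_ANAPHORIC, "other"),
            (NPCategory.NULL_SUBJECT, "other"),
            (NPCategory.LEXICAL_PRONOUN, "other"),
        ],
    )
    def test_macro_mapping(self, cat, expected):
        assert macro_type(cat) == expected

    def test_default_composition_on_worked_example_counts(self):
        counts = {c.value: 0 for c in NPCategory}
        for ex in worked_examples():
            for cat in ex.expected:
                counts[cat.value] += 1
        agg = aggregate_definiteness(counts)
        # definite DP + anaphoric + specific = 3; indefinite DP (x2) + bare plural = 3
        assert agg == {"all_definite": 3, "all_indefinite": 3}

    def test_zeros_and_additivity(self):
        assert aggregate_definiteness({}) == {"all_definite": 0, "all_indefinite": 0}
        base = {c.value: 1 for c in NPCategory}
        bumped = dict(base, definite_dp=2)
        assert (
            aggregate_definiteness(bumped)["all_definite"]
            == aggregate_definiteness(base)["all_definite"] + 1
        )


class TestCohensKappa:
    def test_identical_sequences_kappa_one(self):
        res = cohens_kappa(["x", "y", "z"] * 10, ["x", "y", "z"] * 10)
        assert res.kappa == 1.0 and res.observed_agreement == 1.0

    def test_balanced_two_category_fixture(self):
        # 1000 items, both raters' marginals 500/500, 20 symmetric disagreements
        a = ["A"] * 500 + ["B"] * 500
        b = ["A"] * 490 + ["B"] * 10 + ["A"] * 10 + ["B"] * 490
        res = cohens_kappa(a, b)
        assert res.observed_agreement == pytest.approx(0.98)
        assert res.expected_agreement == pytest.approx(0.5)
        assert res.kappa == pytest.approx(0.96)

    def test_constant_rater_against_balanced_rater(self):
        a = ["A"] * 100
        b = ["A"] * 50 + ["B"] * 50
        res = cohens_kappa(a, b)
        assert res.expected_agreement == pytest.approx(0.5)
        assert res.kappa == pytest.approx((res.observed_agreement - 0.5) / 0.5)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            cohens_kappa(["a"], ["a", "b"])

    def test_matches_sklearn_on_random_sequences(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(20):
            a = rng.integers(0, 3, 50)
            b = rng.integers(0, 3, 50)
            if len(set(a)) == 1 and len(set(b)) == 1:
                continue
            ours = cohens_kappa(list(a), list(b)).kappa
            assert ours == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.sampled_from("abc"), min_size=2, max_size=60),
        st.data(),
    )
    def test_kappa_bounds_and_perfect_agreement_property(self, a, data):
        b = data.draw(st.lists(st.sampled_from("abc"), min_size=len(a), max_size=len(a)))
        res = cohens_kappa(a, b)
        assert res.kappa <= 1.0 + 1e-12
        if res.expected_agreement < 1.0:
            assert (res.kappa == pytest.approx(1.0)) == (res.observed_agreement == 1.0)
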