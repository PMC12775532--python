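"""Canonical Turkish worked examples of the NP taxonomy.

One miniature feature-annotated narration per referential category,
encoding the standard Turkish constructions: *bir* marking
indefiniteness, demonstrative *bu* marking definiteness, bare-NP
anaphora by lemma repetition, accusative -(y)I as a specificity marker,
bare plurals as indefinite quantification, context-generic bare NPs,
the bare-residual fallback, and agreement-licensed null subjects in a
pro-drop clause.

These examples double as executable documentation and as the fixture
for the classifier's reference behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation import ManualFlags, NPCategory, NPSpan
from .datamodel import Transcript, make_tokens


@dataclass(frozen=True)
class WorkedExample:
    name: str
    gloss: str
    transcript: Transcript
    spans: tuple[NPSpan, ...]
    expected: tuple[NPCategory, ...]


def _t(tokens, pid="EX", pic=1) -> Transcript:
    return Transcript(participant_id=pid, group="NC", picture_id=pic, tokens=tokens)


def worked_examples() -> list[WorkedExample]:
    return [
        WorkedExample(
            name="indefinite_dp",
            gloss="yakışıklı bir adam — 'a handsome man'; *bir* introduces a new referent",
            transcript=_t(
                make_tokens(
                    [
                        "yakışıklı",
                        ("bir", {"pos": "det", "determiner": "indefinite"}),
                        ("adam", {"pos": "noun", "lemma": "adam"}),
                    ]
                )
            ),
            spans=(NPSpan(start=0, end=3, head_lemma="adam"),),
            expected=(NPCategory.INDEFINITE_DP,),
        ),
        WorkedExample(
            name="definite_dp",
            gloss="bu adam çalışan olmalı — 'this man should be a worker'; demonstrative *bu*",
            transcript=_t(
                make_tokens(
                    [
                        ("bu", {"pos": "det", "determiner": "demonstrative"}),
                        ("adam", {"pos": "noun", "lemma": "adam"}),
                        "çalışan",
                        "olmalı",
                    ]
                )
            ),
            spans=(NPSpan(start=0, end=2, head_lemma="adam"),),
            expected=(NPCategory.DEFINITE_DP,),
        ),
        WorkedExample(
            name="bare_anaphoric",
            gloss=(
                "bir adam var. adam tarlada çalışıyor — the bare second *adam* refers "
                "back to the man just introduced"
            ),
            transcript=_t(
                make_tokens(
                    [
                        ("bir", {"pos": "det", "determiner": "indefinite"}),
                        ("adam", {"pos": "noun", "lemma": "adam"}),
                        "var",
                        (".", {"is_punct": True}),
                        ("adam", {"pos": "noun", "lemma": "adam"}),
                        "tarlada",
                        "çalışıyor",
                    ]
                )
            ),
            spans=(
                NPSpan(start=0, end=2, head_lemma="adam"),
                NPSpan(start=4, end=5, head_lemma="adam"),
            ),
            expected=(NPCategory.INDEFINITE_DP, NPCategory.BARE_ANAPHORIC),
        ),
        WorkedExample(
            name="bare_specific",
            gloss="adam tarlayı sürüyor — accusative -(y)I on *tarlayı* marks a specific entity",
            transcript=_t(
                make_tokens(
                    [
                        ("adam", {"pos": "noun", "lemma": "adam"}),
                        ("tarlayı", {"pos": "noun", "lemma": "tarla", "case": "accusative"}),
                        "sürüyor",
                    ]
                )
            ),
            spans=(NPSpan(start=1, end=2, head_lemma="tarla"),),
            expected=(NPCategory.BARE_SPECIFIC,),
        ),
        WorkedExample(
            name="bare_indefinite",
            gloss="evler var — plural -lAr on a bare NP: indefinite quantification over houses",
            transcript=_t(
                make_tokens(
                    [
                        ("evler", {"pos": "noun", "lemma": "ev", "plural": True}),
                        "var",
                    ]
                )
            ),
            spans=(NPSpan(start=0, end=1, head_lemma="ev"),),
            expected=(NPCategory.BARE_INDEFINITE,),
        ),
        WorkedExample(
            name="bare_generic",
            gloss=(
                "köy hayatını anlatıyor — 'it is about village life'; the annotator judges "
                "the reference generic from context (the case marker is not read as "
                "specificity-inducing here), recorded as a manual generic flag"
            ),
            transcript=_t(
                make_tokens(
                    [
                        ("köy", {"pos": "noun", "lemma": "köy"}),
                        ("hayatını", {"pos": "noun", "lemma": "hayat"}),
                        "anlatıyor",
                    ]
                )
            ),
            spans=(
                NPSpan(
                    start=0,
                    end=2,
                    head_lemma="hayat",
                    manual_flags=ManualFlags(generic=True),
                ),
            ),
            expected=(NPCategory.BARE_GENERIC,),
        ),
        WorkedExample(
            name="bare_residual",
            gloss=(
                "kız var — 'there is girl': bare, caseless, not anaphoric, no plural or "
                "generic reading; the total fallback class"
            ),
            transcript=_t(
                make_tokens(
                    [
                        ("kız", {"pos": "noun", "lemma": "kız"}),
                        "var",
                    ]
                )
            ),
            spans=(NPSpan(start=0, end=1, head_lemma="kız"),),
            expected=(NPCategory.BARE_RESIDUAL,),
        ),
        WorkedExample(
            name="null_subject",
            gloss=(
                "genç ve güzel — 'she is young and beautiful': the subject is expressed "
                "only through agreement on the (pro-drop) predicate"
            ),
            transcript=_t(
                make_tokens(
                    [
                        "genç",
                        ("ve", {"is_stopword": True}),
                        ("güzel", {"pos": "verb", "agreement_subject": True}),
                    ]
                )
            ),
            spans=(NPSpan(start=2, end=2, is_null_subject=True),),
            expected=(NPCategory.NULL_SUBJECT,),
        ),
    ]
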