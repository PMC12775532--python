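"""Referential noun-phrase taxonomy and inter-rater agreement.

Noun phrases in feature-annotated narrations are classified by a fixed
decision cascade that mirrors how referential expressions are annotated
in article-less, pro-drop languages such as Turkish:

1. null subjects (subjects realised only as verb agreement morphology);
2. lexical pronouns;
3. determiner phrases, split into indefinite (*bir* 'a/one', numerals,
   quantifiers) and definite (demonstratives *bu/şu/o*);
4. bare NPs, split into anaphoric (refer back to an entity already in
   the discourse), specific (accusative or other specificity-inducing
   case marker), indefinite (bare plural), generic, and a residual
   class for bare NPs with none of these marks.

Specificity checks deliberately precede indefiniteness checks
(anaphoric > case-marked > plural/generic), and the residual class is a
total fallback, so every valid span receives exactly one category.

Anaphoricity is approximated by head-lemma identity within the same
narration (the registry of previously mentioned lexical heads), and can
be overridden by a manual flag.  Referential anomalies — uses whose
referent a listener could not track or verify — require world/image
knowledge and are therefore annotator-supplied flags that are only
counted here, never detected.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .datamodel import Token, Transcript, ValidationError


class NPCategory(str, enum.Enum):
    INDEFINITE_DP = "indefinite_dp"
    DEFINITE_DP = "definite_dp"
    BARE_ANAPHORIC = "bare_anaphoric"
    BARE_SPECIFIC = "bare_specific"
    BARE_INDEFINITE = "bare_indefinite"
    BARE_GENERIC = "bare_generic"
    BARE_RESIDUAL = "bare_residual"
    NULL_SUBJECT = "null_subject"
    LEXICAL_PRONOUN = "lexical_pronoun"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


#: Categories whose head is a lexical noun (feed the anaphora registry).
LEXICAL_CATEGORIES = frozenset(
    {
        NPCategory.INDEFINITE_DP,
        NPCategory.DEFINITE_DP,
        NPCategory.BARE_ANAPHORIC,
        NPCategory.BARE_SPECIFIC,
        NPCategory.BARE_INDEFINITE,
        NPCategory.BARE_GENERIC,
        NPCategory.BARE_RESIDUAL,
    }
)

#: The four macro-types whose arrival dynamics are tested.
MACRO_TYPES = ("definite_dp", "indefinite_dp", "bare_indefinite", "bare_residual")


@dataclass(slots=True)
class ManualFlags:
    anaphoric: bool | None = None
    generic: bool | None = None
    anomaly: bool = False


@dataclass(slots=True)
class NPSpan:
    """A noun-phrase span over ``[start, end)`` token indices.

    Null subjects carry an empty range (start == end) anchored at the
    index of the agreeing verb.  ``head`` is the index of the head token
    (defaults to the last token of the span, Turkish NPs being
    head-final).
    """

    start: int
    end: int
    head_lemma: str = ""
    is_pronoun: bool = False
    is_null_subject: bool = False
    head: int | None = None
    manual_flags: ManualFlags = field(default_factory=ManualFlags)

    @property
    def head_index(self) -> int:
        if self.head is not None:
            return self.head
        return self.start if self.is_null_subject else self.end - 1


@dataclass(slots=True)
class AnnotatedSpan:
    span: NPSpan
    category: NPCategory


@dataclass(slots=True)
class AnnotationSet:
    participant_id: str
    group: str
    picture_id: int
    word_count: int
    spans: list[AnnotatedSpan] = field(default_factory=list)

    @property
    def anomaly_count(self) -> int:
        return sum(s.span.manual_flags.anomaly for s in self.spans)


@dataclass(frozen=True, slots=True)
class KappaResult:
    observed_agreement: float
    expected_agreement: float
    kappa: float
    n: int


def _head_token(span: NPSpan, tokens: Sequence[Token]) -> Token:
    idx = span.head_index
    if not 0 <= idx < len(tokens):
        raise ValidationError(f"span head index {idx} outside narration")
    return tokens[idx]


def _span_determiner(span: NPSpan, tokens: Sequence[Token]) -> str:
    for tok in tokens[span.start : span.end]:
        if tok.features.determiner != "none":
            return tok.features.determiner
    return "none"


def classify_np(
    span: NPSpan,
    tokens: Sequence[Token],
    registry: set[str] | frozenset[str] = frozenset(),
) -> NPCategory:
    """Assign the unique referential category of one NP span.

    ``registry`` holds the head lemmas of lexical NPs already mentioned
    earlier in the same narration; it drives the lemma-identity anaphora
    proxy and must reflect the discourse only up to the span start.
    """
    determiner = _span_determiner(span, tokens)
    if span.is_null_subject:
        if span.start != span.end:
            raise ValidationError("null subject span must have an empty range")
        anchor = _head_token(span, tokens)
        if anchor.features.determiner != "none":
            raise ValidationError("null subject cannot carry a determiner")
        if not anchor.features.agreement_subject:
            raise ValidationError(
                "null subject must be anchored at a verb with subject agreement"
            )
        return NPCategory.NULL_SUBJECT
    if span.start >= span.end:
        raise ValidationError("lexical span must have start < end")
    if span.is_pronoun:
        return NPCategory.LEXICAL_PRONOUN
    if not span.head_lemma:
        raise ValidationError("lexical NP requires a non-empty head lemma")
    if determiner == "indefinite":
        return NPCategory.INDEFINITE_DP
    if determiner == "demonstrative":
        return NPCategory.DEFINITE_DP
    # bare NP: specificity before indefiniteness
    flags = span.manual_flags
    if flags.anaphoric or (flags.anaphoric is None and span.head_lemma in registry):
        return NPCategory.BARE_ANAPHORIC
    head = _head_token(span, tokens)
    if head.features.case in ("accusative", "other"):
        return NPCategory.BARE_SPECIFIC
    if head.features.plural:
        return NPCategory.BARE_INDEFINITE
    if flags.generic:
        return NPCategory.BARE_GENERIC
    return NPCategory.BARE_RESIDUAL


def annotate_transcript(t: Transcript, spans: Sequence[NPSpan]) -> AnnotationSet:
    """Classify all spans of one narration in discourse order.

    The anaphora registry is built incrementally from the head lemmas of
    already-classified lexical NPs and never leaks across narrations.
    Overlapping lexical spans are rejected.
    """
    ordered = sorted(spans, key=lambda s: (s.start, s.end))
    prev_end = -1
    for s in ordered:
        if s.start < 0 or s.end > len(t.tokens):
            raise ValidationError(f"span [{s.start}, {s.end}) outside narration")
        if not s.is_null_subject:
            if s.start < prev_end:
                raise ValidationError(
                    f"overlapping lexical spans at token {s.start}"
                )
            prev_end = s.end
    registry: set[str] = set()
    annotated: list[AnnotatedSpan] = []
    for s in ordered:
        cat = classify_np(s, t.tokens, registry)
        annotated.append(AnnotatedSpan(span=s, category=cat))
        if cat in LEXICAL_CATEGORIES:
            registry.add(s.head_lemma)
    return AnnotationSet(
        participant_id=t.participant_id,
        group=t.group,
        picture_id=t.picture_id,
        word_count=t.word_count,
        spans=annotated,
    )


def count_categories(a: AnnotationSet) -> dict[str, int]:
    """Per-category span counts plus the word-count exposure.

    Keys are the category names, ``anomalies`` and ``word_count`` — the
    per-narration rows that the rate models consume.
    """
    counts = Counter(s.category.value for s in a.spans)
    out = {c.value: counts.get(c.value, 0) for c in NPCategory}
    out["anomalies"] = a.anomaly_count
    out["word_count"] = a.word_count
    return out


def macro_type(c: NPCategory | str) -> str:
    """Map a category to its arrival-dynamics macro-type (or ``other``)."""
    value = c.value if isinstance(c, NPCategory) else str(c)
    return value if value in MACRO_TYPES else "other"


DEFAULT_DEFINITE = ("definite_dp", "bare_anaphoric", "bare_specific")
DEFAULT_INDEFINITE = ("indefinite_dp", "bare_indefinite")


def aggregate_definiteness(
    counts: dict[str, int],
    definite: Iterable[str] = DEFAULT_DEFINITE,
    indefinite: Iterable[str] = DEFAULT_INDEFINITE,
) -> dict[str, int]:
    """Collapse category counts into all-definite / all-indefinite totals.

    The default composition places demonstrative DPs, bare anaphoric and
    case-marked specific NPs on the definite side, and indefinite DPs
    plus bare plurals on the indefinite side; null subjects, pronouns
    and generics are modelled separately and excluded by default.  Both
    sides are configurable.
    """
    return {
        "all_definite": sum(counts.get(k, 0) for k in definite),
        "all_indefinite": sum(counts.get(k, 0) for k in indefinite),
    }


def cohens_kappa(a: Sequence, b: Sequence) -> KappaResult:
    """Chance-corrected inter-rater agreement between two label sequences.

    kappa = (po - pe) / (1 - pe) with po the fraction of exact matches
    and pe the chance agreement from the raters' marginal label
    frequencies.  Returns kappa = 1.0 when pe = 1 and the raters agree
    everywhere (both constant and identical).
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    n = len(a)
    if n == 0:
        raise ValueError("empty sequences")
    po = sum(x == y for x, y in zip(a, b)) / n
    ma, mb = Counter(a), Counter(b)
    pe = sum((ma[k] / n) * (mb.get(k, 0) / n) for k in ma)
    kappa = 1.0 if pe >= 1.0 and po >= 1.0 else (po - pe) / (1.0 - pe)
    return KappaResult(observed_agreement=po, expected_agreement=pe, kappa=kappa, n=n)
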