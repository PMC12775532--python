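"""Corpus data model and JSON-lines / tabular interchange.

One *narration* is a single picture description by one participant,
stored as an ordered token sequence with coarse morphosyntactic
features.  Narrations are the atomic analysis unit throughout: token
indices, occurrence positions and anaphora registries are all local to
a narration and reset at picture boundaries.

The on-disk interchange format is JSON lines, one narration per record.
Feature annotation is explicit (determiner type, case, plurality,
subject agreement) rather than raw morphology, so the pipeline is
language-agnostic at the data level.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

GROUPS = ("NC", "FEP", "UHR", "FHP")
"""Participant groups: neurotypical controls, first-episode psychosis,
ultra-high risk, family history of psychosis."""

DETERMINERS = ("none", "indefinite", "demonstrative")
CASES = ("none", "accusative", "other")
POS_TAGS = ("noun", "pronoun", "verb", "det", "other")


class ValidationError(ValueError):
    """A record violates the transcript schema or an invariant."""


@dataclass(frozen=True, slots=True)
class TokenFeatures:
    """Morphosyntactic flags attached to a token.

    determiner
        ``none`` for bare tokens, ``indefinite`` (e.g. Turkish *bir*,
        *birkaç*) or ``demonstrative`` (*bu/şu/o*).
    case
        ``accusative`` marks differential object marking (-(y)I),
        ``other`` any further specificity-inducing case marker.
    plural
        Plural morphology (-lAr), read as indefinite quantification on
        bare nouns.
    lemma
        Citation form used for the lemma-identity anaphora proxy.
    agreement_subject
        True on verbs whose agreement morphology licenses a null
        (pro-dropped) subject.
    """

    determiner: str = "none"
    case: str = "none"
    plural: bool = False
    lemma: str = ""
    agreement_subject: bool = False


_DEFAULT_FEATURES = TokenFeatures()


@dataclass(slots=True)
class Token:
    index: int
    surface: str
    is_punct: bool = False
    is_stopword: bool = False
    pos: str = "other"
    features: TokenFeatures = _DEFAULT_FEATURES


@dataclass(slots=True)
class Transcript:
    """One narration: a participant's one-minute description of one picture."""

    participant_id: str
    group: str
    picture_id: int
    tokens: list[Token] = field(default_factory=list)
    word_count: int | None = None

    def __post_init__(self) -> None:
        if self.word_count is None:
            self.word_count = sum(not t.is_punct for t in self.tokens)

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)


@dataclass(slots=True)
class TranscriptSet:
    transcripts: list[Transcript] = field(default_factory=list)
    provenance: str = "external"

    def __iter__(self):
        return iter(self.transcripts)

    def __len__(self) -> int:
        return len(self.transcripts)


def validate_transcript(t: Transcript) -> list[str]:
    """Check Token/Transcript invariants; violations are returned as data.

    Returns an empty list iff the narration is internally consistent:
    consecutive 0-based token indices, non-empty surfaces, known group
    label and feature values, and a stored word count that matches the
    number of non-punctuation tokens.
    """
    out: list[str] = []
    if t.group not in GROUPS:
        out.append(f"unknown group label {t.group!r}")
    for i, tok in enumerate(t.tokens):
        if tok.index != i:
            out.append(f"token {i}: index {tok.index} not consecutive from 0")
        if not tok.surface:
            out.append(f"token {i}: empty surface")
        if tok.pos not in POS_TAGS:
            out.append(f"token {i}: unknown pos {tok.pos!r}")
        if tok.features.determiner not in DETERMINERS:
            out.append(f"token {i}: unknown determiner {tok.features.determiner!r}")
        if tok.features.case not in CASES:
            out.append(f"token {i}: unknown case {tok.features.case!r}")
    derived = sum(not tok.is_punct for tok in t.tokens)
    if t.word_count != derived:
        out.append(f"word_count {t.word_count} != {derived} non-punctuation tokens")
    return out


def _token_from_dict(d: dict, pos_in_file: str) -> Token:
    try:
        feats = d.get("features", {})
        return Token(
            index=int(d["index"]),
            surface=str(d["surface"]),
            is_punct=bool(d.get("is_punct", False)),
            is_stopword=bool(d.get("is_stopword", False)),
            pos=str(d.get("pos", "other")),
            features=TokenFeatures(
                determiner=str(feats.get("determiner", "none")),
                case=str(feats.get("case", "none")),
                plural=bool(feats.get("plural", False)),
                lemma=str(feats.get("lemma", "")),
                agreement_subject=bool(feats.get("agreement_subject", False)),
            ),
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"{pos_in_file}: malformed token: {exc}") from exc


def transcript_from_dict(d: dict, pos_in_file: str = "<record>") -> Transcript:
    for key in ("participant_id", "group", "picture_id", "tokens"):
        if key not in d:
            raise ValidationError(f"{pos_in_file}: missing field {key!r}")
    t = Transcript(
        participant_id=str(d["participant_id"]),
        group=str(d["group"]),
        picture_id=int(d["picture_id"]),
        tokens=[_token_from_dict(td, pos_in_file) for td in d["tokens"]],
        word_count=None,  # recomputed from tokens
    )
    violations = validate_transcript(t)
    if "word_count" in d and int(d["word_count"]) != t.word_count:
        violations.append(
            f"stored word_count {d['word_count']} != derived {t.word_count}"
        )
    if violations:
        raise ValidationError(f"{pos_in_file}: " + "; ".join(violations))
    return t


def transcript_to_dict(t: Transcript) -> dict:
    return {
        "participant_id": t.participant_id,
        "group": t.group,
        "picture_id": t.picture_id,
        "word_count": t.word_count,
        "tokens": [
            {
                "index": tok.index,
                "surface": tok.surface,
                "is_punct": tok.is_punct,
                "is_stopword": tok.is_stopword,
                "pos": tok.pos,
                "features": asdict(tok.features),
            }
            for tok in t.tokens
        ],
    }


def read_transcripts(path: str | Path) -> TranscriptSet:
    """Read a JSON-lines corpus, validating every record.

    Raises FileNotFoundError for a missing file and ValidationError
    (naming the line number) for malformed records.  (participant,
    picture) pairs must be unique across the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    transcripts: list[Transcript] = []
    seen: set[tuple[str, int]] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"line {lineno}: invalid JSON: {exc}") from exc
            t = transcript_from_dict(record, pos_in_file=f"line {lineno}")
            key = (t.participant_id, t.picture_id)
            if key in seen:
                raise ValidationError(f"line {lineno}: duplicate narration {key}")
            seen.add(key)
            transcripts.append(t)
    return TranscriptSet(transcripts=transcripts, provenance="external")


def write_transcripts(ts: TranscriptSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for t in ts:
            fh.write(json.dumps(transcript_to_dict(t), ensure_ascii=False) + "\n")


def write_table(rows: pd.DataFrame | Sequence[dict], path: str | Path) -> None:
    """Write tabular results as CSV with a header (lossless round-trip)."""
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(list(rows))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    rows.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def make_tokens(
    specs: Iterable[tuple[str, dict] | str],
) -> list[Token]:
    """Build a token list from compact ``(surface, attrs)`` specs.

    Convenience constructor used by fixtures and the worked examples:
    each item is a surface string or ``(surface, attrs)`` where ``attrs``
    may set token fields (``pos``, ``is_punct``, ``is_stopword``) and any
    TokenFeatures field.
    """
    toks: list[Token] = []
    for i, item in enumerate(specs):
        if isinstance(item, str):
            surface, attrs = item, {}
        else:
            surface, attrs = item
        feat_kwargs = {
            k: attrs[k]
            for k in ("determiner", "case", "plural", "lemma", "agreement_subject")
            if k in attrs
        }
        toks.append(
            Token(
                index=i,
                surface=surface,
                is_punct=bool(attrs.get("is_punct", False)),
                is_stopword=bool(attrs.get("is_stopword", False)),
                pos=str(attrs.get("pos", "other")),
                features=TokenFeatures(**feat_kwargs) if feat_kwargs else _DEFAULT_FEATURES,
            )
        )
    return toks
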