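"""Synthetic corpora with the statistical structure the analysis assumes.

The study's transcripts are not public, so every pipeline stage is
exercised on generated narrations that emulate their statistical
skeleton:

* four participant groups with realistic sizes and word-count
  distributions (negative binomial per narration);
* per-category occurrence processes over the token axis, modelled as
  renewal processes — exponential gaps for memoryless production,
  gamma-gap renewals (shape > 1) for the regular, structured placement
  expected of planned reference;
* group rate multipliers on a per-word incidence scale, so Poisson
  rate regression with a word-count offset can recover configured rate
  ratios end to end;
* spans carrying exactly the morphosyntactic features their intended
  category requires, so the taxonomy classifier recovers the generating
  label (the lemma-identity anaphora proxy is respected by giving bare
  non-anaphoric NPs fresh lemmas);
* annotator-style anomaly flags drawn at a per-group rate;
* embedding streams with a tunable consecutive-cosine level, token
  probability streams with a tunable mean negative log-probability, and
  clustered continuous outcomes with exchangeable correlation.

The defaults encode the study conditions: group sizes 34/53/64/39
(NC/FEP/UHR/FHP), four narrations each, per-word category rates of the
order seen in picture-description speech, definite-type production
reduced and bare-residual production elevated in FEP, and a structured
(non-exponential) arrival process for indefinite DPs in every group
except FEP, where it is memoryless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .annotation import AnnotationSet, ManualFlags, NPCategory, NPSpan, annotate_transcript
from .datamodel import Token, TokenFeatures, Transcript, TranscriptSet
from .semantics import (
    DEFAULT_TURKISH_STOPWORDS,
    EmbeddingSequence,
    TokenProbabilitySequence,
)

_FILLER_VOCAB = (
    "resimde bir kadın adam çocuk masa sandalye pencere kapı bakıyor duruyor "
    "görünüyor ev oda lamba kitap ışık akşam sabah tarla bahçe ağaç yol gökyüzü "
    "el yüz göz saç elbise şapka ayakta oturmuş düşünüyor konuşuyor anlatıyor "
    "gözüküyor karanlık aydınlık eski yeni büyük küçük uzun kısa genç yaşlı"
).split()

_STOPWORD_SURFACES = tuple(sorted(DEFAULT_TURKISH_STOPWORDS))[:24]

#: Baseline (NC) incidence rates per word, by category.
DEFAULT_BASE_RATES: dict[str, float] = {
    "indefinite_dp": 0.075,
    "definite_dp": 0.050,
    "bare_anaphoric": 0.028,
    "bare_specific": 0.001,
    "bare_indefinite": 0.040,
    "bare_generic": 0.002,
    "bare_residual": 0.030,
    "null_subject": 0.070,
    "lexical_pronoun": 0.026,
}

#: Group rate multipliers relative to NC (rate ratios on the per-word scale).
DEFAULT_RATE_MULTIPLIERS: dict[str, dict[str, float]] = {
    "NC": {},
    "FEP": {
        "definite_dp": 0.70,
        "bare_anaphoric": 0.80,
        "bare_residual": 1.35,
        "null_subject": 0.90,
    },
    "UHR": {"indefinite_dp": 0.90, "lexical_pronoun": 0.77},
    "FHP": {},
}

#: Narration word-count negative-binomial means by group.
DEFAULT_WORD_MEANS: dict[str, float] = {"NC": 300.0, "FEP": 215.0, "UHR": 230.0, "FHP": 250.0}

#: Probability that a span carries an annotator anomaly flag.
DEFAULT_ANOMALY_RATES: dict[str, float] = {
    "NC": 0.003,
    "FEP": 0.010,
    "UHR": 0.007,
    "FHP": 0.006,
}

#: Renewal families per (group, category); anything missing is exponential.
#: Indefinite DPs arrive on a regular (gamma shape 3) schedule in every
#: group except FEP, where production is memoryless.
DEFAULT_RENEWAL: dict[tuple[str, str], tuple[str, float]] = {
    ("NC", "indefinite_dp"): ("gamma", 3.0),
    ("UHR", "indefinite_dp"): ("gamma", 3.0),
    ("FHP", "indefinite_dp"): ("gamma", 3.0),
}


@dataclass(slots=True)
class GeneratorConfig:
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"NC": 34, "FEP": 53, "UHR": 64, "FHP": 39}
    )
    pictures_per_participant: int = 4
    base_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_RATES))
    rate_multipliers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(m) for g, m in DEFAULT_RATE_MULTIPLIERS.items()}
    )
    renewal: dict[tuple[str, str], tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_RENEWAL)
    )
    word_count_mean: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WORD_MEANS))
    word_count_dispersion: float = 10.0  # NB size parameter; larger = closer to Poisson
    min_words: int = 30
    anomaly_rate: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ANOMALY_RATES)
    )
    punct_every: int = 11  # one utterance-final punctuation mark per ~11 words
    stopword_frac: float = 0.30
    # embedding / probability stream conditions (per group)
    embedding_dim: int = 64
    embedding_rho: dict[str, float] = field(
        default_factory=lambda: {"NC": 0.50, "FEP": 0.513, "UHR": 0.512, "FHP": 0.50}
    )
    mean_nll: dict[str, float] = field(
        default_factory=lambda: {g: float(np.log(10.0)) for g in ("NC", "FEP", "UHR", "FHP")}
    )
    nll_sd: float = 0.5
    # clustered-outcome model
    outcome_beta: float = 0.09
    outcome_rho: float = 0.4
    outcome_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.base_rates.values()):
            raise ValueError("base rates must be non-negative")
        if any(s < 1 for s in self.group_sizes.values()):
            raise ValueError("group sizes must be at least 1")
        for fam, shape in self.renewal.values():
            if fam not in ("exponential", "gamma"):
                raise ValueError(f"unknown renewal family {fam!r}")
            if fam == "gamma" and shape < 1:
                raise ValueError("gamma shape must be >= 1")
        for rho in self.embedding_rho.values():
            if not 0 <= rho < 1:
                raise ValueError("embedding rho must lie in [0, 1)")


@dataclass(slots=True)
class SimulatedNarration:
    transcript: Transcript
    spans: list[NPSpan]
    intended: list[NPCategory]  # generating category per span (span order)


@dataclass(slots=True)
class SimulatedCorpus:
    narrations: list[SimulatedNarration]
    annotations: list[AnnotationSet]

    @property
    def transcript_set(self) -> TranscriptSet:
        return TranscriptSet(
            transcripts=[n.transcript for n in self.narrations], provenance="synthetic"
        )


def _renewal_positions(
    rng: np.random.Generator, rate: float, horizon: float, family: str, shape: float
) -> np.ndarray:
    """Integer arrival positions of a renewal process with mean gap
    ~1/rate in [0, horizon).

    Memoryless (exponential-family) streams use the defining window
    property of the Poisson process transplanted to the grid: the
    number of occurrences is Poisson(rate x horizon) and, given the
    count, positions are uniform over distinct slots.  Counts are then
    exactly Poisson (what the rate models assume) and dequantised gaps
    match a continuous exponential.  Gamma renewals are generated in
    continuous time and floored (shape > 1 makes sub-token gaps rare).
    """
    if rate <= 0 or horizon <= 1:
        return np.empty(0, dtype=np.int64)
    if family == "gamma":
        n_draw = int(rate * horizon * 3) + 10
        gaps = rng.gamma(shape, 1.0 / (rate * shape), size=n_draw)
        pos = np.cumsum(gaps)
        while pos[-1] < horizon:  # pragma: no cover - extremely rare top-up
            extra = rng.gamma(shape, 1.0 / (rate * shape), size=n_draw)
            pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
        return np.unique(np.floor(pos[pos < horizon]).astype(np.int64))
    n_slots = int(horizon)
    n_occ = min(int(rng.poisson(rate * horizon)), n_slots)
    pos = rng.choice(n_slots, size=n_occ, replace=False)
    pos.sort()
    return pos.astype(np.int64)


def _simulate_narration(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    participant_id: str,
    group: str,
    picture_id: int,
) -> SimulatedNarration:
    mean_w = cfg.word_count_mean.get(group, 250.0)
    k = cfg.word_count_dispersion
    wc = int(rng.negative_binomial(k, k / (k + mean_w)))
    wc = max(wc, cfg.min_words)

    mults = cfg.rate_multipliers.get(group, {})
    # occurrences per category on the word axis, nearest-free-slot probing
    # on integer collisions
    occupied: dict[int, str] = {}
    for cat in sorted(cfg.base_rates):
        rate = cfg.base_rates[cat] * mults.get(cat, 1.0)
        family, shape = cfg.renewal.get((group, cat), ("exponential", 1.0))
        for w in _renewal_positions(rng, rate, float(wc), family, shape):
            w = int(w)
            # cross-category collision: probe to the next free word slot
            # (preserves counts; displaces a small fraction of points by
            # one token)
            while w in occupied and w < wc:
                w += 1
            if w < wc:
                occupied[w] = cat

    # word position -> token index with punctuation interleaved
    n_punct = wc // cfg.punct_every
    tok_of_word = np.arange(wc) + np.minimum(
        np.arange(wc) // cfg.punct_every, n_punct
    )
    n_tokens = wc + n_punct

    surf_idx = rng.integers(0, len(_FILLER_VOCAB), size=wc)
    stop_mask = rng.random(wc) < cfg.stopword_frac
    stop_idx = rng.integers(0, len(_STOPWORD_SURFACES), size=wc)

    head_words = sorted(occupied)
    anomaly_p = cfg.anomaly_rate.get(group, 0.0)
    anomaly_draw = rng.random(len(head_words)) < anomaly_p
    anaphora_choice = rng.random(len(head_words))

    # per-word overrides for span-head tokens
    overrides: dict[int, tuple[str, str, TokenFeatures]] = {}  # word -> (surface,pos,feat)
    spans: list[NPSpan] = []
    intended: list[NPCategory] = []
    mentioned: list[str] = []  # lexical lemmas in discourse order
    fresh = 0
    for j, w in enumerate(head_words):
        cat = occupied[w]
        tok_idx = int(tok_of_word[w])
        flags = ManualFlags(anomaly=bool(anomaly_draw[j]))
        fresh += 1
        lemma = f"lem{fresh}"
        if cat == "null_subject":
            overrides[w] = ("yapıyor", "verb", TokenFeatures(agreement_subject=True))
            spans.append(
                NPSpan(start=tok_idx, end=tok_idx, is_null_subject=True, manual_flags=flags)
            )
        elif cat == "lexical_pronoun":
            overrides[w] = ("o", "pronoun", TokenFeatures(lemma="o"))
            spans.append(
                NPSpan(
                    start=tok_idx,
                    end=tok_idx + 1,
                    head_lemma="o",
                    is_pronoun=True,
                    manual_flags=flags,
                )
            )
        else:
            feat_kwargs: dict = {}
            if cat == "indefinite_dp":
                feat_kwargs["determiner"] = "indefinite"
            elif cat == "definite_dp":
                feat_kwargs["determiner"] = "demonstrative"
            elif cat == "bare_specific":
                feat_kwargs["case"] = "accusative"
            elif cat == "bare_indefinite":
                feat_kwargs["plural"] = True
            elif cat == "bare_generic":
                flags.generic = True
            elif cat == "bare_anaphoric":
                if mentioned:
                    lemma = mentioned[int(anaphora_choice[j] * len(mentioned))]
                else:  # nothing to refer back to yet: keep the manual judgment
                    flags.anaphoric = True
            overrides[w] = (lemma, "noun", TokenFeatures(lemma=lemma, **feat_kwargs))
            spans.append(
                NPSpan(start=tok_idx, end=tok_idx + 1, head_lemma=lemma, manual_flags=flags)
            )
            mentioned.append(lemma)
        intended.append(NPCategory(cat))

    tokens: list[Token] = []
    widx = 0
    for i in range(n_tokens):
        if widx < wc and tok_of_word[widx] == i:
            if widx in overrides:
                surface, pos, feats = overrides[widx]
                tokens.append(Token(index=i, surface=surface, pos=pos, features=feats))
            elif stop_mask[widx]:
                tokens.append(
                    Token(
                        index=i,
                        surface=_STOPWORD_SURFACES[stop_idx[widx]],
                        is_stopword=True,
                    )
                )
            else:
                tokens.append(Token(index=i, surface=_FILLER_VOCAB[surf_idx[widx]]))
            widx += 1
        else:
            tokens.append(Token(index=i, surface=".", is_punct=True))

    transcript = Transcript(
        participant_id=participant_id,
        group=group,
        picture_id=picture_id,
        tokens=tokens,
    )
    return SimulatedNarration(transcript=transcript, spans=spans, intended=intended)


def simulate_corpus(cfg: GeneratorConfig, seed: int | None = None) -> SimulatedCorpus:
    """Generate a full corpus and its classified annotations.

    Deterministic: identical config and seed reproduce an identical
    corpus.  ``seed=None`` falls back to ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    narrations: list[SimulatedNarration] = []
    annotations: list[AnnotationSet] = []
    for group in sorted(cfg.group_sizes):
        for i in range(cfg.group_sizes[group]):
            pid = f"{group}{i + 1:03d}"
            for pic in range(1, cfg.pictures_per_participant + 1):
                narr = _simulate_narration(rng, cfg, pid, group, pic)
                narrations.append(narr)
                annotations.append(annotate_transcript(narr.transcript, narr.spans))
    return SimulatedCorpus(narrations=narrations, annotations=annotations)


def round_trip_agreement(corpus: SimulatedCorpus) -> float:
    """Fraction of spans whose classified category equals the generating one."""
    total = agree = 0
    for narr, ann in zip(corpus.narrations, corpus.annotations):
        by_key = {
            (s.span.start, s.span.end): s.category for s in ann.spans
        }
        for span, cat in zip(narr.spans, narr.intended):
            total += 1
            agree += by_key.get((span.start, span.end)) == cat
    return agree / total if total else 1.0


def simulate_embedding_stream(
    n: int, dim: int, rho: float, seed: int | None = None
) -> EmbeddingSequence:
    """Unit-sphere random walk with consecutive-cosine level set by rho.

    e_1 is uniform on the sphere and
    e_{i+1} = normalize(rho * e_i + sqrt(1 - rho^2) * eps_i) with
    eps_i an independent isotropic unit vector, so the expected
    consecutive cosine grows monotonically with rho (rho = 0 gives
    isotropic steps, rho -> 1 a frozen direction).
    """
    if n < 2 or dim < 2:
        raise ValueError("need n >= 2 and dim >= 2")
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n, dim))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    out = np.empty((n, dim))
    out[0] = steps[0]
    w = np.sqrt(1.0 - rho**2)
    for i in range(1, n):
        v = rho * out[i - 1] + w * steps[i]
        out[i] = v / np.linalg.norm(v)
    return EmbeddingSequence(vectors=out)


def simulate_probability_stream(
    n: int, mean_nll: float, sd: float, seed: int | None = None
) -> TokenProbabilitySequence:
    """Token probabilities whose negative logs are truncated-normal.

    -ln P ~ N(mean_nll, sd^2) truncated to (0, inf), so the
    pseudo-perplexity concentrates near exp(mean_nll) for large n and
    equals it exactly at sd = 0.
    """
    if mean_nll <= 0:
        raise ValueError("mean_nll must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        nll = np.full(n, mean_nll)
    else:
        from scipy import stats as sps

        rng = np.random.default_rng(seed)
        a = (0.0 - mean_nll) / sd
        nll = sps.truncnorm.rvs(
            a, np.inf, loc=mean_nll, scale=sd, size=n, random_state=rng
        )
    return TokenProbabilitySequence(probabilities=np.exp(-nll))


def simulate_clustered_outcome(
    n_clusters: int,
    cluster_size: int,
    beta: float,
    rho: float,
    sigma: float,
    seed: int | None = None,
    intercept: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Clustered Gaussian outcome with exchangeable correlation rho.

    y = intercept + beta * x + b_c + e with Var(b_c) = rho * sigma^2 and
    Var(e) = (1 - rho) * sigma^2, so residuals within a cluster share
    correlation rho.  Returns (y, X, cluster_ids) with X holding an
    intercept column and one standard-normal predictor.
    """
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n = n_clusters * cluster_size
    x = rng.standard_normal(n)
    cluster_ids = np.repeat(np.arange(n_clusters), cluster_size)
    b = rng.normal(0.0, np.sqrt(rho) * sigma, size=n_clusters)
    e = rng.normal(0.0, np.sqrt(1.0 - rho) * sigma, size=n)
    y = intercept + beta * x + b[cluster_ids] + e
    X = np.column_stack([np.ones(n), x])
    return y, X, cluster_ids


def small_config(**overrides) -> GeneratorConfig:
    """A desk-scale variant of the default conditions (smaller groups)."""
    cfg = GeneratorConfig()
    cfg = replace(
        cfg, group_sizes={g: max(4, s // 8) for g, s in cfg.group_sizes.items()}
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg
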