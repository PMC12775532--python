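"""Embedding-based coherence metrics: consecutive-cosine similarity,
masked-LM pseudo-perplexity, and image-to-text similarity.

Word-to-word semantic similarity of a processed narration
W = (w_1 ... w_n) with embeddings e_1 ... e_n is the mean cosine over
consecutive pairs:

    similarity(W) = (1 / (n - 1)) * sum_i cos(e_i, e_{i+1})

Pseudo-perplexity (PPPL) summarises predictability from per-token
probabilities under a masked language model:

    PPPL = exp( (1/n) * sum_i -ln P(w_i | context) )

i.e. the inverse geometric mean of the token probabilities; lower means
more predictable speech.  Natural logarithm throughout.

Punctuation and stop words are removed *only* on the similarity path
(so the metric tracks lexical-conceptual content rather than
grammatical scaffolding); the referential and perplexity analyses use
the full token sequence.

Embedding and probability providers are pluggable behind
``EmbeddingProvider``; the shipped ``stub_provider`` is a deterministic,
platform-stable test double (hash-of-surface unit vectors) standing in
for pretrained encoders.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from .datamodel import Token, Transcript

#: Small default Turkish stop-word list (function words, fillers).
#: The list is a configurable input; this default covers the most
#: frequent closed-class items.
DEFAULT_TURKISH_STOPWORDS = frozenset(
    """ve veya ama fakat ancak çünkü ki de da ile için gibi kadar sonra önce
    şey bir bu şu o ben sen biz siz onlar mi mı mu mü ne nasıl neden niye
    çok az daha en var yok evet hayır yani işte şimdi burada orada her hep
    hiç belki galiba sanırım herhalde acaba ya hem böyle şöyle öyle""".split()
)


@dataclass(slots=True)
class EmbeddingSequence:
    vectors: np.ndarray  # (n, dim)

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


@dataclass(slots=True)
class TokenProbabilitySequence:
    probabilities: np.ndarray  # each in (0, 1]

    @property
    def n(self) -> int:
        return len(self.probabilities)


class EmbeddingProvider(Protocol):
    """Capability contract for text/image encoders.

    Implementations must be deterministic: the same input and model id
    yield identical output across runs and platforms.
    """

    model_id: str
    dim: int

    def embed_tokens(self, surfaces: Sequence[str]) -> EmbeddingSequence: ...

    def token_probabilities(self, surfaces: Sequence[str]) -> TokenProbabilitySequence: ...

    def embed_image(self, image_id: str) -> np.ndarray: ...


def preprocess_for_similarity(
    t: Transcript | Sequence[Token],
    stopwords: frozenset[str] | set[str] = DEFAULT_TURKISH_STOPWORDS,
) -> list[str]:
    """Surfaces with punctuation and stop words removed, order preserved.

    Applies only to the similarity path; stop-word membership is checked
    case-insensitively against ``stopwords`` and the token's own
    ``is_stopword`` flag is honoured as well.
    """
    tokens = t.tokens if isinstance(t, Transcript) else t
    return [
        tok.surface
        for tok in tokens
        if not tok.is_punct
        and not tok.is_stopword
        and tok.surface.lower() not in stopwords
    ]


def _unit_rows(vectors: np.ndarray, what: str) -> np.ndarray:
    norms = np.linalg.norm(vectors, axis=-1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError(f"zero-norm vector in {what}")
    return vectors / norms


def consecutive_cosine_similarity(E: EmbeddingSequence | np.ndarray) -> float | None:
    """Mean cosine similarity between consecutive embeddings.

    Returns None (undefined) for fewer than two vectors; raises on a
    zero-norm vector.  Invariant to positive rescaling of any vector.
    """
    vectors = E.vectors if isinstance(E, EmbeddingSequence) else np.asarray(E, dtype=float)
    if vectors.ndim != 2:
        raise ValueError("expected a (n, dim) matrix")
    if vectors.shape[0] < 2:
        return None
    unit = _unit_rows(vectors, "embedding sequence")
    cosines = np.sum(unit[:-1] * unit[1:], axis=1)
    return float(np.mean(cosines))


def pseudo_perplexity(P: TokenProbabilitySequence | np.ndarray) -> float:
    """exp(mean negative log probability) — inverse geometric mean.

    Always >= 1 for probabilities in (0, 1]; raises on non-positive
    probabilities or an empty sequence.
    """
    probs = (
        P.probabilities if isinstance(P, TokenProbabilitySequence) else np.asarray(P, dtype=float)
    )
    if probs.size == 0:
        raise ValueError("empty probability sequence")
    if np.any(probs <= 0):
        raise ValueError("token probabilities must be positive")
    if np.any(probs > 1):
        raise ValueError("token probabilities must be at most 1")
    return float(np.exp(-np.mean(np.log(probs))))


def image_text_similarity(
    image_vec: np.ndarray, text_vecs: Sequence[np.ndarray] | np.ndarray
) -> float:
    """Mean cosine between one image embedding and its text embeddings.

    ``text_vecs`` holds one embedding per sentence (or per narration);
    the mean over them is the participant-level bimodal similarity.
    """
    image_vec = np.asarray(image_vec, dtype=float)
    text = np.atleast_2d(np.asarray(text_vecs, dtype=float))
    if text.shape[0] == 0:
        raise ValueError("at least one text vector required")
    if text.shape[1] != image_vec.shape[0]:
        raise ValueError(
            f"dimension mismatch: image {image_vec.shape[0]}, text {text.shape[1]}"
        )
    img_unit = _unit_rows(image_vec[None, :], "image vector")[0]
    text_unit = _unit_rows(text, "text vectors")
    return float(np.mean(text_unit @ img_unit))


@dataclass(slots=True)
class StubProvider:
    """Deterministic hash-of-surface encoder used as a model stand-in.

    Each surface maps — via BLAKE2 of (model id, seed, surface) — to a
    fixed unit vector and a fixed token probability, so outputs are
    identical across runs, processes and platforms, satisfying the
    provider determinism contract without any pretrained weights.
    """

    seed: int = 0
    dim: int = 64
    model_id: str = "stub"

    def _rng_for(self, kind: str, key: str) -> np.random.Generator:
        digest = hashlib.blake2b(
            f"{self.model_id}|{self.seed}|{kind}|{key}".encode(), digest_size=8
        ).digest()
        return np.random.default_rng(int.from_bytes(digest, "little"))

    def _unit_vector(self, kind: str, key: str) -> np.ndarray:
        v = self._rng_for(kind, key).standard_normal(self.dim)
        return v / np.linalg.norm(v)

    def embed_tokens(self, surfaces: Sequence[str]) -> EmbeddingSequence:
        if len(surfaces) == 0:
            return EmbeddingSequence(vectors=np.empty((0, self.dim)))
        return EmbeddingSequence(
            vectors=np.stack([self._unit_vector("tok", s) for s in surfaces])
        )

    def token_probabilities(self, surfaces: Sequence[str]) -> TokenProbabilitySequence:
        probs = [
            float(self._rng_for("prob", s).uniform(0.05, 1.0)) for s in surfaces
        ]
        return TokenProbabilitySequence(probabilities=np.asarray(probs))

    def embed_image(self, image_id: str) -> np.ndarray:
        return self._unit_vector("img", image_id)

    def embed_text(self, text: str) -> np.ndarray:
        return self._unit_vector("txt", text)


def stub_provider(seed: int = 0, dim: int = 64) -> StubProvider:
    return StubProvider(seed=seed, dim=dim)


def save_embedding_cache(E: EmbeddingSequence, meta: dict, path: str | Path) -> None:
    """Persist an embedding matrix as TSV plus a JSON sidecar."""
    import json

    path = Path(path)
    np.savetxt(path, E.vectors, delimiter="\t")
    sidecar = dict(meta)
    sidecar.update({"n": E.n, "dim": E.dim})
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_embedding_cache(path: str | Path) -> tuple[EmbeddingSequence, dict]:
    import json

    path = Path(path)
    vectors = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return EmbeddingSequence(vectors=vectors), meta
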