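"""Embedding-similarity (semantic) features of the picture-description task.

Nouns and verbs are isolated from a POS-annotated transcript, each content
word is compared (cosine similarity; larger = more similar) with ten fixed
seed words — five action concepts and five non-action concepts — and the
similarity distribution per seed is summarised by six statistics.  Together
with the total word count ``nw`` this yields 10 x 6 + 1 = 61 features.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .descriptors import SEMANTIC_DESCRIPTORS, summarize_distribution
from .errors import ConfigurationError, ParameterError

__all__ = [
    "Transcript",
    "EmbeddingTable",
    "ACTION_SEEDS",
    "NON_ACTION_SEEDS",
    "SEED_WORDS",
    "extract_content_words",
    "similarity",
    "semantic_feature_vector",
    "SEMANTIC_FEATURE_NAMES",
]

ACTION_SEEDS = ("action", "act", "move", "play", "energetic")
NON_ACTION_SEEDS = ("inaction", "sleep", "rest", "sit", "wait")
#: the ten seed concepts the content words are compared against
SEED_WORDS = ACTION_SEEDS + NON_ACTION_SEEDS

CONTENT_TAGS = frozenset({"noun", "verb"})
VALID_TAGS = frozenset({"noun", "verb", "other"})

SEMANTIC_FEATURE_NAMES = tuple(
    f"{seed.upper()} ({d})" for seed in SEED_WORDS for d in SEMANTIC_DESCRIPTORS
) + ("nw",)


@dataclass
class Transcript:
    """Ordered (surface form, POS tag) tokens; tags in {noun, verb, other}."""

    tokens: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ParameterError("transcript must be nonempty")
        bad = {tag for _, tag in self.tokens} - VALID_TAGS
        if bad:
            raise ParameterError(f"unknown POS tags {sorted(bad)}")
        self.tokens = [(w.lower(), tag) for w, tag in self.tokens]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for word, tag in self.tokens:
                fh.write(f"{word}\t{tag}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Transcript":
        tokens = []
        for line in Path(path).read_text().splitlines():
            if line.strip():
                word, tag = line.split("\t")
                tokens.append((word, tag))
        return cls(tokens=tokens)


class EmbeddingTable:
    """word -> fixed-dimension real vector, with a known vocabulary."""

    def __init__(self, vectors: dict[str, np.ndarray]):
        if not vectors:
            raise ParameterError("embedding table must be nonempty")
        dims = {np.asarray(v).shape for v in vectors.values()}
        if len(dims) != 1 or len(next(iter(dims))) != 1:
            raise ParameterError("all embedding vectors must share one dimension")
        self._vectors = {w: np.asarray(v, dtype=np.float64) for w, v in vectors.items()}
        self.dim = next(iter(dims))[0]
        if any(not np.all(np.isfinite(v)) for v in self._vectors.values()):
            raise ParameterError("embedding vectors must be finite")

    def __contains__(self, word: str) -> bool:
        return word in self._vectors

    def __getitem__(self, word: str) -> np.ndarray:
        return self._vectors[word]

    @property
    def vocabulary(self) -> set[str]:
        return set(self._vectors)

    def to_text(self, path: str | Path) -> None:
        """Word-vector text format: 'word v1 v2 ... vd' per line."""
        with open(path, "w") as fh:
            for word in sorted(self._vectors):
                vals = " ".join(f"{x:.8g}" for x in self._vectors[word])
                fh.write(f"{word} {vals}\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "EmbeddingTable":
        vectors = {}
        for line in Path(path).read_text().splitlines():
            parts = line.split()
            if parts:
                vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
        return cls(vectors)


def extract_content_words(transcript: Transcript) -> list[str]:
    """Nouns and verbs in order, duplicates kept."""
    return [w for w, tag in transcript.tokens if tag in CONTENT_TAGS]


def similarity(word: str, seed: str, table: EmbeddingTable) -> float:
    """Cosine similarity between two in-vocabulary words, in [-1, 1]."""
    u, v = table[word], table[seed]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ParameterError(f"zero embedding vector for {word!r} or {seed!r}")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def semantic_feature_vector(
    transcript: Transcript,
    table: EmbeddingTable,
    seeds: tuple[str, ...] = SEED_WORDS,
) -> dict[str, float]:
    """61 named features: 6 descriptors per seed word plus the token count nw.

    Out-of-vocabulary content words are skipped; if fewer than 3 in-vocabulary
    content words remain, all similarity features are NaN (with a warning) and
    only ``nw`` is reported.
    """
    missing = [s for s in seeds if s not in table]
    if missing:
        raise ConfigurationError(f"seed words missing from embedding vocabulary: {missing}")
    names = tuple(f"{s.upper()} ({d})" for s in seeds for d in SEMANTIC_DESCRIPTORS)
    words = [w for w in extract_content_words(transcript) if w in table]
    out: dict[str, float] = {}
    if len(words) < 3:
        warnings.warn(
            f"only {len(words)} in-vocabulary content words; semantic features missing",
            stacklevel=2,
        )
        out.update({name: float("nan") for name in names})
    else:
        vecs = np.stack([table[w] for w in words])
        norms = np.linalg.norm(vecs, axis=1, keepdims=True)
        if np.any(norms == 0.0):
            raise ParameterError("zero embedding vector among content words")
        vecs = vecs / norms
        for seed in seeds:
            sv = table[seed]
            sims = vecs @ (sv / np.linalg.norm(sv))
            desc = summarize_distribution(sims)
            for d in SEMANTIC_DESCRIPTORS:
                out[f"{seed.upper()} ({d})"] = desc[d]
    out["nw"] = float(len(transcript.tokens))
    return out
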