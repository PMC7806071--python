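"""Half-session lexical similarity between conversation partners.

Lexical entrainment complements the acoustic analysis: each session is cut
into a first and second half by time, and within each half two similarity
measures compare the partners' word choices.

Word-usage similarity counts, over word types used by *both* speakers, how
often those shared words occur, normalized by the mean number of words per
speaker segment:

    S = sum_{w in shared types} (c_A(w) + c_B(w)) / ((N_A + N_B) / 2)

S ranges over [0, 2]: 0 for disjoint vocabularies, 2 exactly when every
token belongs to a type both speakers used. Embedding similarity is the
cosine between the two speakers' mean word vectors within the same half,
looked up in a word2vec-format lexicon; out-of-vocabulary tokens are
skipped and tracked as coverage.
"""

from __future__ import annotations

import math
import string
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .segmentation import Transcript


class UndefinedSimilarityError(ValueError):
    """Similarity undefined (empty token list or zero vector)."""


class CoverageError(ValueError):
    """No token of the segment is present in the embedding lexicon."""


_PUNCT_TABLE = str.maketrans("", "", string.punctuation)


def tokenize(text: str) -> list[str]:
    """Lowercase, strip punctuation, split on whitespace."""
    return [tok for tok in text.lower().translate(_PUNCT_TABLE).split() if tok]


@dataclass
class HalfSessionTokens:
    """Per-speaker token lists for one half of a session."""

    half_index: int  # 1 or 2
    tokens_a: list[str]
    tokens_b: list[str]


@dataclass
class EmbeddingLexicon:
    """word -> fixed-dimension vector mapping with case-normalized lookup."""

    vectors: dict[str, np.ndarray]
    dim: int
    language: str = ""
    lowercase_lookup: bool = True

    def __contains__(self, word: str) -> bool:
        return self._key(word) in self.vectors

    def _key(self, word: str) -> str:
        return word.lower() if self.lowercase_lookup else word

    def __getitem__(self, word: str) -> np.ndarray:
        return self.vectors[self._key(word)]

    def __len__(self) -> int:
        return len(self.vectors)

    @classmethod
    def read_word2vec_text(cls, path: str | Path, language: str = "") -> "EmbeddingLexicon":
        """Load a word2vec text-format file ("vocab dim" header, then rows)."""
        vectors: dict[str, np.ndarray] = {}
        with open(path) as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ValueError(f"{path}: expected 'vocab_size dim' header")
            _, dim = int(header[0]), int(header[1])
            for ln in fh:
                parts = ln.rstrip("\n").split(" ")
                if len(parts) < dim + 1:
                    continue
                word = parts[0].lower()
                vectors[word] = np.asarray(parts[1 : dim + 1], dtype=np.float64)
        return cls(vectors=vectors, dim=dim, language=language)

    def write_word2vec_text(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.vectors)} {self.dim}\n")
            for word, vec in self.vectors.items():
                fh.write(word + " " + " ".join(f"{v:.8g}" for v in vec) + "\n")


def split_halves(transcript: Transcript) -> tuple[HalfSessionTokens, HalfSessionTokens]:
    """Cut a session at mid-time and pool each speaker's tokens per half.

    With session span [t0, T), a turn belongs to half 1 iff its start time
    lies in [t0, t0 + (T - t0)/2), half 2 otherwise (half-open convention).
    A half in which either speaker has zero tokens is flagged with a warning;
    similarity for that half is undefined downstream.
    """
    t0, t_end = transcript.span
    if t_end <= t0:
        raise ValueError("transcript must have a positive time span")
    mid = t0 + (t_end - t0) / 2.0
    spk_a, spk_b = transcript.speaker_ids
    halves = {1: {spk_a: [], spk_b: []}, 2: {spk_a: [], spk_b: []}}
    for turn in transcript.turns:
        half = 1 if turn.start < mid else 2
        halves[half][turn.speaker_id].extend(tokenize(turn.text))
    out = []
    for h in (1, 2):
        ha, hb = halves[h][spk_a], halves[h][spk_b]
        if not ha or not hb:
            warnings.warn(
                f"session {transcript.session_id!r}: a speaker has no tokens in "
                f"half {h}; similarity undefined for that half"
            )
        out.append(HalfSessionTokens(half_index=h, tokens_a=ha, tokens_b=hb))
    return out[0], out[1]


def word_usage_similarity(tokens_a: Sequence[str], tokens_b: Sequence[str]) -> float:
    """Shared-vocabulary usage score in [0, 2] (see module docstring)."""
    if not tokens_a or not tokens_b:
        raise UndefinedSimilarityError("word usage similarity needs non-empty token lists")
    ca, cb = Counter(tokens_a), Counter(tokens_b)
    shared = ca.keys() & cb.keys()
    total_shared = sum(ca[w] + cb[w] for w in shared)
    return total_shared / ((len(tokens_a) + len(tokens_b)) / 2.0)


def jaccard_type_similarity(tokens_a: Sequence[str], tokens_b: Sequence[str]) -> float:
    """Type-level Jaccard overlap (non-default alternative score, in [0, 1])."""
    if not tokens_a or not tokens_b:
        raise UndefinedSimilarityError("jaccard similarity needs non-empty token lists")
    sa, sb = set(tokens_a), set(tokens_b)
    return len(sa & sb) / len(sa | sb)


def min_count_overlap_similarity(tokens_a: Sequence[str], tokens_b: Sequence[str]) -> float:
    """Histogram-intersection overlap (non-default alternative score, in [0, 1])."""
    if not tokens_a or not tokens_b:
        raise UndefinedSimilarityError("overlap similarity needs non-empty token lists")
    ca, cb = Counter(tokens_a), Counter(tokens_b)
    inter = sum(min(ca[w], cb[w]) for w in ca.keys() & cb.keys())
    return inter / min(len(tokens_a), len(tokens_b))


USAGE_SCORES = {
    "shared_count": word_usage_similarity,  # default
    "jaccard": jaccard_type_similarity,
    "min_count": min_count_overlap_similarity,
}


def mean_embedding(
    tokens: Sequence[str], lexicon: EmbeddingLexicon
) -> tuple[np.ndarray, float]:
    """Mean vector of in-lexicon tokens plus the lexicon coverage fraction."""
    if not tokens:
        raise UndefinedSimilarityError("mean embedding needs a non-empty token list")
    hits = [lexicon[t] for t in tokens if t in lexicon]
    if not hits:
        raise CoverageError("no token found in the embedding lexicon")
    return np.mean(hits, axis=0), len(hits) / len(tokens)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u||v|) in [-1, 1]; errors on a zero vector."""
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    if u.shape != v.shape:
        raise ValueError("vectors must have equal dimension")
    nu, nv = float(np.linalg.norm(u)), float(np.linalg.norm(v))
    if nu == 0 or nv == 0:
        raise UndefinedSimilarityError("cosine similarity undefined for zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


@dataclass
class LinguisticGroupRow:
    """One group's Table row: half-wise means over that group's sessions."""

    group_id: str
    usage_half1: float
    usage_half2: float
    embedding_half1: Optional[float]  # None when no lexicon is available
    embedding_half2: Optional[float]
    n_sessions: int


def _session_half_scores(
    transcript: Transcript,
    lexicon: Optional[EmbeddingLexicon],
    usage_score: str,
) -> tuple[list[float], list[float]]:
    score_fn = USAGE_SCORES[usage_score]
    usage, embed = [], []
    for half in split_halves(transcript):
        if half.tokens_a and half.tokens_b:
            usage.append(score_fn(half.tokens_a, half.tokens_b))
            if lexicon is not None:
                va, _ = mean_embedding(half.tokens_a, lexicon)
                vb, _ = mean_embedding(half.tokens_b, lexicon)
                embed.append(cosine_similarity(va, vb))
            else:
                embed.append(math.nan)
        else:
            usage.append(math.nan)
            embed.append(math.nan)
    return usage, embed


def linguistic_report(
    sessions: Iterable[tuple[str, Transcript]],
    lexicon: Optional[EmbeddingLexicon] = None,
    usage_score: str = "shared_count",
) -> list[LinguisticGroupRow]:
    """Half-wise mean similarities per group.

    ``sessions`` yields (group_id, transcript) pairs. Each group row holds
    the mean usage similarity per half and, when a lexicon is supplied, the
    mean cosine similarity of the speakers' mean embeddings per half
    (``None`` otherwise, rendered as an em dash in the written table).
    Halves with an empty speaker are excluded from the means.
    """
    by_group: dict[str, list[tuple[list[float], list[float]]]] = {}
    for group_id, transcript in sessions:
        by_group.setdefault(group_id, []).append(
            _session_half_scores(transcript, lexicon, usage_score)
        )
    rows = []
    for group_id in sorted(by_group):
        usage = np.array([u for u, _ in by_group[group_id]], dtype=np.float64)
        embed = np.array([e for _, e in by_group[group_id]], dtype=np.float64)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN halves
            u1, u2 = float(np.nanmean(usage[:, 0])), float(np.nanmean(usage[:, 1]))
            e1 = float(np.nanmean(embed[:, 0])) if lexicon is not None else None
            e2 = float(np.nanmean(embed[:, 1])) if lexicon is not None else None
        rows.append(
            LinguisticGroupRow(
                group_id=group_id,
                usage_half1=u1,
                usage_half2=u2,
                embedding_half1=e1,
                embedding_half2=e2,
                n_sessions=len(by_group[group_id]),
            )
        )
    return rows


def write_linguistic_report(rows: Sequence[LinguisticGroupRow], path: str | Path) -> None:
    """Write the half-wise similarity table; missing embedding cells are em dashes."""
    def fmt(x: Optional[float]) -> str:
        return "—" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.4f}"

    lines = ["group\tusage_half1\tusage_half2\tembedding_half1\tembedding_half2\tn_sessions"]
    for r in rows:
        lines.append(
            f"{r.group_id}\t{fmt(r.usage_half1)}\t{fmt(r.usage_half2)}"
            f"\t{fmt(r.embedding_half1)}\t{fmt(r.embedding_half2)}\t{r.n_sessions}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
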