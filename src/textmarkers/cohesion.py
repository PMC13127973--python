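"""Sequential semantic cohesion from word embeddings.

A sentence is represented as the mean vector of its in-vocabulary content
words (stopwords and punctuation removed); a document's cohesion is the
mean cosine similarity between embeddings of adjacent sentences. Higher
values mean consecutive sentences stay on topic — more coherent discourse.

The scramble test validates the metric: randomizing sentence order within a
document (word order inside sentences untouched) should lower cohesion for
real, topically structured text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import stats as _stats
from .parsed_text import ParsedDocument, Sentence

logger = logging.getLogger(__name__)

_PUNCT_TAGS = frozenset({"PUNCT", "SYM"})


@dataclass(frozen=True)
class EmbeddingTable:
    dim: int
    vectors: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.dim <= 0:
            raise ValueError("embedding dimension must be positive")
        for token, vec in self.vectors.items():
            if token != token.lower():
                raise ValueError(f"embedding token not lowercase: {token!r}")
            if vec.shape != (self.dim,):
                raise ValueError(f"vector for {token!r} has wrong dimension")

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)


@dataclass(frozen=True)
class CohesionScore:
    doc_id: str
    value: float  # NaN when n_pairs == 0
    n_pairs: int
    n_sentences_embedded: int


def load_embeddings(path: str | Path) -> EmbeddingTable:
    """Load word vectors in the whitespace-delimited text format.

    First line: vocabulary size and dimension; each following line a token
    followed by ``dim`` reals. Duplicate tokens keep the first occurrence
    (warning); a line with the wrong number of components is an error naming
    the line.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}:1: expected '<count> <dim>' header")
        dim = int(header[1])
        vectors: dict[str, np.ndarray] = {}
        n_dupes = 0
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            if len(parts) != dim + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected token + {dim} components, got {len(parts) - 1}"
                )
            token = parts[0].lower()
            if token in vectors:
                n_dupes += 1
                continue
            vectors[token] = np.array(parts[1:], dtype=float)
    if n_dupes:
        logger.warning("%s: %d duplicate tokens ignored (first occurrence kept)", path, n_dupes)
    return EmbeddingTable(dim=dim, vectors=vectors)


def write_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(table.vectors)} {table.dim}\n")
        for token in sorted(table.vectors):
            comps = " ".join(f"{v:.6f}" for v in table.vectors[token])
            fh.write(f"{token} {comps}\n")


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Load a stopword file: one token per line, ``#`` comments allowed."""
    path = Path(path)
    words = set()
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                words.add(line.lower())
    return frozenset(words)


def sentence_vector(
    sentence: Sentence,
    emb: EmbeddingTable,
    stopwords: frozenset[str],
    use_lemma: bool = False,
) -> np.ndarray | None:
    """Mean embedding of a sentence's content words, or None if it has none.

    Tokens are dropped when the lowercased surface is a stopword, the UPOS
    is PUNCT/SYM, or the token is out of vocabulary. Lookup keys on the
    surface form by default (``use_lemma=True`` switches to the lemma).
    """
    vecs = []
    for tok in sentence:
        if tok.upos in _PUNCT_TAGS or tok.surface in stopwords:
            continue
        key = tok.lemma if use_lemma else tok.surface
        vec = emb.vectors.get(key)
        if vec is not None:
            vecs.append(vec)
    if not vecs:
        return None
    return np.mean(vecs, axis=0)


def _cosine(v: np.ndarray, w: np.ndarray) -> float | None:
    nv, nw = np.linalg.norm(v), np.linalg.norm(w)
    if nv == 0 or nw == 0:
        return None
    return float(np.dot(v, w) / (nv * nw))


def sequential_cohesion(
    doc: ParsedDocument,
    emb: EmbeddingTable,
    stopwords: frozenset[str],
    use_lemma: bool = False,
) -> CohesionScore:
    """Mean cosine similarity between adjacent sentence embeddings.

    Pairs where either sentence has no embeddable content word (or a
    zero-norm vector) are dropped; the score is NaN when no usable pair
    remains — documents with fewer than two embedded sentences carry no
    sequential-cohesion information.
    """
    vectors = [sentence_vector(s, emb, stopwords, use_lemma) for s in doc.sentences]
    embedded = [v for v in vectors if v is not None]
    cosines = []
    for left, right in zip(vectors, vectors[1:]):
        if left is None or right is None:
            continue
        c = _cosine(left, right)
        if c is None:
            logger.warning("document %s: zero-norm sentence vector; pair dropped", doc.doc_id)
            continue
        cosines.append(c)
    return CohesionScore(
        doc_id=doc.doc_id,
        value=float(np.mean(cosines)) if cosines else float("nan"),
        n_pairs=len(cosines),
        n_sentences_embedded=len(embedded),
    )


# ---------------------------------------------------------------------------
# Scramble validation
# ---------------------------------------------------------------------------

def scramble_sentences(doc: ParsedDocument, rng: np.random.Generator | int) -> ParsedDocument:
    """Randomize sentence order, preserving word order within sentences.

    The permutation is uniform over non-identity permutations (redrawn until
    it differs from the identity), so scrambling always changes the order.
    Deterministic for a given seed or generator state.
    """
    if len(doc.sentences) < 2:
        raise ValueError(f"document {doc.doc_id!r} has < 2 sentences; cannot scramble")
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    n = len(doc.sentences)
    perm = rng.permutation(n)
    while np.array_equal(perm, np.arange(n)):
        perm = rng.permutation(n)
    return ParsedDocument(
        doc_id=doc.doc_id,
        sentences=tuple(doc.sentences[i] for i in perm),
    )


@dataclass(frozen=True)
class ScrambleReport:
    ttest: "_stats.TTestResult"
    original: np.ndarray  # per-document cohesion, original order
    scrambled: np.ndarray  # per-document cohesion, scrambled order
    doc_ids: tuple[str, ...]
    n_used: int


def scramble_validation(
    corpus: Sequence[ParsedDocument],
    emb: EmbeddingTable,
    stopwords: frozenset[str],
    min_sentences: int = 20,
    seed: int | np.random.Generator = 0,
    paired: bool = False,
) -> ScrambleReport:
    """Compare cohesion of original documents against scrambled counterparts.

    The corpus is filtered to documents with at least ``min_sentences``
    sentences; each survivor is scrambled once and both versions scored.
    The default comparison is an unpaired two-sample Welch t-test with
    Cohen's d (``paired=True`` switches to a paired t-test). A positive t
    means original documents cohere more than scrambled ones.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    usable = [d for d in corpus if len(d.sentences) >= min_sentences]
    if len(usable) < 2:
        raise ValueError(
            f"need >= 2 documents with >= {min_sentences} sentences, found {len(usable)}"
        )
    orig_vals, scram_vals, ids = [], [], []
    for doc in usable:
        orig = sequential_cohesion(doc, emb, stopwords)
        scram = sequential_cohesion(scramble_sentences(doc, rng), emb, stopwords)
        if np.isnan(orig.value) or np.isnan(scram.value):
            logger.warning("document %s dropped from scramble validation (no usable pairs)", doc.doc_id)
            continue
        orig_vals.append(orig.value)
        scram_vals.append(scram.value)
        ids.append(doc.doc_id)
    if len(ids) < 2:
        raise ValueError("fewer than 2 documents with defined cohesion in both arms")
    x = np.asarray(orig_vals)
    y = np.asarray(scram_vals)
    ttest = _stats.paired_t(x, y) if paired else _stats.welch_t(x, y)
    return ScrambleReport(ttest=ttest, original=x, scrambled=y, doc_ids=tuple(ids), n_used=len(ids))


def write_scramble_report(report: ScrambleReport, path: str | Path) -> None:
    """Per-document original/scrambled cohesion values plus a summary block."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# t={report.ttest.t:.4f}\tdf={report.ttest.df:.2f}"
                 f"\tp={report.ttest.p:.4g}\td={report.ttest.d:.4f}\tn={report.n_used}\n")
        fh.write("doc_id\toriginal\tscrambled\n")
        for doc_id, o, s in zip(report.doc_ids, report.original, report.scrambled):
            fh.write(f"{doc_id}\t{o:.6f}\t{s:.6f}\n")
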