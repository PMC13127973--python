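"""Lexical sophistication, megalalia, and syntactic complexity.

Three families of per-document scores:

* **Lexical sophistication** — the mean of age-of-acquisition-like norm
  ratings mapped onto a document's lemmas. Higher means a more sophisticated
  vocabulary on average.
* **Megalalia** — the Gini coefficient of the within-document distribution
  of those same ratings. Zero means perfectly uniform sophistication; values
  toward one mean a few highly sophisticated words stand out against an
  otherwise simple text.
* **Syntactic sophistication** — mean sentence length (tokens), mean clauses
  per sentence (verbs including auxiliaries as clause proxies), and mean
  maximal dependency distance (per sentence, the largest absolute positional
  difference between a token and its head), combined into a single composite
  by PCA on the correlation matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .parsed_text import ROOT, ParsedDocument

logger = logging.getLogger(__name__)

_EXCLUDED_TAGS = frozenset({"PUNCT", "SYM", "NUM"})
_CLAUSE_TAGS = frozenset({"VERB", "AUX"})


# ---------------------------------------------------------------------------
# Norm table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormTable:
    """Lemma → sophistication rating, with the scale bounds the table declares."""

    ratings: Mapping[str, float]
    scale_min: float
    scale_max: float

    def __post_init__(self) -> None:
        if self.scale_min >= self.scale_max:
            raise ValueError("scale_min must be < scale_max")
        if self.scale_min < 0:
            raise ValueError("megalalia requires non-negative ratings; scale_min < 0")
        for lemma, r in self.ratings.items():
            if lemma != lemma.lower():
                raise ValueError(f"norm-table lemma not lowercase: {lemma!r}")
            if not self.scale_min <= r <= self.scale_max:
                raise ValueError(f"rating {r} for {lemma!r} outside declared bounds")

    def __contains__(self, lemma: str) -> bool:
        return lemma in self.ratings

    def __len__(self) -> int:
        return len(self.ratings)


def load_norms(path: str | Path) -> NormTable:
    """Load a norm table.

    Format: a first comment line ``# scale <min> <max>`` declaring the
    bounds, a ``lemma<TAB>rating`` header, then one entry per line.
    Duplicate lemmas are an error.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '# scale <min> <max>' declaration line")
        parts = header.lstrip("#").split()
        if len(parts) != 3 or parts[0] != "scale":
            raise ValueError(f"{path}: malformed scale declaration: {header!r}")
        scale_min, scale_max = float(parts[1]), float(parts[2])
        column_line = fh.readline()
        ratings: dict[str, float] = {}
        for lineno, line in enumerate(fh, start=3):
            line = line.strip()
            if not line:
                continue
            lemma, rating = line.split("\t")
            lemma = lemma.lower()
            if lemma in ratings:
                raise ValueError(f"{path}:{lineno}: duplicate lemma {lemma!r}")
            ratings[lemma] = float(rating)
    del column_line
    return NormTable(ratings=ratings, scale_min=scale_min, scale_max=scale_max)


def write_norms(table: NormTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# scale {table.scale_min:g} {table.scale_max:g}\n")
        fh.write("lemma\trating\n")
        for lemma in sorted(table.ratings):
            fh.write(f"{lemma}\t{table.ratings[lemma]:.6g}\n")


# ---------------------------------------------------------------------------
# Lexical sophistication and megalalia
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LexicalResult:
    doc_id: str
    lexical_mean: float  # NaN when no lemma mapped
    mapped_values: tuple[float, ...]
    coverage: float  # mapped / eligible (non-PUNCT/SYM/NUM) tokens


def lexical_sophistication(doc: ParsedDocument, norms: NormTable) -> LexicalResult:
    """Map norm ratings onto a document's lemmas and average them.

    Punctuation, symbols and numbers are excluded; lemmas absent from the
    table are skipped. Coverage (mapped / eligible tokens) is always
    reported so low-coverage documents can be screened downstream.
    """
    mapped: list[float] = []
    eligible = 0
    for tok in doc.iter_tokens():
        if tok.upos in _EXCLUDED_TAGS:
            continue
        eligible += 1
        rating = norms.ratings.get(tok.lemma)
        if rating is not None:
            mapped.append(rating)
    if not mapped:
        logger.warning("document %s: no lemma mapped to the norm table", doc.doc_id)
        return LexicalResult(doc.doc_id, float("nan"), (), 0.0)
    return LexicalResult(
        doc_id=doc.doc_id,
        lexical_mean=float(np.mean(mapped)),
        mapped_values=tuple(mapped),
        coverage=len(mapped) / eligible if eligible else 0.0,
    )


def gini(values: Sequence[float]) -> float:
    """Gini coefficient, mean-absolute-difference form.

    G = sum_ij |x_i - x_j| / (2 n^2 mean(x)), computed with the equivalent
    O(n log n) sorted formula. G lies in [0, 1 - 1/n]; 0 iff all values are
    equal; invariant under multiplication by a positive constant.

    Raises ``ValueError`` for fewer than two values, any negative value, or
    an all-zero vector.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError(f"gini requires at least 2 values, got {n}")
    if np.any(x < 0):
        raise ValueError("gini requires non-negative values")
    total = x.sum()
    if total == 0:
        raise ValueError("gini undefined for an all-zero vector")
    xs = np.sort(x)
    # sum_ij |xi - xj| = 2 * sum_k (2k - n - 1) * x_(k), k = 1..n
    ranks = np.arange(1, n + 1)
    return float(((2 * ranks - n - 1) * xs).sum() / (n * total))


def megalalia(doc: ParsedDocument, norms: NormTable) -> float:
    """Gini coefficient of the document's mapped sophistication ratings.

    Quantifies disproportionate use of sophisticated vocabulary: 0 for a
    uniformly simple (or uniformly sophisticated) text, larger when a few
    high-norm words contrast with otherwise simple vocabulary.
    """
    result = lexical_sophistication(doc, norms)
    return gini(result.mapped_values)


# ---------------------------------------------------------------------------
# Syntactic metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntacticMetrics:
    doc_id: str
    mean_sentence_length: float
    mean_clauses: float
    mean_max_dep_distance: float
    pc1: float | None = None


def syntactic_metrics(doc: ParsedDocument, root_distance_zero: bool = True) -> SyntacticMetrics:
    """Per-document means of the three raw syntactic-complexity metrics.

    * sentence length = tokens per sentence;
    * clauses = tokens tagged VERB or AUX per sentence;
    * dependency distance = per sentence, max over tokens of |i - head(i)|.

    ROOT tokens contribute distance 0 by default; ``root_distance_zero=False``
    excludes them from the maximum instead (a sentence of only a ROOT token
    then scores 0).
    """
    if not doc.sentences:
        raise ValueError(f"document {doc.doc_id!r} has no sentences")
    lengths, clauses, max_dists = [], [], []
    for sentence in doc.sentences:
        lengths.append(len(sentence))
        clauses.append(sum(1 for t in sentence if t.upos in _CLAUSE_TAGS))
        dists = [
            0 if t.head == ROOT else abs(t.index - t.head)
            for t in sentence
            if root_distance_zero or t.head != ROOT
        ]
        max_dists.append(max(dists) if dists else 0)
    return SyntacticMetrics(
        doc_id=doc.doc_id,
        mean_sentence_length=float(np.mean(lengths)),
        mean_clauses=float(np.mean(clauses)),
        mean_max_dep_distance=float(np.mean(max_dists)),
    )


# ---------------------------------------------------------------------------
# PCA composite
# ---------------------------------------------------------------------------

_METRIC_FIELDS = ("mean_sentence_length", "mean_clauses", "mean_max_dep_distance")


@dataclass(frozen=True)
class PcaModel:
    """First principal component of the z-scored syntactic metrics.

    The sign of an eigenvector is arbitrary, so the component is oriented
    so that the loading on mean sentence length is positive — higher pc1
    always means more complex syntax.
    """

    feature_means: tuple[float, float, float]
    feature_sds: tuple[float, float, float]
    loadings: tuple[float, float, float]
    explained_variance_ratio: float
    first_eigenvalue: float
    orientation: int

    def __post_init__(self) -> None:
        if not math.isclose(float(np.linalg.norm(self.loadings)), 1.0, abs_tol=1e-9):
            raise ValueError("PC1 loadings must be unit-norm")
        if not 0.0 <= self.explained_variance_ratio <= 1.0 + 1e-12:
            raise ValueError("explained_variance_ratio outside [0, 1]")


def _metrics_matrix(metrics: Sequence[SyntacticMetrics]) -> np.ndarray:
    return np.array([[getattr(m, f) for f in _METRIC_FIELDS] for m in metrics], dtype=float)


def fit_syntactic_pca(metrics: Sequence[SyntacticMetrics]) -> PcaModel:
    """Fit the composite: correlation-matrix PCA over the three raw metrics.

    The metrics have different units, so each is z-standardized (ddof=1)
    before the fit. Requires at least 3 documents and non-zero variance in
    every metric.
    """
    if len(metrics) < 3:
        raise ValueError("PCA requires at least 3 documents")
    X = _metrics_matrix(metrics)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    for name, sd in zip(_METRIC_FIELDS, sds):
        if sd == 0:
            raise ValueError(f"metric {name!r} has zero variance; PCA composite undefined")
    Z = (X - means) / sds
    pca = PCA(n_components=min(3, len(metrics) - 1)).fit(Z)
    loadings = pca.components_[0]
    orientation = 1 if loadings[0] > 0 else -1
    loadings = orientation * loadings
    return PcaModel(
        feature_means=tuple(means),
        feature_sds=tuple(sds),
        loadings=tuple(loadings),
        explained_variance_ratio=float(pca.explained_variance_ratio_[0]),
        first_eigenvalue=float(pca.explained_variance_[0]),
        orientation=orientation,
    )


def score_pc1(model: PcaModel, metrics: Sequence[SyntacticMetrics]) -> np.ndarray:
    """Oriented PC1 projections of (new or fitting) documents."""
    X = _metrics_matrix(metrics)
    Z = (X - np.asarray(model.feature_means)) / np.asarray(model.feature_sds)
    return Z @ np.asarray(model.loadings)


def save_pca(model: PcaModel, path: str | Path) -> None:
    """Serialize a fitted composite to a plain-text key=value file."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for key in ("feature_means", "feature_sds", "loadings"):
            fh.write(f"{key}=" + ",".join(repr(float(v)) for v in getattr(model, key)) + "\n")
        fh.write(f"explained_variance_ratio={float(model.explained_variance_ratio)!r}\n")
        fh.write(f"first_eigenvalue={float(model.first_eigenvalue)!r}\n")
        fh.write(f"orientation={model.orientation}\n")


def load_pca(path: str | Path) -> PcaModel:
    path = Path(path)
    kv: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            key, value = line.rstrip("\n").split("=", 1)
            kv[key] = value
    triple = lambda s: tuple(float(v) for v in s.split(","))
    return PcaModel(
        feature_means=triple(kv["feature_means"]),
        feature_sds=triple(kv["feature_sds"]),
        loadings=triple(kv["loadings"]),
        explained_variance_ratio=float(kv["explained_variance_ratio"]),
        first_eigenvalue=float(kv["first_eigenvalue"]),
        orientation=int(kv["orientation"]),
    )
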