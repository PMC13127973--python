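"""Synthetic corpus generator with planted statistical structure.

Generates everything the pipeline consumes — participants with Likert
responses, dependency-parsed documents, a norm table, a lexicon, word
embeddings and a stopword list — with known, configurable effects:

* a trait→lexicon link: each participant's probability of producing a
  dictionary lemma is a logistic function of their latent conspiracism, with
  the slope calibrated by root search so the realized corpus correlation
  between measured conspiracism and the lexicon match ratio approaches a
  target value;
* trait-linked insertion of high-norm ("sophisticated") words, which drives
  megalalia;
* topic-blocked sentences whose words cluster around topic centroids in
  embedding space, so adjacent sentences are more similar than scrambled
  ones;
* controllable sentence lengths, verb rates and dependency-head distances,
  including a labeled high- vs low-complexity contrast corpus.

Lemmas are arbitrary strings: the generator emulates the statistical
structure the analysis assumes, not natural language. All randomness flows
from one seeded ``numpy`` generator, so output (including written CoNLL-U)
is byte-identical across runs with the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm as _norm

from .cohesion import EmbeddingTable, write_embeddings
from .parsed_text import ROOT, Lexicon, ParsedDocument, Sentence, Token, write_conllu
from .scales import ScaleSpec
from .sophistication import NormTable, write_norms

# Two trait instruments mirroring the study design: an 11-item mentality
# scale on 1-7 and a 15-item generic-beliefs scale on 1-5.
CMS_SPEC = ScaleSpec(name="CMS", n_items=11, likert_min=1, likert_max=7)
GCB_SPEC = ScaleSpec(name="GCB", n_items=15, likert_min=1, likert_max=5)
SCALE_SPECS = {"CMS": CMS_SPEC, "GCB": GCB_SPEC}

_FUNCTION_WORDS = ("il", "di", "e", "che", "la", "un", "per", "non", "con", "su")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a generated corpus.

    Defaults mirror the emulated study: 385 participants (one essay each,
    285 scored on the 1–7 mentality scale and 100 on the 1–5 generic-beliefs
    scale), a trait–lexicon correlation of .19, and essays of a handful to a
    few dozen sentences.
    """

    n_participants: int = 385
    trait_mean: float = 0.0
    trait_sd: float = 1.0
    item_loading: float = 0.8  # corr of each Likert item's latent with the trait
    lexicon_effect_r: float = 0.19
    base_lexicon_rate: float = 0.10  # lexicon-lemma probability at the mean trait
    n_common: int = 400
    n_verbs: int = 80
    n_sophisticated: int = 100
    n_lexicon: int = 50
    common_norm_range: tuple[float, float] = (1.5, 4.5)
    soph_norm_range: tuple[float, float] = (7.0, 9.5)
    norm_bounds: tuple[float, float] = (1.0, 10.0)
    sentences_per_doc: tuple[int, int] = (5, 15)
    tokens_per_sentence: tuple[int, int] = (6, 14)
    verb_rate: float = 0.20
    function_rate: float = 0.25
    num_rate: float = 0.02
    long_head_prob: float = 0.25
    n_topics: int = 8
    embedding_dim: int = 50
    embedding_noise: float = 0.3
    topic_block_range: tuple[int, int] = (2, 5)
    megalalia_spike_base: float = 0.05
    megalalia_spike_slope: float = 0.10  # added spike probability per unit trait01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_lexicon_rate", "verb_rate", "function_rate", "num_rate",
                     "long_head_prob", "megalalia_spike_base", "megalalia_spike_slope"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("sentences_per_doc", "tokens_per_sentence", "topic_block_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or lo > hi:
                raise ValueError(f"{name} must satisfy 1 <= min <= max")
        if abs(self.lexicon_effect_r) > 0.95:
            raise ValueError("lexicon_effect_r must be in [-0.95, 0.95]")
        if self.n_lexicon > self.n_common + self.n_sophisticated + self.n_lexicon:
            raise ValueError("lexicon larger than vocabulary")
        if self.n_lexicon < 1 or self.n_common < self.n_topics or self.n_verbs < self.n_topics:
            raise ValueError(
                "need >= 1 lexicon lemma and >= n_topics common/verb lemmas "
                f"(n_common={self.n_common}, n_verbs={self.n_verbs}, n_topics={self.n_topics})"
            )
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")


@dataclass(frozen=True)
class SyntheticCorpus:
    participants: pd.DataFrame
    docs: tuple[ParsedDocument, ...]
    norms: NormTable
    lexicon: Lexicon
    embeddings: EmbeddingTable
    stopwords: frozenset[str]
    config: SyntheticConfig
    scale_specs: dict = field(default_factory=lambda: dict(SCALE_SPECS))


# ---------------------------------------------------------------------------
# Participants
# ---------------------------------------------------------------------------

def _likert_items(rng: np.random.Generator, theta: float, spec: ScaleSpec, loading: float) -> list[int]:
    span = spec.likert_max - spec.likert_min + 1
    items = []
    for _ in range(spec.n_items):
        latent = loading * theta + np.sqrt(1 - loading**2) * rng.normal()
        level = spec.likert_min + int(np.floor(_norm.cdf(latent) * span))
        items.append(min(level, spec.likert_max))
    return items


def _generate_participants(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_participants
    theta = config.trait_mean + config.trait_sd * rng.normal(size=n)
    n_study1 = int(round(n * 285 / 385))
    rows = []
    max_items = max(s.n_items for s in SCALE_SPECS.values())
    for i in range(n):
        study = 1 if i < n_study1 else 2
        spec = CMS_SPEC if study == 1 else GCB_SPEC
        items = _likert_items(rng, theta[i], spec, config.item_loading)
        rescaled = [(x - spec.likert_min) / (spec.likert_max - spec.likert_min) for x in items]
        edu_latent = -0.25 * theta[i] + np.sqrt(1 - 0.25**2) * rng.normal()
        llm_latent = 0.08 * theta[i] + np.sqrt(1 - 0.08**2) * rng.normal()
        row = {
            "pid": f"p{i:04d}",
            "doc_id": f"doc{i:04d}",
            "study": study,
            "scale": spec.name,
            "age": int(rng.integers(18, 36)),
            "education": min(1 + int(np.floor(_norm.cdf(edu_latent) * 5)), 5),
            "llm_narrative_score": float(_norm.cdf(llm_latent)),
            "latent_trait": float(theta[i]),
            "conspiracism": float(np.mean(rescaled)),
        }
        for j in range(1, max_items + 1):
            row[f"item_{j}"] = items[j - 1] if j <= spec.n_items else None
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Vocab:
    topic_nouns: tuple[tuple[str, ...], ...]
    topic_verbs: tuple[tuple[str, ...], ...]
    soph_words: tuple[str, ...]
    lexicon_words: tuple[str, ...]
    norms: NormTable
    embeddings: EmbeddingTable


def _make_vocab(config: SyntheticConfig, rng: np.random.Generator) -> _Vocab:
    nouns = tuple(f"noun{i:04d}" for i in range(config.n_common))
    verbs = tuple(f"verb{i:03d}" for i in range(config.n_verbs))
    soph = tuple(f"soph{i:03d}" for i in range(config.n_sophisticated))
    lex = tuple(f"lex{i:03d}" for i in range(config.n_lexicon))
    topic_nouns = tuple(tuple(nouns[t::config.n_topics]) for t in range(config.n_topics))
    topic_verbs = tuple(tuple(verbs[t::config.n_topics]) for t in range(config.n_topics))

    lo, hi = config.common_norm_range
    slo, shi = config.soph_norm_range
    ratings: dict[str, float] = {}
    for w in (*nouns, *verbs, *lex, *_FUNCTION_WORDS):
        ratings[w] = float(np.round(rng.uniform(lo, hi), 4))
    for w in soph:
        ratings[w] = float(np.round(rng.uniform(slo, shi), 4))
    norms = NormTable(ratings=ratings, scale_min=config.norm_bounds[0], scale_max=config.norm_bounds[1])

    dim = config.embedding_dim
    centroids = rng.normal(size=(config.n_topics, dim))
    vectors: dict[str, np.ndarray] = {}
    for t in range(config.n_topics):
        for w in (*topic_nouns[t], *topic_verbs[t]):
            vectors[w] = centroids[t] + rng.normal(0.0, config.embedding_noise, dim)
    for w in (*soph, *lex, *_FUNCTION_WORDS):
        vectors[w] = rng.normal(size=dim)
    embeddings = EmbeddingTable(dim=dim, vectors={k: np.round(v, 6) for k, v in vectors.items()})
    return _Vocab(
        topic_nouns=topic_nouns,
        topic_verbs=topic_verbs,
        soph_words=soph,
        lexicon_words=lex,
        norms=norms,
        embeddings=embeddings,
    )


# ---------------------------------------------------------------------------
# Document skeletons (structure decided before lexical content, so the
# trait->lexicon slope can be calibrated from realized token counts)
# ---------------------------------------------------------------------------

_CAT_FUNC, _CAT_NUM, _CAT_VERB, _CAT_NOUN, _CAT_END = "F", "N", "V", "C", "E"


@dataclass
class _SentencePlan:
    topic: int
    slots: list[str]  # category codes, last is _CAT_END
    end_mark: str  # ".", "?" or "!"


def _plan_sentence(
    rng: np.random.Generator,
    topic: int,
    n_tokens: int,
    verb_rate: float,
    function_rate: float,
    num_rate: float,
) -> _SentencePlan:
    slots = []
    for _ in range(max(n_tokens - 1, 1)):
        u = rng.random()
        if u < function_rate:
            slots.append(_CAT_FUNC)
        elif u < function_rate + num_rate:
            slots.append(_CAT_NUM)
        elif u < function_rate + num_rate + verb_rate:
            slots.append(_CAT_VERB)
        else:
            slots.append(_CAT_NOUN)
    slots.append(_CAT_END)
    u = rng.random()
    end_mark = "?" if u < 0.04 else ("!" if u < 0.07 else ".")
    return _SentencePlan(topic=topic, slots=slots, end_mark=end_mark)


def _plan_document(rng: np.random.Generator, config: SyntheticConfig) -> list[_SentencePlan]:
    n_sentences = int(rng.integers(config.sentences_per_doc[0], config.sentences_per_doc[1] + 1))
    plans: list[_SentencePlan] = []
    topic = int(rng.integers(config.n_topics))
    remaining_in_block = int(rng.integers(config.topic_block_range[0], config.topic_block_range[1] + 1))
    for _ in range(n_sentences):
        if remaining_in_block == 0:
            if config.n_topics > 1:
                new = int(rng.integers(config.n_topics - 1))
                topic = new if new < topic else new + 1
            remaining_in_block = int(
                rng.integers(config.topic_block_range[0], config.topic_block_range[1] + 1)
            )
        n_tokens = int(rng.integers(config.tokens_per_sentence[0], config.tokens_per_sentence[1] + 1))
        plans.append(
            _plan_sentence(rng, topic, n_tokens, config.verb_rate, config.function_rate, config.num_rate)
        )
        remaining_in_block -= 1
    return plans


def _assign_heads(rng: np.random.Generator, slots: list[str], long_head_prob: float) -> list[int]:
    """Head indices realizing the configured distance profile.

    The first verb (or token 0) is the sentence root; the final punctuation
    attaches to the root; every other token attaches to an adjacent
    neighbour (short) or to the root (potentially long) with the configured
    probability. Exactly one ROOT per sentence by construction.
    """
    n = len(slots)
    verb_positions = [i for i, c in enumerate(slots) if c == _CAT_VERB]
    root = verb_positions[0] if verb_positions else 0
    heads = []
    for i in range(n):
        if i == root:
            heads.append(ROOT)
        elif slots[i] == _CAT_END:
            heads.append(root)
        elif rng.random() < long_head_prob and root != i:
            heads.append(root)
        else:
            h = i - 1 if i > 0 else i + 1
            if h == i:  # single-token sentence already handled by root
                h = root
            heads.append(h)
    return heads


def _skeleton_counts(plans: list[_SentencePlan]) -> tuple[int, int]:
    """(noun slots, processed-token denominator) for one document skeleton.

    Processed tokens after lexicon preprocessing: everything except NUM and
    final punctuation, plus retained "?"/"!" marks.
    """
    k = sum(1 for p in plans for c in p.slots if c == _CAT_NOUN)
    d = sum(
        1 for p in plans for c in p.slots if c in (_CAT_FUNC, _CAT_VERB, _CAT_NOUN)
    ) + sum(1 for p in plans if p.end_mark in ("?", "!"))
    return k, d


# ---------------------------------------------------------------------------
# Trait -> lexicon-rate calibration
# ---------------------------------------------------------------------------

def _calibrate_lexicon_slope(
    target_r: float,
    theta: np.ndarray,
    composite: np.ndarray,
    noun_counts: np.ndarray,
    denominators: np.ndarray,
    base_rate: float,
) -> float:
    """Slope b of p(trait) = expit(logit(base) + b*theta) hitting target_r.

    The realized correlation between the measured composite and the lexicon
    match ratio is predicted analytically from the already-drawn traits,
    composites and skeleton token counts — expected ratios carry the signal,
    binomial thinning adds noise — and b is found by 1-D root search on that
    prediction. Deterministic; no simulation involved.
    """
    if target_r == 0:
        return 0.0
    a = logit(base_rate)
    c_var = np.var(composite, ddof=1)
    frac = noun_counts / denominators

    def predicted(b: float) -> float:
        p = expit(a + b * theta)
        expected_ratio = frac * p
        noise = np.mean(noun_counts * p * (1 - p) / denominators**2)
        cov = np.cov(composite, expected_ratio, ddof=1)[0, 1]
        return cov / np.sqrt(c_var * (np.var(expected_ratio, ddof=1) + noise))

    lo, hi = (0.0, 50.0) if target_r > 0 else (-50.0, 0.0)
    edge = predicted(hi if target_r > 0 else lo)
    if abs(edge) < abs(target_r):
        raise ValueError(
            f"target correlation {target_r} infeasible under these conditions "
            f"(attenuation ceiling ~{edge:.3f}); increase document length or item loading"
        )
    return float(brentq(lambda b: predicted(b) - target_r, lo, hi, xtol=1e-6))


# ---------------------------------------------------------------------------
# Corpus assembly
# ---------------------------------------------------------------------------

def _realize_document(
    rng: np.random.Generator,
    doc_id: str,
    plans: list[_SentencePlan],
    vocab: _Vocab,
    p_lexicon: float,
    p_spike: float,
    long_head_prob: float,
) -> ParsedDocument:
    sentences = []
    for plan in plans:
        heads = _assign_heads(rng, plan.slots, long_head_prob)
        tokens = []
        for i, cat in enumerate(plan.slots):
            if cat == _CAT_END:
                surface = plan.end_mark
                lemma, upos = surface, "PUNCT"
            elif cat == _CAT_FUNC:
                lemma = _FUNCTION_WORDS[int(rng.integers(len(_FUNCTION_WORDS)))]
                surface, upos = lemma, "DET"
            elif cat == _CAT_NUM:
                lemma = str(int(rng.integers(0, 1000)))
                surface, upos = lemma, "NUM"
            elif cat == _CAT_VERB:
                group = vocab.topic_verbs[plan.topic]
                lemma = group[int(rng.integers(len(group)))]
                surface = lemma
                upos = "AUX" if rng.random() < 0.3 else "VERB"
            else:  # content noun: lexicon draw, then sophistication spike
                if rng.random() < p_lexicon:
                    lemma = vocab.lexicon_words[int(rng.integers(len(vocab.lexicon_words)))]
                elif rng.random() < p_spike:
                    lemma = vocab.soph_words[int(rng.integers(len(vocab.soph_words)))]
                else:
                    group = vocab.topic_nouns[plan.topic]
                    lemma = group[int(rng.integers(len(group)))]
                surface, upos = lemma, "NOUN"
            tokens.append(Token(index=i, surface=surface, lemma=lemma, upos=upos, head=heads[i]))
        sentences.append(Sentence(tokens=tuple(tokens)))
    return ParsedDocument(doc_id=doc_id, sentences=tuple(sentences))


def generate_corpus(config: SyntheticConfig) -> SyntheticCorpus:
    """Generate a full synthetic study: participants, documents and tables.

    One document per participant. Per-participant lexicon probability is a
    logistic function of the latent trait with slope calibrated to the
    target correlation; the sophisticated-word spike probability rises
    linearly with the rescaled (0–1) trait. Deterministic under
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    participants = _generate_participants(config, rng)
    vocab = _make_vocab(config, rng)

    all_plans = [_plan_document(rng, config) for _ in range(config.n_participants)]
    counts = np.array([_skeleton_counts(p) for p in all_plans], dtype=float)
    theta = participants["latent_trait"].to_numpy()
    composite = participants["conspiracism"].to_numpy()
    slope = _calibrate_lexicon_slope(
        config.lexicon_effect_r, theta, composite, counts[:, 0], counts[:, 1],
        config.base_lexicon_rate,
    )
    p_lexicon = expit(logit(config.base_lexicon_rate) + slope * theta)

    trait01 = _norm.cdf((theta - config.trait_mean) / config.trait_sd)
    p_spike = np.clip(
        config.megalalia_spike_base + config.megalalia_spike_slope * trait01, 0.0, 0.9
    )

    docs = tuple(
        _realize_document(
            rng,
            participants["doc_id"].iloc[i],
            all_plans[i],
            vocab,
            float(p_lexicon[i]),
            float(p_spike[i]),
            config.long_head_prob,
        )
        for i in range(config.n_participants)
    )
    return SyntheticCorpus(
        participants=participants,
        docs=docs,
        norms=vocab.norms,
        lexicon=Lexicon(entries=frozenset(vocab.lexicon_words), name="synthetic-lexicon"),
        embeddings=vocab.embeddings,
        stopwords=frozenset(_FUNCTION_WORDS),
        config=config,
    )


def generate_complexity_contrast(
    n_docs: int,
    seed: int,
    high: dict | None = None,
    low: dict | None = None,
) -> tuple[tuple[ParsedDocument, ...], tuple[str, ...]]:
    """Labeled corpus of explicitly high- vs low-syntactic-complexity documents.

    The high arm has long sentences, many verbs and long head distances; the
    low arm the opposite. Returns ``(docs, labels)`` with labels "high" /
    "low", half each, for downstream t-test validation of the syntactic
    composite.
    """
    if n_docs < 4:
        raise ValueError("need at least 4 documents (2 per arm)")
    high_cfg = {"tokens": (25, 40), "verb_rate": 0.35, "long_head_prob": 0.8, **(high or {})}
    low_cfg = {"tokens": (5, 9), "verb_rate": 0.08, "long_head_prob": 0.05, **(low or {})}
    rng = np.random.default_rng(seed)
    base = SyntheticConfig(n_participants=2, seed=seed)
    vocab = _make_vocab(base, rng)
    docs, labels = [], []
    n_high = n_docs // 2
    for i in range(n_docs):
        arm = high_cfg if i < n_high else low_cfg
        cfg = SyntheticConfig(
            n_participants=2,
            tokens_per_sentence=arm["tokens"],
            verb_rate=arm["verb_rate"],
            long_head_prob=arm["long_head_prob"],
            sentences_per_doc=(8, 15),
            seed=seed,
        )
        plans = _plan_document(rng, cfg)
        docs.append(
            _realize_document(
                rng, f"{'high' if i < n_high else 'low'}{i:03d}", plans, vocab,
                p_lexicon=base.base_lexicon_rate, p_spike=base.megalalia_spike_base,
                long_head_prob=arm["long_head_prob"],
            )
        )
        labels.append("high" if i < n_high else "low")
    return tuple(docs), tuple(labels)


# ---------------------------------------------------------------------------
# Emission of the on-disk input formats
# ---------------------------------------------------------------------------

def write_corpus(corpus: SyntheticCorpus, outdir: str | Path) -> dict[str, Path]:
    """Write every pipeline input format into a self-contained directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "corpus": outdir / "corpus.conllu",
        "lexicon": outdir / "lexicon.txt",
        "norms": outdir / "norms.tsv",
        "embeddings": outdir / "vectors.txt",
        "stopwords": outdir / "stopwords.txt",
        "participants": outdir / "participants.tsv",
    }
    write_conllu(corpus.docs, paths["corpus"])
    with paths["lexicon"].open("w", encoding="utf-8") as fh:
        fh.write(f"# {corpus.lexicon.name}\n")
        for entry in sorted(corpus.lexicon.entries):
            fh.write(entry + "\n")
    write_norms(corpus.norms, paths["norms"])
    write_embeddings(corpus.embeddings, paths["embeddings"])
    with paths["stopwords"].open("w", encoding="utf-8") as fh:
        for w in sorted(corpus.stopwords):
            fh.write(w + "\n")
    corpus.participants.to_csv(paths["participants"], sep="\t", index=False)
    return paths
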