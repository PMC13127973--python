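"""End-to-end orchestration: inputs directory → features table → statistics.

Sequences the per-document markers (lexicon ratio, lexical sophistication,
megalalia, syntactic metrics + PCA composite, sequential cohesion), joins
them to participant trait scores, and emits the exploratory correlation
matrix, the moderation models, and optionally the scramble-validation
report. Every option and seed is echoed into the run log; a malformed
document is skipped and reported, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats as _stats
from .cohesion import (EmbeddingTable, load_embeddings, load_stopwords,
                       scramble_validation, sequential_cohesion, write_scramble_report)
from .lexicon import score_lexicon
from .parsed_text import (CompoundRule, Lexicon, ParsedDocument, load_compound_rules,
                          load_lexicon, read_conllu)
from .scales import ScaleSpec, composite_conspiracism
from .sophistication import (NormTable, fit_syntactic_pca, lexical_sophistication,
                             load_norms, megalalia, save_pca, score_pc1,
                             syntactic_metrics)

logger = logging.getLogger(__name__)

#: Table-1-style variable order for the exploratory correlation matrix.
MATRIX_VARIABLES = (
    "conspiracism",
    "llm_narrative_score",
    "lexicon_ratio",
    "lexical_mean",
    "syntactic_pc1",
    "cohesion",
    "megalalia",
    "word_count",
    "education",
)

#: Moderation models: outcome ~ conspiracism x textual-quality moderator.
MODERATION_OUTCOMES = ("lexicon_ratio", "llm_narrative_score")
MODERATION_MODERATORS = ("syntactic_pc1", "lexical_mean", "cohesion")


@dataclass(frozen=True)
class RunConfig:
    corpus: Path
    lexicon: Path
    norms: Path
    embeddings: Path | None
    stopwords: Path | None
    participants: Path
    output_dir: Path
    compound_rules: Path | None = None
    min_sentences: int = 20
    coverage_threshold: float | None = None
    strict: bool = False
    scramble_validation: bool = False
    cohesion_enabled: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in ("corpus", "lexicon", "norms", "participants"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        if self.compound_rules is not None and not Path(self.compound_rules).exists():
            raise FileNotFoundError(f"compound_rules path does not exist: {self.compound_rules}")
        if self.cohesion_enabled:
            for name in ("embeddings", "stopwords"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(
                        f"cohesion enabled but {name} path missing or absent: {p}"
                    )


def compute_document_features(
    docs: Sequence[ParsedDocument],
    lexicon: Lexicon,
    norms: NormTable,
    embeddings: EmbeddingTable | None = None,
    stopwords: frozenset[str] = frozenset(),
    compound_rules: Sequence[CompoundRule] = (),
    coverage_threshold: float | None = None,
) -> pd.DataFrame:
    """One row of all per-document markers per document.

    Columns: doc_id, word_count, lexicon_ratio, lexical_mean, megalalia,
    coverage, the three raw syntactic metrics, syntactic_pc1, and (when an
    embedding table is given) cohesion with its pair count. Documents whose
    norm coverage falls below ``coverage_threshold`` get NaN lexical scores.
    A document that fails any stage is skipped with a logged error.
    """
    rows = []
    metrics_list = []
    for doc in docs:
        try:
            lex = score_lexicon(doc, lexicon, compound_rules)
            soph = lexical_sophistication(doc, norms)
            syn = syntactic_metrics(doc)
            if len(soph.mapped_values) >= 2:
                mega = megalalia(doc, norms)
            else:
                mega = float("nan")
            row = {
                "doc_id": doc.doc_id,
                "word_count": doc.n_tokens,
                "lexicon_ratio": lex.ratio,
                "lexical_mean": soph.lexical_mean,
                "megalalia": mega,
                "coverage": soph.coverage,
                "mean_sentence_length": syn.mean_sentence_length,
                "mean_clauses": syn.mean_clauses,
                "mean_max_dep_distance": syn.mean_max_dep_distance,
            }
            if coverage_threshold is not None and soph.coverage < coverage_threshold:
                row["lexical_mean"] = float("nan")
                row["megalalia"] = float("nan")
            if embeddings is not None:
                coh = sequential_cohesion(doc, embeddings, stopwords)
                row["cohesion"] = coh.value
                row["cohesion_pairs"] = coh.n_pairs
            rows.append(row)
            metrics_list.append(syn)
        except (ValueError, KeyError) as exc:
            logger.error("document %s skipped: %s", doc.doc_id, exc)
    features = pd.DataFrame(rows)
    if len(metrics_list) >= 3:
        model = fit_syntactic_pca(metrics_list)
        features["syntactic_pc1"] = score_pc1(model, metrics_list)
        features.attrs["pca_model"] = model
    else:
        features["syntactic_pc1"] = float("nan")
    return features


def score_participants(
    participants: pd.DataFrame,
    scale_specs: Mapping[str, ScaleSpec],
    strict: bool = False,
) -> pd.DataFrame:
    """Add/overwrite the composite ``conspiracism`` column from raw items.

    Each participant's ``scale`` column names the instrument they answered;
    item columns are ``item_1`` .. ``item_k`` with blanks for items beyond
    the instrument's length.
    """
    out = participants.copy()
    scores = []
    for _, row in out.iterrows():
        spec = scale_specs[row["scale"]]
        responses = {}
        for item in range(1, spec.n_items + 1):
            v = row.get(f"item_{item}")
            responses[item] = None if pd.isna(v) else int(v)
        scores.append(composite_conspiracism(responses, spec, strict=strict))
    out["conspiracism"] = scores
    return out


def join_features(
    features: pd.DataFrame,
    participants: pd.DataFrame,
    strict: bool = False,
) -> pd.DataFrame:
    """Join per-document features to participant records on doc_id.

    Unmatched rows on either side are logged (and fatal in strict mode); the
    joined table keeps complete cases only.
    """
    doc_ids = set(features["doc_id"])
    pid_ids = set(participants["doc_id"])
    orphan_docs = doc_ids - pid_ids
    orphan_pids = pid_ids - doc_ids
    for doc_id in sorted(orphan_docs):
        logger.warning("document %s has no participant record", doc_id)
    for doc_id in sorted(orphan_pids):
        logger.warning("participant with doc_id %s has no document", doc_id)
    if strict and (orphan_docs or orphan_pids):
        raise ValueError(
            f"join failure in strict mode: {len(orphan_docs)} documents and "
            f"{len(orphan_pids)} participants unmatched"
        )
    keep = [c for c in participants.columns if not c.startswith("item_")]
    return features.merge(participants[keep], on="doc_id", how="inner")


def run_moderations(joined: pd.DataFrame) -> pd.DataFrame:
    """The grid of moderation models: outcome ~ conspiracism × textual quality."""
    rows = []
    for outcome in MODERATION_OUTCOMES:
        for moderator in MODERATION_MODERATORS:
            if outcome not in joined or moderator not in joined:
                continue
            try:
                fit = _stats.moderated_regression(
                    joined[outcome], joined["conspiracism"], joined[moderator]
                )
            except ValueError as exc:
                logger.error("moderation %s ~ conspiracism x %s failed: %s", outcome, moderator, exc)
                continue
            for term, coef in fit.coefficients.iterrows():
                rows.append(
                    {
                        "outcome": outcome,
                        "moderator": moderator,
                        "term": term,
                        "beta": coef["beta"],
                        "se": coef["se"],
                        "t": coef["t"],
                        "p": coef["p"],
                        "ci_low": coef["ci_low"],
                        "ci_high": coef["ci_high"],
                        "n": fit.n,
                    }
                )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, scale_specs: Mapping[str, ScaleSpec]) -> dict:
    """Config-driven end-to-end run; writes the report files and run log.

    Outputs in ``config.output_dir``: features.tsv, correlations.tsv,
    moderation.tsv, pca_model.txt, optionally scramble_report.tsv, and
    run.log echoing every option.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("textmarkers")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        for key, value in vars(config).items():
            logger.info("option %s = %s", key, value)
        docs = read_conllu(config.corpus)
        lexicon = load_lexicon(config.lexicon)
        norms = load_norms(config.norms)
        rules = load_compound_rules(config.compound_rules) if config.compound_rules else ()
        embeddings = stopwords = None
        if config.cohesion_enabled:
            embeddings = load_embeddings(config.embeddings)
            stopwords = load_stopwords(config.stopwords)
        participants = score_participants(
            pd.read_csv(config.participants, sep="\t"),
            scale_specs,
            strict=config.strict,
        )
        features = compute_document_features(
            docs, lexicon, norms, embeddings, stopwords or frozenset(), rules,
            coverage_threshold=config.coverage_threshold,
        )
        joined = join_features(features, participants, strict=config.strict)
        variables = [v for v in MATRIX_VARIABLES if v in joined.columns]
        matrix = _stats.correlation_matrix(joined, variables)
        moderation = run_moderations(joined)

        features.to_csv(outdir / "features.tsv", sep="\t", index=False, float_format="%.6f")
        matrix.formatted.to_csv(outdir / "correlations.tsv", sep="\t")
        moderation.to_csv(outdir / "moderation.tsv", sep="\t", index=False, float_format="%.6g")
        if "pca_model" in features.attrs:
            save_pca(features.attrs["pca_model"], outdir / "pca_model.txt")
        results: dict = {
            "features": features,
            "joined": joined,
            "matrix": matrix,
            "moderation": moderation,
        }
        if config.scramble_validation and embeddings is not None:
            report = scramble_validation(
                docs, embeddings, stopwords, min_sentences=config.min_sentences,
                seed=config.seed,
            )
            write_scramble_report(report, outdir / "scramble_report.tsv")
            logger.info(
                "scramble validation: t=%.3f df=%.2f p=%.4g d=%.3f n=%d",
                report.ttest.t, report.ttest.df, report.ttest.p, report.ttest.d, report.n_used,
            )
            results["scramble"] = report
        return results
    finally:
        root.removeHandler(handler)
        handler.close()
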