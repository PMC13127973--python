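"""Parsed-document data model, CoNLL-U ingestion, and lexicon preprocessing.

The pipeline operates on dependency-parsed text. The canonical input is
CoNLL-U (10-column Universal Dependencies format), so the analysis core is
deterministic and never needs a parser model at run time. Internally heads
are 0-based sentence-internal indices with an explicit ``ROOT`` sentinel;
the CoNLL-U 1-based convention is converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

#: Sentinel head index for the syntactic root of a sentence.
ROOT = -1

#: The 17 Universal Dependencies POS tags, plus a fallback for anything else.
UD_TAGS = frozenset(
    {
        "ADJ", "ADP", "ADV", "AUX", "CCONJ", "DET", "INTJ", "NOUN", "NUM",
        "PART", "PRON", "PROPN", "PUNCT", "SCONJ", "SYM", "VERB", "X",
        "UNKNOWN",
    }
)

#: Tags removed during lexicon preprocessing (the "?"/"!" surfaces survive).
_FILTERED_TAGS = frozenset({"PUNCT", "SYM", "NUM"})
_RETAINED_MARKS = frozenset({"?", "!"})


class ConlluParseError(ValueError):
    """Raised for a structurally malformed CoNLL-U line."""


@dataclass(frozen=True)
class Token:
    """One syntactic word.

    ``index`` and ``head`` are 0-based positions within the sentence;
    ``head`` is :data:`ROOT` for the sentence root. ``lemma`` and
    ``surface`` are lowercased at ingestion so dictionary and norm lookups
    are case-insensitive.
    """

    index: int
    surface: str
    lemma: str
    upos: str
    head: int

    def __post_init__(self) -> None:
        if self.head != ROOT and self.head == self.index:
            raise ValueError(f"token {self.index!r} is its own head")
        if self.surface and not self.lemma:
            raise ValueError(f"token {self.index!r} has surface but empty lemma")
        if self.upos not in UD_TAGS:
            object.__setattr__(self, "upos", "UNKNOWN")


@dataclass(frozen=True)
class Sentence:
    """An ordered, non-empty sequence of tokens.

    A well-formed sentence has exactly one ROOT-headed token; violations are
    logged as warnings rather than rejected, since real parser output is not
    always well formed.
    """

    tokens: tuple[Token, ...]

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("sentence must contain at least one token")
        n_roots = sum(1 for t in self.tokens if t.head == ROOT)
        if n_roots != 1:
            logger.warning("sentence has %d ROOT-headed tokens (expected 1)", n_roots)

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[Token]:
        return iter(self.tokens)


@dataclass(frozen=True)
class ParsedDocument:
    """An ordered sequence of sentences with a corpus-unique identifier."""

    doc_id: str
    sentences: tuple[Sentence, ...]

    def __post_init__(self) -> None:
        if self.n_tokens == 0:
            raise ValueError(f"document {self.doc_id!r} has no tokens")

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sentences)

    def iter_tokens(self) -> Iterator[Token]:
        for sentence in self.sentences:
            yield from sentence.tokens


@dataclass(frozen=True)
class Lexicon:
    """A named set of dictionary entries.

    Entries are single lemmas, underscore-joined multiword lemmas, or the
    literal marks ``?`` and ``!``. All entries are lowercase and contain no
    whitespace.
    """

    entries: frozenset[str]
    name: str = "lexicon"

    def __post_init__(self) -> None:
        for e in self.entries:
            if not e:
                raise ValueError("empty lexicon entry")
            if any(c.isspace() for c in e):
                raise ValueError(f"lexicon entry contains whitespace: {e!r}")
            if e != e.lower():
                raise ValueError(f"lexicon entry not lowercase: {e!r}")

    def __contains__(self, item: str) -> bool:
        return item in self.entries

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# CoNLL-U ingestion
# ---------------------------------------------------------------------------

def _is_range_id(field: str) -> bool:
    return "-" in field


def _is_empty_node_id(field: str) -> bool:
    return "." in field


def read_conllu(path: str | Path, one_doc_per_file: bool = False) -> list[ParsedDocument]:
    """Read a CoNLL-U file into :class:`ParsedDocument` objects.

    Document boundaries come from ``# newdoc id = ...`` comments; with
    ``one_doc_per_file`` the whole file is a single document named after the
    file stem. Multiword-token ranges (``1-2``) are skipped in favour of
    their syntactic words, and empty nodes (``1.1``) are ignored. A HEAD of
    0 maps to the :data:`ROOT` sentinel; an out-of-range head is reassigned
    to ROOT with a warning.

    Raises
    ------
    ConlluParseError
        If a non-comment line does not have 10 tab-separated columns, or has
        a non-integer ID/HEAD, naming the offending line number.
    """
    path = Path(path)
    raw_rows: list[tuple[int, str, str, str, str]] = []  # (1-based id, form, lemma, upos, head)
    current_sentences: list[Sentence] = []
    docs: list[ParsedDocument] = []
    doc_id = path.stem if one_doc_per_file else None
    pending_doc_id: str | None = None

    def flush_sentence() -> None:
        nonlocal raw_rows
        if not raw_rows:
            return
        n = len(raw_rows)
        tokens = []
        for i, (tid, form, lemma, upos, head_field) in enumerate(raw_rows):
            head_1 = int(head_field)
            if head_1 == 0:
                head = ROOT
            else:
                head = head_1 - 1
                if head < 0 or head >= n or head == i:
                    logger.warning(
                        "head index %d out of range in sentence of %d tokens; "
                        "token %d reassigned to ROOT", head_1, n, tid,
                    )
                    head = ROOT
            tokens.append(
                Token(index=i, surface=form.lower(), lemma=lemma.lower(), upos=upos, head=head)
            )
        current_sentences.append(Sentence(tokens=tuple(tokens)))
        raw_rows = []

    def flush_doc(new_id: str | None) -> None:
        nonlocal current_sentences, doc_id
        flush_sentence()
        if current_sentences:
            docs.append(ParsedDocument(doc_id=doc_id or f"doc{len(docs)}", sentences=tuple(current_sentences)))
            current_sentences = []
        doc_id = new_id

    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush_sentence()
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("newdoc id") and not one_doc_per_file:
                    pending_doc_id = body.split("=", 1)[1].strip() if "=" in body else None
                    flush_doc(pending_doc_id)
                continue
            cols = line.split("\t")
            if len(cols) != 10:
                raise ConlluParseError(
                    f"{path}:{lineno}: expected 10 tab-separated columns, got {len(cols)}"
                )
            tok_id, form, lemma, upos, _xpos, _feats, head, _rel, _deps, _misc = cols
            if _is_range_id(tok_id) or _is_empty_node_id(tok_id):
                continue
            try:
                tid = int(tok_id)
                int(head)
            except ValueError as exc:
                raise ConlluParseError(f"{path}:{lineno}: non-integer ID or HEAD field") from exc
            raw_rows.append((tid, form, lemma, upos, head))
    flush_doc(None)
    return docs


def write_conllu(docs: Iterable[ParsedDocument], path: str | Path) -> None:
    """Write documents back out as CoNLL-U with ``# newdoc id`` boundaries.

    Round-trips with :func:`read_conllu`: token count, lemmas, UPOS tags and
    head indices are preserved exactly.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(f"# newdoc id = {doc.doc_id}\n")
            for s_idx, sentence in enumerate(doc.sentences, start=1):
                fh.write(f"# sent_id = {doc.doc_id}-{s_idx}\n")
                for tok in sentence:
                    head_1 = 0 if tok.head == ROOT else tok.head + 1
                    rel = "root" if tok.head == ROOT else "dep"
                    fh.write(
                        f"{tok.index + 1}\t{tok.surface}\t{tok.lemma}\t{tok.upos}"
                        f"\t_\t_\t{head_1}\t{rel}\t_\t_\n"
                    )
                fh.write("\n")


# ---------------------------------------------------------------------------
# Input tables
# ---------------------------------------------------------------------------

def load_lexicon(path: str | Path, name: str | None = None) -> Lexicon:
    """Load a lexicon file: one entry per line, ``#`` comments allowed."""
    path = Path(path)
    entries = set()
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            entries.add(line.lower())
    return Lexicon(entries=frozenset(entries), name=name or path.stem)


CompoundRule = tuple[tuple[str, ...], str]


def load_compound_rules(path: str | Path) -> list[CompoundRule]:
    """Load compound rules: ``lemma lemma<TAB>joined_entry`` per line."""
    path = Path(path)
    rules: list[CompoundRule] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if "\t" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'lemma sequence<TAB>joined entry'")
            seq, joined = line.split("\t", 1)
            parts = tuple(seq.lower().split())
            if not parts or not joined.strip():
                raise ValueError(f"{path}:{lineno}: empty rule side")
            rules.append((parts, joined.strip().lower()))
    return rules


# ---------------------------------------------------------------------------
# Lexicon preprocessing chain
# ---------------------------------------------------------------------------

def _join_compounds(tokens: list[str], rules: Sequence[CompoundRule]) -> list[str]:
    """Greedy non-overlapping left-to-right compound joining.

    At each position the longest matching rule wins; matched spans are
    consumed, so later rules cannot overlap an earlier match.
    """
    if not rules:
        return tokens
    by_len = sorted(rules, key=lambda r: len(r[0]), reverse=True)
    out: list[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        for seq, joined in by_len:
            k = len(seq)
            if tuple(tokens[i : i + k]) == seq:
                out.append(joined)
                i += k
                break
        else:
            out.append(tokens[i])
            i += 1
    return out


def preprocess_for_lexicon(
    doc: ParsedDocument,
    compound_rules: Sequence[CompoundRule] = (),
) -> list[str]:
    """Reconstruct a document as its ordered lemmatized tokens for dictionary scoring.

    Punctuation, symbols and numbers (UPOS PUNCT/SYM/NUM) are removed, except
    that the surfaces ``?`` and ``!`` are kept as literal tokens — they can
    themselves be dictionary entries. Compound rules are then applied
    greedily left to right (e.g. ``sito web`` → ``sito_web``). Removal
    precedes compound joining.
    """
    out: list[str] = []
    for tok in doc.iter_tokens():
        if tok.upos in _FILTERED_TAGS:
            if tok.surface in _RETAINED_MARKS:
                out.append(tok.surface)
            continue
        out.append(tok.lemma)
    processed = _join_compounds(out, compound_rules)
    if not processed:
        logger.warning("document %s is empty after lexicon preprocessing", doc.doc_id)
    return processed
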