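"""Dictionary-based conspiratorial-lexicon scoring.

A document's score is the proportion of its processed tokens that match an
entry of the lexicon: 0 means no dictionary matches, 1 means every token
matched. Each processed token (a joined compound counts as one token)
contributes at most one match.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from .parsed_text import CompoundRule, Lexicon, ParsedDocument, preprocess_for_lexicon

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LexiconScore:
    doc_id: str
    matches: int
    denominator: int
    ratio: float  # NaN when denominator == 0

    def __post_init__(self) -> None:
        if not 0 <= self.matches <= max(self.denominator, 0):
            raise ValueError("matches must lie in [0, denominator]")
        if self.denominator > 0 and not math.isclose(self.ratio, self.matches / self.denominator):
            raise ValueError("ratio inconsistent with matches/denominator")


def score_lexicon(
    doc: ParsedDocument,
    lexicon: Lexicon,
    compound_rules: Sequence[CompoundRule] = (),
    marks_in_denominator: bool = True,
) -> LexiconScore:
    """Match-ratio score of one document against a lexicon.

    Tokens are the output of :func:`~textmarkers.parsed_text.preprocess_for_lexicon`
    (lemmas with punctuation/symbols/numbers removed, ``?``/``!`` retained,
    compounds joined). The denominator is the number of processed tokens,
    including the retained marks by default since they are potential entries
    themselves; ``marks_in_denominator=False`` excludes them from both the
    count and the matching.

    An empty processed token list yields denominator 0 and a NaN ratio.
    """
    tokens = preprocess_for_lexicon(doc, compound_rules)
    if not marks_in_denominator:
        tokens = [t for t in tokens if t not in ("?", "!")]
    if not tokens:
        logger.warning("document %s has no processed tokens; lexicon ratio undefined", doc.doc_id)
        return LexiconScore(doc_id=doc.doc_id, matches=0, denominator=0, ratio=float("nan"))
    matches = sum(1 for t in tokens if t in lexicon)
    return LexiconScore(
        doc_id=doc.doc_id,
        matches=matches,
        denominator=len(tokens),
        ratio=matches / len(tokens),
    )
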