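"""Precision/recall/F1 at the three standard evaluation levels.

``MENTION``   exact span match on (doc, start, end, type);
``CONCEPT``   document-level set match on (doc, type, concept ID), with the
              unmapped sentinel ``-1`` excluded from both sides;
``RELATION``  document-level set match on (doc, chemical ID, disease ID).

All levels use set semantics, so duplicate annotations of the same item
within a document count once.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Sequence

from .corpus import Document, UNMAPPED

__all__ = ["EvalLevel", "EvalResult", "evaluate", "report"]


class EvalLevel(str, Enum):
    MENTION = "MENTION"
    CONCEPT = "CONCEPT"
    RELATION = "RELATION"


@dataclass(frozen=True)
class EvalResult:
    level: EvalLevel
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def _items(doc: Document, level: EvalLevel) -> set[tuple]:
    if level == EvalLevel.MENTION:
        return {(doc.doc_id, m.start, m.end, m.etype) for m in doc.mentions}
    if level == EvalLevel.CONCEPT:
        return {
            (doc.doc_id, m.etype, m.concept_id)
            for m in doc.mentions
            if m.concept_id != UNMAPPED
        }
    return {(doc.doc_id, r.chemical_id, r.disease_id) for r in doc.relations}


def evaluate(
    gold: Sequence[Document],
    pred: Sequence[Document],
    level: EvalLevel | str,
) -> EvalResult:
    """Compare predicted against gold documents at one level.

    The two collections must cover the same document ids.
    """
    level = EvalLevel(level)
    gold_ids = {d.doc_id for d in gold}
    pred_ids = {d.doc_id for d in pred}
    if gold_ids != pred_ids:
        raise ValueError(
            f"document id mismatch: {sorted(gold_ids ^ pred_ids)[:5]} ..."
        )
    gold_items: set[tuple] = set()
    pred_items: set[tuple] = set()
    for d in gold:
        gold_items |= _items(d, level)
    for d in pred:
        pred_items |= _items(d, level)
    tp = len(gold_items & pred_items)
    return EvalResult(
        level=level, tp=tp, fp=len(pred_items) - tp, fn=len(gold_items) - tp
    )


def _pct(x: float) -> str:
    return str(Decimal(100 * x).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def report(results: Iterable[EvalResult]) -> str:
    """Table of P/R/F1 percentages (two decimals, half-up rounding)."""
    lines = [f"{'Level':<10}{'P':>8}{'R':>8}{'F1':>8}"]
    for r in results:
        lines.append(
            f"{r.level.value:<10}{_pct(r.precision):>8}{_pct(r.recall):>8}"
            f"{_pct(r.f1):>8}"
        )
    return "\n".join(lines)
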