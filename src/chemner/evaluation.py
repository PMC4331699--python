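"""Exact-match scoring for mention-level (CEM) and document-indexing (CDI)
tasks.

Precision p = TP/(TP+FP), recall r = TP/(TP+FN), F1 = 2pr/(p+r); empty
denominators score 0 by convention.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from typing import Sequence

from .corpus_io import Mention

__all__ = ["EvalCounts", "cem_evaluate", "cdi_evaluate", "report"]


@dataclass(frozen=True)
class EvalCounts:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp > 0 else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn > 0 else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0


def _count(pred_keys: set, gold_keys: set) -> EvalCounts:
    tp = len(pred_keys & gold_keys)
    return EvalCounts(tp=tp, fp=len(pred_keys) - tp, fn=len(gold_keys) - tp)


def cem_evaluate(
    predicted: Sequence[Mention], gold: Sequence[Mention], strict_type: bool = False
) -> EvalCounts:
    """Exact offset matching on (doc_id, section, start, end); the entity
    type additionally matters only under ``strict_type``."""

    def key(m: Mention):
        k = (m.doc_id, m.section, m.start, m.end)
        return k + (m.entity_type,) if strict_type else k

    return _count({key(m) for m in predicted}, {key(m) for m in gold})


def cdi_evaluate(predicted: Sequence[Mention], gold: Sequence[Mention]) -> EvalCounts:
    """Both sides reduced to unique (doc_id, text) pairs; exact strings."""
    return _count(
        {(m.doc_id, m.text) for m in predicted}, {(m.doc_id, m.text) for m in gold}
    )


def report(counts: EvalCounts, stream=None) -> str:
    """Human-readable percentages (2 decimals) plus a machine-readable row."""
    stream = stream if stream is not None else sys.stdout
    p, r, f = counts.precision, counts.recall, counts.f1
    human = f"{p * 100:.2f} / {r * 100:.2f} / {f * 100:.2f}"
    machine = f"TP={counts.tp}\tFP={counts.fp}\tFN={counts.fn}\tP={p:.6f}\tR={r:.6f}\tF1={f:.6f}"
    stream.write(f"P / R / F1 (%): {human}\n{machine}\n")
    return human
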