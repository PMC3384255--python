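"""Strict evaluation of predicted relations against gold annotations.

Matching is one-to-one per relation key: a gold relation can satisfy at
most one prediction, so duplicated predictions of the same relation cost
a false positive. Metrics follow the usual convention of the shared-task
setting — per-type precision, recall and F1 on a percent scale, and an
overall micro-average obtained by summing TP/FP/FN over types. Reported
values are rounded to two decimals; full precision is retained
internally. Report differences (in percentage points) are computed on
the rounded values, matching how published tables are compared.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .ensemble import Predictions, relation_key
from .errors import ReportError
from .model import Document

OVERALL = "All"


@dataclass
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp,
                          self.fn + other.fn)


def gold_predictions(documents: list[Document]) -> Predictions:
    """The gold relations of *documents*, in the predictions container."""
    return {d.id: list(d.relations) for d in documents}


def match_predictions(
    gold: Predictions, predicted: Predictions, mode: str = "strict"
) -> dict[str, EvalCounts]:
    """One-to-one key matching, split per relation type.

    Type mismatches never match (the type is part of the key). Returns a
    counts entry for every type present on either side.
    """
    gold_keys: Counter = Counter()
    for doc_id, rels in gold.items():
        gold_keys.update(relation_key(doc_id, r, mode) for r in rels)
    pred_keys: Counter = Counter()
    for doc_id, rels in predicted.items():
        pred_keys.update(relation_key(doc_id, r, mode) for r in rels)

    counts: dict[str, EvalCounts] = {}

    def _at(rtype: str) -> EvalCounts:
        return counts.setdefault(rtype, EvalCounts())

    for key in gold_keys.keys() | pred_keys.keys():
        rtype = key[1]
        g = gold_keys.get(key, 0)
        p = pred_keys.get(key, 0)
        m = min(g, p)
        c = _at(rtype)
        c.tp += m
        c.fp += p - m
        c.fn += g - m
    return counts


def prf(counts: EvalCounts) -> tuple[float, float, float]:
    """Precision, recall and F1 on the percent scale (unrounded).

    Zero denominators yield 0 by convention.
    """
    p = 100.0 * counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = 100.0 * counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def micro_overall(per_type: dict[str, EvalCounts]) -> EvalCounts:
    """Counts summed over all relation types."""
    total = EvalCounts()
    for c in per_type.values():
        total = total + c
    return total


@dataclass
class EvalReport:
    """Per-type and overall P/R/F (percent, 2-decimal rounding)."""

    counts: dict[str, EvalCounts] = field(default_factory=dict)

    @classmethod
    def from_predictions(
        cls, gold: Predictions, predicted: Predictions, mode: str = "strict"
    ) -> "EvalReport":
        return cls(counts=match_predictions(gold, predicted, mode))

    def types(self) -> list[str]:
        return sorted(self.counts)

    def metrics(self, rtype: str) -> tuple[float, float, float]:
        """Rounded (P, R, F) of one type, or of the micro-average for
        ``rtype == "All"``."""
        if rtype == OVERALL:
            c = micro_overall(self.counts)
        else:
            c = self.counts[rtype]
        p, r, f = prf(c)
        return round(p, 2), round(r, 2), round(f, 2)

    def overall(self) -> tuple[float, float, float]:
        return self.metrics(OVERALL)

    def to_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("type\ttp\tfp\tfn\tprecision\trecall\tf\n")
            for t in self.types() + [OVERALL]:
                c = (micro_overall(self.counts) if t == OVERALL
                     else self.counts[t])
                p, r, f = self.metrics(t)
                fh.write(f"{t}\t{c.tp}\t{c.fp}\t{c.fn}\t{p}\t{r}\t{f}\n")


def diff_metric_triples(
    a: tuple[float, float, float], b: tuple[float, float, float]
) -> tuple[float, float, float]:
    """Element-wise A minus B of two rounded (P, R, F) triples, in
    percentage points, rounded to two decimals — the arithmetic used when
    comparing published result tables."""
    return tuple(round(x - y, 2) for x, y in zip(a, b))  # type: ignore[return-value]


def diff_reports(a: EvalReport, b: EvalReport) -> dict[str, tuple[float, float, float]]:
    """A minus B per type and overall, in percentage points.

    Differences are taken on the rounded metrics and rounded again to two
    decimals.
    """
    if set(a.counts) != set(b.counts):
        raise ReportError(
            f"type inventories differ: {sorted(a.counts)} vs {sorted(b.counts)}"
        )
    return {
        t: diff_metric_triples(a.metrics(t), b.metrics(t))
        for t in a.types() + [OVERALL]
    }
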