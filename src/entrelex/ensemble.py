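"""Combining prediction sets from different extraction systems.

Predictions are dictionaries mapping document id to a list of
:class:`~entrelex.model.EntityRelation`. Relations are compared across
systems by a canonical key — (document, type, GGP span, term span) in
``strict`` mode, or term *head token* equality in ``head`` mode for
systems whose term spans differ.

Three combiners:

* **intersection** — high precision: keep relations both systems agree on;
* **union** — high recall: keep relations either system proposes;
* **hybrid composition** — run the relation classifier of one system on
  the term candidates produced by the other system's term detector.
"""

from __future__ import annotations

from .model import Document, EntityRelation

Predictions = dict[str, list[EntityRelation]]


def relation_key(
    doc_id: str, rel: EntityRelation, mode: str = "strict"
) -> tuple:
    """Canonical comparison key of one relation.

    ``strict`` keys on exact character spans of both arguments; ``head``
    keys the term by its head token index instead of its span.
    """
    if mode == "strict":
        return (doc_id, rel.type, rel.ggp.span(), rel.term.span())
    if mode == "head":
        return (doc_id, rel.type, rel.ggp.span(), rel.term.head_token)
    raise ValueError(f"unknown match mode {mode!r}")


def _keyed(preds: Predictions, mode: str) -> dict[tuple, tuple[str, EntityRelation]]:
    out: dict[tuple, tuple[str, EntityRelation]] = {}
    for doc_id, rels in preds.items():
        for r in rels:
            out.setdefault(relation_key(doc_id, r, mode), (doc_id, r))
    return out


def _collect(items) -> Predictions:
    out: Predictions = {}
    for doc_id, r in items:
        out.setdefault(doc_id, []).append(r)
    return out


def intersect(a: Predictions, b: Predictions, mode: str = "strict") -> Predictions:
    """Relations whose keys occur in both systems; records taken from A."""
    kb = set(_keyed(b, mode))
    ka = _keyed(a, mode)
    return _collect(v for k, v in ka.items() if k in kb)


def union(a: Predictions, b: Predictions, mode: str = "strict") -> Predictions:
    """Key-wise union; on duplicates A's record wins."""
    ka = _keyed(a, mode)
    kb = _keyed(b, mode)
    merged = {**kb, **ka}
    return _collect(merged.values())


def prediction_count(preds: Predictions) -> int:
    return sum(len(v) for v in preds.values())


def hybrid_compose(
    term_source,
    relation_system,
    documents: list[Document],
) -> Predictions:
    """Terms from one system, relation decisions from another.

    ``term_source(doc, sent_index)`` must return the term candidates of
    one sentence; ``relation_system.predict_with_terms(documents,
    term_source)`` runs its relation classification constrained to those
    candidates.
    """
    return relation_system.predict_with_terms(documents, term_source)
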