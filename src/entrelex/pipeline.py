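"""End-to-end extraction pipelines.

:class:`EdgePipeline` is the graph-based system: an SVM token classifier
proposes domain-term heads (with recall boosting), then a linear
multiclass SVM classifies every GGP-term pair in the sentence into a
relation type or negative.

:class:`SentencePipeline` is the sentence-classification system: one
binary RBF-SVM per relation type decides whether a (sentence, GGP)
instance expresses that relation, and a positive decision is resolved to
a concrete relation by a rule-based dictionary/lexicon search within a
token window around the GGP.

:func:`entrelex.ensemble.hybrid_compose` combines them: the token
classifier of the edge pipeline supplies term candidates, the sentence
pipeline's type models make the relation decision, and attachment is
restricted to the supplied candidates.

Both pipelines share the prediction container (document id -> relations)
consumed by :mod:`entrelex.evaluation` and :mod:`entrelex.ensemble`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ensemble import Predictions
from .features import FeatureConfig, build_instance_vector
from .model import (
    NEGATIVE_LABEL,
    RELATION_TYPES,
    Document,
    EntityMention,
    EntityRelation,
)
from .relations import (
    CVConfig,
    EdgeModel,
    TypeModel,
    generate_candidates,
    train_edge_model,
    train_type_models,
)
from .semantic import SemanticLexicon
from .standoff import _is_embedded
from .terms import (
    RecallBoost,
    TermCandidate,
    TermDictionary,
    TokenTermModel,
    build_term_dictionary,
    detect_terms_rule,
    gold_term_candidates,
    train_token_classifier,
)


def _sentence_ggps(doc: Document, sent_index: int) -> list[EntityMention]:
    return [g for g in doc.ggp_mentions
            if doc.sentence_index_of(g) == sent_index]


def _gold_pair_types(doc: Document, sent_index: int) -> dict[tuple[int, int], str]:
    """(ggp head, term head) -> relation type for one sentence."""
    out: dict[tuple[int, int], str] = {}
    for r in doc.relations:
        if doc.sentence_index_of(r.ggp) == sent_index:
            out[(r.ggp.head_token, r.term.head_token)] = r.type
    return out


def _emit_relation(
    doc: Document, sent_index: int, ggp: EntityMention,
    cand: TermCandidate, rel_type: str, counter: list[int],
) -> EntityRelation:
    counter[0] += 1
    term = EntityMention(
        id=f"TP{counter[0]}", kind="term", type_label="Entity",
        begin=cand.begin, end=cand.end, surface=cand.surface,
        head_token=cand.head_token,
    )
    rel = EntityRelation(
        id=f"RP{counter[0]}", type=rel_type, ggp=ggp, term=term,
    )
    rel.embedded = _is_embedded(ggp, term, doc.sentences[sent_index])
    return rel


@dataclass
class EdgePipeline:
    """Token-level term detection followed by edge classification."""

    token_config: FeatureConfig = field(default_factory=FeatureConfig)
    edge_config: FeatureConfig = field(default_factory=FeatureConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    recall_boost: float = 1.0
    seed: int = 0
    lexicon: SemanticLexicon | None = None

    token_model: TokenTermModel | None = None
    edge_model: EdgeModel | None = None

    def fit(self, documents: list[Document]) -> "EdgePipeline":
        self.cv.seed = self.seed
        self.token_model = train_token_classifier(
            documents, self.token_config, seed=self.seed
        )
        candidates = []
        for doc in documents:
            for si, sent in enumerate(doc.sentences):
                ggps = _sentence_ggps(doc, si)
                terms = gold_term_candidates(doc, si)
                if not ggps or not terms:
                    continue
                pair_types = _gold_pair_types(doc, si)
                for c in generate_candidates(
                    sent, ggps, terms, self.edge_config, self.lexicon
                ):
                    c.label = pair_types.get(
                        (c.ggp.head_token, c.term.head_token), NEGATIVE_LABEL
                    )
                    candidates.append(c)
        self.edge_model = train_edge_model(candidates, self.cv,
                                           self.edge_config)
        return self

    def term_candidates(self, doc: Document, sent_index: int) -> list[TermCandidate]:
        """Term candidates of one sentence (the hybrid's term source)."""
        return self.token_model.predict_terms(
            doc.sentences[sent_index], RecallBoost(self.recall_boost)
        )

    def predict(self, documents: list[Document]) -> Predictions:
        out: Predictions = {d.id: [] for d in documents}
        counter = [0]
        for doc in documents:
            for si, sent in enumerate(doc.sentences):
                ggps = _sentence_ggps(doc, si)
                if not ggps:
                    continue
                terms = self.term_candidates(doc, si)
                if not terms:
                    continue
                cands = generate_candidates(
                    sent, ggps, terms, self.edge_config, self.lexicon
                )
                labels = self.edge_model.predict(cands)
                for c, lbl in zip(cands, labels):
                    if lbl == NEGATIVE_LABEL:
                        continue
                    out[doc.id].append(
                        _emit_relation(doc, si, c.ggp, c.term, lbl, counter)
                    )
        return out


@dataclass
class SentencePipeline:
    """Per-type sentence classification with rule-based term attachment."""

    config: FeatureConfig = field(default_factory=FeatureConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    #: attachment window in tokens; None = calibrate from training data
    #: (max observed GGP-term head distance among gold relations)
    window: int | None = None
    types: tuple[str, ...] = RELATION_TYPES
    seed: int = 0
    lexicon: SemanticLexicon | None = None

    dictionary: TermDictionary | None = None
    type_models: dict[str, TypeModel] | None = None

    def _instance(self, doc: Document, sent_index: int, ggp: EntityMention):
        sent = doc.sentences[sent_index]
        others = [g for g in _sentence_ggps(doc, sent_index) if g is not ggp]
        return build_instance_vector(
            "sentence",
            {"sentence": sent, "ggp": ggp, "other_ggps": others},
            self.config, self.lexicon,
            instance_id=f"{doc.id}:s{sent_index}:{ggp.id}",
        )

    effective_window: int = 5

    def fit(self, documents: list[Document]) -> "SentencePipeline":
        self.cv.seed = self.seed
        self.dictionary = build_term_dictionary(documents)
        if self.window is None:
            distances = [
                abs(r.ggp.head_token - r.term.head_token)
                for doc in documents for r in doc.relations
            ]
            self.effective_window = max(distances, default=5)
        else:
            self.effective_window = self.window
        vectors = []
        label_sets = []
        for doc in documents:
            for si in range(len(doc.sentences)):
                for ggp in _sentence_ggps(doc, si):
                    vectors.append(self._instance(doc, si, ggp))
                    label_sets.append({
                        r.type for r in doc.relations
                        if r.ggp is ggp
                    })
        self.type_models = train_type_models(
            vectors, label_sets, list(self.types), self.cv
        )
        return self

    def _positive_decisions(self, documents: list[Document]):
        """Yield (doc, sent_index, ggp, type) for every positive model."""
        index = []
        vectors = []
        for doc in documents:
            for si in range(len(doc.sentences)):
                for ggp in _sentence_ggps(doc, si):
                    index.append((doc, si, ggp))
                    vectors.append(self._instance(doc, si, ggp).features)
        if not vectors:
            return
        for rel_type in self.types:
            flags = self.type_models[rel_type].predict(vectors)
            for (doc, si, ggp), flag in zip(index, flags):
                if flag:
                    yield doc, si, ggp, rel_type

    def predict(self, documents: list[Document]) -> Predictions:
        """Full system: attach terms by dictionary/lexicon window search."""
        def provider(doc, si, ggp, rel_type):
            return detect_terms_rule(
                doc.sentences[si], ggp, self.effective_window,
                self.dictionary, self.lexicon, rel_type,
            )
        return self._predict_with_provider(documents, provider)

    def predict_with_terms(
        self, documents: list[Document], term_source
    ) -> Predictions:
        """Relation decisions on term candidates from another system.

        Attachment considers only the supplied candidates, preferring
        those whose predicted type matches the decided relation type,
        then the nearest to the GGP (right side on ties).
        """
        def provider(doc, si, ggp, rel_type):
            cands = term_source(doc, si)
            h = ggp.head_token
            typed = [c for c in cands if c.type == rel_type]
            pool = typed or []
            return sorted(
                pool,
                key=lambda c: (abs(c.head_token - h),
                               0 if c.head_token > h else 1),
            )
        return self._predict_with_provider(documents, provider)

    def _predict_with_provider(self, documents, provider) -> Predictions:
        out: Predictions = {d.id: [] for d in documents}
        counter = [0]
        for doc, si, ggp, rel_type in self._positive_decisions(documents):
            cands = provider(doc, si, ggp, rel_type)
            if not cands:
                continue
            out[doc.id].append(
                _emit_relation(doc, si, ggp, cands[0], rel_type, counter)
            )
        return out
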