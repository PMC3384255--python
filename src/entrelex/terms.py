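"""Domain-term detection.

Two strategies, mirroring the two extraction frameworks the toolkit
implements:

* an SVM **token classifier**: every word token of a sentence is
  classified as the head of a domain term (of some relation type) or not,
  using dependency-walk features centred on the token. A *recall boost*
  shrinks the negative class's decision score at prediction time —
  dividing its exponentiated score by ``beta``, i.e. subtracting
  ``log(beta)`` from the margin — trading precision for recall so more
  terms survive into edge detection. The shift is monotone in ``beta``:
  candidate sets are nested, ``beta = 1`` is a no-op and ``beta -> inf``
  accepts every token.
* a **rule-based search**: within a token window around a GGP, tokens and
  phrases are looked up in a dictionary of normalised gold term surfaces
  from the training data (longest-first, leftmost-first) and in the
  semantic lexicons; hits become candidates ordered by distance to the
  GGP, ties preferring the right side.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.svm import LinearSVC

from ._util import csr32
from .errors import CompatibilityError, DegenerateModelError, ParameterError
from .features import FeatureConfig, build_instance_vector
from .model import NEGATIVE_LABEL, Document, EntityMention, Sentence
from .semantic import SemanticLexicon, normalize_term


@dataclass
class TermCandidate:
    """A detected (or gold) domain-term occurrence inside one sentence."""

    token_start: int          # sentence-local, inclusive
    token_end: int            # sentence-local, exclusive
    begin: int                # character offsets into the document
    end: int
    surface: str
    head_token: int
    type: str                 # predicted/majority relation type
    score: float = 0.0
    type_scores: dict[str, float] = field(default_factory=dict)
    provenance: str = "rules"  # "svm" | "rules" | "gold"


@dataclass
class RecallBoost:
    """Multiplier applied to the negative class's (exponentiated) score."""

    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ParameterError(f"recall boost beta must be > 0, got {self.beta}")

    @property
    def margin_shift(self) -> float:
        return math.log(self.beta)


# ---------------------------------------------------------------------------
# dictionary strategy


@dataclass
class TermDictionary:
    """Normalised gold term surfaces with per-relation-type counts."""

    entries: dict[str, Counter] = field(default_factory=dict)
    max_phrase_len: int = 1

    def __contains__(self, normalized: str) -> bool:
        return normalized in self.entries

    def majority_type(self, normalized: str) -> str | None:
        counts = self.entries.get(normalized)
        if not counts:
            return None
        top = max(counts.values())
        return min(t for t, c in counts.items() if c == top)

    def supports_type(self, normalized: str, rel_type: str) -> bool:
        counts = self.entries.get(normalized)
        return bool(counts and counts.get(rel_type, 0) > 0)


def build_term_dictionary(documents: list[Document]) -> TermDictionary:
    """Collect every distinct normalised gold term surface with the
    relation-type counts observed in the training relations."""
    d = TermDictionary()
    for doc in documents:
        for m in doc.term_mentions:
            d.entries.setdefault(normalize_term(m.surface), Counter())
        for r in doc.relations:
            d.entries.setdefault(
                normalize_term(r.term.surface), Counter()
            )[r.type] += 1
    d.max_phrase_len = max(
        (len(k.split()) for k in d.entries), default=1
    )
    return d


def detect_terms_rule(
    sentence: Sentence,
    ggp: EntityMention,
    window: int = 5,
    dictionary: TermDictionary | None = None,
    lexicon: SemanticLexicon | None = None,
    rel_type: str | None = None,
) -> list[TermCandidate]:
    """Dictionary/lexicon search within *window* tokens of the GGP.

    A phrase is a candidate if its normalisation hits the dictionary
    (restricted to entries supporting *rel_type* when one is requested)
    or shares a semantic-lexicon class with a dictionary entry of that
    type. Matching is longest-first, leftmost-first; candidates are
    ordered by token distance to the GGP head, ties preferring the right
    side.
    """
    if dictionary is None:
        dictionary = TermDictionary()
    h = ggp.head_token
    ggp_idx = {t.index for t in sentence.token_at_offset(ggp.begin, ggp.end)}
    n = len(sentence.tokens)
    in_window = [
        i for i in range(n)
        if i not in ggp_idx and abs(i - h) <= window
    ]
    # classes that predict the requested type, via labelled dictionary terms
    type_classes: set[str] = set()
    if lexicon is not None and rel_type is not None:
        for entry, counts in dictionary.entries.items():
            if counts.get(rel_type, 0) > 0:
                type_classes.update(lexicon.classes_of(entry))

    matches: list[tuple[int, int, str]] = []  # (start, length, norm)
    for length in range(min(dictionary.max_phrase_len, 3), 0, -1):
        for i in in_window:
            if i + length > n:
                continue
            span = set(range(i, i + length))
            if span & ggp_idx:
                continue
            norm = " ".join(
                sentence.tokens[j].stem for j in range(i, i + length)
            )
            hit = False
            if norm in dictionary:
                hit = rel_type is None or dictionary.supports_type(norm, rel_type)
            if not hit and length == 1 and lexicon is not None:
                classes = set(lexicon.classes_of(norm))
                hit = bool(classes & type_classes)
            if hit:
                taken = {
                    k for s, ln, _ in matches for k in range(s, s + ln)
                }
                if not (span & taken):
                    matches.append((i, length, norm))

    out: list[TermCandidate] = []
    for start, length, norm in matches:
        toks = sentence.tokens[start:start + length]
        dist = min(abs(j - h) for j in range(start, start + length))
        cand_type = (
            rel_type
            or dictionary.majority_type(norm)
            or NEGATIVE_LABEL
        )
        out.append(
            TermCandidate(
                token_start=start,
                token_end=start + length,
                begin=toks[0].begin,
                end=toks[-1].end,
                surface=" ".join(t.surface for t in toks),
                head_token=start + length - 1,
                type=cand_type,
                score=-float(dist),
                type_scores=dict(dictionary.entries.get(norm, {})),
                provenance="rules",
            )
        )
    out.sort(key=lambda c: (min(abs(j - h) for j in
                                range(c.token_start, c.token_end)),
                            0 if c.token_start > h else 1,
                            c.token_start))
    return out


# ---------------------------------------------------------------------------
# SVM token strategy


class TokenTermModel:
    """Linear multiclass SVM over per-token dependency-walk features."""

    def __init__(self, config: FeatureConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        self._vectorizer = DictVectorizer(sparse=True)
        self._svm = LinearSVC(C=1.0, random_state=seed, max_iter=5000)
        self.classes_: list[str] = []

    def fit(self, vectors: list[dict], labels: list[str]) -> "TokenTermModel":
        if len(set(labels)) < 2:
            raise DegenerateModelError(
                "token training data contains a single class"
            )
        if all(not v for v in vectors):
            raise DegenerateModelError("all token feature vectors are empty")
        x = csr32(self._vectorizer.fit_transform(vectors))
        self._svm.fit(x, labels)
        self.classes_ = list(self._svm.classes_)
        return self

    def decision_scores(self, vectors: list[dict]) -> np.ndarray:
        """Per-class decision scores, shape (n, n_classes)."""
        x = csr32(self._vectorizer.transform(vectors))
        raw = self._svm.decision_function(x)
        if raw.ndim == 1:  # binary: score of classes_[1]
            raw = np.column_stack([-raw, raw])
        return raw

    def predict_terms(
        self,
        sentence: Sentence,
        recall_boost: RecallBoost | float = 1.0,
        config: FeatureConfig | None = None,
    ) -> list[TermCandidate]:
        """Classify every token; return the positives as term candidates.

        The negative class margin is shifted down by log(beta) before the
        argmax, so larger boosts only ever add candidates.
        """
        if config is not None and config != self.config:
            raise CompatibilityError(
                "feature config differs from the one the model was trained with"
            )
        if isinstance(recall_boost, (int, float)):
            recall_boost = RecallBoost(float(recall_boost))
        if NEGATIVE_LABEL not in self.classes_:
            raise CompatibilityError("model has no negative class")
        vectors = [
            build_instance_vector(
                "token", {"sentence": sentence, "token_index": t.index},
                self.config,
            ).features
            for t in sentence.tokens
        ]
        scores = self.decision_scores(vectors)
        neg_col = self.classes_.index(NEGATIVE_LABEL)
        adjusted = scores.copy()
        adjusted[:, neg_col] -= recall_boost.margin_shift
        out: list[TermCandidate] = []
        for t, row in zip(sentence.tokens, adjusted):
            best = int(np.argmax(row))
            if best == neg_col:
                continue
            out.append(
                TermCandidate(
                    token_start=t.index,
                    token_end=t.index + 1,
                    begin=t.begin,
                    end=t.end,
                    surface=t.surface,
                    head_token=t.index,
                    type=self.classes_[best],
                    score=float(row[best] - row[neg_col]),
                    type_scores={
                        c: float(s) for c, s in zip(self.classes_, row)
                        if c != NEGATIVE_LABEL
                    },
                    provenance="svm",
                )
            )
        return out


def train_token_classifier(
    documents: list[Document],
    config: FeatureConfig | None = None,
    seed: int = 0,
) -> TokenTermModel:
    """Train the per-token term classifier from gold annotations.

    Gold term head tokens are positive examples labelled with the type of
    the relation they participate in (the lexically most frequent type if
    several); every other token is negative.
    """
    config = config or FeatureConfig()
    vectors: list[dict] = []
    labels: list[str] = []
    for doc in documents:
        for si, sent in enumerate(doc.sentences):
            head_types: dict[int, str] = {}
            for r in doc.relations:
                if doc.sentence_index_of(r.term) == si:
                    head_types.setdefault(r.term.head_token, r.type)
            for t in sent.tokens:
                vectors.append(
                    build_instance_vector(
                        "token",
                        {"sentence": sent, "token_index": t.index},
                        config,
                    ).features
                )
                labels.append(head_types.get(t.index, NEGATIVE_LABEL))
    model = TokenTermModel(config, seed=seed)
    return model.fit(vectors, labels)


def gold_term_candidates(doc: Document, sent_index: int) -> list[TermCandidate]:
    """Gold term mentions of one sentence, as candidates (oracle source)."""
    sent = doc.sentences[sent_index]
    out = []
    for r in doc.relations:
        if doc.sentence_index_of(r.term) != sent_index:
            continue
        m = r.term
        toks = sent.token_at_offset(m.begin, m.end)
        out.append(
            TermCandidate(
                token_start=toks[0].index,
                token_end=toks[-1].index + 1,
                begin=m.begin, end=m.end, surface=m.surface,
                head_token=m.head_token, type=r.type,
                provenance="gold",
            )
        )
    return out
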