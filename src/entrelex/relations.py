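"""Relation classification.

Two classifier families:

* **edge classification**: one candidate per GGP-term pair in a sentence,
  classified into a relation type or negative with a linear multiclass
  SVM over shortest-dependency-path and blinded lexical features;
* **per-type sentence classification**: one instance per (sentence, GGP)
  pair for every sentence containing at least one GGP, classified by one
  binary RBF-kernel SVM per relation type, with C and gamma chosen by
  5-fold cross-validation on the training data. A positive sentence
  prediction is then resolved to a concrete relation by attaching the
  nearest suitable term candidate within a token window.

Also here: ensemble feature selection — linear SVMs fitted on bootstrap
resamples, features ranked by the magnitude of their mean signed weight —
used both to prune the feature space and to export the most
discriminative patterns per relation type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC, LinearSVC

from ._util import csr32, quiet_convergence
from .errors import DegenerateModelError, ParameterError
from .features import FeatureConfig, FeatureVector, build_instance_vector
from .model import (
    NEGATIVE_LABEL,
    Document,
    EntityMention,
    EntityRelation,
    Sentence,
)
from .semantic import SemanticLexicon
from .terms import TermCandidate


@dataclass
class CVConfig:
    """Cross-validated hyperparameter search settings."""

    folds: int = 5
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple[float, ...] = (0.01, 0.1, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2 or not self.c_grid or not self.gamma_grid:
            raise ParameterError("need folds >= 2 and non-empty grids")


@dataclass
class EdgeCandidate:
    """A potential relation between one GGP and one term candidate."""

    ggp: EntityMention
    term: TermCandidate
    sentence: Sentence
    features: FeatureVector
    label: str = NEGATIVE_LABEL


def generate_candidates(
    sentence: Sentence,
    ggps: list[EntityMention],
    term_candidates: list[TermCandidate],
    config: FeatureConfig | None = None,
    lexicon: SemanticLexicon | None = None,
) -> list[EdgeCandidate]:
    """The cartesian product GGP x term, each pair with edge features."""
    config = config or FeatureConfig()
    out: list[EdgeCandidate] = []
    for g in ggps:
        others = [x for x in ggps if x is not g]
        for tc in term_candidates:
            vec = build_instance_vector(
                "edge",
                {
                    "sentence": sentence,
                    "ggp": g,
                    "term": tc.head_token,
                    "other_ggps": others,
                },
                config,
                lexicon,
            )
            out.append(EdgeCandidate(ggp=g, term=tc, sentence=sentence,
                                     features=vec))
    return out


# ---------------------------------------------------------------------------
# edge model (linear multiclass)


class EdgeModel:
    """Linear multiclass SVM over edge candidates.

    The misclassification penalty C is selected from ``cv.c_grid`` by
    stratified cross-validation accuracy on the training data; fold
    assignment depends only on the seed. Unseen labels at prediction time
    map to the negative class (closed world).
    """

    def __init__(self, config: FeatureConfig, cv: CVConfig):
        self.config = config
        self.cv = cv
        self._vectorizer = DictVectorizer(sparse=True)
        self._svm: LinearSVC | None = None
        self.best_c: float = 1.0

    def fit(self, vectors: list[dict], labels: list[str]) -> "EdgeModel":
        classes = set(labels)
        if classes == {NEGATIVE_LABEL} or len(classes) < 2:
            raise DegenerateModelError(
                "edge training data has no positive class"
            )
        x = csr32(self._vectorizer.fit_transform(vectors))
        y = np.array(labels)
        if len(self.cv.c_grid) > 1:
            folds = min(self.cv.folds, int(np.min(np.bincount(
                np.unique(y, return_inverse=True)[1]))))
            folds = max(folds, 2)
            skf = StratifiedKFold(
                n_splits=folds, shuffle=True, random_state=self.cv.seed
            )
            best = (-1.0, None)
            for c in self.cv.c_grid:
                accs = []
                for tr, te in skf.split(x, y):
                    if len(set(y[tr])) < 2:
                        continue
                    m = LinearSVC(C=c, random_state=self.cv.seed,
                                  max_iter=5000)
                    with quiet_convergence():
                        m.fit(x[tr], y[tr])
                    accs.append(float(np.mean(m.predict(x[te]) == y[te])))
                score = float(np.mean(accs)) if accs else 0.0
                if score > best[0]:
                    best = (score, c)
            self.best_c = best[1]
        else:
            self.best_c = self.cv.c_grid[0]
        self._svm = LinearSVC(C=self.best_c, random_state=self.cv.seed,
                              max_iter=5000)
        self._svm.fit(x, y)
        return self

    def predict(self, candidates: list[EdgeCandidate]) -> list[str]:
        if self._svm is None:
            raise DegenerateModelError("edge model is not fitted")
        if not candidates:
            return []
        x = csr32(self._vectorizer.transform([c.features.features for c in candidates]))
        return [str(lbl) for lbl in self._svm.predict(x)]


def train_edge_model(
    candidates: list[EdgeCandidate],
    cv: CVConfig | None = None,
    config: FeatureConfig | None = None,
) -> EdgeModel:
    """Fit the edge classifier from labelled candidates."""
    cv = cv or CVConfig()
    config = config or FeatureConfig()
    model = EdgeModel(config, cv)
    return model.fit(
        [c.features.features for c in candidates],
        [c.label for c in candidates],
    )


# ---------------------------------------------------------------------------
# per-type sentence models (RBF)


class TypeModel:
    """One binary RBF-SVM for one relation type.

    A type absent from the training data yields an always-negative model
    rather than an error, so prediction over the full closed-world type
    inventory stays total.
    """

    def __init__(self, rel_type: str, cv: CVConfig):
        self.rel_type = rel_type
        self.cv = cv
        self.always_negative = False
        self._vectorizer = DictVectorizer(sparse=True)
        self._svm: SVC | None = None
        self.best_params: tuple[float, float] = (1.0, 0.1)

    def fit(self, vectors: list[dict], positive: list[bool]) -> "TypeModel":
        y = np.array(positive, dtype=int)
        if y.sum() == 0:
            self.always_negative = True
            return self
        x = csr32(self._vectorizer.fit_transform(vectors))
        n_pos = int(y.sum())
        n_neg = int(len(y) - y.sum())
        folds = max(2, min(self.cv.folds, n_pos, n_neg))
        best = (-1.0, self.best_params)
        if n_pos >= 2 and n_neg >= 2 and (
            len(self.cv.c_grid) > 1 or len(self.cv.gamma_grid) > 1
        ):
            skf = StratifiedKFold(n_splits=folds, shuffle=True,
                                  random_state=self.cv.seed)
            for c in self.cv.c_grid:
                for g in self.cv.gamma_grid:
                    f1s = []
                    for tr, te in skf.split(x, y):
                        if y[tr].sum() in (0, len(tr)):
                            continue
                        m = SVC(kernel="rbf", C=c, gamma=g,
                                random_state=self.cv.seed)
                        m.fit(x[tr], y[tr])
                        pred = m.predict(x[te])
                        tp = int(np.sum((pred == 1) & (y[te] == 1)))
                        fp = int(np.sum((pred == 1) & (y[te] == 0)))
                        fn = int(np.sum((pred == 0) & (y[te] == 1)))
                        f1s.append(
                            2 * tp / (2 * tp + fp + fn) if tp else 0.0
                        )
                    score = float(np.mean(f1s)) if f1s else 0.0
                    if score > best[0]:
                        best = (score, (c, g))
            self.best_params = best[1]
        else:
            self.best_params = (self.cv.c_grid[0], self.cv.gamma_grid[0])
        c, g = self.best_params
        self._svm = SVC(kernel="rbf", C=c, gamma=g,
                        random_state=self.cv.seed)
        self._svm.fit(x, y)
        return self

    def predict(self, vectors: list[dict]) -> np.ndarray:
        if self.always_negative:
            return np.zeros(len(vectors), dtype=bool)
        x = csr32(self._vectorizer.transform(vectors))
        return self._svm.predict(x).astype(bool)


def train_type_models(
    vectors: list[FeatureVector],
    label_sets: list[set[str]],
    types: list[str],
    cv: CVConfig | None = None,
) -> dict[str, TypeModel]:
    """One binary model per relation type over (sentence, GGP) instances.

    ``label_sets[i]`` holds the relation types instance *i* realises
    (empty set for negatives).
    """
    cv = cv or CVConfig()
    dicts = [v.features for v in vectors]
    out: dict[str, TypeModel] = {}
    for t in types:
        positives = [t in s for s in label_sets]
        out[t] = TypeModel(t, cv).fit(dicts, positives)
    return out


def attach_terms(
    positive_predictions: list[tuple[Document, int, EntityMention, str]],
    candidate_provider,
    window: int = 5,
) -> list[tuple[str, EntityRelation]]:
    """Resolve positive (document, sentence, GGP, type) predictions to
    concrete relations.

    ``candidate_provider(doc, sent_index, ggp, rel_type)`` must return
    ranked term candidates; the first-ranked one becomes the relation's
    term, and predictions with no candidate are dropped. Returns
    (document id, relation) pairs.
    """
    out: list[tuple[str, EntityRelation]] = []
    k = 0
    for doc, si, ggp, rel_type in positive_predictions:
        cands = candidate_provider(doc, si, ggp, rel_type)
        if not cands:
            continue
        c = cands[0]
        k += 1
        term = EntityMention(
            id=f"TP{k}", kind="term", type_label="Entity",
            begin=c.begin, end=c.end, surface=c.surface,
            head_token=c.head_token,
        )
        out.append(
            (doc.id,
             EntityRelation(id=f"RP{k}", type=rel_type, ggp=ggp, term=term))
        )
    return out


# ---------------------------------------------------------------------------
# ensemble feature selection


@dataclass
class FeatureRanking:
    """Features ranked by the magnitude of their mean signed SVM weight."""

    ranked: list[tuple[str, float]] = field(default_factory=list)
    ensemble_size: int = 1

    def top(self, keep_fraction: float) -> list[str]:
        if not 0 < keep_fraction <= 1:
            raise ParameterError("keep_fraction must be in (0, 1]")
        k = max(1, int(round(keep_fraction * len(self.ranked))))
        return [name for name, _ in self.ranked[:k]]

    def to_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("feature\timportance\n")
            for name, w in self.ranked:
                fh.write(f"{name}\t{w:.6g}\n")


def ensemble_feature_select(
    vectors: list[dict],
    labels: list[bool],
    ensemble_size: int = 10,
    keep_fraction: float = 1.0,
    seed: int = 0,
    max_redraws: int = 20,
) -> FeatureRanking:
    """Rank features by mean signed weight over bootstrap linear SVMs.

    Each of *ensemble_size* fits uses a bootstrap resample of the
    instances; a resample collapsing to one class is redrawn (bounded
    retries). A positive importance marks a feature indicative of the
    positive class.
    """
    if ensemble_size < 1:
        raise ParameterError("ensemble_size must be >= 1")
    if len(set(labels)) < 2:
        raise DegenerateModelError("feature selection needs two classes")
    rng = np.random.default_rng(seed)
    vectorizer = DictVectorizer(sparse=True)
    x = csr32(vectorizer.fit_transform(vectors))
    y = np.array(labels, dtype=int)
    n = x.shape[0]
    total = np.zeros(x.shape[1])
    for b in range(ensemble_size):
        if ensemble_size == 1:
            idx = np.arange(n)
        else:
            idx = rng.integers(0, n, size=n)
            redraws = 0
            while len(set(y[idx])) < 2:
                redraws += 1
                if redraws > max_redraws:
                    raise DegenerateModelError(
                        "could not draw a two-class bootstrap resample"
                    )
                idx = rng.integers(0, n, size=n)
        m = LinearSVC(C=1.0, random_state=seed, max_iter=5000)
        m.fit(x[idx], y[idx])
        total += m.coef_.ravel()
    mean_w = total / ensemble_size
    names = vectorizer.get_feature_names_out()
    order = np.argsort(-np.abs(mean_w), kind="stable")
    ranking = FeatureRanking(
        ranked=[(str(names[i]), float(mean_w[i])) for i in order],
        ensemble_size=ensemble_size,
    )
    if keep_fraction < 1.0:
        keep = set(ranking.top(keep_fraction))
        ranking.ranked = [
            (nm, w) for nm, w in ranking.ranked if nm in keep
        ]
    return ranking
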