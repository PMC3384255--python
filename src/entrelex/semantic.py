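"""Semantic lexicon induction.

Groups lexical variants and synonyms of molecular domain terms ("complex",
"heterodimer", ...) so that downstream feature generation can generalise
over them. Two lexicon sources are supported:

* a **distributional** lexicon: terms are embedded by latent semantic
  analysis (LSA) of a term-context co-occurrence matrix built from a raw
  corpus, and the resulting vectors are grouped with the Markov Cluster
  algorithm (MCL) over a cosine-similarity graph;
* a **category** lexicon mapping lexical patterns (normalised term
  strings) to semantic categories such as ``DNA-domain-or-region`` or
  ``protein-family-or-group``, built from term-category annotation
  records.

Cluster quality is rated by the heuristic ``S = Unknown x HG x
Reliability``: ``Known``/``Unknown`` count the labelled and unlabelled
terms of a cluster, ``HG`` (homogeneity) is the majority-label fraction
among the labelled ones, and ``Reliability = Known / (Known + Unknown)``.
A cluster is valuable when it is homogeneous, anchored by enough labelled
terms, and still covers many unlabelled terms whose label it predicts; a
whole clustering is scored as the sum over its clusters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from collections import Counter

import numpy as np
import scipy.sparse as sp

from .errors import DimensionError, EmptyMatrixError, ParameterError
from .stemming import porter_stem


def normalize_term(surface: str) -> str:
    """Lowercase Porter stem; multi-word terms are stemmed word-wise."""
    if not surface:
        return ""
    return " ".join(porter_stem(w) for w in surface.split())


# ---------------------------------------------------------------------------
# semantic spaces


@dataclass
class SemanticSpace:
    """Terms embedded as real-valued vectors of a reduced context space."""

    vocabulary: list[str]
    vectors: np.ndarray  # shape (len(vocabulary), dims)
    dims: int

    def __post_init__(self) -> None:
        if self.vectors.shape != (len(self.vocabulary), self.dims):
            raise DimensionError(
                f"vectors shape {self.vectors.shape} inconsistent with "
                f"{len(self.vocabulary)} terms x {self.dims} dims"
            )

    def vector(self, term: str) -> np.ndarray:
        return self.vectors[self.vocabulary.index(term)]


def build_term_context_matrix(
    sentences: list[list[str]], window: int = 2, min_count: int = 1
) -> tuple[list[str], sp.csr_matrix]:
    """Windowed co-occurrence counts over normalised, tokenised sentences.

    Rows (and columns) are the terms occurring at least *min_count* times;
    entry (i, j) counts how often term j appears within *window* tokens of
    an occurrence of term i, within a sentence.
    """
    freq: Counter[str] = Counter()
    for sent in sentences:
        freq.update(sent)
    vocab = sorted(t for t, c in freq.items() if c >= min_count)
    if not vocab:
        raise EmptyMatrixError(
            "no term reaches min_count; term-context matrix would be empty"
        )
    index = {t: i for i, t in enumerate(vocab)}
    rows: list[int] = []
    cols: list[int] = []
    for sent in sentences:
        for i, tok in enumerate(sent):
            ti = index.get(tok)
            if ti is None:
                continue
            lo = max(0, i - window)
            hi = min(len(sent), i + window + 1)
            for j in range(lo, hi):
                if j == i:
                    continue
                cj = index.get(sent[j])
                if cj is not None:
                    rows.append(ti)
                    cols.append(cj)
    n = len(vocab)
    mat = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    ).tocsr()
    return vocab, mat


def lsa_reduce(vocab: list[str], counts: sp.spmatrix, k: int) -> SemanticSpace:
    """Latent semantic analysis: rank-*k* truncated SVD of the log-scaled
    count matrix.

    Counts are damped as log(1 + c) before decomposition. Term vectors are
    the row projections U_k * S_k. Each singular component's sign is fixed
    so that its largest-magnitude loading is positive, making the output
    deterministic.
    """
    dense = np.asarray(counts.todense(), dtype=float)
    if k < 1 or k > min(dense.shape):
        raise ParameterError(
            f"k={k} outside valid range 1..{min(dense.shape)}"
        )
    weighted = np.log1p(dense)
    u, s, vt = np.linalg.svd(weighted, full_matrices=False)
    for j in range(k):
        lead = vt[j, np.argmax(np.abs(vt[j]))]
        if lead < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    vectors = u[:, :k] * s[:k]
    return SemanticSpace(vocabulary=list(vocab), vectors=vectors, dims=k)


def cosine_sim(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between *u* and *v*; 0 if either is zero."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise DimensionError(f"shape mismatch {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


# ---------------------------------------------------------------------------
# Markov clustering


@dataclass
class Clustering:
    """A disjoint partition of a term set, with the MCL parameters used."""

    clusters: list[list[str]]
    inflation: float = 2.0
    similarity_threshold: float = 0.5

    def as_mapping(self) -> dict[str, int]:
        return {t: i for i, grp in enumerate(self.clusters) for t in grp}


def markov_cluster(
    nodes: list[str],
    similarity: np.ndarray,
    inflation: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> Clustering:
    """Markov Cluster algorithm over a weighted similarity graph.

    Self-loops of weight 1 are added, columns are normalised to a
    stochastic flow matrix, and expansion (matrix squaring) alternates
    with inflation (entrywise power, then renormalisation) until the
    matrix changes by less than *tol* or *max_iter* rounds have run. Each
    node joins the cluster of the attractor receiving most of its flow;
    ties go to the lowest attractor index. Nodes in different connected
    components can never end up in one cluster, because the flow matrix
    stays block-diagonal throughout.
    """
    if inflation <= 1.0:
        raise ParameterError(f"inflation must exceed 1, got {inflation}")
    n = len(nodes)
    if n == 0:
        return Clustering(clusters=[], inflation=inflation)
    m = np.array(similarity, dtype=float)
    if m.shape != (n, n):
        raise DimensionError(f"similarity must be {n}x{n}, got {m.shape}")
    if (m < 0).any():
        raise ParameterError("similarity weights must be non-negative")
    m = np.maximum(m, m.T)  # undirected graph
    np.fill_diagonal(m, np.maximum(m.diagonal(), 1.0))  # self-loops

    def _col_normalize(a: np.ndarray) -> np.ndarray:
        s = a.sum(axis=0)
        s[s == 0.0] = 1.0
        return a / s

    m = _col_normalize(m)
    for _ in range(max_iter):
        expanded = m @ m
        inflated = _col_normalize(expanded**inflation)
        inflated[inflated < 1e-12] = 0.0
        inflated = _col_normalize(inflated)
        if np.max(np.abs(inflated - m)) < tol:
            m = inflated
            break
        m = inflated
    # attractor of node j = row with the highest flow in column j
    attractor = np.argmax(m, axis=0)  # argmax takes the lowest index on ties
    groups: dict[int, list[str]] = {}
    for j in range(n):
        groups.setdefault(int(attractor[j]), []).append(nodes[j])
    clusters = [groups[a] for a in sorted(groups)]
    return Clustering(clusters=clusters, inflation=inflation)


def cluster_terms(
    space: SemanticSpace,
    threshold: float = 0.5,
    inflation: float = 2.0,
) -> Clustering:
    """Cosine-similarity graph over a semantic space, clustered with MCL.

    An edge joins two terms iff their cosine similarity is at least
    *threshold*; edge weight is the similarity itself.
    """
    n = len(space.vocabulary)
    sim = np.zeros((n, n))
    norms = np.linalg.norm(space.vectors, axis=1)
    safe = np.where(norms == 0.0, 1.0, norms)
    unit = space.vectors / safe[:, None]
    cos = unit @ unit.T
    sim[cos >= threshold] = cos[cos >= threshold]
    np.fill_diagonal(sim, 0.0)
    out = markov_cluster(space.vocabulary, sim, inflation=inflation)
    out.similarity_threshold = threshold
    return out


# ---------------------------------------------------------------------------
# cluster scoring


@dataclass
class ClusterScore:
    known: int
    unknown: int
    hg: float
    reliability: float
    s: float


def compute_cluster_score(
    terms: list[str], label_lookup: dict[str, str]
) -> ClusterScore:
    """Score one cluster by S = Unknown x HG x Reliability.

    *label_lookup* maps a term to its gold relation-type label; terms
    absent from the mapping count as Unknown. Degenerate clusters (empty,
    no labels, or no unlabelled members) score 0 rather than erroring.
    """
    labels = [label_lookup[t] for t in terms if t in label_lookup]
    known = len(labels)
    unknown = len(terms) - known
    hg = (Counter(labels).most_common(1)[0][1] / known) if known else 0.0
    total = known + unknown
    reliability = known / total if total else 0.0
    s = unknown * hg * reliability
    return ClusterScore(known=known, unknown=unknown, hg=hg,
                        reliability=reliability, s=s)


def score_clustering(
    clustering: Clustering, label_lookup: dict[str, str]
) -> float:
    """Total score of a clustering: sum of per-cluster S."""
    return sum(
        compute_cluster_score(grp, label_lookup).s
        for grp in clustering.clusters
    )


# ---------------------------------------------------------------------------
# category lexicon


@dataclass
class CategoryLexicon:
    """Normalised lexical pattern -> semantic category."""

    entries: dict[str, str] = field(default_factory=dict)

    def lookup(self, surface: str) -> str | None:
        return self.entries.get(normalize_term(surface))


def build_category_lexicon(
    records: list[tuple[str, str]]
) -> CategoryLexicon:
    """Aggregate (surface, category) records into a category lexicon.

    Conflicting categories for one normalised pattern are resolved by
    majority vote, ties by lexicographically smallest category.
    """
    votes: dict[str, Counter[str]] = {}
    for surface, category in records:
        votes.setdefault(normalize_term(surface), Counter())[category] += 1
    entries = {}
    for pattern, counter in votes.items():
        top = max(counter.values())
        entries[pattern] = min(c for c, n in counter.items() if n == top)
    return CategoryLexicon(entries=entries)


# ---------------------------------------------------------------------------
# combined lexicon bundle


@dataclass
class SemanticLexicon:
    """Cluster and category lexicons bundled for feature generation."""

    clusters: dict[str, int] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def classes_of(self, token_stem: str) -> list[str]:
        """Semantic class labels a normalised token maps to (may be [])."""
        out: list[str] = []
        if token_stem in self.clusters:
            out.append(f"cluster{self.clusters[token_stem]}")
        if token_stem in self.categories:
            out.append(self.categories[token_stem])
        return out

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {"clusters": self.clusters, "categories": self.categories},
                fh, indent=1, sort_keys=True,
            )

    @classmethod
    def from_json(cls, path: str) -> "SemanticLexicon":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        return cls(
            clusters={k: int(v) for k, v in data.get("clusters", {}).items()},
            categories=dict(data.get("categories", {})),
        )


def build_distributional_lexicon(
    sentences: list[list[str]],
    dims: int = 10,
    window: int = 2,
    min_count: int = 2,
    threshold: float = 0.5,
    inflation: float = 2.0,
    method: str = "lsa",
) -> tuple[SemanticLexicon, Clustering]:
    """Full induction pipeline: counts -> LSA -> MCL -> term->cluster map.

    ``method`` selects the semantic space builder. Only ``"lsa"`` is
    implemented; ``"hal"``, ``"coals"`` and ``"ri"`` are declared
    interface slots and raise :class:`NotImplementedError`.
    """
    if method != "lsa":
        if method in ("hal", "coals", "ri"):
            raise NotImplementedError(
                f"semantic space builder {method!r} is an interface slot "
                f"only; use 'lsa'"
            )
        raise ParameterError(f"unknown semantic space method {method!r}")
    vocab, counts = build_term_context_matrix(
        sentences, window=window, min_count=min_count
    )
    k = min(dims, min(counts.shape))
    space = lsa_reduce(vocab, counts, k)
    clustering = cluster_terms(space, threshold=threshold, inflation=inflation)
    return SemanticLexicon(clusters=clustering.as_mapping()), clustering
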