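"""Sparse named-feature extraction for classification instances.

Three instance granularities feed the classifiers:

* **token** instances (term detection): dependency walks up to a fixed
  depth centred on the candidate token, plus the token's own attributes;
* **edge** instances (relation classification of a GGP-term pair): the
  shortest dependency path between the two heads, plus blinded lexical
  context;
* **sentence** instances (per-GGP sentence classification): bag-of-words
  and n-grams over the blinded sentence, part-of-speech n-grams, and
  semantic-class generalisations.

Blinding replaces the candidate GGP with ``protx`` and every co-occurring
GGP with ``exprotx`` so lexical features generalise across gene names; the
hidden surfaces are kept as separate content features. Tokens found in a
semantic lexicon additionally emit their cluster number or category as a
class-level feature, and class-substituted n-grams.

All features are binary (presence); a :class:`FeatureVector` is a sparse
mapping from stable printable names to 1.0. Extraction is pure: equal
inputs always give equal vectors.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .errors import ConfigError, InstanceError
from .model import EntityMention, Sentence
from .semantic import SemanticLexicon

GGP_PLACEHOLDER = "protx"
OTHER_GGP_PLACEHOLDER = "exprotx"


@dataclass
class FeatureVector:
    features: dict[str, float] = field(default_factory=dict)
    instance_id: str = ""

    def add(self, name: str, value: float = 1.0) -> None:
        if value != 0.0:
            self.features[name] = value

    def update(self, fragment: dict[str, float]) -> None:
        for k, v in fragment.items():
            self.add(k, v)


@dataclass
class FeatureConfig:
    """Switches and sizes for the feature families.

    ``ngram_n`` lists the n-gram orders over the blinded sentence (n=1 is
    plain bag-of-words). ``dep_depth`` bounds the dependency walks of
    token instances. ``window`` restricts sentence n-grams to a token
    window around the candidate GGP; ``None`` means the whole sentence.
    """

    ngram_n: tuple[int, ...] = (1, 2, 3)
    dep_depth: int = 3
    use_semantic_blinding: bool = True
    use_pos_generalization: bool = True
    pos_ngram_n: tuple[int, ...] = (2,)
    window: int | None = None
    use_dep_walks: bool = True
    use_path: bool = True
    use_ngrams: bool = True

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.ngram_n) or self.dep_depth < 1:
            raise ConfigError("ngram orders and dep_depth must be >= 1")


# ---------------------------------------------------------------------------
# lexical fragments


def blind_sentence(
    sentence: Sentence,
    candidate_ggp: EntityMention,
    other_ggps: list[EntityMention] = (),
) -> tuple[list[str], dict[str, float]]:
    """Blinded token sequence plus GGP content features.

    The candidate GGP's tokens collapse to a single ``protx`` token, each
    co-occurring GGP to ``exprotx``; all remaining tokens appear as their
    lowercase stems. Returns (blinded tokens, content-feature fragment).
    """
    cand_idx = {t.index for t in
                sentence.token_at_offset(candidate_ggp.begin, candidate_ggp.end)}
    if not cand_idx:
        raise InstanceError(
            f"candidate GGP {candidate_ggp.id} does not align to any token "
            f"of the sentence"
        )
    other_idx: dict[int, EntityMention] = {}
    for g in other_ggps:
        for t in sentence.token_at_offset(g.begin, g.end):
            other_idx[t.index] = g
    blinded: list[str] = []
    content = {f"ggpcontent:{candidate_ggp.surface.lower()}": 1.0}
    cand_emitted = False
    for t in sentence.tokens:
        if t.index in cand_idx:
            if not cand_emitted:
                blinded.append(GGP_PLACEHOLDER)
                cand_emitted = True
        elif t.index in other_idx:
            g = other_idx[t.index]
            first = min(
                tt.index for tt in sentence.token_at_offset(g.begin, g.end)
            )
            if t.index == first:
                blinded.append(OTHER_GGP_PLACEHOLDER)
                content[f"exggpcontent:{g.surface.lower()}"] = 1.0
        else:
            blinded.append(t.stem)
    return blinded, content


def ngram_features(tokens: list[str], n: int) -> dict[str, float]:
    """Binary features for the distinct n-grams of consecutive tokens."""
    out: dict[str, float] = {}
    for i in range(len(tokens) - n + 1):
        out[f"ng{n}:" + "_".join(tokens[i:i + n])] = 1.0
    return out


def pos_ngram_features(sentence: Sentence, n: int) -> dict[str, float]:
    """n-grams over the part-of-speech tag sequence."""
    tags = [t.pos for t in sentence.tokens]
    if any(not tag for tag in tags):
        raise ConfigError("POS tags missing; cannot build POS n-grams")
    out: dict[str, float] = {}
    for i in range(len(tags) - n + 1):
        out[f"pos{n}:" + "_".join(tags[i:i + n])] = 1.0
    return out


def semantic_class_features(
    blinded_tokens: list[str],
    lexicon: SemanticLexicon | None,
    ngram_n: tuple[int, ...] = (2, 3),
) -> dict[str, float]:
    """Class-level generalisations from the semantic lexicons.

    Every token with a lexicon hit contributes ``sem:<class>`` features
    alongside (not replacing) its lexical features, and n-grams are
    re-emitted with hit tokens substituted by their first class label
    (``semng<n>:...``); only n-grams containing at least one substitution
    are kept.
    """
    out: dict[str, float] = {}
    if lexicon is None:
        return out
    substituted: list[str] = []
    hit: list[bool] = []
    for tok in blinded_tokens:
        classes = lexicon.classes_of(tok)
        for c in classes:
            out[f"sem:{c}"] = 1.0
        substituted.append(classes[0] if classes else tok)
        hit.append(bool(classes))
    for n in ngram_n:
        for i in range(len(substituted) - n + 1):
            if any(hit[i:i + n]):
                out[f"semng{n}:" + "_".join(substituted[i:i + n])] = 1.0
    return out


# ---------------------------------------------------------------------------
# dependency-graph fragments


def _adjacency(
    sentence: Sentence,
) -> dict[int, list[tuple[int, str, str]]]:
    """Undirected adjacency: node -> [(neighbour, label, direction)].

    Direction ``">"`` steps from governor to dependent, ``"<"`` the
    reverse.
    """
    adj: dict[int, list[tuple[int, str, str]]] = {
        t.index: [] for t in sentence.tokens
    }
    for e in sentence.dep_edges:
        adj[e.governor].append((e.dependent, e.label, ">"))
        adj[e.dependent].append((e.governor, e.label, "<"))
    for k in adj:
        adj[k].sort(key=lambda x: (x[1], x[0]))
    return adj


def shortest_dep_path(
    sentence: Sentence, a: int, b: int
) -> list[tuple[int, str, str]] | None:
    """Shortest undirected path through the dependency graph.

    Returns the steps from *a* to *b* as (token index, edge label,
    direction) triples; the empty list for a == b; ``None`` when the
    tokens are disconnected. Among equal-length paths the
    lexicographically smallest by (edge label, token index) per step is
    returned.
    """
    if a == b:
        return []
    adj = _adjacency(sentence)
    if a not in adj or b not in adj:
        raise InstanceError(f"token index {a if a not in adj else b} not in sentence")
    dist = {a: 0}
    q = deque([a])
    while q:
        u = q.popleft()
        for v, _, _ in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    if b not in dist:
        return None
    # walk back from b, at each level picking the smallest (label, index)
    steps: list[tuple[int, str, str]] = []
    cur = b
    while cur != a:
        preds = [
            (lbl, v, d) for v, lbl, d in adj[cur]
            if dist.get(v) == dist[cur] - 1
        ]
        lbl, v, d = min(preds)
        # d is the direction cur->v; the path step v->cur is its inverse
        steps.append((cur, lbl, "<" if d == ">" else ">"))
        cur = v
    steps.reverse()
    return steps


def path_features(
    sentence: Sentence, a: int, b: int
) -> dict[str, float]:
    """Features of the shortest dependency path between two tokens."""
    path = shortest_dep_path(sentence, a, b)
    out: dict[str, float] = {}
    if path is None:
        out["path:NONE"] = 1.0
        return out
    labels = "_".join(f"{d}{lbl}" for _, lbl, d in path)
    out[f"path:{labels or 'SELF'}"] = 1.0
    out[f"pathlen:{len(path)}"] = 1.0
    toks = {t.index: t for t in sentence.tokens}
    for tok_idx, lbl, d in path:
        out[f"pathstep:{d}{lbl}"] = 1.0
        out[f"pathtok:{toks[tok_idx].stem}"] = 1.0
    return out


def dep_walk_features(
    sentence: Sentence, center: int, depth: int = 3
) -> dict[str, float]:
    """Labelled dependency walks up to *depth* steps from a centre token.

    Each walk (a simple path in the undirected dependency graph) yields
    features encoding its direction/label sequence together with the end
    token's stem and POS tag. The zero-length walk contributes the
    centre's own attribute features.
    """
    toks = {t.index: t for t in sentence.tokens}
    if center not in toks:
        raise InstanceError(f"token index {center} not in sentence")
    adj = _adjacency(sentence)
    out: dict[str, float] = {
        f"tok:stem={toks[center].stem}": 1.0,
        f"tok:pos={toks[center].pos}": 1.0,
    }

    def _walk(node: int, steps: list[str], visited: set[int]) -> None:
        if len(steps) == depth:
            return
        for v, lbl, d in adj[node]:
            if v in visited:
                continue
            seq = steps + [f"{d}{lbl}"]
            prefix = "dw:" + "_".join(seq)
            out[f"{prefix}:stem={toks[v].stem}"] = 1.0
            out[f"{prefix}:pos={toks[v].pos}"] = 1.0
            _walk(v, seq, visited | {v})

    _walk(center, [], {center})
    return out


# ---------------------------------------------------------------------------
# instance assembly


def _windowed(
    blinded: list[str], window: int | None
) -> list[str]:
    if window is None:
        return blinded
    try:
        at = blinded.index(GGP_PLACEHOLDER)
    except ValueError:
        return blinded
    return blinded[max(0, at - window): at + window + 1]


def build_instance_vector(
    kind: str,
    context: dict,
    config: FeatureConfig | None = None,
    lexicon: SemanticLexicon | None = None,
    instance_id: str = "",
) -> FeatureVector:
    """Assemble the full feature vector for one classification instance.

    ``kind`` selects the recipe: ``"token"`` needs ``sentence`` and
    ``token_index``; ``"edge"`` needs ``sentence``, ``ggp`` and ``term``
    (mentions or head token indices); ``"sentence"`` needs ``sentence``
    and ``ggp``. ``other_ggps`` is optional everywhere.
    """
    config = config or FeatureConfig()
    vec = FeatureVector(instance_id=instance_id)
    try:
        sentence: Sentence = context["sentence"]
    except KeyError as exc:
        raise InstanceError("context lacks 'sentence'") from exc

    if kind == "token":
        try:
            idx = context["token_index"]
        except KeyError as exc:
            raise InstanceError("token instance lacks 'token_index'") from exc
        if config.use_dep_walks:
            vec.update(dep_walk_features(sentence, idx, config.dep_depth))
        return vec

    try:
        ggp: EntityMention = context["ggp"]
    except KeyError as exc:
        raise InstanceError(f"{kind} instance lacks 'ggp'") from exc
    other = list(context.get("other_ggps", []))
    blinded, content = blind_sentence(sentence, ggp, other)
    vec.update(content)

    if kind == "edge":
        try:
            term = context["term"]
        except KeyError as exc:
            raise InstanceError("edge instance lacks 'term'") from exc
        term_head = term if isinstance(term, int) else term.head_token
        if config.use_path:
            vec.update(path_features(sentence, ggp.head_token, term_head))
        term_tok = next(
            (t for t in sentence.tokens if t.index == term_head), None
        )
        if term_tok is not None:
            vec.add(f"termstem:{term_tok.stem}")
            vec.add(f"termpos:{term_tok.pos}")
            if lexicon is not None and config.use_semantic_blinding:
                for c in lexicon.classes_of(term_tok.stem):
                    vec.add(f"termsem:{c}")
    elif kind != "sentence":
        raise InstanceError(f"unknown instance kind {kind!r}")

    scoped = _windowed(blinded, config.window)
    if config.use_ngrams:
        for n in config.ngram_n:
            vec.update(ngram_features(scoped, n))
    if config.use_semantic_blinding and lexicon is not None:
        vec.update(
            semantic_class_features(
                scoped, lexicon,
                tuple(n for n in config.ngram_n if n >= 1),
            )
        )
    if config.use_pos_generalization:
        for n in config.pos_ngram_n:
            vec.update(pos_ngram_features(sentence, n))
    return vec
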