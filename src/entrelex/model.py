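"""Core data model: annotated, dependency-parsed documents.

A :class:`Document` is the unit every pipeline stage operates on. It holds
the raw text, a sentence segmentation with tokens and dependency edges, and
two layers of standoff annotation: gene/gene-product (GGP) mentions and
domain-term mentions, linked by typed entity relations. Character offsets
are 0-based and end-exclusive everywhere.

An entity relation always connects exactly one GGP and one domain term, and
both mentions lie within a single sentence. Relations realised inside one
noun phrase (e.g. "Esr-1 promoter") carry ``embedded=True``; relations
between separate nominals are non-embedded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import MalformedAnnotationError

#: The four entity-relation types handled throughout the toolkit.
RELATION_TYPES = (
    "Subunit-Complex",
    "Protein-Component",
    "Member-Collection",
    "Equivalence",
)

#: Label used for the negative class in every classifier.
NEGATIVE_LABEL = "neg"

#: Token index marker for the syntactic root (no governor inside sentence).
ROOT = -1


@dataclass
class Token:
    """A word token inside a sentence.

    ``begin``/``end`` are character offsets into the *document* text;
    ``index`` is the 0-based position within the sentence. ``stem`` is the
    lowercase Porter stem of the surface form.
    """

    index: int
    begin: int
    end: int
    surface: str
    pos: str
    stem: str

    def __post_init__(self) -> None:
        if self.begin >= self.end:
            raise MalformedAnnotationError(
                f"token {self.index}: begin {self.begin} >= end {self.end}"
            )


@dataclass(frozen=True)
class DependencyEdge:
    """A labelled syntactic dependency between two tokens of one sentence.

    ``governor`` and ``dependent`` are sentence-local token indices. The
    root token is not represented as an edge; it simply has no incoming
    edge.
    """

    governor: int
    dependent: int
    label: str


@dataclass
class Sentence:
    """A sentence span with its token and dependency layers."""

    begin: int
    end: int
    tokens: list[Token] = field(default_factory=list)
    dep_edges: list[DependencyEdge] = field(default_factory=list)

    def token_at_offset(self, begin: int, end: int) -> list[Token]:
        """Tokens overlapping the character span [begin, end)."""
        return [t for t in self.tokens if t.begin < end and t.end > begin]

    def governor_of(self, idx: int) -> int:
        """Token index of *idx*'s governor, or ``ROOT`` if it has none."""
        for e in self.dep_edges:
            if e.dependent == idx:
                return e.governor
        return ROOT

    def dependents_of(self, idx: int) -> list[tuple[int, str]]:
        return [(e.dependent, e.label) for e in self.dep_edges if e.governor == idx]


@dataclass
class EntityMention:
    """A character-offset-anchored mention: a GGP or a domain term.

    ``head_token`` is the sentence-local index of the mention's syntactic
    head token (multi-token mentions are represented by their head). It is
    -1 until the mention has been aligned to a sentence.
    """

    id: str
    kind: str  # "ggp" | "term"
    type_label: str
    begin: int
    end: int
    surface: str
    head_token: int = -1

    def span(self) -> tuple[int, int]:
        return (self.begin, self.end)


@dataclass
class EntityRelation:
    """A typed link between one GGP mention and one domain-term mention."""

    id: str
    type: str
    ggp: EntityMention
    term: EntityMention
    embedded: bool = False

    def __post_init__(self) -> None:
        if self.ggp.kind != "ggp" or self.term.kind != "term":
            raise MalformedAnnotationError(
                f"relation {self.id}: arguments must be one GGP and one term, "
                f"got kinds ({self.ggp.kind}, {self.term.kind})"
            )


@dataclass
class Document:
    id: str
    text: str
    sentences: list[Sentence] = field(default_factory=list)
    ggp_mentions: list[EntityMention] = field(default_factory=list)
    term_mentions: list[EntityMention] = field(default_factory=list)
    relations: list[EntityRelation] = field(default_factory=list)

    def sentence_of(self, mention: EntityMention) -> Sentence:
        """The unique sentence whose span contains *mention*."""
        for s in self.sentences:
            if s.begin <= mention.begin and mention.end <= s.end:
                return s
        raise MalformedAnnotationError(
            f"document {self.id}: mention {mention.id} "
            f"[{mention.begin},{mention.end}) lies in no sentence"
        )

    def sentence_index_of(self, mention: EntityMention) -> int:
        for i, s in enumerate(self.sentences):
            if s.begin <= mention.begin and mention.end <= s.end:
                return i
        raise MalformedAnnotationError(
            f"document {self.id}: mention {mention.id} lies in no sentence"
        )

    def validate(self) -> None:
        """Check the structural invariants; raise on the first violation.

        Sentence spans must be ordered, non-overlapping and inside the
        text; mention surfaces must equal their text slice; every relation
        must join one GGP and one term within a single sentence.
        """
        prev_end = 0
        for s in self.sentences:
            if s.begin < prev_end or s.end > len(self.text) or s.begin >= s.end:
                raise MalformedAnnotationError(
                    f"document {self.id}: bad sentence span [{s.begin},{s.end})"
                )
            prev_end = s.end
            for t in s.tokens:
                if t.begin < s.begin or t.end > s.end:
                    raise MalformedAnnotationError(
                        f"document {self.id}: token span [{t.begin},{t.end}) "
                        f"outside sentence [{s.begin},{s.end})"
                    )
            n = len(s.tokens)
            for e in s.dep_edges:
                if e.governor == e.dependent:
                    raise MalformedAnnotationError(
                        f"document {self.id}: self-loop dependency on {e.governor}"
                    )
                if not (0 <= e.governor < n and 0 <= e.dependent < n):
                    raise MalformedAnnotationError(
                        f"document {self.id}: dependency index out of range"
                    )
        for m in self.ggp_mentions + self.term_mentions:
            if self.text[m.begin:m.end] != m.surface:
                raise MalformedAnnotationError(
                    f"document {self.id}: mention {m.id} surface "
                    f"{m.surface!r} != text slice "
                    f"{self.text[m.begin:m.end]!r}"
                )
        mention_ids = {id(m) for m in self.ggp_mentions + self.term_mentions}
        for r in self.relations:
            if id(r.ggp) not in mention_ids or id(r.term) not in mention_ids:
                raise MalformedAnnotationError(
                    f"document {self.id}: relation {r.id} references a "
                    f"mention not attached to this document"
                )
            if self.sentence_index_of(r.ggp) != self.sentence_index_of(r.term):
                raise MalformedAnnotationError(
                    f"document {self.id}: relation {r.id} spans two sentences"
                )
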