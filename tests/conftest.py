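"""Shared fixtures and construction helpers for the test suite."""

from __future__ import annotations

import pytest

from entrelex.model import (
    DependencyEdge,
    Document,
    EntityMention,
    EntityRelation,
    Sentence,
    Token,
)
from entrelex.stemming import porter_stem
from entrelex.synth import SynthConfig, generate_corpus


def make_sentence(
    tokens: list[tuple[str, str]],
    edges: list[tuple[int, int, str]],
    begin: int = 0,
) -> Sentence:
    """Build a sentence from (surface, POS) pairs joined by single spaces."""
    sent = Sentence(begin=begin, end=begin)
    cursor = begin
    for i, (surface, pos) in enumerate(tokens):
        sent.tokens.append(
            Token(index=i, begin=cursor, end=cursor + len(surface),
                  surface=surface, pos=pos, stem=porter_stem(surface))
        )
        cursor += len(surface) + 1
    sent.end = cursor - 1
    sent.dep_edges = [DependencyEdge(g, d, lbl) for g, d, lbl in edges]
    return sent


def sentence_text(sent: Sentence) -> str:
    return " ".join(t.surface for t in sent.tokens)


def mention_for(sent: Sentence, token_index: int, mid: str, kind: str,
                type_label: str | None = None) -> EntityMention:
    t = sent.tokens[token_index]
    return EntityMention(
        id=mid, kind=kind,
        type_label=type_label or ("Protein" if kind == "ggp" else "Entity"),
        begin=t.begin, end=t.end, surface=t.surface, head_token=t.index,
    )


def make_document(
    sentences: list[Sentence],
    ggps: list[EntityMention] = (),
    terms: list[EntityMention] = (),
    relations: list[EntityRelation] = (),
    doc_id: str = "doc0000",
) -> Document:
    text = " ".join(sentence_text(s) for s in sentences)
    doc = Document(id=doc_id, text=text, sentences=list(sentences),
                   ggp_mentions=list(ggps), term_mentions=list(terms),
                   relations=list(relations))
    doc.validate()
    return doc


@pytest.fixture(scope="session")
def small_corpus():
    """A 60-document synthetic corpus shared by the cheaper tests."""
    return generate_corpus(
        SynthConfig(seed=20260930, n_documents=60, sentences_per_document=3)
    )
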