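"""Standoff and parse-file I/O.

Documents live in four sibling files sharing a basename:

``.txt``
    the raw UTF-8 document text;
``.a1``
    given GGP mentions, one per line: ``Tid<TAB>Type begin end<TAB>surface``;
``.rel``
    domain-term mentions (same ``T`` line format) and entity relations:
    ``Rid<TAB>Type Arg1:Tggp Arg2:Tterm`` — Arg1 is always the GGP, Arg2
    the term;
``.dep``
    the dependency parse, one blank-line-separated block per sentence. Each
    block opens with a header ``#sent <begin> <end>`` anchoring the
    sentence in the text, followed by CoNLL-style token lines
    ``ID<TAB>FORM<TAB>POS<TAB>HEAD<TAB>DEPREL`` with 1-based HEAD (0 =
    root).

Offsets are 0-based, end-exclusive. Sentence segmentation is always taken
from the parse file, never recomputed. Mention surfaces are verified
against the text slice on read; any disagreement raises
:class:`~entrelex.errors.MalformedAnnotationError` naming the line.
"""

from __future__ import annotations

import os
import re

from .errors import (
    AlignmentError,
    MalformedAnnotationError,
    UnresolvedReferenceError,
    WriteError,
)
from .model import (
    ROOT,
    DependencyEdge,
    Document,
    EntityMention,
    EntityRelation,
    Sentence,
    Token,
)
from .stemming import porter_stem

#: Dependency labels that realise a relation inside a single noun phrase.
_NP_INTERNAL_LABELS = frozenset({"nn", "compound", "amod", "appos"})

_T_LINE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")
_R_LINE = re.compile(r"^(R\d+)\t(\S+) Arg1:(T\d+) Arg2:(T\d+)\s*$")


def read_parse_file(path: str, text: str) -> list[Sentence]:
    """Read a ``.dep`` file into sentences anchored in *text*.

    Token character offsets are recovered by scanning for each FORM in
    order inside the sentence span; a FORM that cannot be found raises
    :class:`AlignmentError`.
    """
    sentences: list[Sentence] = []
    with open(path, encoding="utf-8") as fh:
        blocks = [b for b in fh.read().split("\n\n") if b.strip()]
    for block in blocks:
        lines = [ln for ln in block.splitlines() if ln.strip()]
        header = lines[0]
        if not header.startswith("#sent"):
            raise MalformedAnnotationError(
                f"{path}: block does not start with '#sent' header: {header!r}"
            )
        try:
            _, b, e = header.split()
            begin, end = int(b), int(e)
        except ValueError as exc:
            raise MalformedAnnotationError(
                f"{path}: bad sentence header {header!r}"
            ) from exc
        if end > len(text):
            raise MalformedAnnotationError(
                f"{path}: sentence span [{begin},{end}) exceeds text length"
            )
        sent = Sentence(begin=begin, end=end)
        cursor = begin
        heads: list[tuple[int, int, str]] = []
        for i, ln in enumerate(lines[1:]):
            cols = ln.split("\t")
            if len(cols) != 5:
                raise MalformedAnnotationError(
                    f"{path}: expected 5 tab-separated columns: {ln!r}"
                )
            _, form, pos, head, deprel = cols
            at = text.find(form, cursor, end)
            if at < 0:
                raise AlignmentError(
                    f"{path}: token {form!r} not found in sentence "
                    f"[{begin},{end}) after offset {cursor}"
                )
            sent.tokens.append(
                Token(
                    index=i,
                    begin=at,
                    end=at + len(form),
                    surface=form,
                    pos=pos,
                    stem=porter_stem(form),
                )
            )
            cursor = at + len(form)
            heads.append((i, int(head), deprel))
        n = len(sent.tokens)
        for dep, head, label in heads:
            if head == 0:
                continue  # root: no incoming edge
            gov = head - 1
            if not (0 <= gov < n) or gov == dep:
                raise MalformedAnnotationError(
                    f"{path}: invalid head {head} for token {dep + 1}"
                )
            sent.dep_edges.append(DependencyEdge(gov, dep, label))
        sentences.append(sent)
    return sentences


def _read_t_lines(path: str, text: str, kind: str) -> dict[str, EntityMention]:
    mentions: dict[str, EntityMention] = {}
    with open(path, encoding="utf-8") as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("R"):
                continue
            m = _T_LINE.match(ln)
            if m is None:
                raise MalformedAnnotationError(f"{path}: malformed line {ln!r}")
            tid, type_label, b, e, surface = m.groups()
            begin, end = int(b), int(e)
            if end > len(text) or begin >= end:
                raise MalformedAnnotationError(
                    f"{path}: offsets out of range in line {ln!r}"
                )
            if text[begin:end] != surface:
                raise MalformedAnnotationError(
                    f"{path}: surface {surface!r} != text slice "
                    f"{text[begin:end]!r} in line {ln!r}"
                )
            mentions[tid] = EntityMention(
                id=tid, kind=kind, type_label=type_label,
                begin=begin, end=end, surface=surface,
            )
    return mentions


def align_mention_to_head(mention: EntityMention, sentence: Sentence) -> int:
    """Sentence-local index of the mention's syntactic head token.

    The head is the unique in-span token governed from outside the span
    (or ungoverned, i.e. the root). When no such token is unique the
    rightmost in-span token is used — English noun phrases are
    right-headed, which makes this a sound deterministic fallback.
    """
    in_span = sentence.token_at_offset(mention.begin, mention.end)
    if not in_span:
        raise AlignmentError(
            f"mention {mention.id} [{mention.begin},{mention.end}) "
            f"overlaps no token"
        )
    span_idx = {t.index for t in in_span}
    external = [
        t for t in in_span
        if sentence.governor_of(t.index) == ROOT
        or sentence.governor_of(t.index) not in span_idx
    ]
    if len(external) == 1:
        return external[0].index
    return in_span[-1].index


def _is_embedded(ggp: EntityMention, term: EntityMention, sent: Sentence) -> bool:
    """Noun-phrase-internal relation: GGP and term heads directly linked
    by a noun-compound / adjectival / appositive dependency."""
    a, b = ggp.head_token, term.head_token
    for e in sent.dep_edges:
        if {e.governor, e.dependent} == {a, b} and e.label in _NP_INTERNAL_LABELS:
            return True
    return False


def read_standoff_document(
    txt_path: str,
    a1_path: str,
    parse_path: str,
    rel_path: str | None = None,
    doc_id: str | None = None,
) -> Document:
    """Assemble a :class:`Document` from its standoff and parse files.

    GGP mentions come from ``.a1``, term mentions and relations from the
    optional ``.rel``. Every mention is aligned to its head token; every
    relation is resolved to mention references and checked against the
    one-GGP/one-term/same-sentence constraint. The ``embedded`` flag of
    each relation is inferred from the dependency parse.
    """
    if doc_id is None:
        doc_id = os.path.splitext(os.path.basename(txt_path))[0]
    with open(txt_path, encoding="utf-8") as fh:
        text = fh.read()
    sentences = read_parse_file(parse_path, text)
    doc = Document(id=doc_id, text=text, sentences=sentences)

    ggps = _read_t_lines(a1_path, text, kind="ggp")
    doc.ggp_mentions = list(ggps.values())

    terms: dict[str, EntityMention] = {}
    if rel_path is not None and os.path.exists(rel_path):
        terms = _read_t_lines(rel_path, text, kind="term")
        doc.term_mentions = list(terms.values())

    by_id = {**ggps, **terms}
    for m in by_id.values():
        sent = doc.sentence_of(m)
        m.head_token = align_mention_to_head(m, sent)

    if rel_path is not None and os.path.exists(rel_path):
        with open(rel_path, encoding="utf-8") as fh:
            for ln in fh:
                ln = ln.rstrip("\n")
                if not ln.startswith("R"):
                    continue
                m = _R_LINE.match(ln)
                if m is None:
                    raise MalformedAnnotationError(
                        f"{rel_path}: malformed relation line {ln!r}"
                    )
                rid, rtype, arg1, arg2 = m.groups()
                if arg1 not in by_id or arg2 not in by_id:
                    missing = arg1 if arg1 not in by_id else arg2
                    raise UnresolvedReferenceError(
                        f"{rel_path}: relation {rid} references unknown "
                        f"annotation {missing}"
                    )
                ggp, term = by_id[arg1], by_id[arg2]
                si_g = doc.sentence_index_of(ggp)
                si_t = doc.sentence_index_of(term)
                if si_g != si_t:
                    raise MalformedAnnotationError(
                        f"{rel_path}: relation {rid} spans sentences "
                        f"{si_g} and {si_t}"
                    )
                rel = EntityRelation(id=rid, type=rtype, ggp=ggp, term=term)
                rel.embedded = _is_embedded(ggp, term, doc.sentences[si_g])
                doc.relations.append(rel)
    return doc


def write_relations(
    document: Document, out_path: str, starting_id: int = 1
) -> None:
    """Write the document's relations (and their term mentions) as ``.rel``.

    Term mentions referenced by at least one relation are emitted as ``T``
    lines with fresh identifiers numbered from *starting_id*; relations
    follow as ``R`` lines. GGP arguments keep the identifiers of the
    ``.a1`` layer. Duplicate identifiers raise :class:`WriteError`.
    """
    term_ids: dict[int, str] = {}
    next_t = starting_id
    lines: list[str] = []
    ordered_terms: list[EntityMention] = []
    for r in document.relations:
        if id(r.term) not in term_ids:
            ordered_terms.append(r.term)
            term_ids[id(r.term)] = f"T{next_t}"
            next_t += 1
    ggp_ids = [m.id for m in document.ggp_mentions]
    seen: set[str] = set()
    for gid in ggp_ids:
        if gid in seen:
            raise WriteError(f"duplicate GGP identifier {gid}")
        seen.add(gid)
    for t in ordered_terms:
        tid = term_ids[id(t)]
        if tid in seen:
            raise WriteError(f"duplicate identifier {tid}")
        seen.add(tid)
        lines.append(f"{tid}\t{t.type_label} {t.begin} {t.end}\t{t.surface}")
    for k, r in enumerate(document.relations, start=1):
        lines.append(
            f"R{k}\t{r.type} Arg1:{r.ggp.id} Arg2:{term_ids[id(r.term)]}"
        )
    with open(out_path, "w", encoding="utf-8") as fh:
        for ln in lines:
            fh.write(ln + "\n")


def write_a1(document: Document, out_path: str) -> None:
    """Write the GGP mention layer as a ``.a1`` file."""
    with open(out_path, "w", encoding="utf-8") as fh:
        for m in document.ggp_mentions:
            fh.write(f"{m.id}\t{m.type_label} {m.begin} {m.end}\t{m.surface}\n")


def write_parse(document: Document, out_path: str) -> None:
    """Write the sentence/token/dependency layer as a ``.dep`` file."""
    blocks: list[str] = []
    for s in document.sentences:
        gov = {e.dependent: (e.governor, e.label) for e in s.dep_edges}
        lines = [f"#sent {s.begin} {s.end}"]
        for t in s.tokens:
            head, label = gov.get(t.index, (ROOT, "root"))
            lines.append(
                f"{t.index + 1}\t{t.surface}\t{t.pos}\t{head + 1}\t{label}"
            )
        blocks.append("\n".join(lines))
    with open(out_path, "w", encoding="utf-8") as fh:
        fh.write("\n\n".join(blocks) + "\n")


def write_document(document: Document, out_dir: str) -> None:
    """Write all four files (.txt/.a1/.rel/.dep) for *document*."""
    os.makedirs(out_dir, exist_ok=True)
    base = os.path.join(out_dir, document.id)
    with open(base + ".txt", "w", encoding="utf-8") as fh:
        fh.write(document.text)
    write_a1(document, base + ".a1")
    write_relations(document, base + ".rel",
                    starting_id=len(document.ggp_mentions) + 1)
    write_parse(document, base + ".dep")


def read_corpus_dir(corpus_dir: str) -> list[Document]:
    """Read every ``.txt`` basename in *corpus_dir* as a document."""
    docs = []
    for name in sorted(os.listdir(corpus_dir)):
        if not name.endswith(".txt"):
            continue
        base = os.path.join(corpus_dir, name[:-4])
        docs.append(
            read_standoff_document(
                base + ".txt", base + ".a1", base + ".dep",
                rel_path=base + ".rel",
            )
        )
    return docs
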