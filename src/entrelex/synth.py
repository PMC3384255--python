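"""Synthetic annotated corpora for end-to-end testing.

Generates fully annotated documents — text, GGP standoff, gold term and
relation standoff, and dependency parses — from a small set of sentence
templates with known relation semantics, so every pipeline stage can be
exercised without any external corpus or parser.

Each relation sentence instantiates a type-specific template with a
sampled GGP name and a domain term drawn from that type's vocabulary
pool. Embedded templates place the term inside the GGP's noun phrase
("the Esr-1 promoter was cloned"); non-embedded templates connect GGP and
term across the sentence ("p65 is a subunit of the complex"). Distractor
sentences contain a GGP but no relation, providing the negative class.
Parses are template-attached: hand-written per template, deterministic,
and guaranteed to give a dependency path between GGP and term.

The generator also emits the side inputs the semantic-lexicon module
consumes: gold relation-type labels per term (for cluster scoring) and
term-category annotation records (for the category lexicon).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, SplitError
from .model import (
    RELATION_TYPES,
    DependencyEdge,
    Document,
    EntityMention,
    EntityRelation,
    Sentence,
    Token,
)
from .semantic import normalize_term
from .standoff import write_document
from .stemming import porter_stem

NONE_TYPE = "none"

_DEFAULT_GGPS = (
    "Esr-1", "STAT1", "NF-kappaB", "TNF-alpha", "IL-6", "p65", "relA",
    "Myc", "Max", "IkB", "Ikaros", "GATA1", "p50", "JAK2",
)

_DEFAULT_TERMS = {
    "Subunit-Complex": ("complex", "heterodimer", "homodimer", "dimer", "trimer"),
    "Protein-Component": ("promoter", "domain", "site", "element", "motif"),
    "Member-Collection": ("family", "group", "cluster", "subfamily"),
    "Equivalence": ("gene", "mRNA", "transcript", "homolog"),
}

_DEFAULT_CATEGORIES = {
    "Subunit-Complex": "protein-complex",
    "Protein-Component": "DNA-domain-or-region",
    "Member-Collection": "protein-family-or-group",
    "Equivalence": "equivalent-nominal",
}


@dataclass
class SynthConfig:
    """Study conditions for corpus generation.

    ``type_mixture`` gives the per-sentence probability of each relation
    type plus ``"none"`` (a distractor sentence with a GGP but no
    relation); it must sum to 1. ``embedded_fraction`` is the probability
    that a relation sentence uses the noun-phrase-internal template of
    its type.
    """

    seed: int = 0
    n_documents: int = 100
    sentences_per_document: int = 4
    type_mixture: dict[str, float] = field(
        default_factory=lambda: {
            "Subunit-Complex": 0.2,
            "Protein-Component": 0.2,
            "Member-Collection": 0.2,
            "Equivalence": 0.2,
            NONE_TYPE: 0.2,
        }
    )
    embedded_fraction: float = 0.5
    ggp_pool: tuple[str, ...] = _DEFAULT_GGPS
    term_pools: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_TERMS)
    )
    categories: dict[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_CATEGORIES)
    )

    @property
    def noise_rate(self) -> float:
        return self.type_mixture.get(NONE_TYPE, 0.0)

    def validate(self) -> None:
        total = sum(self.type_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"type mixture sums to {total}, not 1")
        if any(p < 0 for p in self.type_mixture.values()):
            raise ConfigError("mixture probabilities must be >= 0")
        if not 0.0 <= self.embedded_fraction <= 1.0:
            raise ConfigError("embedded_fraction must lie in [0, 1]")
        if not self.ggp_pool:
            raise ConfigError("empty GGP pool")
        for t, p in self.type_mixture.items():
            if t != NONE_TYPE and p > 0 and not self.term_pools.get(t):
                raise ConfigError(f"empty term pool for requested type {t}")


# ---------------------------------------------------------------------------
# templates: (form-or-slot, POS) tokens plus hand-written dependencies


@dataclass(frozen=True)
class _Template:
    tokens: tuple[tuple[str, str], ...]
    edges: tuple[tuple[int, int, str], ...]  # (governor, dependent, label)
    rel_type: str | None
    embedded: bool
    two_ggps: bool = False


def _embedded_template(rel_type: str, verb: str) -> _Template:
    return _Template(
        tokens=(("the", "DT"), ("{G}", "NNP"), ("{T}", "NN"),
                ("was", "VBD"), (verb, "VBN"), (".", ".")),
        edges=((2, 0, "det"), (2, 1, "nn"), (4, 2, "nsubjpass"),
               (4, 3, "auxpass"), (4, 5, "punct")),
        rel_type=rel_type,
        embedded=True,
    )


_TEMPLATES: dict[str, tuple[_Template, ...]] = {
    "Subunit-Complex": (
        _embedded_template("Subunit-Complex", "purified"),
        _Template(  # "{G} is a subunit of the {T} ."
            tokens=(("{G}", "NNP"), ("is", "VBZ"), ("a", "DT"),
                    ("subunit", "NN"), ("of", "IN"), ("the", "DT"),
                    ("{T}", "NN"), (".", ".")),
            edges=((3, 0, "nsubj"), (3, 1, "cop"), (3, 2, "det"),
                   (3, 4, "prep"), (4, 6, "pobj"), (6, 5, "det"),
                   (3, 7, "punct")),
            rel_type="Subunit-Complex", embedded=False,
        ),
        _Template(  # "{G} and {G2} form the {T} ."
            tokens=(("{G}", "NNP"), ("and", "CC"), ("{G2}", "NNP"),
                    ("form", "VBP"), ("the", "DT"), ("{T}", "NN"),
                    (".", ".")),
            edges=((3, 0, "nsubj"), (0, 1, "cc"), (0, 2, "conj"),
                   (3, 5, "dobj"), (5, 4, "det"), (3, 6, "punct")),
            rel_type="Subunit-Complex", embedded=False, two_ggps=True,
        ),
    ),
    "Protein-Component": (
        _embedded_template("Protein-Component", "cloned"),
        _Template(  # "{G} binds to the {T} ."
            tokens=(("{G}", "NNP"), ("binds", "VBZ"), ("to", "IN"),
                    ("the", "DT"), ("{T}", "NN"), (".", ".")),
            edges=((1, 0, "nsubj"), (1, 2, "prep"), (2, 4, "pobj"),
                   (4, 3, "det"), (1, 5, "punct")),
            rel_type="Protein-Component", embedded=False,
        ),
    ),
    "Member-Collection": (
        _embedded_template("Member-Collection", "studied"),
        _Template(  # "{G} belongs to the {T} ."
            tokens=(("{G}", "NNP"), ("belongs", "VBZ"), ("to", "IN"),
                    ("the", "DT"), ("{T}", "NN"), (".", ".")),
            edges=((1, 0, "nsubj"), (1, 2, "prep"), (2, 4, "pobj"),
                   (4, 3, "det"), (1, 5, "punct")),
            rel_type="Member-Collection", embedded=False,
        ),
    ),
    "Equivalence": (
        _embedded_template("Equivalence", "sequenced"),
        _Template(  # "{G} is also known as the {T} ."
            tokens=(("{G}", "NNP"), ("is", "VBZ"), ("also", "RB"),
                    ("known", "VBN"), ("as", "IN"), ("the", "DT"),
                    ("{T}", "NN"), (".", ".")),
            edges=((3, 0, "nsubjpass"), (3, 1, "auxpass"), (3, 2, "advmod"),
                   (3, 4, "prep"), (4, 6, "pobj"), (6, 5, "det"),
                   (3, 7, "punct")),
            rel_type="Equivalence", embedded=False,
        ),
    ),
    NONE_TYPE: (
        _Template(  # "{G} was measured in patients ."
            tokens=(("{G}", "NNP"), ("was", "VBD"), ("measured", "VBN"),
                    ("in", "IN"), ("patients", "NNS"), (".", ".")),
            edges=((2, 0, "nsubjpass"), (2, 1, "auxpass"), (2, 3, "prep"),
                   (3, 4, "pobj"), (2, 5, "punct")),
            rel_type=None, embedded=False,
        ),
        _Template(  # "expression of {G} remained unchanged ."
            tokens=(("expression", "NN"), ("of", "IN"), ("{G}", "NNP"),
                    ("remained", "VBD"), ("unchanged", "JJ"), (".", ".")),
            edges=((3, 0, "nsubj"), (0, 1, "prep"), (1, 2, "pobj"),
                   (3, 4, "acomp"), (3, 5, "punct")),
            rel_type=None, embedded=False,
        ),
    ),
}


@dataclass
class SynthCorpus:
    """A generated corpus with its lexicon-side gold data."""

    documents: list[Document]
    gold_term_labels: dict[str, str]     # normalised term -> relation type
    category_records: list[tuple[str, str]]  # (surface, category)
    config: SynthConfig

    def lexicon_sentences(self) -> list[list[str]]:
        """Normalised token sequences for semantic-space induction."""
        return [
            [t.stem for t in sent.tokens]
            for doc in self.documents
            for sent in doc.sentences
        ]


def _pick_template(cfg: SynthConfig, rng: np.random.Generator,
                   rel_type: str) -> _Template:
    options = _TEMPLATES[rel_type]
    if rel_type == NONE_TYPE:
        return options[int(rng.integers(len(options)))]
    if rng.random() < cfg.embedded_fraction:
        return options[0]
    rest = options[1:]
    return rest[int(rng.integers(len(rest)))]


def generate_corpus(config: SynthConfig | None = None) -> SynthCorpus:
    """Generate a corpus under *config*; same seed, same corpus."""
    cfg = config or SynthConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    mixture = sorted(cfg.type_mixture.items())
    mix_types = [t for t, _ in mixture]
    mix_probs = np.array([p for _, p in mixture])
    mix_probs = mix_probs / mix_probs.sum()

    documents: list[Document] = []
    for d in range(cfg.n_documents):
        doc = Document(id=f"doc{d:04d}", text="")
        text_parts: list[str] = []
        offset = 0
        next_tid = 1
        pending_terms: list[EntityMention] = []
        for _ in range(cfg.sentences_per_document):
            rel_type = mix_types[int(rng.choice(len(mix_types), p=mix_probs))]
            tpl = _pick_template(cfg, rng, rel_type)
            ggp = str(rng.choice(cfg.ggp_pool))
            ggp2 = None
            if tpl.two_ggps:
                others = [g for g in cfg.ggp_pool if g != ggp]
                ggp2 = str(rng.choice(others))
            term = (str(rng.choice(cfg.term_pools[rel_type]))
                    if tpl.rel_type else None)

            forms: list[str] = []
            slot_at: dict[str, int] = {}
            for i, (form, _pos) in enumerate(tpl.tokens):
                if form == "{G}":
                    slot_at["G"] = i
                    forms.append(ggp)
                elif form == "{G2}":
                    slot_at["G2"] = i
                    forms.append(ggp2)
                elif form == "{T}":
                    slot_at["T"] = i
                    forms.append(term)
                else:
                    forms.append(form)

            s_begin = offset
            sent = Sentence(begin=s_begin, end=0)
            cursor = s_begin
            for i, form in enumerate(forms):
                sent.tokens.append(
                    Token(index=i, begin=cursor, end=cursor + len(form),
                          surface=form, pos=tpl.tokens[i][1],
                          stem=porter_stem(form))
                )
                cursor += len(form) + 1
            sent.end = cursor - 1
            sent.dep_edges = [DependencyEdge(g, dep, lbl)
                              for g, dep, lbl in tpl.edges]
            doc.sentences.append(sent)
            text_parts.append(" ".join(forms))
            offset = cursor

            ggp_tok = sent.tokens[slot_at["G"]]
            gm = EntityMention(
                id=f"T{next_tid}", kind="ggp", type_label="Protein",
                begin=ggp_tok.begin, end=ggp_tok.end, surface=ggp_tok.surface,
                head_token=ggp_tok.index,
            )
            next_tid += 1
            doc.ggp_mentions.append(gm)
            gm2 = None
            if ggp2 is not None:
                g2_tok = sent.tokens[slot_at["G2"]]
                gm2 = EntityMention(
                    id=f"T{next_tid}", kind="ggp", type_label="Protein",
                    begin=g2_tok.begin, end=g2_tok.end,
                    surface=g2_tok.surface, head_token=g2_tok.index,
                )
                next_tid += 1
                doc.ggp_mentions.append(gm2)

            if tpl.rel_type is not None:
                t_tok = sent.tokens[slot_at["T"]]
                tm = EntityMention(
                    id="", kind="term", type_label="Entity",
                    begin=t_tok.begin, end=t_tok.end, surface=t_tok.surface,
                    head_token=t_tok.index,
                )
                pending_terms.append(tm)
                doc.relations.append(
                    EntityRelation(id=f"R{len(doc.relations) + 1}",
                                   type=tpl.rel_type, ggp=gm, term=tm,
                                   embedded=tpl.embedded)
                )
                if gm2 is not None:
                    doc.relations.append(
                        EntityRelation(id=f"R{len(doc.relations) + 1}",
                                       type=tpl.rel_type, ggp=gm2, term=tm,
                                       embedded=tpl.embedded)
                    )
        # term ids follow the GGP ids within each document
        for tm in pending_terms:
            tm.id = f"T{next_tid}"
            next_tid += 1
        doc.term_mentions = pending_terms
        doc.text = " ".join(text_parts)
        doc.validate()
        documents.append(doc)

    gold_labels = {
        normalize_term(term): rtype
        for rtype in RELATION_TYPES
        for term in cfg.term_pools.get(rtype, ())
    }
    category_records = [
        (term, cfg.categories[rtype])
        for rtype in RELATION_TYPES
        if rtype in cfg.categories
        for term in cfg.term_pools.get(rtype, ())
    ]
    return SynthCorpus(documents=documents, gold_term_labels=gold_labels,
                       category_records=category_records, config=cfg)


def write_corpus(corpus: SynthCorpus, out_dir: str) -> None:
    """Emit the standoff + parse quadruple for every document."""
    for doc in corpus.documents:
        write_document(doc, out_dir)


def split_train_test(
    documents: list[Document], fraction: float, seed: int = 0
) -> tuple[list[Document], list[Document]]:
    """Document-level split: *fraction* of documents go to the train side."""
    if not 0.0 < fraction < 1.0:
        raise SplitError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(documents))
    n_train = int(round(fraction * len(documents)))
    if n_train == 0 or n_train == len(documents):
        raise SplitError(
            f"fraction {fraction} leaves an empty side for "
            f"{len(documents)} documents"
        )
    train_idx = sorted(order[:n_train])
    test_idx = sorted(order[n_train:])
    return ([documents[i] for i in train_idx],
            [documents[i] for i in test_idx])


def corpus_stats(documents: list[Document]) -> dict[tuple[str, bool], int]:
    """Relation counts per (type, embedded flag)."""
    out: dict[tuple[str, bool], int] = {}
    for doc in documents:
        for r in doc.relations:
            key = (r.type, r.embedded)
            out[key] = out.get(key, 0) + 1
    return out
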