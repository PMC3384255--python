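# entrelex

Extraction of **entity relations** — non-causal links between a gene or
gene product (GGP) mention and a molecular *domain term* within one
sentence — from biomedical text in BioNLP-ST standoff format. An entity
relation types a phrase like *"the Esr-1 promoter"* as
`Protein-Component(Esr-1, promoter)`, or *"p50 or relA, the two major
subunits of NF-kappaB"* as `Subunit-Complex(p50, NF-kappaB complex)`.
Four relation types are handled: **Subunit-Complex**,
**Protein-Component**, **Member-Collection** and **Equivalence**.
Getting these relations right is what lets literature-scale text mining
resolve complex noun phrases to the correct database records: *Esr-1
promoter* and *Esr-1 inhibitor* embed the same gene symbol but denote
different molecular entities.

The package is aimed at biomedical text-mining researchers and
re-implements, as one toolkit, two complementary supervised systems and
their combinations:

* **Edge (graph-based) system** — an SVM classifies every word token as
  a domain-term head or not (with a *recall boost* that shifts the
  negative class margin by −log β, trading precision for recall), then
  a linear multiclass SVM classifies each GGP–term pair in the sentence
  into a relation type or negative, using features from the shortest
  dependency path between the two heads.
* **Sentence system** — one binary RBF-kernel SVM per relation type
  decides whether a (sentence, GGP) instance expresses that relation
  (features: bag-of-words and n-grams over the GGP-blinded sentence,
  POS n-grams, semantic-class generalisations; C and γ chosen by 5-fold
  cross-validation); positive decisions are resolved to a concrete term
  by a rule-based dictionary/lexicon search in a token window around
  the GGP.
* **Ensembles** — a hybrid (terms from the edge system's token
  classifier, relation decisions from the sentence system), plus
  high-precision **intersection** and high-recall **union** of two
  prediction sets keyed on (document, type, GGP span, term span).

Supporting machinery: semantic lexicons induced by latent semantic
analysis (truncated SVD of a log-scaled term-context matrix) and Markov
clustering of the cosine-similarity graph, rated by the cluster score

    S = Unknown × HG × Reliability,   Reliability = Known / (Known + Unknown)

where *Known*/*Unknown* count labelled and unlabelled cluster members
and *HG* is the majority-label fraction; ensemble feature selection
(mean signed weights over bootstrap linear SVMs); a strict standoff
evaluator (per-type and micro-averaged P/R/F, with
F = 2PR/(P+R)); and a deterministic synthetic-corpus generator so the
whole stack is testable without external corpora or parsers.

Syntactic parsing itself is out of scope: dependency parses are
consumed from CoNLL-style input files, never produced.

## Worked example

```python
from entrelex import (SynthConfig, generate_corpus, split_train_test,
                      gold_predictions, EvalReport)
from entrelex.pipeline import EdgePipeline, SentencePipeline
from entrelex.ensemble import hybrid_compose

corpus = generate_corpus(SynthConfig(seed=7, n_documents=120))
train, test = split_train_test(corpus.documents, 0.8, seed=7)
gold = gold_predictions(test)

edge = EdgePipeline(seed=7).fit(train)
sentence = SentencePipeline(seed=7).fit(train)

for name, preds in [
    ("edge", edge.predict(test)),
    ("sentence", sentence.predict(test)),
    ("hybrid", hybrid_compose(edge.term_candidates, sentence, test)),
]:
    p, r, f = EvalReport.from_predictions(gold, preds).overall()
    print(f"{name:9s} P={p:6.2f}  R={r:6.2f}  F={f:6.2f}")

doc = test[0]
for rel in edge.predict([doc])[doc.id][:3]:
    print(f"  {rel.type}: {rel.ggp.surface} -> {rel.term.surface} "
          f"(embedded={rel.embedded})")
```

prints

```
edge      P=100.00  R=100.00  F=100.00
sentence  P=100.00  R=100.00  F=100.00
hybrid    P=100.00  R=100.00  F=100.00
  Subunit-Complex: Myc -> trimer (embedded=False)
  Subunit-Complex: IkB -> trimer (embedded=False)
  Protein-Component: NF-kappaB -> promoter (embedded=True)
```

The metrics are on the percent scale; P, R and F are precision, recall
and their harmonic mean, micro-averaged over relation types. Perfect
scores are expected here: the synthetic corpus plants deterministic
lexical cues (each relation type has its own term vocabulary and
sentence templates), so a correct implementation must recover them —
that is the point of the parameter-recovery check, not a claim about
real literature.

## Command line

Every step is also a subcommand of the `entrelex` console script:

```bash
entrelex synth --seed 1 --docs 100 --out corpus/
entrelex build-lexicon --corpus corpus/ --dims 10 --out lexicon.json
entrelex train --system edge --corpus corpus/ --seed 1 --model edge.pkl
entrelex predict --model edge.pkl --corpus corpus/ --out pred/
entrelex evaluate --gold corpus/ --pred pred/ --out report.tsv
entrelex combine --mode intersect --corpus corpus/ --a predA/ --b predB/ --out both/
entrelex detect-terms --corpus corpus/ --strategy rules --out terms.tsv
```

A corpus directory holds one `.txt`/`.a1`/`.rel`/`.dep` quadruple per
document (text, GGP mentions, terms + relations, dependency parse);
see `entrelex.standoff` for the exact formats.

## Layout

| module | contents |
| --- | --- |
| `entrelex.model` | Document / Sentence / Token / mention / relation types |
| `entrelex.standoff` | standoff + parse readers and writers |
| `entrelex.stemming` | Porter stemmer |
| `entrelex.semantic` | LSA spaces, MCL, cluster score S, category lexicon |
| `entrelex.features` | blinding, n-grams, dependency paths and walks |
| `entrelex.terms` | term dictionary, rule search, token classifier, recall boost |
| `entrelex.relations` | edge and per-type models, attachment, feature selection |
| `entrelex.pipeline` | the two end-to-end systems |
| `entrelex.ensemble` | intersection, union, hybrid composition |
| `entrelex.evaluation` | strict matching, P/R/F, report differencing |
| `entrelex.synth` | synthetic corpus generator |
| `entrelex.cli` | the `entrelex` console script |

Methodological details, parameter defaults and known limitations are
documented in [docs/methods.md](docs/methods.md).
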