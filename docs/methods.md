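# Methods

This note documents the models implemented in entrelex, the parameters
that matter, what the synthetic data does and does not emulate, and the
design choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Task and data model

An entity relation is a non-causal typed link between exactly one gene
or gene product mention (GGP) and one domain term, both inside a single
sentence. GGP mentions are given (gold standoff annotations, the
shared-task setting); domain terms and relations are predicted. Four
types are modelled: Subunit-Complex (complex vs. its subunits),
Protein-Component (a GGP and its parts — promoters, domains, sites),
Member-Collection (family/collection membership) and Equivalence
(alternative nominals for the same entity). A relation realised inside
one noun phrase ("the Esr-1 promoter") is *embedded*; relations between
separate nominals are *non-embedded*.

Character offsets are 0-based and end-exclusive everywhere. Sentence
segmentation and tokenisation always come from the parse file; they are
never recomputed. Multi-token mentions are represented by their
syntactic head: the unique in-span token governed from outside the
span, falling back to the rightmost in-span token (English noun phrases
are right-headed, so this fallback is deterministic and rarely wrong).

The `.rel` standoff format does not carry the embedded flag, so the
reader infers it: a relation is embedded iff a direct
noun-phrase-internal dependency (`nn`/`compound`/`amod`/`appos`) links
the GGP head to the term head. Argument order in `R` lines is fixed as
Arg1 = GGP, Arg2 = term. Predicted multi-token terms are emitted with
their full phrase span (head-only spans would also round-trip, but full
spans match how gold terms are annotated).

## The two systems

### Edge (graph-based) system

1. **Term detection.** Every word token is an instance of a linear
   multiclass SVM (liblinear, C = 1). Features are labelled dependency
   walks up to depth 3 centred on the token — each walk encodes its
   direction/label sequence plus the end token's stem and POS — and the
   token's own stem and POS. Positives are gold term heads, labelled
   with their relation's type.
2. **Recall boosting.** At prediction time the negative class's margin
   is shifted down by log β (equivalently, its exponentiated decision
   score is divided by β) before the argmax. This form is exactly
   monotone: candidate sets are nested and non-decreasing in β, β = 1
   is a no-op, and β → ∞ accepts every token. A plain division of the
   signed margin would *not* be monotone when the margin is negative,
   which is why the shift acts on the log scale. The default is β = 1
   (no boost); the boost only matters when the downstream edge
   classifier can exploit extra candidates.
3. **Edge detection.** One candidate per GGP–term pair per sentence
   (the exact cartesian product), classified into a type or negative by
   a linear multiclass SVM. Features: the shortest undirected path
   through the dependency graph between the two heads (full label
   sequence, per-step labels, path length, traversed stems), the
   blinded lexical context, and the term token's stem/POS/semantic
   classes. C is selected from {0.1, 1, 10, 100} by stratified
   cross-validation accuracy; fold assignment depends only on the seed.

### Sentence system

1. **Instances.** One instance per (sentence, GGP) pair for every
   sentence containing at least one GGP. With several GGPs in a
   sentence, each gets its own instance — necessary so a positive
   decision can be attached to the right GGP.
2. **Blinding.** The candidate GGP collapses to `protx`, every
   co-occurring GGP to `exprotx`; the hidden surfaces are kept as
   separate content features. All other tokens are lowercase Porter
   stems. This lets lexical patterns like the trigram
   `human protx promot` generalise across gene names.
3. **Features.** n-grams for n ∈ {1, 2, 3} over the blinded sentence
   (n = 1 is the bag of words), POS bigrams, and — when a semantic
   lexicon is supplied — `sem:<class>` features plus class-substituted
   n-grams for every token with a lexicon hit. A window mode restricts
   n-grams to ±w tokens around `protx`; the default uses the whole
   sentence.
4. **Classification.** One binary RBF-kernel SVM per relation type;
   C ∈ {0.1, 1, 10, 100} × γ ∈ {0.01, 0.1, 1} selected per type by
   5-fold stratified cross-validation F1 on the training data only. A
   type with no positive training instance yields an always-negative
   model rather than an error.
5. **Term attachment.** A positive (sentence, GGP, type) decision is
   resolved by a rule-based search in a token window around the GGP:
   phrases are matched longest-first, leftmost-first against a
   dictionary of normalised gold term surfaces from training (with
   per-type counts), or against semantic-lexicon classes shared with
   dictionary terms of the requested type. Candidates are ranked by
   token distance to the GGP head, ties preferring the right side; the
   first-ranked candidate becomes the relation's term, and decisions
   with no candidate are dropped.

   The attachment window is *calibrated from training data* by default:
   it is set to the maximum GGP–term head distance observed among gold
   training relations. A fixed window is a structural recall ceiling —
   any relation whose term lies outside it is unreachable no matter how
   good the classifiers are — whereas the calibrated window adapts to
   the corpus at hand exactly like the dictionary does. An explicit
   integer window still overrides (the `detect-terms` CLI default is 5
   tokens).

### Ensembles

Relations are compared across systems by the canonical key (document,
type, GGP span, term span); a relaxed `head` mode keys the term by its
head token instead, for combining systems with different span
conventions. Intersection keeps keys present in both systems (metadata
from the first operand), union keeps keys present in either. Both are
pure set operations: membership is symmetric in the operands. The
hybrid runs the sentence system's type models but restricts attachment
to the term candidates supplied by the edge system's token classifier,
preferring candidates whose predicted type matches the decision, then
nearest-to-GGP with right-side tie-break.

## Semantic lexicons

The distributional lexicon is induced in four steps: (1) a term-context
matrix of windowed co-occurrence counts (window 2, min count 2 by
default) over lowercased, Porter-stemmed sentences; (2) log(1 + c)
damping — the standard LSA weighting choice; (3) rank-k truncated SVD,
term vectors U_k S_k, k = 10 by default (bounded by the matrix rank);
(4) Markov clustering of the cosine-similarity graph with an edge iff
cosine ≥ 0.5. Each SVD component's sign is fixed so its
largest-magnitude loading is positive, making vectors — and therefore
clusters — deterministic.

MCL uses self-loops of weight 1, column-normalised expansion (matrix
squaring) alternating with inflation (entrywise power 2.0, then
renormalisation), pruning entries below 1e-12, until the matrix changes
by less than 1e-6 or 100 iterations. Nodes join the cluster of the
attractor receiving most of their flow, ties to the lowest attractor
index. Because the flow matrix stays block-diagonal, nodes of different
connected components can never share a cluster — a property the test
suite checks against random disconnected graphs.

Cluster quality is rated by S = Unknown × HG × Reliability with
Reliability = Known/(Known + Unknown). HG ("homogeneity", the internal
agreement of the labels) is defined here as the majority-label fraction
among labelled members: simple, bounded in [0, 1], and 1 iff unanimous.
S is 0 whenever a cluster has no unlabelled members (nothing to
predict) or no label agreement; a clustering scores the sum over its
clusters, which is additive and permutation-invariant. The gold-label
lookup used for scoring labels each training term with its majority
relation type.

Alternative space builders (HAL, COALS, random indexing) are declared
interface slots that raise `NotImplementedError`; LSA is the
implemented and preferred method. The category lexicon maps normalised
lexical patterns to semantic categories (e.g. `DNA-domain-or-region`,
`protein-family-or-group`) from annotation records, resolving conflicts
by majority vote, ties by lexicographically smallest category.

## Ensemble feature selection

Linear SVMs are fitted on bootstrap resamples of the instances
(ensemble size 10 by default); a resample that collapses to one class
is redrawn with bounded retries. A feature's importance is its mean
signed weight across the ensemble; ranking is by magnitude. The top
fraction defines a reduced feature space, and the signed ranking is
exportable as TSV — positive weights mark features indicative of the
positive class. Mean-over-bootstraps is the simplest member of the
ensemble-selection family and keeps the ranking deterministic per seed.

## Evaluation

Matching is one-to-one per key: tp is the per-key minimum of gold and
predicted multiplicities, so duplicate predictions of one gold relation
cost false positives. P = 100·tp/(tp+fp), R = 100·tp/(tp+fn),
F = 2PR/(P+R); zero denominators yield 0. Reports round to two decimals
for display; full precision is kept internally. Report differences (in
percentage points) are computed on the *rounded* values, matching how
published result tables are compared; the test suite regression-checks
a frozen table of reference benchmark triples for harmonic-mean
consistency at ±0.01.

## Synthetic data

The generator emulates the annotated-corpus setting end to end: each
document is a sequence of template sentences with hand-written
dependency parses. Per sentence, a relation type (or a distractor) is
drawn from a configurable mixture — default 0.2 for each of the four
types and 0.2 distractors, matching a setting where roughly one
sentence in five mentions a GGP without any relation. Relation
sentences instantiate an embedded template (term inside the GGP's noun
phrase, probability 0.5 by default) or a non-embedded one; each type
has its own single-token term vocabulary (e.g. complex/heterodimer/…
for Subunit-Complex, promoter/domain/… for Protein-Component), which is
what makes the task learnable with deterministic cues. One
Subunit-Complex template carries two coordinated GGPs sharing one term,
exercising multi-GGP sentences, `exprotx` blinding and shared-term
standoff output. The generator also emits gold term→type labels and
term→category records so the lexicon machinery is testable.

What the generator does *not* emulate: parser errors, discontinuous or
multi-token terms, annotation noise, type-ambiguous terms, long-range
relations beyond its templates, or realistic vocabulary sizes.
Consequently the parameter-recovery checks (held-out F ≥ 90 for each
system, ≥ 85 for the hybrid, on a seed-fixed 400-document corpus)
demonstrate that the pipelines are implemented correctly — they recover
a recoverable signal — and say nothing about absolute performance on
real literature, where term detection is the dominant error source and
the same architectures score far lower.

Problem sizes used by the default test run and the acceptance script —
400 documents × 3 sentences for parameter recovery, 60-120 documents
for unit-level checks, 200/50/50 random graphs for the path/walk/MCL
oracles, 1,000 random clusters for the score heuristic — were chosen to
exercise every code path at comfortable statistical margins on a single
CPU.

## Numerical and degenerate-input conventions

* Cosine of a zero vector is 0 by convention; length mismatches raise.
* `lsa_reduce` requires 1 ≤ k ≤ min(matrix shape); full-rank reduction
  preserves pairwise cosines of the weighted matrix to 1e-8 (tested).
* Shortest dependency paths break length ties by the lexicographically
  smallest (edge label, token index) per step; disconnected pairs yield
  a distinguished `path:NONE` feature rather than an error.
* Dependency walks are simple paths (no revisited node), so the feature
  set is finite and equals exhaustive enumeration (tested).
* Empty clusters, all-labelled clusters and label-free clusters all
  score S = 0 instead of raising.
* Single-class training data raises a degenerate-model error for
  mandatory models; per-type models degrade to always-negative.
* All randomness (splits, CV folds, bootstraps, corpus sampling) flows
  from explicit integer seeds; repeated runs are bit-identical.

## Known limitations

* The rule-based attachment picks exactly one term per positive
  decision; sentences with two same-type relations for one GGP lose
  one of them by construction.
* The embedded/non-embedded inference from `nn`-type links is a
  heuristic; corpora with different parse conventions may need the
  label set extended.
* The Porter stemmer implements the classic algorithm, not the later
  "Porter2" revision; stems like `promot` are intentional.
* `head`-mode relation keys compare sentence-local head indices and
  assume both systems share tokenisation — true within this toolkit,
  not across arbitrary external systems.
* The CLI pickles trained pipelines; models are not portable across
  scikit-learn versions.
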