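# Methods

## Text mining model

Mentions are detected at abstract level with a dictionary matcher. Text and
lexicon terms are normalized by the same function: lowercase, every run of
characters outside `[a-z0-9']` becomes a single space, leading/trailing
separators trimmed. Mapping internal punctuation to spaces (slightly more
than the minimal "strip edge punctuation" policy) is what makes the term key
space and the text tokenizer identical, so matching is pure n-gram equality;
the policy string is recorded on every `TermLexicon`. No stemming and no
case-sensitive acronym handling: all surface forms are treated alike.

Matching is longest-match and non-overlapping on token boundaries; a term
naming several classes yields all of them. Title and body are concatenated
before matching. Mention presence is boolean per abstract.

Detected mentions are closed upward over the subclass hierarchy: a mention
of a class is a mention of all its superclasses. This is applied on the
phenotype side and, by default, symmetrically on the disease side
(`propagate_disease=False` restores asymmetric counting); the symmetric
choice follows from Terms(·) being defined uniformly over classes.

Counting is over the *restricted corpus*: only abstracts with at least one
disease and one phenotype mention contribute to any tally. Using the same
universe for `n_tot`, the marginals and the joint guarantees
`n_CD ≤ min(n_C, n_D) ≤ n_tot`, hence npmi ∈ [−1, 1]. Degenerate
conventions: `n_CD = 0` → −1, `n_CD = n_tot` → +1 (the denominator
vanishes); the positive-only pipeline never visits the −1 branch, but the
library defines it. Natural logarithms throughout — NPMI is base-invariant.
Per-disease ranks sort by descending NPMI with ties broken by lexicographic
phenotype id, for run-to-run determinism.

The index behind counting is an internal inverted scan, not an external
search engine; bit-identical counts, not index internals, are the contract.
Sentence-level co-occurrence, negation handling and full-text mining are out
of scope.

## Harvesting model

Associations carry exactly one provenance tag out of
{`umls_direct`, `hpo_via_umls`, `hpo_via_wikidata`, `wikidata`, `expert`,
`prop_icd`, `prop_lexical`}. When a pair arrives from several sources the
highest-precedence provenance (that order) is kept; direct terminology
mappings outrank bridged ones because bridged OMIM routes are the dominant
error pathway, and propagation ranks last.

ICD propagation emits one `prop_icd` record per proper descendant of an
annotated class, skipping pairs already present from *any* source — the
stronger dedup makes propagation idempotent. Only asserted (non-propagated)
records are expanded; expansion covers all depths in one pass, so a second
application adds nothing. Parent links come from the loaded disease
hierarchy; without one, a fallback derives 4-character→3-character parents
from code syntax (G30.0 → G30) and therefore only sees codes present in the
input. Propagation is parent→child only; no upward propagation.

Lexical propagation applies only to diseases with no record from any other
provenance: if a phenotype-class label occurs as a token-boundary substring
of the disease label, the disease inherits that class; the longest matching
label wins, with all classes kept on ties. The containment criterion is the
minimal reading of the one documented example (hemorrhoids ⊂ "external
hemorrhoids with complications") and is isolated in `propagate_lexical`.

The generic-phenotype block list ships with the five published example ids
(HP:0000005, HP:0000006, HP:0012824, HP:0025285, HP:0012834) and is
user-extensible; the remaining members of the original 21-item expert list
were never published, so they are not invented here. The common-disease
restriction takes an id list as input (e.g. codes with ≥ 100 biobank
patients); it is never computed internally. Curation overrides are replayed
from a file: removals are marked `removed_fp` and reported, additions enter
as `expert`/`added_fn`; nothing is silently dropped.

## Embeddings

The annotation graph has one node per phenotype class and per entity, with
subclass edges plus entity→phenotype annotation edges — a simplification of
axiom-pattern graph construction that is exact for the data handled here
(plain hierarchies plus annotations). Uniform random walks (depth 3,
default 10 walks per node; depth is the published setting, walks-per-node is
unstated and chosen as a conventional default) feed a skip-gram model with
negative sampling written on numpy: vector size 100, window 5, min count 1,
5 negatives from the unigram^0.75 distribution, 5 epochs, learning rate
0.025 → 1e-4 linear decay. Training is single-threaded and seeded; a
(corpus, seed) pair reproduces vectors bit for bit. Similarity is cosine;
ranking quality is ROC AUC in the rank (Mann–Whitney) formulation with ties
counted ½.

## Evaluation

Strict comparison is exact set algebra on (disease, phenotype) pairs. Soft
comparison closes both prediction and gold under phenotype-ancestor addition
per disease — phenotype-side only, disease-side closure is not applied —
then compares the closures; soft tp can only exceed strict tp. F is the
harmonic mean of precision and recall; values are rounded to two decimals
(coverage to whole percents) only at report time. The review-corrected
report relabels a caller-supplied number of false positives as true
positives; the subset size comes from manual review and is never inferred.
Rank sweeps evaluate per-disease top-k profiles over a cutoff grid and
report the F-maximising k (smallest k on ties).

## Synthetic data

The fixture generators emulate the shape of the real inputs at desk scale:
two ~40-class rooted DAG terminologies (complete depth-3, branching-3 trees
with a 10% chance of a second parent; disease ids use dotted ICD-like
codes), 2,000 abstracts, 20 planted leaf-level disease–phenotype pairs
co-mentioned per document with probability 0.3 against a 0.02 background
(every non-planted leaf pair), 20% lone-mention documents to exercise the
restricted-corpus rule, and synonym rate 0.3. Labels are unique multi-token
adjective–noun strings; child labels extend their parent's label ~30% of the
time, so longest-match resolution and lexical superclass containment occur
by construction. Gold standards lift a fraction of planted phenotypes to an
ancestor (strict/soft divergence); mapping bridges can inject wrong links;
genes carry noisy copies of disease profiles. Everything is a pure function
of `(FixtureSpec, seed)`.

What passing on these fixtures does *not* show: robustness to natural
language (no negation, anaphora, or morphological variation), to ambiguity
at the scale of a real metathesaurus, or to the label lengths and synonymy
structure of real clinical terminologies. The planted-signal recovery
results are sanity checks of the statistical machinery, not projections of
corpus-scale performance.

## Numerical and degenerate-input choices

- Cycle in a subclass file → `CyclicHierarchyError`; dangling parent →
  `UnknownClassError`; empty restricted corpus → `EmptyCorpusError`.
- npmi with a joint count above a marginal → `InconsistentCountsError`.
- Zero vectors are rejected in cosine (`ZeroNormError`); single-class AUC is
  undefined (`UndefinedAUCError`); P/R on empty sets → `UndefinedMetricError`.
- Rank thresholds must be ≥ 1; diseases with fewer scored phenotypes than
  the threshold return all of them.
- Problem sizes in the default test run and the acceptance script (2,000-doc
  corpora, 40-class ontologies, 5 seeds for recovery, 10 seeds for embedding
  ranking) were chosen so the full suite completes in well under a minute of
  mining and a few seconds of training per seed on one CPU.

## Known limitations

- The matcher has no approximate matching; a single character difference in
  a synonym hides a mention.
- Disease-side mention propagation is a modelling choice exposed as a flag;
  real hierarchies mix is-a with coding conventions, and propagating through
  the latter can inflate high-level disease counts.
- The lexical propagation criterion (label containment) is deliberately
  conservative and will miss paraphrased superclass relations.
- Skip-gram on tiny walk corpora has high seed variance; conclusions should
  be drawn from seed-averaged statistics, as the tests do.
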