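# Methods

## Data model and filters

All evidence is keyed by the **StudyKey**, the joint (PMID, allele)
pair: one curated study of one genetic variant. Gene-keyed GO
association files (GAF 2.1/2.2) can be re-keyed through an optional
gene→allele mapping table (gene_id, allele_id, pmid); without one the
gene accession itself is used as the pairing key and the reader logs
that mode. Training admits GO annotations only from the
biological-process aspect with IMP evidence; NOT-qualified annotations
are excluded everywhere, since a NOT annotation is evidence against
function, not for it. MP records pass unfiltered (minus the NOT
rule). PMIDs are stored without the `PMID:` prefix and term
accessions are zero-padded to seven digits, giving stable join keys.

The training network keeps exactly the StudyKeys carrying at least one
MP and at least one GO annotation (the co-curated studies rules are
learned from); the test network keeps the MP-only StudyKeys. The two
universes are disjoint by construction. `PM(t)` — the set of
StudyKeys annotated to term `t` — is the sole query primitive; the
network exists to serve it and deliberately offers no generic graph
analytics.

Annotations are used exactly as curated: no ancestor (true-path)
closure is applied by default, so results reflect the term sets the
curators chose. Closure over `is_a` ancestors can be layered on by
callers using the OBO utilities in `phenogo.evaluate`, but every
number this package reports comes from the unclosed sets.

## Significance model

The null hypothesis treats each of the N StudyKeys as an independent
draw succeeding with probability 1/N. The p-value of a success set S
inside an incidence set PM(t) is the exact upper tail of
Binomial(n = |PM(t)|, 1/N) at threshold j = |S|. The simple rule
MPᵢ → GOⱼ is scored by the single MP-side factor p[S ⊆ PM(MPᵢ)];
composite rules multiply one tail factor per participating set:

- plus: f(S,MP₁)·f(S,MP₂)·f(S,GO₁) with S = PM(MP₁)∩PM(MP₂);
- minus: f(S,MP₁)·f(S,GO₁)·f(S^c,MP₂) with S = PM(MP₁)\PM(MP₂) and
  S^c the complement of S **within PM(MP₁)**, i.e. PM(MP₁)∩PM(MP₂).
  The complement must be read relative to PM(MP₁): relative to the
  full universe the threshold j would exceed |PM(MP₂)| for any
  realistic corpus and the factor would be identically zero.

The three extended patterns have no published factorization; this
package extends the plus/minus forms minimally by pooling the union
clause as a single pseudo-term factor with n = |PM(MP₂)∪PM(MP₃)|
(plus-plus: f(S,MP₁)·f(S,MP₂∪MP₃)·f(S,GO₁), and analogously for
minus-minus and plus-minus with the complement taken within the
positive-conjunct intersection). Rule outputs carry full factor
provenance — (term, n, j) per factor — so any alternative
factorization can be recomputed from the serialized rules.

### Numerics

Tail probabilities are computed **exactly over the rationals** by an
integer suffix summation (each term derived from its neighbour by one
exact multiply/divide), not in floating point. This is a correctness
requirement, not a luxury: composite products at realistic corpus
scale reach 1e-41 and the working range of the acceptance checks
extends to N^-300 ≈ 1e-1070, far below the double-precision floor, and
rule *ranking* — the quantity that drives every downstream decision —
must not collapse into underflow ties. Floats and log₁₀ values are
projections taken at serialization time; TSV floats are written with
`repr` so extreme exponents round-trip losslessly. At the relevant
scales (n ≤ a few hundred) exact integer arithmetic costs microseconds
per tail. An alternative per-draw success probability can be supplied
(`binomial_tail(..., p=...)`) but 1/N, independent of |S|, is the
definition used throughout. Raw p-values are used for ranking; a
Benjamini–Hochberg helper is available but never applied implicitly.

## Mining

Each pattern's set identity is equivalent to "S ⊆ PM(GO₁)" for that
pattern's S, which reduces candidate search to false-positive
bookkeeping: the second conjunct of a plus rule must avoid
FP = PM(MP₁)\PM(GO₁) entirely, the negated term of a minus rule must
cover FP, union clauses must avoid or cover it jointly. Candidates
are generated through inverted indexes (terms co-annotated with the
relevant study sets); this pruning is an optimization whose
completeness is enforced by a brute-force equivalence test over random
networks, not assumed.

Two defaults shape mined output:

- `min_support` ≥ 1 always (an empty success set is a vacuous
  identity). The library default is 1 — the literal conditions; the
  CLI default is 2, suppressing single-study coincidences for
  end users. Both are documented flags.
- the **degeneracy guard** (`require_false_positive`, default on):
  composites exist to explain away false positives of the underlying
  simple pair, so a composite is only emitted where there is something
  to fix — plus-family patterns require FP nonempty for at least one
  conjunct, minus-family patterns require a nonempty set for the
  negated clause to exclude (for plus-minus,
  (PM(MP₁)∩PM(MP₂))\PM(GO₁) ≠ ∅). Disabling the guard reproduces the
  literal identity conditions, which is how the oracle-equivalence
  tests run. With the guard off, a perfect simple pair licenses
  arbitrary negated terms (any MP₂ yields a valid minus rule with an
  identical p-value) — the guard exists precisely to exclude that
  degeneracy.

Symmetric rule positions (plus and plus-minus conjuncts, union
clauses) are canonicalized lexicographically; mining is fully
deterministic and mining twice yields byte-identical files. Iterating
the composition beyond these five patterns is deliberately not
implemented.

Note an asymmetry the identities inherit: a disjunct that never
co-occurs with MP₁ trivially avoids FP, so plus-plus (and, through
covering, minus-minus) instances admit "idle" second disjuncts that
add nothing to the success set. These are valid instances of the
literal pattern and are emitted as such; their pooled union factor is
correspondingly weaker, so they rank below their two-term core. This
is why plus-plus is by far the most numerous kind in any corpus.

## Prediction and evaluation

A rule fires on a test StudyKey when all positive terms are annotated,
no negated term is, and a union clause has at least one member
annotated (plus-plus) or none (minus-minus) — the closed-world
assumption: absence of an annotation is treated as absence of the
phenotype, the acknowledged weakness of minus-family rules. Multiple
rules predicting the same (study, GO) collapse to the minimum-p rule
with all contributing rule ids kept; studies mapping to several genes
emit one prediction per gene, flagged ambiguous.

The ROC validates the p-value as a confidence score by
resubstitution on the training network (no held-out scheme): one
instance per (StudyKey, antecedent term, consequent term) with the
antecedent annotated, positive iff the consequent is annotated to the
same StudyKey, scored by the pair's tail p-value (as log₁₀ — a
monotone transform avoiding underflow ties), thresholds swept over
distinct scores with ties as one step, area by trapezoid. Both
prediction directions (MP→GO and GO→MP) are computable. The
instance construction follows the rule semantics — a prediction is
made per study, not per pair; a pair-level alternative would weight
every pair equally regardless of how many studies it fires on.

PPV = TP/(TP+FP) is computed over labeled predictions at each p-value
cutoff, reported as missing (not zero) where no prediction passes.
Labels come from an explicit per-prediction table so a curator review
can be replayed; nothing infers truth automatically. Ontology term
depth (shortest `is_a` path from the aspect root, BFS; longest-path
available as an option) is provided for rule-set profiling; depth
conventions differ across tools and depth carries no weight in the
method itself.

## Synthetic corpora

The generator emulates the statistical structure the method assumes,
not any real database. Each study draws one latent *process* — a
single underlying perturbation — owning one GO term and a small set of
MP terms; the study emits each linked term independently with
`emission_prob` (default 0.9, strong but imperfect co-curation). An
uncorrelated background flips each (study, term) cell with
`background_density` = 6e-4 by default, the graph density measured for
the real co-curation corpus this emulates. Defaults are 1000 studies
and a 400 MP + 200 GO vocabulary with 80 processes of 4 MP terms: a
roughly 4–6×-scaled-down universe chosen for tractability. Because
the vocabulary shrinks ~12× while per-study annotation counts stay
realistic, overall synthetic density sits well above 6e-4; the
background dial, not the total density, is the calibrated quantity.

Planted rules are injected with exact guarantees: supporting studies
receive the full pattern (alternating the satisfied disjunct for
plus-plus), *contrast rows* instantiate the near-misses that motivate
the pattern (a lone conjunct without the GO term for plus-family
rules; a blocked antecedent — negated term present, GO absent — for
minus-family rules), and a repair pass (iterated to fixpoint, never
touching a rule's own supports) removes every violation of the
pattern's identity from the remaining training rows. Contrast rows
also guarantee that excluded terms occur in the corpus at all — a term
planted only as an absence would otherwise be invisible to any miner —
and prevent sibling degeneracy (without a false positive to cover,
every other term would yield an equal-p minus variant). Planted
specifications should use pairwise term-disjoint rules; the repair
logic relies on it. A `test_fraction` of studies is emitted MP-only
with their GO annotations recorded in the ground-truth ledger.

What passing recovery tests show — and what they do not: corpora here
have clean latent structure, no curation bias, no evidence-code
diversity, no ontology structure, and one allele per study. Recovery
under these conditions demonstrates the machinery is sound, not that
real corpora yield comparable AUCs or PPVs; synthetic AUCs (~0.98) are
substantially higher than anything real co-curation data produces.
The recovery experiments use *weak* processes (two MP terms each, many
processes) so that multi-term co-occurrence outside the planted rules
is chance-dominated — with rich processes, the processes themselves
are real signal and legitimately out-rank a support-5 planted rule.

## Problem sizes

Test-suite and acceptance-script runs use desk-scale corpora (up to
~600 studies, 200-term vocabularies, 100 seeds per repeated-trial
check; the exactness grid runs to n = 300 at N = 3662). The full
suite completes in well under a minute on one CPU; the acceptance
script in a few seconds.

## Known limitations

- Minus-family rules inherit the closed-world assumption and are the
  least reliable kind; they are mined and scored like the others and
  left to the reviewer to weigh.
- The extended-pattern factorization is this package's documented
  extension (pooled union factor); other factorizations are plausible
  and recomputable from the serialized factor provenance.
- Resubstitution ROC overstates generalization by construction; it
  measures ranking quality of the score on the data the rules came
  from.
- The generator's repair pass guarantees identities only for
  term-disjoint planted rule sets; overlapping planted rules may fail
  to converge and raise.
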