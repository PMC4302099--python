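# phenogo

Infer Gene Ontology (GO) biological-process annotations from Mammalian
Phenotype (MP) annotations by mining set-theoretic rules over a
study/allele-keyed incidence network.

## The problem

Model-organism databases such as MGI curate two largely independent
annotation corpora from the same literature: GO annotations describing
canonical gene function, and MP annotations describing mutant
phenotypes. Because a set of varied phenotypes often traces back to a
single underlying functional perturbation, co-curated studies carry a
statistical signal linking MP terms to GO biological-process terms —
without any lexical or semantic comparison of the ontologies. This
package is for curation teams and computational biologists who want to
turn that signal into reviewable GO annotation suggestions for
publications that have phenotype annotations but no GO annotation yet.

## The model

The unit of evidence is the **StudyKey** — a (PMID, allele) pair. The
training corpus is arranged as two rectangular incidence matrices with
StudyKeys as rows and MP or GO terms as columns; `PM(t)` denotes the
set of StudyKeys annotated to term *t*. Only GO annotations in the
biological-process aspect with IMP ("inferred from mutant phenotype")
evidence enter training.

Five antecedent patterns over MP terms imply one GO term, each defined
by an exact set identity, all reducible to "the pattern's success set
S is contained in PM(GO₁)":

| rule | antecedent | success set S |
|---|---|---|
| plus | MP₁ ∧ MP₂ | PM(MP₁) ∩ PM(MP₂) |
| minus | MP₁ ∧ ¬MP₂ | PM(MP₁) \ PM(MP₂) |
| plus-plus | MP₁ ∧ (MP₂ ∨ MP₃) | PM(MP₁) ∩ (PM(MP₂) ∪ PM(MP₃)) |
| minus-minus | MP₁ ∧ ¬(MP₂ ∨ MP₃) | PM(MP₁) \ (PM(MP₂) ∪ PM(MP₃)) |
| plus-minus | MP₁ ∧ MP₂ ∧ ¬MP₃ | (PM(MP₁) ∩ PM(MP₂)) \ PM(MP₃) |

Significance against chance co-annotation uses the upper tail of a
Binomial(n, 1/N) with N the universe size:

```
p(Xₙ ≥ j) = Σᵢ₌ⱼⁿ C(n, i) (1/N)ⁱ (1 − 1/N)ⁿ⁻ⁱ,
```

evaluated at n = |PM(t)| and j = |S| for each participating set (the
simple rule MPᵢ → GOⱼ uses the single MP-side factor; composite rules
multiply one factor per set, with a pooled factor for union clauses).
Tails are computed exactly over the rationals, so products that fall
below the double-precision range (real rule p-values reach 1e-41 and
beyond) remain meaningful; floats and log₁₀ values are derived at
reporting time.

Mined rules are applied to an MP-only test corpus to emit
(study, gene, GO term) suggestions, the simple-rule p-value is
validated as a confidence score by ROC/AUC in both prediction
directions, and reviewed predictions are summarized as positive
predictive value (PPV = TP/(TP+FP)) versus p-value cutoff.

## Worked example

```python
from phenogo import (AnnotationNetwork, StudyKey, RuleKind,
                     make_rule, composite_pvalue, simple_rule_pvalue)

s = lambda i: StudyKey(pmid=f"p{i}", allele_id="a")
net = AnnotationNetwork.from_sets(
    {"MP:0000001": {s(1), s(2), s(3)}, "MP:0000002": {s(1), s(2)}},
    {"GO:0000001": {s(1), s(2), s(4)}},
    universe=[s(i) for i in range(1, 7)],
)
simple = simple_rule_pvalue("MP:0000001", "GO:0000001", net)
print(float(simple.p_value))          # 0.07407407407407407
plus = make_rule(RuleKind.PLUS, ("MP:0000001", "MP:0000002"), "GO:0000001")
print(float(composite_pvalue(plus, net).p_value))  # 0.00015241579027587258
```

The simple rule MP₁ → GO₁ has S = {s1, s2} inside |PM(MP₁)| = 3 draws
at 1/6 each, giving p = 16/216 ≈ 0.074 — weak evidence. Requiring MP₂
as well makes the association exact on the data (every MP₁∧MP₂ study
carries GO₁) and the three-factor product drops to 1.5e-4: the
composite antecedent has excluded the simple rule's false positive s3.

The same pipeline runs from the shell on synthetic or real corpora
(GAF 2.1/2.2 and tab-delimited MP reports):

```sh
phenogo run-all --out-dir out --seed 3
# network: N=287 density=3.136e-02
# mined 42864 rules
# 122 predictions
# mp->go AUC 0.9920
```

producing `rules.tsv`, `predictions.tsv`, `roc_mp_to_go.tsv`,
`ppv.tsv` and a `ground_truth.json` ledger; `phenogo ingest` /
`mine-rules` / `predict` / `evaluate-roc` / `evaluate-ppv` run the
stages individually.

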