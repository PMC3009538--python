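# gorelax

Network-based protein function prediction by **relaxation labelling** with
GO semantic-similarity compatibilities.

## The problem

For most sequenced genomes, a third to a half of proteins have no
experimentally supported function.  Because proteins act through
interactions, a protein's function can often be inferred from the
annotations of its neighbours in a functional-association network
("guilt by association").  Most neighbourhood classifiers treat each GO
term as an independent prediction problem, but GO terms are organised in
a DAG and are strongly interdependent: evidence that a protein's
neighbours are involved in, say, DNA replication is also evidence for DNA
repair.  `gorelax` exploits exactly this dependence.

## The method

Given a weighted network with association scores `a_ij ∈ (0, 1]` and a
labelled gold standard over terms `L = {l_1, …, l_m}`:

1. **Weighted voting** initialises each protein's affinity for each term
   from its labelled direct neighbours,

       P_i(l_k)⁰ = Σ_j a_ij θ(o_j, l_k) / Σ_j a_ij,

   falling back to the term's prior when no neighbour carries it.  This
   local classifier is also the comparison baseline.

2. **Relaxation labelling** iteratively re-estimates the probabilities
   using a term–term compatibility matrix `C`,

       Δ_i(l_k) = Σ_j ω_ij Σ_l C(l_k, l_l) P_j(l_l),
       P_i(l_k) ← P_i(l_k)(1 + Δ_i(l_k)) / Σ_l P_i(l_l)(1 + Δ_i(l_l)),

   with score-proportional neighbour weights ω and training proteins
   clamped to their known labels, until the probabilities stabilise.

3. `C(l_k, l_l)` is **Wang semantic similarity** computed on the GO DAG:
   ancestors receive max-product S-values along `is_a`/`part_of` edges
   (factors 0.8 / 0.6) and similarity is the normalised S-value overlap
   of the two terms' ancestor closures.

The package also implements gold-standard construction (evidence-code,
description-word and 30–400 term-size filters), stratified five-fold
cross-validation with per-term ROC AUC and micro-averaged
precision/recall, and a fully seeded synthetic benchmark generator
(planted modules with semantically correlated labels), so the entire
pipeline runs without any external data. See `docs/methods.md` for the
full model description and design rationale.

## Worked example

```python
from gorelax import ScenarioSpec, planted_scenario, compatibility_matrix, cross_validate

spec = ScenarioSpec(n_proteins=120, n_terms=4, n_modules=4, rho=0.8, seed=42)
net, annotations, ontology = planted_scenario(spec)
C = compatibility_matrix(ontology, annotations.terms)

result = cross_validate(net, annotations, C, k=5, seed=42)
for term in result.terms:
    print(f"{term}  n_pos={result.n_pos[term]:3d}  "
          f"voting={result.auc_voting[term]:.3f}  relax={result.auc_relax[term]:.3f}")
print(f"mean AUC: voting {result.mean_auc('voting'):.3f} -> relax {result.mean_auc('relax'):.3f}")
```

prints

```
T:0000009  n_pos= 56  voting=0.766  relax=0.735
T:0000010  n_pos= 55  voting=0.781  relax=0.736
T:0000015  n_pos= 53  voting=0.683  relax=0.767
T:0000019  n_pos= 58  voting=0.673  relax=0.777
mean AUC: voting 0.726 -> relax 0.754
```

Four modules of 30 proteins each carry one of four label terms (two
ontology sibling pairs); with correlation `rho = 0.8` a protein also
carries its term's sibling.  The per-term numbers are pooled held-out
AUCs: weighted voting is limited by the sparse, noisy neighbourhood
vote, while relaxation labelling recovers additional signal by letting
sibling terms support each other, raising the mean AUC here from 0.726
to 0.754 (individual terms can go either way; the margin grows with the
label correlation).

The same pipeline is scriptable from the shell:

```sh
gorelax synth --seed 4 --out-dir demo            # OBO + network + annotations
gorelax evaluate --network demo/network.tsv \
    --annotations demo/annotations.tsv --obo demo/ontology.obo \
    --min-count 1 --evidence IPI --folds 5 --seed 4 --out-dir demo
```

which writes `auc_per_term.tsv` and `pr_curves.tsv` with provenance
headers (tool version, config hash, seed).

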