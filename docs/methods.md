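# Methods

## Problem setting

Given a weighted protein functional-association network — an undirected
graph over proteins `O = {o_1, …, o_n}` whose edge weights `a_ij ∈ (0, 1]`
express the confidence that two proteins share function — and a partial
assignment of GO terms `L = {l_1, …, l_m}` to some of the proteins, the
task is to estimate, for every protein `o_i` and term `l_k`, the
probability `P_i(l_k)` that `l_k` is a correct label for `o_i`.  The
distinguishing feature of the method is that it exploits the dependence
*between* functional terms: GO terms are organised in a DAG and are far
from independent, so evidence for one term should lend support to
semantically related terms.

## The two-stage predictor

### Stage 1 — weighted voting (local classifier)

Initial probabilities come from a score-weighted vote of each protein's
labelled direct neighbours:

    P_i(l_k)^(0) = Σ_{j∈N_i} a_ij · θ(o_j, l_k)  /  Σ_{j∈N_i} a_ij

where `N_i` ranges over the labelled neighbours of `o_i` and
`θ(o_j, l_k) ∈ {0, 1}` indicates whether `o_j` carries `l_k`.  When no
neighbour carries `l_k` — in particular for isolated proteins — the term's
prior frequency among the labelled (training) proteins is substituted.
These raw voting scores are themselves the baseline classifier in all
comparisons.

### Stage 2 — relaxation labelling

Probabilities are refined iteratively.  At generation `T` the
neighbourhood support for `(o_i, l_k)` is

    Δ_i(l_k)^(T) = Σ_{j∈N_i} ω_ij · Σ_l C(l_k, l_l) · P_j(l_l)^(T)

with neighbour weights `ω_ij = a_ij / Σ_{j'} a_ij'` (score-proportional,
summing to 1) and `C` the m×m term–term compatibility matrix.  The
re-estimation is the classic multiplicative, normalised relaxation update
(Rosenfeld, Hummel & Zucker 1976):

    P_i(l_k)^(T+1) = P_i(l_k)^(T) (1 + Δ_i(l_k)^(T))
                     / Σ_l P_i(l_l)^(T) (1 + Δ_i(l_l)^(T))

Updates are synchronous (Jacobi-style): all supports are computed from
generation `T` before any row moves.  Iteration stops when the largest
absolute probability change falls below `tolerance` (default `1e-4`) or at
`max_iterations` (default 100).

Design choices made where the procedure admits variants:

* **Neighbour weights.** Only the normalisation constraint Σω = 1 is
  fixed by the formulation; we use score-proportional weights so stronger
  associations count for more.  Any other normalised weighting can be
  slotted in behind `neighbor_weights`.
* **Row normalisation.** Voting outputs are multi-label affinities and
  need not sum to 1; the relaxation update, however, renormalises each
  row.  We therefore rescale each unclamped row of `P^(0)` onto the
  simplex before iterating and keep the raw voting scores as a separate
  output.  A consequence worth knowing: the relaxation scores of one
  protein compete across terms, so they sharpen towards the dominant
  label; rankings *within* a term column (what AUC measures) are the
  intended use of the output.
* **Clamping.** Training proteins' rows are fixed at their 0/1 indicator
  vectors during iteration (configurable off).  Indicator rows are not
  renormalised — a protein with three known labels contributes support
  for all three at full strength.
* **Degenerate rows.** A row that is identically zero before an update is
  left unchanged (its normaliser would vanish) with a warning; isolated
  proteins have no neighbourhood support and keep their prior row.

### Compatibility from GO semantic similarity

`C(l_k, l_l)` is Wang's graph-structural semantic similarity.  For a term
`A`, every ancestor `q` receives an S-value via the max-product recurrence

    S_A(A) = 1,   S_A(q) = max_{q' ∈ children(q) ∩ T_A} r_e(q'→q) · S_A(q')

where `r_e` is a per-relation contribution factor (defaults `r_is_a = 0.8`,
`r_part_of = 0.6`, the customary values for this measure) and `T_A` is the
ancestor closure of `A`.  With `SV(A) = Σ_q S_A(q)`,

    Sim(A, B) = Σ_{q ∈ T_A ∩ T_B} (S_A(q) + S_B(q)) / (SV(A) + SV(B)).

`Sim` is symmetric, lies in [0, 1], equals 1 at identity, and is 0 for
terms with disjoint ancestor closures (e.g. different GO namespaces — the
intended use is a single namespace, biological process).  The raw
symmetric similarity is used as `C` without row normalisation; relations
other than `is_a`/`part_of` are ignored with a warning because the measure
defines contributions only for relation kinds the user weights.

## Gold-standard construction

Raw annotations (GAF 2.x or 3-column TSV) are filtered in a fixed,
logged order:

1. proteins whose product description contains a banned word
   (case-insensitive substring; defaults "hypothetical", "predicted",
   "putative") are dropped;
2. terms with no annotation carrying a required evidence code (defaults
   IPI, IGC) are dropped — this removes whole terms, as the filter is
   about whether a term has any interaction-derived support; a
   per-annotation-line variant is available (`evidence_per_annotation`);
3. terms annotating fewer than 30 or more than 400 proteins are dropped
   (too small to cross-validate / too general to be informative).

The order matters because the description filter changes term counts;
fixing it makes the retained-term counts reproducible.  No ancestor
("true-path") propagation of annotations is performed before counting.

## Evaluation protocol

Five-fold cross-validation over the labelled proteins, stratified per
term: a greedy multi-label stratifier processes proteins rarest-label
first and assigns each to the fold with the largest remaining deficit for
that label (ties: emptier fold, then seeded random), keeping per-term
fold counts within one of the balanced share whenever achievable.  For
each fold, the held-out proteins' annotations are excluded from voting,
from the priors and from clamping; both classifiers' held-out predictions
are pooled across folds (each labelled protein held out exactly once).

* **AUC** per term is the Mann–Whitney statistic (ties credited 0.5),
  computed on the pooled predictions; per-fold AUCs are also recorded.
  Terms with a single class are reported as missing rather than given an
  arbitrary value.
* **Precision/recall** follow the micro-averaged convention: at each
  threshold `t` a label is predicted when its probability strictly
  exceeds `t`, and precision = Σk_i/Σm_i, recall = Σk_i/Σn_i with
  m/n/k the per-protein predicted / known / correct counts.  The grid is
  101 evenly spaced thresholds; points with no predictions are dropped.
  A macro-averaged mode exists behind a flag.

## The synthetic benchmark

`planted_scenario` generates the regime the predictor assumes: proteins
grouped into functional modules that are more densely connected inside
than between, with module-aligned labels whose co-occurrence mirrors
ontology structure.

* A layered, single-rooted term DAG is generated (`random_dag`); label
  terms are chosen as sibling pairs sharing a parent, so each label has a
  designated semantically-close partner.
* Each module's proteins carry the module's primary term; with
  probability `rho` a protein also carries the primary's sibling.  This
  makes empirical label co-occurrence increase with `rho` in proportion
  to Wang similarity — the dependence structure the relaxation stage is
  designed to exploit.
* Annotation noise flips each (protein, term) indicator independently at
  the `noise` rate (default 0.1).
* Edges are Bernoulli, `within_p = 0.05` inside modules and
  `between_p = 0.005` across (10:1 odds), scored uniformly on
  [0.75, 1.0] — the post-filter band of a high-confidence network.  The
  densities are chosen so that a held-out protein has on the order of one
  labelled neighbour carrying its true term, which matches the operative
  statistic of genome-scale association networks (degree a few tens, a
  third of proteins labelled, per-term prevalence a few percent — on the
  order of one direct carrier per protein).  In this weak-direct-evidence
  regime the local vote is noisy and propagating correlated-label support
  matters; in much denser networks both classifiers saturate and their
  difference is within noise.

Default scenario: 300 proteins, 6 equal modules, 8 label terms (4 sibling
pairs; modules take pair-first terms before pair-second ones so that every
term gains carriers when `rho > 0`), `rho = 0.8`, seed-driven and fully
deterministic.

What the generator does **not** emulate: realistic degree distributions
(hubs), operon/complex substructure, biased annotation depth, or
inter-module edges enriched between functionally related modules.
Passing results on this benchmark show the machinery behaves as designed
under its own assumptions; they are not evidence about any particular
organism's network.

## Numerical notes

* All relaxation state is dense `float64`; the update is one matrix
  product per generation (`W P C`), deterministic and independent of term
  or protein ordering up to permutation.
* Uniform compatibility matrices make the support identical across terms,
  so the update is the identity; the convergence test detects this after
  one iteration.
* Network scores are serialised with `repr` so a written network re-reads
  to bit-identical floats and filter outcomes.
* Seeds: every stochastic component (fold assignment, generators) takes
  an explicit seed; identical inputs and seeds give byte-identical
  outputs.

## Known limitations

* The relaxation output is a per-protein distribution over terms, not a
  calibrated per-(protein, term) probability; thresholded multi-label
  recall is consequently conservative (see row-normalisation note above).
* The evidence-code filter's term-level interpretation can keep proteins
  whose own annotation to the term is electronically inferred.
* Wang similarity across disconnected ontology components is defined as
  0, which is the desired behaviour for GO namespaces but means a forest
  ontology yields block-diagonal compatibilities.
* Cross-validation problem sizes in the shipped benchmark (hundreds of
  proteins, single-digit terms) are chosen for fast, deterministic test
  cycles; the implementation itself is vectorised and handles
  thousands of proteins and tens of terms comfortably.
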