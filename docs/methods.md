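# Methods

## Model

Conflux is a hierarchical factor graph over three index sets: variants
*i*, individuals *j*, genes *g*.  Observed data are the genotype counts
`D_ij ∈ {0,1,2}` and the case/control labels `pheno_j`.  Latent variables:

| variable | support | meaning |
|---|---|---|
| `X_i` | {0,1} | variant damages the protein product |
| `Y_ij = X_i·D_ij` | {0,1,2} | damaging dosage carried by *j* at *i* |
| `Q_gj` | {0,1,2} | aggregate dysfunction of gene *g* in *j* |
| `H_g` | {0,1} | gene is associated with the disease |
| `G_gj = H_g·Q_gj` | {0,1,2} | gene relevant to *j*'s phenotype |

`Y`, `Q` and `G` nodes are instantiated only on carried support
(`D_ij > 0`), which keeps the graph linear in the number of non-zero
genotypes.  `H` nodes exist for every gene with at least one variant or
one network edge.

### Factor parametrizations

The two conditional factors that tie the tiers together are parametrized
as follows (these are this package's own documented choices):

* **φ₂ (gene dysfunction).**  `P(Q = min(2, ΣY)) = 1 − ε_q` with the
  leak `ε_q` (default 0.01) split evenly over the other two states.  The
  capped sum encodes that one damaged allele yields partial dysfunction
  (e.g. haploinsufficiency) and two or more yield full dysfunction.  The
  leak exists for numerical reasons: strictly positive factor entries keep
  loopy BP messages finite.
* **φ₄ (phenotype).**  A noisy-OR over the count *c* of active `G`
  variables: `P(case | c) = 1 − (1 − ε_bg)(1 − p_pen)^c` with penetrance
  `p_pen` (default 0.7) and phenocopy/background rate `ε_bg` (default
  0.01).  It is monotone in *c*, treats `G=1` and `G=2` alike (the count
  collapses `G ≥ 1`; dysfunction severity already acted through φ₂), and
  depends on the count only — the property the counting-factor machinery
  requires.
* **Sparsity.**  A constant per-gene prior `τ` (default 0.0025) plus a
  geometric cardinality factor `ρ(k) = γ^k` over the number of active `H`
  (default γ = 0.9).  The geometric form composes exactly with
  counting-factor message passing and adds a single interpretable knob;
  γ = 1 switches the regularization off.
* **X prior** fixed at 0.5 (non-informative).  A per-variant prior hook
  exists for plugging in harmfulness predictions, but defaults to 0.5.

### The calibrated network prior

Each undirected interaction produces two *directed* factors.  Toward
target *t* from source *s*: `P(H_t=1 | H_s=0) = 0.5` (exactly
uninformative) and `P(H_t=1 | H_s=1) = δ(deg(t))`.  No message is sent
toward the source, so a gene is never penalized for inactive or
uninvolved neighbours.

δ is calibrated per target degree *d*:

1. `M_c` (maximal contribution) solves
   `τ/(1−τ) · M_c/(1−M_c) = ceiling/(1−ceiling)` with ceiling 0.02.
2. `a_min(d)` is the smallest *a* with
   `P(Binomial(d, τ) ≥ a) ≤ 0.05 / n_genes_total` — an exact binomial
   tail, no approximation, so `a_min` is integer-stable.  The tail is
   defined as 0 for `a > d`; for low degrees where no `a ≤ d` is
   significant (d = 1, 2 under defaults) the function returns `d+1`,
   which only makes δ smaller — a conservative convention for a case the
   calibration otherwise leaves open.
3. δ solves `(δ/(1−δ))^a_min = M_c/(1−M_c)`, then is capped at 0.9 so a
   sole neighbour's influence stays bounded.

Second-order neighbourhoods (default) are handled by calibrating and
placing factors on the distance-≤2 closure of the network, using the
closure degree and no distance decay — the closure keeps the capping
arithmetic uniform across orders.  During inference the summed positive
network log-odds into each gene is additionally clipped at
`log-odds(M_c)` on every sweep, because more than `a_min` neighbours may
be active at run time.  Net guarantee (tested by exhaustive neighbour
clamping): a gene with no data evidence can never exceed the 0.02
ceiling, far below the 0.2 detection threshold.

`n_genes_total` in the significance denominator defaults to the analysis
gene universe when the pipeline knows it, else 12,000.

## Inference

Damped loopy belief propagation, two-tier schedule:

* **Outer sweep** updates the variant-tier messages (X priors, Y=X·D
  links, φ₂) once.  These are the most numerous and the slowest to move.
* **Inner loop** then relaxes the tightly coupled gene tier (φ₃, φ₄, Θ,
  τ, ρ) up to 10 times, stopping early when no H marginal moves by more
  than `inner_tol` (1e-4).

Numerical and scheduling choices:

* Damping is a convex combination in probability space with α = 0.5;
  damped messages stay normalized by construction.
* Messages are kept normalized; products over many factors (variant
  carriers into X, φ₃ messages into H) are accumulated as sums of logs,
  and binary quantities are carried as log-odds.
* Updates within a tier are synchronous, with variants in input order and
  genes in lexicographic order, so results are bit-reproducible; the
  `seed` field of `InferenceConfig` exists for interface stability only.
* Convergence is declared on *marginals* (max absolute change < 1e-4 by
  default), not raw messages, since marginals are the output contract.
* Clamping (`clamp_h`) pins chosen H variables at ±50 log-odds — used by
  the ceiling diagnostics.

**Counting factors.**  φ₄ and ρ depend only on the number of active
inputs.  The generic implementation builds a balanced binary tree of
partial-count distributions (upward convolutions, downward
expected-potential pulls; FFT convolutions at large internal nodes give
O(n log² n)) and is verified against a direct O(n²) convolution reference
and brute-force enumeration.  Both model potentials happen to be affine
in `r^c` (noisy-OR: `1 − A·r^c`; geometric: `γ^c`), for which the cavity
expectation factorizes and the exact messages reduce to a closed O(n)
form; the engine uses that closed form, which is tested equal to the tree
and the naive reference.  This is a pure efficiency choice — semantics
are identical.

**Accuracy.**  BP is exact on trees (verified to ≤1e-6 against full
enumeration; in practice ≈1e-12).  On loopy graphs it is approximate:
across weakly coupled fixtures of the kind rare-variant cohorts produce
(low carrier overlap between individuals), gene-level marginals stay
within 0.02 of the exact values.  Variant-level (`X`) marginals inside
tight loops — a variant shared by a case and a control both coupled
through the same gene — can drift further (observed up to ≈0.06), and
per-patient `G` marginals on such loops further still; the worst observed
deviations occur for homozygous shared variants, where the deterministic
`Y = 2X` link makes the loop maximally stiff.  These are fixed-point
properties of loopy BP, not implementation artifacts, and the tests
assert them at their observed magnitudes rather than hiding them.

The enumeration oracle (`exact_marginals_bruteforce`) evaluates the
literal joint distribution, entering the directed Θ tables as ordinary
pairwise potentials with no runtime cap.  The production engine
intentionally deviates from sum-product on that joint in two respects
(no message toward the Θ source; capped Θ aggregate), so tight
oracle-equivalence checks use Θ-free fixtures.

## Simulator

The generator emulates, at desk scale, a population where a complex
disease is driven by rare damaging coding variants in a network-clustered
gene set:

* **Scale.**  1,000 genes × 20,000 individuals by default (standing in
  for ~12,000 genes × 900,000), Poisson-distributed variant counts per
  gene (mean 30).
* **Site frequency spectrum.**  Allele frequencies from a bounded Pareto
  on [1/(2N), 0.01] with shape 0.5 — rare-skewed, so ≥90% of polymorphic
  sites in realistic samples are below 1%.  Genotypes are independent
  Binomial(2, f) draws (Hardy–Weinberg), stored sparse.
* **Harmfulness.**  A Bernoulli flag per variant (default fraction 0.2)
  stands in for a selection-coefficient threshold; downstream, only the
  flag matters.
* **Causal sets.**  Neighbourhood sampling (a seed gene plus P−1 genes
  within distance 2, the seed resampled until the neighbourhood is large
  enough), or fixed topologies: star (all neighbours of a center, center
  excluded), clique (a fraction of the largest clique), chain (grown
  greedily, each pick adjacent to the last, non-adjacent to all earlier
  picks, minimum-degree-first with id tie-breaks, internal picks needing
  degree ≥ 2).
* **Disease.**  Individuals are ranked by their harmful-allele burden
  inside the causal genes; the top 600 (3% prevalence) are patients, ties
  broken by individual id.  At this scale 3% keeps every labelled patient
  an actual causal-burden carrier while leaving a patient pool larger
  than the biggest sampled case group (400).  Cohorts draw n/2 cases and
  n/2 controls uniformly from the two strata; variants monomorphic in the
  cohort are dropped (count recorded).
* **Synthetic network.**  A preferential-attachment backbone (heavy
  degree tail, exercising the degree-dependent δ) with a planted 36-gene
  clique, a 60-leaf hub star and a 30-gene low-degree path bridged in, so
  every topology sampler has a guaranteed target.

What the generator does *not* emulate: linkage disequilibrium, realistic
demography and relatedness, genotyping error, covariates, common-variant
architecture, and the curated structure of real PPI databases.  Passing
recovery benchmarks on these simulations therefore demonstrates the
machinery works under the model's own assumptions — not performance on
real cohorts.

## Evaluation

Detection at marginal ≥ 0.2 ("detected") and ≥ 0.05 ("suggestive"), or
top-P selection with P the causal-set size; sensitivity, precision,
F-measure with deterministic lexicographic tie-breaks.  Reported
percentages are truncated to whole percent (14/22 → 63%); exact fractions
are kept in all tables.  Precision of an empty selection is defined as 1
and flagged, leaving F = 0 through sensitivity.  The internal baseline is
a per-gene two-sided Fisher exact test on carrier status × case/control —
deliberately simple plumbing that makes the benchmark self-contained.
The benchmark harness (`run_benchmark`) runs 1,000-gene scenarios with
P = 10 and n = 800 at a handful of replicates; these sizes keep a full
benchmark in minutes on one CPU while preserving the qualitative contrast
between the joint model and the burden test.

## Known limitations

* Loopy-BP marginal accuracy degrades in tight loops (above); marginals
  near 0.5 on densely overlapping support should be read as rankings, not
  calibrated probabilities.
* The exact forms of φ₂ and φ₄ are this package's parametrizations; other
  monotone choices would change marginal values (not the calibration
  guarantees, which act on the network side).
* The chain sampler is greedy with restarts; it reports the longest chain
  achieved when the requested length is infeasible.
* No covariates, continuous phenotypes, or variant-harmfulness
  integration beyond the optional per-variant prior hook.
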