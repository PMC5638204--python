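# conflux-genes

Network-aware probabilistic gene prioritization from rare-variant
case/control data.

## The problem

Rare-variant association studies are chronically underpowered: at
realistic cohort sizes a per-gene burden test detects only a fraction of a
complex disease's causal genes.  Protein–protein interaction (PPI)
networks carry complementary evidence — disease genes tend to cluster in
network neighbourhoods — but diffusion-style methods that propagate
per-gene summary statistics over the network can manufacture false
positives around hubs and depend on hard-to-choose hyper-parameters.

Conflux instead models variants, genes and individuals jointly in one
hierarchical factor graph and treats the network as a *calibrated prior*
whose total influence on any gene is bounded.  Its output is a posterior
marginal probability per gene, so genes can be ranked or thresholded, plus
per-patient gene relevance and ranked candidate variants.

## The model

For variants *i*, individuals *j* and genes *g*:

* `D_ij` — observed allele count (0/1/2);
* `X_i`  — variant damages the protein (prior 0.5);
* `Y_ij = X_i · D_ij` — damaging dosage carried by *j*;
* `Q_gj ∈ {0,1,2}` — aggregate dysfunction of gene *g* in *j*
  (`φ₂(Q|Y)` puts mass `1−ε_q` on `min(2, ΣY)`);
* `H_g`  — gene is disease associated (prior `τ`, sparsity `ρ(k)=γᵏ`,
  network factors `Θ`); **the posteriors over `H_g` are the output**;
* `G_gj = H_g · Q_gj` — gene relevant in this individual (`φ₃` indicator);
* `pheno_j` — observed label, tied to the count `c` of active `G` by a
  noisy-OR `φ₄`: `P(case|c) = 1 − (1 − ε_bg)(1 − p_pen)^c`.

The joint is `P(X,G,H,Q,pheno|D) ∝ P(pheno|G) P(G|H,Q) P(Q|X,D) P(X) P(H)`.
Inference is damped loopy belief propagation (α = 0.5) on a two-tier
schedule, with counting-factor messages for the potentials that depend
only on the number of active inputs.

**The network prior is calibrated, not trusted.**  Each interaction
becomes two directed factors `P(target=1 | source=1) = δ`,
`P(target=1 | source=0) = 0.5` — an inactive neighbour says nothing.  δ is
set per target degree *d* so that the smallest *significantly enriched*
number of active neighbours (`a_min`, exact Binomial(d, τ) tail at
0.05 / #genes) contributes exactly the maximal contribution `M_c`, where
`M_c` solves `τ/(1−τ) · M_c/(1−M_c) = 0.02/0.98`.  δ is capped at 0.9 and
the summed network log-odds into each gene is clipped at `log-odds(M_c)`
during inference.  Consequence: the network alone can never push a silent
gene past a 0.02 marginal — an order of magnitude below the 0.2 detection
threshold.

The package also ships the disease simulator (rare-skewed site-frequency
spectrum, Hardy–Weinberg genotypes, network-embedded causal gene sets,
burden-ranked disease assignment) and the evaluation harness
(threshold / top-P selection, sensitivity / precision / F-measure, an
internal Fisher-exact carrier-burden baseline), so the whole method is
testable end to end with no external data.

## Worked example

Simulate a cohort (1,000 genes, 20,000 individuals, 10 causal genes in a
network neighbourhood, 400 cases + 400 controls), run inference, score:

```sh
$ cat sim.yaml
simulation:
  n: 800
  p: 10
$ conflux simulate --config sim.yaml --seed 7 --out scenario
wrote scenario with 10 causal genes, 8543 cohort variants (21544 monomorphic dropped) to scenario
$ conflux run --genotypes scenario/genotypes.tsv --variant-map scenario/variant_map.tsv \
    --phenotypes scenario/phenotypes.tsv --network scenario/network.tsv --out out
inference converged after 28 sweeps; wrote out/gene_marginals.tsv
$ conflux evaluate --marginals out/gene_marginals.tsv --truth scenario/causal_genes.txt --mode threshold
suggestive (0.05 <= marginal < 0.2): 0 genes
mode=threshold TP=10 FP=0 FN=0
sensitivity=1.0000 (100%) precision=1.0000 (100%) F=1.0000
$ head -12 out/gene_marginals.tsv
gene    posterior
G0007   1
G0025   1
G0038   1
G0103   1
G0160   1
G0201   1
G0329   1
G0361   1
G0498   1
G0859   0.9999991336
G0273   0.01990626379
```

All ten simulated causal genes reach marginal ≈ 1 and are detected at the
0.2 threshold with no false positives.  The highest-ranked *non*-causal
gene (`G0273`) sits at 0.0199 — just below the 0.02 network ceiling,
showing the contribution cap doing its job: network context alone cannot
make a gene look causal.

The same pieces are available as a library:

```python
from conflux import simulate_scenario, score_scenario
scenario, network = simulate_scenario(seed=7, n=800, p=10)
scores = score_scenario(scenario, network)      # {'conflux': ..., 'burden': ...}
```

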