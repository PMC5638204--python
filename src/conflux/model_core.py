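"""The hierarchical factor graph over variants, genes and individuals.

Variables (binary unless noted):

* ``X_i``    -- does variant i damage the protein?  (prior 0.5)
* ``Y_ij``   -- ``X_i * D_ij``: damaging allele dosage carried by individual
  j at variant i; instantiated only where the observed genotype D_ij > 0.
* ``Q_gj``   -- ternary {0,1,2}: aggregate dysfunction of gene g in
  individual j (normal / partially / fully dysfunctional protein);
  instantiated only where j carries >= 1 variant of g.
* ``H_g``    -- is gene g associated with the disease?  (the main output)
* ``G_gj``   -- ternary ``H_g * Q_gj``: is gene g relevant in individual j?
* ``pheno_j``-- observed case/control label.

Factors:

* ``phi2(Q | Y...)`` -- near-deterministic CPT putting mass 1 - eps_q on
  Q = min(2, sum of Y), the rest split over the other states.
* ``phi3(G, H, Q) = 1[G = H * Q]`` -- exact indicator.
* ``phi4(pheno | #active G)`` -- noisy-OR with per-gene penetrance and a
  background (phenocopy) rate; a function of the count of G >= 1 only.
* ``tau`` prior and geometric cardinality factor ``rho(k) = gamma**k`` over
  the H variables, plus the directed network factors Theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import GenotypeData, PhenotypeLabels
from .network_prior import DirectedPairPrior, PriorConfig

__all__ = [
    "ModelConfig",
    "joint_log_likelihood",
    "FactorGraph",
    "build_factor_graph",
    "phi2_distribution",
    "phi2_cpt",
    "phi3_indicator",
    "phi4_potential",
    "sparsity_potential",
]


@dataclass(frozen=True)
class ModelConfig:
    """Parameters of the conditional factors.

    eps_q:
        probability mass leaked off the deterministic value of Q given Y;
        keeps every message strictly positive, which loopy BP needs.
    p_pen:
        per-active-gene penetrance in the noisy-OR phenotype factor.
    eps_bg:
        background (phenocopy) disease probability with zero active genes.
    gamma:
        multiplicative sparsity penalty per active H; gamma = 1 disables
        the cardinality regularization.
    x_prior:
        prior on variant harmfulness; deliberately non-informative (0.5).
    """

    eps_q: float = 0.01
    p_pen: float = 0.7
    eps_bg: float = 0.01
    gamma: float = 0.9
    x_prior: float = 0.5

    def __post_init__(self) -> None:
        for name in ("eps_q", "p_pen", "eps_bg", "x_prior"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError(f"gamma must be in (0,1], got {self.gamma}")


def phi2_distribution(y_values: Iterable[int], config: ModelConfig) -> np.ndarray:
    """P(Q | Y = y_values): mass 1 - eps_q on min(2, sum), rest split evenly."""
    s = min(2, int(sum(y_values)))
    return phi2_cpt(config)[s].copy()


def phi2_cpt(config: ModelConfig) -> np.ndarray:
    """3x3 table: row = capped sum of Y, column = Q state."""
    table = np.full((3, 3), config.eps_q / 2.0)
    np.fill_diagonal(table, 1.0 - config.eps_q)
    return table


def phi3_indicator(g: int, h: int, q: int) -> int:
    """1 iff g = h * q: a gene helps an individual only if globally relevant."""
    if g not in (0, 1, 2) or h not in (0, 1) or q not in (0, 1, 2):
        raise ValueError(f"states out of range: g={g}, h={h}, q={q}")
    return int(g == h * q)


def phi4_potential(pheno: int, active_count: int, config: ModelConfig) -> float:
    """Noisy-OR phenotype likelihood given the number of active genes.

    P(case | c) = 1 - (1 - eps_bg) * (1 - p_pen)**c.
    """
    if active_count < 0:
        raise ValueError("active_count must be >= 0")
    p_case = 1.0 - (1.0 - config.eps_bg) * (1.0 - config.p_pen) ** active_count
    return p_case if pheno == 1 else 1.0 - p_case


def sparsity_potential(k_active: int, config: ModelConfig) -> float:
    """Geometric cardinality penalty gamma**k over the active H count."""
    if k_active < 0:
        raise ValueError("k_active must be >= 0")
    return config.gamma ** k_active


def joint_log_likelihood(graph: "FactorGraph",
                         x: Mapping[str, int],
                         h: Mapping[str, int],
                         q: Mapping[tuple[str, str], int]) -> float:
    """Unnormalized log joint of a complete assignment.

    ``x`` maps variant -> {0,1}, ``h`` gene -> {0,1}, ``q`` (gene,
    individual) -> {0,1,2} for every instantiated Q node.  Y and G are
    deterministic (Y = X*D, G = H*Q); the phenotype is observed.  Mainly a
    testing aid: the value is the product of every factor table entry.
    """
    mc = graph.model_config
    pc = graph.prior_config
    cpt = phi2_cpt(mc)
    total = 0.0
    for k, variant in enumerate(graph.variants):
        p1 = graph.x_prior[k]
        total += math.log(p1 if x[variant] else 1.0 - p1)
    active_count = np.zeros(len(graph.individuals), dtype=np.int64)
    for p in range(graph.n_q_nodes):
        gene = graph.genes[graph.pair_gene[p]]
        indiv = graph.individuals[graph.pair_indiv[p]]
        sl = slice(graph.pair_y_start[p], graph.pair_y_stop[p])
        s = min(2, int(sum(graph.y_dose[t] * x[graph.variants[graph.y_variant[t]]]
                           for t in range(sl.start, sl.stop))))
        q_val = q[(gene, indiv)]
        total += math.log(cpt[s, q_val])
        g_val = h[gene] * q_val  # phi3 indicator holds by construction
        if g_val >= 1:
            active_count[graph.pair_indiv[p]] += 1
    for j in range(len(graph.individuals)):
        total += math.log(phi4_potential(int(graph.pheno[j]),
                                         int(active_count[j]), mc))
    for gene in graph.genes:
        total += math.log(pc.tau if h[gene] else 1.0 - pc.tau)
    total += math.log(sparsity_potential(sum(h.values()), mc))
    for e in range(graph.n_theta_factors):
        hs = h[graph.genes[graph.theta_source[e]]]
        ht = h[graph.genes[graph.theta_target[e]]]
        d = graph.theta_delta[e]
        total += math.log(0.5 if hs == 0 else (d if ht == 1 else 1.0 - d))
    return total


@dataclass
class FactorGraph:
    """Indexed, array-backed representation of the assembled model.

    The graph is stored flat for vectorized message passing:

    * ``variants`` / ``genes`` / ``individuals``: ordered id lists
      (variants in input order, genes lexicographic).
    * per carried (variant, individual) slot t (a Y node): ``y_variant[t]``,
      ``y_pair[t]``, ``y_dose[t] = D_ij``.
    * per (gene, individual) support pair p (a Q/G node): ``pair_gene[p]``,
      ``pair_indiv[p]``; Y slots of a pair are contiguous
      (``pair_y_start[p]:pair_y_stop[p]``).
    * directed network factors as arrays ``theta_source``, ``theta_target``
      (gene indices) and ``theta_delta``.
    """

    variants: list[str]
    genes: list[str]
    individuals: list[str]
    pheno: np.ndarray          # per individual, 0/1
    y_variant: np.ndarray      # int index into variants
    y_pair: np.ndarray         # int index into pairs
    y_dose: np.ndarray         # 1 or 2
    pair_gene: np.ndarray      # int index into genes
    pair_indiv: np.ndarray     # int index into individuals
    pair_y_start: np.ndarray
    pair_y_stop: np.ndarray
    theta_source: np.ndarray
    theta_target: np.ndarray
    theta_delta: np.ndarray
    x_prior: np.ndarray        # per variant P(X=1) prior
    model_config: ModelConfig
    prior_config: PriorConfig

    # ---- bookkeeping properties used by tests and diagnostics ----
    @property
    def n_x_nodes(self) -> int:
        return len(self.variants)

    @property
    def n_y_nodes(self) -> int:
        return len(self.y_variant)

    @property
    def n_q_nodes(self) -> int:
        return len(self.pair_gene)

    n_g_nodes = n_q_nodes

    @property
    def n_h_nodes(self) -> int:
        return len(self.genes)

    @property
    def n_theta_factors(self) -> int:
        return len(self.theta_source)

    @property
    def n_phi4_factors(self) -> int:
        return len(self.individuals)

    def pair_index(self, gene: str, individual: str) -> int:
        g = self.genes.index(gene)
        j = self.individuals.index(individual)
        hits = np.flatnonzero((self.pair_gene == g) & (self.pair_indiv == j))
        if len(hits) != 1:
            raise KeyError(f"no Q/G node for ({gene}, {individual})")
        return int(hits[0])


def build_factor_graph(genotypes: GenotypeData,
                       labels: PhenotypeLabels,
                       priors: Sequence[DirectedPairPrior],
                       model_config: ModelConfig | None = None,
                       prior_config: PriorConfig | None = None,
                       x_prior: dict[str, float] | None = None) -> FactorGraph:
    """Assemble the factor graph from genotypes, labels and pair priors.

    An H node exists for every gene with >= 1 variant or >= 1 network prior
    edge; Y/Q/G nodes exist only on carried support (D > 0).
    """
    model_config = model_config or ModelConfig()
    prior_config = prior_config or PriorConfig()
    if set(labels.individuals) != set(genotypes.individuals):
        raise ValueError("phenotype individuals do not match genotype individuals")

    genotype_genes = set(genotypes.genes)
    prior_genes = {p.source for p in priors} | {p.target for p in priors}
    genes = sorted(genotype_genes | prior_genes)
    gene_index = {g: k for k, g in enumerate(genes)}
    individuals = list(genotypes.individuals)
    indiv_index = {j: k for k, j in enumerate(individuals)}
    variants = list(genotypes.variants)
    pheno = np.array([labels.labels[j] for j in individuals], dtype=np.int8)

    # carried support, grouped by (gene, individual)
    coo = genotypes.counts.tocoo()
    order = np.lexsort((coo.row, coo.col))
    rows, cols, doses = coo.row[order], coo.col[order], coo.data[order]
    v_gene = np.array([gene_index[genotypes.variant_gene[v]] for v in variants])
    pair_key = {}
    pair_gene, pair_indiv = [], []
    y_variant, y_pair, y_dose = [], [], []
    # sort slots by (gene, individual, variant) so pair slots are contiguous
    slot_order = sorted(range(len(rows)),
                        key=lambda t: (v_gene[rows[t]], cols[t], rows[t]))
    for t in slot_order:
        i, j, d = int(rows[t]), int(cols[t]), int(doses[t])
        key = (int(v_gene[i]), j)
        if key not in pair_key:
            pair_key[key] = len(pair_gene)
            pair_gene.append(key[0])
            pair_indiv.append(j)
        y_variant.append(i)
        y_pair.append(pair_key[key])
        y_dose.append(d)
    y_pair_arr = np.asarray(y_pair, dtype=np.int64)
    n_pairs = len(pair_gene)
    pair_y_start = np.searchsorted(y_pair_arr, np.arange(n_pairs), side="left")
    pair_y_stop = np.searchsorted(y_pair_arr, np.arange(n_pairs), side="right")

    theta_source = np.array([gene_index[p.source] for p in priors], dtype=np.int64)
    theta_target = np.array([gene_index[p.target] for p in priors], dtype=np.int64)
    theta_delta = np.array([p.delta for p in priors], dtype=float)

    xp = np.full(len(variants), model_config.x_prior, dtype=float)
    if x_prior:
        for k, v in enumerate(variants):
            if v in x_prior:
                xp[k] = x_prior[v]

    return FactorGraph(
        variants=variants,
        genes=genes,
        individuals=individuals,
        pheno=pheno,
        y_variant=np.asarray(y_variant, dtype=np.int64),
        y_pair=y_pair_arr,
        y_dose=np.asarray(y_dose, dtype=np.int64),
        pair_gene=np.asarray(pair_gene, dtype=np.int64),
        pair_indiv=np.asarray(pair_indiv, dtype=np.int64),
        pair_y_start=pair_y_start,
        pair_y_stop=pair_y_stop,
        theta_source=theta_source,
        theta_target=theta_target,
        theta_delta=theta_delta,
        x_prior=xp,
        model_config=model_config,
        prior_config=prior_config,
    )
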