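"""Calibrated directed pairwise priors derived from a PPI network.

The interaction network is used as *soft* prior evidence over the per-gene
disease indicators H, not as hard structure.  Three safeguards keep the
network from dominating the data:

1. **Directed, asymmetric factors.**  For an edge between genes j and i the
   factor toward i is P(H_i=1 | H_j=0) = 0.5 (an inactive neighbour says
   nothing) and P(H_i=1 | H_j=1) = delta.  No message flows back toward j,
   so genes are never penalized for having uninvolved neighbours.

2. **Degree-dependent delta.**  delta is calibrated per *target* degree d so
   that the log-odds contributed by the smallest significantly-enriched
   number of active neighbours (a_min, from an exact Binomial(d, tau) tail
   test at 0.05 / n_genes_total) equals the maximal contribution M_c, the
   odds boost that lifts a silent gene from its prior tau to a fixed
   ceiling (0.02 by default).  delta is additionally capped (0.9) so a sole
   neighbour can never contribute dramatically.

3. **Runtime capping.**  During inference more than a_min neighbours may be
   active, so the summed positive log-odds entering a gene is clipped at
   log-odds(M_c) on every sweep.

Together these guarantee that network context alone can never push a gene's
marginal past the ceiling, far below the 0.2 detection threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import networkx as nx
from scipy.stats import binom

from .io_formats import GeneNetwork

__all__ = [
    "PriorConfig",
    "DirectedPairPrior",
    "max_contribution",
    "min_active_neighbours",
    "delta_for_degree",
    "build_augmented_adjacency",
    "build_pair_priors",
    "cap_network_contribution",
]


def _logit(p: float) -> float:
    return math.log(p) - math.log1p(-p)


@dataclass(frozen=True)
class PriorConfig:
    """Knobs of the network-prior calibration (all probabilities).

    tau:
        baseline prior that any one gene is disease associated.
    ceiling:
        the marginal a gene with no data signal is allowed to reach from
        network evidence alone.
    detection_threshold:
        the marginal needed to call a gene detected; must sit well above
        the ceiling for the guarantee to be meaningful.
    significance_base / n_genes_total:
        a neighbourhood is "significantly enriched" when its active-neighbour
        count clears a Binomial(d, tau) tail test at
        significance_base / n_genes_total (a Bonferroni-style cut over the
        gene universe).
    delta_cap:
        hard upper bound on delta, limiting single-neighbour influence.
    neighbourhood_order:
        1 uses direct interactions only; 2 also links neighbours of
        neighbours (the default).
    """

    tau: float = 0.0025
    ceiling: float = 0.02
    detection_threshold: float = 0.2
    significance_base: float = 0.05
    n_genes_total: int = 12_000
    delta_cap: float = 0.9
    neighbourhood_order: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.tau <= self.ceiling < self.detection_threshold < 1.0):
            raise ValueError(
                "need 0 < tau <= ceiling < detection_threshold < 1, got "
                f"tau={self.tau}, ceiling={self.ceiling}, "
                f"threshold={self.detection_threshold}"
            )
        if not (0.0 < self.delta_cap < 1.0):
            raise ValueError(f"delta_cap must be in (0,1), got {self.delta_cap}")
        if self.neighbourhood_order not in (1, 2):
            raise ValueError("neighbourhood_order must be 1 or 2")

    @property
    def significance_threshold(self) -> float:
        return self.significance_base / self.n_genes_total

    def with_n_genes(self, n: int) -> "PriorConfig":
        return replace(self, n_genes_total=n)


@dataclass(frozen=True)
class DirectedPairPrior:
    """One directed network factor: P(target=1 | source=1) = delta.

    When the source is inactive the factor is exactly uninformative
    (P(target=1 | source=0) = 0.5).
    """

    source: str
    target: str
    delta: float

    def __post_init__(self) -> None:
        if not (0.0 < self.delta < 1.0):
            raise ValueError(f"delta must be in (0,1), got {self.delta}")


def max_contribution(config: PriorConfig) -> float:
    """Maximal network contribution M_c, as a probability.

    Solves  tau/(1-tau) * M_c/(1-M_c) = ceiling/(1-ceiling):  combining the
    prior odds with the M_c odds yields a marginal of exactly the ceiling.
    """
    odds = (config.ceiling / (1.0 - config.ceiling)) * (1.0 - config.tau) / config.tau
    return odds / (1.0 + odds)


def max_contribution_log_odds(config: PriorConfig) -> float:
    """log-odds form of :func:`max_contribution` (the runtime cap value)."""
    return _logit(config.ceiling) - _logit(config.tau)


def min_active_neighbours(d: int, config: PriorConfig) -> int:
    """Smallest a with P(Binomial(d, tau) >= a) <= the significance cut.

    The upper tail is taken as 0 for a > d, so for low degrees where no
    a <= d is significant the function returns d + 1 (which only makes the
    resulting delta smaller -- a conservative convention).
    """
    if d < 1:
        raise ValueError(f"degree must be >= 1, got {d} (isolated genes get no priors)")
    threshold = config.significance_threshold
    # binom.sf(a - 1, d, tau) is the exact upper tail P(K >= a)
    for a in range(1, d + 1):
        if binom.sf(a - 1, d, config.tau) <= threshold:
            return a
    return d + 1


def delta_for_degree(d: int, config: PriorConfig) -> float:
    """Pair-factor parameter delta for a target gene of degree d.

    Solves (delta/(1-delta))**a_min = M_c/(1-M_c), then applies the cap.
    a_min active neighbours, each contributing log-odds(delta/(1-delta)),
    then jointly contribute exactly log-odds(M_c).
    """
    a_min = min_active_neighbours(d, config)
    log_odds_mc = max_contribution_log_odds(config)
    delta_odds = math.exp(log_odds_mc / a_min)
    delta = delta_odds / (1.0 + delta_odds)
    return min(delta, config.delta_cap)


def build_augmented_adjacency(network: GeneNetwork, order: int = 2) -> GeneNetwork:
    """Graph linking every pair at distance <= order (order in {1, 2})."""
    if order == 1:
        return network
    if order != 2:
        raise ValueError("neighbourhood order must be 1 or 2")
    closure: GeneNetwork = nx.Graph()
    closure.add_nodes_from(network.nodes)
    closure.add_edges_from(network.edges)
    for hub in network.nodes:
        neigh = list(network.neighbors(hub))
        for k, a in enumerate(neigh):
            for b in neigh[k + 1:]:
                closure.add_edge(a, b)
    return closure


def build_pair_priors(network: GeneNetwork,
                      config: PriorConfig) -> list[DirectedPairPrior]:
    """Two directed priors per augmented edge, each with its target-degree delta."""
    augmented = build_augmented_adjacency(network, config.neighbourhood_order)
    delta_cache: dict[int, float] = {}
    priors: list[DirectedPairPrior] = []
    for a, b in sorted(tuple(sorted(e)) for e in augmented.edges):
        for source, target in ((a, b), (b, a)):
            d = augmented.degree(target)
            if d not in delta_cache:
                delta_cache[d] = delta_for_degree(d, config)
            priors.append(DirectedPairPrior(source=source, target=target,
                                            delta=delta_cache[d]))
    return priors


def cap_network_contribution(incoming_log_odds, config: PriorConfig) -> float:
    """Clip the summed positive network log-odds at log-odds(M_c).

    Positive per-neighbour contributions are summed and clipped at the
    maximal contribution; non-positive contributions (which the asymmetric
    factors never produce) pass through unmodified.
    """
    cap = max_contribution_log_odds(config)
    positive = sum(c for c in incoming_log_odds if c > 0.0)
    negative = sum(c for c in incoming_log_odds if c <= 0.0)
    return min(positive, cap) + negative
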