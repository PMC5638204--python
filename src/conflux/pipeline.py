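"""End-to-end drivers tying the simulator, the model and the scorers together."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .evaluation import burden_baseline
from .inference_engine import InferenceConfig, MarginalTable, run_inference
from .io_formats import GeneNetwork, GenotypeData, PhenotypeLabels
from .model_core import ModelConfig, build_factor_graph
from .network_prior import PriorConfig, build_pair_priors
from .simulator import (DiseaseScenario, PopulationConfig, assign_disease_status,
                        generate_synthetic_network, sample_case_control,
                        select_causal_neighbourhood, select_chain, select_clique,
                        select_star, simulate_population)

logger = logging.getLogger("conflux")

__all__ = ["simulate_scenario", "score_scenario", "run_conflux"]


def simulate_scenario(seed: int = 0,
                      n_genes: int = 1000,
                      n: int = 800,
                      p: int = 10,
                      topology: str = "neighbourhood",
                      top_k: int = 600,
                      population_config: PopulationConfig | None = None,
                      network: GeneNetwork | None = None,
                      clique_fraction: float = 0.5,
                      star_center: str | None = None,
                      ) -> tuple[DiseaseScenario, GeneNetwork]:
    """Simulate one complete disease scenario (network, cohort, truth).

    ``top_k`` is the number of top-burden individuals labelled as patients
    at the population level (3% of the default 20,000-individual
    population); ``n`` is the sampled cohort size (n/2 cases, n/2 controls).
    """
    population_config = population_config or PopulationConfig(n_genes=n_genes,
                                                              seed=seed)
    if network is None:
        network = generate_synthetic_network(population_config.n_genes, seed=seed)
    genotypes, truth_harmful = simulate_population(population_config)
    if topology == "neighbourhood":
        causal = select_causal_neighbourhood(network, p, seed=seed + 1)
    elif topology == "star":
        center = star_center or max(network.degree, key=lambda kv: (kv[1], kv[0]))[0]
        causal = select_star(network, center, seed=seed + 1)
    elif topology == "clique":
        causal = select_clique(network, clique_fraction, seed=seed + 1)
    elif topology == "chain":
        causal = set(select_chain(network, p, seed=seed + 1))
    else:
        raise ValueError(f"unknown topology {topology!r}")
    population_labels = assign_disease_status(genotypes, truth_harmful, causal,
                                              top_k=top_k)
    scenario = sample_case_control(genotypes, population_labels, truth_harmful,
                                   causal, n=n, seed=seed + 2, topology=topology)
    return scenario, network


def run_conflux(genotypes: GenotypeData, labels: PhenotypeLabels,
                network: GeneNetwork,
                prior_config: PriorConfig | None = None,
                model_config: ModelConfig | None = None,
                inference_config: InferenceConfig | None = None,
                x_prior: dict[str, float] | None = None) -> MarginalTable:
    """Build priors and the factor graph from raw inputs and run inference.

    The neighbourhood-significance denominator defaults to the size of the
    analysis gene universe (network plus genotype genes).
    """
    universe = set(network.nodes) | set(genotypes.genes)
    if prior_config is None:
        prior_config = PriorConfig().with_n_genes(max(len(universe), 1))
    priors = build_pair_priors(network, prior_config)
    graph = build_factor_graph(genotypes, labels, priors,
                               model_config=model_config,
                               prior_config=prior_config,
                               x_prior=x_prior)
    table = run_inference(graph, inference_config)
    if not table.converged:
        logger.warning("loopy BP stopped at the iteration cap (%d sweeps)",
                       table.n_iterations)
    return table


def score_scenario(scenario: DiseaseScenario, network: GeneNetwork,
                   methods=("conflux", "burden"),
                   inference_config: InferenceConfig | None = None
                   ) -> dict[str, pd.Series]:
    """Score one scenario with each method, aligned on the gene universe.

    Returns per method a Series over all genes: posterior marginals for
    conflux (genes outside the model get 0), p-values for the burden
    baseline (genes without carriers get 1).
    """
    universe = sorted(set(network.nodes) | set(scenario.genotypes.genes))
    out: dict[str, pd.Series] = {}
    for method in methods:
        if method == "conflux":
            table = run_conflux(scenario.genotypes, scenario.labels, network,
                                inference_config=inference_config)
            out[method] = table.gene_posterior.reindex(universe, fill_value=0.0)
        elif method == "burden":
            pvals = burden_baseline(scenario.genotypes, scenario.labels)
            out[method] = pvals.reindex(universe, fill_value=1.0)
        else:
            raise ValueError(f"unknown method {method!r}")
    return out
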