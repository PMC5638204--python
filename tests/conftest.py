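"""Shared builders for small synthetic fixtures (no data files on disk)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from conflux.io_formats import GenotypeData, PhenotypeLabels
from conflux.model_core import ModelConfig, build_factor_graph
from conflux.network_prior import PriorConfig, build_pair_priors


def make_genotypes(counts, variant_genes, individuals=None,
                   variants=None) -> GenotypeData:
    """GenotypeData from a dense list-of-lists (variants x individuals)."""
    counts = np.asarray(counts, dtype=np.int8)
    n_var, n_ind = counts.shape
    individuals = individuals or [f"i{k + 1}" for k in range(n_ind)]
    variants = variants or [f"v{k + 1}" for k in range(n_var)]
    return GenotypeData(
        individuals=list(individuals),
        variants=list(variants),
        counts=sp.csr_matrix(counts),
        variant_gene=dict(zip(variants, variant_genes)),
    )


def make_labels(values, individuals=None) -> PhenotypeLabels:
    individuals = individuals or [f"i{k + 1}" for k in range(len(values))]
    return PhenotypeLabels(pd.Series(list(values), index=list(individuals)))


def make_graph(counts, variant_genes, phenotypes, network=None,
               model_config=None, prior_config=None):
    """Factor graph straight from dense fixture arrays."""
    genotypes = make_genotypes(counts, variant_genes)
    labels = make_labels(phenotypes)
    prior_config = prior_config or PriorConfig()
    priors = build_pair_priors(network, prior_config) if network is not None else []
    return build_factor_graph(genotypes, labels, priors,
                              model_config=model_config or ModelConfig(),
                              prior_config=prior_config)


@pytest.fixture
def two_gene_graph():
    """Forest-structured fixture: 2 genes, disjoint carriers, 1 case."""
    return make_graph(
        counts=[[1, 0], [0, 2]],
        variant_genes=["A", "B"],
        phenotypes=[1, 0],
    )
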