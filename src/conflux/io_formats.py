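"""Tabular input/output for networks, genotypes, phenotypes and marginals.

The tool deliberately sticks to the lowest-common-denominator formats used
for exchanging PPI networks and rare-variant count data:

* network: 2-column (or SIF-style 3-column) whitespace/tab edge list;
* genotypes: variants x individuals TSV of allele counts in {0, 1, 2},
  plus a 2-column variant -> gene map;
* phenotypes: 2-column TSV of individual id and case(1)/control(0) label;
* marginals: 2-column TSV of gene id and posterior P(H=1).

All identifiers are opaque strings; no gene-symbol normalization is done.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger("conflux")

#: A gene interaction network is an undirected simple graph over gene ids.
GeneNetwork = nx.Graph


class ParseError(ValueError):
    """Raised when an input file violates its documented format."""


@dataclass
class GenotypeData:
    """Coding-variant allele counts for a cohort plus the variant -> gene map.

    ``counts`` is stored sparse (CSR, variants x individuals) because rare
    variants make the matrix overwhelmingly zero; ``to_dense`` reproduces the
    dense matrix exactly.
    """

    individuals: list[str]
    variants: list[str]
    counts: sp.csr_matrix
    variant_gene: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts, dtype=np.int8)
        if self.counts.shape != (len(self.variants), len(self.individuals)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.variants)} variants x {len(self.individuals)} individuals"
            )
        if self.counts.nnz and (
            self.counts.data.min() < 0 or self.counts.data.max() > 2
        ):
            raise ValueError("allele counts must lie in {0, 1, 2}")
        missing = [v for v in self.variants if v not in self.variant_gene]
        if missing:
            raise ValueError(f"variants with no gene mapping: {missing}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def genes(self) -> list[str]:
        """Genes covered by at least one variant, sorted."""
        return sorted({self.variant_gene[v] for v in self.variants})

    def to_dense(self) -> np.ndarray:
        return self.counts.toarray()

    def subset_individuals(self, keep: Iterable[str]) -> "GenotypeData":
        keep = list(keep)
        pos = {ind: k for k, ind in enumerate(self.individuals)}
        cols = [pos[i] for i in keep]
        return GenotypeData(
            individuals=keep,
            variants=list(self.variants),
            counts=self.counts[:, cols],
            variant_gene=dict(self.variant_gene),
        )

    def drop_monomorphic(self) -> tuple["GenotypeData", int]:
        """Drop variants with no carrier; returns (data, n_dropped)."""
        carried = np.asarray((self.counts > 0).sum(axis=1)).ravel() > 0
        n_dropped = int((~carried).sum())
        if n_dropped == 0:
            return self, 0
        rows = np.flatnonzero(carried)
        kept = [self.variants[r] for r in rows]
        out = GenotypeData(
            individuals=list(self.individuals),
            variants=kept,
            counts=self.counts[rows],
            variant_gene={v: self.variant_gene[v] for v in kept},
        )
        return out, n_dropped


@dataclass
class PhenotypeLabels:
    """Binary case(1)/control(0) labels keyed by individual id."""

    labels: pd.Series  # index: individual id, values in {0, 1}

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels).astype(np.int8)
        bad = set(self.labels.unique()) - {0, 1}
        if bad:
            raise ValueError(f"phenotype labels must be 0/1, found {sorted(bad)}")

    @property
    def individuals(self) -> list[str]:
        return list(self.labels.index)

    @property
    def cases(self) -> list[str]:
        return list(self.labels.index[self.labels == 1])

    @property
    def controls(self) -> list[str]:
        return list(self.labels.index[self.labels == 0])

    def subset(self, keep: Iterable[str]) -> "PhenotypeLabels":
        return PhenotypeLabels(self.labels.loc[list(keep)])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_network(path: str | Path) -> GeneNetwork:
    """Read an undirected edge list; SIF-style middle columns are ignored.

    Self-loops and duplicate edges are silently dropped (with a logged count);
    lines with fewer than two tokens are a :class:`ParseError`.
    """
    path = Path(path)
    graph: GeneNetwork = nx.Graph()
    self_loops = 0
    duplicates = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected at least 2 columns, got {len(tokens)}"
                )
            if len(tokens) == 3:
                # SIF edge lines carry an interaction type in the middle column.
                a, b = tokens[0], tokens[2]
            else:
                a, b = tokens[0], tokens[1]
            if a == b:
                self_loops += 1
                graph.add_node(a)
                continue
            if graph.has_edge(a, b):
                duplicates += 1
                continue
            graph.add_edge(a, b)
    if self_loops or duplicates:
        logger.info(
            "read_network(%s): dropped %d self-loop(s) and %d duplicate edge(s)",
            path, self_loops, duplicates,
        )
    return graph


def write_network(graph: GeneNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")
        for node in sorted(n for n in graph.nodes if graph.degree(n) == 0):
            # isolated nodes kept as degenerate self-descriptive single column
            fh.write(f"{node}\t{node}\n")


def read_genotypes(matrix_path: str | Path, map_path: str | Path) -> GenotypeData:
    """Read the variants x individuals count matrix and the variant -> gene map."""
    matrix_path, map_path = Path(matrix_path), Path(map_path)
    frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
    individuals = [str(c) for c in frame.columns]
    variants = [str(v) for v in frame.index]
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        try:
            as_int = values.astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{matrix_path}: non-integer genotype entry: {exc}") from exc
        if not np.array_equal(as_int, values.astype(float)):
            bad = np.argwhere(as_int != values.astype(float))[0]
            raise ParseError(
                f"{matrix_path}: non-integer entry at variant "
                f"{variants[bad[0]]!r}, individual {individuals[bad[1]]!r}"
            )
        values = as_int
    out_of_range = (values < 0) | (values > 2)
    if out_of_range.any():
        r, c = np.argwhere(out_of_range)[0]
        raise ParseError(
            f"{matrix_path}: genotype {values[r, c]} out of range {{0,1,2}} at "
            f"variant {variants[r]!r}, individual {individuals[c]!r}"
        )
    vmap_frame = pd.read_csv(map_path, sep="\t", header=None, names=["variant", "gene"],
                             dtype=str)
    variant_gene = dict(zip(vmap_frame["variant"], vmap_frame["gene"]))
    unmapped = [v for v in variants if v not in variant_gene]
    if unmapped:
        raise ParseError(f"{map_path}: variants missing from the map: {unmapped}")
    return GenotypeData(
        individuals=individuals,
        variants=variants,
        counts=sp.csr_matrix(values, dtype=np.int8),
        variant_gene={v: variant_gene[v] for v in variants},
    )


def write_genotypes(data: GenotypeData, matrix_path: str | Path,
                    map_path: str | Path) -> None:
    frame = pd.DataFrame(data.to_dense(), index=data.variants,
                         columns=data.individuals)
    frame.index.name = "variant"
    frame.to_csv(matrix_path, sep="\t")
    with open(map_path, "w") as fh:
        for v in data.variants:
            fh.write(f"{v}\t{data.variant_gene[v]}\n")


def read_phenotypes(path: str | Path) -> PhenotypeLabels:
    frame = pd.read_csv(path, sep="\t", header=None, names=["individual", "label"],
                        dtype={"individual": str})
    labels = pd.Series(frame["label"].to_numpy(), index=frame["individual"])
    return PhenotypeLabels(labels)


def write_phenotypes(labels: PhenotypeLabels, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ind, lab in labels.labels.items():
            fh.write(f"{ind}\t{int(lab)}\n")


def write_marginals(gene_posterior: Mapping[str, float], path: str | Path) -> None:
    """Write per-gene posteriors sorted by posterior desc, ties by gene id."""
    rows = sorted(gene_posterior.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w") as fh:
        fh.write("gene\tposterior\n")
        for gene, p in rows:
            fh.write(f"{gene}\t{p:.10g}\n")


def read_marginals(path: str | Path) -> dict[str, float]:
    frame = pd.read_csv(path, sep="\t", dtype={"gene": str})
    return dict(zip(frame["gene"], frame["posterior"].astype(float)))
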