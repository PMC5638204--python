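"""Scoring recovered gene sets against ground truth, plus a burden baseline.

Two selection protocols are supported:

* **threshold** -- a gene is *detected* when its posterior marginal is
  >= 0.2 and *suggestive* when it is in [0.05, 0.2);
* **top-P** -- the P highest-ranked genes are selected, with P the number
  of simulated causal genes.

Sensitivity is the fraction of causal genes recovered, precision the
fraction of recovered genes that are causal, and the F-measure their
harmonic mean.  Reported percentages are truncated to whole percent;
exact fractions are always kept alongside.

The internal baseline is a per-gene carrier burden test: a two-sided
Fisher exact test on the 2x2 table of (carries >= 1 variant in the gene)
by case/control status.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .io_formats import GenotypeData, PhenotypeLabels

__all__ = [
    "EvaluationResult",
    "detect_at_threshold",
    "top_p_selection",
    "confusion_metrics",
    "burden_baseline",
    "run_benchmark",
]

DETECTED_CUT = 0.2
SUGGESTIVE_CUT = 0.05


@dataclass
class EvaluationResult:
    true_positives: int
    false_positives: int
    false_negatives: int
    sensitivity: float
    precision: float
    f_measure: float
    mode: str = "threshold"
    thresholds: tuple = ()
    empty_selection: bool = False

    @property
    def sensitivity_percent(self) -> int:
        """Truncated whole-percent sensitivity (floor)."""
        return int(math.floor(self.sensitivity * 100 + 1e-12))

    @property
    def precision_percent(self) -> int:
        return int(math.floor(self.precision * 100 + 1e-12))


def detect_at_threshold(marginals: pd.Series,
                        detected_cut: float = DETECTED_CUT,
                        suggestive_cut: float = SUGGESTIVE_CUT
                        ) -> tuple[set[str], set[str]]:
    """Split genes into detected (>= detected_cut) and suggestive bands."""
    if not (0.0 < suggestive_cut < detected_cut < 1.0):
        raise ValueError("need 0 < suggestive_cut < detected_cut < 1")
    marginals = pd.Series(marginals)
    detected = set(marginals.index[marginals >= detected_cut])
    suggestive = set(marginals.index[(marginals >= suggestive_cut)
                                     & (marginals < detected_cut)])
    return detected, suggestive


def top_p_selection(marginals: pd.Series, p: int) -> set[str]:
    """The P highest-marginal genes; ties resolved by gene id."""
    marginals = pd.Series(marginals)
    if p > len(marginals):
        raise ValueError(f"P={p} exceeds the {len(marginals)} scored genes")
    ranked = sorted(marginals.items(), key=lambda kv: (-kv[1], kv[0]))
    return {gene for gene, _ in ranked[:p]}


def confusion_metrics(selected: set[str], truth: set[str],
                      mode: str = "threshold", thresholds: tuple = ()
                      ) -> EvaluationResult:
    """Confusion counts and derived fractions for one selected gene set."""
    if not truth:
        raise ValueError("truth set must be nonempty")
    tp = len(selected & truth)
    fp = len(selected - truth)
    fn = len(truth - selected)
    sensitivity = tp / (tp + fn)
    empty = (tp + fp) == 0
    precision = 1.0 if empty else tp / (tp + fp)
    if sensitivity + precision == 0.0:
        f_measure = 0.0
    else:
        f_measure = 2.0 * sensitivity * precision / (sensitivity + precision)
    return EvaluationResult(
        true_positives=tp, false_positives=fp, false_negatives=fn,
        sensitivity=sensitivity, precision=precision, f_measure=f_measure,
        mode=mode, thresholds=thresholds, empty_selection=empty)


def burden_baseline(genotypes: GenotypeData,
                    labels: PhenotypeLabels) -> pd.Series:
    """Per-gene carrier-burden p-values (two-sided Fisher exact test).

    A gene with no carriers at all gets p = 1 (degenerate, flagged by the
    attached ``flagged_empty`` attribute listing those genes).
    """
    status = np.array([labels.labels[j] for j in genotypes.individuals])
    n_cases = int(status.sum())
    n_controls = len(status) - n_cases
    carrier = genotypes.counts > 0  # variants x individuals, bool
    gene_of = np.array([genotypes.variant_gene[v] for v in genotypes.variants])
    pvals: dict[str, float] = {}
    empty: list[str] = []
    for gene in sorted(set(gene_of)):
        rows = np.flatnonzero(gene_of == gene)
        carries = np.asarray(carrier[rows].sum(axis=0)).ravel() > 0
        a = int((carries & (status == 1)).sum())   # case carriers
        b = int((carries & (status == 0)).sum())   # control carriers
        if a + b == 0:
            pvals[gene] = 1.0
            empty.append(gene)
            continue
        table = [[a, n_cases - a], [b, n_controls - b]]
        pvals[gene] = float(fisher_exact(table, alternative="two-sided")[1])
    out = pd.Series(pvals, name="pvalue").sort_values(kind="mergesort")
    out.flagged_empty = empty
    return out


def run_benchmark(scenarios, methods=("conflux", "burden"), replicates: int = 3,
                  seed: int = 0, progress=None) -> pd.DataFrame:
    """Run methods over simulated scenarios and tabulate recovery metrics.

    ``scenarios`` is a list of dicts of keyword arguments understood by
    :func:`conflux.pipeline.simulate_scenario`; each is rerun ``replicates``
    times with distinct derived seeds.  Returns one row per (scenario,
    method, replicate, mode).  Failed replicates are recorded with an
    ``error`` column rather than dropped.
    """
    from .pipeline import score_scenario, simulate_scenario

    rows = []
    for s_idx, scenario_kwargs in enumerate(scenarios):
        for rep in range(replicates):
            rep_seed = (seed + 7919 * s_idx + 104729 * rep) % (2 ** 31)
            try:
                scenario, network = simulate_scenario(seed=rep_seed,
                                                      **scenario_kwargs)
                scores = score_scenario(scenario, network, methods=methods)
            except Exception as exc:  # recorded, not silently dropped
                for method in methods:
                    for mode in ("threshold", "topP"):
                        rows.append({"scenario": s_idx, "method": method,
                                     "replicate": rep, "mode": mode,
                                     "error": str(exc)})
                continue
            p = len(scenario.causal_genes)
            for method in methods:
                marginals = scores[method]
                if method == "burden":
                    # ascending p-values -> descending score
                    ranking = 1.0 - marginals
                    detected, _ = detect_at_threshold(
                        ranking, detected_cut=1.0 - 0.05 / len(marginals),
                        suggestive_cut=0.5)
                else:
                    ranking = marginals
                    detected, _ = detect_at_threshold(ranking)
                for mode, selected in (
                        ("threshold", detected),
                        ("topP", top_p_selection(ranking, p))):
                    res = confusion_metrics(selected, scenario.causal_genes,
                                            mode=mode)
                    rows.append({
                        "scenario": s_idx, "method": method, "replicate": rep,
                        "mode": mode, "tp": res.true_positives,
                        "fp": res.false_positives, "fn": res.false_negatives,
                        "sensitivity": res.sensitivity,
                        "precision": res.precision,
                        "f_measure": res.f_measure, "error": "",
                    })
            if progress is not None:
                progress(s_idx, rep)
    return pd.DataFrame(rows)
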