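"""Empirical type I error and power over simulation replicates.

Per replicate, the type I error rate is the fraction of known-null genes
called significant at a fixed level alpha, and power is the fraction of
known-causal genes called significant — the denominators are the full null
and causal gene counts, so degenerate genes (whose statistic is undefined)
stay in the denominator but can never be significant.  Across replicates we
track, per gene, how often it reaches significance; that per-gene frequency
is the per-gene power estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import GeneTestResult

__all__ = [
    "ReplicateEvaluation",
    "GeneSignificanceTally",
    "AggregateSummary",
    "evaluate_replicate",
    "tally_gene",
    "aggregate",
]


@dataclass(frozen=True)
class ReplicateEvaluation:
    """Type I error and power of one replicate at one significance level."""

    replicate_index: int
    alpha: float
    n_null_genes: int
    n_causal_genes: int
    false_positives: int
    true_positives: int

    @property
    def type_I_rate(self) -> float:
        return self.false_positives / self.n_null_genes

    @property
    def power_rate(self) -> float:
        return self.true_positives / self.n_causal_genes


@dataclass(frozen=True)
class GeneSignificanceTally:
    """How often one gene reaches significance across replicates."""

    gene: str
    alpha: float
    n_significant: int
    n_replicates: int

    @property
    def frequency(self) -> float:
        return self.n_significant / self.n_replicates


@dataclass(frozen=True)
class AggregateSummary:
    """Mean and sample SD (ddof=1) of per-replicate rates at one level."""

    alpha: float
    n_replicates: int
    mean_type_I: float
    sd_type_I: float  # nan when fewer than 2 replicates
    mean_power: float
    sd_power: float


def _significant(result: GeneTestResult, alpha: float) -> bool:
    return not math.isnan(result.p_value) and result.p_value < alpha


def evaluate_replicate(
    results: Sequence[GeneTestResult],
    causal_genes: set[str],
    alpha: float,
    replicate_index: int = 0,
) -> ReplicateEvaluation:
    """Count false and true positives among one replicate's gene results.

    Significance is strict (p < alpha); degenerate genes with undefined
    p-values count as non-significant but remain in the denominators.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not causal_genes:
        raise ValueError("empty causal-gene truth set")
    tested = {r.gene for r in results}
    unknown = causal_genes - tested
    if unknown:
        raise ValueError(f"causal genes absent from results: {sorted(unknown)[:5]}")

    fp = tp = n_null = n_causal = 0
    for r in results:
        causal = r.gene in causal_genes
        sig = _significant(r, alpha)
        if causal:
            n_causal += 1
            tp += sig
        else:
            n_null += 1
            fp += sig
    if n_null == 0:
        raise ValueError("no null genes in results")
    return ReplicateEvaluation(replicate_index, alpha, n_null, n_causal, fp, tp)


def tally_gene(
    results_by_replicate: Sequence[Sequence[GeneTestResult]], gene: str, alpha: float
) -> GeneSignificanceTally:
    """Count the replicates in which ``gene`` is significant at ``alpha``."""
    n_sig = 0
    for i, results in enumerate(results_by_replicate):
        match = [r for r in results if r.gene == gene]
        if not match:
            raise ValueError(f"gene {gene!r} absent from replicate {i}")
        n_sig += _significant(match[0], alpha)
    return GeneSignificanceTally(gene, alpha, n_sig, len(results_by_replicate))


def aggregate(evaluations: Sequence[ReplicateEvaluation]) -> AggregateSummary:
    """Mean and sample standard deviation of rates across replicates."""
    if not evaluations:
        raise ValueError("no evaluations to aggregate")
    alphas = {e.alpha for e in evaluations}
    if len(alphas) != 1:
        raise ValueError(f"evaluations mix alpha levels: {sorted(alphas)}")
    t1 = np.array([e.type_I_rate for e in evaluations])
    pw = np.array([e.power_rate for e in evaluations])
    n = len(evaluations)
    return AggregateSummary(
        alpha=evaluations[0].alpha,
        n_replicates=n,
        mean_type_I=float(t1.mean()),
        sd_type_I=float(t1.std(ddof=1)) if n >= 2 else math.nan,
        mean_power=float(pw.mean()),
        sd_power=float(pw.std(ddof=1)) if n >= 2 else math.nan,
    )
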