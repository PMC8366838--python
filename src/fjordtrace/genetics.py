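"""Bayesian assignment of individuals to ecotype from SNP genotypes.

Implements the Rannala–Mountain individual-assignment likelihood: each
candidate source population's allele frequencies get a symmetric
Dirichlet(1/k) prior with uniform mean (k = number of alleles observed at
the locus across all samples), and an individual's multilocus genotype is
scored by the posterior-predictive probability given the reference allele
counts.  Likelihoods are accumulated in log space and converted to
percentage scores via log-sum-exp; an individual is labelled only if its
top score exceeds a threshold (80% here) and it was typed at enough loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "SnpGenotype",
    "ReferencePanel",
    "AssignmentResult",
    "genotype_loglik",
    "assign",
    "assign_all",
]

Call = tuple[str, str] | None


@dataclass(frozen=True)
class SnpGenotype:
    """One individual's diploid calls, ordered as the panel's loci."""

    individual_id: str
    calls: tuple[Call, ...]

    @property
    def n_typed(self) -> int:
        return sum(c is not None for c in self.calls)


@dataclass
class ReferencePanel:
    """Per-locus allele-count registry for the candidate source populations.

    ``counts[pop][locus][allele]`` holds reference gene-copy counts; the
    allele registry per locus spans every allele seen in any block of the
    input (reference or study), so study-only alleles carry zero reference
    count rather than raising.
    """

    loci: tuple[str, ...]
    populations: tuple[str, ...]
    counts: dict[str, list[dict[str, int]]]

    def __post_init__(self) -> None:
        for pop in self.populations:
            if pop not in self.counts:
                raise ValueError(f"missing counts for population {pop!r}")
            if len(self.counts[pop]) != len(self.loci):
                raise ValueError(f"counts for {pop!r} do not cover all loci")
        for pop_counts in self.counts.values():
            for locus_counts in pop_counts:
                if any(c < 0 for c in locus_counts.values()):
                    raise ValueError("negative allele count")

    def alleles(self, locus_index: int) -> tuple[str, ...]:
        seen: set[str] = set()
        for pop in self.populations:
            seen.update(self.counts[pop][locus_index])
        return tuple(sorted(seen))

    def k(self, locus_index: int) -> int:
        """Distinct alleles observed anywhere at this locus (>= 1)."""
        return max(1, len(self.alleles(locus_index)))

    def register_alleles(self, genotypes: list[SnpGenotype]) -> None:
        """Ensure every study allele exists in the registry (count 0)."""
        for g in genotypes:
            if len(g.calls) != len(self.loci):
                raise ValueError(
                    f"genotype {g.individual_id} has {len(g.calls)} calls "
                    f"for {len(self.loci)} loci"
                )
            for li, call in enumerate(g.calls):
                if call is None:
                    continue
                for allele in call:
                    for pop in self.populations:
                        self.counts[pop][li].setdefault(allele, 0)


@dataclass(frozen=True)
class AssignmentResult:
    individual_id: str
    n_typed: int
    loglik: dict[str, float]
    scores: dict[str, float]
    label: str  # population name or "unassigned"
    reason: str  # passed | score_below_threshold | too_few_loci


def _locus_genotype_logprob(
    call: tuple[str, str], locus_counts: dict[str, int], k: int
) -> float:
    """Posterior-predictive log-probability of one diploid genotype.

    With reference copy counts n_a (total n) and a symmetric Dirichlet(1/k)
    prior the predictive genotype probabilities are

        P(aa) = (n_a + 1/k)(n_a + 1 + 1/k) / ((n + 1)(n + 2))
        P(ab) = 2 (n_a + 1/k)(n_b + 1/k) / ((n + 1)(n + 2))
    """
    a, b = call
    for allele in (a, b):
        if allele not in locus_counts:
            raise KeyError(
                f"allele {allele!r} absent from the locus registry; "
                "register study alleles before scoring"
            )
    n = sum(locus_counts.values())
    prior = 1.0 / k
    denom = (n + 1.0) * (n + 2.0)
    na = locus_counts[a] + prior
    if a == b:
        p = na * (na + 1.0) / denom
    else:
        nb = locus_counts[b] + prior
        p = 2.0 * na * nb / denom
    return math.log(p)


def genotype_loglik(
    genotype: SnpGenotype, panel: ReferencePanel, population: str
) -> float:
    """Multilocus log-likelihood of a genotype under one source population.

    Missing loci contribute nothing (log 1); an individual typed at zero
    loci therefore has log-likelihood 0 under every population.
    """
    if population not in panel.populations:
        raise KeyError(f"unknown population {population!r}")
    if len(genotype.calls) != len(panel.loci):
        raise ValueError("genotype does not cover the panel's loci")
    pop_counts = panel.counts[population]
    total = 0.0
    for li, call in enumerate(genotype.calls):
        if call is None:
            continue
        total += _locus_genotype_logprob(call, pop_counts[li], panel.k(li))
    return total


def assign(
    genotype: SnpGenotype,
    panel: ReferencePanel,
    threshold: float = 80.0,
    min_loci: int = 20,
) -> AssignmentResult:
    """Score a genotype against all candidate populations and label it.

    Scores are percentages of the summed likelihoods over candidates
    (computed via log-sum-exp).  The label is the top-scoring population iff
    its score strictly exceeds ``threshold`` and the individual was typed at
    ``min_loci`` or more loci; the loci filter takes precedence in the
    recorded reason.  Ties never exceed a >50 threshold, so they fall to
    "unassigned".
    """
    if not 50.0 < threshold <= 100.0:
        raise ValueError("threshold must be in (50, 100]")
    if min_loci < 0:
        raise ValueError("min_loci must be >= 0")
    logliks = {pop: genotype_loglik(genotype, panel, pop) for pop in panel.populations}
    values = np.array(list(logliks.values()))
    lse = logsumexp(values)
    scores = {
        pop: float(100.0 * math.exp(ll - lse)) for pop, ll in logliks.items()
    }
    best = max(panel.populations, key=lambda p: scores[p])
    if genotype.n_typed < min_loci:
        label, reason = "unassigned", "too_few_loci"
    elif scores[best] > threshold:
        label, reason = best, "passed"
    else:
        label, reason = "unassigned", "score_below_threshold"
    return AssignmentResult(
        individual_id=genotype.individual_id,
        n_typed=genotype.n_typed,
        loglik=logliks,
        scores=scores,
        label=label,
        reason=reason,
    )


def assign_all(
    genotypes: list[SnpGenotype],
    panel: ReferencePanel,
    threshold: float = 80.0,
    min_loci: int = 20,
) -> pd.DataFrame:
    """Assignment report for a cohort, one row per individual."""
    panel.register_alleles(genotypes)
    rows = []
    for g in genotypes:
        res = assign(g, panel, threshold=threshold, min_loci=min_loci)
        row: dict[str, object] = {
            "individual_id": res.individual_id,
            "n_typed": res.n_typed,
        }
        for pop in panel.populations:
            row[f"loglik_{pop.lower()}"] = res.loglik[pop]
        for pop in panel.populations:
            row[f"score_{pop.lower()}"] = res.scores[pop]
        row["label"] = res.label
        row["reason"] = res.reason
        rows.append(row)
    return pd.DataFrame(rows)
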