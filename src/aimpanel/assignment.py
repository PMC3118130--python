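"""Likelihood-based assignment of individual genotypes to reference breeds.

The genotype-frequency assignment test: under Hardy–Weinberg proportions and
independence between loci, the likelihood of a diploid multilocus genotype in
population *i* is the product over loci of p² (reference-allele homozygote),
2p(1−p) (heterozygote) or (1−p)² (alternate homozygote), with p the
population's reference-allele frequency.  Frequencies of exactly 0 or 1 are
clamped to small substitutes before taking logs.  Confidence is graded by the
base-10 log-likelihood ratio (LLR) of the origin population against the best
alternative: thresholds 0/1/2/3 demand the origin be 1/10/100/1000 times more
likely than any other reference population.  An individual whose LLR fails
the threshold falls back to the population with the highest likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import FrequencyPanel, GenotypeTable
from .simulate import sample_frequencies

__all__ = ["AssignmentConfig", "AssignmentResult", "genotype_loglik",
           "assign", "pool_populations"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssignmentConfig:
    """Clamping constants and LLR stringency thresholds (base-10 logs)."""

    zero_replacement: float = 1e-5
    one_replacement: float = 0.99999
    thresholds: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)

    def __post_init__(self):
        object.__setattr__(self, "thresholds",
                           tuple(float(t) for t in self.thresholds))
        if not (0.0 < self.zero_replacement < self.one_replacement < 1.0):
            raise ValueError(
                "need 0 < zero_replacement < one_replacement < 1")
        if any(b < a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be non-decreasing")


@dataclass(frozen=True)
class AssignmentResult:
    """Per-individual log-likelihoods, LLR and per-threshold assignments.

    ``llr[i]`` is the base-10 log-likelihood of individual *i*'s origin
    population minus the best log-likelihood among the other populations.
    ``correct[t][i]`` is True iff ``llr[i] > t`` (strict).  ``assigned[t][i]``
    is the origin when correct, otherwise the argmax-likelihood population
    (which can coincide with the origin when 0 < llr <= t without counting
    as a confident assignment at that stringency).
    """

    individuals: tuple[str, ...]
    populations: tuple[str, ...]
    true_pop: tuple[str, ...]
    loglik: np.ndarray                      # (N, K)
    llr: np.ndarray                         # (N,)
    best_pop: tuple[str, ...]               # argmax population per individual
    assigned: Mapping[float, tuple[str, ...]]
    correct: Mapping[float, np.ndarray]

    @property
    def thresholds(self) -> tuple[float, ...]:
        return tuple(self.correct)

    def success_rate(self, threshold: float) -> float:
        """Fraction of individuals confidently assigned to their origin."""
        return float(np.mean(self.correct[threshold]))

    def success_pct(self, threshold: float) -> float:
        return 100.0 * self.success_rate(threshold)

    def per_population_success(self, threshold: float) -> dict[str, float]:
        """Per-breed fraction of its own individuals correctly assigned."""
        labels = np.asarray(self.true_pop)
        ok = np.asarray(self.correct[threshold])
        return {p: float(ok[labels == p].mean())
                for p in dict.fromkeys(self.true_pop)}


def _clamp(freq: np.ndarray, cfg: AssignmentConfig) -> np.ndarray:
    out = freq.copy()
    out[out <= 0.0] = cfg.zero_replacement
    out[out >= 1.0] = cfg.one_replacement
    return out


def genotype_loglik(gt: GenotypeTable, panel: FrequencyPanel,
                    loci: Sequence[str] | None = None,
                    cfg: AssignmentConfig | None = None) -> np.ndarray:
    """Base-10 multilocus log-likelihood of each individual in each population.

    Missing genotypes contribute a factor of 1 (log 0.0), so likelihoods are
    comparable across populations within an individual but not across
    individuals with different call patterns.
    """
    cfg = cfg or AssignmentConfig()
    loci = tuple(loci) if loci is not None else panel.loci
    if len(loci) == 0:
        raise ValueError("empty locus subset")
    sub_panel = panel.subset_loci(loci)
    sub_gt = gt.subset_loci(loci)

    p = _clamp(sub_panel.freq, cfg)         # (K, L)
    logp = np.log10(p)
    logq = np.log10(1.0 - p)
    hom_ref = 2.0 * logp                    # dosage 2
    het = np.log10(2.0) + logp + logq       # dosage 1
    hom_alt = 2.0 * logq                    # dosage 0

    g = sub_gt.dosage
    a2 = (g == 2.0).astype(float)
    a1 = (g == 1.0).astype(float)
    a0 = (g == 0.0).astype(float)
    return a2 @ hom_ref.T + a1 @ het.T + a0 @ hom_alt.T


def assign(gt: GenotypeTable, panel: FrequencyPanel,
           loci: Sequence[str] | None = None,
           cfg: AssignmentConfig | None = None) -> AssignmentResult:
    """Run the LLR assignment test for every individual at every threshold."""
    cfg = cfg or AssignmentConfig()
    if panel.n_populations < 2:
        raise ValueError("assignment requires at least two reference "
                         "populations")
    missing = set(gt.true_pop) - set(panel.populations)
    if missing:
        raise ValueError(f"origin populations absent from panel: "
                         f"{sorted(missing)}")
    ll = genotype_loglik(gt, panel, loci, cfg)
    pops = panel.populations
    N, K = ll.shape

    true_idx = np.array([panel.pop_index(p) for p in gt.true_pop])
    own = ll[np.arange(N), true_idx]
    others = ll.copy()
    others[np.arange(N), true_idx] = -np.inf
    llr = own - others.max(axis=1)

    # argmax with deterministic tie-breaking by population identifier
    best = []
    n_ties = 0
    pop_order = sorted(range(K), key=lambda i: pops[i])
    for i in range(N):
        m = ll[i].max()
        winners = [j for j in pop_order if ll[i, j] == m]
        if len(winners) > 1:
            n_ties += 1
        best.append(pops[winners[0]])
    if n_ties:
        log.warning("assignment: %d argmax ties resolved by population "
                    "identifier order", n_ties)

    assigned: dict[float, tuple[str, ...]] = {}
    correct: dict[float, np.ndarray] = {}
    for t in cfg.thresholds:
        ok = llr > t
        assigned[t] = tuple(tp if o else b
                            for tp, b, o in zip(gt.true_pop, best, ok))
        correct[t] = ok
    return AssignmentResult(gt.individuals, pops, gt.true_pop, ll, llr,
                            tuple(best), assigned, correct)


def pool_populations(panel: FrequencyPanel, gt: GenotypeTable,
                     pops_to_merge: Sequence[str],
                     new_name: str | None = None
                     ) -> tuple[FrequencyPanel, GenotypeTable]:
    """Merge undifferentiated reference populations into a single breed.

    The merged population's frequencies are re-estimated from the union of
    the member genotypes (allele-count weighting, missing-aware); the other
    populations keep their panel rows.  The merged row takes the position of
    the first merged population in the panel's order.
    """
    pops_to_merge = [str(p) for p in pops_to_merge]
    if len(pops_to_merge) < 2:
        raise ValueError("need at least two populations to pool")
    for p in pops_to_merge:
        panel.pop_index(p)                  # raises on unknown population
    if len(set(pops_to_merge)) >= panel.n_populations:
        raise ValueError("cannot merge all populations into one")
    name = new_name or "+".join(pops_to_merge)

    mapping = {p: name for p in pops_to_merge}
    new_gt = gt.relabel(mapping)

    member_ids = [ind for ind, p in zip(gt.individuals, gt.true_pop)
                  if p in pops_to_merge]
    if not member_ids:
        raise ValueError("no genotyped individuals in the populations to merge")
    merged_block = new_gt.subset_individuals(member_ids)
    merged_freqs = sample_frequencies(merged_block)
    merged_row = merged_freqs.freq[0]
    merged_n = int(merged_freqs.n[0])

    keep_pops, keep_rows, keep_n = [], [], []
    inserted = False
    for i, p in enumerate(panel.populations):
        if p in pops_to_merge:
            if not inserted:
                keep_pops.append(name)
                keep_rows.append(merged_row)
                keep_n.append(merged_n)
                inserted = True
            continue
        keep_pops.append(p)
        keep_rows.append(panel.freq[i])
        keep_n.append(int(panel.n[i]))
    new_panel = FrequencyPanel(keep_pops, panel.loci, np.vstack(keep_rows),
                               np.array(keep_n))
    return new_panel, new_gt
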