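"""Multi-breed SNP genotype simulator under the Balding–Nichols F-model.

Emulates the statistical structure of a dense SNP-chip dataset spanning
several livestock breeds: an ancestral allele frequency per locus, Beta
(Balding–Nichols) divergence of each breed around it parameterized directly
by a per-breed F, optional recently-split breed pairs that remain nearly
undifferentiated from one another (the Angus / Red Angus situation), and a
chip-style ascertainment filter that discards loci whose pooled minor-allele
frequency falls below a threshold.

Every locus has its own random stream derived from ``(seed, locus_counter)``
so that enlarging a simulation appends loci without perturbing the ones
already drawn.  The emitted :class:`~aimpanel.core.FrequencyPanel` holds the
SAMPLE frequencies recomputed from the emitted genotypes, so panel and
genotypes are mutually consistent by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np

from .core import FrequencyPanel, GenotypeTable

__all__ = ["SimulationConfig", "simulate_panel", "sample_frequencies"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated multi-breed dataset.

    Parameters
    ----------
    n_breeds
        Number of breeds K (>= 2).
    n_loci
        Number of loci L that must PASS the ascertainment filter.
    breed_fst
        Per-breed divergence F_i in (0, 1), length K.  This is the quantity
        the F_ST estimators downstream are trying to recover.
    sample_sizes
        Diploid individuals per breed, each >= 2 (study-style breed panels
        run from ~10 to ~50).
    ancestral_maf_range
        Interval within (0, 0.5] the ancestral minor-allele frequency is
        drawn from (uniform); the minor allele is assigned to either allele
        with probability 1/2.
    min_maf_filter
        Loci with pooled sample MAF below this are discarded and redrawn,
        mimicking chip ascertainment toward common variants.
    related_pairs
        Breed-index pairs simulated from a shared recently-split ancestor,
        so the two members are nearly indistinguishable.
    within_pair_fst
        Divergence of each related-pair member from the pair ancestor.
    missing_rate
        Probability any single genotype call is missing (MCAR).
    seed
        Master seed; all randomness derives from it.
    """

    n_breeds: int
    n_loci: int
    breed_fst: tuple[float, ...]
    sample_sizes: tuple[int, ...]
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    min_maf_filter: float = 0.05
    related_pairs: tuple[tuple[int, int], ...] = ()
    within_pair_fst: float = 0.01
    missing_rate: float = 0.0
    seed: int = 0
    max_attempts: int | None = None     # default: 200 per locus + 1000

    def __post_init__(self):
        object.__setattr__(self, "breed_fst", tuple(float(f) for f in self.breed_fst))
        object.__setattr__(self, "sample_sizes", tuple(int(n) for n in self.sample_sizes))
        object.__setattr__(self, "related_pairs",
                           tuple((int(a), int(b)) for a, b in self.related_pairs))
        if self.n_breeds < 2:
            raise ValueError("n_breeds must be >= 2")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if len(self.breed_fst) != self.n_breeds:
            raise ValueError("breed_fst length must equal n_breeds")
        if len(self.sample_sizes) != self.n_breeds:
            raise ValueError("sample_sizes length must equal n_breeds")
        if not all(0.0 < f < 1.0 for f in self.breed_fst):
            raise ValueError("all breed_fst values must lie in (0, 1)")
        if not all(n >= 2 for n in self.sample_sizes):
            raise ValueError("all sample sizes must be >= 2")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.min_maf_filter < 0.5):
            raise ValueError("min_maf_filter must lie in [0, 0.5)")
        if self.min_maf_filter >= hi:
            raise ValueError("min_maf_filter must be below the upper end of "
                             "ancestral_maf_range")
        if not (0.0 < self.within_pair_fst < 1.0):
            raise ValueError("within_pair_fst must lie in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        flat = [i for pair in self.related_pairs for i in pair]
        if any(not 0 <= i < self.n_breeds for i in flat):
            raise ValueError("related_pairs indices out of range")
        if len(set(flat)) != len(flat):
            raise ValueError("a breed may belong to at most one related pair")
        if any(a == b for a, b in self.related_pairs):
            raise ValueError("a related pair must name two distinct breeds")

    @property
    def population_names(self) -> tuple[str, ...]:
        return tuple(f"B{i + 1:02d}" for i in range(self.n_breeds))

    @classmethod
    def study_like(cls, n_loci: int = 4000, seed: int = 0,
                   **overrides) -> "SimulationConfig":
        """A 17-breed configuration shaped like a real cattle-breed survey.

        Unequal diploid sample sizes between 10 and 28 per breed, per-breed
        divergence spread over 0.02–0.30 (so some breeds are much more
        distinct than others, as in real breed panels), and one
        recently-split breed pair that stays nearly undifferentiated.
        """
        sizes = (23, 25, 24, 25, 10, 21, 25, 25, 28,
                 25, 21, 19, 15, 23, 25, 25, 25)
        k = len(sizes)
        fst = tuple(round(f, 4)
                    for f in np.linspace(0.02, 0.30, k))
        defaults = dict(n_breeds=k, n_loci=n_loci, breed_fst=fst,
                        sample_sizes=sizes, related_pairs=((0, 12),),
                        seed=seed)
        defaults.update(overrides)
        return cls(**defaults)


def _bn_draw(rng: np.random.Generator, p: float, f: float, size=None):
    """Balding–Nichols draw: Beta(p(1-F)/F, (1-p)(1-F)/F) around p."""
    ratio = (1.0 - f) / f
    return rng.beta(max(p * ratio, 1e-12), max((1.0 - p) * ratio, 1e-12), size=size)


def _draw_locus(cfg: SimulationConfig, counter: int):
    """Draw one candidate locus; returns (per-breed genotype arrays)."""
    rng = np.random.default_rng([cfg.seed, counter])
    lo, hi = cfg.ancestral_maf_range
    p = rng.uniform(lo, hi)
    if rng.random() < 0.5:          # minor allele is A or a with equal odds
        p = 1.0 - p

    paired = {}
    for a, b in cfg.related_pairs:
        f_pair = 0.5 * (cfg.breed_fst[a] + cfg.breed_fst[b])
        q = _bn_draw(rng, p, f_pair)
        paired[a] = _bn_draw(rng, q, cfg.within_pair_fst)
        paired[b] = _bn_draw(rng, q, cfg.within_pair_fst)

    freqs = np.empty(cfg.n_breeds)
    for i in range(cfg.n_breeds):
        freqs[i] = paired[i] if i in paired else _bn_draw(rng, p, cfg.breed_fst[i])

    genos = []
    for i, n_i in enumerate(cfg.sample_sizes):
        g = rng.binomial(2, freqs[i], size=n_i).astype(float)
        if cfg.missing_rate > 0.0:
            g[rng.random(n_i) < cfg.missing_rate] = np.nan
        genos.append(g)
    return genos


def _pooled_maf(genos: list[np.ndarray]) -> float:
    alls = np.concatenate(genos)
    ok = ~np.isnan(alls)
    if not ok.any():
        return np.nan
    p = alls[ok].sum() / (2.0 * ok.sum())
    return min(p, 1.0 - p)


def simulate_panel(cfg: SimulationConfig) -> tuple[FrequencyPanel, GenotypeTable]:
    """Simulate genotypes for K breeds and the matching frequency panel.

    Loci are drawn one at a time and kept only if their pooled sample MAF
    passes ``cfg.min_maf_filter`` and every (breed, locus) cell retains at
    least one non-missing call; rejected loci are replaced until ``n_loci``
    pass.  Raises ``RuntimeError`` if the filter rejects so many candidates
    that the attempt budget (200 per requested locus + 1000) is exhausted.
    """
    pops = cfg.population_names
    accepted: list[list[np.ndarray]] = []
    max_attempts = cfg.max_attempts or (200 * cfg.n_loci + 1000)
    counter = 0
    while len(accepted) < cfg.n_loci:
        if counter >= max_attempts:
            raise RuntimeError(
                f"ascertainment filter min_maf={cfg.min_maf_filter} rejected "
                f"{counter - len(accepted)} of {counter} candidate loci; "
                "filter appears unattainable for this configuration"
            )
        genos = _draw_locus(cfg, counter)
        counter += 1
        maf = _pooled_maf(genos)
        if np.isnan(maf) or maf < cfg.min_maf_filter:
            continue
        if any(np.isnan(g).all() for g in genos):
            continue                      # a breed lost every call at this locus
        accepted.append(genos)

    loci = [f"SNP{j + 1:06d}" for j in range(cfg.n_loci)]
    individuals = [f"{pop}_{k + 1:03d}"
                   for pop, n_i in zip(pops, cfg.sample_sizes)
                   for k in range(n_i)]
    true_pop = [pop for pop, n_i in zip(pops, cfg.sample_sizes)
                for _ in range(n_i)]

    dosage = np.empty((len(individuals), cfg.n_loci))
    for j, genos in enumerate(accepted):
        dosage[:, j] = np.concatenate(genos)

    gt = GenotypeTable(individuals, loci, dosage, true_pop)
    panel = sample_frequencies(gt)
    return panel, gt


def sample_frequencies(gt: GenotypeTable) -> FrequencyPanel:
    """Estimate per-population reference-allele frequencies from genotypes.

    p = (sum of dosages) / (2 × non-missing calls) per (population, locus).
    A cell with zero non-missing calls is an error (the frequency would be
    undefined); the offending population and locus are named.
    """
    pops = gt.populations
    labels = np.asarray(gt.true_pop)
    K, L = len(pops), gt.n_loci
    freq = np.empty((K, L))
    n = np.empty(K, dtype=int)
    for i, pop in enumerate(pops):
        block = gt.dosage[labels == pop, :]
        n[i] = block.shape[0]
        calls = (~np.isnan(block)).sum(axis=0)
        if np.any(calls == 0):
            j = int(np.argmax(calls == 0))
            raise ValueError(
                f"population {pop!r} has no non-missing calls at locus "
                f"{gt.loci[j]!r}; frequency undefined"
            )
        freq[i, :] = np.nansum(block, axis=0) / (2.0 * calls)
    return FrequencyPanel(pops, gt.loci, freq, n)
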