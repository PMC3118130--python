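"""Per-locus informativeness scores and marker rankings.

Implements the four families of single-SNP informativeness statistics used
for building reduced ancestry-informative panels from a breed × locus
allele-frequency matrix:

* ``delta`` — mean absolute allele-frequency difference over population pairs;
* Wright's F_ST — var(p)/(p̄(1−p̄)), globally over all K populations or
  averaged over pairs;
* Weir & Cockerham's F_ST in the variance-components (ANOVA) form, which
  corrects for unequal sample sizes and may legitimately be negative;
* a PCA loading score — the sum of a locus's squared loadings over the
  principal components deemed significant against randomized panels.

All scores are computed from population allele frequencies alone; ranking
uses a deterministic total order (decreasing score, ties broken by locus
identifier).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .core import FrequencyPanel

__all__ = [
    "MarkerRanking",
    "PcaConfig",
    "delta_informativeness",
    "wright_fst",
    "wc_fst",
    "pca_informativeness",
    "rank_markers",
    "compare_rankings",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarkerRanking:
    """Scores for one method plus the induced deterministic marker order."""

    method: str
    loci: tuple[str, ...]
    scores: np.ndarray
    order: np.ndarray      # permutation of range(L): positions into loci/scores

    def __init__(self, method, loci, scores, order):
        object.__setattr__(self, "method", str(method))
        object.__setattr__(self, "loci", tuple(str(l) for l in loci))
        object.__setattr__(self, "scores", np.asarray(scores, dtype=float))
        object.__setattr__(self, "order", np.asarray(order, dtype=int))
        if self.scores.shape != (len(self.loci),):
            raise ValueError("scores length must match loci")
        if sorted(self.order.tolist()) != list(range(len(self.loci))):
            raise ValueError("order must be a permutation of the locus indices")

    @property
    def ranked_loci(self) -> tuple[str, ...]:
        return tuple(self.loci[j] for j in self.order)

    def top(self, n: int) -> tuple[str, ...]:
        return self.ranked_loci[:n]

    def score_of(self, locus: str) -> float:
        return float(self.scores[self.loci.index(locus)])


def rank_markers(loci: Sequence[str], scores: Sequence[float],
                 method: str = "custom") -> MarkerRanking:
    """Order loci by decreasing score, ties broken by locus identifier.

    NaN scores are rejected (they have no place in a total order) with the
    offending loci named.
    """
    loci = tuple(str(l) for l in loci)
    scores = np.asarray(scores, dtype=float)
    if np.isnan(scores).any():
        bad = [l for l, s in zip(loci, scores) if np.isnan(s)]
        raise ValueError(f"NaN scores for loci: {bad}")
    order = sorted(range(len(loci)), key=lambda j: (-scores[j], loci[j]))
    return MarkerRanking(method, loci, scores, np.array(order, dtype=int))


def delta_informativeness(panel: FrequencyPanel) -> MarkerRanking:
    """Mean |p_i − p_j| over all unordered population pairs, per locus."""
    K = panel.n_populations
    if K < 2:
        raise ValueError("delta requires at least two populations")
    p = panel.freq
    total = np.zeros(panel.n_loci)
    pairs = list(combinations(range(K), 2))
    for i, j in pairs:
        total += np.abs(p[i] - p[j])
    return rank_markers(panel.loci, total / len(pairs), "delta")


def _wright_two(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Wright's F_ST for one population pair, vectorized over loci."""
    pbar = 0.5 * (p + q)
    denom = pbar * (1.0 - pbar)
    var = 0.25 * (p - q) ** 2           # population (divide-by-K) variance, K=2
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(denom > 0.0, var / np.where(denom > 0.0, denom, 1.0), 0.0)
    return fst


def wright_fst(panel: FrequencyPanel, mode: str = "global") -> MarkerRanking:
    """Wright's F_ST = var(p_A) / (p̄(1−p̄)) per locus.

    ``mode="global"`` uses the population (divide-by-K) variance and the
    unweighted mean over all K populations; ``mode="pairwise"`` computes the
    two-population statistic for each pair and averages.  A locus whose mean
    frequency is 0 or 1 (monomorphic everywhere) scores 0.
    """
    K = panel.n_populations
    if K < 2:
        raise ValueError("Wright's F_ST requires at least two populations")
    p = panel.freq
    if mode == "global":
        pbar = p.mean(axis=0)
        var = p.var(axis=0)             # ddof=0
        denom = pbar * (1.0 - pbar)
        mono = denom <= 0.0
        if mono.any():
            log.warning("global Wright's F_ST: %d monomorphic loci scored 0",
                        int(mono.sum()))
        score = np.where(mono, 0.0, var / np.where(mono, 1.0, denom))
        return rank_markers(panel.loci, score, "wright_global")
    if mode == "pairwise":
        pairs = list(combinations(range(K), 2))
        total = np.zeros(panel.n_loci)
        for i, j in pairs:
            total += _wright_two(p[i], p[j])
        return rank_markers(panel.loci, total / len(pairs), "wright_pairwise")
    raise ValueError(f"unknown mode {mode!r}")


def _wc_components(p: np.ndarray, n: np.ndarray,
                   warn: bool = True) -> np.ndarray:
    """Weir–Cockerham F_ST from sample frequencies, vectorized over loci.

    ANOVA mean squares among (MSP) and within (MSG) populations with the
    unequal-sample-size correction n_c; negative estimates are retained.
    ``p`` is (r, L), ``n`` is (r,) sample sizes in ALLELES (gametes): the
    ANOVA is on gametes, and with allele counts the estimator is unbiased
    in the undifferentiated limit (checked by Monte Carlo).
    """
    r = p.shape[0]
    n = n.astype(float)
    N = n.sum()
    pw = (n[:, None] * p).sum(axis=0) / N
    msp = (n[:, None] * (p - pw) ** 2).sum(axis=0) / (r - 1)
    msg = (n[:, None] * p * (1.0 - p)).sum(axis=0) / (n - 1.0).sum()
    n_c = (N - (n ** 2).sum() / N) / (r - 1)
    denom = msp + (n_c - 1.0) * msg
    degenerate = denom == 0.0
    if degenerate.any():
        # common in pairwise mode (locus monomorphic in both members of a
        # pair), so callers may downgrade to debug
        (log.warning if warn else log.debug)(
            "W&C F_ST: %d degenerate loci scored 0", int(degenerate.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(degenerate, 0.0, (msp - msg) / np.where(degenerate, 1.0, denom))
    return fst


def wc_fst(panel: FrequencyPanel, mode: str = "global") -> MarkerRanking:
    """Weir & Cockerham's F_ST per locus (variance-components form).

    The panel's diploid sample sizes are converted to allele counts (2n)
    inside the variance-components formulas; estimates can be negative and
    are left so.  ``mode="pairwise"`` averages the two-population estimates
    over all pairs.
    """
    K = panel.n_populations
    if K < 2:
        raise ValueError("W&C's F_ST requires at least two populations")
    if np.any(panel.n < 2):
        raise ValueError("W&C's F_ST requires per-population sample sizes >= 2")
    alleles = 2 * panel.n
    if mode == "global":
        score = _wc_components(panel.freq, alleles)
        return rank_markers(panel.loci, score, "wc_global")
    if mode == "pairwise":
        pairs = list(combinations(range(K), 2))
        total = np.zeros(panel.n_loci)
        for i, j in pairs:
            total += _wc_components(panel.freq[[i, j]], alleles[[i, j]],
                                    warn=False)
        return rank_markers(panel.loci, total / len(pairs), "wc_pairwise")
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class PcaConfig:
    """Settings for the randomized significance test of principal components.

    ``n_random_matrices`` panels are built by resampling, independently per
    locus, the K frequency values with replacement across populations; a
    component rank is significant when the observed eigenvalue exceeds the
    ``significance_rule`` quantile of the randomized eigenvalues of the same
    rank.
    """

    n_random_matrices: int = 100
    significance_rule: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if self.n_random_matrices < 1:
            raise ValueError("n_random_matrices must be >= 1")
        if not (0.0 < self.significance_rule <= 1.0):
            raise ValueError("significance_rule must lie in (0, 1]")


def _locus_stream(seed: int, locus: str) -> np.random.Generator:
    # seeded from the locus identifier so results are invariant to column order
    digest = hashlib.blake2b(locus.encode(), digest_size=8).digest()
    return np.random.default_rng([seed, int.from_bytes(digest, "big")])


def _eigvals_rows(x: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of the column covariance of a (K, L) matrix."""
    xc = x - x.mean(axis=0, keepdims=True)
    gram = xc @ xc.T / (x.shape[0] - 1)
    return np.sort(np.linalg.eigvalsh(gram))[::-1]


def pca_informativeness(panel: FrequencyPanel,
                        cfg: PcaConfig | None = None) -> MarkerRanking:
    """Sum of squared loadings over the significant principal components.

    PCA is run on the population × locus frequency matrix with each locus
    (column) centered by its across-population mean and no scaling; loadings
    are the unit right-singular vectors.  Component significance is decided
    against per-locus randomized panels (see :class:`PcaConfig`).  If no
    component is significant every score is 0 (with a warning).
    """
    cfg = cfg or PcaConfig()
    K, L = panel.n_populations, panel.n_loci
    if K < 3:
        raise ValueError("PCA informativeness requires at least 3 populations")
    if L < K:
        raise ValueError("PCA informativeness requires at least as many loci "
                         "as populations")
    x = panel.freq
    xc = x - x.mean(axis=0, keepdims=True)
    # SVD of the centered matrix: eigenvalues from singular values, loadings
    # from the right singular vectors.
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigvals = s ** 2 / (K - 1)

    m = cfg.n_random_matrices
    rand = np.empty((m, K, L))
    for j, locus in enumerate(panel.loci):
        rng = _locus_stream(cfg.seed, locus)
        idx = rng.integers(0, K, size=(m, K))
        rand[:, :, j] = x[idx, j]
    randc = rand - rand.mean(axis=1, keepdims=True)
    grams = np.einsum("mkl,mjl->mkj", randc, randc) / (K - 1)
    rand_eigs = np.sort(np.linalg.eigvalsh(grams), axis=1)[:, ::-1]  # (m, K)

    thresh = np.quantile(rand_eigs[:, : len(eigvals)], cfg.significance_rule,
                         axis=0)
    significant = eigvals > thresh
    n_sig = int(significant.sum())
    log.info("PCA informativeness: %d significant components of %d", n_sig,
             len(eigvals))
    if n_sig == 0:
        log.warning("PCA informativeness: no significant components; "
                    "all scores set to 0")
        return rank_markers(panel.loci, np.zeros(L), "pca")
    loadings = vt[significant, :]       # (n_sig, L) unit right singular vectors
    score = (loadings ** 2).sum(axis=0)
    return rank_markers(panel.loci, score, "pca")


def compare_rankings(r1: MarkerRanking, r2: MarkerRanking,
                     top_n: int = 500) -> tuple[float, int]:
    """Spearman rank correlation of two score vectors and top-n overlap.

    Scores are aligned on the shared locus set (which must be identical);
    ties receive average ranks, as in the standard Spearman statistic.
    """
    if set(r1.loci) != set(r2.loci):
        raise ValueError("rankings cover different locus sets")
    loci = sorted(r1.loci)
    pos1 = {l: j for j, l in enumerate(r1.loci)}
    pos2 = {l: j for j, l in enumerate(r2.loci)}
    s1 = r1.scores[[pos1[l] for l in loci]]
    s2 = r2.scores[[pos2[l] for l in loci]]
    rho = stats.spearmanr(s1, s2).statistic
    overlap = len(set(r1.top(top_n)) & set(r2.top(top_n)))
    return float(rho), overlap
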