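"""Experiment orchestration: panel-size curves, controls, cross-validation.

Given a ranked marker list, assignment success is traced by cumulatively
adding markers in blocks (default 20, up to 400).  The resulting
success-vs-panel-size curve follows a law of diminishing returns and is
summarized by the asymptotic regression y = a + b·exp(c·x) (a the asymptote,
b the deficit at x = 0, c the log rate); inverting the fit yields the panel
size needed for a target success level.  Controls and diagnostics:
randomly-drawn panels (negative control), leave-out cross-validation with
re-estimated training frequencies and re-ranked markers, per-breed type I/II
error rates, per-breed mean MAF, and the correlation between a breed's mean
differentiation and its assignment success.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .assignment import AssignmentConfig, AssignmentResult, assign
from .core import FrequencyPanel, GenotypeTable
from .informativeness import MarkerRanking, _wright_two, wright_fst
from .simulate import sample_frequencies

__all__ = [
    "CurvePoint", "CurveFit", "ErrorTable",
    "cumulative_assignment", "fit_assignment_curve", "invert_curve",
    "random_panel_control", "cross_validate", "error_rates",
    "differentiation_vs_success", "per_breed_differentiation", "per_breed_maf",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CurvePoint:
    """Assignment success (percent) at one cumulative panel size."""

    n_markers: int
    success_pct: Mapping[float, float]              # threshold -> overall %
    per_pop_pct: Mapping[float, Mapping[str, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class CurveFit:
    """Parameters of the asymptotic success curve y = a + b·exp(c·x).

    A diminishing-returns fit has a > 0 (the asymptotic success), b < 0
    (the deficit at zero markers) and c < 0 (decay rate).  ``targets`` maps
    a success level to the marker count obtained by inverting the fit.
    """

    a: float
    b: float
    c: float
    targets: Mapping[float, float] = field(default_factory=dict)

    def predict(self, x) -> np.ndarray:
        return self.a + self.b * np.exp(self.c * np.asarray(x, dtype=float))

    @property
    def diminishing_returns(self) -> bool:
        return self.a > 0 and self.b < 0 and self.c < 0


@dataclass(frozen=True)
class ErrorTable:
    """Per-population type I / type II assignment error fractions.

    type I: a breed's own individuals assigned elsewhere, out of its own;
    type II: foreign individuals assigned to the breed, out of everyone
    assigned to it (0 when nobody is assigned to it).
    """

    populations: tuple[str, ...]
    type_I: np.ndarray
    type_II: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"type_I": self.type_I, "type_II": self.type_II},
                            index=list(self.populations))


def marker_grid(max_markers: int, step: int) -> list[int]:
    if step <= 0:
        raise ValueError("step must be positive")
    if max_markers < step:
        raise ValueError("max_markers must be at least one step")
    return list(range(step, max_markers + 1, step))


def cumulative_assignment(panel: FrequencyPanel, gt: GenotypeTable,
                          ranking: MarkerRanking, max_markers: int = 400,
                          step: int = 20,
                          cfg: AssignmentConfig | None = None
                          ) -> list[CurvePoint]:
    """Success curve from cumulatively added top-ranked markers.

    For every grid point n = step, 2·step, ..., max_markers the top-n loci
    of ``ranking`` form the panel and every individual is assigned; overall
    and per-breed success percentages are recorded at each threshold.
    """
    cfg = cfg or AssignmentConfig()
    if len(ranking.loci) < max_markers:
        raise ValueError(
            f"ranking covers {len(ranking.loci)} loci < max_markers="
            f"{max_markers}")
    points = []
    for n in marker_grid(max_markers, step):
        res = assign(gt, panel, ranking.top(n), cfg)
        succ = {t: res.success_pct(t) for t in cfg.thresholds}
        per_pop = {t: {p: 100.0 * v
                       for p, v in res.per_population_success(t).items()}
                   for t in cfg.thresholds}
        points.append(CurvePoint(n, succ, per_pop))
    return points


def _asymptotic(x, a, b, c):
    return a + b * np.exp(c * x)


def fit_assignment_curve(points: Sequence[CurvePoint],
                         threshold: float = 0.0,
                         targets: Sequence[float] = ()) -> CurveFit:
    """Least-squares fit of y = a + b·exp(c·x) to a success curve.

    Initialized at a₀ = max success, c₀ = −0.01, b₀ = y(first) − a₀;
    unweighted residuals, tolerance 1e−8.  Degenerate (constant) curves and
    non-convergence raise, the latter carrying the best iterate found.
    """
    if len(points) < 4:
        raise ValueError("need at least 4 curve points to fit 3 parameters")
    x = np.array([p.n_markers for p in points], dtype=float)
    y = np.array([p.success_pct[threshold] for p in points], dtype=float)
    if np.ptp(y) == 0.0:
        raise ValueError("success curve is constant; asymptotic fit is "
                         "degenerate")
    a0 = float(y.max())
    c0 = -0.01
    b0 = float(y[0] - a0)
    if b0 == 0.0:
        b0 = -1.0
    res = optimize.least_squares(
        lambda p: _asymptotic(x, *p) - y, x0=[a0, b0, c0],
        ftol=1e-8, xtol=1e-8, gtol=1e-8, max_nfev=10000)
    if not res.success:
        raise RuntimeError(
            f"asymptotic fit did not converge: {res.message}; best iterate "
            f"a={res.x[0]:.4g}, b={res.x[1]:.4g}, c={res.x[2]:.4g}")
    a, b, c = (float(v) for v in res.x)
    fit = CurveFit(a, b, c)
    inv = {}
    for tgt in targets:
        try:
            inv[float(tgt)] = invert_curve(fit, tgt)
        except ValueError as e:
            log.warning("target %.4g%% not invertible: %s", tgt, e)
            inv[float(tgt)] = float("nan")
    return CurveFit(a, b, c, inv)


def invert_curve(fit: CurveFit, target_pct: float) -> float:
    """Marker count at which the fitted curve reaches ``target_pct``.

    Closed form x* = ln((target − a)/b)/c; a target at or above the
    asymptote is unreachable and raises.
    """
    if target_pct >= fit.a:
        raise ValueError(
            f"asymptote below target: a = {fit.a:.4g} <= {target_pct:.4g}")
    ratio = (target_pct - fit.a) / fit.b
    if ratio <= 0.0 or fit.c == 0.0:
        raise ValueError("target not reachable from the fitted parameters")
    return float(np.log(ratio) / fit.c)


def random_panel_control(panel: FrequencyPanel, gt: GenotypeTable,
                         n_sets: int = 20, set_size: int = 400,
                         step: int = 20,
                         cfg: AssignmentConfig | None = None,
                         seed: int = 0) -> dict[float, np.ndarray]:
    """Mean success curve over randomly drawn marker panels.

    ``n_sets`` uniform without-replacement draws of ``set_size`` loci, each
    evaluated cumulatively on the same grid; the per-grid-point mean success
    is returned for every threshold (the LLR > 3 row is the conventional
    negative control).  The RNG stream is independent of the simulator's.
    """
    cfg = cfg or AssignmentConfig()
    if set_size > panel.n_loci:
        raise ValueError(f"set_size {set_size} exceeds panel loci "
                         f"{panel.n_loci}")
    rng = np.random.default_rng([seed, 0x7A2D0])
    grid = marker_grid(set_size, step)
    acc = {t: np.zeros(len(grid)) for t in cfg.thresholds}
    for _ in range(n_sets):
        chosen = rng.choice(panel.n_loci, size=set_size, replace=False)
        loci = [panel.loci[j] for j in chosen]
        scores = np.arange(set_size, 0, -1, dtype=float)   # draw order
        ranking = MarkerRanking("random", loci, scores,
                                np.arange(set_size))
        pts = cumulative_assignment(panel, gt, ranking, set_size, step, cfg)
        for k, p in enumerate(pts):
            for t in cfg.thresholds:
                acc[t][k] += p.success_pct[t]
    return {t: v / n_sets for t, v in acc.items()}


@dataclass(frozen=True)
class CrossValidationResult:
    points: tuple[CurvePoint, ...]
    holdout_individuals: tuple[str, ...]
    training_panel: FrequencyPanel
    ranking: MarkerRanking


def cross_validate(gt: GenotypeTable,
                   rank_fn: Callable[[FrequencyPanel], MarkerRanking]
                   | None = None,
                   cfg: AssignmentConfig | None = None,
                   size_cutoff: int = 50, holdout_small: int = 5,
                   seed: int = 0, max_markers: int = 400, step: int = 20,
                   queries: Mapping[str, Sequence[str]] | None = None,
                   reuse_ranking: MarkerRanking | None = None
                   ) -> CrossValidationResult:
    """Training/holdout evaluation with re-estimated reference frequencies.

    Per breed: if its reference size exceeds ``size_cutoff`` the holdout is
    all of its designated query individuals (``queries[breed]``; such breeds
    must have reference individuals beyond the queries), otherwise
    ``holdout_small`` randomly chosen members.  Training frequencies are
    re-estimated without the holdouts and markers re-ranked on them via
    ``rank_fn`` (default: pairwise Wright's F_ST) unless ``reuse_ranking``
    supplies a fixed full-data ranking; holdouts are then assigned against
    the training panel over the cumulative grid.
    """
    cfg = cfg or AssignmentConfig()
    rank_fn = rank_fn or (lambda p: wright_fst(p, "pairwise"))
    rng = np.random.default_rng([seed, 0xCF])

    holdout: list[str] = []
    for pop in gt.populations:
        members = list(gt.members(pop))
        if len(members) > size_cutoff:
            pool = list(queries.get(pop, members)) if queries else members
            chosen = pool
        else:
            pool = list(queries.get(pop, members)) if queries else members
            if len(pool) < holdout_small:
                raise ValueError(
                    f"breed {pop!r} has only {len(pool)} query individuals; "
                    f"cannot hold out {holdout_small}")
            chosen = [pool[i] for i in
                      rng.choice(len(pool), size=holdout_small,
                                 replace=False)]
        if len(members) - len(set(chosen) & set(members)) < 2:
            raise ValueError(
                f"breed {pop!r} would retain fewer than 2 training "
                "individuals after holding out its queries")
        holdout.extend(chosen)

    holdout_set = set(holdout)
    training_ids = [i for i in gt.individuals if i not in holdout_set]
    train_gt = gt.subset_individuals(training_ids)
    train_panel = sample_frequencies(train_gt)
    ranking = reuse_ranking if reuse_ranking is not None \
        else rank_fn(train_panel)
    hold_gt = gt.subset_individuals(holdout)
    points = cumulative_assignment(train_panel, hold_gt, ranking,
                                   max_markers, step, cfg)
    return CrossValidationResult(tuple(points), tuple(holdout), train_panel,
                                 ranking)


def error_rates(result: AssignmentResult, threshold: float) -> ErrorTable:
    """Type I / II error fractions per breed at one stringency level.

    Uses the assigned labels at the threshold, so the identity
    overall assigned-accuracy = 1 − (size-weighted mean type I) holds
    exactly.
    """
    if threshold not in result.assigned:
        raise ValueError(f"no assignments computed at threshold {threshold}")
    assigned = np.asarray(result.assigned[threshold])
    labels = np.asarray(result.true_pop)
    pops = result.populations
    t1 = np.zeros(len(pops))
    t2 = np.zeros(len(pops))
    for i, p in enumerate(pops):
        own = labels == p
        if own.any():
            t1[i] = np.mean(assigned[own] != p)
        to_p = assigned == p
        t2[i] = np.mean(labels[to_p] != p) if to_p.any() else 0.0
    return ErrorTable(pops, t1, t2)


def per_breed_differentiation(panel: FrequencyPanel) -> dict[str, float]:
    """Mean pairwise Wright's F_ST per breed over the full locus set.

    Each pair's F_ST is averaged across loci; a breed's differentiation is
    the mean over its pairs with every other breed.
    """
    K = panel.n_populations
    if K < 2:
        raise ValueError("need at least two populations")
    acc = {p: [] for p in panel.populations}
    for i, j in combinations(range(K), 2):
        mean_fst = float(np.mean(_wright_two(panel.freq[i], panel.freq[j])))
        acc[panel.populations[i]].append(mean_fst)
        acc[panel.populations[j]].append(mean_fst)
    return {p: float(np.mean(v)) for p, v in acc.items()}


def differentiation_vs_success(per_breed_success: Mapping[str, float],
                               per_breed_fst: Mapping[str, float]
                               ) -> tuple[float, float]:
    """Spearman correlation between breed success and breed differentiation."""
    breeds = sorted(per_breed_success)
    if set(breeds) != set(per_breed_fst):
        raise ValueError("success and differentiation cover different breeds")
    if len(breeds) < 3:
        raise ValueError("need at least 3 breeds for a rank correlation")
    s = np.array([per_breed_success[b] for b in breeds])
    f = np.array([per_breed_fst[b] for b in breeds])
    if np.ptp(s) == 0.0 or np.ptp(f) == 0.0:
        raise ValueError("constant vector: rank correlation undefined")
    r = stats.spearmanr(s, f)
    return float(r.statistic), float(r.pvalue)


def per_breed_maf(panel: FrequencyPanel) -> dict[str, float]:
    """Mean minor-allele frequency min(p, 1−p) across loci, per breed."""
    maf = np.minimum(panel.freq, 1.0 - panel.freq)
    return {p: float(maf[i].mean()) for i, p in enumerate(panel.populations)}
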