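"""Curves, asymptotic regression, controls, CV, error tables."""

import numpy as np
import pytest

from aimpanel import (AssignmentConfig, CurveFit, CurvePoint, FrequencyPanel,
                      GenotypeTable, assign, cross_validate,
                      cumulative_assignment, differentiation_vs_success,
                      error_rates, fit_assignment_curve, invert_curve,
                      per_breed_differentiation, per_breed_maf,
                      random_panel_control, sample_frequencies,
                      wright_fst)
from aimpanel.evaluation import marker_grid


def _points(xs, ys, threshold=0.0):
    return [CurvePoint(int(x), {threshold: float(y)}) for x, y in zip(xs, ys)]


class TestCumulativeAssignment:
    def test_grid_has_expected_points(self):
        assert marker_grid(400, 20) == list(range(20, 401, 20))
        assert len(marker_grid(400, 20)) == 20

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            marker_grid(400, 0)

    def test_perfectly_discriminating_loci_reach_full_success(self):
        eye = np.array([[1.0] * 6, [0.0] * 6])
        panel = FrequencyPanel(["A", "B"], [f"L{j}" for j in range(6)],
                               eye, [10, 10])
        dosage = np.vstack([np.full(6, 2.0), np.zeros(6)])
        gt = GenotypeTable(["a1", "b1"], panel.loci, dosage, ["A", "B"])
        ranking = wright_fst(panel, "pairwise")
        pts = cumulative_assignment(panel, gt, ranking, 6, 2)
        for p in pts:
            for t in (0.0, 1.0, 2.0, 3.0):
                assert p.success_pct[t] == 100.0

    def test_related_pair_success_lags_separated_breeds(self):
        from aimpanel import SimulationConfig, simulate_panel
        cfg = SimulationConfig(n_breeds=6, n_loci=800,
                               breed_fst=(0.15,) * 6,
                               sample_sizes=(25,) * 6,
                               related_pairs=((0, 1),), seed=21)
        panel, gt = simulate_panel(cfg)
        ranking = wright_fst(panel, "pairwise")
        pts = cumulative_assignment(panel, gt, ranking, 100, 100)
        per_pop = pts[0].per_pop_pct[0.0]
        related = np.mean([per_pop["B01"], per_pop["B02"]])
        others = np.mean([per_pop[b] for b in per_pop
                          if b not in ("B01", "B02")])
        assert related < others


class TestCurveFitting:
    def test_exact_synthetic_points_recovered(self):
        xs = np.arange(20, 401, 20)
        a, b, c = 100.0, -50.0, -0.01
        pts = _points(xs, a + b * np.exp(c * xs))
        fit = fit_assignment_curve(pts)
        assert fit.a == pytest.approx(a, abs=1e-6)
        assert fit.b == pytest.approx(b, abs=1e-6)
        assert fit.c == pytest.approx(c, abs=1e-6)
        assert fit.diminishing_returns

    def test_constant_curve_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_assignment_curve(_points([20, 40, 60, 80], [90, 90, 90, 90]))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_assignment_curve(_points([20, 40, 60], [50, 60, 70]))

    def test_noisy_points_recover_asymptote(self):
        xs = np.arange(20, 401, 20)
        a, b, c = 98.0, -60.0, -0.015
        rng = np.random.default_rng(123)
        recovered = []
        for _ in range(100):
            ys = a + b * np.exp(c * xs) + rng.normal(0, 1.0, size=len(xs))
            recovered.append(fit_assignment_curve(_points(xs, ys)).a)
        assert np.mean(recovered) == pytest.approx(a, abs=2.0)

    def test_inversion_round_trips_the_fit(self):
        xs = np.arange(20, 401, 20)
        fit = fit_assignment_curve(
            _points(xs, 100 - 50 * np.exp(-0.01 * xs)))
        for x in (50.0, 124.0, 333.0):
            y = float(fit.predict(x))
            assert invert_curve(fit, y) == pytest.approx(x, abs=1e-6)


class TestInvertCurve:
    def test_closed_form_hand_computation(self):
        fit = CurveFit(100.0, -60.0, -0.02)
        assert invert_curve(fit, 95.0) == pytest.approx(
            np.log(5.0 / 60.0) / -0.02)
        assert invert_curve(fit, 95.0) == pytest.approx(124.245, abs=1e-3)

    def test_x_zero_at_intercept_value(self):
        fit = CurveFit(100.0, -60.0, -0.02)
        assert invert_curve(fit, 40.0) == pytest.approx(0.0, abs=1e-12)

    def test_target_above_asymptote_rejected(self):
        with pytest.raises(ValueError, match="asymptote"):
            invert_curve(CurveFit(99.0, -50.0, -0.01), 99.9)


class TestRandomPanelControl:
    def test_reproducible_under_fixed_seed(self, standard_sim):
        panel, gt = standard_sim
        a = random_panel_control(panel, gt, n_sets=1, set_size=40, step=20,
                                 seed=5)
        b = random_panel_control(panel, gt, n_sets=1, set_size=40, step=20,
                                 seed=5)
        for t in a:
            assert np.array_equal(a[t], b[t])

    def test_chance_level_under_no_differentiation(self):
        from aimpanel import SimulationConfig, simulate_panel
        cfg = SimulationConfig(n_breeds=4, n_loci=300,
                               breed_fst=(0.002,) * 4,
                               sample_sizes=(25,) * 4, seed=13)
        panel, _ = simulate_panel(cfg)
        # fresh query individuals drawn from the POOLED frequencies: they
        # carry no breed signal at all (true chance-level queries), unlike
        # reference individuals, whose own genotypes shaped the panel
        rng = np.random.default_rng(99)
        per_pop = 25
        pooled = panel.freq.mean(axis=0)
        dosage = rng.binomial(
            2, pooled, size=(per_pop * panel.n_populations, panel.n_loci)
        ).astype(float)
        pops = [p for p in panel.populations for _ in range(per_pop)]
        gt = GenotypeTable([f"q{k}" for k in range(len(pops))], panel.loci,
                           dosage, pops)
        rc = random_panel_control(panel, gt, n_sets=3, set_size=100, step=100,
                                  seed=1)
        # at LLR > 0 success hovers near the 1/K chance level
        assert abs(rc[0.0][-1] - 100.0 / 4) < 15.0

    def test_oversized_set_rejected(self, small_panel, tiny_gt):
        with pytest.raises(ValueError):
            random_panel_control(small_panel, tiny_gt, n_sets=1, set_size=10)


class TestCrossValidate:
    def test_holdouts_never_in_training_frequencies(self, standard_sim):
        _, gt = standard_sim
        cv = cross_validate(gt, seed=3, max_markers=40, step=40)
        held = set(cv.holdout_individuals)
        train_ids = [i for i in gt.individuals if i not in held]
        expected = sample_frequencies(gt.subset_individuals(train_ids))
        assert np.array_equal(cv.training_panel.freq, expected.freq)
        assert len(held) == 5 * len(gt.populations)

    def test_breed_too_small_raises_naming_breed(self):
        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 3, size=(10, 30)).astype(float)
        pops = ["big"] * 6 + ["tiny"] * 4
        gt = GenotypeTable([f"i{k}" for k in range(10)],
                           [f"L{j}" for j in range(30)], dosage, pops)
        with pytest.raises(ValueError, match="tiny"):
            cross_validate(gt, holdout_small=4, max_markers=30, step=30)

    def test_cv_success_not_above_resubstitution_on_average(self):
        from aimpanel import SimulationConfig, simulate_panel
        cv_s, resub_s = [], []
        for rep in range(3):
            cfg = SimulationConfig(n_breeds=5, n_loci=500,
                                   breed_fst=(0.08,) * 5,
                                   sample_sizes=(20,) * 5, seed=40 + rep)
            panel, gt = simulate_panel(cfg)
            ranking = wright_fst(panel, "pairwise")
            res = assign(gt, panel, ranking.top(60))
            resub_s.append(res.success_pct(0.0))
            cv = cross_validate(gt, seed=rep, max_markers=60, step=60)
            cv_s.append(cv.points[-1].success_pct[0.0])
        assert np.mean(cv_s) <= np.mean(resub_s)


class TestErrorRates:
    def _result(self):
        freq = np.array([[0.95, 0.9, 0.92], [0.05, 0.1, 0.6], [0.5, 0.45, 0.05]])
        panel = FrequencyPanel(["A", "B", "C"], ["L0", "L1", "L2"], freq,
                               [10, 10, 10])
        rng = np.random.default_rng(8)
        dosage = rng.integers(0, 3, size=(15, 3)).astype(float)
        gt = GenotypeTable([f"i{k}" for k in range(15)], panel.loci, dosage,
                           ["A"] * 5 + ["B"] * 5 + ["C"] * 5)
        return assign(gt, panel)

    def test_perfect_assignment_gives_zero_errors(self):
        panel = FrequencyPanel(["A", "B"], ["L0"], np.array([[1.0], [0.0]]),
                               [5, 5])
        gt = GenotypeTable(["a", "b"], ["L0"], np.array([[2.0], [0.0]]),
                           ["A", "B"])
        err = error_rates(assign(gt, panel), 0.0)
        assert np.allclose(err.type_I, 0.0) and np.allclose(err.type_II, 0.0)

    def test_direct_count_arithmetic(self):
        res = self._result()
        err = error_rates(res, 0.0)
        assigned = np.asarray(res.assigned[0.0])
        labels = np.asarray(res.true_pop)
        for i, p in enumerate(err.populations):
            own = labels == p
            assert err.type_I[i] == pytest.approx(
                np.sum((assigned != p) & own) / own.sum())

    def test_overall_accuracy_consistent_with_weighted_type_one(self):
        res = self._result()
        err = error_rates(res, 0.0)
        labels = np.asarray(res.true_pop)
        weights = np.array([(labels == p).sum() for p in err.populations])
        acc = np.mean(np.asarray(res.assigned[0.0]) == labels)
        assert acc == pytest.approx(
            1.0 - np.average(err.type_I, weights=weights))

    def test_population_receiving_no_assignments_has_zero_type_two(self):
        panel = FrequencyPanel(["A", "B", "C"], ["L0"],
                               np.array([[1.0], [0.0], [0.5]]), [5, 5, 5])
        gt = GenotypeTable(["a", "b"], ["L0"], np.array([[2.0], [0.0]]),
                           ["A", "B"])
        err = error_rates(assign(gt, panel), 0.0)
        assert err.type_II[err.populations.index("C")] == 0.0


class TestDifferentiationVsSuccess:
    def test_monotone_relationship_has_rho_one(self):
        succ = {"a": 60.0, "b": 80.0, "c": 95.0, "d": 99.0}
        fst = {"a": 0.02, "b": 0.05, "c": 0.1, "d": 0.2}
        rho, p = differentiation_vs_success(succ, fst)
        assert rho == pytest.approx(1.0)

    def test_constant_success_rejected(self):
        succ = {"a": 100.0, "b": 100.0, "c": 100.0}
        fst = {"a": 0.02, "b": 0.05, "c": 0.1}
        with pytest.raises(ValueError):
            differentiation_vs_success(succ, fst)

    def test_too_few_breeds_rejected(self):
        with pytest.raises(ValueError):
            differentiation_vs_success({"a": 1.0, "b": 2.0},
                                       {"a": 0.1, "b": 0.2})

    def test_positive_on_heterogeneous_simulation(self, study_sim):
        panel, gt = study_sim
        ranking = wright_fst(panel, "pairwise")
        res = assign(gt, panel, ranking.top(20))
        succ = {p: 100 * v
                for p, v in res.per_population_success(0.0).items()}
        rho, _ = differentiation_vs_success(succ,
                                            per_breed_differentiation(panel))
        assert rho > 0


class TestPerBreedMaf:
    def test_half_frequency_gives_half_maf(self):
        panel = FrequencyPanel(["A"], ["L0", "L1"],
                               np.array([[0.5, 0.5]]), [5])
        assert per_breed_maf(panel)["A"] == pytest.approx(0.5)

    def test_hand_computed_mean(self):
        panel = FrequencyPanel(["A"], ["L0", "L1"],
                               np.array([[0.9, 0.2]]), [5])
        assert per_breed_maf(panel)["A"] == pytest.approx(0.15)

    def test_invariant_to_allele_relabelling(self):
        rng = np.random.default_rng(2)
        f = rng.uniform(0, 1, size=(2, 10))
        p1 = FrequencyPanel(["A", "B"], [f"L{j}" for j in range(10)], f,
                            [5, 5])
        p2 = FrequencyPanel(["A", "B"], [f"L{j}" for j in range(10)], 1 - f,
                            [5, 5])
        assert per_breed_maf(p1) == pytest.approx(per_breed_maf(p2))
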