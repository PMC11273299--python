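import numpy as np
import pytest

from cocoonsex.optimize import (
    Dim,
    GAConfig,
    HyperParamSpace,
    classical_ga,
    crossover_rate,
    default_space,
    first_hitting_generation,
    grid_search,
    single_point_crossover,
    tlbo_refine,
    tlbpsga,
    tournament_select,
)


def _unit_space(d=7):
    return HyperParamSpace(tuple(Dim(f"x{i}", 0.0, 1.0) for i in range(d)))


def sphere(genes):
    """Maximum 1.0 at genes = 0.5 everywhere."""
    g = np.asarray(genes, dtype=float)
    return 1.0 - float(np.mean((g - 0.5) ** 2)) * 4.0


class TestDecode:
    def test_gene_bounds_map_to_dimension_bounds(self):
        space = default_space()
        lo = space.decode(np.zeros(7))
        hi = space.decode(np.ones(7))
        assert lo["learning_rate"] == pytest.approx(0.01)
        assert hi["learning_rate"] == pytest.approx(0.3)
        assert lo["n_estimators"] == 50 and hi["n_estimators"] == 500
        assert lo["subsample"] == 0.5 and hi["subsample"] == 1.0

    def test_integer_rounds_half_up(self):
        d = Dim("max_depth", 3, 10, "int")
        assert d.decode(0.5) == 7  # 6.5 rounds up

    def test_log_scale_midpoint_is_geometric_mean(self):
        d = Dim("learning_rate", 0.01, 0.3, "float", "log")
        assert d.decode(0.5) == pytest.approx(np.sqrt(0.01 * 0.3))

    def test_encode_decode_round_trip(self):
        space = default_space()
        params = {
            "learning_rate": 0.05, "n_estimators": 200, "max_depth": 6,
            "min_child_weight": 2.5, "gamma": 1.0, "subsample": 0.8,
            "colsample_bytree": 0.9,
        }
        back = space.decode(space.encode(params))
        for k, v in params.items():
            assert back[k] == pytest.approx(v, rel=1e-9)

    def test_out_of_range_gene_clipped_with_warning(self):
        space = _unit_space(2)
        with pytest.warns(UserWarning, match="clipped"):
            out = space.decode(np.array([-0.5, 1.5]))
        assert out["x0"] == 0.0 and out["x1"] == 1.0

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            Dim("bad", 1.0, 1.0)
        with pytest.raises(ValueError):
            Dim("bad", 0.0, 1.0, scale="log")


class TestOperators:
    def test_crossover_rate_linear_schedule(self):
        cfg = GAConfig(generations=100, r_min=0.6, r_max=0.95)
        assert crossover_rate(0, cfg) == pytest.approx(0.6)
        assert crossover_rate(100, cfg) == pytest.approx(0.95)
        assert crossover_rate(50, cfg) == pytest.approx(0.775)
        with pytest.raises(ValueError):
            crossover_rate(101, cfg)

    def test_single_point_crossover_swaps_tails(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([5.0, 6.0, 7.0, 8.0])
        c1, c2 = single_point_crossover(a, b, 2)
        assert np.array_equal(c1, [1, 2, 7, 8])
        assert np.array_equal(c2, [5, 6, 3, 4])

    def test_tournament_full_population_returns_global_best(self):
        rng = np.random.default_rng(0)
        pop = np.arange(10.0)[:, None]
        fits = np.arange(10.0)
        best = tournament_select(pop, fits, k=10, rng=rng)
        assert best[0] == 9.0

    def test_tournament_selection_pressure(self):
        rng = np.random.default_rng(1)
        pop = np.arange(10.0)[:, None]
        fits = np.arange(10.0)
        counts = np.zeros(10)
        for _ in range(10_000):
            counts[int(tournament_select(pop, fits, k=3, rng=rng)[0])] += 1
        assert counts.argmax() == 9
        assert np.all(np.diff(counts[2:]) >= 0)  # monotone in fitness (noise-proof tail)

    def test_tournament_oversized_k_rejected(self):
        with pytest.raises(ValueError):
            tournament_select(np.zeros((3, 1)), np.zeros(3), k=4,
                              rng=np.random.default_rng(0))


class TestGridSearch:
    def test_full_cartesian_product_evaluated(self):
        result = grid_search(_unit_space(7), [2] * 7, sphere)
        assert result.n_evaluations == 128

    def test_known_optimal_cell_found(self):
        space = _unit_space(2)
        target = np.array([1.0, 0.0])

        def rigged(genes):
            return -float(np.sum((np.asarray(genes) - target) ** 2))

        result = grid_search(space, [3, 3], rigged)
        assert np.allclose(result.best_genes, target)

    def test_deterministic_across_reruns(self):
        r1 = grid_search(_unit_space(3), [3, 3, 3], sphere)
        r2 = grid_search(_unit_space(3), [3, 3, 3], sphere)
        assert np.array_equal(r1.best_genes, r2.best_genes)
        assert r1.best_fitness == r2.best_fitness

    def test_budget_overflow_reports_cell_count(self):
        with pytest.raises(ValueError, match="2187"):
            grid_search(_unit_space(7), [3] * 7, sphere, budget=1000)


class TestTLBORefine:
    def test_hand_worked_teacher_update(self):
        # 1-D maximize f(x) = -x^2 on learners {0 (teacher), 4}, mean 2.
        # With rand = 1 and TF = 1 the learner moves to 4 + (0 - 2) = 2,
        # improving f from -16 to -4, so the update is accepted.
        old, teacher, mean, tf, rand = 4.0, 0.0, 2.0, 1.0, 1.0
        new = old + rand * (teacher - tf * mean)
        assert new == 2.0
        assert -(new**2) > -(old**2)

    def test_output_size_and_quality(self):
        rng = np.random.default_rng(2)
        pop = rng.random((20, 5))
        fits = np.array([sphere(p) for p in pop])
        refined, refined_fits = tlbo_refine(pop, fits, sphere, 10, rng)
        assert refined.shape == (10, 5)
        assert len(refined_fits) == 10
        # greedy acceptance + truncation: kept minimum beats the old median
        assert refined_fits.min() >= np.median(fits)

    def test_genes_stay_in_unit_box(self):
        rng = np.random.default_rng(3)
        pop = rng.random((15, 4))
        fits = np.array([sphere(p) for p in pop])
        refined, _ = tlbo_refine(pop, fits, sphere, 15, rng)
        assert refined.min() >= 0.0 and refined.max() <= 1.0

    def test_oversized_refined_size_rejected(self):
        rng = np.random.default_rng(4)
        pop = rng.random((5, 3))
        fits = np.zeros(5)
        with pytest.raises(ValueError):
            tlbo_refine(pop, fits, sphere, 6, rng)


class TestOptimizers:
    def test_classical_ga_solves_sphere(self):
        cfg = GAConfig(population_size=30, refined_size=30, generations=100,
                       seed=0)
        result = classical_ga(_unit_space(7), sphere, cfg)
        assert result.best_fitness >= 0.99
        assert np.all(np.diff(result.trajectory) >= 0)  # elitism

    def test_tlbpsga_solves_sphere(self):
        cfg = GAConfig(population_size=30, refined_size=30, generations=100,
                       seed=0)
        result = tlbpsga(_unit_space(7), sphere, cfg)
        assert result.best_fitness >= 0.99
        assert np.all(np.diff(result.trajectory) >= 0)

    def test_tlbpsga_converges_faster_on_paired_seeds(self):
        wins = 0
        for seed in range(6):
            cfg = GAConfig(population_size=30, refined_size=30,
                           generations=60, seed=seed)
            ga = classical_ga(_unit_space(7), sphere, cfg)
            tl = tlbpsga(_unit_space(7), sphere, cfg)
            hg = first_hitting_generation(ga.trajectory, 0.99)
            ht = first_hitting_generation(tl.trajectory, 0.99)
            if ht is not None and (hg is None or ht <= hg):
                wins += 1
        assert wins >= 5

    def test_tlbpsga_finds_rigged_optimum(self):
        target = np.array([0.25, 0.75, 0.5])

        def rigged(genes):
            return -float(np.sum((np.asarray(genes) - target) ** 2))

        for seed in range(3):
            cfg = GAConfig(population_size=50, refined_size=25,
                           generations=50, seed=seed)
            result = tlbpsga(_unit_space(3), rigged, cfg)
            assert np.allclose(result.best_genes, target, atol=0.05)

    def test_null_dynamics_without_variation_operators(self):
        # no mutation, no crossover, no refinement: every individual in
        # every generation is a copy of an initial one, and the best-so-far
        # trajectory is flat
        cfg = GAConfig(population_size=10, refined_size=10, generations=5,
                       r_min=0.0, r_max=0.0, mutation_rate=0.0, seed=3,
                       refine_each_generation=False, stagnation_window=0)
        result = classical_ga(_unit_space(4), sphere, cfg)
        assert np.allclose(result.trajectory, result.trajectory[0])

    def test_memoized_fitness_counts_and_values(self):
        from cocoonsex.optimize import make_cv_fitness

        rng = np.random.default_rng(5)
        y = np.repeat([0, 1], 30)
        X = rng.normal(size=(60, 3))
        X[:, 0] += y * 3
        space = default_space()
        fitness = make_cv_fitness(X, y, space, k=3, seed=0)
        genes = np.full(7, 0.5)
        assert fitness(genes) == fitness(genes)  # memoized, identical

    def test_stagnation_stops_early(self):
        cfg = GAConfig(population_size=10, refined_size=10, generations=200,
                       stagnation_window=5, mutation_rate=0.0,
                       r_min=0.0, r_max=0.0, refine_each_generation=False,
                       seed=6)
        result = tlbpsga(_unit_space(3), sphere, cfg)
        assert len(result.trajectory) < 50

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=10, refined_size=20)
        with pytest.raises(ValueError):
            GAConfig(mutation_rate=1.5)
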