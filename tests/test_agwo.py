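"""Grey wolf optimizer: update laws, archive, leader election, front-ends."""

import numpy as np
import pytest
from scipy import stats

from fswolf.agwo import (
    FeatureSelectionProblem,
    HypercubeGrid,
    LeaderSet,
    ParetoArchive,
    SearchSpace,
    Wolf,
    agwo_minimize,
    cell_probabilities,
    coefficient_vectors,
    decode_feature_mask,
    decode_hyperparams,
    dominates,
    encircle,
    gwo_minimize,
    hunt_position,
    linear_decay,
    select_cell,
    select_features_agwo,
    select_leaders,
    update_archive,
)
from fswolf.synthetic import PlantedFeatureSpec, generate_feature_table


class TestUpdateLaws:
    @pytest.mark.parametrize("t,T,expected", [(0, 100, 2.0), (100, 100, 0.0), (50, 100, 1.0)])
    def test_linear_decay(self, t, T, expected):
        assert linear_decay(t, T) == pytest.approx(expected)

    def test_decay_rejects_zero_horizon(self):
        with pytest.raises(ValueError):
            linear_decay(0, 0)

    def test_coefficient_ranges_and_mean(self):
        rng = np.random.default_rng(0)
        A, C = coefficient_vectors(0.0, rng, 4)
        assert np.allclose(A, 0.0)
        assert np.all((C >= 0) & (C <= 2))
        draws_A = np.concatenate(
            [coefficient_vectors(2.0, rng, 10)[0] for _ in range(1000)]
        )
        assert draws_A.min() >= -2 and draws_A.max() <= 2
        assert abs(draws_A.mean()) < 0.05

    def test_coefficients_deterministic_by_seed(self):
        a1 = coefficient_vectors(1.5, np.random.default_rng(42), 6)
        a2 = coefficient_vectors(1.5, np.random.default_rng(42), 6)
        assert np.array_equal(a1[0], a2[0]) and np.array_equal(a1[1], a2[1])

    def test_encircle_hand_case(self):
        new = encircle(
            np.array([0.0, 0.0]), np.array([1.0, 1.0]), np.array([0.5, 0.5]), np.array([1.0, 1.0])
        )
        assert np.allclose(new, [0.5, 0.5])

    def test_encircle_zero_A_jumps_to_leader(self):
        new = encircle(np.array([3.0]), np.array([-1.0]), np.array([0.0]), np.array([1.7]))
        assert np.allclose(new, [-1.0])

    def test_hunt_centroid_at_zero_a(self):
        leaders = LeaderSet(
            Wolf(np.array([0.0, 0.0]), (0.0,)),
            Wolf(np.array([3.0, 0.0]), (0.0,)),
            Wolf(np.array([0.0, 3.0]), (0.0,)),
        )
        new = hunt_position(np.array([9.0, 9.0]), leaders, 0.0, np.random.default_rng(0))
        assert np.allclose(new, [1.0, 1.0])

    def test_hunt_matches_hand_trace_dim1(self):
        rng = np.random.default_rng(5)
        leaders = LeaderSet(
            Wolf(np.array([1.0]), (0.0,)),
            Wolf(np.array([2.0]), (0.0,)),
            Wolf(np.array([3.0]), (0.0,)),
        )
        x = np.array([0.5])
        a = 1.2
        # replay the rng stream exactly as hunt_position consumes it
        replay = np.random.default_rng(5)
        parts = []
        for lead in (1.0, 2.0, 3.0):
            r1 = replay.uniform(size=1)
            r2 = replay.uniform(size=1)
            A = 2 * a * r1 - a
            C = 2 * r2
            parts.append(lead - A * np.abs(C * lead - x))
        expected = (parts[0] + parts[1] + parts[2]) / 3
        assert np.allclose(hunt_position(x, leaders, a, rng), expected, atol=1e-12)


class TestGwoMinimize:
    def test_sphere_convergence_and_monotone_history(self):
        space = SearchSpace(-5 * np.ones(5), 5 * np.ones(5))
        best, history = gwo_minimize(lambda x: float(x @ x), space, 30, 300, seed=0)
        assert best.fitness[0] < 1e-2
        assert all(b >= a for a, b in zip(history[1:], history[:-1]))

    def test_single_iteration_contract(self):
        space = SearchSpace(np.array([-1.0]), np.array([1.0]))
        best, history = gwo_minimize(lambda x: float(x[0] ** 2), space, 5, 1, seed=3)
        assert len(history) == 1
        assert best.fitness[0] <= history[0] + 1e-15

    def test_positions_stay_in_bounds(self):
        space = SearchSpace(np.array([0.0, 0.0]), np.array([1.0, 1.0]))
        seen = []

        def objective(x):
            seen.append(x.copy())
            return float((x - 2) @ (x - 2))  # optimum outside the box

        gwo_minimize(objective, space, 6, 30, seed=1)
        arr = np.array(seen)
        assert arr.min() >= 0 and arr.max() <= 1

    def test_nonfinite_objective_reported(self):
        space = SearchSpace(np.array([0.0]), np.array([1.0]))
        with pytest.raises(ValueError, match="non-finite"):
            gwo_minimize(lambda x: float("nan"), space, 3, 2, seed=0)


class TestDominance:
    @pytest.mark.parametrize(
        "f,g,expected",
        [((1, 1), (2, 2), True), ((1, 2), (2, 1), False), ((1, 1), (1, 1), False)],
    )
    def test_cases(self, f, g, expected):
        assert dominates(f, g) is expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            dominates((1.0,), (1.0, 2.0))


def _brute_force_front(points):
    front = []
    for i, f in enumerate(points):
        if not any(dominates(tuple(g), tuple(f)) for j, g in enumerate(points) if j != i):
            front.append(tuple(f))
    return set(front)


class TestArchive:
    def test_dominated_candidate_rejected(self):
        rng = np.random.default_rng(0)
        archive = ParetoArchive(capacity=10)
        grid = HypercubeGrid()
        update_archive(archive, Wolf(np.zeros(1), (1.0, 1.0)), grid, rng)
        update_archive(archive, Wolf(np.zeros(1), (2.0, 2.0)), grid, rng)
        assert [m.fitness for m in archive.members] == [(1.0, 1.0)]

    def test_dominating_candidate_clears_archive(self):
        rng = np.random.default_rng(0)
        archive = ParetoArchive(capacity=10)
        grid = HypercubeGrid()
        for f in [(1.0, 3.0), (3.0, 1.0), (2.0, 2.0)]:
            update_archive(archive, Wolf(np.zeros(1), f), grid, rng)
        update_archive(archive, Wolf(np.zeros(1), (0.5, 0.5)), grid, rng)
        assert [m.fitness for m in archive.members] == [(0.5, 0.5)]

    def test_stream_equals_bruteforce_front(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            points = rng.uniform(size=(200, 2))
            archive = ParetoArchive(capacity=10**9)
            grid = HypercubeGrid()
            for k, f in enumerate(points):
                update_archive(archive, Wolf(np.array([float(k)]), tuple(f)), grid, rng)
            assert {m.fitness for m in archive.members} == _brute_force_front(points)

    def test_capacity_enforced(self):
        rng = np.random.default_rng(1)
        archive = ParetoArchive(capacity=5)
        grid = HypercubeGrid(divisions=4)
        # anti-correlated objectives: every candidate is non-dominated
        for t in np.linspace(0, 1, 50):
            update_archive(archive, Wolf(np.zeros(1), (float(t), float(1 - t))), grid, rng)
        assert len(archive.members) == 5


class TestLeaderElection:
    def test_single_member_is_alpha(self):
        rng = np.random.default_rng(0)
        archive = ParetoArchive(members=[Wolf(np.array([1.0]), (0.5, 0.5))])
        grid = HypercubeGrid()
        grid.rebuild(archive.objectives())
        leaders = select_leaders(archive, grid, 2.0, rng)
        assert leaders.alpha.fitness == (0.5, 0.5)

    def test_roulette_law_probabilities(self):
        p = cell_probabilities(np.array([1, 2, 4]), c=2.0)
        assert np.allclose(p, [4 / 7, 2 / 7, 1 / 7])

    def test_roulette_frequencies_match_law(self):
        rng = np.random.default_rng(2024)
        occ = np.array([1, 2, 4])
        counts = np.zeros(3)
        n = 20000
        for _ in range(n):
            counts[select_cell(occ, 2.0, rng)] += 1
        expected = np.array([4 / 7, 2 / 7, 1 / 7])
        assert np.abs(counts / n - expected).max() < 0.01
        chi2 = stats.chisquare(counts, expected * n)
        assert chi2.pvalue > 0.01

    def test_distinct_leaders_with_three_members(self):
        rng = np.random.default_rng(0)
        members = [Wolf(np.array([float(k)]), (float(k), float(2 - k))) for k in range(3)]
        archive = ParetoArchive(members=members)
        grid = HypercubeGrid()
        grid.rebuild(archive.objectives())
        for _ in range(20):
            leaders = select_leaders(archive, grid, 2.0, rng)
            ids = {leaders.alpha.position[0], leaders.beta.position[0], leaders.delta.position[0]}
            assert len(ids) == 3

    def test_empty_archive_rejected(self):
        with pytest.raises(ValueError):
            select_leaders(ParetoArchive(), HypercubeGrid(), 2.0, np.random.default_rng(0))


class TestAgwoMinimize:
    def test_biobjective_front_nondominated(self):
        e1 = np.array([1.0, 0.0])

        def objectives(x):
            return (float((x - e1) @ (x - e1)), float((x + e1) @ (x + e1)))

        space = SearchSpace(-2 * np.ones(2), 2 * np.ones(2))
        archive, history = agwo_minimize(objectives, space, 30, 200, seed=0)
        assert len(archive.members) >= 20
        fits = [m.fitness for m in archive.members]
        for i, f in enumerate(fits):
            assert not any(dominates(g, f) for j, g in enumerate(fits) if j != i)

    def test_capacity_one(self):
        def objectives(x):
            return (float(x[0] ** 2), float((x[0] - 1) ** 2))

        space = SearchSpace(np.array([0.0]), np.array([1.0]))
        archive, _ = agwo_minimize(objectives, space, 3, 1, capacity=1, seed=0)
        assert len(archive.members) == 1

    def test_deterministic_under_seed(self):
        def objectives(x):
            return (float(x @ x), float((x - 1) @ (x - 1)))

        space = SearchSpace(np.zeros(2), np.ones(2))
        a1, h1 = agwo_minimize(objectives, space, 8, 20, seed=9)
        a2, h2 = agwo_minimize(objectives, space, 8, 20, seed=9)
        assert [m.fitness for m in a1.members] == [m.fitness for m in a2.members]
        assert h1 == h2


class TestFrontEnds:
    def test_decode_mask_threshold_and_coercion(self):
        assert decode_feature_mask(np.array([0.9, 0.1]), 0.5).tolist() == [True, False]
        low = decode_feature_mask(np.array([0.2, 0.4, 0.1]), 0.5)
        assert low.tolist() == [False, True, False]
        assert decode_feature_mask(np.array([0.3, 0.6]), 0.0).all()

    @pytest.mark.parametrize(
        "p,expected",
        [
            ((0, 0, 0), (1e-4, 32, 1e-6)),
            ((1, 1, 1), (1e-2, 128, 1e-2)),
            ((0.5, 0.5, 0.5), (1e-3, 64, 1e-4)),
        ],
    )
    def test_decode_hyperparams(self, p, expected):
        lr, batch, wd = decode_hyperparams(np.array(p, dtype=float))
        assert lr == pytest.approx(expected[0])
        assert batch == expected[1]
        assert wd == pytest.approx(expected[2])

    def test_objectives_separable_data_zero_error(self):
        X, y, truth = generate_feature_table(
            PlantedFeatureSpec(n=120, d=10, informative=(0, 1), effect_size=6.0, seed=0)
        )
        problem = FeatureSelectionProblem(X, y, seed=0)
        error, frac = problem.evaluate_mask(truth)
        assert error < 0.02
        assert frac == pytest.approx(0.2)

    def test_objectives_noise_feature_near_chance(self):
        errors = []
        for seed in range(3):
            X, y, _ = generate_feature_table(
                PlantedFeatureSpec(n=200, d=6, informative=(0,), effect_size=4.0, seed=seed)
            )
            problem = FeatureSelectionProblem(X, y, seed=seed)
            mask = np.zeros(6, dtype=bool)
            mask[5] = True  # pure-noise feature
            errors.append(problem.evaluate_mask(mask)[0])
        assert 0.35 < np.mean(errors) < 0.65

    def test_selected_fraction_arithmetic(self):
        X, y, _ = generate_feature_table(
            PlantedFeatureSpec(n=80, d=50, informative=(0, 1, 2, 3, 4), effect_size=3.0, seed=1)
        )
        problem = FeatureSelectionProblem(X, y, seed=1)
        mask = np.zeros(50, dtype=bool)
        mask[:5] = True
        assert problem.evaluate_mask(mask)[1] == pytest.approx(0.1)

    def test_selection_recovers_planted_features(self):
        X, y, truth = generate_feature_table(
            PlantedFeatureSpec(n=300, d=20, informative=(0, 1, 2), effect_size=3.0, seed=4)
        )
        mask, archive, _ = select_features_agwo(X, y, n_wolves=12, T=15, seed=4)
        assert (mask & truth).sum() >= 2
        assert mask.sum() <= 10
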