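import math

import numpy as np
import pytest

from enfrn.core_network import (
    SIGMA_MIN,
    ENFRNModel,
    FuzzySet,
    InputVariable,
    InvalidModelError,
    OutputNode,
    Rule,
    model_to_dict,
    sequence_rmse,
)
from enfrn.structure_learning import StructureConfig, build_initial_structure
from enfrn.swarm_optimization import (
    Particle,
    SwarmConfig,
    apply_rule_mask,
    bpso_step,
    decode_parameters,
    encode_parameters,
    exhaustive_best_mask,
    mask_fitness_batch,
    minimize_bpso,
    minimize_pso,
    parameter_fitness,
    pso_position_update,
    pso_velocity_update,
    simplify_structure,
    structure_fitness,
    train_parameters,
)


def _particle(x, v=None, best=None):
    x = np.asarray(x, dtype=float)
    return Particle(position=x, velocity=np.zeros_like(x) if v is None else np.asarray(v, float),
                    best_position=x.copy() if best is None else np.asarray(best, float))


class TestVelocityUpdate:
    def test_converged_particle_stays(self, rng):
        p = _particle([1.0, 2.0])
        v = pso_velocity_update(p, p.position, SwarmConfig(), rng)
        np.testing.assert_array_equal(v, 0.0)

    def test_cognitive_pull_sign(self, rng):
        cfg = SwarmConfig(inertia=0.0, c2=1e-12)
        p = _particle([0.0, 0.0], best=[1.0, -1.0])
        v = pso_velocity_update(p, [0.0, 0.0], cfg, rng)
        assert v[0] >= 0.0 and v[1] <= 0.0

    def test_expected_velocity(self, rng):
        # with c1 = c2, E[v'] = W*v + (c/2)(B_i - X) + (c/2)(B_G - X)
        cfg = SwarmConfig(v_max=100.0)
        p = _particle([0.2], v=[0.1], best=[0.8])
        g = np.array([0.4])
        n = 100_000
        draws = np.array([pso_velocity_update(_particle([0.2], v=[0.1], best=[0.8]), g, cfg, rng)[0]
                          for _ in range(n)])
        expected = cfg.inertia * 0.1 + cfg.c1 / 2 * 0.6 + cfg.c2 / 2 * 0.2
        # each term is c*U(0,1)*d: var = c^2 d^2 / 12
        se = math.sqrt((cfg.c1**2 * 0.6**2 + cfg.c2**2 * 0.2**2) / 12 / n)
        assert abs(draws.mean() - expected) < 3 * se

    def test_clipped_to_vmax(self, rng):
        cfg = SwarmConfig(v_max=0.5)
        p = _particle([0.0], best=[100.0])
        v = pso_velocity_update(p, [100.0], cfg, rng)
        assert abs(v[0]) <= 0.5


class TestPositionUpdate:
    def test_additivity(self):
        p = _particle([0.0, 1.0], v=[0.5, -0.25])
        np.testing.assert_allclose(pso_position_update(p), [0.5, 0.75])
        half = _particle([0.0], v=[0.5])
        one_step = pso_position_update(_particle([0.0], v=[1.0]))
        two_half = pso_position_update(_particle(pso_position_update(half), v=[0.5]))
        np.testing.assert_allclose(one_step, two_half)


class TestBpsoStep:
    def test_zero_velocity_half_probability(self, rng):
        cfg = SwarmConfig(inertia=1.0)
        flips = [bpso_step(_particle([0.0], v=[0.0]), np.array([0.0]), cfg, rng)[0]
                 for _ in range(100_000)]
        freq = np.mean(flips)
        assert abs(freq - 0.5) < 3 * math.sqrt(0.25 / 100_000)

    def test_saturated_velocity_frequency(self, rng):
        cfg = SwarmConfig(inertia=1.0, v_max=4.0)
        p_on = 1.0 / (1.0 + math.exp(-4.0))
        flips = [bpso_step(_particle([0.0], v=[50.0]), np.array([0.0]), cfg, rng)[0]
                 for _ in range(100_000)]
        freq = np.mean(flips)
        assert abs(freq - p_on) < 3 * math.sqrt(p_on * (1 - p_on) / 100_000)


def _redundant_model():
    """Two identical rules (one redundant) plus one distinct rule."""
    inputs = [InputVariable(
        sets=[FuzzySet(0.2, 0.15), FuzzySet(0.8, 0.15)],
        feedback_weights=[0.0, 0.0], state=[0.0, 0.0])]
    outputs = [OutputNode(0.25, 0.2), OutputNode(0.75, 0.2)]
    rules = [Rule([0], 0), Rule([0], 0), Rule([1], 1)]
    return ENFRNModel(inputs=inputs, rules=rules, outputs=outputs)


@pytest.fixture
def pair_data(toy_pair):
    x, y = toy_pair
    return x[None, :], y


class TestStructureFitness:
    def test_full_mask_is_plain_mse(self, pair_data):
        model = build_initial_structure(*pair_data)
        fit = structure_fitness(model, np.ones(model.n_rules), pair_data)
        sub_rmse = sequence_rmse(model, *pair_data)
        assert fit == pytest.approx(sub_rmse**2)

    def test_fewer_rules_win_ties(self):
        model = _redundant_model()
        x = np.array([[0.2, 0.8, 0.2, 0.8, 0.2]])
        y = np.array([0.25, 0.25, 0.75, 0.25, 0.75])
        data = (x, y)
        full = structure_fitness(model, [1, 1, 1], data)
        dedup = structure_fitness(model, [1, 0, 1], data)
        # duplicate rule removal leaves predictions (hence MSE) unchanged
        assert dedup < full
        assert dedup == pytest.approx(full * (3 - 3 + 1) / (3 - 2 + 1))

    def test_empty_mask_is_infinite(self):
        assert structure_fitness(_redundant_model(), [0, 0, 0], (np.zeros((1, 4)), np.zeros(4))) == math.inf

    def test_batch_matches_scalar_path(self, rng, pair_data):
        model = build_initial_structure(*pair_data)
        M = model.n_rules
        masks = (rng.random((16, M)) < 0.6).astype(float)
        masks[0] = 1.0
        batch = mask_fitness_batch(model, masks, pair_data)
        for k in range(masks.shape[0]):
            if masks[k].sum() == 0:
                assert batch[k] == math.inf
            else:
                assert batch[k] == pytest.approx(
                    structure_fitness(model, masks[k], pair_data), rel=1e-12)


class TestApplyRuleMask:
    def test_orphans_removed_and_remapped(self):
        model = _redundant_model()
        sub = apply_rule_mask(model, [1, 1, 0])
        assert sub.n_rules == 2
        assert sub.n_outputs == 1  # node 1 lost its only rule
        assert all(r.consequent == 0 for r in sub.rules)
        sub.validate()

    def test_empty_mask_rejected(self):
        with pytest.raises(InvalidModelError):
            apply_rule_mask(_redundant_model(), [0, 0, 0])


class TestSimplifyStructure:
    def test_duplicate_rule_pruned_to_exhaustive_optimum(self):
        model = _redundant_model()
        x = np.array([[0.2, 0.8, 0.2, 0.8, 0.2, 0.8]])
        y = np.array([0.25, 0.25, 0.75, 0.25, 0.75, 0.25])
        data = (x, y)
        _, best_fit = exhaustive_best_mask(model, data)
        sub = simplify_structure(model, data, SwarmConfig.bpso_defaults(seed=0))
        kept = np.zeros(0)
        fit = sequence_rmse(sub, *data) ** 2 / (model.n_rules - sub.n_rules + 1)
        assert fit == pytest.approx(best_fit, rel=1e-9)
        assert sub.n_rules < model.n_rules

    def test_never_worse_than_unpruned(self, pair_data):
        model = build_initial_structure(*pair_data)
        full_fit = structure_fitness(model, np.ones(model.n_rules), pair_data)
        sub = simplify_structure(model, pair_data, SwarmConfig.bpso_defaults(seed=3))
        fit = sequence_rmse(sub, *pair_data) ** 2 / (model.n_rules - sub.n_rules + 1)
        assert fit <= full_fit + 1e-12

    def test_short_series_unchanged(self, pair_data):
        model = build_initial_structure(*pair_data)
        short = (pair_data[0][:, :2], pair_data[1][:2])
        sub = simplify_structure(model, short, SwarmConfig.bpso_defaults(seed=0))
        assert model_to_dict(sub) == model_to_dict(model)


class TestParameterVector:
    def test_round_trip_exact(self, pair_data):
        model = build_initial_structure(*pair_data)
        theta = encode_parameters(model)
        clone = decode_parameters(model, theta)
        assert model_to_dict(clone) == model_to_dict(model)

    def test_width_clipping(self, pair_data):
        model = build_initial_structure(*pair_data)
        theta = encode_parameters(model)
        theta[len(model.inputs[0].sets):2 * len(model.inputs[0].sets)] = -1.0
        decoded = decode_parameters(model, theta)
        assert all(s.width == SIGMA_MIN for s in decoded.inputs[0].sets)

    def test_shape_mismatch_rejected(self, pair_data):
        model = build_initial_structure(*pair_data)
        with pytest.raises(InvalidModelError):
            parameter_fitness(model, np.zeros(3), pair_data)


class TestParameterFitness:
    def test_self_encoding_is_own_rmse(self, pair_data):
        model = build_initial_structure(*pair_data)
        theta = encode_parameters(model)
        assert parameter_fitness(model, theta, pair_data) == pytest.approx(
            sequence_rmse(model, *pair_data))

    def test_consistent_with_structure_fitness(self, pair_data):
        model = build_initial_structure(*pair_data)
        rmse = parameter_fitness(model, encode_parameters(model), pair_data)
        mse = structure_fitness(model, np.ones(model.n_rules), pair_data)
        assert rmse == pytest.approx(math.sqrt(mse))

    def test_perfect_model_scores_zero(self):
        model = ENFRNModel(
            inputs=[InputVariable([FuzzySet(0.5, 0.3)], [0.0], [0.0])],
            rules=[Rule([0], 0)], outputs=[OutputNode(0.4, 0.2)])
        data = (np.full((1, 6), 0.5), np.full(6, 0.4))
        assert parameter_fitness(model, encode_parameters(model), data) == pytest.approx(0.0)


class TestTrainParameters:
    def test_zero_iterations_is_identity(self, pair_data):
        model = build_initial_structure(*pair_data)
        cfg = SwarmConfig.pso_defaults(seed=0)
        cfg.n_iterations = 0
        assert model_to_dict(train_parameters(model, pair_data, cfg)) == model_to_dict(model)

    def test_rmse_never_increases(self, pair_data):
        model = build_initial_structure(*pair_data)
        before = sequence_rmse(model, *pair_data)
        trained = train_parameters(model, pair_data, SwarmConfig.pso_defaults(seed=1))
        assert sequence_rmse(trained, *pair_data) <= before + 1e-12

    def test_deterministic_given_seed(self, pair_data):
        model = build_initial_structure(*pair_data)
        a = train_parameters(model, pair_data, SwarmConfig.pso_defaults(seed=9))
        b = train_parameters(model, pair_data, SwarmConfig.pso_defaults(seed=9))
        assert model_to_dict(a) == model_to_dict(b)


class TestSwarmDynamics:
    def test_global_best_monotone(self, rng):
        sphere = lambda X: np.sum(X**2, axis=1)
        cfg = SwarmConfig(n_particles=10, n_iterations=50, seed=0)
        res = minimize_pso(sphere, rng.uniform(-5, 5, (10, 4)), cfg, rng)
        assert all(b <= a + 1e-15 for a, b in zip(res.history[:-1], res.history[1:]))
        onemax = lambda M: M.shape[1] - M.sum(axis=1).astype(float)
        resb = minimize_bpso(onemax, (rng.random((10, 12)) < 0.5).astype(float), cfg, rng)
        assert all(b <= a + 1e-15 for a, b in zip(resb.history[:-1], resb.history[1:]))

    def test_bit_identical_trajectories(self):
        sphere = lambda X: np.sum(X**2, axis=1)
        cfg = SwarmConfig(n_particles=8, n_iterations=40, seed=5)
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(5)
            init = rng.uniform(-5, 5, (8, 3))
            runs.append(minimize_pso(sphere, init, cfg, rng))
        assert runs[0].history == runs[1].history
        np.testing.assert_array_equal(runs[0].best_position, runs[1].best_position)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SwarmConfig(n_particles=1)
        with pytest.raises(ValueError):
            SwarmConfig(c1=0.0)
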