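import numpy as np
import pytest
from scipy.linalg import fractional_matrix_power

from maxsdm import (
    MLPArch,
    SyntheticLandscapeConfig,
    SyntheticTransitionSpec,
    TransitionMatrix,
    allocate_change,
    crosstab_transition,
    demand_from_matrix,
    generate_landcover_pair,
    generate_raster_stack,
    percent_area_change,
    scale_matrix,
    train_transition_mlp,
)
from maxsdm.evaluation import auc
from maxsdm.raster import RasterGrid


def cat_grid(values):
    values = np.asarray(values, dtype=float)
    return RasterGrid(values, np.ones_like(values, dtype=bool), categorical=True)


class TestCrosstab:
    def test_identical_maps_give_identity(self):
        g = cat_grid([[1, 2], [3, 1]])
        m = crosstab_transition(g, g.copy())
        assert np.array_equal(m.P, np.eye(3))

    def test_direct_counting_example(self):
        t1 = cat_grid([[1, 1], [2, 2]])
        t2 = cat_grid([[1, 2], [2, 2]])
        m = crosstab_transition(t1, t2)
        assert np.allclose(m.P, [[0.5, 0.5], [0.0, 1.0]])

    def test_class_absent_at_t1_gets_identity_row(self):
        t1 = cat_grid([[1, 1], [1, 1]])
        t2 = cat_grid([[1, 1], [1, 2]])
        m = crosstab_transition(t1, t2)
        i = list(m.classes).index(2)
        row = np.zeros(2)
        row[i] = 1.0
        assert np.allclose(m.P[i], row)

    def test_rows_are_stochastic(self):
        rng = np.random.default_rng(0)
        t1 = cat_grid(rng.integers(1, 5, (30, 30)))
        t2 = cat_grid(rng.integers(1, 5, (30, 30)))
        m = crosstab_transition(t1, t2)
        assert np.allclose(m.P.sum(axis=1), 1.0, atol=1e-9)

    def test_misaligned_maps_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            crosstab_transition(cat_grid([[1]]), cat_grid([[1, 2]]))


class TestScaleMatrix:
    def test_identity_is_a_fixed_point(self):
        m = TransitionMatrix(np.array([1, 2]), np.eye(2), 10.0)
        out = scale_matrix(m, 35.0)
        assert np.allclose(out.P, np.eye(2))

    def test_unit_power_returns_input(self):
        P = np.array([[0.9, 0.1], [0.3, 0.7]])
        m = TransitionMatrix(np.array([1, 2]), P, 10.0)
        out = scale_matrix(m, 10.0)
        assert np.allclose(out.P, P, atol=1e-9)

    def test_fractional_power_matches_linear_algebra_oracle(self):
        P = np.array([[0.9, 0.1], [0.0, 1.0]])
        m = TransitionMatrix(np.array([1, 2]), P, 1.0)
        out = scale_matrix(m, 3.5)
        oracle = fractional_matrix_power(P, 3.5)
        assert np.allclose(out.P, oracle, atol=1e-6)

    def test_result_remains_stochastic(self):
        rng = np.random.default_rng(1)
        A = rng.random((4, 4)) + 4 * np.eye(4)
        P = A / A.sum(axis=1, keepdims=True)
        m = TransitionMatrix(np.arange(1, 5), P, 10.0)
        out = scale_matrix(m, 35.0)
        assert np.all(out.P >= 0)
        assert np.allclose(out.P.sum(axis=1), 1.0, atol=1e-9)


@pytest.fixture(scope="module")
def driver_stack():
    cfg = SyntheticLandscapeConfig(grid_rows=60, grid_cols=60, n_continuous=2, seed=50)
    return generate_raster_stack(cfg).subset(["env1", "env2"])


class TestTransitionMlp:
    def test_fixed_seed_is_bit_identical(self, driver_stack):
        spec = SyntheticTransitionSpec(np.array([[0.7, 0.3], [0.2, 0.8]]))
        t1, t2 = generate_landcover_pair(spec, driver_stack, seed=51)
        arch = MLPArch(epochs=100, seed=52)
        a = train_transition_mlp(t1, t2, driver_stack, arch)
        b = train_transition_mlp(t1, t2, driver_stack, arch)
        for pair in a.potentials:
            assert np.array_equal(a[pair].values, b[pair].values)

    def test_noise_drivers_give_flat_potentials(self, driver_stack):
        # drivers carry no information about transitions: potentials should
        # be nearly constant over space
        spec = SyntheticTransitionSpec(np.array([[0.7, 0.3], [0.2, 0.8]]))
        t1, t2 = generate_landcover_pair(spec, driver_stack, seed=53)
        pot = train_transition_mlp(t1, t2, driver_stack, MLPArch(epochs=200, seed=54))
        for pair, grid in pot.potentials.items():
            assert grid.valid_values().std() < 0.15

    def test_separating_driver_ranks_transitions(self, driver_stack):
        # transition 1->2 happens exactly where env1 >= 0 (perfect
        # separation): the potential must rank transitioned cells above
        # persistent ones almost perfectly
        spec = SyntheticTransitionSpec(
            np.array([[0.0, 1.0], [0.0, 1.0]]),
            driver_effects={(1, 2): [("env1", lambda v: (v >= 0).astype(float))]},
        )
        t1, t2 = generate_landcover_pair(spec, driver_stack, seed=55)
        pot = train_transition_mlp(t1, t2, driver_stack, MLPArch(epochs=400, seed=56))
        grid = pot[(1, 2)]
        src = t1.values == 1
        moved = src & (t2.values == 2)
        stayed = src & (t2.values == 1)
        assert auc(grid.values[moved], grid.values[stayed]) > 0.95

    def test_potentials_lie_in_unit_interval(self, driver_stack):
        spec = SyntheticTransitionSpec(np.array([[0.8, 0.2], [0.3, 0.7]]))
        t1, t2 = generate_landcover_pair(spec, driver_stack, seed=57)
        pot = train_transition_mlp(t1, t2, driver_stack, MLPArch(epochs=100, seed=58))
        for grid in pot.potentials.values():
            v = grid.valid_values()
            assert v.min() >= 0.0 and v.max() <= 1.0


class TestDemandAndAllocation:
    def test_largest_remainder_conserves_row_totals(self):
        P = np.array([[0.62, 0.23, 0.15], [0.1, 0.8, 0.1], [0.0, 0.0, 1.0]])
        m = TransitionMatrix(np.array([1, 2, 3]), P, 1.0)
        rng = np.random.default_rng(2)
        cur = cat_grid(rng.integers(1, 4, (30, 30)))
        demand = demand_from_matrix(m, cur)
        v = cur.valid_values()
        for i in (1, 2, 3):
            out = sum(d for (a, b), d in demand.items() if a == i)
            assert out <= np.count_nonzero(v == i)

    def test_empty_demand_is_a_no_op(self):
        cur = cat_grid([[1, 2], [2, 1]])
        from maxsdm.landcover import TransitionPotentialSet
        out = allocate_change(cur, {}, TransitionPotentialSet({}), seed=0)
        assert np.array_equal(out.values, cur.values)

    def test_top_potential_cells_convert_first(self):
        cur = cat_grid(np.ones((10, 10)))
        scores = np.arange(100, dtype=float).reshape(10, 10)
        from maxsdm.landcover import TransitionPotentialSet
        pot = TransitionPotentialSet({
            (1, 2): RasterGrid(scores / 100, np.ones((10, 10), bool))
        })
        out = allocate_change(cur, {(1, 2): 5}, pot, seed=1)
        converted = out.values == 2
        assert converted.sum() == 5
        assert np.all(converted.ravel()[np.argsort(-scores.ravel())[:5]])

    def test_allocation_reproduces_demanded_counts_exactly(self, driver_stack):
        spec = SyntheticTransitionSpec(
            np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]])
        )
        t1, t2 = generate_landcover_pair(
            spec, driver_stack, seed=59
        )
        m = crosstab_transition(t1, t2)
        demand = demand_from_matrix(m, t1)
        from maxsdm.landcover import TransitionPotentialSet
        with pytest.warns(UserWarning, match="uniform potential"):
            out = allocate_change(t1, demand, TransitionPotentialSet({}), seed=3)
        check = crosstab_transition(t1, out)
        idx = {c: i for i, c in enumerate(check.classes)}
        v1 = t1.valid_values()
        for (i, j), d in demand.items():
            n_i = np.count_nonzero(v1 == i)
            counts = check.P[idx[i]] * n_i
            assert counts[idx[j]] == pytest.approx(d, abs=1e-9)
        assert out.mask.sum() == t1.mask.sum()

    def test_excess_demand_scaled_down_with_warning(self):
        cur = cat_grid(np.ones((3, 3)))
        from maxsdm.landcover import TransitionPotentialSet
        with pytest.warns(UserWarning, match="exceeds"):
            out = allocate_change(
                cur, {(1, 2): 50}, TransitionPotentialSet({}), seed=4
            )
        assert (out.values == 2).sum() <= 9


def test_percent_area_change_formula():
    assert percent_area_change(100.0, 60.0) == pytest.approx(-40.0)
    with pytest.raises(ValueError):
        percent_area_change(0.0, 5.0)
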