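import numpy as np
import pytest
from scipy.stats import chisquare

from maxsdm import (
    SyntheticLandscapeConfig,
    SyntheticTransitionSpec,
    SyntheticTruth,
    generate_landcover_pair,
    generate_raster_stack,
    sample_presences,
    truth_suitability,
)
from maxsdm.features import FeatureDefinition
from maxsdm.landcover import crosstab_transition

from conftest import make_truth


def corr(stack, a, b):
    return np.corrcoef(stack[a].valid_values(), stack[b].valid_values())[0, 1]


class TestGenerateRasterStack:
    def test_uncorrelated_target_yields_low_empirical_r(self):
        cfg = SyntheticLandscapeConfig(
            grid_rows=100, grid_cols=100, n_continuous=2,
            target_correlations=np.eye(2), seed=5,
        )
        stack = generate_raster_stack(cfg)
        assert abs(corr(stack, "env1", "env2")) < 0.15

    def test_perfect_correlation_limit(self):
        cfg = SyntheticLandscapeConfig(
            grid_rows=100, grid_cols=100, n_continuous=2,
            target_correlations=np.array([[1.0, 1.0], [1.0, 1.0]]), seed=6,
        )
        stack = generate_raster_stack(cfg)
        assert corr(stack, "env1", "env2") > 0.99

    def test_empirical_correlation_converges_to_target(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        cfg = SyntheticLandscapeConfig(
            grid_rows=300, grid_cols=300, n_continuous=2,
            target_correlations=R, seed=7,
        )
        stack = generate_raster_stack(cfg)
        assert corr(stack, "env1", "env2") == pytest.approx(0.5, abs=0.05)

    def test_categorical_layer_holds_exact_class_set(self):
        cfg = SyntheticLandscapeConfig(
            grid_rows=50, grid_cols=50, n_landcover_classes=3, seed=8
        )
        stack = generate_raster_stack(cfg)
        assert set(stack["landcover"].valid_values()) == {1.0, 2.0, 3.0}

    def test_indefinite_correlation_matrix_rejected(self):
        R = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            generate_raster_stack(SyntheticLandscapeConfig(
                n_continuous=3, target_correlations=R, seed=9,
                grid_rows=20, grid_cols=20,
            ))

    def test_fixed_seed_is_bit_reproducible(self):
        cfg = SyntheticLandscapeConfig(grid_rows=30, grid_cols=30, seed=10)
        a = generate_raster_stack(cfg)
        b = generate_raster_stack(cfg)
        for n in a.names:
            assert np.array_equal(a[n].values, b[n].values)


class TestTruthSuitability:
    def test_zero_weights_give_uniform(self, small_stack):
        truth = make_truth(small_stack, [("L", "env1", 0.0)])
        suit = truth_suitability(small_stack, truth)
        n = small_stack.mask.sum()
        assert np.allclose(suit.values[suit.mask], 1.0 / n)

    def test_single_positive_linear_weight_is_monotone(self, small_stack):
        truth = make_truth(small_stack, [("L", "env1", 3.0)])
        suit = truth_suitability(small_stack, truth)
        v = small_stack["env1"].valid_values()
        s = suit.values[suit.mask]
        order = np.argsort(v)
        assert np.all(np.diff(s[order]) >= 0)

    def test_normalization(self, small_stack):
        truth = make_truth(
            small_stack, [("L", "env1", 2.5), ("Q", "env2", -1.5)]
        )
        suit = truth_suitability(small_stack, truth)
        assert suit.values[suit.mask].sum() == pytest.approx(1.0, abs=1e-9)

    def test_missing_layer_is_named(self, small_stack):
        bad = SyntheticTruth(
            {FeatureDefinition("L", ("ghost",), ((0.0, 1.0),)): 1.0}
        )
        with pytest.raises(KeyError, match="ghost"):
            truth_suitability(small_stack, bad)


class TestSamplePresences:
    def test_uniform_counts_pass_chi_square(self, small_stack):
        truth = make_truth(small_stack, [("L", "env1", 0.0)])
        suit = truth_suitability(small_stack, truth)
        occ = sample_presences(suit, 10_000, seed=31)
        t = small_stack.template
        r, c = t.xy_to_rowcol(occ.x, occ.y)
        counts = np.bincount(r * t.ncols + c, minlength=t.nrows * t.ncols)
        assert chisquare(counts).pvalue > 0.001

    def test_degenerate_distribution(self, small_stack):
        vals = np.zeros(small_stack.shape)
        vals[3, 4] = 1.0
        from maxsdm.raster import RasterGrid
        suit = RasterGrid(vals, small_stack.mask.copy())
        occ = sample_presences(suit, 50, seed=32)
        x, y = small_stack.template.rowcol_to_xy(3, 4)
        assert np.all(occ.x == x) and np.all(occ.y == y)

    def test_fixed_seed_determinism(self, signal_data):
        a = sample_presences(signal_data["suit"], 100, seed=33)
        b = sample_presences(signal_data["suit"], 100, seed=33)
        assert np.array_equal(a.points, b.points)

    def test_all_zero_suitability_rejected(self, small_stack):
        from maxsdm.raster import RasterGrid
        suit = RasterGrid(np.zeros(small_stack.shape), small_stack.mask.copy())
        with pytest.raises(ValueError, match="all zero"):
            sample_presences(suit, 10, seed=1)


class TestLandcoverPair:
    def test_identity_matrix_means_no_change(self, small_stack):
        drivers = small_stack.subset(["env1", "env2"])
        spec = SyntheticTransitionSpec(np.eye(3))
        t1, t2 = generate_landcover_pair(spec, drivers, seed=41)
        assert np.array_equal(t1.values, t2.values)

    def test_empirical_crosstab_recovers_spec_rows(self):
        cfg = SyntheticLandscapeConfig(grid_rows=300, grid_cols=300, seed=42)
        drivers = generate_raster_stack(cfg).subset(["env1"])
        P = np.array([[0.8, 0.15, 0.05], [0.1, 0.85, 0.05], [0.2, 0.2, 0.6]])
        spec = SyntheticTransitionSpec(P)
        t1, t2 = generate_landcover_pair(spec, drivers, seed=43)
        m = crosstab_transition(t1, t2)
        assert np.max(np.abs(m.P - P)) < 0.02

    def test_driver_can_forbid_a_transition(self, small_stack):
        drivers = small_stack.subset(["env1"])
        P = np.array([[0.5, 0.5], [0.0, 1.0]])
        spec = SyntheticTransitionSpec(
            P,
            driver_effects={(1, 2): [("env1", lambda v: (v >= 0).astype(float))]},
        )
        t1, t2 = generate_landcover_pair(spec, drivers, seed=44)
        env = small_stack["env1"].values
        moved = (t1.values == 1) & (t2.values == 2)
        assert not np.any(moved & (env < 0))

    def test_cell_count_conserved(self, small_stack):
        drivers = small_stack.subset(["env1"])
        spec = SyntheticTransitionSpec(np.array([[0.6, 0.4], [0.3, 0.7]]))
        t1, t2 = generate_landcover_pair(spec, drivers, seed=45)
        assert t1.mask.sum() == t2.mask.sum() == small_stack.mask.sum()

    def test_missing_driver_layer_rejected(self, small_stack):
        drivers = small_stack.subset(["env1"])
        spec = SyntheticTransitionSpec(
            np.eye(2),
            driver_effects={(1, 2): [("roads", lambda v: v)]},
        )
        with pytest.raises(KeyError, match="roads"):
            generate_landcover_pair(spec, drivers, seed=46)

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticTransitionSpec(np.array([[0.5, 0.4], [0.0, 1.0]]))
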