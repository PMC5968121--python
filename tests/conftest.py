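import numpy as np
import pandas as pd
import pytest

from maxsdm import (
    MaxEntSDM,
    SyntheticLandscapeConfig,
    SyntheticTruth,
    generate_raster_stack,
    sample_background,
    sample_presences,
    truth_suitability,
)
from maxsdm.features import FeatureDefinition


def layer_bounds(stack, name):
    v = stack[name].valid_values()
    return (float(v.min()), float(v.max()))


def make_truth(stack, weights):
    """weights: list of (kind, variable(s), weight) on stack layers."""
    w = {}
    for kind, var, weight in weights:
        vars_ = var if isinstance(var, tuple) else (var,)
        bounds = tuple(layer_bounds(stack, v) for v in vars_)
        w[FeatureDefinition(kind, vars_, bounds)] = weight
    return SyntheticTruth(w)


@pytest.fixture(scope="session")
def small_stack():
    cfg = SyntheticLandscapeConfig(
        grid_rows=40, grid_cols=40, n_continuous=2, n_landcover_classes=3, seed=11
    )
    return generate_raster_stack(cfg)


@pytest.fixture(scope="session")
def signal_data(small_stack):
    """Presence/background predictor tables from a strong known truth."""
    truth = make_truth(
        small_stack, [("L", "env1", 6.0), ("Q", "env1", -4.0), ("L", "env2", 2.0)]
    )
    suit = truth_suitability(small_stack, truth)
    occ = sample_presences(suit, 400, seed=21)
    bg = sample_background(small_stack, 800, seed=22)
    t = small_stack.template
    ro, co = t.xy_to_rowcol(occ.x, occ.y)
    rb, cb = t.xy_to_rowcol(bg.x, bg.y)
    X_occ = small_stack.table(ro, co)
    X_bg = small_stack.table(rb, cb)
    X = pd.concat([X_occ, X_bg], ignore_index=True)
    y = np.r_[np.ones(len(X_occ)), np.zeros(len(X_bg))]
    return {
        "stack": small_stack,
        "truth": truth,
        "suit": suit,
        "occ": occ,
        "bg": bg,
        "X_occ": X_occ,
        "X_bg": X_bg,
        "X": X,
        "y": y,
    }


@pytest.fixture(scope="session")
def fitted_model(signal_data):
    return MaxEntSDM(
        feature_classes=("L", "Q"), categorical=("landcover",), reg_multiplier=1.0
    ).fit(signal_data["X"], signal_data["y"])
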