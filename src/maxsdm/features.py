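"""Maxent feature expansion: basis functions over scaled predictors.

Feature classes follow the standard presence-only maxent vocabulary:

* ``L`` linear — the predictor min–max scaled to [0, 1];
* ``Q`` quadratic — the scaled value squared;
* ``P`` product — product of two distinct scaled predictors;
* ``T`` threshold — step indicator ``value > knot``;
* ``H`` hinge — ``max(0, value − knot) / (max − knot)``;
* ``C`` category indicator — one-hot level of a categorical predictor.

Scaling bounds are frozen from the training support; out-of-range values at
projection time are clamped back into the bounds so every feature stays in
[0, 1] (the extrapolation rule used when projecting onto scenario stacks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

VALID_CLASSES = ("L", "Q", "P", "T", "H")

__all__ = ["FeatureDefinition", "MaxentFeatureExpander", "evaluate_feature"]


@dataclass(frozen=True)
class FeatureDefinition:
    """One basis function of the maxent model.

    ``variables`` holds one name (L/Q/T/H/C) or two (P). ``bounds`` are the
    (min, max) scaling bounds per variable, frozen from training support.
    ``knot`` applies to T/H only, ``level`` to C only.
    """

    kind: str
    variables: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    knot: float | None = None
    level: int | None = None

    def __post_init__(self):
        if self.kind not in VALID_CLASSES + ("C",):
            raise ValueError(f"unknown feature class {self.kind!r}")
        if self.kind == "P" and len(self.variables) != 2:
            raise ValueError("product features reference exactly two variables")
        if self.kind in ("T", "H") and self.knot is None:
            raise ValueError(f"{self.kind} feature needs a knot")
        if self.kind == "C" and self.level is None:
            raise ValueError("category feature needs a level")

    @property
    def name(self) -> str:
        if self.kind == "P":
            return f"P({self.variables[0]}*{self.variables[1]})"
        if self.kind in ("T", "H"):
            return f"{self.kind}({self.variables[0]}@{self.knot:.6g})"
        if self.kind == "C":
            return f"C({self.variables[0]}={self.level})"
        return f"{self.kind}({self.variables[0]})"


def _scaled(v: np.ndarray, lo: float, hi: float, clamp: bool) -> np.ndarray:
    if hi <= lo:
        return np.zeros_like(v, dtype=float)
    s = (np.asarray(v, dtype=float) - lo) / (hi - lo)
    if clamp:
        s = np.clip(s, 0.0, 1.0)
    return s


def evaluate_feature(defn: FeatureDefinition, columns: dict, clamp: bool = True) -> np.ndarray:
    """Evaluate one feature over per-variable value arrays.

    ``columns`` maps variable name -> 1-D array of raw values. Used both by
    the fitted expander and by the synthetic ground-truth suitability, so the
    generating model and the fitted model share one basis.
    """
    for var in defn.variables:
        if var not in columns:
            raise KeyError(f"feature {defn.name} references missing layer {var!r}")
    v = np.asarray(columns[defn.variables[0]], dtype=float)
    lo, hi = defn.bounds[0]
    if defn.kind == "L":
        return _scaled(v, lo, hi, clamp)
    if defn.kind == "Q":
        return _scaled(v, lo, hi, clamp) ** 2
    if defn.kind == "P":
        v2 = np.asarray(columns[defn.variables[1]], dtype=float)
        lo2, hi2 = defn.bounds[1]
        return _scaled(v, lo, hi, clamp) * _scaled(v2, lo2, hi2, clamp)
    if defn.kind == "T":
        return (v > defn.knot).astype(float)
    if defn.kind == "H":
        denom = hi - defn.knot
        if denom <= 0:
            return np.zeros_like(v, dtype=float)
        f = np.maximum(0.0, v - defn.knot) / denom
        if clamp:
            f = np.clip(f, 0.0, 1.0)
        return f
    # C
    return (np.round(v).astype(int) == defn.level).astype(float)


class MaxentFeatureExpander(TransformerMixin, BaseEstimator):
    """Expand raw predictors into a [0, 1] maxent feature matrix.

    Parameters
    ----------
    feature_classes : iterable of {"L","Q","P","T","H"}
        Which basis classes to generate for continuous predictors.
        Categorical predictors always expand to one-hot class indicators.
    n_knots : int
        Knots per variable for T and H, placed at equally spaced quantiles
        of the training support (deciles by default).
    categorical : iterable of str or int
        Names (or column indices) of categorical predictors.
    clamp : bool
        Clamp transform-time values into the training bounds.
    """

    def __init__(self, feature_classes=("L", "Q"), n_knots=10, categorical=(), clamp=True):
        self.feature_classes = feature_classes
        self.n_knots = n_knots
        self.categorical = categorical
        self.clamp = clamp

    # -- helpers ------------------------------------------------------------

    def _columns(self, X) -> tuple[dict, list[str]]:
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            cols = {n: X[c].to_numpy(dtype=float) for n, c in zip(names, X.columns)}
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            names = [f"x{i}" for i in range(X.shape[1])]
            cols = {n: X[:, i] for i, n in enumerate(names)}
        return cols, names

    def _categorical_names(self, names) -> set:
        out = set()
        for c in self.categorical:
            if isinstance(c, (int, np.integer)):
                out.add(names[c])
            else:
                out.add(str(c))
        return out

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y=None):
        classes = tuple(dict.fromkeys(self.feature_classes))
        bad = [c for c in classes if c not in VALID_CLASSES]
        if bad:
            raise ValueError(f"unknown feature classes: {bad}")
        if not classes:
            raise ValueError("at least one feature class is required")
        cols, names = self._columns(X)
        cat = self._categorical_names(names)
        defs: list[FeatureDefinition] = []
        bounds: dict[str, tuple[float, float]] = {}
        for n in names:
            v = cols[n]
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite values in predictor {n!r}")
            bounds[n] = (float(np.min(v)), float(np.max(v)))

        continuous = [n for n in names if n not in cat]
        usable = []
        for n in continuous:
            lo, hi = bounds[n]
            if hi <= lo:
                warnings.warn(
                    f"predictor {n!r} is constant over the training support; "
                    "its features are suppressed"
                )
                continue
            usable.append(n)

        for n in usable:
            b = (bounds[n],)
            if "L" in classes:
                defs.append(FeatureDefinition("L", (n,), b))
            if "Q" in classes:
                defs.append(FeatureDefinition("Q", (n,), b))
        if "P" in classes:
            for a, bn in combinations(usable, 2):
                defs.append(
                    FeatureDefinition("P", (a, bn), (bounds[a], bounds[bn]))
                )
        for n in usable:
            lo, hi = bounds[n]
            if "T" in classes or "H" in classes:
                qs = np.quantile(
                    cols[n], [(i + 1) / (self.n_knots + 1) for i in range(self.n_knots)]
                )
                # keep knots strictly inside the observed range, dedup exact ties
                knots = sorted({float(k) for k in qs if lo < k < hi})
                for k in knots:
                    if "T" in classes:
                        defs.append(FeatureDefinition("T", (n,), ((lo, hi),), knot=k))
                    if "H" in classes:
                        defs.append(FeatureDefinition("H", (n,), ((lo, hi),), knot=k))
        for n in names:
            if n in cat:
                levels = sorted({int(round(x)) for x in cols[n]})
                for lv in levels:
                    defs.append(
                        FeatureDefinition("C", (n,), (bounds[n],), level=lv)
                    )

        self.feature_names_in_ = names
        self.definitions_ = defs
        self.bounds_ = bounds
        self.categorical_names_ = cat
        self.n_features_in_ = len(names)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "definitions_"):
            raise RuntimeError("expander is not fitted")
        cols, names = self._columns(X)
        missing = [n for n in self.feature_names_in_ if n not in cols]
        if missing:
            raise KeyError(f"predictors missing at transform time: {missing}")
        n_rows = len(next(iter(cols.values())))
        out = np.empty((n_rows, len(self.definitions_)), dtype=float)
        for j, d in enumerate(self.definitions_):
            out[:, j] = evaluate_feature(d, cols, clamp=self.clamp)
        return out

    def get_feature_names_out(self, input_features=None):
        return np.array([d.name for d in self.definitions_], dtype=object)
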