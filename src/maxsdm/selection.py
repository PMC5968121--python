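"""AICc-based model selection over feature classes and regularization.

Candidates are the Cartesian product of all non-empty feature-class subsets
with a grid of regularization multipliers. Each candidate is scored by the
small-sample-corrected AIC computed from landscape-standardized raw
probabilities at the occurrence cells, with k = the number of features
carrying nonzero weight after the L1 fit; the lowest-AICc candidate wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .model import MaxEntSDM

DEFAULT_FEATURE_GRID = ("L", "Q", "H", "P", "T")
DEFAULT_REG_GRID = (0.1, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10)

__all__ = [
    "CandidateSpec",
    "CandidateScore",
    "enumerate_candidates",
    "compute_aicc",
    "select_best",
    "tune",
    "DEFAULT_FEATURE_GRID",
    "DEFAULT_REG_GRID",
]


@dataclass(frozen=True)
class CandidateSpec:
    """One tuning candidate: a feature-class subset and a multiplier."""

    feature_classes: tuple[str, ...]
    reg_multiplier: float

    def __post_init__(self):
        object.__setattr__(
            self, "feature_classes", tuple(sorted(self.feature_classes))
        )
        if not self.feature_classes:
            raise ValueError("feature_classes must be non-empty")

    @property
    def label(self) -> str:
        return "".join(self.feature_classes) + f"@{self.reg_multiplier:g}"


@dataclass
class CandidateScore:
    """AICc score of a fitted candidate."""

    spec: CandidateSpec
    k: int
    lnL: float
    aicc: float
    valid: bool


def enumerate_candidates(
    feature_grid=DEFAULT_FEATURE_GRID, reg_grid=DEFAULT_REG_GRID
) -> list[CandidateSpec]:
    """All non-empty feature-class subsets crossed with all multipliers."""
    feature_grid = tuple(feature_grid)
    reg_grid = tuple(reg_grid)
    if not feature_grid or not reg_grid:
        raise ValueError("grids must be non-empty")
    out = []
    for r in range(1, len(feature_grid) + 1):
        for subset in combinations(feature_grid, r):
            for beta in reg_grid:
                out.append(CandidateSpec(subset, float(beta)))
    return out


def aicc_value(lnL: float, k: int, n: int) -> tuple[float, bool]:
    """Small-sample AIC: −2lnL + 2k + 2k(k+1)/(n−k−1); invalid if n ≤ k+1."""
    if n <= k + 1:
        return np.inf, False
    return -2.0 * lnL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1), True


def compute_aicc(
    model: MaxEntSDM, X_landscape, occurrence_indices
) -> CandidateScore:
    """Score a fitted model by AICc on landscape-standardized probabilities.

    Raw Gibbs values are renormalized to sum to 1 over all landscape cells;
    lnL is the sum of log standardized probabilities at the occurrence
    cells (given as row indices into ``X_landscape``); the candidate is
    invalid (non-finite AICc) when n <= k + 1.
    """
    occurrence_indices = np.asarray(occurrence_indices, dtype=int)
    n = len(occurrence_indices)
    raw = model.predict_raw(X_landscape)
    if np.any(occurrence_indices < 0) or np.any(occurrence_indices >= len(raw)):
        raise IndexError("occurrence cell outside the landscape")
    p = raw / raw.sum()
    with np.errstate(divide="ignore"):
        lnL = float(np.sum(np.log(p[occurrence_indices])))
    k = model.nonzero_count()
    spec = CandidateSpec(tuple(model.feature_classes), float(model.reg_multiplier))
    aicc, valid = aicc_value(lnL, k, n)
    return CandidateScore(spec, k, lnL, float(aicc), valid=valid)


def select_best(scores: list[CandidateScore]) -> CandidateSpec:
    """Lowest-AICc valid candidate.

    Ties break toward fewer features (smaller k), then smaller multiplier,
    then lexicographically earlier feature set.
    """
    valid = [s for s in scores if s.valid and np.isfinite(s.aicc)]
    if not valid:
        raise ValueError("no valid candidates to select from")
    return min(
        valid,
        key=lambda s: (s.aicc, s.k, s.spec.reg_multiplier, s.spec.feature_classes),
    ).spec


def tune(
    X,
    y,
    candidates: list[CandidateSpec],
    occurrence_indices=None,
    categorical=(),
    n_knots=10,
    tol=1e-6,
    max_iter=5000,
) -> tuple[CandidateSpec, pd.DataFrame]:
    """Fit every candidate on the full occurrence set and pick the best.

    ``X``/``y`` follow the estimator convention (y=1 presence, 0 background).
    The likelihood support ("landscape") is the set of unique cells among
    the rows of X — presence rows duplicated into the background, or drawn
    repeatedly from the same cell, count once; occurrence cells default to
    the presence rows. Returns the winning spec and the selection table.
    """
    y = np.asarray(y)
    X_arr = np.ascontiguousarray(
        X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame)
        else np.asarray(X, dtype=float)
    )
    _, first, inverse = np.unique(
        X_arr, axis=0, return_index=True, return_inverse=True
    )
    if isinstance(X, pd.DataFrame):
        X_landscape = X.iloc[first].reset_index(drop=True)
    else:
        X_landscape = X_arr[first]
    if occurrence_indices is None:
        occurrence_indices = np.flatnonzero(y == 1)
    occ_cells = inverse[np.asarray(occurrence_indices, dtype=int)]
    scores = []
    for spec in candidates:
        m = MaxEntSDM(
            feature_classes=spec.feature_classes,
            reg_multiplier=spec.reg_multiplier,
            categorical=categorical,
            n_knots=n_knots,
            tol=tol,
            max_iter=max_iter,
        ).fit(X, y)
        scores.append(compute_aicc(m, X_landscape, occ_cells))
    best = select_best(scores)
    table = pd.DataFrame(
        {
            "feature_set": ["".join(s.spec.feature_classes) for s in scores],
            "reg_multiplier": [s.spec.reg_multiplier for s in scores],
            "k": [s.k for s in scores],
            "lnL": [s.lnL for s in scores],
            "AICc": [s.aicc for s in scores],
            "valid": [s.valid for s in scores],
        }
    )
    table["selected"] = [
        (s.spec.feature_classes == best.feature_classes)
        and (s.spec.reg_multiplier == best.reg_multiplier)
        for s in scores
    ]
    return best, table
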