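"""Replicated model fitting, threshold binarization and scenario projection.

The calibrated model is refit on repeated random 75/25 train/validation
partitions of the occurrences (a with-replacement bootstrap option is also
available); the per-replicate logistic maps are averaged into the working
suitability surface. That mean map is binarized at the 10-percentile
training-presence threshold, and future predictor stacks are projected
through every replicate model (with training-range clamping) to quantify
percent range change against the current binary map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MaxEntSDM
from .evaluation import auc

__all__ = [
    "ReplicateSet",
    "ThresholdedMap",
    "ScenarioResult",
    "run_replicates",
    "ten_percentile_threshold",
    "binarize_and_measure",
    "project_scenario",
]


@dataclass
class ReplicateSet:
    """Replicate models, their landscape maps, and the mean map."""

    models: list[MaxEntSDM]
    maps: np.ndarray                 # (n_replicates, n_cells) logistic values
    mean_map: np.ndarray             # (n_cells,)
    train_indices: list[np.ndarray]  # indices into the occurrence array
    test_indices: list[np.ndarray]
    train_auc: np.ndarray
    test_auc: np.ndarray
    seed: int
    train_frac: float

    @property
    def n_replicates(self) -> int:
        return len(self.models)


def run_replicates(
    X_occ,
    X_bg,
    X_landscape,
    feature_classes=("L", "Q"),
    reg_multiplier: float = 1.0,
    n_replicates: int = 20,
    train_frac: float = 0.75,
    seed: int = 0,
    bootstrap: bool = False,
    categorical=(),
    **fit_kwargs,
) -> ReplicateSet:
    """Fit the selected model on repeated random occurrence partitions.

    Each replicate draws a seeded train/test split (``train_frac`` of the
    occurrences to calibration; with-replacement resampling of the training
    part when ``bootstrap=True``), fits on training occurrences against the
    shared background, and predicts the logistic map over the landscape
    rows. The mean map is the cell-wise arithmetic mean across replicates.
    """
    X_occ = _as_frame(X_occ)
    X_bg = _as_frame(X_bg, like=X_occ)
    X_landscape = _as_frame(X_landscape, like=X_occ)
    n_occ = len(X_occ)
    if n_occ < 1:
        raise ValueError("no occurrences")
    rng = np.random.default_rng(seed)
    models, maps, tr_idx, te_idx, tr_auc, te_auc = [], [], [], [], [], []
    for _ in range(n_replicates):
        n_train = max(int(round(train_frac * n_occ)), 1)
        perm = rng.permutation(n_occ)
        train = perm[:n_train]
        test = perm[n_train:]
        if bootstrap:
            train = rng.choice(train, size=len(train), replace=True)
        if len(train) == 0:
            raise ValueError("empty training partition")
        X_train = X_occ.iloc[train]
        X_fit = pd.concat([X_train, X_bg], ignore_index=True)
        y_fit = np.r_[np.ones(len(X_train)), np.zeros(len(X_bg))]
        m = MaxEntSDM(
            feature_classes=feature_classes,
            reg_multiplier=reg_multiplier,
            categorical=categorical,
            **fit_kwargs,
        ).fit(X_fit, y_fit)
        models.append(m)
        maps.append(m.predict_logistic(X_landscape))
        tr_idx.append(train)
        te_idx.append(test)
        bg_scores = m.predict_logistic(X_bg)
        tr_auc.append(auc(m.predict_logistic(X_train), bg_scores))
        if len(test) > 0:
            te_auc.append(auc(m.predict_logistic(X_occ.iloc[test]), bg_scores))
        else:
            te_auc.append(np.nan)
    maps = np.asarray(maps)
    return ReplicateSet(
        models=models,
        maps=maps,
        mean_map=maps.mean(axis=0),
        train_indices=tr_idx,
        test_indices=te_idx,
        train_auc=np.asarray(tr_auc),
        test_auc=np.asarray(te_auc),
        seed=seed,
        train_frac=train_frac,
    )


def _as_frame(X, like: pd.DataFrame | None = None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    cols = like.columns if like is not None else [f"x{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=cols)


# ---------------------------------------------------------------------------
# Thresholding
# ---------------------------------------------------------------------------

def ten_percentile_threshold(training_presence_suitabilities) -> float:
    """The 10-percentile training-presence threshold tau10.

    The ascending order statistic at rank ceil(0.10 n): at most 10% of the
    training presences fall strictly below the returned value. No
    interpolation — the threshold is always an observed suitability.
    """
    v = np.sort(np.asarray(training_presence_suitabilities, dtype=float))
    if v.size == 0:
        raise ValueError("no training presence suitabilities")
    rank = int(np.ceil(0.10 * v.size))
    rank = max(rank, 1)
    return float(v[rank - 1])


@dataclass
class ThresholdedMap:
    """A binary suitable/unsuitable map at threshold tau."""

    threshold: float
    binary: np.ndarray        # bool per landscape cell
    suitable_count: int
    suitable_fraction: float


def binarize_and_measure(suitability, threshold: float) -> ThresholdedMap:
    """Binarize a suitability vector at ``threshold`` (suitable = >= tau)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    s = np.asarray(suitability, dtype=float)
    binary = s >= threshold
    count = int(np.count_nonzero(binary))
    return ThresholdedMap(
        threshold=float(threshold),
        binary=binary,
        suitable_count=count,
        suitable_fraction=count / s.size if s.size else 0.0,
    )


# ---------------------------------------------------------------------------
# Scenario projection
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    """Per-scenario suitability, binary map and percent range change."""

    label: str
    suitability: np.ndarray
    thresholded: ThresholdedMap
    percent_change: float


def project_scenario(
    replicates: ReplicateSet,
    X_future,
    label: str,
    threshold: float,
    current: ThresholdedMap,
) -> ScenarioResult:
    """Project every replicate model onto a future predictor stack.

    Predictor values outside each model's training range are clamped;
    replicate logistic maps are averaged, binarized at the *current-data*
    threshold, and the suitable-area change is reported as
    100 × (future − current) / current.
    """
    X_future = _as_frame(X_future)
    missing = [
        v for v in replicates.models[0].feature_names_in_ if v not in X_future.columns
    ]
    if missing:
        raise KeyError(f"future stack is missing predictors: {missing}")
    maps = np.asarray([m.predict_logistic(X_future) for m in replicates.models])
    mean_map = maps.mean(axis=0)
    thr = binarize_and_measure(mean_map, threshold)
    if current.suitable_count == 0:
        raise ValueError("current suitable area is zero; percent change undefined")
    delta = 100.0 * (thr.suitable_count - current.suitable_count) / current.suitable_count
    return ScenarioResult(
        label=label,
        suitability=mean_map,
        thresholded=thr,
        percent_change=float(delta),
    )
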