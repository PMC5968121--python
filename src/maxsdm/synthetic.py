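"""Synthetic landscapes, occurrences and land-cover pairs with known truth.

Everything downstream (preprocessing, maxent fitting, model selection,
evaluation, Markov land-cover simulation, scenario projection) is testable
against the ground truth generated here: the suitability surface is an exact
log-linear (Gibbs) model with known weights, presences are multinomial draws
from it, and land-cover map pairs are driven by a known transition matrix.

Continuous predictors are spatially autocorrelated random fields built from
Gaussian-smoothed white noise, standardized, then linearly mixed through a
symmetric square root of the target correlation matrix so the fields hit a
requested pairwise correlation structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .features import FeatureDefinition, evaluate_feature
from .geodata import OccurrenceSet
from .raster import RasterGrid, RasterStack

__all__ = [
    "SyntheticLandscapeConfig",
    "SyntheticTruth",
    "SyntheticTransitionSpec",
    "generate_raster_stack",
    "truth_suitability",
    "sample_presences",
    "generate_landcover_pair",
]


@dataclass
class SyntheticLandscapeConfig:
    """Recipe for one synthetic predictor stack.

    ``target_correlations`` must be symmetric with unit diagonal and positive
    semi-definite; ``smoothing_sigma`` (in cells) sets the autocorrelation
    range of the random fields.
    """

    grid_rows: int = 100
    grid_cols: int = 100
    cell_size: float = 1.0
    n_continuous: int = 4
    target_correlations: np.ndarray | None = None
    n_landcover_classes: int = 3
    seed: int = 0
    smoothing_sigma: float = 3.0
    landcover_name: str = "landcover"

    def __post_init__(self):
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.n_continuous < 1:
            raise ValueError("n_continuous must be >= 1")
        if self.n_landcover_classes < 2:
            raise ValueError("n_landcover_classes must be >= 2")
        if self.target_correlations is None:
            self.target_correlations = np.eye(self.n_continuous)
        self.target_correlations = np.asarray(self.target_correlations, dtype=float)
        R = self.target_correlations
        if R.shape != (self.n_continuous, self.n_continuous):
            raise ValueError("target_correlations shape mismatch")
        if not np.allclose(R, R.T):
            raise ValueError("target_correlations must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("target_correlations must have unit diagonal")
        if np.any(np.abs(R) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class SyntheticTruth:
    """The generating log-linear suitability model.

    ``true_weights`` maps each :class:`FeatureDefinition` to its generating
    weight; the implied normalizer makes the surface sum to 1.
    """

    true_weights: dict[FeatureDefinition, float]

    def __post_init__(self):
        if not any(w != 0 for w in self.true_weights.values()):
            # an all-zero truth is allowed as the uniform limit, but an empty
            # weight map is a configuration error
            if not self.true_weights:
                raise ValueError("truth needs at least one feature weight")

    @property
    def feature_classes_used(self) -> set:
        return {d.kind for d in self.true_weights}


@dataclass
class SyntheticTransitionSpec:
    """Generating land-cover dynamics: class prior, transitions, drivers.

    ``driver_effects`` maps a transition pair ``(i, j)`` to a list of
    ``(driver_name, effect)`` where ``effect`` is a callable mapping driver
    values to a non-negative multiplicative factor on the transition odds.
    """

    transition_matrix: np.ndarray
    interval_years: float = 10.0
    class_prior: np.ndarray | None = None
    driver_effects: dict = field(default_factory=dict)
    classes: np.ndarray | None = None

    def __post_init__(self):
        P = np.asarray(self.transition_matrix, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(P < 0):
            raise ValueError("transition probabilities must be >= 0")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1 (±1e-9)")
        if not self.interval_years > 0:
            raise ValueError("interval_years must be positive")
        self.transition_matrix = P
        k = P.shape[0]
        if self.classes is None:
            self.classes = np.arange(1, k + 1)
        self.classes = np.asarray(self.classes)
        if self.class_prior is None:
            self.class_prior = np.full(k, 1.0 / k)
        self.class_prior = np.asarray(self.class_prior, dtype=float)
        if not np.isclose(self.class_prior.sum(), 1.0):
            raise ValueError("class prior must sum to 1")


# ---------------------------------------------------------------------------
# Predictor stack
# ---------------------------------------------------------------------------

def _correlation_factor(R: np.ndarray) -> np.ndarray:
    """Symmetric square root of a correlation matrix.

    Accepts positive semi-definite matrices (perfectly correlated layers are
    a legitimate degenerate request); rejects indefinite ones.
    """
    vals, vecs = np.linalg.eigh(R)
    if np.min(vals) < -1e-8:
        raise ValueError(
            "target correlation matrix is not positive semi-definite "
            f"(min eigenvalue {np.min(vals):.3g})"
        )
    vals = np.clip(vals, 0.0, None)
    return vecs @ np.diag(np.sqrt(vals)) @ vecs.T


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_raster_stack(config: SyntheticLandscapeConfig) -> RasterStack:
    """Generate aligned continuous predictors plus one categorical layer.

    Continuous layers are smoothed-noise fields mixed to approximate
    ``target_correlations``; the categorical land-cover layer is obtained by
    quantile-binning an independent smooth field into
    ``n_landcover_classes`` classes labelled 1..K.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.grid_rows, config.grid_cols)
    A = _correlation_factor(config.target_correlations)
    raw = np.stack(
        [_smooth_field(rng, shape, config.smoothing_sigma).ravel()
         for _ in range(config.n_continuous)]
    )
    mixed = A @ raw
    mask = np.ones(shape, dtype=bool)
    layers: dict[str, RasterGrid] = {}
    for i in range(config.n_continuous):
        layers[f"env{i + 1}"] = RasterGrid(
            mixed[i].reshape(shape), mask.copy(), (0.0, 0.0), config.cell_size
        )
    lc_field = _smooth_field(rng, shape, config.smoothing_sigma)
    edges = np.quantile(
        lc_field, np.linspace(0, 1, config.n_landcover_classes + 1)[1:-1]
    )
    lc = np.digitize(lc_field, edges) + 1  # classes 1..K
    layers[config.landcover_name] = RasterGrid(
        lc.astype(float), mask.copy(), (0.0, 0.0), config.cell_size, categorical=True
    )
    return RasterStack(layers)


# ---------------------------------------------------------------------------
# Truth suitability and presence sampling
# ---------------------------------------------------------------------------

def truth_suitability(stack: RasterStack, truth: SyntheticTruth) -> RasterGrid:
    """Ground-truth suitability exp(lambda* . f(x)), normalized to sum to 1.

    Features are evaluated with the same basis the fitted model uses, so
    parameter-recovery experiments compare like with like.
    """
    rows, cols = stack.valid_rowcol()
    columns = {name: layer.values[rows, cols] for name, layer in stack.items()}
    s = np.zeros(len(rows))
    for defn, w in truth.true_weights.items():
        if w == 0:
            continue
        s += w * evaluate_feature(defn, columns)
    s -= s.max()  # numeric stability; normalization removes the shift
    p = np.exp(s)
    p /= p.sum()
    vals = np.zeros(stack.shape)
    vals[rows, cols] = p
    return RasterGrid(vals, stack.mask.copy(), stack.origin, stack.cell_size)


def sample_presences(suitability: RasterGrid, n: int, seed: int) -> OccurrenceSet:
    """Draw ``n`` presence points (cell centres, with replacement).

    Cells are drawn with probability proportional to the suitability
    surface; coordinates are exact cell centres (no within-cell jitter).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p = suitability.values[suitability.mask].astype(float)
    total = p.sum()
    if total <= 0:
        raise ValueError("suitability is all zero; cannot sample presences")
    p = p / total
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(suitability.mask)
    idx = rng.choice(len(rows), size=n, replace=True, p=p)
    x, y = suitability.rowcol_to_xy(rows[idx], cols[idx])
    return OccurrenceSet(
        np.column_stack([x, y]),
        provenance=f"synthetic multinomial sample (n={n}, seed={seed})",
    )


# ---------------------------------------------------------------------------
# Land-cover pairs
# ---------------------------------------------------------------------------

def generate_landcover_pair(
    spec: SyntheticTransitionSpec, drivers: RasterStack, seed: int
) -> tuple[RasterGrid, RasterGrid]:
    """Generate (t1, t2) categorical maps from known transition dynamics.

    t1 is iid from the class prior over valid cells; each cell's t2 class is
    drawn from its t1 row of the transition matrix, re-weighted cell-wise by
    any driver effects and renormalized.
    """
    rng = np.random.default_rng(seed)
    P = spec.transition_matrix
    K = P.shape[0]
    classes = spec.classes
    mask = drivers.mask
    rows, cols = np.nonzero(mask)
    n = len(rows)
    t1_idx = rng.choice(K, size=n, p=spec.class_prior)

    driver_vals = {name: layer.values[rows, cols] for name, layer in drivers.items()}
    for (i, j), effects in spec.driver_effects.items():
        for name, _ in effects:
            if name not in driver_vals:
                raise KeyError(f"driver layer {name!r} missing from stack")

    t2_idx = np.empty(n, dtype=int)
    cls_index = {c: k for k, c in enumerate(classes)}
    for k in range(K):
        sel = np.nonzero(t1_idx == k)[0]
        if sel.size == 0:
            continue
        probs = np.tile(P[k], (sel.size, 1))
        for (ci, cj), effects in spec.driver_effects.items():
            if cls_index.get(ci) != k:
                continue
            j = cls_index[cj]
            for name, effect in effects:
                mult = np.asarray(effect(driver_vals[name][sel]), dtype=float)
                if np.any(mult < 0):
                    raise ValueError("driver effects must be non-negative")
                probs[:, j] = probs[:, j] * mult
        totals = probs.sum(axis=1)
        dead = totals <= 0
        if np.any(dead):
            # all transitions suppressed: the cell persists
            probs[dead] = 0.0
            probs[dead, k] = 1.0
            totals[dead] = 1.0
        probs /= totals[:, None]
        u = rng.random(sel.size)
        t2_idx[sel] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)

    def to_grid(idx):
        vals = np.zeros(drivers.shape)
        vals[rows, cols] = classes[idx]
        return RasterGrid(
            vals, mask.copy(), drivers.origin, drivers.cell_size, categorical=True
        )

    return to_grid(t1_idx), to_grid(t2_idx)
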