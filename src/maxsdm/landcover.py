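"""Land-cover change simulation: cross-tabulated Markov transitions, matrix
powers for horizon scaling, MLP transition potentials on driver variables,
and spatially explicit change allocation.

The workflow mirrors the classic MLP–Markov land-change recipe: estimate a
row-stochastic transition matrix from two dated maps, assume stationarity to
scale it to the projection horizon, model where each transition is likely
with a small neural network on driver rasters, then convert the demanded
number of cells at the highest-potential locations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier

from .raster import RasterGrid, RasterStack

__all__ = [
    "TransitionMatrix",
    "MLPArch",
    "TransitionPotentialSet",
    "crosstab_transition",
    "scale_matrix",
    "train_transition_mlp",
    "demand_from_matrix",
    "allocate_change",
    "class_area_report",
]


@dataclass
class TransitionMatrix:
    """Row-stochastic class-to-class transition probabilities."""

    classes: np.ndarray
    P: np.ndarray
    interval_years: float
    method: str = "crosstab"

    def __post_init__(self):
        self.classes = np.asarray(self.classes)
        self.P = np.asarray(self.P, dtype=float)
        k = len(self.classes)
        if self.P.shape != (k, k):
            raise ValueError("matrix shape does not match class count")
        if np.any(self.P < -1e-12):
            raise ValueError("transition probabilities must be >= 0")
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows must sum to 1 (±1e-9)")
        if not self.interval_years > 0:
            raise ValueError("interval_years must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.classes, columns=self.classes)


def _class_values(grid: RasterGrid) -> np.ndarray:
    return np.round(grid.values[grid.mask]).astype(int)


def crosstab_transition(map_t1: RasterGrid, map_t2: RasterGrid) -> TransitionMatrix:
    """Estimate the transition matrix by cross-tabulating two dated maps.

    P[i, j] = (# cells of class i at t1 and j at t2) / (# cells of class i
    at t1). Classes present only at t2 get identity rows. The interval is
    set to 1 by default; callers carrying real dates should construct the
    result with the appropriate ``interval_years``.
    """
    if not map_t1.same_grid(map_t2):
        raise ValueError("maps are not aligned")
    if not np.array_equal(map_t1.mask, map_t2.mask):
        raise ValueError("maps have different validity masks")
    v1, v2 = _class_values(map_t1), _class_values(map_t2)
    classes = np.unique(np.concatenate([v1, v2]))
    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((k, k))
    np.add.at(counts, ([index[c] for c in v1], [index[c] for c in v2]), 1)
    row_tot = counts.sum(axis=1)
    P = np.eye(k)
    present = row_tot > 0
    P[present] = counts[present] / row_tot[present, None]
    return TransitionMatrix(classes, P, interval_years=1.0)


def scale_matrix(m: TransitionMatrix, target_years: float) -> TransitionMatrix:
    """Raise the matrix to the power target_years / interval_years.

    The real (possibly fractional) matrix power is taken through the
    eigendecomposition; tiny negative entries are clipped and rows
    renormalized. If the eigendecomposition route yields materially negative
    or complex entries, falls back to integer powers of the per-interval
    matrix with linear interpolation of the fractional step (flagged in
    ``method``).
    """
    if not target_years > 0:
        raise ValueError("target_years must be positive")
    t = target_years / m.interval_years
    P = m.P
    try:
        vals, vecs = np.linalg.eig(P)
        # principal branch of the power for possibly complex eigenvalues
        powed = vecs @ np.diag(np.power(vals.astype(complex), t)) @ np.linalg.inv(vecs)
        ok = np.max(np.abs(powed.imag)) < 1e-8 and np.min(powed.real) > -1e-8
        method = "eig"
    except np.linalg.LinAlgError:
        ok = False
    if ok:
        Q = np.clip(powed.real, 0.0, None)
    else:
        # repeated multiplication with linear interpolation of the fraction
        n = int(np.floor(t))
        frac = t - n
        Q = np.linalg.matrix_power(P, n)
        if frac > 0:
            Q = Q @ ((1 - frac) * np.eye(len(P)) + frac * P)
        Q = np.clip(Q, 0.0, None)
        method = "interp"
        warnings.warn(
            "matrix power via eigendecomposition unstable; "
            "fell back to interpolated integer powers"
        )
    Q = Q / Q.sum(axis=1, keepdims=True)
    return TransitionMatrix(m.classes, Q, interval_years=target_years, method=method)


# ---------------------------------------------------------------------------
# MLP transition potentials
# ---------------------------------------------------------------------------

@dataclass
class MLPArch:
    """Architecture/training settings of the transition-potential networks."""

    hidden: int = 10
    epochs: int = 1000
    learning_rate: float = 0.01
    seed: int = 0
    max_per_class: int = 2000  # balanced-sampling cap per destination class


@dataclass
class TransitionPotentialSet:
    """Per-transition potential rasters in [0, 1] plus the fitted networks."""

    potentials: dict[tuple[int, int], RasterGrid]
    models: dict[int, MLPClassifier] = field(default_factory=dict)
    arch: MLPArch = field(default_factory=MLPArch)

    def __getitem__(self, pair):
        return self.potentials[pair]

    def __contains__(self, pair):
        return pair in self.potentials


def train_transition_mlp(
    map_t1: RasterGrid,
    map_t2: RasterGrid,
    drivers: RasterStack,
    arch: MLPArch | None = None,
) -> TransitionPotentialSet:
    """Model transition potentials with one MLP per source class.

    For each source class with at least one observed transition, a single-
    hidden-layer network with logistic activations (softmax output over
    destination classes) is trained on a balanced, seeded subsample of that
    class's cells; the potential raster of pair (i, j) holds the predicted
    probability of destination j at every valid cell.
    """
    if arch is None:
        arch = MLPArch()
    if not map_t1.same_grid(drivers.template):
        raise ValueError("land-cover maps and drivers are not aligned")
    if len(drivers) < 1:
        raise ValueError("at least one driver layer is required")
    rows, cols = np.nonzero(map_t1.mask & drivers.mask)
    X_all = np.column_stack(
        [drivers[n].values[rows, cols] for n in drivers.names]
    )
    # standardize drivers for stable training
    mu, sd = X_all.mean(axis=0), X_all.std(axis=0)
    sd[sd == 0] = 1.0
    X_all = (X_all - mu) / sd
    v1 = np.round(map_t1.values[rows, cols]).astype(int)
    v2 = np.round(map_t2.values[rows, cols]).astype(int)

    rng = np.random.default_rng(arch.seed)
    potentials: dict[tuple[int, int], RasterGrid] = {}
    models: dict[int, MLPClassifier] = {}
    for i in np.unique(v1):
        sel = np.nonzero(v1 == i)[0]
        dests = np.unique(v2[sel])
        if len(dests) < 2:
            continue  # pure persistence: nothing to model for this source
        # balanced subsample across destination classes
        parts = []
        for j in dests:
            cells = sel[v2[sel] == j]
            if len(cells) > arch.max_per_class:
                cells = rng.choice(cells, size=arch.max_per_class, replace=False)
            parts.append(cells)
        train = np.concatenate(parts)
        net = MLPClassifier(
            hidden_layer_sizes=(arch.hidden,),
            activation="logistic",
            solver="adam",
            learning_rate_init=arch.learning_rate,
            max_iter=arch.epochs,
            random_state=arch.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter at small epochs
            net.fit(X_all[train], v2[train])
        models[int(i)] = net
        proba = net.predict_proba(X_all)
        for j in dests:
            if j == i:
                continue
            col = list(net.classes_).index(j)
            vals = np.zeros(map_t1.shape)
            vals[rows, cols] = proba[:, col]
            potentials[(int(i), int(j))] = RasterGrid(
                vals, map_t1.mask.copy(), map_t1.origin, map_t1.cell_size
            )
    observed_pairs = {(int(a), int(b)) for a, b in zip(v1, v2) if a != b}
    skipped = observed_pairs - set(potentials)
    for pair in skipped:
        warnings.warn(f"transition {pair} observed but not modelled (degenerate data)")
    return TransitionPotentialSet(potentials, models, arch)


# ---------------------------------------------------------------------------
# Demand and allocation
# ---------------------------------------------------------------------------

def demand_from_matrix(
    matrix: TransitionMatrix, map_current: RasterGrid
) -> dict[tuple[int, int], int]:
    """Integer per-pair conversion demand from a transition matrix.

    Expected counts (class count × row probability) are integerized by the
    largest-remainder rule within each row so the row total is conserved
    exactly. Returns only off-diagonal (true conversion) demands > 0.
    """
    v = _class_values(map_current)
    classes = list(matrix.classes)
    demand: dict[tuple[int, int], int] = {}
    for i, ci in enumerate(classes):
        n_i = int(np.count_nonzero(v == ci))
        if n_i == 0:
            continue
        exact = n_i * matrix.P[i]
        floor = np.floor(exact).astype(int)
        short = n_i - floor.sum()
        order = np.argsort(-(exact - floor), kind="stable")
        alloc = floor.copy()
        alloc[order[:short]] += 1
        for j, cj in enumerate(classes):
            if ci != cj and alloc[j] > 0:
                demand[(int(ci), int(cj))] = int(alloc[j])
    return demand


def allocate_change(
    map_current: RasterGrid,
    demand: dict[tuple[int, int], int],
    potentials: TransitionPotentialSet,
    seed: int = 0,
) -> RasterGrid:
    """Convert the demanded cell counts at the highest-potential locations.

    Transitions are processed in descending demand order; each converts the
    demanded number of source-class cells with the highest potential (ties
    broken by a seeded random draw); a cell converts at most once and all
    other cells persist.
    """
    rng = np.random.default_rng(seed)
    out = map_current.copy()
    vals = np.round(out.values).astype(int)
    rows, cols = np.nonzero(out.mask)
    converted = np.zeros(out.shape, dtype=bool)

    # scale down per-class if total outgoing demand exceeds availability
    demand = dict(demand)
    by_source: dict[int, int] = {}
    for (i, j), d in demand.items():
        by_source[i] = by_source.get(i, 0) + d
    for i, total in by_source.items():
        avail = int(np.count_nonzero(vals[out.mask] == i))
        if total > avail:
            warnings.warn(
                f"outgoing demand {total} for class {i} exceeds its {avail} cells; "
                "scaling down proportionally"
            )
            scale = avail / total
            for key in [k for k in demand if k[0] == i]:
                demand[key] = int(np.floor(demand[key] * scale))

    for (i, j), d in sorted(demand.items(), key=lambda kv: -kv[1]):
        if d <= 0:
            continue
        cand = out.mask & (vals == i) & ~converted
        r, c = np.nonzero(cand)
        if len(r) == 0:
            continue
        if (i, j) in potentials:
            score = potentials[(i, j)].values[r, c]
        else:
            warnings.warn(
                f"no potential raster for transition {(i, j)}; using uniform potential"
            )
            score = np.zeros(len(r))
        tie = rng.random(len(r))
        order = np.lexsort((tie, -score))
        take = order[: min(d, len(r))]
        vals[r[take], c[take]] = j
        converted[r[take], c[take]] = True

    out.values = vals.astype(float)
    out.categorical = True
    return out


def class_area_report(
    map_t1: RasterGrid,
    map_t2: RasterGrid,
    class_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-class area change table (area units = cell_size² per cell).

    Columns: class_id, name, area_t1, area_t2, percent_change; the percent
    change is recomputed from the areas (100 × (t2 − t1)/t1).
    """
    if not map_t1.same_grid(map_t2):
        raise ValueError("maps are not aligned")
    cell_area = map_t1.cell_size**2
    v1, v2 = _class_values(map_t1), _class_values(map_t2)
    classes = np.unique(np.concatenate([v1, v2]))
    rows = []
    for c in classes:
        a1 = np.count_nonzero(v1 == c) * cell_area
        a2 = np.count_nonzero(v2 == c) * cell_area
        pct = 100.0 * (a2 - a1) / a1 if a1 > 0 else np.nan
        rows.append(
            {
                "class_id": int(c),
                "name": (class_names or {}).get(int(c), str(int(c))),
                "area_t1": a1,
                "area_t2": a2,
                "percent_change": pct,
            }
        )
    return pd.DataFrame(rows)


def percent_area_change(area_t1: float, area_t2: float) -> float:
    """Percent change between two class areas: 100 × (t2 − t1) / t1."""
    if area_t1 <= 0:
        raise ValueError("baseline area must be positive")
    return 100.0 * (area_t2 - area_t1) / area_t1


__all__.append("percent_area_change")
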