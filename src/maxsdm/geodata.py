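"""Occurrence cleaning, spatial rarefaction, background sampling and
collinearity filtering of predictor layers.

Rarefaction keeps exactly one occurrence per occupied grid cell (the first in
input order), the standard spatial-thinning step used to damp spatial
autocorrelation in presence-only records. The collinearity filter greedily
drops predictors until no retained pair exceeds the |r| cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OccurrenceSet",
    "VariableFilterResult",
    "read_occurrences_csv",
    "clean_and_rarefy",
    "sample_background",
    "correlation_filter",
]


@dataclass
class OccurrenceSet:
    """Presence point coordinates with provenance notes."""

    points: np.ndarray  # (n, 2) array of x, y
    provenance: str = ""

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of x, y")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y": self.y})

    def to_csv(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)


def read_occurrences_csv(path) -> OccurrenceSet:
    """Read occurrences from a CSV with at least columns x, y."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "x" not in cols or "y" not in cols:
        raise ValueError(f"{path}: occurrence CSV needs columns x and y")
    pts = df[[cols["x"], cols["y"]]].to_numpy(dtype=float)
    return OccurrenceSet(pts, provenance=f"read from {path}")


# ---------------------------------------------------------------------------
# Cleaning and rarefaction
# ---------------------------------------------------------------------------

def clean_and_rarefy(occ: OccurrenceSet, grid) -> OccurrenceSet:
    """Drop bad records, deduplicate, and thin to one point per grid cell.

    Steps, in order: drop non-finite coordinates; drop exact duplicate
    points; drop points falling outside the grid or on masked cells; keep
    only the first point (input order) in each occupied cell.
    """
    pts = occ.points
    finite = np.all(np.isfinite(pts), axis=1)
    pts = pts[finite]
    # stable exact dedup, first occurrence wins
    seen: set = set()
    keep = []
    for i, (px, py) in enumerate(pts):
        key = (px, py)
        if key not in seen:
            seen.add(key)
            keep.append(i)
    pts = pts[keep]

    rows, cols = grid.xy_to_rowcol(pts[:, 0], pts[:, 1])
    inb = grid.in_bounds(rows, cols)
    valid = inb.copy()
    valid[inb] &= grid.mask[rows[inb], cols[inb]]
    pts, rows, cols = pts[valid], rows[valid], cols[valid]

    cells: set = set()
    keep = []
    for i, (r, c) in enumerate(zip(rows, cols)):
        if (r, c) not in cells:
            cells.add((r, c))
            keep.append(i)
    out = pts[keep]
    if len(out) == 0:
        raise ValueError("no usable occurrences after cleaning and rarefaction")
    return OccurrenceSet(out, provenance=occ.provenance + " | cleaned+rarefied")


# ---------------------------------------------------------------------------
# Background sampling
# ---------------------------------------------------------------------------

def sample_background(stack, n: int, seed: int) -> OccurrenceSet:
    """Sample ``n`` background cell centres uniformly without replacement.

    If ``n`` is at least the number of valid cells, every valid cell is
    returned once (with a warning).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rows, cols = stack.valid_rowcol()
    total = len(rows)
    if total == 0:
        raise ValueError("stack is fully masked; no background available")
    if n >= total:
        if n > total:
            warnings.warn(
                f"requested {n} background points but only {total} valid cells; "
                "returning all valid cells"
            )
        idx = np.arange(total)
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(total, size=n, replace=False)
    x, y = stack.template.rowcol_to_xy(rows[idx], cols[idx])
    return OccurrenceSet(
        np.column_stack([x, y]),
        provenance=f"uniform background sample (n={len(idx)}, seed={seed})",
    )


# ---------------------------------------------------------------------------
# Collinearity filter
# ---------------------------------------------------------------------------

@dataclass
class VariableFilterResult:
    """Outcome of the pairwise-correlation screen."""

    retained: list[str]
    dropped: list[tuple[str, str, float]]  # (name, partner, r at drop time)
    cutoff: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"name": n, "partner": "", "r": np.nan, "action": "retained"}
            for n in self.retained
        ] + [
            {"name": n, "partner": p, "r": r, "action": "dropped"}
            for n, p, r in self.dropped
        ]
        return pd.DataFrame(rows, columns=["name", "partner", "r", "action"])


def correlation_filter(
    stack,
    cells: tuple[np.ndarray, np.ndarray] | None = None,
    cutoff: float = 0.85,
    priority: list[str] | None = None,
) -> VariableFilterResult:
    """Greedy Pearson-correlation screen of continuous predictors.

    Correlations are computed over ``cells`` (rows, cols — typically the
    union of presence and background cells; defaults to all valid cells).
    While any retained pair exceeds ``|r| > cutoff``, the member with the
    higher mean absolute correlation against the other retained layers is
    dropped; a user ``priority`` list (earlier = keep) overrides that rule.
    Categorical layers pass through untouched; constant layers are dropped
    with a warning.
    """
    cont = stack.continuous_names
    if len(cont) < 2:
        raise ValueError("correlation filter needs at least two continuous layers")
    if cells is None:
        rows, cols = stack.valid_rowcol()
    else:
        rows, cols = cells
    data = {n: stack[n].values[rows, cols] for n in cont}
    dropped: list[tuple[str, str, float]] = []
    retained = []
    for n in cont:
        if np.std(data[n]) == 0:
            warnings.warn(f"layer {n!r} is constant over the support; dropped")
            dropped.append((n, "", np.nan))
        else:
            retained.append(n)

    def corr_matrix(names):
        mat = np.corrcoef(np.stack([data[n] for n in names]))
        return np.atleast_2d(mat)

    while len(retained) >= 2:
        R = corr_matrix(retained)
        np.fill_diagonal(R, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(R)), R.shape)
        r = R[i, j]
        if abs(r) <= cutoff:
            break
        a, b = retained[i], retained[j]
        if priority is not None:
            def rank(name):
                return priority.index(name) if name in priority else len(priority)
            drop = b if rank(a) < rank(b) else a if rank(b) < rank(a) else None
        else:
            drop = None
        if drop is None:
            mean_abs = np.abs(R).sum(axis=0) / max(len(retained) - 1, 1)
            drop = a if mean_abs[i] >= mean_abs[j] else b
        keep = b if drop == a else a
        retained.remove(drop)
        dropped.append((drop, keep, float(r)))

    return VariableFilterResult(
        retained=retained + stack.categorical_names, dropped=dropped, cutoff=cutoff
    )
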