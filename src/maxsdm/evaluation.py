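"""Model evaluation: rank AUC with qualitative bands, the Continuous Boyce
Index, jackknife variable importance, and percent variable contribution.

The Boyce index scans overlapping suitability windows across the prediction
gradient, compares the fraction of presences falling in each window (P) with
the fraction of landscape cells there (E), and reports the Spearman rank
correlation of P/E against the window midpoint — +1 when higher-suitability
areas hold disproportionately more presences, ~0 for a random model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .model import MaxEntSDM

__all__ = [
    "auc",
    "auc_band",
    "BoyceResult",
    "boyce_index",
    "jackknife_gains",
    "percent_contribution",
    "EvaluationReport",
]


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def auc(presence_scores, background_scores) -> float:
    """Rank-based (Mann–Whitney) AUC; ties count one half.

    The probability that a randomly drawn presence outranks a randomly
    drawn background point under the model's scores.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    r_p = ranks[: p.size].sum()
    u = r_p - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


_BANDS = [
    (0.5, 0.6, "Failed"),
    (0.6, 0.7, "Poor"),
    (0.7, 0.8, "Fair"),
    (0.8, 0.9, "Good"),
    (0.9, 1.0 + 1e-12, "Excellent"),
]


def auc_band(value: float) -> str:
    """Qualitative AUC band (Swets-style); boundaries go to the upper band."""
    if not 0.0 <= value <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    if value < 0.5:
        return "worse than random"
    label = "Excellent"
    for lo, hi, name in _BANDS:
        if lo <= value < hi:
            label = name
            break
    return label


# ---------------------------------------------------------------------------
# Continuous Boyce Index
# ---------------------------------------------------------------------------

@dataclass
class BoyceResult:
    """Windowed predicted-to-expected ratios and their rank correlation."""

    midpoints: np.ndarray
    pe_ratio: np.ndarray
    cbi: float
    window_count: int
    window_width: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"midpoint": self.midpoints, "pe_ratio": self.pe_ratio})


def boyce_index(
    presence_suitability,
    landscape_suitability,
    window_count: int = 101,
    window_width: float | None = None,
) -> BoyceResult:
    """Continuous Boyce Index over overlapping suitability windows.

    ``window_width`` defaults to 10% of the landscape suitability range.
    Windows with zero expected (landscape) mass are dropped; fewer than 3
    usable windows leaves the rank correlation undefined and raises.
    """
    pres = np.asarray(presence_suitability, dtype=float)
    land = np.asarray(landscape_suitability, dtype=float)
    if pres.size == 0 or land.size == 0:
        raise ValueError("presence and landscape suitabilities must be non-empty")
    lo, hi = float(np.min(land)), float(np.max(land))
    rng = hi - lo
    if window_width is None:
        window_width = 0.1 * rng if rng > 0 else 0.1
    starts = np.linspace(lo, hi - window_width, window_count)
    mids, pe = [], []
    n_p, n_l = pres.size, land.size
    for s in starts:
        e = s + window_width
        p_frac = np.count_nonzero((pres >= s) & (pres <= e)) / n_p
        e_frac = np.count_nonzero((land >= s) & (land <= e)) / n_l
        if e_frac == 0:
            continue
        mids.append(s + window_width / 2)
        pe.append(p_frac / e_frac)
    if len(mids) < 3:
        raise ValueError(
            f"only {len(mids)} usable windows; Boyce correlation undefined"
        )
    mids = np.asarray(mids)
    pe = np.asarray(pe)
    if np.all(pe == pe[0]):
        cbi = 0.0  # flat P/E: indistinguishable from random
    else:
        cbi = float(spearmanr(mids, pe).statistic)
    return BoyceResult(mids, pe, cbi, window_count, float(window_width))


# ---------------------------------------------------------------------------
# Jackknife variable importance
# ---------------------------------------------------------------------------

def jackknife_gains(
    X: pd.DataFrame,
    y,
    feature_classes=("L", "Q"),
    reg_multiplier: float = 1.0,
    categorical=(),
    variables=None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Leave-one-out / only-one variable importance by training gain.

    Refits the model with each variable omitted and with each variable
    alone, keeping the feature classes and regularization fixed, and
    reports the training gains next to the full-model gain.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"x{i}" for i in range(X.shape[1])]
    variables = list(variables) if variables is not None else [str(c) for c in X.columns]
    if len(variables) < 2:
        raise ValueError("jackknife needs at least two variables")

    def fit_on(cols):
        cats = tuple(c for c in categorical if c in cols)
        m = MaxEntSDM(
            feature_classes=feature_classes,
            reg_multiplier=reg_multiplier,
            categorical=cats,
            **fit_kwargs,
        ).fit(X[cols], y)
        return m.gain_

    full_gain = fit_on(variables)
    rows = []
    for v in variables:
        without = [c for c in variables if c != v]
        rows.append(
            {
                "variable": v,
                "gain_without": fit_on(without),
                "gain_alone": fit_on([v]),
                "full_gain": full_gain,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Percent contribution
# ---------------------------------------------------------------------------

def percent_contribution(model: MaxEntSDM) -> pd.Series:
    """Per-variable percent contribution from the fit's gain credits.

    Objective-improvement credits accumulated during coordinate ascent are
    summed per source variable (product features split evenly between their
    two variables), floored at zero, and normalized to sum to 100.
    """
    model._check_fitted()
    credits: dict[str, float] = {n: 0.0 for n in model.feature_names_in_}
    for d, c in zip(model.feature_definitions_, model.feature_credits_):
        share = c / len(d.variables)
        for v in d.variables:
            credits[v] += share
    s = pd.Series(credits).clip(lower=0.0)
    total = s.sum()
    if total <= 0:
        warnings.warn("zero total gain; reporting uniform contributions")
        return pd.Series(100.0 / len(s), index=s.index)
    return 100.0 * s / total


# ---------------------------------------------------------------------------
# Report container
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Bundled evaluation outputs for one calibrated model."""

    auc_train: float
    auc_test: float
    band: str
    cbi: float
    jackknife: pd.DataFrame
    contributions: pd.Series

    def to_dict(self) -> dict:
        return {
            "auc_train": self.auc_train,
            "auc_test": self.auc_test,
            "band": self.band,
            "cbi": self.cbi,
            "jackknife": self.jackknife.to_dict(orient="records"),
            "percent_contribution": self.contributions.to_dict(),
        }
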