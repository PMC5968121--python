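"""L1-regularized maximum-entropy habitat-suitability model.

The model is the Gibbs distribution q_lambda(x) = exp(lambda . f(x)) / Z over
the background cells, fitted to presence records by maximizing the penalized
log-likelihood

    sum_presence log q_lambda(x_i)  -  sum_j beta_j |lambda_j|

with per-feature penalties beta_j = reg_multiplier * class_default *
sd_j / sqrt(n_presence), sd_j taken over presence sites. Optimization is
coordinate-wise sequential ascent: at each iteration the coordinate with the
largest effective (penalty-adjusted) gradient is updated by a safeguarded
proximal Newton step, so the penalized objective never decreases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .features import MaxentFeatureExpander

# Editable per-feature-class penalty defaults (multiplied into beta_j).
DEFAULT_CLASS_PENALTIES: dict[str, float] = {
    "L": 1.0,
    "Q": 1.0,
    "P": 1.0,
    "T": 1.0,
    "H": 0.5,
    "C": 1.0,
}

__all__ = ["FitConfig", "MaxentFit", "fit_maxent", "penalized_objective", "MaxEntSDM",
           "DEFAULT_CLASS_PENALTIES"]


@dataclass
class FitConfig:
    """Solver settings: regularization strength and stopping rule."""

    reg_multiplier: float = 1.0
    class_penalties: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PENALTIES))
    tol: float = 1e-6
    max_iter: int = 5000

    def __post_init__(self):
        if self.reg_multiplier < 0:
            raise ValueError("reg_multiplier must be >= 0")
        if not self.tol > 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class MaxentFit:
    """Raw solver output for a fixed feature basis."""

    lambdas: np.ndarray
    objective: float            # penalized sum-form objective
    gain: float                 # mean presence log prob + log N_background
    reg_gain_trajectory: np.ndarray  # penalized (regularized) gain per iteration
    feature_credits: np.ndarray # objective improvement credited per feature
    converged: bool
    n_iter: int
    log_z: float                # log normalizer over the background


def penalized_objective(lambdas, F_pres, F_bg, betas) -> float:
    """Sum-form penalized log-likelihood at ``lambdas`` (the fit criterion)."""
    lambdas = np.asarray(lambdas, dtype=float)
    s_pres = F_pres @ lambdas
    log_z = logsumexp(F_bg @ lambdas)
    return float(np.sum(s_pres) - len(F_pres) * log_z - np.sum(betas * np.abs(lambdas)))


def _soft_threshold(z: float, t: float) -> float:
    return np.sign(z) * max(abs(z) - t, 0.0)


def fit_maxent(F_pres, F_bg, betas, tol: float = 1e-6, max_iter: int = 5000) -> MaxentFit:
    """Fit maxent weights by penalized coordinate ascent.

    Parameters
    ----------
    F_pres, F_bg : ndarray
        Feature matrices (rows = presence / background cells) in [0, 1].
    betas : ndarray
        Per-feature L1 penalties on the *sum-form* objective.
    tol : float
        Convergence threshold on the maximum penalty-adjusted gradient of
        the mean-form objective (first-order optimality).
    max_iter : int
        Iteration cap; non-convergence is flagged, not raised.
    """
    F_pres = np.asarray(F_pres, dtype=float)
    F_bg = np.asarray(F_bg, dtype=float)
    if F_pres.ndim != 2 or F_bg.ndim != 2:
        raise ValueError("feature matrices must be 2-D")
    if not (np.all(np.isfinite(F_pres)) and np.all(np.isfinite(F_bg))):
        raise ValueError("non-finite feature values")
    m, k = F_pres.shape
    n_bg = F_bg.shape[0]
    if m < 1:
        raise ValueError("at least one presence row is required")
    if n_bg < 2:
        raise ValueError("at least two background rows are required")
    if F_bg.shape[1] != k:
        raise ValueError("presence/background feature dimension mismatch")
    betas = np.asarray(betas, dtype=float)
    b = betas / m  # mean-form penalties

    fbar = F_pres.mean(axis=0)
    lam = np.zeros(k)
    s_bg = np.zeros(n_bg)       # F_bg @ lam, maintained incrementally
    s_pres_mean = 0.0           # fbar @ lam

    def mean_objective(log_z):
        return s_pres_mean - log_z - float(b @ np.abs(lam))

    log_z = np.log(n_bg)
    obj = mean_objective(log_z)
    log_unif = np.log(n_bg)
    traj = [obj + log_unif]     # regularized gain trajectory
    credits = np.zeros(k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = np.exp(s_bg - log_z)            # background Gibbs weights, sum to 1
        e_f = F_bg.T @ w                    # E_q[f]
        g = fbar - e_f                      # unpenalized gradient (mean form)
        # effective gradient magnitude under the L1 penalty
        eff = np.where(
            lam != 0.0,
            np.abs(g - b * np.sign(lam)),
            np.maximum(np.abs(g) - b, 0.0),
        )
        j = int(np.argmax(eff))             # ties -> lowest index
        if eff[j] <= tol:                   # first-order optimality reached
            converged = True
            traj.append(obj + log_unif)
            break
        fj = F_bg[:, j]
        h = float(fj**2 @ w - e_f[j] ** 2)
        h = max(h, 1e-10)
        lam_new = _soft_threshold(lam[j] + g[j] / h, b[j] / h)
        # safeguarded step: backtrack until the penalized objective improves
        improved = False
        for _ in range(60):
            d = lam_new - lam[j]
            if d == 0.0:
                break
            s_bg_try = s_bg + d * fj
            log_z_try = logsumexp(s_bg_try)
            s_pres_try = s_pres_mean + d * fbar[j]
            obj_try = (
                s_pres_try - log_z_try
                - float(b @ np.abs(lam)) - b[j] * (abs(lam_new) - abs(lam[j]))
            )
            if obj_try >= obj:
                improved = True
                break
            lam_new = lam[j] + 0.5 * d
        if improved:
            delta = obj_try - obj
            credits[j] += delta
            lam[j] = lam_new
            s_bg = s_bg_try
            log_z = log_z_try
            s_pres_mean = s_pres_try
            obj = obj_try
            traj.append(obj + log_unif)
        else:
            # backtracking exhausted: at the numerical limit of improvement
            traj.append(obj + log_unif)
            converged = True
            break
    if not converged:
        warnings.warn(
            f"maxent fit did not converge in {max_iter} iterations "
            f"(residual gradient {eff[j]:.3g})"
        )
    gain = s_pres_mean - log_z + log_unif
    objective = penalized_objective(lam, F_pres, F_bg, betas)
    return MaxentFit(
        lambdas=lam,
        objective=objective,
        gain=float(gain),
        reg_gain_trajectory=np.asarray(traj),
        feature_credits=credits,
        converged=converged,
        n_iter=it,
        log_z=float(log_z),
    )


class MaxEntSDM(BaseEstimator):
    """Presence/background maximum-entropy species distribution model.

    A scikit-learn style estimator: ``fit(X, y)`` takes raw predictor values
    (rows = cells) and a binary target where 1 marks presence cells and 0
    background cells. Feature expansion (see
    :class:`~maxsdm.features.MaxentFeatureExpander`) happens inside ``fit``
    with scaling bounds frozen from the pooled training support.

    Parameters
    ----------
    feature_classes : iterable of {"L","Q","P","T","H"}
        Basis classes for continuous predictors.
    reg_multiplier : float
        Global regularization multiplier (larger = sparser model).
    n_knots : int
        Knots per variable for threshold/hinge features.
    categorical : iterable
        Names or indices of categorical predictors.
    tol, max_iter :
        Solver stopping rule (penalized-gain improvement / iteration cap).
    clamp : bool
        Clamp projection-time predictor values into the training bounds.

    Attributes
    ----------
    lambdas_ : ndarray — fitted feature weights.
    feature_definitions_ : list of FeatureDefinition.
    Z_ : float — normalizer over the training background.
    entropy_ : float — entropy H of the raw distribution over background.
    gain_ : float — training gain (mean presence log-prob − log uniform).
    gain_trajectory_ : ndarray — regularized gain per iteration (non-decreasing).
    feature_credits_ : ndarray — per-feature objective-improvement credits.
    converged_ : bool
    """

    def __init__(
        self,
        feature_classes=("L", "Q"),
        reg_multiplier=1.0,
        n_knots=10,
        categorical=(),
        class_penalties=None,
        tol=1e-6,
        max_iter=5000,
        clamp=True,
    ):
        self.feature_classes = feature_classes
        self.reg_multiplier = reg_multiplier
        self.n_knots = n_knots
        self.categorical = categorical
        self.class_penalties = class_penalties
        self.tol = tol
        self.max_iter = max_iter
        self.clamp = clamp

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y):
        y = np.asarray(y)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("y must be binary: 1 = presence, 0 = background")
        pres_idx = np.flatnonzero(y == 1)
        bg_idx = np.flatnonzero(y == 0)
        if len(pres_idx) < 1:
            raise ValueError("at least one presence row is required")
        if len(bg_idx) < 2:
            raise ValueError("at least two background rows are required")

        self.expander_ = MaxentFeatureExpander(
            feature_classes=self.feature_classes,
            n_knots=self.n_knots,
            categorical=self.categorical,
            clamp=self.clamp,
        ).fit(X)
        F = self.expander_.transform(X)
        F_pres, F_bg = F[pres_idx], F[bg_idx]
        m = len(pres_idx)

        table = dict(DEFAULT_CLASS_PENALTIES)
        if self.class_penalties:
            table.update(self.class_penalties)
        sd = F_pres.std(axis=0)
        class_mult = np.array(
            [table[d.kind] for d in self.expander_.definitions_], dtype=float
        )
        self.betas_ = self.reg_multiplier * class_mult * np.maximum(sd, 1e-6) / np.sqrt(m)

        fit = fit_maxent(
            F_pres, F_bg, self.betas_, tol=self.tol, max_iter=self.max_iter
        )
        self.fit_result_ = fit
        self.lambdas_ = fit.lambdas
        self.feature_definitions_ = self.expander_.definitions_
        self.log_Z_ = fit.log_z
        self.Z_ = float(np.exp(fit.log_z))
        self.gain_ = fit.gain
        self.gain_trajectory_ = fit.reg_gain_trajectory
        self.feature_credits_ = fit.feature_credits
        self.converged_ = fit.converged
        self.objective_ = fit.objective
        self.n_iter_ = fit.n_iter

        # raw distribution over the training background
        s_bg = F_bg @ self.lambdas_
        w = np.exp(s_bg - logsumexp(s_bg))
        with np.errstate(divide="ignore", invalid="ignore"):
            lw = np.where(w > 0, np.log(np.where(w > 0, w, 1.0)), 0.0)
        self.entropy_ = float(-np.sum(w * lw))

        # stored training summaries for response curves
        cols, names = self.expander_._columns(X)
        self.feature_names_in_ = names
        bg_cols = {n: cols[n][bg_idx] for n in names}
        self.background_means_ = {
            n: float(np.mean(bg_cols[n]))
            for n in names
            if n not in self.expander_.categorical_names_
        }
        self.background_modes_ = {}
        for n in self.expander_.categorical_names_:
            vals, counts = np.unique(np.round(bg_cols[n]).astype(int), return_counts=True)
            self.background_modes_[n] = int(vals[np.argmax(counts)])
        self.n_presence_ = m
        self.n_background_ = len(bg_idx)
        return self

    # -- prediction ---------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "lambdas_"):
            raise RuntimeError("model is not fitted")

    def predict_raw(self, X) -> np.ndarray:
        """Raw Gibbs output exp(lambda . f(x)) / Z.

        Over the training background these values sum to 1.
        """
        self._check_fitted()
        F = self.expander_.transform(X)
        return np.exp(F @ self.lambdas_ - self.log_Z_)

    def predict_logistic(self, X) -> np.ndarray:
        """Logistic suitability c*q/(1+c*q) with c = exp(H), in (0, 1).

        Anchored so a cell of "typical" raw probability exp(−H) scores 0.5.
        """
        q = self.predict_raw(X)
        c = np.exp(self.entropy_)
        return c * q / (1.0 + c * q)

    # sklearn-friendly alias: the model's headline output is the suitability
    predict = predict_logistic

    # -- interpretation -----------------------------------------------------

    def response_curve(self, variable: str, n_points: int = 100):
        """Suitability as one predictor sweeps its training range.

        All other continuous predictors are held at their background mean,
        categorical ones at their background modal class. Returns
        ``(grid_values, logistic_suitability)``.
        """
        self._check_fitted()
        if variable not in self.feature_names_in_:
            raise KeyError(f"unknown variable {variable!r}")
        if variable in self.expander_.categorical_names_:
            lo, hi = self.expander_.bounds_[variable]
            grid = np.arange(int(round(lo)), int(round(hi)) + 1)
        else:
            lo, hi = self.expander_.bounds_[variable]
            grid = np.linspace(lo, hi, n_points)
        data = {}
        for n in self.feature_names_in_:
            if n == variable:
                data[n] = grid.astype(float)
            elif n in self.expander_.categorical_names_:
                data[n] = np.full(len(grid), self.background_modes_[n], dtype=float)
            else:
                data[n] = np.full(len(grid), self.background_means_[n])
        Xs = pd.DataFrame(data, columns=self.feature_names_in_)
        return grid, self.predict_logistic(Xs)

    def nonzero_count(self) -> int:
        """Number of features with nonzero fitted weight (the AICc k)."""
        self._check_fitted()
        return int(np.count_nonzero(self.lambdas_))

    # -- serialization ------------------------------------------------------

    def to_lambdas_text(self) -> str:
        """Serialize the fitted model as a plain-text lambdas file."""
        self._check_fitted()
        lines = [
            "# maxsdm lambdas file",
            f"logZ {self.log_Z_!r}",
            f"entropy {self.entropy_!r}",
            f"reg_multiplier {self.reg_multiplier!r}",
            f"feature_classes {','.join(self.feature_classes)}",
        ]
        for d, lam in zip(self.feature_definitions_, self.lambdas_):
            bounds = ";".join(f"{lo!r}:{hi!r}" for lo, hi in d.bounds)
            lines.append(f"{d.name}\t{lam!r}\t{bounds}")
        return "\n".join(lines) + "\n"
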