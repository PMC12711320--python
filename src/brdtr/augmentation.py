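"""Doubly-robust augmentation of the stage weights.

Plain outcome-weighted learning at stage t gives weight
``(sum of future rewards) * prod of future agreement-indicators / propensities``
to each subject, so anyone whose later observed treatments disagree with the
already-fitted later rules is zeroed out.  Augmentation restores those
subjects by predicting their forgone future reward with regression models:
the augmented Q-value ``Qhat_{t+1}`` combines the IPW term with correction
terms built from linear regressions ``mu_{t,j}`` (fitted by weighted least
squares) and the stage weight becomes ``|Y_t + Qhat_{t+1} - mu_t(H_t)|``,
with the treatment sign flipped when the residual is negative, which changes
the hinge objective only by an additive constant.  Misspecifying the
regressions costs efficiency but not consistency (double robustness).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class LinearModel:
    """OLS/WLS fit ``y ~ 1 + H``; ``coef[0]`` is the intercept."""

    coef: np.ndarray

    def predict(self, H) -> np.ndarray:
        H = np.atleast_2d(np.asarray(H, dtype=float))
        return self.coef[0] + H @ self.coef[1:]

    def to_json(self) -> list:
        return np.asarray(self.coef, dtype=float).tolist()


def _lstsq(X: np.ndarray, y: np.ndarray, w: np.ndarray | None = None) -> LinearModel:
    design = np.column_stack([np.ones(len(X)), X])
    if w is not None:
        sw = np.sqrt(w)
        design = design * sw[:, None]
        y = y * sw
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        logger.info("rank-deficient nuisance design (rank %d < %d); minimum-norm fit", rank, design.shape[1])
    return LinearModel(coef=coef)


@dataclass
class NuisanceModels:
    """Main-effect models ``mu_t`` and future-reward models ``mu_{t,j}``."""

    mu_t: dict = field(default_factory=dict)  # t -> LinearModel on H_t
    mu_tj: dict = field(default_factory=dict)  # (t, j) -> LinearModel on H_j


@dataclass
class AugmentedStage:
    """Nonnegative pseudo-weights, pseudo-treatments and the Q-values behind them."""

    W: np.ndarray
    A_hat: np.ndarray
    Q_next: np.ndarray


def _agreement(data, fitted: dict, s: int) -> np.ndarray:
    """Indicator that the observed stage-s treatment matches the fitted rule."""
    f = fitted.get(s)
    if f is None:
        raise ValueError(f"no fitted decision function for stage {s}")
    return (data.A[s] * f.predict(data.H[s]) > 0).astype(float)


def fit_mu_t(data, Q_next: np.ndarray, t: int) -> LinearModel:
    """Least squares of ``Y_t + Qhat_{t+1}`` on ``(1, H_t)`` over all subjects."""
    return _lstsq(data.H[t], data.Y[t] + np.asarray(Q_next, dtype=float))


def fit_mu_tj(data, fitted: dict, t: int, j: int) -> LinearModel:
    """Weighted least squares for the future-reward model ``mu_{t,j}``.

    Response is the cumulative reward from stage t on, regressed on ``H_j``
    with weights built from agreement indicators of the *later* stages
    (s = t+1..T; the stage-t rule is not yet fitted in the backward loop) and
    the propensity products of stages t..T and t..j.  Zero-weight subjects
    drop out of the fit.
    """
    T = data.T
    if not (1 <= t <= j <= T):
        raise ValueError(f"need 1 <= t <= j <= T, got t={t}, j={j}")
    n = data.n
    ind = np.ones(n)
    for s in range(t + 1, T + 1):
        ind *= _agreement(data, fitted, s)
    p_all = np.ones(n)
    for s in range(t, T + 1):
        p_all *= data.P[s]
    p_tj = np.ones(n)
    for s in range(t, j + 1):
        p_tj *= data.P[s]
    wls_w = ind / p_all * (1.0 - data.P[j]) / p_tj
    y = np.sum([data.Y[s] for s in range(t, T + 1)], axis=0)
    keep = wls_w > 0
    if not np.any(keep):
        raise ValueError(
            f"all weights vanish fitting mu_({t},{j}); too few subjects follow the "
            "fitted later-stage rules -- a larger sample is needed"
        )
    return _lstsq(data.H[j][keep], y[keep], wls_w[keep])


def fit_nuisance_for_stage(data, fitted: dict, t: int) -> NuisanceModels:
    """All ``mu_{t+1, j}`` models needed by ``augmented_q`` at stage t."""
    nuis = NuisanceModels()
    for j in range(t + 1, data.T + 1):
        nuis.mu_tj[(t + 1, j)] = fit_mu_tj(data, fitted, t + 1, j)
    return nuis


def augmented_q(data, fitted: dict, nuis: NuisanceModels, t: int) -> np.ndarray:
    """Augmented Q-values ``Qhat_{i,t+1}`` (zero at the final stage).

    IPW cumulative-future-reward term minus regression corrections, one per
    later stage j, each scaled by the centered agreement weight
    ``I(A_j fhat_j > 0)/p_j - 1`` and the agreement products of the stages in
    between.  Empty products are 1.
    """
    T = data.T
    n = data.n
    if t >= T:
        return np.zeros(n)
    ipw = np.ones(n)
    total_y = np.zeros(n)
    for s in range(t + 1, T + 1):
        total_y += data.Y[s]
        ipw *= _agreement(data, fitted, s) / data.P[s]
    q = total_y * ipw
    prefix = np.ones(n)  # prod over s = t+1..j-1 of I_s / p_s
    for j in range(t + 1, T + 1):
        model = nuis.mu_tj.get((t + 1, j))
        if model is None:
            raise ValueError(f"missing nuisance model mu_({t + 1},{j})")
        centered = _agreement(data, fitted, j) / data.P[j] - 1.0
        q -= prefix * centered * model.predict(data.H[j])
        prefix = prefix * _agreement(data, fitted, j) / data.P[j]
    return q


def build_augmented_stage(data, fitted: dict, nuis: NuisanceModels, t: int) -> AugmentedStage:
    """Pseudo-weights and pseudo-treatments for the stage-t fit.

    ``W_i = |Y_t + Qhat_{t+1} - mu_t(H_t)|`` and the treatment sign flips
    with the residual (``sign(0) := +1``).  Risk and propensity are used
    downstream with the *original* treatments; augmentation only touches the
    benefit term.
    """
    Q_next = augmented_q(data, fitted, nuis, t)
    mu = nuis.mu_t.get(t)
    if mu is None:
        mu = fit_mu_t(data, Q_next, t)
        nuis.mu_t[t] = mu
    resid = data.Y[t] + Q_next - mu.predict(data.H[t])
    signs = np.where(resid >= 0, 1.0, -1.0)
    return AugmentedStage(W=np.abs(resid), A_hat=data.A[t] * signs, Q_next=Q_next)
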