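"""Synthetic two-stage trials for verifying the benefit-risk learner.

Both built-in settings draw an 8-dimensional baseline covariate vector
``X ~ U[0,1]^8`` and randomize two binary treatments with probability 1/2.
Setting I has rewards and risks linear in the evolving history, with the
stage-2 reward depending on the realized stage-1 reward and treatment
(a delayed treatment effect).  Setting II makes the stage-2 reward a
quadratic function of ``(X1, X2)`` -- the optimal stage-2 boundary is a
circle -- and concentrates the stage-2 risk entirely on the stage-1
treatment arm.  Reward noise is standard normal, risk noise uniform on
[-0.5, 0.5].

A fixed seed fully determines the draw; covariate and noise streams are
separate from the treatment stream, so generating the same population under
a policy instead of randomization reuses identical covariates and noises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .backward import TrialData

_D_BASELINE = 8


@dataclass(frozen=True)
class SimulationSpec:
    """Which built-in setting to draw, the sample size and the seed."""

    setting: str  # "I" or "II"
    n: int
    seed: int = 0
    randomize_p: float = 0.5

    def __post_init__(self):
        s = str(self.setting).upper()
        if s in ("1", "I"):
            object.__setattr__(self, "setting", "I")
        elif s in ("2", "II"):
            object.__setattr__(self, "setting", "II")
        else:
            raise ValueError(f"unknown setting {self.setting!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0 < self.randomize_p < 1):
            raise ValueError("randomize_p must lie in (0, 1)")


class OraclePolicy:
    """Adapter turning plain callables ``h -> f(h)`` into a two-stage policy."""

    def __init__(self, *fs):
        self._fs = fs

    def recommend(self, t: int, H) -> np.ndarray:
        vals = np.asarray(self._fs[t - 1](np.atleast_2d(np.asarray(H, dtype=float))))
        return np.where(vals >= 0, 1.0, -1.0)


def constant_policy(a1: float, a2: float) -> OraclePolicy:
    return OraclePolicy(
        lambda H: np.full(len(H), float(a1)), lambda H: np.full(len(H), float(a2))
    )


def _streams(spec: SimulationSpec):
    children = np.random.SeedSequence(spec.seed).spawn(6)
    return [np.random.default_rng(c) for c in children]


def _generate(spec: SimulationSpec, policy=None) -> TrialData:
    rng_x, rng_ey1, rng_er1, rng_ey2, rng_er2, rng_a = _streams(spec)
    n = spec.n
    X = rng_x.uniform(0.0, 1.0, size=(n, _D_BASELINE))
    ey1 = rng_ey1.standard_normal(n)
    er1 = rng_er1.uniform(-0.5, 0.5, n)
    ey2 = rng_ey2.standard_normal(n)
    er2 = rng_er2.uniform(-0.5, 0.5, n)
    p = spec.randomize_p
    x1, x2 = X[:, 0], X[:, 1]

    if policy is None:
        A1 = np.where(rng_a.uniform(size=n) < p, 1.0, -1.0)
    else:
        A1 = np.asarray(policy.recommend(1, X), dtype=float)

    if spec.setting == "I":
        Y1 = 1.0 - x1 + A1 * (-x1 - x2 + 1.0) + ey1
        R1 = 2.0 + x1 + A1 * (-x1 / 2.0 + x2 + 1.0) + er1
    else:
        Y1 = 1.0 + A1 * (-x1 - x2 / 3.0 + 1.2) + ey1
        R1 = 1.5 + A1 * (-x1 / 3.0 + 1.5) + er1

    H2 = np.column_stack([X, A1, Y1, R1])
    if policy is None:
        A2 = np.where(rng_a.uniform(size=n) < p, 1.0, -1.0)
    else:
        A2 = np.asarray(policy.recommend(2, H2), dtype=float)

    if spec.setting == "I":
        Y2 = 1.0 - x1 + A2 * (Y1 - 3.0 * x1 + A1 + 1.0) + ey2
        # the printed stage-2 risk depends on the realized stage-2 reward
        R2 = 1.0 + x1 + A2 * (Y2 / 2.0 - x1 + A2 / 2.0 + 1.0) + er2
    else:
        Y2 = 1.0 + A2 * (-(x1**2) / 2.0 - (x2**2) / 2.0 + 3.0 * A1 / 2.0 + 1.5) + ey2
        R2 = 1.0 + A2 * (2.0 * A1 + 2.0) + er2

    if policy is None:
        P = {1: np.full(n, p), 2: np.full(n, p)}
    else:  # deterministic assignments: no meaningful propensity to record
        P = {1: None, 2: None}
    return TrialData(
        H={1: X, 2: H2},
        A={1: A1, 2: A2},
        Y={1: Y1, 2: Y2},
        R={1: R1, 2: R2},
        P=P,
    )


def simulate_setting1(spec: SimulationSpec) -> TrialData:
    """Randomized draw from setting I (all outcomes linear in history)."""
    if spec.setting != "I":
        raise ValueError("spec.setting must be 'I'")
    return _generate(spec)


def simulate_setting2(spec: SimulationSpec) -> TrialData:
    """Randomized draw from setting II (circular stage-2 benefit boundary)."""
    if spec.setting != "II":
        raise ValueError("spec.setting must be 'II'")
    return _generate(spec)


def simulate(spec: SimulationSpec) -> TrialData:
    return _generate(spec)


def apply_policy_generate(spec: SimulationSpec, policy) -> TrialData:
    """Generate the same population but assign treatments by ``policy``.

    Covariate and noise streams match the randomized draw with the same
    seed; only the treatment assignments (and everything downstream of
    them) differ.  Recorded propensities are 1 (treatments are
    deterministic given history).
    """
    return _generate(spec, policy=policy)


# -- closed-form conditional means of the generative models -----------------

def _delta_r1(spec: SimulationSpec, X: np.ndarray) -> np.ndarray:
    x1, x2 = X[:, 0], X[:, 1]
    if spec.setting == "I":
        return 2.0 * (-x1 / 2.0 + x2 + 1.0)
    return 2.0 * (-x1 / 3.0 + 1.5)


def _mean_r1(spec: SimulationSpec, X: np.ndarray, a) -> np.ndarray:
    x1, x2 = X[:, 0], X[:, 1]
    if spec.setting == "I":
        return 2.0 + x1 + a * (-x1 / 2.0 + x2 + 1.0)
    return 1.5 + a * (-x1 / 3.0 + 1.5)


def _delta_q1(spec: SimulationSpec, X: np.ndarray, rng, n_noise: int = 64) -> np.ndarray:
    """Monte-Carlo treatment effect on stage-1 reward plus optimally-continued
    stage-2 reward; stage-1 reward noise propagates into stage 2 in setting I."""
    x1, x2 = X[:, 0], X[:, 1]
    out = np.zeros((2, len(X)))
    for k, a1 in enumerate((-1.0, 1.0)):
        if spec.setting == "II":
            m_y1 = 1.0 + a1 * (-x1 - x2 / 3.0 + 1.2)
            d2 = -(x1**2) / 2.0 - (x2**2) / 2.0 + 3.0 * a1 / 2.0 + 1.5
            out[k] = m_y1 + 1.0 + np.abs(d2)
        else:
            acc = np.zeros(len(X))
            for _ in range(n_noise):
                y1 = 1.0 - x1 + a1 * (-x1 - x2 + 1.0) + rng.standard_normal(len(X))
                d2 = y1 - 3.0 * x1 + a1 + 1.0
                acc += y1 + 1.0 - x1 + np.abs(d2)
            out[k] = acc / n_noise
    return out[1] - out[0]


def feasible_tau_range(
    spec: SimulationSpec, stage: int, n_mc: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo bounds on the achievable stage risk.

    ``tau_min`` is the population risk of the risk-minimizing rule
    ``sign(-delta_R)`` and ``tau_max`` that of the reward-maximizing rule
    ``sign(delta_Q)``; a budget strictly between them is required for the
    constrained problem to be both feasible and binding.  Uses the known
    treatment-effect terms of the generative equations.  Warns when the risk
    effect is degenerate (``delta_R = 0`` with positive probability).
    """
    if stage not in (1, 2):
        raise ValueError("stage must be 1 or 2")
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, size=(n_mc, _D_BASELINE))
    x1 = X[:, 0]

    if stage == 1:
        d_r = _delta_r1(spec, X)
        rule_min = np.where(-d_r >= 0, 1.0, -1.0)
        tau_min = float(np.mean(_mean_r1(spec, X, rule_min)))
        d_q = _delta_q1(spec, X, rng)
        rule_max = np.where(d_q >= 0, 1.0, -1.0)
        tau_max = float(np.mean(_mean_r1(spec, X, rule_max)))
        if np.mean(d_r == 0) > 0:
            warnings.warn("stage-1 risk effect is degenerate on part of the support")
        return tau_min, tau_max

    # stage 2: risks under the behavior distribution of (X, A1, Y1)
    a1 = np.where(rng.uniform(size=n_mc) < spec.randomize_p, 1.0, -1.0)
    if spec.setting == "II":
        d_r = 2.0 * (2.0 * a1 + 2.0)
        d_q = 2.0 * (-(x1**2) / 2.0 - (X[:, 1] ** 2) / 2.0 + 3.0 * a1 / 2.0 + 1.5)

        def mean_r2(a):
            return 1.0 + a * (2.0 * a1 + 2.0)

    else:
        y1 = 1.0 - x1 + a1 * (-x1 - X[:, 1] + 1.0) + rng.standard_normal(n_mc)
        base = y1 - 3.0 * x1 + a1 + 1.0

        def mean_y2(a):
            return 1.0 - x1 + a * base

        def mean_r2(a):
            return 1.0 + x1 + a * (mean_y2(a) / 2.0 - x1 + a / 2.0 + 1.0)

        d_r = mean_r2(1.0) - mean_r2(-1.0)
        d_q = mean_y2(1.0) - mean_y2(-1.0)

    if np.mean(d_r == 0) > 0:
        warnings.warn(
            "stage-2 risk effect is degenerate (delta_R = 0) on part of the support; "
            "the constraint does not bind there and the range is only indicative"
        )
    rule_min = np.where(-d_r >= 0, 1.0, -1.0)
    rule_max = np.where(d_q >= 0, 1.0, -1.0)
    tau_min = float(np.mean(mean_r2(rule_min)))
    tau_max = float(np.mean(mean_r2(rule_max)))
    return tau_min, tau_max
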