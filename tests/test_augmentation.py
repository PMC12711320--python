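"""Doubly-robust augmentation: Q-values, nuisance fits, weight construction."""

import numpy as np
import pytest

from brdtr import (
    DecisionFunction,
    KernelSpec,
    StageTransform,
    TrialData,
    augmented_q,
    build_augmented_stage,
    fit_mu_t,
    fit_mu_tj,
)
from brdtr.augmentation import LinearModel, NuisanceModels, fit_nuisance_for_stage
from brdtr.surrogates import hinge


def _linear_rule(w, b=0.0):
    w = np.atleast_1d(np.asarray(w, dtype=float))
    return DecisionFunction(
        kernel=KernelSpec("linear"), support_points=w[None, :], alpha=np.ones(1), intercept=b
    )


def _random_trial(seed, n=40, T=3, d=2):
    rng = np.random.default_rng(seed)
    H, A, Y, R, P = {}, {}, {}, {}, {}
    for t in range(1, T + 1):
        H[t] = rng.normal(size=(n, d + t - 1))
        A[t] = rng.choice([-1.0, 1.0], n)
        Y[t] = rng.normal(size=n)
        R[t] = rng.uniform(0.1, 1.0, n)
        P[t] = rng.uniform(0.3, 0.7, n)
    return TrialData(H=H, A=A, Y=Y, R=R, P=P)


def test_augmented_q_zero_at_last_stage():
    data = _random_trial(0, T=2)
    q = augmented_q(data, {}, NuisanceModels(), 2)
    assert np.allclose(q, 0.0)


def test_augmented_q_two_stage_plugin():
    """T=2: follower gets 2*Y2 - mu_22(H2); non-follower gets +mu_22(H2)."""
    data = _random_trial(1, T=2)
    data.P[2][:] = 0.5
    f2 = _linear_rule(np.ones(data.H[2].shape[1]))
    nuis = NuisanceModels(mu_tj={(2, 2): LinearModel(coef=np.zeros(data.H[2].shape[1] + 1))})
    nuis.mu_tj[(2, 2)].coef[0] = 1.7  # constant prediction
    q = augmented_q(data, {2: f2}, nuis, 1)
    follows = data.A[2] * f2.predict(data.H[2]) > 0
    expected = np.where(follows, 2.0 * data.Y[2] - 1.7, 1.7)
    assert np.allclose(q, expected)


def test_augmented_q_matches_literal_loop_oracle():
    """T=3: vectorized Q-values equal a direct transcription double loop."""
    data = _random_trial(2, T=3)
    fitted = {
        2: _linear_rule(np.ones(data.H[2].shape[1]), 0.1),
        3: _linear_rule(-np.ones(data.H[3].shape[1]), -0.2),
    }
    nuis = fit_nuisance_for_stage(data, fitted, 1)
    q = augmented_q(data, fitted, nuis, 1)

    n, T, t = data.n, 3, 1
    expected = np.zeros(n)
    for i in range(n):
        ind = {
            ss: float(data.A[ss][i] * fitted[ss].predict(data.H[ss][i : i + 1])[0] > 0)
            for ss in (2, 3)
        }
        prod = 1.0
        ysum = 0.0
        for ss in range(t + 1, T + 1):
            ysum += data.Y[ss][i]
            prod *= ind[ss] / data.P[ss][i]
        val = ysum * prod
        for j in range(t + 1, T + 1):
            prefix = 1.0
            for ss in range(t + 1, j):
                prefix *= ind[ss] / data.P[ss][i]
            bracket = ind[j] / data.P[j][i] - 1.0
            mu = nuis.mu_tj[(t + 1, j)].predict(data.H[j][i : i + 1])[0]
            val -= prefix * bracket * mu
        expected[i] = val
    assert np.allclose(q, expected, atol=1e-12)


def test_fit_mu_t_ols_properties():
    data = _random_trial(3, T=2)
    # constant target -> intercept-only fit
    data.Y[1][:] = 2.5
    model = fit_mu_t(data, np.zeros(data.n), 1)
    assert np.allclose(model.predict(data.H[1]), 2.5, atol=1e-10)
    # exact linear target recovered to numerical precision
    beta = np.array([0.5, -1.0])
    data.Y[1] = data.H[1] @ beta + 3.0
    model = fit_mu_t(data, np.zeros(data.n), 1)
    assert np.max(np.abs(model.predict(data.H[1]) - data.Y[1])) < 1e-10
    # random targets match the normal-equations solution
    rng = np.random.default_rng(4)
    data.Y[1] = rng.normal(size=data.n)
    model = fit_mu_t(data, np.zeros(data.n), 1)
    X = np.column_stack([np.ones(data.n), data.H[1]])
    coef = np.linalg.solve(X.T @ X, X.T @ data.Y[1])
    assert np.allclose(model.coef, coef, atol=1e-8)


def test_fit_mu_tj_reduces_to_plain_ols_when_weights_equal():
    data = _random_trial(5, T=2)
    for t in (1, 2):
        data.P[t][:] = 0.5
    f2 = _linear_rule(np.zeros(data.H[2].shape[1]), 1.0)  # always agree-with +1?
    data.A[2][:] = 1.0  # all observed +1, rule constant +1 -> indicators all 1
    model = fit_mu_tj(data, {2: f2}, 1, 2)
    y = data.Y[1] + data.Y[2]
    X = np.column_stack([np.ones(data.n), data.H[2]])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    assert np.allclose(model.coef, coef, atol=1e-8)


def test_fit_mu_tj_matches_weighted_normal_equations():
    data = _random_trial(6, T=2)
    f2 = _linear_rule(np.ones(data.H[2].shape[1]), -0.3)
    model = fit_mu_tj(data, {2: f2}, 1, 2)
    ind = (data.A[2] * f2.predict(data.H[2]) > 0).astype(float)
    w = ind / (data.P[1] * data.P[2]) * (1 - data.P[2]) / (data.P[1] * data.P[2])
    y = data.Y[1] + data.Y[2]
    keep = w > 0
    X = np.column_stack([np.ones(data.n), data.H[2]])[keep]
    Wm = np.diag(w[keep])
    coef = np.linalg.solve(X.T @ Wm @ X, X.T @ Wm @ y[keep])
    assert np.allclose(model.coef, coef, atol=1e-7)


def test_fit_mu_tj_all_zero_weights_errors():
    data = _random_trial(7, T=2)
    f2 = _linear_rule(np.zeros(data.H[2].shape[1]), 1.0)  # rule constant +1
    data.A[2][:] = -1.0  # nobody follows
    with pytest.raises(ValueError, match="larger sample"):
        fit_mu_tj(data, {2: f2}, 1, 2)


def test_build_augmented_stage_signs_and_weights():
    data = _random_trial(8, T=2)
    nuis = NuisanceModels(mu_t={1: LinearModel(coef=np.zeros(data.H[1].shape[1] + 1))})
    nuis.mu_tj[(2, 2)] = LinearModel(coef=np.zeros(data.H[2].shape[1] + 1))
    f2 = _linear_rule(np.ones(data.H[2].shape[1]))
    stage = build_augmented_stage(data, {2: f2}, nuis, 1)
    resid = data.Y[1] + augmented_q(data, {2: f2}, nuis, 1)
    assert np.allclose(stage.W, np.abs(resid))
    assert np.allclose(stage.A_hat, data.A[1] * np.where(resid >= 0, 1.0, -1.0))


def test_flip_consistency_up_to_constant():
    """The flipped-weight hinge objective differs from the signed construction
    by a constant independent of f."""
    data = _random_trial(9, T=2)
    nuis = fit_nuisance_for_stage(data, {2: _linear_rule(np.ones(data.H[2].shape[1]))}, 1)
    stage = build_augmented_stage(data, {2: _linear_rule(np.ones(data.H[2].shape[1]))}, nuis, 1)
    resid = data.Y[1] + stage.Q_next - nuis.mu_t[1].predict(data.H[1])
    rng = np.random.default_rng(10)
    diffs = []
    # the identity is exact on the hinge's linear region |f| <= 1
    for _ in range(6):
        fvals = rng.uniform(-1.0, 1.0, size=data.n)
        flipped = np.mean(stage.W / data.P[1] * hinge(stage.A_hat * fvals))
        signed = np.mean(resid / data.P[1] * hinge(data.A[1] * fvals))
        diffs.append(flipped - signed)
    assert np.std(diffs) < 1e-12


def test_double_robustness_smoke_zero_nuisance_recovers_ipw():
    """With all regressions zeroed, Qhat is the plain IPW future reward."""
    data = _random_trial(11, T=2)
    f2 = _linear_rule(np.ones(data.H[2].shape[1]))
    nuis = NuisanceModels(mu_tj={(2, 2): LinearModel(coef=np.zeros(data.H[2].shape[1] + 1))})
    q = augmented_q(data, {2: f2}, nuis, 1)
    ind = (data.A[2] * f2.predict(data.H[2]) > 0).astype(float)
    assert np.allclose(q, data.Y[2] * ind / data.P[2])
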