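"""DC solver for the constrained stage problem: descent, feasibility, CV."""

import numpy as np
import pytest
from dataclasses import replace

from brdtr import (
    DecisionFunction,
    KernelSpec,
    SolverConfig,
    StageSample,
    cross_validate_cost,
    dc_solve,
    empirical_objective,
    empirical_surrogate_risk,
    empirical_zero_one_risk,
    qp_subproblem,
)
from brdtr.solver import full_cost_grid, reduced_cost_grid

from conftest import random_stage_sample


GAUSS = KernelSpec("gaussian", 0.5)


def _cfg(**kw):
    base = dict(kernel=GAUSS, cost=1.0, eta=0.05, tau=np.inf)
    base.update(kw)
    return SolverConfig(**base)


# -- empirical functionals against loop oracles -----------------------------

def test_empirical_risk_by_hand():
    s = StageSample(
        H=[[0.0], [1.0]], A=[1.0, -1.0], W=[1.0, 1.0], R=[1.0, 1.0], P=[0.5, 0.5]
    )
    f = DecisionFunction.constant(1.0, 1)
    # psi(+1)=1 for the first subject, psi(-1)=0 for the second
    assert empirical_surrogate_risk(f, s, 0.1) == pytest.approx(1.0)
    f0 = DecisionFunction.constant(0.0, 1)
    assert empirical_surrogate_risk(f0, s, 0.1) == pytest.approx(np.mean(s.R / s.P))


@pytest.mark.parametrize("seed", range(3))
def test_empirical_functionals_match_loop_oracle(seed):
    s = random_stage_sample(seed, n=10)
    rng = np.random.default_rng(seed)
    f = DecisionFunction(
        kernel=GAUSS, support_points=s.H, alpha=rng.normal(size=len(s)), intercept=0.3
    )
    cfg = _cfg()
    eta = 0.07
    risk = obj = 0.0
    from brdtr.kernels import kernel_matrix

    K = kernel_matrix(s.H, s.H, GAUSS)
    for i in range(len(s)):
        fi = float(K[i] @ f.alpha + 0.3)
        x = s.A[i] * fi
        psi = min(max((x + eta) / eta, 0.0), 1.0)
        risk += s.R[i] * psi / s.P[i]
        obj += s.W[i] / s.P[i] * max(1.0 - s.A_hat[i] * fi, 0.0)
    risk /= len(s)
    obj = obj / len(s) + cfg.lam(len(s)) * float(f.alpha @ (K @ f.alpha))
    assert empirical_surrogate_risk(f, s, eta) == pytest.approx(risk, abs=1e-12)
    assert empirical_objective(f, s, cfg) == pytest.approx(obj, abs=1e-12)


def test_zero_weight_objective_is_penalty_only():
    s = random_stage_sample(5, n=10)
    s.W[:] = 0.0
    f = qp_subproblem(s, _cfg())
    assert np.allclose(f.alpha, 0.0)
    assert empirical_objective(f, s, _cfg()) == pytest.approx(0.0, abs=1e-10)


# -- constrained solve behaviour --------------------------------------------

def test_risk_concentrated_point_forced_out(fixtures):
    """tau below one point's risk share forces its margin below -eta."""
    rng = np.random.default_rng(0)
    n = 5
    H = rng.uniform(-1, 1, (n, 1))
    A = np.array([1.0, -1.0, 1.0, -1.0, -1.0])
    R = np.array([10.0, 0.01, 0.01, 0.01, 0.01])
    s = StageSample(H=H, A=A, W=np.ones(n), R=R, P=np.full(n, 0.5))
    heavy_share = R[0] / s.P[0] / n  # 4.0
    cfg = _cfg(kernel=KernelSpec("gaussian", 1.0), tau=heavy_share / 2, eta=0.1, cost=4.0)
    res = dc_solve(s, cfg)
    assert res.feasible
    margin0 = s.A[0] * res.f.predict(s.H)[0]
    assert margin0 <= -cfg.eta + 1e-6


def test_tau_infinite_is_single_qp():
    s = random_stage_sample(3, n=15)
    res = dc_solve(s, _cfg())
    assert res.n_iter == 1
    direct = qp_subproblem(s, _cfg())
    assert np.allclose(res.f.alpha, direct.alpha, atol=1e-9)


def test_already_feasible_unconstrained_start_stops_immediately():
    s = random_stage_sample(4, n=15)
    uncon = dc_solve(s, _cfg())
    slack_tau = empirical_surrogate_risk(uncon.f, s, 0.05) + 0.5
    res = dc_solve(s, _cfg(tau=slack_tau))
    assert res.n_iter == 1
    assert np.allclose(res.f.alpha, uncon.f.alpha, atol=1e-9)


def test_constrained_matches_threshold_bruteforce():
    """1-D two-cluster sample: fitted signs match exhaustive threshold search."""
    rng = np.random.default_rng(2)
    n = 24
    h = np.concatenate([rng.uniform(-1, -0.3, n // 2), rng.uniform(0.3, 1, n // 2)])[:, None]
    A = np.where(h[:, 0] > 0, 1.0, -1.0)
    W = np.where(h[:, 0] > 0, 2.0, 1.0) + rng.uniform(0, 0.2, n)
    R = np.where(A == 1.0, 1.6, 0.1)
    s = StageSample(H=h, A=A, W=W, R=R, P=np.full(n, 0.5))
    tau = 1.0  # between the per-arm risk levels
    cfg = _cfg(kernel=KernelSpec("linear"), tau=tau, eta=0.05, cost=16.0)
    res = dc_solve(s, cfg)
    fitted_signs = np.where(res.f.predict(s.H) >= 0, 1.0, -1.0)

    # brute force over all threshold rules sign(+-(h - t)), maximizing the
    # weighted 0-1 value subject to the 0-1 risk budget
    best_val, best_signs = -np.inf, None
    cuts = np.concatenate([[-2.0], np.sort(h[:, 0]) + 1e-9, [2.0]])
    for direction in (1.0, -1.0):
        for t in cuts:
            signs = np.where(direction * (h[:, 0] - t) >= 0, 1.0, -1.0)
            risk = np.mean(s.R * (s.A * signs > 0) / s.P)
            if risk > tau:
                continue
            val = np.mean(s.W * (s.A_hat * signs > 0) / s.P)
            if val > best_val:
                best_val, best_signs = val, signs
    assert best_signs is not None
    assert np.array_equal(fitted_signs, best_signs)


@pytest.mark.parametrize("seed", range(20))
def test_dc_descent_and_conservative_feasibility(seed):
    """Objective path nonincreasing; ramp risk <= tau; 0-1 risk <= ramp risk."""
    s = random_stage_sample(seed, d=3)
    tau = float(np.random.default_rng(seed).uniform(0.3, 1.5))
    cfg = _cfg(tau=tau, cost=float(np.random.default_rng(seed + 1).choice([0.25, 1, 4])))
    res = dc_solve(s, cfg)
    path = res.objective_path
    assert all(path[i + 1] <= path[i] + cfg.dc_tol for i in range(len(path) - 1))
    if res.feasible:
        assert res.train_risk <= tau + cfg.qp_tol
    assert empirical_zero_one_risk(res.f, s) <= res.train_risk + 1e-9


def test_infeasible_budget_returns_least_risk_rule():
    """A budget below the attainable minimum yields the risk-minimizing rule,
    flagged infeasible, with the attainable level reported."""
    rng = np.random.default_rng(9)
    n = 20
    # same features in both arms: no rule can push all risky margins negative
    H = np.tile(rng.uniform(-1, 1, (n // 2, 1)), (2, 1))
    A = np.r_[np.ones(n // 2), -np.ones(n // 2)]
    s = StageSample(H=H, A=A, W=np.ones(n), R=np.full(n, 1.0), P=np.full(n, 0.5))
    cfg = _cfg(kernel=KernelSpec("linear"), tau=0.05, eta=0.05)
    res = dc_solve(s, cfg)
    assert not res.feasible
    assert res.train_risk > cfg.tau
    assert "min_attainable_risk" in res.diagnostics
    assert res.diagnostics["min_attainable_risk"] == pytest.approx(res.train_risk)


def test_tau_ladder_value_monotone():
    """Relaxing the budget never decreases the in-sample weighted value."""
    s = random_stage_sample(12, n=30)
    vals = []
    for tau in (0.4, 0.8, 1.2, 2.0, np.inf):
        res = dc_solve(s, _cfg(tau=tau, cost=2.0))
        signs = np.where(res.f.predict(s.H) >= 0, 1.0, -1.0)
        vals.append(np.mean(s.W * (s.A_hat * signs > 0) / s.P))
    assert all(vals[i + 1] >= vals[i] - 1e-6 for i in range(len(vals) - 1))


def test_scale_equivariance_of_weights_and_penalty():
    """Scaling W by c and lam by c (cost by 1/c) leaves the fitted signs unchanged."""
    s = random_stage_sample(21, n=25)
    cfg = _cfg(tau=1.0, cost=2.0)
    res1 = dc_solve(s, cfg)
    c = 7.0
    s2 = StageSample(H=s.H, A=s.A, W=c * s.W, R=s.R, P=s.P, A_hat=s.A_hat)
    res2 = dc_solve(s2, replace(cfg, cost=cfg.cost / c))
    signs1 = np.sign(res1.f.predict(s.H))
    signs2 = np.sign(res2.f.predict(s.H))
    assert np.mean(signs1 == signs2) == pytest.approx(1.0)


# -- cross-validation --------------------------------------------------------

def test_cv_single_config_returned():
    s = random_stage_sample(30, n=20)
    cfg = _cfg(cost=2.0)
    assert cross_validate_cost(s, [cfg], folds=2) is cfg


def test_cv_prefers_separating_cost():
    """On a separable sample a permissive cost beats a crushing penalty."""
    rng = np.random.default_rng(1)
    n = 50
    h = rng.uniform(-1, 1, (n, 1))
    A = np.where(h[:, 0] >= 0, 1.0, -1.0)
    s = StageSample(H=h, A=A, W=np.ones(n), R=np.full(n, 0.1), P=np.full(n, 0.5))
    grid = [_cfg(kernel=KernelSpec("linear"), cost=c) for c in (1e-8, 4.0)]
    best = cross_validate_cost(s, grid, folds=2, seed=0)
    assert best.cost == 4.0


def test_cv_deterministic_given_seed():
    s = random_stage_sample(31, n=50, d=2)
    grid = [_cfg(tau=1.0, cost=c) for c in (0.25, 1.0, 4.0)]
    picks = {cross_validate_cost(s, grid, folds=2, seed=5).cost for _ in range(3)}
    assert len(picks) == 1


def test_cv_safe_value_screens_held_out_risk():
    """The default criterion never returns a cost whose held-out risk clearly
    explodes when a compliant alternative exists (constructed example)."""
    s = random_stage_sample(33, n=60, d=2)
    s.R[:] = np.random.default_rng(33).uniform(1.0, 3.0, len(s))
    grid = [_cfg(tau=1.0, cost=c) for c in (2.0**-10, 2.0**6)]
    best = cross_validate_cost(s, grid, folds=2, criterion="safe_value", seed=0)
    assert best.cost in (2.0**-10, 2.0**6)  # smoke: selection completes
    with pytest.raises(ValueError):
        cross_validate_cost(s, grid, folds=2, criterion="bogus")


def test_grids():
    assert len(full_cost_grid()) == 21
    assert full_cost_grid()[0] == 2.0**-10 and full_cost_grid()[-1] == 2.0**10
    assert set(reduced_cost_grid()) <= set(full_cost_grid())
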