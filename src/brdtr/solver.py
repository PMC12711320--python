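"""One stage of constrained outcome-weighted learning.

The stage problem is a weighted SVM with an extra smooth risk constraint:

    min_f  (1/n) sum_i (W_i / P_i) phi(Ahat_i f(H_i))  +  lam ||f||^2
    s.t.   (1/n) sum_i (R_i / P_i) psi(A_i f(H_i), eta)  <=  tau,

where ``phi`` is the hinge loss, ``psi`` the shifted ramp loss, ``W`` the
nonnegative (possibly augmented) reward weights with pseudo-treatments
``Ahat``, and ``R`` the stage risks with the *original* treatments ``A``.
Writing ``psi = u - v`` with convex ``u, v``, the constraint is a difference
of convex functions, so the problem is solved by DC iterations: linearize
``v`` at the current iterate and solve the resulting convex QP.  Because the
linearized constraint dominates ``psi``, every DC iterate is feasible for the
ramp constraint, and the hinge objective is nonincreasing along iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._qp import QPError, solve_stage_qp
from .kernels import GRAM_JITTER, KernelSpec, kernel_matrix
from .surrogates import hinge, shifted_ramp


class FeasibilityError(RuntimeError):
    """No rule satisfies the (linearized) risk constraint at this tau.

    Carries ``min_risk``, the minimum attainable linearized risk, so callers
    can report how far the requested budget is from feasibility.
    """

    def __init__(self, tau: float, min_risk: float, detail: str = ""):
        self.tau = tau
        self.min_risk = min_risk
        msg = f"risk budget tau={tau:.6g} is below the minimum attainable risk {min_risk:.6g}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


@dataclass
class StageSample:
    """Per-stage training arrays for one constrained weighted-SVM fit.

    ``A`` are the observed treatments used in the risk constraint; ``A_hat``
    the (possibly sign-flipped) pseudo-treatments used in the hinge term.
    Weights ``W`` must already be nonnegative (flipping applied upstream).
    """

    H: np.ndarray
    A: np.ndarray
    W: np.ndarray
    R: np.ndarray
    P: np.ndarray
    A_hat: np.ndarray | None = None

    def __post_init__(self):
        self.H = np.atleast_2d(np.asarray(self.H, dtype=float))
        self.A = np.asarray(self.A, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if self.A_hat is None:
            self.A_hat = self.A.copy()
        else:
            self.A_hat = np.asarray(self.A_hat, dtype=float)
        n = len(self.A)
        if not all(len(v) == n for v in (self.W, self.R, self.P, self.A_hat)) or self.H.shape[0] != n:
            raise ValueError("StageSample arrays have inconsistent lengths")
        if np.any(self.W < 0):
            raise ValueError("weights W must be nonnegative (sign-flip upstream)")
        if np.any((self.P <= 0) | (self.P >= 1)):
            raise ValueError("propensities must lie strictly in (0, 1)")
        if not np.all(np.isin(self.A, (-1.0, 1.0))) or not np.all(np.isin(self.A_hat, (-1.0, 1.0))):
            raise ValueError("treatments must be coded -1/+1")

    def __len__(self):
        return len(self.A)

    def subset(self, idx) -> "StageSample":
        return StageSample(
            H=self.H[idx], A=self.A[idx], W=self.W[idx], R=self.R[idx],
            P=self.P[idx], A_hat=self.A_hat[idx],
        )


@dataclass(frozen=True)
class SolverConfig:
    """Stage-solver settings.

    ``cost`` is the SVM cost parameter ``C = 1 / (2 n lam)``; the RKHS
    penalty used for a sample of size n is ``lam = 1 / (2 n cost)``.
    ``tau = inf`` disables the risk constraint.
    """

    kernel: KernelSpec
    cost: float = 1.0
    eta: float = 0.02
    tau: float = np.inf
    dc_tol: float = 1e-6
    dc_max_iter: int = 50
    qp_tol: float = 1e-6
    dc_split: str = "progressive"

    def __post_init__(self):
        if self.cost <= 0:
            raise ValueError("cost must be positive")
        if self.dc_max_iter < 1:
            raise ValueError("dc_max_iter must be >= 1")
        if not (0 < self.eta <= 1):
            raise ValueError("eta must lie in (0, 1]")
        if self.dc_split not in ("anchored", "progressive"):
            raise ValueError("dc_split must be 'anchored' or 'progressive'")

    def lam(self, n: int) -> float:
        return 1.0 / (2.0 * n * self.cost)


@dataclass
class DecisionFunction:
    """Kernelized rule ``f(h) = sum_j alpha_j k(support_j, h) + intercept``.

    The recommended treatment is ``sign(f)`` with ``sign(0) := +1``.
    """

    kernel: KernelSpec
    support_points: np.ndarray
    alpha: np.ndarray
    intercept: float

    def __post_init__(self):
        self.support_points = np.atleast_2d(np.asarray(self.support_points, dtype=float))
        self.alpha = np.asarray(self.alpha, dtype=float)

    def predict(self, H) -> np.ndarray:
        H = np.atleast_2d(np.asarray(H, dtype=float))
        K = kernel_matrix(H, self.support_points, self.kernel)
        return K @ self.alpha + self.intercept

    def decide(self, H) -> np.ndarray:
        return np.where(self.predict(H) >= 0.0, 1.0, -1.0)

    def to_json(self) -> dict:
        return {
            "kernel": self.kernel.to_json(),
            "support_points": self.support_points.tolist(),
            "alpha": self.alpha.tolist(),
            "intercept": float(self.intercept),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "DecisionFunction":
        return cls(
            kernel=KernelSpec.from_json(obj["kernel"]),
            support_points=np.asarray(obj["support_points"], dtype=float),
            alpha=np.asarray(obj["alpha"], dtype=float),
            intercept=float(obj["intercept"]),
        )

    @classmethod
    def constant(cls, value: float, d: int, kernel: KernelSpec | None = None) -> "DecisionFunction":
        kern = kernel or KernelSpec("linear")
        return cls(kernel=kern, support_points=np.zeros((1, d)), alpha=np.zeros(1), intercept=value)


@dataclass
class StageFitResult:
    """A fitted stage rule plus DC diagnostics."""

    f: DecisionFunction
    objective_path: list = field(default_factory=list)
    train_risk: float = np.nan
    feasible: bool = False
    n_iter: int = 0
    diagnostics: dict = field(default_factory=dict)


def empirical_surrogate_risk(f: DecisionFunction, s: StageSample, eta: float) -> float:
    """Empirical ramp-surrogate risk ``(1/n) sum R_i psi(A_i f(H_i), eta) / P_i``."""
    margins = s.A * f.predict(s.H)
    return float(np.mean(s.R * shifted_ramp(margins, eta) / s.P))


def empirical_zero_one_risk(f: DecisionFunction, s: StageSample) -> float:
    """Empirical 0-1 risk ``(1/n) sum R_i I(A_i f(H_i) > 0) / P_i``."""
    margins = s.A * f.predict(s.H)
    return float(np.mean(s.R * (margins > 0) / s.P))


def empirical_objective(f: DecisionFunction, s: StageSample, cfg: SolverConfig) -> float:
    """Weighted hinge objective plus RKHS penalty at ``f``.

    The penalty ``lam * alpha' K alpha`` is evaluated on the decision
    function's own support points.
    """
    margins = s.A_hat * f.predict(s.H)
    hinge_part = float(np.mean(s.W / s.P * hinge(margins)))
    K = kernel_matrix(f.support_points, f.support_points, f.kernel)
    lam = cfg.lam(len(s))
    return hinge_part + lam * float(f.alpha @ (K @ f.alpha))


def _training_gram(s: StageSample, kernel: KernelSpec) -> np.ndarray:
    K = kernel_matrix(s.H, s.H, kernel)
    K[np.diag_indices_from(K)] += GRAM_JITTER
    return K


def _feature_map(s: StageSample, kernel: KernelSpec):
    """Explicit feature map for the QP plus the map back to a decision rule.

    A linear kernel is solved in its primal weight space (the fitted rule is
    stored with the weight vector as a single support point); an RKHS solve
    uses ``Phi = Q L^1/2`` from the eigendecomposition of the jittered Gram
    matrix, for which the ridge penalty on the QP coefficients equals the
    RKHS norm and the kernel coefficients are ``alpha = Q L^-1/2 beta``.
    """
    if kernel.family == "linear":
        Phi = s.H

        def to_rule(beta, b):
            return DecisionFunction(
                kernel=kernel, support_points=beta[None, :], alpha=np.ones(1), intercept=b
            )

        return Phi, to_rule

    K = _training_gram(s, kernel)
    evals, Q = np.linalg.eigh(K)
    evals = np.maximum(evals, 0.5 * GRAM_JITTER)
    sqrt_l = np.sqrt(evals)
    Phi = Q * sqrt_l[None, :]
    support = s.H.copy()

    def to_rule(beta, b):
        return DecisionFunction(
            kernel=kernel, support_points=support, alpha=Q @ (beta / sqrt_l), intercept=b
        )

    return Phi, to_rule


def _dc_linearization(s: StageSample, eta: float, f_current: DecisionFunction | None, split: str):
    """Risk-row data for one DC subproblem.

    The weighted ramp risk ``(1/n) sum r_i psi(m_i)`` (margins
    ``m_i = A_i f(H_i)``) admits two difference-of-convex decompositions,
    applied pointwise by the sign of ``r_i`` so that every slack coefficient
    in the QP's risk row stays nonnegative (a negative coefficient would let
    the slack nullify the constraint):

    ``split="progressive"``: ``psi = (m+eta)_+/eta - (m)_+/eta``.  The
    increasing concave part is linearized; a point currently classified to
    its observed treatment costs its full risk regardless of margin size,
    so the subproblem can re-select which points sit on the risky side in a
    single step.

    ``split="anchored"``: ``psi = [1 + (-m-eta)_+/eta] - (-m)_+/eta``.  The
    decreasing concave part is linearized; risk relief is granted only at
    the rate earned at the current margins, so moving a point across the
    boundary costs its full traversed margin (``~|m|/eta`` times its risk)
    and iterates stay close to their initialization.  This is the more
    conservative iteration.

    Both dominate ``psi`` (the linearized concave part lies below the true
    one), so every feasible iterate of either split is ramp-feasible, and
    both are exact at the linearization point, which gives monotone descent.

    ``f_current = None`` requests the most permissive linearization (the
    virtual iterate granting every point its maximal relief); it is
    feasible whenever any ramp-feasible rule of unrestricted magnitude is.

    Returns ``(a_row, zeta_coef, zeta_shift, lin_f, rhs_offset, min_risk)``
    where ``min_risk`` is the infimum of the linearized risk over all
    margin vectors, on the same scale as ``tau``.
    """
    n = len(s)
    r = s.R / s.P
    pos = r >= 0
    absr = np.abs(r)
    zeta_coef = absr / (n * eta)

    if split == "progressive":
        a_row = s.A
        zeta_shift = np.where(pos, eta, 0.0)
        if f_current is None:
            m0 = np.where(pos, -eta, eta)
        else:
            m0 = s.A * f_current.predict(s.H)
        g = np.where(pos, (m0 > 0), (m0 > -eta)) / eta
        c_lin = float(np.sum(absr[~pos] * (m0[~pos] > -eta)) / n)
        lin_f = -(absr * g * s.A) / n
        min_risk = float(np.sum(r[pos & (g > 0)]) / n) - c_lin
        return a_row, zeta_coef, zeta_shift, lin_f, c_lin, min_risk

    # anchored; the maximally permissive linearization coincides with the
    # progressive one and its encoding is better scaled, so use that
    if f_current is None:
        return _dc_linearization(s, eta, None, "progressive")
    a_row = -s.A
    zeta_shift = np.where(pos, -eta, 0.0)
    m0 = s.A * f_current.predict(s.H)
    g = np.where(pos, (m0 < 0), (m0 < -eta)) / eta
    lin_f = (absr * g * s.A) / n
    c_lin = -float(np.sum(r[pos]) / n) + float(np.sum(absr[~pos] * (m0[~pos] >= -eta)) / n)
    min_risk = float(np.sum(r[pos & (g == 0)]) / n) - float(
        np.sum(absr[~pos & (m0 >= -eta)]) / n
    )
    return a_row, zeta_coef, zeta_shift, lin_f, c_lin, min_risk


def qp_subproblem(
    s: StageSample,
    cfg: SolverConfig,
    f_current: DecisionFunction | None = None,
    _fm=None,
    _tighten: float = 0.0,
) -> DecisionFunction:
    """Solve one convex inner QP of the DC iteration.

    With ``cfg.tau = inf`` this is a plain weighted hinge SVM.  Otherwise
    ``f_current`` provides the linearization point for the concave part of
    the ramp constraint (``f_current=None`` means the maximally conservative
    linearization ``g = 0``).  ``_fm`` optionally carries the precomputed
    feature map so DC loops factor the Gram only once.
    """
    if _fm is None:
        _fm = _feature_map(s, cfg.kernel)
    Phi, to_rule = _fm
    lam = cfg.lam(len(s))
    c = s.W / s.P
    if np.isinf(cfg.tau):
        beta, b, info = solve_stage_qp(Phi, s.A_hat, c, lam, tol=min(cfg.qp_tol, 1e-8))
    else:
        tau_eff = cfg.tau - _tighten
        a_row, zeta_coef, zeta_shift, lin_f, c_lin, min_risk = _dc_linearization(
            s, cfg.eta, f_current, cfg.dc_split
        )
        if min_risk > tau_eff + cfg.qp_tol:
            raise FeasibilityError(cfg.tau, min_risk, "linearized subproblem infeasible")
        beta, b, info = solve_stage_qp(
            Phi, s.A_hat, c, lam,
            a=a_row, zeta_coef=zeta_coef, zeta_shift=zeta_shift, lin_f=lin_f,
            rhs_risk=tau_eff + c_lin,
            tol=min(cfg.qp_tol, 1e-8),
        )
    f = to_rule(beta, b)
    f.last_qp_info = info
    return f


def dc_solve(
    s: StageSample, cfg: SolverConfig, f_init: DecisionFunction | None = None
) -> StageFitResult:
    """DC iteration for the constrained stage problem.

    Starts from the unconstrained hinge-SVM solution (or ``f_init``); if that
    rule already satisfies the ramp constraint the iteration stops there.
    Otherwise successive linearized QPs are solved, refreshing the
    subgradients at each iterate, until the hinge objective stabilizes.
    When the first linearized subproblem at the warm start is infeasible
    (its follower risk exceeds tau), the iteration restarts from the most
    permissive linearization; if the budget is unattainable within the
    function class altogether, the phase-1 least-risk rule is returned
    flagged infeasible with the attainable minimum in the diagnostics.
    """
    fm = _feature_map(s, cfg.kernel)
    from_unconstrained = f_init is None
    if f_init is None:
        f_init = qp_subproblem(s, replace(cfg, tau=np.inf), None, _fm=fm)
    obj = empirical_objective(f_init, s, cfg)
    if np.isinf(cfg.tau):
        if not from_unconstrained:
            f_init = qp_subproblem(s, replace(cfg, tau=np.inf), None, _fm=fm)
            obj = empirical_objective(f_init, s, cfg)
        risk = empirical_surrogate_risk(f_init, s, cfg.eta)
        return StageFitResult(
            f=f_init, objective_path=[obj], train_risk=risk, feasible=True, n_iter=1,
            diagnostics=getattr(f_init, "last_qp_info", {}),
        )

    risk = empirical_surrogate_risk(f_init, s, cfg.eta)
    if from_unconstrained and risk <= cfg.tau + cfg.qp_tol:
        # the unconstrained optimum already satisfies the ramp constraint,
        # hence solves the constrained problem: one DC iteration
        return StageFitResult(
            f=f_init, objective_path=[obj], train_risk=risk, feasible=True, n_iter=1,
            diagnostics=getattr(f_init, "last_qp_info", {}),
        )
    risk_init = risk

    def run_dc(cfg_run, f_start):
        """One DC pass; raises FeasibilityError/QPError only on the first QP."""
        try:
            f = qp_subproblem(s, cfg_run, f_start, _fm=fm)
        except (FeasibilityError, QPError):
            # restart from the most permissive linearization; if even that
            # subproblem cannot be solved, the budget is unattainable
            f = qp_subproblem(s, cfg_run, None, _fm=fm)
        path = [empirical_objective(f, s, cfg_run)]
        for _ in range(cfg_run.dc_max_iter - 1):
            try:
                f_next = qp_subproblem(s, cfg_run, f, _fm=fm)
            except (FeasibilityError, QPError):
                break  # keep the best iterate reached
            obj_next = empirical_objective(f_next, s, cfg_run)
            improved = path[-1] - obj_next
            f = f_next
            path.append(obj_next)
            if abs(improved) < cfg_run.dc_tol:
                break
        # feasibility polish: finite-precision QPs may leave the ramp risk a
        # little above the budget; re-solving the final subproblem with the
        # budget tightened by the observed excess removes it (the linearized
        # constraint dominates psi, so tightening only reduces true risk)
        risk = empirical_surrogate_risk(f, s, cfg_run.eta)
        tighten, polish = 0.0, 0
        while risk > cfg_run.tau + cfg_run.qp_tol and polish < 3:
            tighten += 1.5 * (risk - cfg_run.tau)
            try:
                f_new = qp_subproblem(s, cfg_run, f, _fm=fm, _tighten=tighten)
            except (FeasibilityError, QPError):
                break
            f = f_new
            risk = empirical_surrogate_risk(f, s, cfg_run.eta)
            polish += 1
        return f, path, risk, polish

    min_attainable = None
    try:
        f, path, risk, polish = run_dc(cfg, f_init)
    except (FeasibilityError, QPError):
        # the budget may be unattainable within this function class (tau
        # below the class's minimum achievable ramp risk), or the warm start
        # may sit where the linearized subproblem cannot be certified.
        # Phase 1: minimize the ramp risk itself (risk term moved into the
        # objective -- always a well-posed QP).  If the least-risk rule
        # meets the budget, restart the constrained DC from it; otherwise
        # return it, flagged infeasible, with the attainable minimum
        # reported in the diagnostics.
        f_mr, risk_mr = _min_risk_solve(s, cfg, fm)
        min_attainable = risk_mr
        if risk_mr <= cfg.tau + cfg.qp_tol:
            try:
                f, path, risk, polish = run_dc(cfg, f_mr)
            except (FeasibilityError, QPError):
                f, risk, polish = f_mr, risk_mr, 0
                path = [empirical_objective(f_mr, s, cfg)]
        else:
            f, risk, polish = f_mr, risk_mr, 0
            path = [empirical_objective(f_mr, s, cfg)]
    diagnostics = dict(getattr(f, "last_qp_info", {}))
    diagnostics["polish_steps"] = polish
    if min_attainable is not None:
        diagnostics["min_attainable_risk"] = min_attainable
    return StageFitResult(
        f=f, objective_path=path, train_risk=risk,
        feasible=bool(risk <= cfg.tau + cfg.qp_tol), n_iter=len(path),
        diagnostics=diagnostics,
    )


def _min_risk_solve(s: StageSample, cfg: SolverConfig, fm) -> tuple:
    """DC minimization of the empirical ramp risk itself (phase 1).

    The risk term is moved into the QP objective, so every subproblem is
    well posed even when no rule satisfies the budget.  Returns the
    least-risk rule found and its ramp risk; used to certify (in)feasibility
    of a stage budget within the function class and as the fallback rule
    when the budget is unattainable.
    """
    Phi, to_rule = fm
    lam = cfg.lam(len(s))
    zeros = np.zeros(len(s))
    f = None
    best_f, best_risk = None, np.inf
    for _ in range(max(cfg.dc_max_iter, 10)):
        a_row, zc, zs, lf, _, _ = _dc_linearization(s, cfg.eta, f, "progressive")
        beta, b, _ = solve_stage_qp(
            Phi, s.A_hat, zeros, lam,
            a=a_row, zeta_coef=zc, zeta_shift=zs, lin_f=lf, risk_weight=1.0,
            tol=min(cfg.qp_tol, 1e-8),
        )
        f = to_rule(beta, b)
        risk = empirical_surrogate_risk(f, s, cfg.eta)
        if risk < best_risk - cfg.dc_tol:
            best_f, best_risk = f, risk
        else:
            if best_f is None:
                best_f, best_risk = f, risk
            break
    return best_f, best_risk


def _weighted_value(f: DecisionFunction, s: StageSample) -> float:
    """Validation score: ``(1/n) sum W_i I(Ahat_i f(H_i) > 0) / P_i``."""
    margins = s.A_hat * f.predict(s.H)
    return float(np.mean(s.W / s.P * (margins > 0)))


def cross_validate_cost(
    s: StageSample,
    cfg_grid: list[SolverConfig],
    folds: int = 2,
    criterion: str = "safe_value",
    seed: int = 0,
) -> SolverConfig:
    """Select the cost parameter by k-fold cross-validation.

    ``criterion="safe_value"`` (default) scores each config by the held-out
    weighted value of the fitted rule, *restricted to configs whose held-out
    ramp risk also meets the stage budget*; if no config passes the
    screening, the one with the smallest held-out risk is returned.  For an
    unconstrained stage the screening is vacuous.  This matters because the
    risk constraint is enforced on the training half only: aggressive costs
    can exhaust the budget with overfitted margins whose held-out risk far
    exceeds it, and a pure value criterion would select exactly those.

    ``criterion="value"`` is the unscreened held-out value;
    ``criterion="dual"`` scores by the converged inner QP's Lagrange dual
    objective on the training folds.  Ties break toward the smaller cost.
    """
    if not cfg_grid:
        raise ValueError("empty configuration grid")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if criterion not in ("safe_value", "value", "dual"):
        raise ValueError(f"unknown CV criterion {criterion!r}")
    n = len(s)
    if folds > n:
        raise ValueError("more folds than samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_ids = np.array_split(perm, folds)

    order = np.argsort([cfg.cost for cfg in cfg_grid], kind="stable")
    best_cfg, best_score = None, -np.inf
    fallback_cfg, fallback_risk = None, np.inf
    for idx in order:
        cfg = cfg_grid[idx]
        scores, risk_terms = [], []
        try:
            for k in range(folds):
                val_idx = fold_ids[k]
                train_idx = np.concatenate([fold_ids[j] for j in range(folds) if j != k])
                if len(val_idx) == 0 or len(train_idx) == 0:
                    raise ValueError("empty cross-validation fold")
                fit = dc_solve(s.subset(train_idx), cfg)
                val = s.subset(val_idx)
                if criterion == "dual":
                    scores.append(fit.diagnostics.get("dual_objective", -np.inf))
                else:
                    scores.append(_weighted_value(fit.f, val))
                if criterion == "safe_value" and np.isfinite(cfg.tau):
                    margins = val.A * fit.f.predict(val.H)
                    risk_terms.append(val.R * (margins > 0) / val.P)
        except (FeasibilityError, QPError):
            continue
        score = float(np.mean(scores))
        if criterion == "safe_value" and np.isfinite(cfg.tau):
            # screen at tau plus one standard error of the held-out risk
            # estimate (the usual 1-SE rule), so configs whose violation is
            # within sampling noise are not discarded
            terms = np.concatenate(risk_terms)
            val_risk = float(np.mean(terms))
            val_se = float(np.std(terms) / np.sqrt(len(terms)))
            if val_risk < fallback_risk - 1e-12:
                fallback_cfg, fallback_risk = cfg, val_risk
            if val_risk > cfg.tau + val_se:
                continue
        if score > best_score + 1e-12:
            best_cfg, best_score = cfg, score
    if best_cfg is None:
        best_cfg = fallback_cfg
    if best_cfg is None:
        raise FeasibilityError(
            cfg_grid[0].tau, np.nan, "no configuration in the grid produced a usable fit"
        )
    return best_cfg


def full_cost_grid() -> list[float]:
    """The 21-point cost grid ``2^-10, ..., 2^10``."""
    return [2.0**k for k in range(-10, 11)]


def reduced_cost_grid() -> list[float]:
    """Every other point of the full grid (11 points); the fast default."""
    return [2.0**k for k in range(-10, 11, 2)]
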