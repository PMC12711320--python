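"""Dense primal-dual interior-point solver for the stage subproblem QP.

Each DC iteration of the constrained stage problem is a convex QP over
coefficients ``beta`` of an explicit feature map ``Phi`` (margins
``f = Phi beta + b``), hinge slacks ``xi`` and constraint slacks ``zeta``:

    minimize    (1/n) sum_i c_i xi_i  +  lam ||beta||^2
    subject to  xi_i >= 0,  xi_i >= 1 - yhat_i f_i               (hinge)
                zeta_i >= 0,  zeta_i >= a_i f_i + shift_i         (ramp part)
                sum_i q_i zeta_i + sum_i lin_i f_i <= rhs         (risk row)

with ``q_i >= 0``.  A linear kernel passes its raw features as ``Phi`` and
recovers the primal weight vector; an RKHS solve passes ``Phi = Q L^{1/2}``
from the eigendecomposition of its (jittered) Gram matrix, for which
``lam ||beta||^2`` is exactly the RKHS penalty.  The caller encodes the DC
linearization of the ramp-loss risk constraint in ``(q, shift, lin, rhs)``:
positive-risk points keep their convex piece ``(m + eta)_+`` as a slack and
contribute the linearized concave piece through ``lin``; negative-risk
points keep ``|r| (m)_+`` (shift 0) and linearize the other piece, so every
slack coefficient in the risk row is nonnegative and the subproblem
constraint genuinely over-approximates the ramp risk.

The Newton step exploits the structure: slack blocks are diagonal and
eliminated analytically, the single risk row is a rank-one Sherman-Morrison
update, and only a ``(p+1) x (p+1)`` ridge system in ``(beta, b)`` is
factorized per iteration.  Mehrotra predictor-corrector, infeasible start,
common primal-dual step length (required for a quadratic objective).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve


class QPError(RuntimeError):
    """Raised when the interior-point iteration fails to converge."""


def _max_step(v, dv):
    """Largest step in [0, 1] keeping ``v + step*dv`` nonnegative."""
    neg = dv < 0
    if not np.any(neg):
        return 1.0
    return min(1.0, float(np.min(-v[neg] / dv[neg])))


def solve_stage_qp(
    Phi,
    yhat,
    c,
    lam,
    *,
    a=None,
    zeta_coef=None,
    zeta_shift=None,
    lin_f=None,
    rhs_risk=None,
    risk_weight=None,
    tol=1e-8,
    accept_tol=1e-4,
    max_iter=60,
):
    """Solve the stage subproblem QP over margins ``f = Phi beta + b``.

    Parameters
    ----------
    Phi : (n, p) feature map (raw features, or ``Q L^1/2`` for an RKHS).
    yhat : (n,) hinge labels (pseudo-treatments) in {-1, +1}.
    c : (n,) nonnegative hinge weights; points with ``c_i = 0`` are dropped
        from the hinge term (no slack variable).
    lam : ridge penalty ``lam * ||beta||^2``.
    a, zeta_coef, zeta_shift, lin_f, rhs_risk : risk-row data (observed
        treatments, nonnegative slack coefficients, per-point slack shifts,
        linear margin coefficients, right-hand side).  ``rhs_risk is None``
        solves the unconstrained QP.
    tol, accept_tol : target and fallback KKT tolerance.  The iteration aims
        for ``tol``; if floating point stalls it first (degenerate active
        sets), the best iterate is accepted provided its scaled KKT merit is
        below ``accept_tol``.

    Returns
    -------
    beta, b, info : coefficients, intercept and a diagnostics dict with
        ``primal_objective``, ``dual_objective``, ``iterations``,
        ``risk_multiplier``, ``kkt_residual``.
    """
    Phi = np.asarray(Phi, dtype=float)
    n, p = Phi.shape
    yhat = np.asarray(yhat, dtype=float)
    c = np.asarray(c, dtype=float)
    constrained = rhs_risk is not None
    if constrained and risk_weight is not None:
        raise ValueError("risk term is either a constraint or an objective, not both")
    penalized = risk_weight is not None
    if constrained or penalized:
        a = np.asarray(a, dtype=float)
        zeta_coef = np.asarray(zeta_coef, dtype=float)
        zeta_shift = np.asarray(zeta_shift, dtype=float)
        lin_f = np.asarray(lin_f, dtype=float)
        if np.any(zeta_coef < 0):
            raise ValueError("risk-row slack coefficients must be nonnegative")
        if constrained:
            # equilibrate the risk row against the unit-scale hinge/slack rows
            row_scale = max(1.0, float(np.sqrt(zeta_coef @ zeta_coef + lin_f @ lin_f)))
            zeta_coef = zeta_coef / row_scale
            lin_f = lin_f / row_scale
            rhs_risk = rhs_risk / row_scale
        Z = np.flatnonzero(zeta_coef > 0)
    else:
        Z = np.zeros(0, dtype=int)

    S = np.flatnonzero(c > 0)
    ns = len(S)
    nz = len(Z)
    if ns == 0 and not constrained and not penalized:
        info = {
            "primal_objective": 0.0,
            "dual_objective": 0.0,
            "iterations": 0,
            "risk_multiplier": 0.0,
            "kkt_residual": 0.0,
        }
        return np.zeros(p), 0.0, info

    cS = c[S] / n
    yS = yhat[S]
    if constrained or penalized:
        qZ = zeta_coef[Z]
        aZ = a[Z]
        shiftZ = zeta_shift[Z]

    nab = p + 1  # (beta, b)
    m = 2 * ns + 2 * nz + (1 if constrained else 0)

    # h vector by row blocks: [-xi<=0 | hinge | -zeta<=0 | ramp | risk]
    h = np.concatenate(
        [
            np.zeros(ns),
            -np.ones(ns),
            np.zeros(nz),
            -shiftZ if nz else np.zeros(0),
            np.array([rhs_risk]) if constrained else np.zeros(0),
        ]
    )

    def split_rows(v):
        i = 0
        v1 = v[i : i + ns]; i += ns
        v2 = v[i : i + ns]; i += ns
        v3 = v[i : i + nz]; i += nz
        v4 = v[i : i + nz]; i += nz
        v5 = v[i] if constrained else 0.0
        return v1, v2, v3, v4, v5

    def f_of(ab):
        return Phi @ ab[:p] + ab[p]

    def G_mul(ab, xi, zeta):
        f = f_of(ab)
        rows = [-xi, -yS * f[S] - xi]
        if nz:
            rows += [-zeta, aZ * f[Z] - zeta]
        if constrained:
            rows += [np.array([lin_f @ f + qZ @ zeta])]
        return np.concatenate(rows)

    def GT_mul(v):
        v1, v2, v3, v4, v5 = split_rows(v)
        d_f = np.zeros(n)
        d_f[S] -= yS * v2
        out_xi = -v1 - v2
        if nz:
            d_f[Z] += aZ * v4
            out_zeta = -v3 - v4
            if constrained:
                d_f += v5 * lin_f
                out_zeta = out_zeta + v5 * qZ
        else:
            out_zeta = np.zeros(0)
        ab = np.empty(nab)
        ab[:p] = Phi.T @ d_f
        ab[p] = d_f.sum()
        return ab, out_xi, out_zeta

    q_xi = cS
    if penalized:
        q_zeta = risk_weight * qZ
        q_ab = np.empty(p + 1)
        q_ab[:p] = risk_weight * (Phi.T @ lin_f)
        q_ab[p] = risk_weight * lin_f.sum()
    else:
        q_zeta = np.zeros(nz)
        q_ab = np.zeros(p + 1)
    reg = 1e-10 * max(1.0, 2.0 * lam)

    # state
    ab = np.zeros(nab)
    xi = np.ones(ns)
    zeta = np.ones(nz)
    s = np.maximum(1.0, np.abs(h))
    z = np.ones(m)

    obj_scale = 1.0 + abs(float(np.sum(cS))) + float(np.max(np.abs(h), initial=1.0))
    it = 0
    best = None
    best_merit = np.inf
    best_it = 0
    for it in range(1, max_iter + 1):
        Gx = G_mul(ab, xi, zeta)
        GTz_ab, GTz_xi, GTz_zeta = GT_mul(z)
        rd_ab = GTz_ab + q_ab
        rd_ab[:p] += 2.0 * lam * ab[:p]
        rd_xi = q_xi + GTz_xi
        rd_zeta = q_zeta + GTz_zeta
        rp = Gx + s - h
        mu = float(s @ z) / m

        rd_norm = max(
            np.max(np.abs(rd_ab), initial=0.0),
            np.max(np.abs(rd_xi), initial=0.0),
            np.max(np.abs(rd_zeta), initial=0.0),
        )
        rp_norm = float(np.max(np.abs(rp), initial=0.0))
        merit = max(rd_norm, rp_norm, mu) / obj_scale
        if merit < best_merit:
            best_merit = merit
            best_it = it
            best = (ab.copy(), xi.copy(), zeta.copy(), s.copy(), z.copy())
        if merit <= tol:
            break
        # degenerate active sets make ultra-tight convergence unattainable:
        # once progress stalls, fall back to the best iterate seen
        if it - best_it > 10:
            break

        # cap the scaling weights: with w <= 1e10 the rounding error of the
        # normal equations stays well below the acceptance tolerance, while
        # uncapped weights make the late Newton directions pure noise
        w = np.minimum(z / s, 1e10)
        w1, w2, w3, w4, w5 = split_rows(w)

        # eliminate the diagonal xi / zeta blocks; the remaining (beta, b)
        # system is ridge + Phi' E Phi with diagonal E, bordered by b
        e = np.zeros(n)
        D1 = w1 + w2
        e[S] += w1 * w2 / D1
        if nz:
            D2 = w3 + w4
            e[Z] += w3 * w4 / D2
        C = Phi * np.sqrt(e)[:, None]
        inner = C.T @ C
        inner[np.diag_indices(p)] += 2.0 * lam + reg + 1e-14 * float(np.max(np.diag(inner)))
        try:
            cho = cho_factor(inner, lower=True, check_finite=False)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise QPError("inner Newton matrix not positive definite") from exc

        def M_solve(v):
            return cho_solve(cho, v, check_finite=False)

        mb = Phi.T @ e
        yK = M_solve(mb)
        bb = float(e.sum() + reg - mb @ yK)
        bb = max(bb, 1e-12 * (1.0 + float(e.sum())))

        def ab_solve(rhs):
            x1 = M_solve(rhs[:p])
            xb = (rhs[p] - mb @ x1) / bb
            out = np.empty(nab)
            out[:p] = x1 - xb * yK
            out[p] = xb
            return out

        def m0_solve(y_ab, y_xi, y_zeta):
            rhs = y_ab.copy()
            d_f = np.zeros(n)
            d_f[S] += yS * w2 * y_xi / D1
            if nz:
                d_f[Z] += -aZ * w4 * y_zeta / D2
            rhs[:p] -= Phi.T @ d_f
            rhs[p] -= d_f.sum()
            x_ab = ab_solve(rhs)
            f = f_of(x_ab)
            x_xi = (y_xi - w2 * yS * f[S]) / D1
            x_zeta = (y_zeta + w4 * aZ * f[Z]) / D2 if nz else np.zeros(0)
            return x_ab, x_xi, x_zeta

        if constrained:
            t_ab = np.empty(nab)
            t_ab[:p] = Phi.T @ lin_f
            t_ab[p] = lin_f.sum()
            ti_ab, ti_xi, ti_zeta = m0_solve(t_ab, np.zeros(ns), qZ)
            denom = 1.0 + w5 * (t_ab @ ti_ab + qZ @ ti_zeta)

        def m_solve(y_ab, y_xi, y_zeta):
            x_ab, x_xi, x_zeta = m0_solve(y_ab, y_xi, y_zeta)
            if constrained:
                tdoty = t_ab @ x_ab + qZ @ x_zeta
                coef = w5 * tdoty / denom
                x_ab = x_ab - coef * ti_ab
                x_xi = x_xi - coef * ti_xi
                x_zeta = x_zeta - coef * ti_zeta
            return x_ab, x_xi, x_zeta

        def newton(rc):
            vrow = (rc + z * rp) / s
            gt_ab, gt_xi, gt_zeta = GT_mul(vrow)
            rhs_ab = -rd_ab - gt_ab
            dx = m_solve(rhs_ab, -rd_xi - gt_xi, -rd_zeta - gt_zeta)
            ds = -rp - G_mul(*dx)
            dz = (rc - z * ds) / s
            return dx, ds, dz

        # affine-scaling (predictor) direction
        dx_a, ds_a, dz_a = newton(-s * z)
        ap = _max_step(s, ds_a)
        ad = _max_step(z, dz_a)
        mu_aff = float((s + ap * ds_a) @ (z + ad * dz_a)) / m
        sigma = (mu_aff / mu) ** 3 if mu > 0 else 0.0

        # corrector; a common primal-dual step length keeps the residual
        # recursions exact for a quadratic objective
        rc = -s * z + sigma * mu - ds_a * dz_a
        (dab, dxi, dzeta), ds, dz = newton(rc)
        step = 0.99 * min(_max_step(s, ds), _max_step(z, dz))
        ab += step * dab
        xi += step * dxi
        zeta += step * dzeta
        s += step * ds
        z += step * dz

    if best_merit > accept_tol:
        raise QPError(
            f"interior-point iteration did not converge in {it} steps "
            f"(best scaled KKT merit {best_merit:.2e} > {accept_tol:.0e})"
        )
    ab, xi, zeta, s, z = best

    beta, b = ab[:p], float(ab[p])
    primal = float(q_xi @ xi + lam * beta @ beta)
    if penalized:
        primal += float(q_zeta @ zeta + q_ab @ ab)
    dual = float(-lam * beta @ beta - h @ z)
    _, _, _, _, z5 = split_rows(z)
    info = {
        "primal_objective": primal,
        "dual_objective": dual,
        "iterations": it,
        "risk_multiplier": float(z5) / (row_scale if constrained else 1.0),
        "kkt_residual": best_merit * obj_scale,
    }
    return beta, b, info
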