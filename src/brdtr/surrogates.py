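"""Surrogate losses for value maximization under a risk constraint.

The benefit term of the stage problem uses the hinge loss ``phi(x) = (1-x)_+``,
the standard convex surrogate of the 0-1 loss in weighted classification.  The
risk constraint replaces the indicator ``I(x >= 0)`` with the shifted ramp loss
``psi(x, eta)``, a piecewise-linear *upper bound* of the indicator that equals
it outside ``(-eta, 0)``.  Because ``psi`` dominates the indicator, any rule
that is feasible for the surrogate constraint is feasible for the 0-1 risk:
the surrogate is conservative for every ``eta`` in ``(0, 1]``.

``psi`` is not convex, but it is a difference of convex functions,

    psi(x, eta) = (x + eta)_+ / eta  -  (x)_+ / eta,

which is the split the DC (difference-of-convex) solver linearizes.
"""

from __future__ import annotations

import numpy as np


def hinge(x):
    """Hinge loss ``(1 - x)_+``, elementwise."""
    return np.maximum(1.0 - np.asarray(x, dtype=float), 0.0)


def _check_eta(eta: float) -> float:
    eta = float(eta)
    if not (0.0 < eta <= 1.0):
        raise ValueError(f"shifting parameter eta must lie in (0, 1], got {eta}")
    return eta


def shifted_ramp(x, eta: float):
    """Shifted ramp loss ``psi(x, eta)``.

    Equals 1 for ``x >= 0``, ``(x + eta)/eta`` on ``(-eta, 0)`` and 0 for
    ``x <= -eta``.  Values lie in [0, 1] and dominate ``I(x >= 0)`` pointwise.
    """
    eta = _check_eta(eta)
    x = np.asarray(x, dtype=float)
    return np.clip((x + eta) / eta, 0.0, 1.0)


def ramp_dc_parts(x, eta: float):
    """Convex components ``(u, v)`` with ``psi(x, eta) = u(x) - v(x)``.

    ``u(x) = (x + eta)_+ / eta`` and ``v(x) = (x)_+ / eta``; both convex.
    """
    eta = _check_eta(eta)
    x = np.asarray(x, dtype=float)
    u = np.maximum(x + eta, 0.0) / eta
    v = np.maximum(x, 0.0) / eta
    return u, v


def ramp_concave_subgradient(x, eta: float):
    """Subgradient of the concave part ``-v`` used by the DC linearization.

    Returns ``g`` with ``g = 1/eta`` where ``x > 0`` and 0 elsewhere.  At the
    kink ``x = 0`` the one-sided (left) choice ``g = 0`` is taken, which keeps
    the first DC step from an unconstrained start maximally conservative and
    makes the iteration deterministic.
    """
    eta = _check_eta(eta)
    x = np.asarray(x, dtype=float)
    return np.where(x > 0.0, 1.0 / eta, 0.0)
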