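"""Kernels and the median-heuristic bandwidth for the stage decision functions.

Decision functions live in an RKHS generated by either a linear kernel
``k(h, h') = h^T h'`` or a Gaussian radial basis kernel

    k(h, h') = exp(-sigma^2 ||h - h'||^2),

where ``sigma`` is the *inverse* bandwidth.  Rather than tuning ``sigma``,
the bandwidth ``1/sigma`` is fixed to twice the median Euclidean distance
between feature vectors of subjects who received opposite treatments -- the
usual median heuristic restricted to across-arm pairs, which adapts the
kernel scale to the classification geometry of the stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

#: jitter added to training Gram matrices so QP solvers see a strictly PD matrix
GRAM_JITTER = 1e-8


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus, for the Gaussian family, the inverse bandwidth sigma."""

    family: str  # "linear" | "gaussian"
    inv_bandwidth: float | None = None

    def __post_init__(self):
        if self.family not in ("linear", "gaussian"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "gaussian":
            if self.inv_bandwidth is None or not self.inv_bandwidth > 0:
                raise ValueError("gaussian kernel requires a positive inv_bandwidth")
        elif self.inv_bandwidth is not None:
            raise ValueError("linear kernel takes no bandwidth")

    def to_json(self) -> dict:
        out = {"family": self.family}
        if self.family == "gaussian":
            out["inv_bandwidth"] = float(self.inv_bandwidth)
        return out

    @classmethod
    def from_json(cls, obj: dict) -> "KernelSpec":
        return cls(family=obj["family"], inv_bandwidth=obj.get("inv_bandwidth"))


def kernel_matrix(X, Z, spec: KernelSpec) -> np.ndarray:
    """Gram matrix ``K[i, j] = k(X[i], Z[j])`` under ``spec``.

    No jitter is added here; callers that need strict positive definiteness
    (the QP solver) add ``GRAM_JITTER * I`` on the square training Gram.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[1] != Z.shape[1]:
        raise ValueError(f"feature dimension mismatch: {X.shape[1]} vs {Z.shape[1]}")
    if spec.family == "linear":
        return X @ Z.T
    d2 = cdist(X, Z, metric="sqeuclidean")
    return np.exp(-(spec.inv_bandwidth**2) * d2)


def median_bandwidth(X, A) -> KernelSpec:
    """Gaussian spec with ``1/sigma = 2 * median{||H_i - H_j|| : A_i != A_j}``.

    Raises if either treatment arm is empty (the across-arm median is then
    undefined, signalling degenerate randomization rather than mis-scaling).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    A = np.asarray(A)
    pos = X[A == 1]
    neg = X[A == -1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("median bandwidth undefined: one treatment arm is empty")
    dists = cdist(pos, neg, metric="euclidean").ravel()
    med = float(np.median(dists))
    if med <= 0:
        raise ValueError("median across-arm distance is zero; features are degenerate")
    return KernelSpec(family="gaussian", inv_bandwidth=1.0 / (2.0 * med))
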