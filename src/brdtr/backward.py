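"""Backward induction for benefit-risk dynamic treatment regimens.

Stages are fitted from the last to the first.  At stage t the future is
summarized by the augmented Q-values under the already-fitted later rules,
the stage weights and pseudo-treatments are built, the SVM cost is chosen by
cross-validation, and the constrained stage problem is solved by the DC
solver with the stage's risk budget ``tau_t``.  Three modes are supported:

``brdtr``
    the full constrained, augmented procedure;
``unconstrained``
    the same augmented backward fits with every ``tau = inf`` (the augmented
    outcome-weighted-learning comparator that ignores risk);
``naive``
    later stages as in ``brdtr``, but the first stage weights use the raw
    cumulative reward ``sum_t Y_t`` with no indicator/augmentation
    adjustment for delayed effects (the risk constraint is kept).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import augmentation as aug
from .kernels import KernelSpec, median_bandwidth
from .solver import (
    DecisionFunction,
    FeasibilityError,
    SolverConfig,
    StageFitResult,
    StageSample,
    cross_validate_cost,
    dc_solve,
    reduced_cost_grid,
)

MODES = ("brdtr", "naive", "unconstrained")


@dataclass
class TrialData:
    """Per-subject, per-stage records of a T-stage sequential trial.

    All dict fields are keyed by stage ``t = 1..T``: features ``H[t]``
    (n x d_t, with histories nested so d_1 <= ... <= d_T), treatments
    ``A[t]`` in {-1, +1}, rewards ``Y[t]``, risks ``R[t]`` and randomization
    probabilities ``P[t]`` of the *observed* treatment (``None`` for a stage
    means the propensity must be estimated).
    """

    H: dict
    A: dict
    Y: dict
    R: dict
    P: dict

    def __post_init__(self):
        stages = sorted(self.H)
        if stages != list(range(1, len(stages) + 1)):
            raise ValueError("stages must be numbered 1..T")
        n = None
        for t in stages:
            self.H[t] = np.atleast_2d(np.asarray(self.H[t], dtype=float))
            self.A[t] = np.asarray(self.A[t], dtype=float)
            self.Y[t] = np.asarray(self.Y[t], dtype=float)
            self.R[t] = np.asarray(self.R[t], dtype=float)
            if self.P.get(t) is not None:
                self.P[t] = np.asarray(self.P[t], dtype=float)
            if n is None:
                n = self.H[t].shape[0]
            if not np.all(np.isin(self.A[t], (-1.0, 1.0))):
                raise ValueError(f"stage {t}: treatments must be coded -1/+1")
            lengths = [self.H[t].shape[0], len(self.A[t]), len(self.Y[t]), len(self.R[t])]
            if self.P.get(t) is not None:
                lengths.append(len(self.P[t]))
                if np.any((self.P[t] <= 0) | (self.P[t] >= 1)):
                    raise ValueError(f"stage {t}: propensities must lie in (0, 1)")
            if any(m != n for m in lengths):
                raise ValueError(f"stage {t}: inconsistent array lengths")

    @property
    def T(self) -> int:
        return len(self.H)

    @property
    def n(self) -> int:
        return self.H[1].shape[0]

    def subset(self, idx) -> "TrialData":
        return TrialData(
            H={t: self.H[t][idx] for t in self.H},
            A={t: self.A[t][idx] for t in self.A},
            Y={t: self.Y[t][idx] for t in self.Y},
            R={t: self.R[t][idx] for t in self.R},
            P={t: (self.P[t][idx] if self.P.get(t) is not None else None) for t in self.H},
        )


@dataclass
class StageTransform:
    """Center to mean 0 and rescale each feature into [-1, 1]."""

    center: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, H: np.ndarray) -> "StageTransform":
        center = H.mean(axis=0)
        scale = np.max(np.abs(H - center), axis=0)
        scale[scale == 0] = 1.0
        return cls(center=center, scale=scale)

    def apply(self, H) -> np.ndarray:
        H = np.atleast_2d(np.asarray(H, dtype=float))
        if H.shape[1] != len(self.center):
            raise ValueError(f"expected {len(self.center)} features, got {H.shape[1]}")
        return (H - self.center) / self.scale


@dataclass
class DTRPolicy:
    """An ordered set of stage rules plus the feature transforms they expect.

    ``recommend(t, h)`` applies the stored stage-t transform and returns
    ``sign(f_t)`` with ``sign(0) := +1``; features are passed untransformed.
    """

    stages: dict  # t -> DecisionFunction (on transformed features)
    preprocessing: dict  # t -> StageTransform
    configs: dict = field(default_factory=dict)  # t -> SolverConfig
    seed: int | None = None
    mode: str = "brdtr"
    stage_results: dict = field(default_factory=dict)  # t -> StageFitResult
    nuisance: aug.NuisanceModels | None = None

    @property
    def T(self) -> int:
        return len(self.stages)

    def decision_values(self, t: int, H) -> np.ndarray:
        return self.stages[t].predict(self.preprocessing[t].apply(H))

    def recommend(self, t: int, H) -> np.ndarray:
        return np.where(self.decision_values(t, H) >= 0.0, 1.0, -1.0)

    def to_json(self) -> dict:
        out = {
            "format": "brdtr-policy",
            "version": 1,
            "T": self.T,
            "seed": self.seed,
            "mode": self.mode,
            "stages": [self.stages[t].to_json() for t in range(1, self.T + 1)],
            "preprocessing": [
                {
                    "center": self.preprocessing[t].center.tolist(),
                    "scale": self.preprocessing[t].scale.tolist(),
                }
                for t in range(1, self.T + 1)
            ],
        }
        if self.configs:
            out["config"] = [
                {
                    "kernel": self.configs[t].kernel.to_json(),
                    "cost": self.configs[t].cost,
                    "eta": self.configs[t].eta,
                    "tau": (None if np.isinf(self.configs[t].tau) else self.configs[t].tau),
                }
                for t in range(1, self.T + 1)
            ]
        return out

    @classmethod
    def from_json(cls, obj: dict) -> "DTRPolicy":
        if obj.get("format") != "brdtr-policy" or obj.get("version") != 1:
            raise ValueError("not a version-1 brdtr policy file")
        T = int(obj["T"])
        if T < 1 or len(obj["stages"]) != T:
            raise ValueError("policy must contain one decision function per stage")
        stages = {
            t: DecisionFunction.from_json(obj["stages"][t - 1]) for t in range(1, T + 1)
        }
        pre = {
            t: StageTransform(
                center=np.asarray(obj["preprocessing"][t - 1]["center"], dtype=float),
                scale=np.asarray(obj["preprocessing"][t - 1]["scale"], dtype=float),
            )
            for t in range(1, T + 1)
        }
        configs = {}
        for t, cfg in enumerate(obj.get("config", []), start=1):
            configs[t] = SolverConfig(
                kernel=KernelSpec.from_json(cfg["kernel"]),
                cost=cfg["cost"],
                eta=cfg["eta"],
                tau=(np.inf if cfg["tau"] is None else cfg["tau"]),
            )
        return cls(
            stages=stages, preprocessing=pre, configs=configs,
            seed=obj.get("seed"), mode=obj.get("mode", "brdtr"),
        )


def recommend(policy: DTRPolicy, t: int, h) -> np.ndarray:
    """Recommended treatment(s) at stage t for raw feature vector(s) ``h``."""
    return policy.recommend(t, h)


def estimate_propensity(data: TrialData, t: int) -> np.ndarray:
    """Logistic-regression estimate of ``P(A_t = observed | H_t)``.

    For observational data without recorded randomization probabilities.
    Probabilities are clipped to [0.01, 0.99] so inverse weighting stays
    bounded even under separation.
    """
    from sklearn.linear_model import LogisticRegression

    A = data.A[t]
    if len(np.unique(A)) < 2:
        raise ValueError(f"stage {t}: only one treatment arm present")
    model = LogisticRegression(C=np.inf, max_iter=1000)
    model.fit(data.H[t], A)
    p1 = model.predict_proba(data.H[t])[:, list(model.classes_).index(1.0)]
    p_obs = np.where(A == 1.0, p1, 1.0 - p1)
    return np.clip(p_obs, 0.01, 0.99)


def _broadcast(value, T: int, name: str) -> list:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if len(arr) == 1:
        arr = np.repeat(arr, T)
    if len(arr) != T:
        raise ValueError(f"{name} must be a scalar or have one entry per stage ({T})")
    return list(arr)


def fit_brdtr(
    data: TrialData,
    taus,
    etas=0.02,
    kernel: str = "gaussian",
    cost_grid=None,
    cv_folds: int = 2,
    mode: str = "brdtr",
    seed: int = 0,
    cv_criterion: str = "safe_value",
    dc_tol: float = 1e-6,
    dc_max_iter: int = 50,
    qp_tol: float = 1e-6,
    dc_split: str = "progressive",
) -> DTRPolicy:
    """Fit a T-stage benefit-risk policy by backward induction.

    ``taus``/``etas`` are scalars or per-stage sequences; ``tau = inf``
    (or ``None``) leaves a stage unconstrained.  ``kernel`` is "linear" or
    "gaussian" (median-heuristic bandwidth per stage).  The SVM cost is
    selected per stage by ``cv_folds``-fold cross-validation over
    ``cost_grid`` (default: the reduced 5-point powers-of-2 grid).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if kernel not in ("linear", "gaussian"):
        raise ValueError("kernel must be 'linear' or 'gaussian'")
    T = data.T
    raw_taus = list(taus) if isinstance(taus, (list, tuple, np.ndarray)) else [taus]
    raw_taus = [np.inf if v is None else float(v) for v in raw_taus]
    taus = _broadcast(raw_taus, T, "taus")
    etas = _broadcast(etas, T, "etas")
    if mode == "unconstrained":
        taus = [np.inf] * T
    if cost_grid is None:
        cost_grid = reduced_cost_grid()

    transforms = {t: StageTransform.fit(data.H[t]) for t in range(1, T + 1)}
    tdata = TrialData(
        H={t: transforms[t].apply(data.H[t]) for t in range(1, T + 1)},
        A=dict(data.A), Y=dict(data.Y), R=dict(data.R),
        P={
            t: (data.P[t] if data.P.get(t) is not None else estimate_propensity(data, t))
            for t in range(1, T + 1)
        },
    )

    fitted: dict[int, DecisionFunction] = {}
    results: dict[int, StageFitResult] = {}
    configs: dict[int, SolverConfig] = {}
    all_nuis = aug.NuisanceModels()
    total_y = np.sum([tdata.Y[t] for t in range(1, T + 1)], axis=0)

    for t in range(T, 0, -1):
        if mode == "naive" and t == 1:
            signs = np.where(total_y >= 0, 1.0, -1.0)
            W, A_hat = np.abs(total_y), tdata.A[1] * signs
        else:
            nuis = aug.fit_nuisance_for_stage(tdata, fitted, t)
            stage = aug.build_augmented_stage(tdata, fitted, nuis, t)
            W, A_hat = stage.W, stage.A_hat
            all_nuis.mu_t.update(nuis.mu_t)
            all_nuis.mu_tj.update(nuis.mu_tj)

        sample = StageSample(
            H=tdata.H[t], A=tdata.A[t], W=W, R=tdata.R[t], P=tdata.P[t], A_hat=A_hat
        )
        kern = (
            KernelSpec("linear")
            if kernel == "linear"
            else median_bandwidth(tdata.H[t], tdata.A[t])
        )
        grid = [
            SolverConfig(
                kernel=kern, cost=c, eta=etas[t - 1], tau=taus[t - 1],
                dc_tol=dc_tol, dc_max_iter=dc_max_iter, qp_tol=qp_tol, dc_split=dc_split,
            )
            for c in cost_grid
        ]
        try:
            cfg = cross_validate_cost(
                sample, grid, folds=cv_folds, criterion=cv_criterion,
                seed=(seed + 1000003 * t) % (2**31 - 1),
            )
            result = dc_solve(sample, cfg)
        except FeasibilityError as exc:
            raise FeasibilityError(
                taus[t - 1], exc.min_risk, f"stage {t} risk budget infeasible"
            ) from exc
        fitted[t] = result.f
        results[t] = result
        configs[t] = cfg

    return DTRPolicy(
        stages=fitted, preprocessing=transforms, configs=configs, seed=seed,
        mode=mode, stage_results=results, nuisance=all_nuis,
    )
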