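"""CSV trial schema, policy JSON files and deterministic micro-fixtures.

Trial CSV schema (strict): a leading ``id`` column, then for each stage
``t = 1..T`` the columns ``A{t}``, ``Y{t}``, ``R{t}``, optionally ``p{t}``,
and features ``H{t}_1 .. H{t}_d``.  Stage numbering is 1-based.  A missing
``p{t}`` column flags the stage for logistic propensity estimation.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .backward import DTRPolicy, TrialData
from .solver import StageSample


def write_trial_csv(data: TrialData, path) -> None:
    cols = {"id": np.arange(1, data.n + 1)}
    for t in range(1, data.T + 1):
        cols[f"A{t}"] = data.A[t].astype(int)
        cols[f"Y{t}"] = data.Y[t]
        cols[f"R{t}"] = data.R[t]
        if data.P.get(t) is not None:
            cols[f"p{t}"] = data.P[t]
        for j in range(data.H[t].shape[1]):
            cols[f"H{t}_{j + 1}"] = data.H[t][:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_trial_csv(path) -> TrialData:
    frame = pd.read_csv(path)
    if "id" not in frame.columns:
        raise ValueError("trial CSV must have an 'id' column")
    stages = sorted(
        {int(m.group(1)) for c in frame.columns for m in [re.fullmatch(r"A(\d+)", c)] if m}
    )
    if not stages or stages != list(range(1, len(stages) + 1)):
        raise ValueError(f"treatment columns must be A1..AT, found stages {stages}")
    H, A, Y, R, P = {}, {}, {}, {}, {}
    for t in stages:
        for required in (f"A{t}", f"Y{t}", f"R{t}"):
            if required not in frame.columns:
                raise ValueError(f"missing column {required}")
        a = frame[f"A{t}"].to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isin(a, (-1.0, 1.0)))
        if len(bad):
            raise ValueError(
                f"column A{t}: treatments must be -1/+1; offending rows (0-based): {bad[:10].tolist()}"
            )
        feat_cols = sorted(
            (c for c in frame.columns if re.fullmatch(rf"H{t}_(\d+)", c)),
            key=lambda c: int(c.rsplit("_", 1)[1]),
        )
        if not feat_cols:
            raise ValueError(f"no feature columns H{t}_1.. found")
        expected = [f"H{t}_{j + 1}" for j in range(len(feat_cols))]
        if feat_cols != expected:
            raise ValueError(f"stage {t} feature columns must be consecutive: {expected}")
        A[t] = a
        Y[t] = frame[f"Y{t}"].to_numpy(dtype=float)
        R[t] = frame[f"R{t}"].to_numpy(dtype=float)
        H[t] = frame[feat_cols].to_numpy(dtype=float)
        P[t] = frame[f"p{t}"].to_numpy(dtype=float) if f"p{t}" in frame.columns else None
    return TrialData(H=H, A=A, Y=Y, R=R, P=P)


def write_policy(policy: DTRPolicy, path) -> None:
    Path(path).write_text(json.dumps(policy.to_json(), indent=1))


def read_policy(path) -> DTRPolicy:
    obj = json.loads(Path(path).read_text())
    return DTRPolicy.from_json(obj)


def make_fixtures(seed: int = 0) -> dict:
    """Deterministic micro-datasets exercising solver corner cases.

    ``separable``: 1-D sample whose optimal unconstrained rule has zero
    training misclassification against the sign of the feature.
    ``risk_concentrated``: all risk mass on the positive arm, so tightening
    the budget forces the rule away from it.
    ``zero_weight``: a block of zero reward weights that must still count in
    the risk constraint.  ``single_arm``: degenerate randomization that
    bandwidth/propensity code must reject.
    """
    rng = np.random.default_rng(seed)

    n = 24
    h = np.sort(rng.uniform(-1, 1, n))[:, None]
    a = np.where(h[:, 0] >= 0, 1.0, -1.0)
    separable = StageSample(
        H=h, A=a, W=rng.uniform(0.5, 1.5, n), R=rng.uniform(0.1, 0.5, n),
        P=np.full(n, 0.5),
    )

    n = 30
    h = rng.uniform(-1, 1, (n, 1))
    a = rng.choice([-1.0, 1.0], n)
    risk = np.where(a == 1.0, rng.uniform(1.5, 2.5, n), rng.uniform(0.05, 0.15, n))
    risk_concentrated = StageSample(
        H=h, A=a, W=np.abs(h[:, 0]) + 0.2, R=risk, P=np.full(n, 0.5)
    )

    n = 20
    w = rng.uniform(0.5, 2.0, n)
    w[: n // 2] = 0.0
    zero_weight = StageSample(
        H=rng.uniform(-1, 1, (n, 2)), A=rng.choice([-1.0, 1.0], n), W=w,
        R=rng.uniform(0.2, 1.0, n), P=np.full(n, 0.5),
    )

    n = 12
    single_arm = StageSample(
        H=rng.uniform(-1, 1, (n, 1)), A=np.ones(n), W=rng.uniform(0.5, 1.0, n),
        R=rng.uniform(0.2, 1.0, n), P=np.full(n, 0.5),
    )

    return {
        "separable": separable,
        "risk_concentrated": risk_concentrated,
        "zero_weight": zero_weight,
        "single_arm": single_arm,
    }
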