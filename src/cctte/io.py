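"""Delimited-text formats and validated run configuration.

Trial datasets travel as CSV with header
``cluster_id,subject_id,time,event,x1,...,xK,arm`` (``arm`` empty before
randomization); times are serialized with 17 significant digits so a
write/read round trip is bit-exact.  Allocation spaces are one row per
allocation: ``assignment`` (bitstring, cluster 1 first), ``score``,
``constrained``.  Scenario configuration is YAML validated against a typed
schema; unknown keys are rejected.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .datagen import TrialDataset, TrialDesign
from .engine import METHODS, Scenario
from .randomization import AllocationSpace

__all__ = [
    "read_trial_csv",
    "write_trial_csv",
    "read_covariates_csv",
    "write_space_csv",
    "read_space_csv",
    "write_validity_report",
    "RunConfig",
    "GridConfig",
    "load_config",
]

_FLOAT_FMT = "%.17g"


def write_trial_csv(dataset: TrialDataset, path: str | Path) -> None:
    frame = dataset.to_frame()
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trial_csv(path: str | Path) -> TrialDataset:
    """Read and validate a subject-level trial CSV.

    Raises a schema error naming the offending column/row for missing
    columns, non-binary event indicators, nonpositive times, or clusters
    whose rows disagree on a cluster-level covariate or arm.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    required = ["cluster_id", "subject_id", "time", "event"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    xcols = sorted(
        (c for c in frame.columns if c.startswith("x") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if not xcols:
        raise ValueError("no covariate columns (x1, x2, ...) found")
    if "arm" not in frame.columns:
        raise ValueError("missing required column: arm (may be empty)")

    event = frame["event"].to_numpy()
    bad = np.flatnonzero(~np.isin(event, (0, 1)))
    if bad.size:
        raise ValueError(f"non-binary event indicator at row {bad[0] + 1}")
    time = frame["time"].to_numpy(dtype=float)
    bad = np.flatnonzero(~(time > 0))
    if bad.size:
        raise ValueError(f"nonpositive follow-up time at row {bad[0] + 1}")

    x = frame[xcols].to_numpy()
    bad = np.flatnonzero(~np.isin(x, (0, 1)).all(axis=1))
    if bad.size:
        raise ValueError(f"non-binary covariate at row {bad[0] + 1}")

    arm_raw = frame["arm"]
    if arm_raw.isna().all():
        arm = None
    elif arm_raw.isna().any():
        raise ValueError("arm column is partially empty")
    else:
        arm = arm_raw.to_numpy(dtype=float)
        if not np.isin(arm, (0, 1)).all():
            raise ValueError("arm labels must be 0/1")
        arm = arm.astype(int)

    for cid, sub in frame.groupby("cluster_id"):
        for c in xcols:
            if sub[c].nunique() > 1:
                raise ValueError(
                    f"cluster {cid} has inconsistent values of cluster-level "
                    f"covariate {c}"
                )
        if arm is not None and sub["arm"].nunique() > 1:
            raise ValueError(f"cluster {cid} has inconsistent arm labels")

    return TrialDataset(
        cluster_id=frame["cluster_id"].to_numpy(dtype=int),
        subject_id=frame["subject_id"].to_numpy(dtype=int),
        time=time,
        event=event.astype(np.int8),
        x=x.astype(np.int8),
        arm=arm,
    )


def read_covariates_csv(path: str | Path) -> np.ndarray:
    """Cluster-level covariate CSV (`cluster_id,x1,...,xK`) -> (2g, K) matrix."""
    frame = pd.read_csv(path).sort_values("cluster_id")
    xcols = [c for c in frame.columns if c != "cluster_id"]
    if not xcols:
        raise ValueError("covariate file has no covariate columns")
    return frame[xcols].to_numpy(dtype=float)


def write_space_csv(space: AllocationSpace, path: str | Path) -> None:
    bits = ["".join(map(str, row)) for row in space.assignments]
    mask = (
        space.constrained_mask
        if space.constrained_mask is not None
        else np.ones(space.size, dtype=bool)
    )
    scores = space.scores if space.scores is not None else np.full(space.size, np.nan)
    pd.DataFrame(
        {"assignment": bits, "score": scores, "constrained": mask.astype(int)}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_space_csv(path: str | Path) -> AllocationSpace:
    frame = pd.read_csv(path, dtype={"assignment": str}, float_precision="round_trip")
    a = np.array([[int(ch) for ch in s] for s in frame["assignment"]], dtype=np.int8)
    scores = frame["score"].to_numpy(dtype=float) if "score" in frame else None
    mask = (
        frame["constrained"].to_numpy(dtype=bool) if "constrained" in frame else None
    )
    return AllocationSpace(a, scores=scores, constrained_mask=mask)


def write_validity_report(report, matrix_path: str | Path, pairs_path: str | Path):
    pd.DataFrame(report.coassignment).to_csv(
        matrix_path, index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame(report.flagged_pairs, columns=["cluster_i", "cluster_j"]).to_csv(
        pairs_path, index=False
    )


class RunConfig(BaseModel):
    """Single-scenario configuration; mirrors TrialDesign plus q/n_sim/seed."""

    model_config = ConfigDict(extra="forbid")

    g: int
    n: int = 100
    num_covariates: int = 4
    covariate_prob: float = 0.3
    tau: float = 2.0
    baseline_cum_incidence: float = 0.25
    delta: float = 1.0
    beta: float | list[float] = 0.0
    frailty_var: float = 0.0
    q: float = 1.0
    n_sim: int = 1000
    seed: int = 20240901
    n_alloc_draws: int = 20_000
    methods: list[str] = list(METHODS)
    s_values: list[int] = [0, 1, 2, 3, 4]
    n_jobs: int = 1
    verbosity: int = 0

    @field_validator("methods")
    @classmethod
    def _known_methods(cls, v):
        unknown = set(v) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        return v

    def design(self) -> TrialDesign:
        beta = self.beta if np.isscalar(self.beta) else np.asarray(self.beta)
        return TrialDesign(
            g=self.g,
            n=self.n,
            num_covariates=self.num_covariates,
            covariate_prob=self.covariate_prob,
            tau=self.tau,
            baseline_cum_incidence=self.baseline_cum_incidence,
            delta=self.delta,
            beta=beta,
            frailty_var=self.frailty_var,
        )

    def scenario(self) -> Scenario:
        return Scenario(
            design=self.design(),
            q=self.q,
            methods=tuple(self.methods),
            s_values=tuple(self.s_values),
            n_sim=self.n_sim,
            seed=self.seed,
            n_alloc_draws=self.n_alloc_draws,
        )


class GridConfig(BaseModel):
    """Scenario-grid configuration for the full simulation study."""

    model_config = ConfigDict(extra="forbid")

    g_values: list[int] = [8, 13]
    deltas: list[float] = [1.0, 0.5]
    q_values: list[float] = [1.0, 0.10, 0.01]
    betas: list[float] = []
    sigma2s: list[float] = []
    settings: list[dict] = []
    n: int = 100
    baseline_cum_incidence: float = 0.25
    tau: float = 2.0
    covariate_prob: float = 0.3
    n_sim: int = 1000
    seed: int = 20240901
    methods: list[str] = list(METHODS)
    s_values: list[int] = [0, 1, 2, 3, 4]
    n_jobs: int = 1


def load_config(path: str | Path, kind: str = "run") -> RunConfig | GridConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    model = RunConfig if kind == "run" else GridConfig
    return model.model_validate(raw)


def result_to_json(result) -> str:
    return json.dumps(
        {
            f"{method}_S{s}": {
                "reject_rate": result.rejection_rate[(method, s)],
                "mcse": result.mcse[(method, s)],
                "n_used": result.n_used[(method, s)],
                "n_flagged": result.n_flagged[(method, s)],
            }
            for (method, s) in result.rejection_rate
        },
        indent=2,
    )
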