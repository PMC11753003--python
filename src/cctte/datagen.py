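"""Simulation of clustered exponential time-to-event trial data.

A two-arm cluster randomized trial has ``g`` clusters per arm and ``n``
subjects per cluster.  Latent event times are exponential with subject rate

    lambda_ij = lambda0 * gamma_i * exp(x_i' beta + T_i * log(delta)),

where ``gamma_i`` is a mean-one gamma frailty shared by cluster ``i``,
``x_i`` are binary cluster-level covariates, ``T_i`` is the treatment
indicator and ``delta`` the treatment hazard ratio.  All subjects still
event-free at the administrative censoring time ``tau`` are censored there.
The baseline hazard ``lambda0`` is calibrated so that a reference subject
(x = 0, T = 0, gamma = 1) has a stated cumulative event probability by
``tau``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrialDesign",
    "TrialDataset",
    "FrailtyVector",
    "solve_baseline_hazard",
    "draw_cluster_covariates",
    "draw_frailties",
    "simulate_trial",
    "empirical_icc",
]


def solve_baseline_hazard(cum_incidence: float, tau: float) -> float:
    """Baseline rate ``lambda0`` giving ``1 - exp(-lambda0*tau) = cum_incidence``.

    Parameters
    ----------
    cum_incidence : float
        Target cumulative event probability by time ``tau`` for a reference
        subject, in ``[0, 1)``.
    tau : float
        Follow-up horizon (years), positive.
    """
    if not 0.0 <= cum_incidence < 1.0:
        raise ValueError(
            f"cumulative incidence must be in [0, 1), got {cum_incidence}"
        )
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    return -np.log1p(-cum_incidence) / tau


@dataclass(frozen=True)
class TrialDesign:
    """Scenario parameters for one simulated trial configuration.

    ``beta`` may be given as a scalar, which is broadcast to all
    ``num_covariates`` coefficients; the stored value is always a vector.
    ``lambda0`` is derived from ``(baseline_cum_incidence, tau)`` rather
    than stored as a free parameter.
    """

    g: int
    n: int = 100
    num_covariates: int = 4
    covariate_prob: float = 0.3
    tau: float = 2.0
    baseline_cum_incidence: float = 0.25
    delta: float = 1.0
    beta: np.ndarray | float = 0.0
    frailty_var: float = 0.0

    def __post_init__(self) -> None:
        if self.g < 2:
            raise ValueError(f"need at least 2 clusters per arm, got g={self.g}")
        if self.n < 1:
            raise ValueError(f"cluster size must be >= 1, got n={self.n}")
        if not 0.0 < self.baseline_cum_incidence < 1.0:
            raise ValueError("baseline_cum_incidence must be in (0, 1)")
        if self.delta <= 0:
            raise ValueError(f"hazard ratio delta must be positive, got {self.delta}")
        if self.frailty_var < 0:
            raise ValueError(f"frailty variance must be >= 0, got {self.frailty_var}")
        if not 0.0 <= self.covariate_prob <= 1.0:
            raise ValueError("covariate_prob must be in [0, 1]")
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if beta.size == 1:
            beta = np.full(self.num_covariates, beta.item())
        if beta.shape != (self.num_covariates,):
            raise ValueError(
                f"beta must be scalar or length {self.num_covariates}, got shape {beta.shape}"
            )
        beta.setflags(write=False)
        object.__setattr__(self, "beta", beta)

    @property
    def num_clusters(self) -> int:
        return 2 * self.g

    @property
    def lambda0(self) -> float:
        return solve_baseline_hazard(self.baseline_cum_incidence, self.tau)


@dataclass(frozen=True)
class FrailtyVector:
    """Per-cluster multiplicative hazard frailties (positive, mean one)."""

    gamma: np.ndarray

    def __post_init__(self) -> None:
        gamma = np.asarray(self.gamma, dtype=float)
        if gamma.ndim != 1 or np.any(gamma <= 0):
            raise ValueError("frailties must be a 1-d vector of positive values")
        gamma.setflags(write=False)
        object.__setattr__(self, "gamma", gamma)

    def __len__(self) -> int:
        return len(self.gamma)


@dataclass
class TrialDataset:
    """Subject-level trial records.

    Attributes
    ----------
    cluster_id : array of int, 1..2g
    subject_id : array of int, 1..n within cluster
    time : observed follow-up (min of latent time and ``tau``)
    event : 1 if the latent event time was <= ``tau``, else 0
    x : (n_subjects, K) binary cluster-level covariates, constant in cluster
    arm : treatment indicator per subject (constant in cluster), or None
        before randomization
    latent_time : pre-censoring event times; retained so the empirical ICC
        can be measured before administrative censoring. None for datasets
        read from disk.
    """

    cluster_id: np.ndarray
    subject_id: np.ndarray
    time: np.ndarray
    event: np.ndarray
    x: np.ndarray
    arm: np.ndarray | None = None
    latent_time: np.ndarray | None = None
    tau: float | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.time)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.cluster_id))

    @property
    def num_covariates(self) -> int:
        return self.x.shape[1]

    def cluster_index(self) -> np.ndarray:
        """Zero-based cluster index per subject (cluster ids are 1-based)."""
        return np.asarray(self.cluster_id, dtype=int) - 1

    def cluster_covariates(self) -> np.ndarray:
        """(2g, K) cluster-level covariate matrix, one row per cluster."""
        idx = self.cluster_index()
        first = np.zeros(self.n_clusters, dtype=int)
        seen = np.full(self.n_clusters, False)
        for j, c in enumerate(idx):
            if not seen[c]:
                first[c] = j
                seen[c] = True
        return self.x[first]

    def cluster_arms(self) -> np.ndarray:
        if self.arm is None:
            raise ValueError("dataset has no arm labels yet")
        idx = self.cluster_index()
        arms = np.zeros(self.n_clusters, dtype=int)
        arms[idx] = self.arm
        return arms

    def with_arm(self, allocation: np.ndarray) -> "TrialDataset":
        """Return a copy with per-cluster treatment labels attached."""
        allocation = np.asarray(allocation, dtype=int)
        if allocation.shape != (self.n_clusters,):
            raise ValueError("allocation length must equal the number of clusters")
        return TrialDataset(
            cluster_id=self.cluster_id,
            subject_id=self.subject_id,
            time=self.time,
            event=self.event,
            x=self.x,
            arm=allocation[self.cluster_index()],
            latent_time=self.latent_time,
            tau=self.tau,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "cluster_id": self.cluster_id,
            "subject_id": self.subject_id,
            "time": self.time,
            "event": self.event,
        }
        for k in range(self.num_covariates):
            cols[f"x{k + 1}"] = self.x[:, k]
        cols["arm"] = (
            pd.array([pd.NA] * self.n_subjects)
            if self.arm is None
            else self.arm
        )
        return pd.DataFrame(cols)


def draw_cluster_covariates(
    num_clusters: int, p: float, rng: np.random.Generator, num_covariates: int = 4
) -> np.ndarray:
    """Independent Bernoulli(p) cluster-level covariates, shape (num_clusters, K)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"Bernoulli probability must be in [0, 1], got {p}")
    return (rng.random((num_clusters, num_covariates)) < p).astype(np.int8)


def draw_frailties(
    num_clusters: int, frailty_var: float, rng: np.random.Generator
) -> FrailtyVector:
    """Mean-one gamma frailties: Gamma(shape=1/sigma^2, scale=sigma^2).

    ``frailty_var = 0`` returns the all-ones vector exactly (no frailty).
    """
    if frailty_var < 0:
        raise ValueError(f"frailty variance must be >= 0, got {frailty_var}")
    if frailty_var == 0:
        return FrailtyVector(np.ones(num_clusters))
    shape = 1.0 / frailty_var
    return FrailtyVector(rng.gamma(shape=shape, scale=frailty_var, size=num_clusters))


def simulate_trial(
    design: TrialDesign,
    covariates: np.ndarray,
    frailties: FrailtyVector,
    allocation: np.ndarray | None,
    rng: np.random.Generator | None = None,
    *,
    uniforms: np.ndarray | None = None,
) -> TrialDataset:
    """Simulate one trial dataset under the exponential proportional-hazards model.

    Parameters
    ----------
    covariates : (2g, K) binary matrix, one row per cluster.
    frailties : per-cluster positive multipliers, length 2g.
    allocation : per-cluster treatment indicator with g ones and g zeros,
        or None for an unrandomized dataset (treatment hazard term omitted).
    rng : random generator for the latent-time draws. May be omitted when
        ``uniforms`` is supplied.
    uniforms : optional (2g*n,) uniforms used via inverse transform; passing
        the same uniforms across scenario variants yields identical latent
        times whenever the subject rates agree (e.g. across q under delta=1).
    """
    m = design.num_clusters
    covariates = np.asarray(covariates)
    if covariates.shape != (m, design.num_covariates):
        raise ValueError(
            f"covariates must have shape ({m}, {design.num_covariates}), "
            f"got {covariates.shape}"
        )
    if len(frailties) != m:
        raise ValueError(f"expected {m} frailties, got {len(frailties)}")
    if allocation is not None:
        allocation = np.asarray(allocation, dtype=int)
        if allocation.shape != (m,):
            raise ValueError("allocation length must equal 2g")
        if allocation.sum() != design.g or not np.isin(allocation, (0, 1)).all():
            raise ValueError("allocation must assign exactly g clusters to each arm")

    log_rate = np.log(design.lambda0) + np.log(frailties.gamma)
    log_rate = log_rate + covariates @ design.beta
    if allocation is not None:
        log_rate = log_rate + allocation * np.log(design.delta)
    rate = np.exp(log_rate)  # per-cluster subject hazard

    n_sub = m * design.n
    if uniforms is None:
        if rng is None:
            raise ValueError("either rng or uniforms must be provided")
        uniforms = rng.random(n_sub)
    else:
        uniforms = np.asarray(uniforms, dtype=float)
        if uniforms.shape != (n_sub,):
            raise ValueError(f"uniforms must have shape ({n_sub},)")

    cluster_idx = np.repeat(np.arange(m), design.n)
    # inverse-CDF draw; guards U=0 which would give an infinite time
    u = np.clip(uniforms, np.finfo(float).tiny, 1.0)
    latent = -np.log(u) / rate[cluster_idx]
    event = (latent <= design.tau).astype(np.int8)
    time = np.minimum(latent, design.tau)

    return TrialDataset(
        cluster_id=cluster_idx + 1,
        subject_id=np.tile(np.arange(1, design.n + 1), m),
        time=time,
        event=event,
        x=covariates[cluster_idx],
        arm=None if allocation is None else allocation[cluster_idx],
        latent_time=latent,
        tau=design.tau,
    )


def empirical_icc(times: np.ndarray, cluster_ids: np.ndarray) -> float:
    """Empirical intraclass correlation of (pre-censoring) outcomes.

    ICC = sigma2_b / (sigma2_b + sigma2_w), where sigma2_b is the sample
    variance of the cluster means and sigma2_w is the within-cluster sample
    variance averaged over clusters (both with n-1 denominators).
    """
    times = np.asarray(times, dtype=float)
    cluster_ids = np.asarray(cluster_ids)
    labels, inv = np.unique(cluster_ids, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 clusters")
    counts = np.bincount(inv)
    if counts.min() < 2:
        raise ValueError("need at least 2 subjects in every cluster")
    means = np.bincount(inv, weights=times) / counts
    sq = np.bincount(inv, weights=times**2)
    within = (sq - counts * means**2) / (counts - 1)
    sigma2_b = float(np.var(means, ddof=1))
    sigma2_w = float(within.mean())
    total = sigma2_b + sigma2_w
    if total == 0.0:
        raise ValueError("ICC undefined: both variance components are zero")
    return sigma2_b / total
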