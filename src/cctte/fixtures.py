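"""Small reproducible datasets with oracle-computed expectations.

Three fixtures are generated programmatically (nothing is stored on disk):

* ``tiny`` — a six-subject, one-covariate dataset small enough that the
  Breslow partial likelihood can be maximized by brute-force grid search;
  the sidecar carries the grid-search maximizer.
* ``worked`` — a 2g=4, n=3 randomized trial whose permutation space (all
  C(4,2)=6 allocations) is enumerated by plain Python loops, independent of
  the vectorized test implementation; the sidecar carries every null
  statistic and the exact p-value.
* ``null`` — a delta=1, g=8 trial for smoke tests.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .coxcore import cox_snell_residuals, deviance_residuals, fit_cox
from .datagen import TrialDataset, TrialDesign, draw_cluster_covariates, draw_frailties, simulate_trial
from .randomization import enumerate_allocation_space, select_allocation

__all__ = ["make_fixture", "grid_search_cox"]


def grid_search_cox(
    time: np.ndarray,
    event: np.ndarray,
    x: np.ndarray,
    lo: float = -5.0,
    hi: float = 5.0,
    step: float = 1e-4,
) -> float:
    """Brute-force maximizer of the one-covariate Breslow partial likelihood.

    Written as a direct transcription of the partial-likelihood definition
    (event terms over risk-set sums), independent of the Newton fitter it
    oracles.
    """
    time = np.asarray(time, float)
    event = np.asarray(event)
    x = np.asarray(x, float)
    grid = np.arange(lo, hi + step / 2, step)
    ll = np.zeros_like(grid)
    for j in np.flatnonzero(event == 1):
        at_risk = time >= time[j]
        # log sum_{k at risk} exp(beta * x_k), vectorized over the grid
        xr = x[at_risk]
        mats = np.exp(np.outer(grid, xr))
        ll += grid * x[j] - np.log(mats.sum(axis=1))
    return float(grid[np.argmax(ll)])


def _tiny() -> tuple[TrialDataset, dict]:
    # chosen so the one-covariate partial likelihood has an interior maximum
    # (an x=0 event with x=1 subjects at risk bounds the likelihood above)
    time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    event = np.array([1, 1, 0, 1, 0, 1], dtype=np.int8)
    x = np.array([[1], [0], [1], [1], [0], [0]], dtype=np.int8)
    ds = TrialDataset(
        cluster_id=np.arange(1, 7),
        subject_id=np.ones(6, dtype=int),
        time=time,
        event=event,
        x=x,
        arm=None,
    )
    sidecar = {
        "beta_grid_search": grid_search_cox(time, event, x[:, 0]),
        "provenance": "grid search of the Breslow partial likelihood over "
        "beta in [-5, 5], step 1e-4",
    }
    return ds, sidecar


def _worked(seed: int) -> tuple[TrialDataset, dict]:
    design = TrialDesign(g=2, n=3, num_covariates=1, beta=0.5, delta=1.0,
                         baseline_cum_incidence=0.5)
    rng = np.random.default_rng(seed)
    x = draw_cluster_covariates(4, 0.5, rng, num_covariates=1)
    if np.ptp(x[:, 0]) == 0:  # keep the covariate informative
        x[0, 0] = 1 - x[0, 0]
    gamma = draw_frailties(4, 0.0, rng)
    space = enumerate_allocation_space(4)
    allocation = select_allocation(space, rng)
    ds = simulate_trial(design, x, gamma, allocation, rng)

    # brute-force oracle: plain loops over all 6 allocations
    fit = fit_cox(ds, covariate_count=0, include_treatment=False, cluster_robust=False)
    rd = deviance_residuals(cox_snell_residuals(fit), ds.event)
    rbar = [float(np.mean(rd[ds.cluster_id == c])) for c in (1, 2, 3, 4)]
    stats = []
    for ones in combinations(range(4), 2):
        t = [1 if i in ones else 0 for i in range(4)]
        stats.append(sum((2 * t[i] - 1) * rbar[i] for i in range(4)) / 2)
    obs = ds.cluster_arms()
    s_obs = sum((2 * obs[i] - 1) * rbar[i] for i in range(4)) / 2
    p = sum(1 for s in stats if abs(s) >= abs(s_obs) - 1e-12) / len(stats)
    sidecar = {
        "space_size": len(stats),
        "cluster_residual_means": rbar,
        "null_stats": stats,
        "statistic": float(s_obs),
        "p_value": float(p),
        "provenance": "plain-Python enumeration of all C(4,2)=6 allocations",
    }
    return ds, sidecar


def _null(seed: int) -> tuple[TrialDataset, dict]:
    design = TrialDesign(g=8, n=25, delta=1.0, beta=0.0)
    rng = np.random.default_rng(seed)
    x = draw_cluster_covariates(16, design.covariate_prob, rng)
    gamma = draw_frailties(16, 0.0, rng)
    ones = rng.permutation(16)[:8]
    allocation = np.zeros(16, dtype=np.int8)
    allocation[ones] = 1
    ds = simulate_trial(design, x, gamma, allocation, rng)
    return ds, {"delta": 1.0, "provenance": "smoke-test null trial, g=8, n=25"}


def make_fixture(kind: str, seed: int = 0) -> tuple[TrialDataset, dict]:
    """Return (dataset, expected-values sidecar) for ``kind`` in
    {'tiny', 'worked', 'null'}.  Identical seeds give identical fixtures."""
    if kind == "tiny":
        return _tiny()
    if kind == "worked":
        return _worked(seed)
    if kind == "null":
        return _null(seed)
    raise ValueError(f"unknown fixture kind {kind!r}")
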