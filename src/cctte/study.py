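"""Preset scenarios for the headline simulation-study quantities.

These helpers pin down the study conditions used throughout the package's
own reproduction runs: g clusters per arm with n = 100 subjects each, four
Bernoulli(0.3) cluster-level covariates, a 25% two-year baseline cumulative
incidence with administrative censoring at tau = 2 years, 20,000 sampled
allocation schemes per trial, and either prognostic covariates (beta > 0 on
all four, no frailty) or non-prognostic covariates (beta = 0, mean-one
gamma frailty).  Each function runs the Monte-Carlo engine from scratch and
returns the measured quantity.
"""

from __future__ import annotations

import numpy as np

from .datagen import FrailtyVector, TrialDesign, simulate_trial
from .engine import Scenario, ScenarioResult, run_scenario

__all__ = [
    "type1_scenario",
    "power_scenario",
    "rejection_rate",
    "baseline_event_percent",
    "min_power_percent",
    "mean_permutation_power_percent",
]


def type1_scenario(
    *,
    g: int = 8,
    beta: float = 0.25,
    sigma2: float = 0.0,
    q: float = 1.0,
    method: str,
    s: int,
    n_sim: int = 500,
    seed: int,
) -> Scenario:
    """A null-hypothesis (delta = 1) cell of the rejection-rate study."""
    design = TrialDesign(g=g, n=100, delta=1.0, beta=beta, frailty_var=sigma2)
    return Scenario(
        design=design, q=q, methods=(method,), s_values=(s,), n_sim=n_sim, seed=seed
    )


def power_scenario(
    *,
    g: int = 8,
    beta: float = 0.0,
    sigma2: float = 0.0,
    q: float = 0.10,
    methods=("cox_robust", "cox_frailty", "permutation"),
    s_values=(0, 1, 2, 3, 4),
    n_sim: int = 300,
    seed: int,
) -> Scenario:
    """A delta = 0.5 (50% efficacy) cell of the power study."""
    design = TrialDesign(g=g, n=100, delta=0.5, beta=beta, frailty_var=sigma2)
    return Scenario(
        design=design, q=q, methods=tuple(methods), s_values=tuple(s_values),
        n_sim=n_sim, seed=seed,
    )


def rejection_rate(scenario: Scenario) -> tuple[float, float, ScenarioResult]:
    """Run a single-cell scenario; returns (rate, mcse, full result)."""
    result = run_scenario(scenario)
    ((key, rate),) = result.rejection_rate.items()
    return rate, result.mcse[key], result


def baseline_event_percent(seed: int, n_subjects: int = 100_000) -> float:
    """Percent of reference subjects (x = 0, T = 0, gamma = 1) with an event
    by the end of follow-up under the calibrated baseline hazard."""
    per_cluster = n_subjects // 4
    design = TrialDesign(g=2, n=per_cluster)
    rng = np.random.default_rng(seed)
    ds = simulate_trial(
        design,
        np.zeros((4, 4), dtype=np.int8),
        FrailtyVector(np.ones(4)),
        np.array([1, 0, 1, 0]),
        rng,
    )
    return 100.0 * float(np.mean(ds.event))


def min_power_percent(result: ScenarioResult) -> float:
    """Smallest rejection percentage over every (method, S) cell."""
    return 100.0 * min(result.rejection_rate.values())


def mean_permutation_power_percent(result: ScenarioResult) -> float:
    """Permutation-test rejection percentage averaged over S."""
    vals = [v for (m, _), v in result.rejection_rate.items() if m == "permutation"]
    return 100.0 * float(np.mean(vals))
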