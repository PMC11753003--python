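"""Monte-Carlo orchestration of the type-I-error / power simulation study.

One replicate draws the cluster covariates and frailties, builds the
candidate allocation space from 20,000 sampled schemes (duplicates
removed), scores and constrains it, selects the trial allocation, simulates
outcomes, and runs each requested analysis at each level of covariate
adjustment S.  The same covariate matrix, frailties and latent-time
uniforms are produced for a given (master seed, replicate index) regardless
of the constraint percentile q, so simple and constrained runs of the same
scenario analyze the same underlying data.

Replicate ``i`` always consumes the random substream derived from
``(seed, i)``, so results do not depend on worker scheduling when
replicates are run in parallel.

Non-converged model fits are recorded and excluded from that method's
rejection-rate denominator (counting them either way would bias rates
invisibly); flagged counts are reported alongside each rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coxcore import fit_cox, wald_reject
from .datagen import (
    TrialDataset,
    TrialDesign,
    draw_cluster_covariates,
    draw_frailties,
    simulate_trial,
)
from .frailty import fit_mixed_cox, mixed_wald_reject
from .permtest import permutation_test
from .randomization import (
    AllocationSpace,
    constrain,
    sample_allocation_space,
    score_space,
    select_allocation,
)

__all__ = [
    "Scenario",
    "ScenarioResult",
    "METHODS",
    "mcse",
    "run_replicate",
    "run_scenario",
    "scenario_grid",
    "analyze_dataset",
]

METHODS = ("cox_robust", "cox_frailty", "permutation")
DEFAULT_ALLOC_DRAWS = 20_000


def mcse(p_hat: float, n_sim: int) -> float:
    """Monte-Carlo standard error of a simulated proportion: sqrt(p(1-p)/n)."""
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError("proportion must be in [0, 1]")
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    return float(np.sqrt(p_hat * (1.0 - p_hat) / n_sim))


@dataclass(frozen=True)
class Scenario:
    """One cell of the simulation grid."""

    design: TrialDesign
    q: float = 1.0
    methods: tuple[str, ...] = METHODS
    s_values: tuple[int, ...] = (0, 1, 2, 3, 4)
    n_sim: int = 1000
    seed: int = 20240901
    n_alloc_draws: int = DEFAULT_ALLOC_DRAWS
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        if not 0.0 < self.q <= 1.0:
            raise ValueError("q must be in (0, 1]")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        bad_s = [s for s in self.s_values if not 0 <= s <= self.design.num_covariates]
        if bad_s:
            raise ValueError(f"S values out of range: {bad_s}")


@dataclass
class ScenarioResult:
    """Rejection rate and MCSE per (method, S) cell, with flagged-fit counts."""

    scenario: Scenario
    rejection_rate: dict[tuple[str, int], float]
    mcse: dict[tuple[str, int], float]
    n_used: dict[tuple[str, int], int]
    n_flagged: dict[tuple[str, int], int]

    def to_frame(self) -> pd.DataFrame:
        d = self.scenario.design
        rows = []
        for (method, s), rate in self.rejection_rate.items():
            rows.append(
                {
                    "g": d.g,
                    "n": d.n,
                    "delta": d.delta,
                    "beta": d.beta[0],
                    "sigma2": d.frailty_var,
                    "q": self.scenario.q,
                    "method": method,
                    "S": s,
                    "reject_rate": rate,
                    "mcse": self.mcse[(method, s)],
                    "n_sim": self.scenario.n_sim,
                    "n_used": self.n_used[(method, s)],
                    "n_flagged": self.n_flagged[(method, s)],
                }
            )
        return pd.DataFrame(rows)


def _replicate_rngs(seed: int, rep: int) -> dict[str, np.random.Generator]:
    """Independent substreams per replicate; replicate identity fixes them."""
    children = np.random.SeedSequence(entropy=(seed, rep)).spawn(5)
    names = ("covariates", "frailties", "uniforms", "space", "select")
    return {k: np.random.default_rng(c) for k, c in zip(names, children)}


def generate_replicate(
    scenario: Scenario, rep: int
) -> tuple[TrialDataset, AllocationSpace, np.ndarray]:
    """Data-generation half of one replicate: dataset, scored+constrained
    allocation space, and the selected treatment allocation."""
    d = scenario.design
    rngs = _replicate_rngs(scenario.seed, rep)
    x = draw_cluster_covariates(
        d.num_clusters, d.covariate_prob, rngs["covariates"], d.num_covariates
    )
    gamma = draw_frailties(d.num_clusters, d.frailty_var, rngs["frailties"])
    space = sample_allocation_space(d.num_clusters, scenario.n_alloc_draws, rngs["space"])
    space = score_space(space, x, skip_degenerate=True)
    space = constrain(space, scenario.q)
    allocation = select_allocation(space, rngs["select"])
    uniforms = rngs["uniforms"].random(d.num_clusters * d.n)
    dataset = simulate_trial(d, x, gamma, allocation, uniforms=uniforms)
    return dataset, space, allocation


def analyze_dataset(
    dataset: TrialDataset,
    space: AllocationSpace,
    method: str,
    covariate_count: int,
    alpha: float = 0.05,
) -> bool | None:
    """One analysis decision; None flags a non-converged fit."""
    if method == "cox_robust":
        fit = fit_cox(
            dataset, covariate_count, include_treatment=True, cluster_robust=True
        )
        if not fit.converged:
            return None
        return wald_reject(fit, variance="robust", level=1 - alpha).reject
    if method == "cox_frailty":
        fit = fit_mixed_cox(dataset, covariate_count, include_treatment=True)
        if not fit.converged:
            return None
        return mixed_wald_reject(fit, level=1 - alpha).reject
    if method == "permutation":
        null_fit = fit_cox(
            dataset, covariate_count, include_treatment=False, cluster_robust=False
        )
        if not null_fit.converged:
            return None
        return permutation_test(
            dataset, space, covariate_count, use_constrained=True,
            alpha=alpha, null_fit=null_fit,
        ).reject
    raise ValueError(f"unknown method {method!r}")


def run_replicate(scenario: Scenario, rep: int) -> dict[tuple[str, int], bool | None]:
    """Run every requested (method, S) analysis on replicate ``rep``."""
    dataset, space, _ = generate_replicate(scenario, rep)
    out: dict[tuple[str, int], bool | None] = {}
    for s in scenario.s_values:
        for method in scenario.methods:
            out[(method, s)] = analyze_dataset(
                dataset, space, method, s, scenario.alpha
            )
    return out


def run_scenario(scenario: Scenario, n_jobs: int = 1) -> ScenarioResult:
    """Aggregate rejection rates and MCSE over ``n_sim`` replicates."""
    if n_jobs == 1:
        flag_lists = [run_replicate(scenario, rep) for rep in range(scenario.n_sim)]
    else:
        from joblib import Parallel, delayed

        flag_lists = Parallel(n_jobs=n_jobs)(
            delayed(run_replicate)(scenario, rep) for rep in range(scenario.n_sim)
        )
    keys = [(m, s) for s in scenario.s_values for m in scenario.methods]
    rate: dict[tuple[str, int], float] = {}
    err: dict[tuple[str, int], float] = {}
    used: dict[tuple[str, int], int] = {}
    flagged: dict[tuple[str, int], int] = {}
    for key in keys:
        flags = [r[key] for r in flag_lists]
        valid = [f for f in flags if f is not None]
        n_valid = len(valid)
        used[key] = n_valid
        flagged[key] = len(flags) - n_valid
        p = float(np.mean(valid)) if n_valid else float("nan")
        rate[key] = p
        err[key] = mcse(p, n_valid) if n_valid else float("nan")
    return ScenarioResult(scenario, rate, err, used, flagged)


def scenario_grid(config: dict) -> list[Scenario]:
    """Expand a configuration into the study's scenario grid.

    The grid is the Cartesian product of ``deltas`` x ``g_values`` x
    ``q_values`` with the covariate settings, where a setting is either
    prognostic (beta > 0, no frailty) or non-prognostic (beta = 0, gamma
    frailty): ``betas`` lists prognostic coefficient values (paired with
    sigma2 = 0) and ``sigma2s`` lists non-prognostic frailty variances
    (paired with beta = 0).  Explicit ``settings`` entries pairing beta > 0
    with sigma2 > 0 are rejected: the covariate effect already drives the
    between-cluster variance, and stacking a frailty on top makes the
    prognostic/non-prognostic comparison uninterpretable.
    """
    deltas = list(config.get("deltas", [1.0, 0.5]))
    g_values = list(config.get("g_values", [8, 13]))
    q_values = list(config.get("q_values", [1.0, 0.10, 0.01]))
    settings: list[tuple[float, float]] = []
    for b in config.get("betas", []):
        settings.append((float(b), 0.0))
    for s2 in config.get("sigma2s", []):
        settings.append((0.0, float(s2)))
    for pair in config.get("settings", []):
        settings.append((float(pair["beta"]), float(pair["sigma2"])))
    if not settings:
        raise ValueError("config lists no covariate settings (betas/sigma2s)")
    for b, s2 in settings:
        if b > 0 and s2 > 0:
            raise ValueError(
                f"invalid pairing beta={b}, sigma2={s2}: a prognostic covariate "
                "effect already induces between-cluster variance, and adding a "
                "frailty on top makes interpretation of comparisons impossible"
            )
    base = dict(
        n=int(config.get("n", 100)),
        baseline_cum_incidence=float(config.get("baseline_cum_incidence", 0.25)),
        tau=float(config.get("tau", 2.0)),
        covariate_prob=float(config.get("covariate_prob", 0.3)),
    )
    n_sim = int(config.get("n_sim", 1000))
    seed = int(config.get("seed", 20240901))
    methods = tuple(config.get("methods", METHODS))
    s_values = tuple(config.get("s_values", (0, 1, 2, 3, 4)))
    out = []
    for g in g_values:
        for delta in deltas:
            for beta, s2 in settings:
                for q in q_values:
                    design = TrialDesign(
                        g=int(g), delta=float(delta), beta=beta, frailty_var=s2, **base
                    )
                    out.append(
                        Scenario(
                            design=design,
                            q=float(q),
                            methods=methods,
                            s_values=s_values,
                            n_sim=n_sim,
                            seed=seed,
                        )
                    )
    return out
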