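"""Permutation test for clustered survival data based on deviance residuals.

A Cox model is fitted under the null hypothesis (no treatment term, with
the design-phase balancing covariates optionally adjusted for), deviance
residuals are averaged within clusters, and the statistic

    S = g^{-1} sum_i (2 T_i - 1) rbar_i

(the scaled difference of cluster-mean residuals between arms) is referred
to its permutation distribution.  Because the null fit does not involve the
treatment labels, the residual means are computed once per dataset and the
permutation re-labels ``T_i`` over the randomization space actually used by
the design: the full deduplicated space under simple randomization, or the
constrained subset under constrained randomization.  The two-sided p-value
counts allocations with |S*| >= |S_obs|, the observed allocation included,
so p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coxcore import CoxFit, cox_snell_residuals, deviance_residuals, fit_cox
from .datagen import TrialDataset
from .randomization import AllocationSpace

__all__ = [
    "PermutationResult",
    "cluster_residual_means",
    "statistic_S",
    "permutation_pvalue",
    "permutation_test",
]

_TIE_EPS = 1e-12


@dataclass
class PermutationResult:
    statistic: float
    null_stats: np.ndarray
    p_value: float
    space_size: int
    reject: bool
    alpha: float = 0.05


def cluster_residual_means(
    residuals: np.ndarray, cluster_ids: np.ndarray
) -> np.ndarray:
    """Arithmetic mean of (deviance) residuals within each cluster."""
    residuals = np.asarray(residuals, dtype=float)
    ids = np.asarray(cluster_ids)
    labels, inv = np.unique(ids, return_inverse=True)
    counts = np.bincount(inv)
    if counts.min() == 0:
        raise ValueError("empty cluster in residual means")
    return np.bincount(inv, weights=residuals) / counts


def statistic_S(assignment: np.ndarray, rbar: np.ndarray, g: int) -> float:
    """S = g^{-1} sum_i (2 T_i - 1) rbar_i; antisymmetric under arm swap."""
    assignment = np.asarray(assignment, dtype=float)
    rbar = np.asarray(rbar, dtype=float)
    if assignment.shape != rbar.shape:
        raise ValueError("assignment and rbar must have matching length")
    if assignment.sum() != g or len(assignment) != 2 * g:
        raise ValueError("assignment must place exactly g of 2g clusters per arm")
    return float((2 * assignment - 1) @ rbar / g)


def permutation_pvalue(
    rbar: np.ndarray,
    space: AllocationSpace,
    observed: np.ndarray,
    use_constrained: bool = True,
    alpha: float = 0.05,
) -> PermutationResult:
    """Two-sided permutation p-value of the observed allocation's statistic.

    The reference set is the constrained subset when ``use_constrained`` and
    the full deduplicated space otherwise; the observed allocation (or its
    arm-swapped mirror, which carries the same |S|) must be a member,
    otherwise the analysis does not match the design that produced the data.
    """
    observed = np.asarray(observed, dtype=np.int8)
    g = space.g
    perms = (
        space.constrained_assignments() if use_constrained else space.assignments
    )
    member = (perms == observed).all(axis=1).any() or (
        (perms == 1 - observed).all(axis=1).any()
    )
    if not member:
        raise ValueError(
            "observed allocation is not in the permutation space; "
            "the analysis space must match the randomization actually used"
        )
    s_obs = statistic_S(observed, rbar, g)
    null_stats = (2.0 * perms - 1.0) @ np.asarray(rbar, dtype=float) / g
    p = float(np.mean(np.abs(null_stats) >= abs(s_obs) - _TIE_EPS))
    return PermutationResult(
        statistic=s_obs,
        null_stats=null_stats,
        p_value=p,
        space_size=len(null_stats),
        reject=bool(p <= alpha),
        alpha=alpha,
    )


def permutation_test(
    dataset: TrialDataset,
    space: AllocationSpace,
    covariate_count: int = 0,
    use_constrained: bool = True,
    alpha: float = 0.05,
    null_fit: CoxFit | None = None,
) -> PermutationResult:
    """End-to-end permutation test on an arm-labeled dataset.

    Fits the treatment-free null Cox model with ``covariate_count``
    adjustment covariates, converts its Cox-Snell residuals to deviance
    residuals, and refers the cluster-mean statistic to the permutation
    space.  A pre-computed ``null_fit`` may be supplied to share the fit
    across analyses.
    """
    if dataset.arm is None:
        raise ValueError("dataset has no arm labels")
    fit = null_fit
    if fit is None:
        fit = fit_cox(
            dataset, covariate_count, include_treatment=False, cluster_robust=False
        )
    rd = deviance_residuals(cox_snell_residuals(fit), dataset.event)
    rbar = cluster_residual_means(rd, dataset.cluster_id)
    observed = dataset.cluster_arms()
    return permutation_pvalue(rbar, space, observed, use_constrained, alpha)
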