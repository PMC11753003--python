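"""Candidate allocation spaces for covariate-constrained cluster randomization.

An allocation assigns ``g`` of the ``2g`` clusters to each arm.  The
candidate space is either fully enumerated (small ``2g``) or built from a
large number of uniform draws with duplicates removed.  Two mutually
exclusive balance strategies are provided:

* an inverse-variance-weighted imbalance score
  ``B = sum_k w_k (xbar_Ak - xbar_Bk)^2`` with ``w_k = 1/var_k``, keeping
  allocations whose score falls in the bottom ``q`` percentile; and
* per-covariate ratio bounds (arm-A mean over arm-B mean inside an
  interval), optionally with a categorical count-balance rule — the scheme
  used by the motivating vector-control trial.

A validity check reports, for every cluster pair, how often the pair is
co-assigned across the retained allocations; pairs co-assigned in <=25% or
>=75% of allocations are flagged as constrained designs that no longer
randomize those clusters (almost) independently.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import comb

import numpy as np

__all__ = [
    "AllocationSpace",
    "ValidityReport",
    "enumerate_allocation_space",
    "sample_allocation_space",
    "imbalance_score",
    "score_space",
    "constrain",
    "ratio_balance_filter",
    "check_validity",
    "select_allocation",
    "mirror",
]

ENUMERATION_LIMIT = 10**6


def mirror(assignment: np.ndarray) -> np.ndarray:
    """The arm-swapped complement of an assignment."""
    return 1 - np.asarray(assignment)


@dataclass
class AllocationSpace:
    """A deduplicated set of candidate g-of-2g assignments.

    ``assignments`` has one allocation per row (values 0/1, row sums g).
    ``scores`` and ``constrained_mask`` are attached by :func:`score_space`
    and :func:`constrain` / :func:`ratio_balance_filter`.
    """

    assignments: np.ndarray
    scores: np.ndarray | None = None
    q: float | None = None
    constrained_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.assignments, dtype=np.int8)
        if a.ndim != 2:
            raise ValueError("assignments must be a 2-d array")
        g = a.shape[1] // 2
        if a.shape[1] != 2 * g or not (a.sum(axis=1) == g).all():
            raise ValueError("every assignment must place exactly g of 2g clusters per arm")
        self.assignments = a

    @property
    def size(self) -> int:
        return self.assignments.shape[0]

    @property
    def num_clusters(self) -> int:
        return self.assignments.shape[1]

    @property
    def g(self) -> int:
        return self.num_clusters // 2

    def constrained_assignments(self) -> np.ndarray:
        """Rows of the retained (constrained) subset; full space if unconstrained."""
        if self.constrained_mask is None:
            return self.assignments
        return self.assignments[self.constrained_mask]

    @property
    def constrained_size(self) -> int:
        if self.constrained_mask is None:
            return self.size
        return int(self.constrained_mask.sum())


@dataclass
class ValidityReport:
    """Pairwise co-assignment proportions over a (constrained) space."""

    coassignment: np.ndarray
    flagged_pairs: list[tuple[int, int]]

    @property
    def valid(self) -> bool:
        return not self.flagged_pairs


def _pack(assignments: np.ndarray) -> np.ndarray:
    """Encode each 0/1 row as one integer (requires 2g <= 63)."""
    m = assignments.shape[1]
    if m > 63:
        raise ValueError("packing supports at most 63 clusters")
    powers = (1 << np.arange(m, dtype=np.int64))
    return assignments.astype(np.int64) @ powers


def enumerate_allocation_space(num_clusters: int) -> AllocationSpace:
    """All C(2g, g) balanced assignments (small designs only)."""
    if num_clusters % 2 != 0 or num_clusters < 4:
        raise ValueError("num_clusters must be an even number >= 4")
    g = num_clusters // 2
    total = comb(num_clusters, g)
    if total > ENUMERATION_LIMIT:
        raise ValueError(
            f"C({num_clusters},{g}) = {total} allocations exceeds the "
            f"enumeration limit {ENUMERATION_LIMIT}; use sample_allocation_space"
        )
    from itertools import combinations

    out = np.zeros((total, num_clusters), dtype=np.int8)
    for row, ones in enumerate(combinations(range(num_clusters), g)):
        out[row, list(ones)] = 1
    return AllocationSpace(out)


def sample_allocation_space(
    num_clusters: int, n_draws: int, rng: np.random.Generator
) -> AllocationSpace:
    """``n_draws`` uniform g-of-2g assignments with duplicates removed.

    This mirrors the generation procedure of the simulation study: a fixed
    number of candidate schemes is drawn (with replacement) and reduced to
    its unique members, so for small 2g the space is close to, but not
    exactly, the full enumeration.
    """
    if num_clusters % 2 != 0 or num_clusters < 4:
        raise ValueError("num_clusters must be an even number >= 4")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    g = num_clusters // 2
    u = rng.random((n_draws, num_clusters))
    ones = np.argpartition(u, g - 1, axis=1)[:, :g]
    a = np.zeros((n_draws, num_clusters), dtype=np.int8)
    np.put_along_axis(a, ones, 1, axis=1)
    if num_clusters <= 63:
        _, keep = np.unique(_pack(a), return_index=True)
        a = a[np.sort(keep)]
    else:
        a = np.unique(a, axis=0)
    return AllocationSpace(a)


def _covariate_weights(covariates: np.ndarray, skip_degenerate: bool) -> np.ndarray:
    """Inverse-variance weights; degenerate covariates get weight 0 or raise."""
    var = covariates.var(axis=0, ddof=1)
    weights = np.zeros_like(var, dtype=float)
    for k, v in enumerate(var):
        if v == 0.0:
            if not skip_degenerate:
                raise ValueError(
                    f"covariate {k + 1} is constant across clusters; "
                    "its inverse-variance weight is undefined"
                )
            # a constant covariate is perfectly balanced under every
            # allocation, so its limiting score contribution is zero
        else:
            weights[k] = 1.0 / v
    return weights


def imbalance_score(allocation: np.ndarray, covariates: np.ndarray) -> float:
    """Inverse-variance-weighted squared difference of arm covariate means.

    ``covariates`` is the (2g, K) cluster-level matrix; variances use the
    (2g - 1) sample denominator.
    """
    allocation = np.asarray(allocation, dtype=float)
    covariates = np.asarray(covariates, dtype=float)
    g = allocation.sum()
    if g * 2 != len(allocation):
        raise ValueError("allocation must place exactly g of 2g clusters per arm")
    w = _covariate_weights(covariates, skip_degenerate=False)
    mean_a = allocation @ covariates / g
    mean_b = (1 - allocation) @ covariates / g
    return float(w @ (mean_a - mean_b) ** 2)


def score_space(
    space: AllocationSpace,
    covariates: np.ndarray,
    *,
    skip_degenerate: bool = False,
) -> AllocationSpace:
    """Attach the imbalance score of every allocation in the space.

    ``skip_degenerate=True`` assigns zero-variance covariates a zero score
    contribution instead of raising (used by the simulation engine, where a
    Bernoulli covariate draw occasionally comes out constant).
    """
    covariates = np.asarray(covariates, dtype=float)
    if covariates.shape[0] != space.num_clusters:
        raise ValueError("covariate matrix rows must match the number of clusters")
    w = _covariate_weights(covariates, skip_degenerate=skip_degenerate)
    a = space.assignments.astype(float)
    g = space.g
    diff = (a @ covariates - (1 - a) @ covariates) / g
    scores = diff**2 @ w
    return replace(space, scores=scores)


def constrain(space: AllocationSpace, q: float) -> AllocationSpace:
    """Keep allocations with score at or below the empirical q-quantile.

    The cutoff is the ``ceil(q*M)``-th smallest score with inclusive
    comparison, so ties at the cutoff are all retained and the constrained
    set is never empty.  ``q = 1`` keeps the full space (simple
    randomization).
    """
    if space.scores is None:
        raise ValueError("space has no scores; call score_space first")
    if not 0.0 < q <= 1.0:
        raise ValueError(f"q must be in (0, 1], got {q}")
    k = max(1, int(np.ceil(q * space.size)))
    cutoff = np.partition(space.scores, k - 1)[k - 1]
    mask = space.scores <= cutoff
    return replace(space, q=q, constrained_mask=mask)


def ratio_balance_filter(
    space: AllocationSpace,
    covariates: np.ndarray,
    lower: float = 1 / 1.1,
    upper: float = 1.1,
    count_covariate: np.ndarray | None = None,
    count_tolerance: int = 1,
) -> AllocationSpace:
    """Ratio-based constraint: arm-A/arm-B covariate mean ratio in (lower, upper).

    For every covariate, an allocation is retained only when
    ``mean_A / mean_B`` lies strictly inside ``(lower, upper)``.  Allocations
    with a zero arm mean on any covariate are excluded (the ratio is
    undefined; the exclusion reason is recorded on the returned space as
    ``exclusion_reasons``).  When ``count_covariate`` (per-cluster
    categorical labels) is given, per-category cluster counts must also
    differ between arms by at most ``count_tolerance``.
    """
    covariates = np.asarray(covariates, dtype=float)
    if covariates.shape[0] != space.num_clusters:
        raise ValueError("covariate matrix rows must match the number of clusters")
    a = space.assignments.astype(float)
    g = space.g
    mean_a = a @ covariates / g
    mean_b = (1 - a) @ covariates / g
    reasons: dict[int, str] = {}
    zero = (mean_a <= 0) | (mean_b <= 0)
    ok = ~zero.any(axis=1)
    for i in np.flatnonzero(~ok):
        k = int(np.argmax(zero[i]))
        reasons[i] = f"covariate {k + 1} has a zero arm mean; ratio undefined"
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mean_a / mean_b
    in_band = (ratio > lower) & (ratio < upper)
    ok &= np.where(zero, False, in_band).all(axis=1)

    if count_covariate is not None:
        labels = np.asarray(count_covariate)
        if labels.shape != (space.num_clusters,):
            raise ValueError("count_covariate must have one label per cluster")
        for cat in np.unique(labels):
            ind = (labels == cat).astype(float)
            diff = np.abs(a @ ind - (1 - a) @ ind)
            ok &= diff <= count_tolerance

    if not ok.any():
        raise ValueError("ratio balance filter excluded every allocation")
    out = replace(space, constrained_mask=ok)
    out.exclusion_reasons = reasons  # type: ignore[attr-defined]
    return out


def check_validity(space: AllocationSpace) -> ValidityReport:
    """Pairwise same-arm proportions over the retained allocations.

    Pairs co-assigned in <= 25% or >= 75% of allocations are flagged: the
    constraint has (nearly) hard-wired those clusters together or apart.
    """
    a = space.constrained_assignments().astype(float)
    m = a.shape[0]
    if m == 0:
        raise ValueError("constrained set is empty")
    co = (a.T @ a + (1 - a).T @ (1 - a)) / m
    flagged = [
        (i + 1, j + 1)
        for i in range(space.num_clusters)
        for j in range(i + 1, space.num_clusters)
        if co[i, j] <= 0.25 or co[i, j] >= 0.75
    ]
    return ValidityReport(coassignment=co, flagged_pairs=flagged)


def select_allocation(space: AllocationSpace, rng: np.random.Generator) -> np.ndarray:
    """Draw the trial allocation: uniform over the retained set, then a fair
    coin decides which side is the treatment arm.

    Returns the per-cluster treatment indicator ``T`` (g ones, g zeros).
    """
    candidates = space.constrained_assignments()
    row = candidates[rng.integers(candidates.shape[0])]
    if rng.random() < 0.5:
        return row.copy()
    return mirror(row)
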