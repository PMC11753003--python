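import numpy as np
import pytest
from scipy import stats

from cctte import (
    check_validity,
    constrain,
    enumerate_allocation_space,
    imbalance_score,
    mirror,
    ratio_balance_filter,
    sample_allocation_space,
    score_space,
    select_allocation,
)
from cctte.randomization import AllocationSpace

from conftest import rng_for


def test_enumeration_counts_and_balance():
    space = enumerate_allocation_space(4)
    assert space.size == 6
    assert (space.assignments.sum(axis=1) == 2).all()
    assert enumerate_allocation_space(8).size == 70


def test_sampling_dedups_and_respects_bound():
    rng = rng_for("sampling")
    space = sample_allocation_space(16, 20_000, rng)
    packed = space.assignments @ (1 << np.arange(16))
    assert len(np.unique(packed)) == space.size  # no duplicates survive
    assert space.size <= 12_870  # C(16, 8)
    assert (space.assignments.sum(axis=1) == 8).all()


def test_sampled_members_are_valid_enumeration_members():
    rng = rng_for("membership")
    space = sample_allocation_space(8, 500, rng)
    full = enumerate_allocation_space(8)
    pk = lambda a: set(map(tuple, a))
    assert pk(space.assignments) <= pk(full.assignments)


class TestImbalanceScore:
    def test_perfect_balance_scores_zero(self):
        x = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        assert imbalance_score([1, 0, 1, 0], x) == pytest.approx(0.0)

    def test_hand_example(self):
        # one covariate (1,1,0,0), arms {1,2} vs {3,4}: var 1/3, diff^2 = 1
        x = np.array([[1], [1], [0], [0]], dtype=float)
        assert imbalance_score([1, 1, 0, 0], x) == pytest.approx(3.0)

    def test_mirror_symmetry_over_enumerated_space(self):
        rng = rng_for("mirror")
        for m in (4, 6, 8):
            x = rng.random((m, 4))
            space = score_space(enumerate_allocation_space(m), x)
            for a, s in zip(space.assignments, space.scores):
                assert imbalance_score(mirror(a), x) == pytest.approx(s, rel=1e-10)

    def test_zero_variance_covariate_named_in_error(self):
        x = np.array([[1, 1], [0, 1], [1, 1], [0, 1]], dtype=float)
        with pytest.raises(ValueError, match="covariate 2"):
            imbalance_score([1, 0, 1, 0], x)
        # the engine's scoring path treats it as perfectly balanced instead
        space = score_space(enumerate_allocation_space(4), x, skip_degenerate=True)
        assert np.isfinite(space.scores).all()


class TestConstrain:
    def test_q_one_keeps_everything(self):
        rng = rng_for("q1")
        space = score_space(enumerate_allocation_space(6), rng.random((6, 4)))
        out = constrain(space, 1.0)
        assert out.constrained_mask.all()

    def test_percentile_count_against_sort(self):
        scores = rng_for("pct").permutation(100).astype(float)
        space = AllocationSpace(
            enumerate_allocation_space(10).assignments[:100], scores=scores
        )
        out = constrain(space, 0.10)
        assert out.constrained_mask.sum() == 10
        assert set(scores[out.constrained_mask]) == set(np.sort(scores)[:10])

    def test_all_ties_all_retained(self):
        space = AllocationSpace(
            enumerate_allocation_space(4).assignments, scores=np.ones(6)
        )
        assert constrain(space, 0.01).constrained_mask.all()

    def test_monotone_in_q(self):
        rng = rng_for("monotone")
        space = score_space(sample_allocation_space(12, 2000, rng), rng.random((12, 4)))
        tight = constrain(space, 0.01).constrained_mask
        loose = constrain(space, 0.10).constrained_mask
        assert not (tight & ~loose).any()


class TestRatioFilter:
    def test_identical_means_retained_and_extreme_excluded(self):
        x = np.array([[1, 2], [1, 2], [1, 2], [1, 2]], dtype=float)
        space = enumerate_allocation_space(4)
        out = ratio_balance_filter(space, x)
        assert out.constrained_mask.all()  # ratio exactly 1 everywhere

    def test_out_of_band_ratio_excluded(self):
        # arms {1,2} vs {3,4}: means 1.2 vs 1.0 -> ratio 1.2 outside (0.909, 1.1)
        x = np.array([[1.4], [1.0], [1.4], [1.0]])
        out = ratio_balance_filter(enumerate_allocation_space(4), x)
        bad = np.array([1, 0, 1, 0], dtype=np.int8)
        idx = next(
            i for i, a in enumerate(out.assignments) if np.array_equal(a, bad)
        )
        assert not out.constrained_mask[idx]

    def test_zero_arm_mean_excluded_with_reason(self):
        x = np.array([[1.0], [1.0], [0.0], [0.0]])
        out = ratio_balance_filter(enumerate_allocation_space(4), x)
        assert len(out.exclusion_reasons) > 0
        assert "zero arm mean" in next(iter(out.exclusion_reasons.values()))

    def test_categorical_count_tolerance(self):
        x = np.ones((6, 1)) + 0.01 * rng_for("cat").random((6, 1))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        out = ratio_balance_filter(
            enumerate_allocation_space(6), x, count_covariate=labels, count_tolerance=1
        )
        # per-category counts (3,0) vs (0,3) differ by 3 > 1 -> excluded
        all_a = np.array([1, 1, 1, 0, 0, 0], dtype=np.int8)
        idx = next(
            i for i, a in enumerate(out.assignments) if np.array_equal(a, all_a)
        )
        assert not out.constrained_mask[idx]
        # counts (2,1) vs (1,2): |2-1| = 1 <= 1 -> retained if ratio passes
        mixed = np.array([1, 1, 0, 1, 0, 0], dtype=np.int8)
        idx = next(
            i for i, a in enumerate(out.assignments) if np.array_equal(a, mixed)
        )
        assert out.constrained_mask[idx]


class TestValidity:
    def test_full_space_coassignment_third_and_unflagged(self):
        report = check_validity(enumerate_allocation_space(4))
        off_diag = report.coassignment[~np.eye(4, dtype=bool)]
        assert np.allclose(off_diag, 1 / 3)
        assert report.flagged_pairs == []
        assert np.allclose(np.diag(report.coassignment), 1.0)

    def test_forced_pair_flagged(self):
        a = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=np.int8)
        report = check_validity(AllocationSpace(a))
        assert (1, 2) in report.flagged_pairs
        assert not report.valid


class TestSelection:
    def test_single_allocation_space(self):
        a = np.array([[1, 1, 0, 0]], dtype=np.int8)
        rng = rng_for("single")
        seen = {tuple(select_allocation(AllocationSpace(a), rng)) for _ in range(50)}
        assert seen == {(1, 1, 0, 0), (0, 0, 1, 1)}  # coin flips the labels

    def test_uniform_over_space_and_fair_coin(self):
        space = enumerate_allocation_space(4)
        rng = rng_for("uniform")
        n = 6000
        counts = {}
        for _ in range(n):
            t = select_allocation(space, rng)
            counts[tuple(t)] = counts.get(tuple(t), 0) + 1
        # all 6 allocations and their mirrors = 6 patterns (mirrors coincide
        # with other members of the enumerated space): chi-square uniformity
        observed = np.array(list(counts.values()))
        chi2 = ((observed - n / len(counts)) ** 2 / (n / len(counts))).sum()
        assert stats.chi2.sf(chi2, df=len(counts) - 1) > 1e-4
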