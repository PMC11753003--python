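import numpy as np
import pytest

from cctte import (
    TrialDataset,
    cox_snell_residuals,
    deviance_residuals,
    fit_cox,
    robust_variance,
    wald_reject,
)
from cctte.fixtures import grid_search_cox

from conftest import rng_for


def _one_cov_dataset(time, event, x):
    n = len(time)
    return TrialDataset(
        cluster_id=np.arange(1, n + 1),
        subject_id=np.ones(n, dtype=int),
        time=np.asarray(time, float),
        event=np.asarray(event, np.int8),
        x=np.asarray(x, np.int8).reshape(-1, 1),
    )


class TestNewtonAgainstGridOracle:
    def test_tiny_fixture(self, tiny):
        ds, sidecar = tiny
        fit = fit_cox(ds, covariate_count=1, cluster_robust=False)
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(
            sidecar["beta_grid_search"], abs=1e-3
        )

    @pytest.mark.parametrize("seed", [11, 13, 17, 19])
    def test_random_small_datasets(self, seed):
        """On <=12-subject datasets with an interior maximizer, Newton matches
        the brute-force grid search of the Breslow partial likelihood."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        time = rng.exponential(1.0, n)
        event = (rng.random(n) < 0.7).astype(int)
        x = (rng.random(n) < 0.5).astype(int)
        if event.sum() == 0 or np.ptp(x) == 0:
            pytest.skip("degenerate draw")
        b_grid = grid_search_cox(time, event, x)
        ds = _one_cov_dataset(time, event, x)
        fit = fit_cox(ds, covariate_count=1, cluster_robust=False)
        if abs(b_grid) > 4.9 or not fit.converged:
            # monotone likelihood: both routes must agree the MLE diverges
            assert abs(b_grid) > 4.9 and not fit.converged
        else:
            assert fit.coefficients[0] == pytest.approx(b_grid, abs=1e-3)


def test_matches_lifelines_coefficients_and_robust_se(medium_trial):
    lifelines = pytest.importorskip("lifelines")
    dataset, _, _ = medium_trial
    fit = fit_cox(dataset, covariate_count=4, include_treatment=True)
    df = dataset.to_frame()
    df["arm"] = df["arm"].astype(int)
    cph = lifelines.CoxPHFitter()
    cph.fit(
        df[["time", "event", "arm", "x1", "x2", "x3", "x4", "cluster_id"]],
        duration_col="time",
        event_col="event",
        cluster_col="cluster_id",
        robust=True,
    )
    assert fit.coefficients == pytest.approx(cph.params_.values, abs=1e-4)
    assert fit.se(robust=True) == pytest.approx(
        cph.standard_errors_.values, rel=1e-3
    )


def test_null_model_baseline_is_nelson_aalen(medium_trial):
    lifelines = pytest.importorskip("lifelines")
    dataset, _, _ = medium_trial
    fit = fit_cox(dataset, covariate_count=0, cluster_robust=False)
    assert fit.n_params == 0
    naf = lifelines.NelsonAalenFitter(nelson_aalen_smoothing=False)
    naf.fit(dataset.time, event_observed=dataset.event)
    at = fit.baseline_times
    ours = np.asarray(fit.Hhat0(at))
    theirs = naf.cumulative_hazard_at_times(at).values
    assert ours == pytest.approx(theirs, rel=1e-10)


def test_first_event_cox_snell_is_one_over_n(tiny):
    ds, _ = tiny
    fit = fit_cox(ds, covariate_count=0, cluster_robust=False)
    rc = cox_snell_residuals(fit)
    j = np.argmin(ds.time)  # earliest time is an event in this fixture
    assert ds.event[j] == 1
    assert rc[j] == pytest.approx(1 / ds.n_subjects, abs=1e-12)


@pytest.mark.parametrize("covariate_count,include_treatment", [(0, False), (4, False), (4, True)])
def test_martingale_identity_at_mle(medium_trial, covariate_count, include_treatment):
    dataset, _, _ = medium_trial
    fit = fit_cox(dataset, covariate_count, include_treatment, cluster_robust=False)
    assert np.sum(dataset.event - fit.cox_snell) == pytest.approx(0.0, abs=1e-8)


class TestDevianceResiduals:
    @pytest.mark.parametrize(
        "event, rc, expected",
        [
            (1, 1.0, 0.0),
            (0, 0.5, -1.0),
            (1, 0.5, np.sqrt(-2 * (0.5 + np.log(0.5)))),  # +0.62153...
            (0, 0.0, 0.0),
        ],
    )
    def test_hand_values(self, event, rc, expected):
        out = deviance_residuals(np.array([rc]), np.array([event]))
        assert out[0] == pytest.approx(expected, abs=1e-6)

    def test_sign_agrees_with_event_minus_cox_snell(self, medium_trial):
        dataset, _, _ = medium_trial
        fit = fit_cox(dataset, 2, include_treatment=True, cluster_robust=False)
        rc = cox_snell_residuals(fit)
        rd = deviance_residuals(rc, dataset.event)
        nonzero = rd != 0
        assert np.array_equal(
            np.sign(rd[nonzero]), np.sign(dataset.event - rc)[nonzero]
        )

    def test_event_with_zero_residual_raises(self):
        with pytest.raises(ValueError):
            deviance_residuals(np.array([0.0]), np.array([1]))


def test_time_scale_invariance(medium_trial):
    dataset, _, _ = medium_trial
    fit = fit_cox(dataset, 3, include_treatment=True, cluster_robust=False)
    scaled = TrialDataset(
        cluster_id=dataset.cluster_id,
        subject_id=dataset.subject_id,
        time=dataset.time * 37.0,
        event=dataset.event,
        x=dataset.x,
        arm=dataset.arm,
    )
    fit2 = fit_cox(scaled, 3, include_treatment=True, cluster_robust=False)
    assert fit.coefficients == pytest.approx(fit2.coefficients, abs=1e-7)


def test_monotone_likelihood_is_flagged_not_fatal():
    # every informative risk set has x=1, so the partial likelihood increases
    # in beta without bound
    ds = _one_cov_dataset(
        [1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 1], [1, 1, 1, 0, 0, 0]
    )
    fit = fit_cox(ds, covariate_count=1, cluster_robust=False)
    assert not fit.converged
    assert abs(fit.coefficients[0]) >= 14.9  # capped


def test_constant_covariate_dropped_and_no_events_raises(medium_trial):
    dataset, _, _ = medium_trial
    ds = TrialDataset(
        cluster_id=dataset.cluster_id,
        subject_id=dataset.subject_id,
        time=dataset.time,
        event=dataset.event,
        x=np.column_stack([np.ones(dataset.n_subjects, dtype=np.int8), dataset.x[:, 1:]]),
        arm=dataset.arm,
    )
    fit = fit_cox(ds, 4, include_treatment=True, cluster_robust=False)
    assert "x1" in fit.dropped_terms and "x1" not in fit.terms
    ds0 = TrialDataset(
        cluster_id=dataset.cluster_id,
        subject_id=dataset.subject_id,
        time=dataset.time,
        event=np.zeros(dataset.n_subjects, dtype=np.int8),
        x=dataset.x,
        arm=dataset.arm,
    )
    with pytest.raises(ValueError):
        fit_cox(ds0, 0)


class TestRobustVariance:
    def test_one_subject_per_cluster_reduces_to_lin_wei(self, tiny):
        lifelines = pytest.importorskip("lifelines")
        ds, _ = tiny
        fit = fit_cox(ds, covariate_count=1, cluster_robust=True)
        df = ds.to_frame()[["time", "event", "x1"]]
        cph = lifelines.CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event", robust=True)
        assert fit.se(robust=True)[0] == pytest.approx(
            cph.standard_errors_.values[0], rel=1e-3
        )

    def test_symmetric_psd(self, medium_trial):
        dataset, _, _ = medium_trial
        fit = fit_cox(dataset, 4, include_treatment=True)
        v = fit.robust_cov
        assert np.allclose(v, v.T)
        assert (np.linalg.eigvalsh(v) > -1e-12).all()

    def test_duplicating_clusters_preserves_coefficients(self, medium_trial):
        dataset, _, _ = medium_trial
        dup = TrialDataset(
            cluster_id=np.concatenate(
                [dataset.cluster_id, dataset.cluster_id + dataset.n_clusters]
            ),
            subject_id=np.tile(dataset.subject_id, 2),
            time=np.tile(dataset.time, 2),
            event=np.tile(dataset.event, 2),
            x=np.tile(dataset.x, (2, 1)),
            arm=np.tile(dataset.arm, 2),
        )
        f1 = fit_cox(dataset, 2, include_treatment=True)
        f2 = fit_cox(dup, 2, include_treatment=True)
        assert f1.coefficients == pytest.approx(f2.coefficients, abs=1e-6)
        # doubled data: information doubles, meat doubles -> sandwich halves
        assert f2.robust_cov == pytest.approx(f1.robust_cov / 2, rel=1e-4)


class TestWaldDecision:
    def _fit_with(self, beta_t, se, medium_trial):
        dataset, _, _ = medium_trial
        fit = fit_cox(dataset, 0, include_treatment=True)
        fit.coefficients = np.array([beta_t])
        fit.robust_cov = np.array([[se**2]])
        return fit

    def test_null_estimate_never_rejects(self, medium_trial):
        fit = self._fit_with(0.0, 0.2, medium_trial)
        assert not wald_reject(fit, variance="robust").reject

    def test_halved_hazard_with_small_se_rejects(self, medium_trial):
        fit = self._fit_with(-0.6931, 0.1, medium_trial)
        res = wald_reject(fit, variance="robust")
        assert res.reject
        assert res.ci_low == pytest.approx(0.41, abs=0.01)
        assert res.ci_high == pytest.approx(0.61, abs=0.01)

    def test_rejection_monotone_in_z(self, medium_trial):
        rejects = [
            self._fit_with(-0.3, se, medium_trial) for se in (0.3, 0.2, 0.1, 0.05)
        ]
        flags = [wald_reject(f, variance="robust").reject for f in rejects]
        assert flags == sorted(flags)  # once it rejects it keeps rejecting

    def test_missing_treatment_errors(self, medium_trial):
        dataset, _, _ = medium_trial
        fit = fit_cox(dataset, 2, include_treatment=False, cluster_robust=False)
        with pytest.raises(ValueError):
            wald_reject(fit, variance="model")
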