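"""Residual diagnostics, bootstrap and prediction-corrected VPC."""

import copy

import numpy as np
import pytest

from ciprofol_pkpd import diagnostics as dg
from ciprofol_pkpd import estimation as est
from ciprofol_pkpd.core_model import InputError
from conftest import make_intercept_subjects


def _refit_result(fit, subjects, theta):
    """FitResult at modified theta with etas re-estimated (deliberate misfit helper)."""
    theta = np.asarray(theta, float)
    _, etas, _ = est.ofv_focei(subjects, fit.model, theta, fit.omega2_vector, fit.sigma2, details=True)
    out = copy.copy(fit)
    out.theta = dict(zip(fit.model.theta_names, theta))
    out.eta_hat = fit.eta_hat.copy()
    for s in subjects:
        out.eta_hat.loc[s.id] = etas[s.id]
    return out


class TestResidualTable:
    def test_no_random_effects_additive_error_is_plain_zscore(self):
        rng = np.random.default_rng(0)
        subs = make_intercept_subjects(rng, 6, 5, mu=10.0, omega2=0.0, sigma2=0.25)
        model = est.LinearInterceptModel()
        fit = est.fit_nlme(subs, model, np.array([10.0]), np.array([1e-9]), 0.25,
                           est.FitSettings(outer_maxiter=40))
        table = dg.residual_table(fit, subs)
        sigma = np.sqrt(fit.sigma2)
        expected = (table["DV"] - table["PRED"]) / sigma
        assert np.allclose(table["CWRES"], expected, rtol=1e-8)

    def test_row_count_equals_usable_observations(self, pk_fit_main, study_first_replicate):
        subs = est.subjects_from_dataset(study_first_replicate, "pk")
        table = dg.residual_table(pk_fit_main, subs)
        n_obs = sum(s.n_obs for s in subs)
        assert len(table) == n_obs
        assert np.isfinite(table["CWRES"]).all()

    def test_cwres_moments_on_well_specified_fit(self, pk_fit_main, study_first_replicate):
        """CWRES of a correctly specified fit behaves like N(0,1) at n ~ 360."""
        subs = est.subjects_from_dataset(study_first_replicate, "pk")
        table = dg.residual_table(pk_fit_main, subs)
        assert -0.15 < table["CWRES"].mean() < 0.15
        assert 0.85 < table["CWRES"].std() < 1.15

    def test_cwres_detects_halved_clearance(self, pk_fit_main, study_first_replicate):
        subs = est.subjects_from_dataset(study_first_replicate, "pk")
        theta = pk_fit_main.theta_vector.copy()
        theta[3] *= 0.5  # CL
        bad = _refit_result(pk_fit_main, subs, theta)
        table = dg.residual_table(bad, subs)
        assert abs(table["CWRES"].mean()) > 0.5

    def test_tad_resets_at_dose_starts(self, pk_fit_main, study_first_replicate):
        subs = est.subjects_from_dataset(study_first_replicate, "pk")
        table = dg.residual_table(pk_fit_main, subs)
        one = table[table["ID"] == subs[0].id]
        assert (one["TAD"] <= one["TIME"] + 1e-12).all()
        # samples during the maintenance infusion are timed from its start at 5 min
        during = one[(one["TIME"] > 5.0) & (one["TAD"] > 0)]
        assert np.allclose(
            during[during["TIME"] <= 65.0]["TAD"], during[during["TIME"] <= 65.0]["TIME"] - 5.0
        )


class TestBootstrap:
    def test_resample_relabels_subjects(self, study_main):
        rng = np.random.default_rng(0)
        rep = dg.resample_dataset(study_main, rng)
        assert rep.subject_ids == list(range(1, 21))
        assert len(rep.df) > 0

    def test_single_replicate_runs_and_is_deterministic(self, study_first_replicate):
        settings = est.FitSettings(outer_maxiter=10, max_restarts=0)
        a = dg.bootstrap(study_first_replicate, n_reps=1, seed=5, settings=settings)
        b = dg.bootstrap(study_first_replicate, n_reps=1, seed=5, settings=settings)
        assert a.replicates.equals(b.replicates)
        assert a.n_requested == 1

    def test_percentiles_bracket_median_and_cl_near_truth(self, study_first_replicate):
        """Scaled-down bootstrap (5 replicates, capped iterations): the CL
        percentile interval contains the replicate median by construction and
        the median clearance stays near the generating 1.01 L/min."""
        settings = est.FitSettings(outer_maxiter=25, max_restarts=1)
        res = dg.bootstrap(study_first_replicate, n_reps=5, seed=11, settings=settings)
        s = res.summary
        assert (s["p2.5"] <= s["median"] + 1e-12).all()
        assert (s["median"] <= s["p97.5"] + 1e-12).all()
        assert res.convergence_fraction > 0.5
        assert s.loc["CL", "median"] == pytest.approx(1.01, rel=0.15)

    def test_zero_reps_rejected(self, study_main):
        with pytest.raises(InputError):
            dg.bootstrap(study_main, n_reps=0, seed=1)


class TestPcVpc:
    def test_identity_correction_when_pred_constant(self):
        """Equal PRED within a bin: prediction correction must be a no-op."""
        rng = np.random.default_rng(1)
        subs = make_intercept_subjects(rng, 8, 4, mu=10.0, omega2=0.05, sigma2=0.2)
        model = est.InterceptModel()
        fit = est.fit_nlme(subs, model, np.array([10.0]), np.array([0.05]), 0.2,
                           est.FitSettings(outer_maxiter=20))
        res = dg.pc_vpc(subs, fit, n_sim=50, bins=2, seed=3)
        y = np.concatenate([s.y for s in subs])
        # per-bin observed medians equal raw medians (no heterogeneity to remove)
        times = np.concatenate([s.times for s in subs])
        for _, row in res.table.iterrows():
            m = (times >= row.t_lo) & (times < row.t_hi)
            assert row.obs_50 == pytest.approx(np.median(y[m]), rel=1e-12)

    def test_self_consistency_coverage(self, pk_fit_main, study_first_replicate):
        """A model checked against data simulated from itself passes the VPC."""
        subs = est.subjects_from_dataset(study_first_replicate, "pk")
        res = dg.pc_vpc(subs, pk_fit_main, n_sim=150, bins=8, seed=4)
        assert res.coverage_fraction >= 0.9

    def test_detects_doubled_clearance(self, pk_fit_main, study_first_replicate):
        subs = est.subjects_from_dataset(study_first_replicate, "pk")
        theta = pk_fit_main.theta_vector.copy()
        theta[3] *= 2.0
        bad = _refit_result(pk_fit_main, subs, theta)
        res = dg.pc_vpc(subs, bad, n_sim=100, bins=8, seed=4)
        assert res.coverage_fraction < 0.9
        # the median percentile specifically must fail somewhere
        assert not res.table["cover_50"].all()

    def test_ordered_percentiles_in_table(self, pk_fit_main, study_first_replicate):
        subs = est.subjects_from_dataset(study_first_replicate, "pk")
        res = dg.pc_vpc(subs, pk_fit_main, n_sim=60, bins=6, seed=9)
        t = res.table
        assert (t["obs_5"] <= t["obs_50"]).all()
        assert (t["obs_50"] <= t["obs_95"]).all()

    def test_too_few_simulations_rejected(self, pk_fit_main, study_first_replicate):
        subs = est.subjects_from_dataset(study_first_replicate, "pk")
        with pytest.raises(InputError):
            dg.pc_vpc(subs, pk_fit_main, n_sim=1, bins=4, seed=0)
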