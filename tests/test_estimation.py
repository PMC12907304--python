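"""FOCE-I engine: objective correctness, oracle equivalence, recovery limits."""

import math

import numpy as np
import pytest

from ciprofol_pkpd import estimation as est
from ciprofol_pkpd import population as pop
from ciprofol_pkpd import synthetic_study as ss
from conftest import TRUTH, make_intercept_subjects


def _pd_init_from(fit):
    quiet = pop.reference_population().without_variability()
    pd_type = type(quiet.pd)
    return pop.PopulationModel(
        pk=quiet.pk,
        pd=pd_type(ke0=fit.theta["KE0"], E0=fit.theta["E0"], Emax=fit.theta["EMAX"],
                   EC50=fit.theta["EC50"], gamma=fit.theta["GAMMA"]),
    )


def _one_obs_subject(y, t=0.0):
    return est.SubjectData(
        id=1, times=np.array([t]), y=np.array([float(y)]),
        seg_t=np.array([0.0, np.inf]), seg_r=np.array([0.0]),
    )


class TestInnerObjective:
    def test_scalar_gaussian_closed_form(self):
        """One observation, additive error, linear model: hand-computed -2 log density."""
        model = est.LinearInterceptModel()
        subj = _one_obs_subject(3.0)
        omega2, sigma2, eta = np.array([0.5]), 0.25, np.array([0.4])
        got = est.inner_objective(subj, model, np.array([2.0]), omega2, sigma2, eta)
        resid = 3.0 - (2.0 + 0.4)
        expected = (
            math.log(2 * math.pi * sigma2) + resid**2 / sigma2
            + 0.4**2 / 0.5 + math.log(2 * math.pi * 0.5)
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_vanishing_prior_for_large_omega(self):
        """With eta = 0 and huge omega the data term dominates; the prior adds only its constant."""
        model = est.LinearInterceptModel()
        subj = _one_obs_subject(3.0)
        big = 1e8
        got = est.inner_objective(subj, model, np.array([2.0]), np.array([big]), 0.25, np.array([0.0]))
        data_term = math.log(2 * math.pi * 0.25) + 1.0 / 0.25
        assert got - math.log(2 * math.pi * big) == pytest.approx(data_term, rel=1e-12)

    def test_sigma_doubling_identity_proportional(self):
        """Doubling sigma^2 adds n log 2 and halves the standardized quadratic term."""
        rng = np.random.default_rng(0)
        subs = make_intercept_subjects(rng, 1, 6, mu=10.0, omega2=0.1, sigma2=0.5)
        model = est.InterceptModel(residual_kind="prop")
        subj = subs[0]
        theta, omega2, eta = np.array([10.0]), np.array([0.1]), np.array([0.2])
        s2 = 0.04
        f = model.predict(theta, eta, subj)
        quad = float(np.sum((subj.y - f) ** 2 / (s2 * f * f)))
        a = est.inner_objective(subj, model, theta, omega2, s2, eta)
        b = est.inner_objective(subj, model, theta, omega2, 2 * s2, eta)
        assert b - a == pytest.approx(subj.n_obs * math.log(2.0) - quad / 2.0, rel=1e-10)

    def test_nonzero_eta_on_null_space_rejected(self):
        model = est.LinearInterceptModel()
        with pytest.raises(est.EstimationError):
            est.inner_objective(_one_obs_subject(1.0), model, np.array([1.0]), np.array([0.0]), 1.0, np.array([0.5]))


class TestOfvFocei:
    def test_equals_exact_marginal_for_linear_model(self):
        """Laplace/FOCE is exact for models linear in eta with additive error."""
        rng = np.random.default_rng(42)
        mu, om2, sg2 = 10.0, 0.5, 0.3
        subs = []
        for i in range(8):
            n = int(rng.integers(3, 7))
            y = mu + rng.normal(0, math.sqrt(om2)) + rng.normal(0, math.sqrt(sg2), n)
            subs.append(est.SubjectData(id=i, times=np.arange(n, dtype=float), y=y,
                                        seg_t=np.array([0.0, np.inf]), seg_r=np.array([0.0])))
        ofv = est.ofv_focei(subs, est.LinearInterceptModel(), np.array([mu]), np.array([om2]), sg2)
        exact = 0.0
        for s in subs:
            S = sg2 * np.eye(s.n_obs) + om2 * np.ones((s.n_obs, s.n_obs))
            r = s.y - mu
            exact += np.linalg.slogdet(2 * np.pi * S)[1] + r @ np.linalg.solve(S, r)
        assert ofv == pytest.approx(exact, abs=1e-4)

    def test_omega_zero_reduces_to_pooled_els(self, ref_pop, study_main):
        """With no random effects the OFV is the extended-least-squares -2LL at eta = 0."""
        subs = est.subjects_from_dataset(study_main, "pk")[:5]
        model = est.ThreeCompartmentModel(est.FINAL_PK_COVARIATES)
        theta = np.array([TRUTH[k] for k in model.theta_names])
        sg2 = 0.26
        ofv = est.ofv_focei(subs, model, theta, np.zeros(6), sg2)
        direct = 0.0
        for s in subs:
            f = model.predict(theta, np.zeros(6), s)
            v = sg2 * f * f
            direct += float(np.sum(np.log(2 * np.pi * v) + (s.y - f) ** 2 / v))
        assert ofv == pytest.approx(direct, rel=1e-12)

    def test_invariant_to_relabeling_and_row_order(self, ref_pop, study_main):
        subs = est.subjects_from_dataset(study_main, "pk")[:6]
        model = est.ThreeCompartmentModel(est.FINAL_PK_COVARIATES)
        theta = np.array([TRUTH[k] for k in model.theta_names])
        om = ref_pop.omega.pk_variances()
        a = est.ofv_focei(subs, model, theta, om, 0.26)
        relabeled = [est.SubjectData(id=100 - i, times=s.times, y=s.y, seg_t=s.seg_t,
                                     seg_r=s.seg_r, covariates=s.covariates)
                     for i, s in enumerate(subs)]
        b = est.ofv_focei(list(reversed(relabeled)), model, theta, om, 0.26)
        assert a == pytest.approx(b, rel=1e-12)

    def test_truth_beats_perturbed_parameters(self, ref_pop, study_main):
        subs = est.subjects_from_dataset(study_main, "pk")
        model = est.ThreeCompartmentModel(est.FINAL_PK_COVARIATES)
        theta = np.array([TRUTH[k] for k in model.theta_names])
        om = ref_pop.omega.pk_variances()
        pert = theta * np.array([1.5, 1.5, 1.5, 1.5, 1.5, 1.5, 1.0, 1.0])
        assert est.ofv_focei(subs, model, theta, om, 0.26) < est.ofv_focei(subs, model, pert, om, 0.26)


class TestFitting:
    def test_noiseless_exact_fit_recovers_parameters(self, ref_pop):
        """Omega = 0, sigma ~ 0 data: the PK fixed effects are recovered to <= 0.1 %.

        Subjects are pinned at the reference covariates so the typical CL is
        the only clearance in play.
        """
        quiet = ref_pop.without_variability()
        demo = [ss.SubjectRecord(id=i + 1, age=72.5, wt=66.0, sex="M") for i in range(6)]
        study = ss.generate_study(ss.StudyDesign(n_subjects=6), quiet, seed=12, subjects=demo)
        subjects = est.subjects_from_dataset(study, "pk")
        model = est.ThreeCompartmentModel()
        theta0 = quiet.pk.as_array() * np.array([1.2, 0.85, 1.2, 0.85, 1.2, 0.85])
        fit = est.fit_nlme(subjects, model, theta0, np.zeros(6) + 1e-9, 1e-4,
                           est.FitSettings(outer_maxiter=300, outer_ftol=1e-12))
        # polish with a finer finite-difference step once sigma^2 has collapsed
        fit = est.fit_nlme(subjects, model, fit.theta_vector, np.zeros(6) + 1e-9,
                           max(fit.sigma2, 1e-9),
                           est.FitSettings(outer_maxiter=400, outer_ftol=1e-13, fd_step=1e-7))
        for name, true in zip(model.theta_names, quiet.pk.as_array()):
            assert fit.theta[name] == pytest.approx(true, rel=1e-3)

    def test_noiseless_pd_sequential_recovery(self, ref_pop):
        """Noise-free BIS data: PD fixed effects recovered to <= 0.5 %."""
        quiet = ref_pop.without_variability()
        demo = [ss.SubjectRecord(id=i + 1, age=72.5, wt=66.0, sex="M") for i in range(6)]
        study = ss.generate_study(ss.StudyDesign(n_subjects=6), quiet, seed=13, subjects=demo)
        pk_subs = est.subjects_from_dataset(study, "pk")
        model = est.ThreeCompartmentModel()
        pk_fit = est.fit_nlme(pk_subs, model, quiet.pk.as_array() * 1.1, np.zeros(6) + 1e-9, 1e-4,
                              est.FitSettings(outer_maxiter=300, outer_ftol=1e-10))
        init = pop.PopulationModel(
            pk=quiet.pk,
            pd=type(quiet.pd)(ke0=1.09 * 1.3, E0=93.4 * 0.97, Emax=45.77 * 1.2, EC50=233.91 * 1.3, gamma=3.0 * 0.8),
        )
        # IIV off (the generating model has none): per-subject etas would
        # otherwise absorb typical-value error in the exact-fit limit
        pd_fit = est.fit_pd_sequential(study, pk_fit, init=init,
                                       settings=est.FitSettings(outer_maxiter=300, outer_ftol=1e-12),
                                       omega2_init=np.zeros(2), sigma2_init=1e-4)
        pd_fit = est.fit_pd_sequential(study, pk_fit, init=_pd_init_from(pd_fit),
                                       settings=est.FitSettings(outer_maxiter=400, outer_ftol=1e-13, fd_step=1e-7),
                                       omega2_init=np.zeros(2), sigma2_init=max(pd_fit.sigma2, 1e-9))
        for name, true in zip(("KE0", "E0", "EMAX", "EC50", "GAMMA"),
                              (1.09, 93.40, 45.77, 233.91, 3.00)):
            assert pd_fit.theta[name] == pytest.approx(true, rel=5e-3)

    def test_nested_models_never_increase_ofv(self):
        """Adding a free covariate coefficient cannot worsen the optimized OFV."""
        rng = np.random.default_rng(3)
        subs = make_intercept_subjects(rng, 12, 5, covariate="X", beta=0.0)
        base = est.fit_nlme(subs, est.InterceptModel(), np.array([9.0]), np.array([0.1]), 0.4)
        full_model = est.InterceptModel((est.CovariateEffect("MU", "X", "power", 1.0),))
        full = est.fit_nlme(subs, full_model, np.array([9.0, 0.0]), np.array([0.1]), 0.4)
        assert full.ofv <= base.ofv + 1e-6

    def test_multi_start_agrees_from_different_inits(self):
        # the multiplicative intercept has a flat theta-vs-mean(eta) ridge, so
        # the inner modes must be solved tightly for the optima to coincide
        st = est.FitSettings(inner_tol=1e-9, outer_maxiter=300, outer_ftol=1e-7, max_restarts=4)
        rng = np.random.default_rng(8)
        subs = make_intercept_subjects(rng, 10, 5, mu=10.0)
        a = est.fit_nlme(subs, est.InterceptModel(), np.array([5.0]), np.array([0.3]), 1.0, st)
        b = est.fit_nlme(subs, est.InterceptModel(), np.array([15.0]), np.array([0.1]), 0.2, st)
        assert a.theta["MU"] == pytest.approx(b.theta["MU"], rel=1e-3)
        assert a.ofv == pytest.approx(b.ofv, abs=1e-2)

    def test_empty_subjects_rejected(self):
        with pytest.raises(est.EstimationError):
            est.fit_nlme([], est.LinearInterceptModel(), np.array([1.0]), np.array([0.1]), 1.0)


class TestShrinkage:
    def test_sparse_data_shrinks_etas_toward_zero(self):
        """One observation per subject with large noise: eta-shrinkage near 100 %."""
        rng = np.random.default_rng(5)
        subs = make_intercept_subjects(rng, 10, 1, mu=10.0, omega2=0.01, sigma2=25.0)
        fit = est.fit_nlme(subs, est.InterceptModel(), np.array([10.0]), np.array([0.01]), 25.0,
                           est.FitSettings(outer_maxiter=10))
        assert fit.eta_shrinkage["MU"] > 60.0

    def test_rich_data_low_shrinkage(self):
        rng = np.random.default_rng(6)
        subs = make_intercept_subjects(rng, 40, 50, mu=10.0, omega2=0.2, sigma2=0.05)
        fit = est.fit_nlme(subs, est.InterceptModel(), np.array([10.0]), np.array([0.2]), 0.05,
                           est.FitSettings(outer_maxiter=10))
        assert abs(fit.eta_shrinkage["MU"]) < 20.0
        assert abs(fit.eps_shrinkage) < 15.0

    def test_replicate_fits_shrinkage_within_range(self, replicate_fits):
        """Well-behaved study fits report shrinkage inside [0, 100] with sane magnitude."""
        for pk_fit, pd_fit in replicate_fits[:2]:
            for v in pk_fit.eta_shrinkage.values():
                assert -20.0 <= v <= 100.0
            assert -20.0 <= pk_fit.eps_shrinkage <= 100.0


class TestSerialization:
    def test_fit_roundtrip(self, pk_fit_main, tmp_path):
        path = tmp_path / "fit.json"
        est.save_fit(pk_fit_main, path)
        back = est.load_fit(path)
        assert back.theta == pytest.approx(pk_fit_main.theta)
        assert back.omega2 == pytest.approx(pk_fit_main.omega2)
        assert back.ofv == pytest.approx(pk_fit_main.ofv)
        assert list(back.eta_hat.columns) == list(pk_fit_main.eta_hat.columns)
        assert np.allclose(back.eta_hat.to_numpy(), pk_fit_main.eta_hat.to_numpy())
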