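"""Shared fixtures: the reference population model and fitted virtual studies.

The expensive session fixtures (replicate simulate-and-refit runs) are shared
between the estimator, diagnostic and acceptance tests so the full FOCE-I
pipeline runs once per session per replicate.
"""

import numpy as np
import pytest

from ciprofol_pkpd import estimation, population, synthetic_study, workflows

#: base seed for the session's replicate protocol
BASE_SEED = 1
N_REPLICATES = 5

#: reference (generating) fixed effects used throughout the suite
TRUTH = {
    "V1": 2.95, "V2": 45.15, "V3": 76.79, "CL": 1.01, "Q2": 0.76, "Q3": 0.66,
    "WT_on_CL": 0.74, "AGE_on_CL": -0.21,
    "KE0": 1.09, "E0": 93.40, "EMAX": 45.77, "EC50": 233.91, "GAMMA": 3.00,
}


@pytest.fixture(scope="session")
def ref_pop():
    return population.reference_population()


@pytest.fixture(scope="session")
def study_main(ref_pop):
    """One 20-subject virtual study under the reference model."""
    return synthetic_study.generate_study(synthetic_study.StudyDesign(), ref_pop, seed=20260919)


@pytest.fixture(scope="session")
def replicate_fits():
    """The 5-replicate simulate-and-refit protocol (PK + sequential PD)."""
    seeds = workflows.replicate_seeds(BASE_SEED, N_REPLICATES)
    return [workflows.run_replicate(s) for s in seeds]


@pytest.fixture(scope="session")
def pk_fit_main(replicate_fits):
    return replicate_fits[0][0]


@pytest.fixture(scope="session")
def pd_fit_main(replicate_fits):
    return replicate_fits[0][1]


@pytest.fixture(scope="session")
def study_first_replicate():
    """The study behind replicate_fits[0], regenerated (generation is deterministic)."""
    seed = workflows.replicate_seeds(BASE_SEED, N_REPLICATES)[0]
    return synthetic_study.generate_study(
        synthetic_study.StudyDesign(), population.reference_population(), seed=seed
    )


@pytest.fixture(scope="session")
def false_inclusion_rate():
    """Type-I calibration of the forward-inclusion gate on null data.

    500 candidate tests (125 null datasets x 4 independent covariates) on the
    linear random-intercept model, where the FOCE objective is the exact
    likelihood and the chi-squared reference for the OFV drop is the textbook
    one.  16 subjects x 8 observations keeps the LRT in its asymptotic
    regime.  Returns (n_tests, rate).
    """
    from ciprofol_pkpd import covariate_search as cs

    quick = estimation.FitSettings(outer_maxiter=40, outer_ftol=1e-5, max_restarts=1)
    rng = np.random.default_rng(7)
    threshold = cs.chi2_threshold(0.05, 1)
    n_pass = 0
    n_tests = 0
    covs = ("X", "Z", "W", "V")
    for _ in range(125):
        subs = []
        for i in range(16):
            y = 10.0 + rng.normal(0, np.sqrt(0.3)) + rng.normal(0, np.sqrt(0.5), 8)
            subs.append(
                estimation.SubjectData(
                    id=i + 1, times=np.arange(8, dtype=float), y=y,
                    seg_t=np.array([0.0, np.inf]), seg_r=np.array([0.0]),
                    covariates={c: float(rng.uniform(-1.0, 1.0)) for c in covs},
                )
            )
        fit = estimation.fit_nlme(subs, estimation.LinearInterceptModel(), np.array([10.0]),
                                  np.array([0.2]), 0.4, quick)
        for cov in covs:
            model = fit.model.with_covariate(estimation.CovariateEffect("MU", cov, "shift", ref=0.0))
            cand = estimation.fit_nlme(subs, model, np.array([fit.theta["MU"], 0.0]),
                                       np.maximum(fit.omega2_vector, 1e-4), fit.sigma2, quick)
            n_tests += 1
            if fit.ofv - cand.ofv >= threshold:
                n_pass += 1
    return n_tests, n_pass / n_tests


def make_intercept_subjects(rng, n_subjects, n_obs, mu=10.0, omega2=0.2, sigma2=0.5,
                            covariate=None, beta=0.0):
    """Toy log-normal intercept datasets for the estimation/SCM machinery."""
    subs = []
    for i in range(n_subjects):
        covs = {}
        fac = 1.0
        if covariate is not None:
            x = float(rng.uniform(0.5, 2.0))
            covs[covariate] = x
            fac = x**beta
        f = mu * fac * np.exp(rng.normal(0.0, np.sqrt(omega2)))
        y = f + rng.normal(0.0, np.sqrt(sigma2), n_obs)
        subs.append(
            estimation.SubjectData(
                id=i + 1,
                times=np.arange(n_obs, dtype=float),
                y=y,
                seg_t=np.array([0.0, np.inf]),
                seg_r=np.array([0.0]),
                covariates=covs,
            )
        )
    return subs
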