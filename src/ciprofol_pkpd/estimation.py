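"""Nonlinear mixed-effects estimation by FOCE with interaction.

The marginal likelihood of each subject's data is approximated by a
Laplace-type expansion around the conditional mode of the random effects
(eta): the inner problem minimizes the conditional -2 log posterior

    h(eta) = sum_j [ log(2 pi v_j(eta)) + (y_j - f_j(eta))^2 / v_j(eta) ]
             + eta' Omega^-1 eta + log|2 pi Omega|,

with the residual variance v evaluated at the eta-dependent prediction
(the "interaction"), and the curvature term uses the Gauss-Newton (Fisher)
approximation G' V^-1 G + Omega^-1 with G = df/deta at the mode.  The
subject objective, in a form stable as omega -> 0, is

    OFV_i = sum_j [ log(2 pi v_j) + r_j^2 / v_j ] + eta' Omega^-1 eta
            + log det(I + Omega^1/2 G' V^-1 G Omega^1/2),

which reduces to the pooled extended-least-squares -2LL when Omega = 0 and
equals the exact marginal normal -2LL for models linear in eta with additive
error.

Structural adapters map (theta, eta, subject) to predictions: the
three-compartment concentration model (optionally with power/fractional-shift
covariate effects), the effect-site sigmoid-Emax BIS model with individual PK
fixed (sequential IPP fitting), and simple intercept models used as exact
oracles.  Fixed effects are optimized on the log scale (exponents on the
natural scale) by quasi-Newton iteration with finite-difference gradients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from . import population as pop_mod
from .core_model import InputError, _profile_arrays

_LOG2PI = math.log(2.0 * math.pi)
_PENALTY = 1e12

PK_THETA_NAMES = ("V1", "V2", "V3", "CL", "Q2", "Q3")
PD_THETA_NAMES = ("KE0", "E0", "EMAX", "EC50", "GAMMA")


class EstimationError(RuntimeError):
    pass


@dataclass
class SubjectData:
    """One subject's observation vector plus its compiled dosing input."""

    id: object
    times: np.ndarray
    y: np.ndarray
    seg_t: np.ndarray
    seg_r: np.ndarray
    covariates: dict = field(default_factory=dict)
    pk_params: np.ndarray | None = None  # fixed individual PK (sequential PD fits)

    @property
    def n_obs(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate-parameter relation.

    ``power``: multiplies the parameter by (cov/ref)^theta (continuous,
    centered at ``ref``); ``shift``: multiplies by (1 + theta * x) for a 0/1
    covariate (fractional shift).
    """

    param: str
    cov: str
    form: str = "power"
    ref: float = 1.0

    def __post_init__(self):
        if self.form not in ("power", "shift"):
            raise InputError(f"unknown covariate form {self.form!r}")
        if self.form == "power" and self.ref <= 0:
            raise InputError("power covariates need a positive reference value")

    @property
    def theta_name(self) -> str:
        return f"{self.cov}_on_{self.param}"


class NlmeModel:
    """Structural-model interface consumed by the FOCE engine."""

    theta_names: tuple[str, ...]
    log_scale: np.ndarray  # bool per theta: optimized as log
    eta_names: tuple[str, ...]
    residual_kind: str  # "prop" | "add"
    linear_eta: bool = False  # predictions linear in eta: the inner mode is closed-form

    def predict(self, theta: np.ndarray, eta: np.ndarray, subj: SubjectData) -> np.ndarray:
        raise NotImplementedError

    def predict_batch(self, theta: np.ndarray, etas: np.ndarray, subj: SubjectData) -> np.ndarray:
        """Predictions for several eta vectors at once (rows of ``etas``)."""
        return np.stack([self.predict(theta, e, subj) for e in etas])


def _covariate_factors(
    effects: Sequence[CovariateEffect], theta_tail: np.ndarray, covariates: dict, param_names: Sequence[str]
) -> np.ndarray:
    fac = np.ones(len(param_names))
    for i, eff in enumerate(effects):
        x = covariates[eff.cov]
        j = list(param_names).index(eff.param)
        if eff.form == "power":
            fac[j] *= (x / eff.ref) ** theta_tail[i]
        else:
            fac[j] *= max(1.0 + theta_tail[i] * x, 1e-6)
    return fac


class ThreeCompartmentModel(NlmeModel):
    """Concentration (ng/mL) predictions of the three-compartment model.

    theta: (V1, V2, V3, CL, Q2, Q3) on the log scale plus one natural-scale
    coefficient per covariate effect; eta (log-normal) on all six structural
    parameters; proportional residual error.
    """

    residual_kind = "prop"
    eta_names = PK_THETA_NAMES

    def __init__(self, covariate_effects: Sequence[CovariateEffect] = ()):
        for e in covariate_effects:
            if e.param not in PK_THETA_NAMES:
                raise InputError(f"covariate target {e.param!r} is not a PK parameter")
        self.covariate_effects = tuple(covariate_effects)
        self.theta_names = PK_THETA_NAMES + tuple(e.theta_name for e in self.covariate_effects)
        self.log_scale = np.array([True] * 6 + [False] * len(self.covariate_effects))

    def with_covariate(self, effect: CovariateEffect) -> "ThreeCompartmentModel":
        return ThreeCompartmentModel(self.covariate_effects + (effect,))

    def without_covariate(self, effect: CovariateEffect) -> "ThreeCompartmentModel":
        return ThreeCompartmentModel(tuple(e for e in self.covariate_effects if e != effect))

    def subject_params(self, theta: np.ndarray, eta: np.ndarray, subj: SubjectData) -> np.ndarray:
        fac = _covariate_factors(self.covariate_effects, theta[6:], subj.covariates, PK_THETA_NAMES)
        return theta[:6] * fac * np.exp(eta)

    def predict(self, theta, eta, subj):
        with np.errstate(over="ignore"):
            p = self.subject_params(theta, eta, subj)
        if not np.all(np.isfinite(p)) or np.any(p <= 1e-7) or np.any(p >= 1e7):
            return np.full(len(subj.times), -1.0)  # rejected by the proportional-error guard
        out = _profile_arrays(p, 1.0, subj.seg_t, subj.seg_r, subj.times)
        return out[:, 3]

    def predict_batch(self, theta, etas, subj):
        fac = _covariate_factors(self.covariate_effects, theta[6:], subj.covariates, PK_THETA_NAMES)
        base = theta[:6] * fac
        out = np.empty((len(etas), len(subj.times)))
        for k in range(len(etas)):
            with np.errstate(over="ignore"):
                p = base * np.exp(etas[k])
            if not np.all(np.isfinite(p)) or np.any(p <= 1e-7) or np.any(p >= 1e7):
                out[k] = -1.0
            else:
                out[k] = _profile_arrays(p, 1.0, subj.seg_t, subj.seg_r, subj.times)[:, 3]
        return out


class EffectSiteEmaxModel(NlmeModel):
    """BIS predictions: effect-site link + sigmoid Emax, individual PK fixed.

    theta: (ke0, E0, Emax, EC50, gamma), all log scale; eta (log-normal) on
    EC50 and gamma only; additive residual error.  Effect-site concentration
    profiles are cached per (subject, ke0) since eta does not perturb them.
    """

    residual_kind = "add"
    theta_names = PD_THETA_NAMES
    eta_names = ("EC50", "GAMMA")
    log_scale = np.array([True] * 5)

    def __init__(self):
        self._ce_cache: dict = {}

    def _ce(self, ke0: float, subj: SubjectData) -> np.ndarray:
        key = id(subj)
        hit = self._ce_cache.get(key)
        if hit is not None and hit[0] == ke0:
            return hit[1]
        if subj.pk_params is None:
            raise EstimationError(f"subject {subj.id} has no individual PK parameters attached")
        ce = _profile_arrays(np.asarray(subj.pk_params, float), ke0, subj.seg_t, subj.seg_r, subj.times)[:, 4]
        ce = np.maximum(ce, 0.0)
        self._ce_cache[key] = (ke0, ce)
        return ce

    def predict(self, theta, eta, subj):
        ke0, e0, emax, ec50, gamma = theta[:5]
        ce = self._ce(ke0, subj)
        with np.errstate(over="ignore", invalid="ignore"):
            ec50_i = ec50 * np.exp(eta[0])
            gamma_i = gamma * np.exp(eta[1])
            if not (np.isfinite(ec50_i) and np.isfinite(gamma_i) and ec50_i > 0 and gamma_i > 0):
                return np.full(len(ce), np.nan)
            x = np.power(ce / ec50_i, gamma_i, where=ce > 0, out=np.zeros_like(ce))
            return e0 - emax * np.where(np.isinf(x), 1.0, x / (1.0 + x))


class LinearInterceptModel(NlmeModel):
    """y_ij = theta + sum_c beta_c (x_c - ref_c) + eta_i + eps.

    Linear in eta and theta: the FOCE objective equals the exact marginal
    -2 log likelihood, which makes this the engine's closed-form oracle and
    the clean test bed for likelihood-ratio calibration.  Covariate effects
    enter additively, centered at ``ref``.
    """

    residual_kind = "add"
    eta_names = ("MU",)
    linear_eta = True

    def __init__(self, covariate_effects: Sequence[CovariateEffect] = ()):
        self.covariate_effects = tuple(covariate_effects)
        self.theta_names = ("MU",) + tuple(e.theta_name for e in self.covariate_effects)
        self.log_scale = np.array([False] * (1 + len(self.covariate_effects)))

    def with_covariate(self, effect: CovariateEffect) -> "LinearInterceptModel":
        return LinearInterceptModel(self.covariate_effects + (effect,))

    def without_covariate(self, effect: CovariateEffect) -> "LinearInterceptModel":
        return LinearInterceptModel(tuple(e for e in self.covariate_effects if e != effect))

    def predict(self, theta, eta, subj):
        mu = theta[0] + eta[0]
        for i, e in enumerate(self.covariate_effects):
            mu += theta[1 + i] * (subj.covariates[e.cov] - e.ref)
        return np.full(subj.n_obs, mu)


class InterceptModel(NlmeModel):
    """Log-normal intercept model with optional covariate effects.

    f_ij = theta * covariate factors * exp(eta_i); additive or proportional
    error.  Cheap nonlinear test bed for the stepwise covariate machinery.
    """

    theta_base = ("MU",)
    eta_names = ("MU",)

    def __init__(self, covariate_effects: Sequence[CovariateEffect] = (), residual_kind: str = "add"):
        self.covariate_effects = tuple(covariate_effects)
        self.theta_names = self.theta_base + tuple(e.theta_name for e in self.covariate_effects)
        self.log_scale = np.array([True] + [False] * len(self.covariate_effects))
        self.residual_kind = residual_kind

    def with_covariate(self, effect: CovariateEffect) -> "InterceptModel":
        return InterceptModel(self.covariate_effects + (effect,), self.residual_kind)

    def without_covariate(self, effect: CovariateEffect) -> "InterceptModel":
        return InterceptModel(tuple(e for e in self.covariate_effects if e != effect), self.residual_kind)

    def predict(self, theta, eta, subj):
        fac = _covariate_factors(self.covariate_effects, theta[1:], subj.covariates, self.theta_base)
        with np.errstate(over="ignore"):
            return np.full(subj.n_obs, theta[0] * fac[0] * np.exp(min(eta[0], 300.0)))


# --------------------------------------------------------------------------
# FOCE-I objective
# --------------------------------------------------------------------------

def _variance(f: np.ndarray, kind: str, sigma2: float) -> np.ndarray:
    return sigma2 * f * f if kind == "prop" else np.full_like(f, sigma2)


def inner_objective(
    subj: SubjectData, model: NlmeModel, theta: np.ndarray, omega2: np.ndarray, sigma2: float, eta: np.ndarray
) -> float:
    """Conditional -2 log joint density of (residuals, eta) — the inner target.

    Dimensions of ``eta`` with ``omega2 == 0`` must be 0 (they are excluded
    from the prior term).
    """
    omega2 = np.asarray(omega2, float)
    eta = np.asarray(eta, float)
    active = omega2 > 0
    if np.any(~active & (eta != 0.0)):
        raise EstimationError("eta must be zero where omega^2 is zero")
    f = model.predict(theta, eta, subj)
    if not np.all(np.isfinite(f)) or (model.residual_kind == "prop" and np.any(f < 1e-6)):
        return _PENALTY
    v = _variance(f, model.residual_kind, sigma2)
    r = subj.y - f
    lik = float(np.sum(np.log(2.0 * np.pi * v) + r * r / v))
    if active.any():
        om = omega2[active]
        e = eta[active]
        lik += float(np.sum(e * e / om) + np.sum(np.log(2.0 * np.pi * om)))
    return lik


def _predict_with_jac(model, theta, eta_full, active_idx, subj, h=1e-5):
    """Prediction and finite-difference Jacobian wrt the active etas."""
    etas = np.tile(eta_full, (len(active_idx) + 1, 1))
    for c, k in enumerate(active_idx):
        etas[c + 1, k] += h
    batch = model.predict_batch(theta, etas, subj)
    f0 = batch[0]
    with np.errstate(invalid="ignore"):
        G = (batch[1:] - f0).T / h
    return f0, G


def _solve_inner(subj, model, theta, omega2, sigma2, eta0, tol=1e-5, maxiter=60):
    """Newton (Gauss-Newton curvature) minimization of the conditional objective.

    Returns (eta_full, converged, f, G, v) at the mode.
    """
    omega2 = np.asarray(omega2, float)
    active = np.flatnonzero(omega2 > 0)
    eta = np.asarray(eta0, float).copy()
    eta[omega2 <= 0] = 0.0
    q = len(active)
    if q == 0:
        f = model.predict(theta, eta, subj)
        v = _variance(f, model.residual_kind, sigma2)
        return eta, True, f, np.zeros((len(f), 0)), v

    om = omega2[active]
    prop = model.residual_kind == "prop"

    if model.linear_eta and not prop:
        # quadratic inner problem: one Gauss-Newton step from zero is exact
        zero = np.zeros_like(eta)
        f0, G = _predict_with_jac(model, theta, zero, active, subj)
        v = _variance(f0, model.residual_kind, sigma2)
        H = G.T @ (G / v[:, None]) + np.diag(1.0 / om)
        e_hat = np.linalg.solve(H, G.T @ ((subj.y - f0) / v))
        eta_out = zero
        eta_out[active] = e_hat
        f = f0 + G @ e_hat
        return eta_out, True, f, G, v

    prior_const = float(np.sum(np.log(2.0 * np.pi * om)))
    n_log2pi = subj.n_obs * _LOG2PI
    y = subj.y

    def objective(e_act):
        # inlined conditional -2 log density (hot path of the line search)
        full = eta.copy()  # inactive dimensions are already pinned at zero
        full[active] = e_act
        f = model.predict(theta, full, subj)
        if prop:
            if f.min() < 1e-6 or not np.isfinite(f).all():
                return _PENALTY, full
            v = sigma2 * f * f
        else:
            if not np.isfinite(f).all():
                return _PENALTY, full
            v = np.full(len(f), sigma2)
        r = y - f
        val = n_log2pi + float(np.log(v).sum() + (r * r / v).sum())
        val += float((e_act * e_act / om).sum()) + prior_const
        return val, full

    e_act = eta[active].copy()
    h_val, _ = objective(e_act)
    if h_val >= _PENALTY:  # recover from an invalid warm start
        e_act = np.zeros(q)
        h_val, _ = objective(e_act)
    converged = False
    f = G = v = None
    stale = True
    for _ in range(maxiter):
        full = eta.copy()
        full[active] = e_act
        f, G = _predict_with_jac(model, theta, full, active, subj)
        stale = False
        if not np.all(np.isfinite(f)) or (prop and np.any(f < 1e-6)):
            converged = False
            break
        v = _variance(f, model.residual_kind, sigma2)
        r = subj.y - f
        if prop:
            grad_half = G.T @ (1.0 / f * (1.0 - r * r / v) - r / v) + e_act / om
        else:
            grad_half = -G.T @ (r / v) + e_act / om
        H_half = G.T @ (G / v[:, None]) + np.diag(1.0 / om)
        try:
            step = -np.linalg.solve(H_half, grad_half)
        except np.linalg.LinAlgError:
            break
        norm = np.max(np.abs(step))
        if norm > 3.0:  # trust region: eta is on the log scale, excursions beyond e^3 are pathological
            step *= 3.0 / norm
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        # backtracking line search
        t = 1.0
        improved = False
        for _ls in range(12):
            cand = e_act + t * step
            h_new, _ = objective(cand)
            if h_new < h_val:
                drop = h_val - h_new
                e_act = cand
                h_val = h_new
                improved = True
                stale = True
                break
            t *= 0.5
        if not improved:
            converged = True  # no further descent along the Newton direction
            break
        if drop < 1e-9:  # objective has stopped moving: done
            converged = True
            break
    eta_out = eta.copy()
    eta_out[active] = e_act
    if f is None or stale:
        f, G = _predict_with_jac(model, theta, eta_out, active, subj)
        v = _variance(f, model.residual_kind, sigma2)
    return eta_out, converged, f, G, v


def _subject_ofv(subj, model, theta, omega2, sigma2, eta0, inner_tol=1e-8, inner_maxiter=40):
    """FOCE-I contribution of one subject; returns (ofv_i, eta_hat, info)."""
    eta_hat, conv, f, G, v = _solve_inner(
        subj, model, theta, omega2, sigma2, eta0, tol=inner_tol, maxiter=inner_maxiter
    )
    if not np.all(np.isfinite(f)) or (model.residual_kind == "prop" and np.any(f < 1e-6)):
        return _PENALTY, eta_hat, None
    r = subj.y - f
    active = np.flatnonzero(np.asarray(omega2) > 0)
    ofv = float(np.sum(np.log(2.0 * np.pi * v) + r * r / v))
    if len(active):
        om = np.asarray(omega2)[active]
        e = eta_hat[active]
        ofv += float(np.sum(e * e / om))
        A = G.T @ (G / v[:, None])  # Fisher-type curvature of the data term
        W = np.sqrt(om)
        B = np.eye(len(active)) + (W[:, None] * A * W[None, :])
        sign, logdet = np.linalg.slogdet(B)
        if sign <= 0:
            return _PENALTY, eta_hat, None
        ofv += float(logdet)
    info = {"f": f, "G": G, "v": v, "r": r, "converged": conv}
    return ofv, eta_hat, info


def ofv_focei(
    subjects: Sequence[SubjectData],
    model: NlmeModel,
    theta: np.ndarray,
    omega2: np.ndarray,
    sigma2: float,
    eta_init: dict | None = None,
    inner_tol: float = 1e-8,
    inner_maxiter: int = 40,
    details: bool = False,
):
    """FOCE-I objective function value: sum of subject approximations to -2 log L.

    Deterministic given the data; ``eta_init`` warm-starts the inner modes.
    With ``details=True`` returns (ofv, eta_hat dict, per-subject info dict).
    """
    for s in subjects:
        if s.n_obs < 1:
            raise EstimationError(f"subject {s.id} has no usable observations")
    total = 0.0
    etas = {}
    infos = {}
    nz = np.count_nonzero(np.asarray(omega2) > 0)
    for s in subjects:
        e0 = eta_init.get(s.id) if eta_init else None
        if e0 is None:
            e0 = np.zeros(len(omega2))
        ofv_i, eta_hat, info = _subject_ofv(
            s, model, theta, omega2, sigma2, e0, inner_tol=inner_tol, inner_maxiter=inner_maxiter
        )
        total += ofv_i
        etas[s.id] = eta_hat
        infos[s.id] = info
    if details:
        return total, etas, infos
    return total


# --------------------------------------------------------------------------
# outer optimization
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FitSettings:
    """Optimizer controls.

    outer_ftol is the absolute OFV decrease below which the outer quasi-Newton
    iteration stops; fd_step the outer finite-difference step on the internal
    (mostly log) scale; n_starts > 1 adds multi-start jitter (sd ``jitter_sd``
    on the internal scale).
    """

    outer_ftol: float = 1e-4
    outer_maxiter: int = 150
    inner_tol: float = 1e-5
    inner_maxiter: int = 60
    fd_step: float = 1e-5
    n_starts: int = 1
    jitter_sd: float = 0.2
    seed: int = 0
    max_restarts: int = 3  # fresh-Hessian BFGS rounds until the OFV stabilizes
    restart_ftol: float = 0.5

    def __post_init__(self):
        if self.outer_ftol <= 0 or self.inner_tol <= 0 or self.fd_step <= 0:
            raise InputError("tolerances must be > 0")


@dataclass
class FitResult:
    """Estimates, OFV, empirical Bayes etas and shrinkage of one fit."""

    model: NlmeModel
    theta: dict
    omega2: dict
    sigma2: float
    ofv: float
    eta_hat: pd.DataFrame
    eta_shrinkage: dict
    eps_shrinkage: float
    converged: bool
    message: str
    n_obs: int
    n_subjects: int
    inner_failures: int
    settings: FitSettings

    @property
    def theta_vector(self) -> np.ndarray:
        return np.array([self.theta[n] for n in self.model.theta_names])

    @property
    def omega2_vector(self) -> np.ndarray:
        return np.array([self.omega2[n] for n in self.model.eta_names])

    def to_report(self) -> dict:
        return {
            "theta": self.theta,
            "omega2": self.omega2,
            "sigma2": self.sigma2,
            "ofv": self.ofv,
            "eta_shrinkage_pct": self.eta_shrinkage,
            "eps_shrinkage_pct": self.eps_shrinkage,
            "converged": self.converged,
            "message": self.message,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
        }


_OM_FLOOR = 1e-8


def _pack(theta, omega2, sigma2, model):
    x_t = np.where(model.log_scale, np.log(np.maximum(theta, 1e-300)), theta)
    return np.concatenate([x_t, np.log(np.maximum(omega2, _OM_FLOOR)), [np.log(sigma2)]])


def _unpack(x, model, n_eta):
    nt = len(model.theta_names)
    theta = np.where(model.log_scale, np.exp(x[:nt]), x[:nt])
    omega2 = np.exp(x[nt : nt + n_eta])
    omega2 = np.where(omega2 <= 2 * _OM_FLOOR, 0.0, omega2)
    sigma2 = float(np.exp(x[-1]))
    return theta, omega2, sigma2


@dataclass
class _OptResult:
    x: np.ndarray
    fun: float
    nit: int
    nfev: int
    success: bool
    message: str


def _minimize_bfgs(
    fun,
    x0: np.ndarray,
    bounds: np.ndarray,
    ftol: float = 1e-4,
    maxiter: int = 150,
    fd_step: float = 1e-5,
    max_first_step: float = 0.5,
) -> _OptResult:
    """Safeguarded BFGS with forward-difference gradients and box projection.

    Tailored to likelihood surfaces guarded by large penalty plateaus: the
    backtracking (Armijo) line search starts from a step capped at
    ``max_first_step`` per coordinate, so a huge first gradient cannot fling
    the iterate into the penalty region; stagnating line searches terminate
    the iteration.  Stops when the OFV improvement over an iteration falls
    below ``ftol`` (absolute) twice in a row.
    """
    nfev = [0]
    lo, hi = bounds[:, 0], bounds[:, 1]

    def f(x):
        nfev[0] += 1
        return fun(np.clip(x, lo, hi))

    def grad(x, fx):
        g = np.empty_like(x)
        for i in range(len(x)):
            xp = x.copy()
            xp[i] += fd_step
            g[i] = (f(xp) - fx) / fd_step
        return g

    x = np.clip(np.asarray(x0, float), lo, hi)
    fx = f(x)
    if not np.isfinite(fx) or fx >= _PENALTY:
        return _OptResult(x, fx, 0, nfev[0], False, "objective not finite at the initial point")
    g = grad(x, fx)
    H = np.eye(len(x))  # inverse-Hessian approximation
    small_count = 0
    message = "maximum iterations reached"
    success = False
    nit = 0
    for nit in range(1, maxiter + 1):
        d = -H @ g
        if d @ g >= 0:  # not a descent direction: reset
            H = np.eye(len(x))
            d = -g
        t = 1.0
        dmax = np.max(np.abs(d))
        if nit == 1 and dmax > max_first_step:
            t = max_first_step / dmax
        slope = d @ g
        accepted = False
        for _ in range(30):
            xn = np.clip(x + t * d, lo, hi)
            fn = f(xn)
            if fn <= fx + 1e-4 * t * slope and fn < _PENALTY:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            success = True
            message = "line search found no further decrease"
            break
        gn = grad(xn, fn)
        s = xn - x
        yv = gn - g
        sy = s @ yv
        if sy > 1e-12:
            if nit == 1:
                H = (sy / (yv @ yv)) * np.eye(len(x))
            rho = 1.0 / sy
            V = np.eye(len(x)) - rho * np.outer(s, yv)
            H = V @ H @ V.T + rho * np.outer(s, s)
        drop = fx - fn
        x, fx, g = xn, fn, gn
        if drop < ftol:
            small_count += 1
            if small_count >= 2:
                success = True
                message = "OFV improvement below tolerance"
                break
        else:
            small_count = 0
    return _OptResult(x, fx, nit, nfev[0], success, message)


def fit_nlme(
    subjects: Sequence[SubjectData],
    model: NlmeModel,
    theta0: np.ndarray,
    omega2_0: np.ndarray,
    sigma2_0: float,
    settings: FitSettings | None = None,
) -> FitResult:
    """Maximize the FOCE-I approximate likelihood over (theta, omega^2, sigma^2)."""
    settings = settings or FitSettings()
    subjects = list(subjects)
    if not subjects:
        raise EstimationError("no subjects to fit")
    n_eta = len(model.eta_names)
    nt = len(model.theta_names)
    warm: dict = {}

    def objective(x):
        theta, omega2, sigma2 = _unpack(x, model, n_eta)
        ofv, etas, _ = ofv_focei(
            subjects, model, theta, omega2, sigma2, eta_init=warm,
            inner_tol=settings.inner_tol, inner_maxiter=settings.inner_maxiter, details=True,
        )
        if np.isfinite(ofv) and ofv < _PENALTY:
            warm.update(etas)
        return ofv

    x0 = _pack(np.asarray(theta0, float), np.asarray(omega2_0, float), float(sigma2_0), model)
    bounds = (
        [(-12.0, 12.0) if model.log_scale[i] else (-10.0, 10.0) for i in range(nt)]
        + [(np.log(_OM_FLOOR), np.log(25.0))] * n_eta
        + [(np.log(1e-10), np.log(1e6))]
    )

    starts = [x0]
    if settings.n_starts > 1:
        rng = np.random.default_rng(settings.seed)
        starts += [x0 + rng.normal(0.0, settings.jitter_sd, size=len(x0)) for _ in range(settings.n_starts - 1)]

    def run_one(xs):
        # quasi-Newton rounds with a fresh inverse-Hessian each round: the
        # first round's curvature estimate is often poor on these surfaces,
        # so restarting from the incumbent recovers progress cheaply
        res = _minimize_bfgs(
            objective, xs, bounds=np.asarray(bounds),
            ftol=settings.outer_ftol, maxiter=settings.outer_maxiter, fd_step=settings.fd_step,
        )
        for _ in range(settings.max_restarts):
            nxt = _minimize_bfgs(
                objective, res.x, bounds=np.asarray(bounds),
                ftol=settings.outer_ftol, maxiter=settings.outer_maxiter, fd_step=settings.fd_step,
            )
            improved = res.fun - nxt.fun
            if nxt.fun < res.fun:
                nxt.nit += res.nit
                nxt.nfev += res.nfev
                res = nxt
            if improved < settings.restart_ftol:
                break
        return res

    best = None
    for xs in starts:
        warm.clear()
        res = run_one(xs)
        if best is None or res.fun < best.fun:
            best = res
    res = best

    theta, omega2, sigma2 = _unpack(res.x, model, n_eta)
    warm.clear()
    ofv, etas, infos = ofv_focei(
        subjects, model, theta, omega2, sigma2,
        inner_tol=settings.inner_tol, inner_maxiter=settings.inner_maxiter, details=True,
    )
    eta_df = pd.DataFrame(
        {name: [etas[s.id][k] for s in subjects] for k, name in enumerate(model.eta_names)},
        index=pd.Index([s.id for s in subjects], name="ID"),
    )
    inner_failures = sum(1 for i in infos.values() if i is None or not i["converged"])
    eta_shr, eps_shr = _shrinkage_from(eta_df, omega2, model, infos)
    return FitResult(
        model=model,
        theta={n: float(t) for n, t in zip(model.theta_names, theta)},
        omega2={n: float(o) for n, o in zip(model.eta_names, omega2)},
        sigma2=sigma2,
        ofv=float(ofv),
        eta_hat=eta_df,
        eta_shrinkage=eta_shr,
        eps_shrinkage=eps_shr,
        converged=bool(res.success) and inner_failures == 0,
        message=str(res.message),
        n_obs=sum(s.n_obs for s in subjects),
        n_subjects=len(subjects),
        inner_failures=inner_failures,
        settings=settings,
    )


def _shrinkage_from(eta_df, omega2, model, infos):
    eta_shr = {}
    for k, name in enumerate(model.eta_names):
        om = omega2[k]
        if om <= 0:
            eta_shr[name] = float("nan")
        else:
            sd = float(eta_df[name].std(ddof=1)) if len(eta_df) > 1 else 0.0
            eta_shr[name] = 100.0 * (1.0 - sd / math.sqrt(om))
    iwres = np.concatenate([i["r"] / np.sqrt(i["v"]) for i in infos.values() if i is not None])
    eps_shr = 100.0 * (1.0 - float(np.std(iwres, ddof=1))) if len(iwres) > 1 else float("nan")
    return eta_shr, eps_shr


def shrinkage(fit: FitResult) -> tuple[dict, float]:
    """Eta-shrinkage (%) per random effect and epsilon-shrinkage (%) of a fit."""
    return fit.eta_shrinkage, fit.eps_shrinkage


# --------------------------------------------------------------------------
# dataset adapters and the PK / PD drivers
# --------------------------------------------------------------------------

def save_fit(fit: FitResult, path) -> None:
    """Serialize a fit (estimates, OFV, etas, model spec) to JSON."""
    import json

    if isinstance(fit.model, ThreeCompartmentModel):
        model_spec = {
            "type": "ThreeCompartmentModel",
            "covariates": [
                {"param": e.param, "cov": e.cov, "form": e.form, "ref": e.ref} for e in fit.model.covariate_effects
            ],
        }
    elif isinstance(fit.model, EffectSiteEmaxModel):
        model_spec = {"type": "EffectSiteEmaxModel"}
    else:
        raise InputError(f"cannot serialize model of type {type(fit.model).__name__}")
    payload = fit.to_report()
    payload["model"] = model_spec
    payload["eta_hat"] = {str(k): fit.eta_hat.loc[k].to_dict() for k in fit.eta_hat.index}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_fit(path) -> FitResult:
    """Reload a serialized fit; subject IDs in eta_hat are restored as ints when possible."""
    import json

    with open(path) as fh:
        payload = json.load(fh)
    spec = payload["model"]
    if spec["type"] == "ThreeCompartmentModel":
        model = ThreeCompartmentModel(tuple(CovariateEffect(**c) for c in spec["covariates"]))
    elif spec["type"] == "EffectSiteEmaxModel":
        model = EffectSiteEmaxModel()
    else:
        raise InputError(f"unknown model type {spec['type']!r}")

    def _id(k):
        try:
            return int(k)
        except ValueError:
            return k

    eta = pd.DataFrame.from_dict({_id(k): v for k, v in payload["eta_hat"].items()}, orient="index")
    eta.index.name = "ID"
    return FitResult(
        model=model,
        theta=payload["theta"],
        omega2=payload["omega2"],
        sigma2=payload["sigma2"],
        ofv=payload["ofv"],
        eta_hat=eta[list(model.eta_names)],
        eta_shrinkage=payload["eta_shrinkage_pct"],
        eps_shrinkage=payload["eps_shrinkage_pct"],
        converged=payload["converged"],
        message=payload["message"],
        n_obs=payload["n_obs"],
        n_subjects=payload["n_subjects"],
        inner_failures=0,
        settings=FitSettings(),
    )


def subjects_from_dataset(dataset, kind: str = "pk") -> list[SubjectData]:
    """Build estimation subjects from an event-format study dataset.

    PK subjects carry non-BLQ concentration rows (M1 handling); PD subjects
    carry the BIS rows.  Covariates (WT, AGE, SEX + any laboratory columns)
    are taken from the subject's rows.
    """
    out = []
    for sid in dataset.subject_ids:
        obs = dataset.observations(kind)
        obs = obs[obs["ID"] == sid]
        if kind == "pk":
            obs = obs[obs["BLQ"] == 0]
        reg = dataset.regimen_for(sid)
        seg_t, seg_r = reg.segments()
        covs = dataset.covariates_for(sid)
        if covs.get("SEX") is not None:
            covs["MALE"] = 1.0 if covs["SEX"] == "M" else 0.0
        out.append(
            SubjectData(
                id=sid,
                times=obs["TIME"].to_numpy(float),
                y=obs["DV"].to_numpy(float),
                seg_t=seg_t,
                seg_r=seg_r,
                covariates=covs,
            )
        )
    return out


FINAL_PK_COVARIATES = (
    CovariateEffect(param="CL", cov="WT", form="power", ref=66.0),
    CovariateEffect(param="CL", cov="AGE", form="power", ref=72.5),
)


def fit_pk(
    dataset,
    init: pop_mod.PopulationModel | None = None,
    settings: FitSettings | None = None,
    covariate_effects: Sequence[CovariateEffect] | str = "final",
    omega2_init: np.ndarray | None = None,
    sigma2_init: float | None = None,
) -> FitResult:
    """Fit the population PK model by FOCE-I.

    ``covariate_effects``: "final" (weight and age power terms on CL, centered
    at 66 kg / 72.5 y), "base" (none), or an explicit sequence.  ``init``
    defaults to the reference population model.
    """
    if covariate_effects == "final":
        effects = FINAL_PK_COVARIATES
    elif covariate_effects == "base":
        effects = ()
    else:
        effects = tuple(covariate_effects)
    model = ThreeCompartmentModel(effects)
    init = init or pop_mod.reference_population()
    theta0 = np.concatenate(
        [
            init.pk.as_array(),
            [
                {"WT_on_CL": init.covariates.theta_wt, "AGE_on_CL": init.covariates.theta_age}.get(e.theta_name, 0.0)
                for e in effects
            ],
        ]
    )
    omega2_0 = np.maximum(init.omega.pk_variances(), 0.01) if omega2_init is None else omega2_init
    sigma2_0 = (max(init.residual.pk_sigma2, 0.01) if sigma2_init is None else sigma2_init)
    subjects = subjects_from_dataset(dataset, "pk")
    return fit_nlme(subjects, model, theta0, omega2_0, sigma2_0, settings)


def individual_pk_parameters(pk_fit: FitResult, dataset) -> dict:
    """Empirical-Bayes individual PK parameter vectors (V1..Q3) per subject."""
    model: ThreeCompartmentModel = pk_fit.model
    out = {}
    for subj in subjects_from_dataset(dataset, "pk"):
        eta = pk_fit.eta_hat.loc[subj.id].to_numpy()
        out[subj.id] = model.subject_params(pk_fit.theta_vector, eta, subj)
    return out


def fit_pd_sequential(
    dataset,
    pk_fit: FitResult,
    init: pop_mod.PopulationModel | None = None,
    settings: FitSettings | None = None,
    omega2_init: np.ndarray | None = None,
    sigma2_init: float | None = None,
) -> FitResult:
    """Sequential (IPP) PD fit: individual PK fixed at empirical Bayes values.

    Effect-site concentrations are recomputed from each subject's individual
    PK model; ke0, E0, Emax, EC50, gamma plus IIV on EC50/gamma and the
    additive BIS variance are estimated by FOCE-I on the BIS rows.
    """
    subjects = subjects_from_dataset(dataset, "pd")
    if not subjects or any(s.n_obs == 0 for s in subjects):
        raise EstimationError("dataset has subjects without BIS observations")
    ipp = individual_pk_parameters(pk_fit, dataset)
    for s in subjects:
        s.pk_params = ipp[s.id]
    model = EffectSiteEmaxModel()
    init = init or pop_mod.reference_population()
    theta0 = np.array([init.pd.ke0, init.pd.E0, init.pd.Emax, init.pd.EC50, init.pd.gamma])
    omega2_0 = np.maximum(init.omega.pd_variances(), 0.01) if omega2_init is None else omega2_init
    sigma2_0 = (max(init.residual.pd_sigma2, 0.1) if sigma2_init is None else sigma2_init)
    return fit_nlme(subjects, model, theta0, omega2_0, sigma2_0, settings)
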