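"""Hierarchical (population) layer over the structural model.

Fixed effects + power-law covariate model on clearance, log-normal
inter-individual variability (IIV), and the residual-error models:
proportional for plasma concentration, additive for BIS.

Individual parameters follow theta_i = theta_pop * covariate factor * exp(eta),
eta ~ N(0, omega^2) independently per parameter (diagonal Omega), which keeps
every structural parameter positive and makes the *median* (not mean) of the
sampled parameters equal the typical value at reference covariates.

Convention note: published NLME tables often label entries just "omega"/"sigma"
while the model is written with omega^2/sigma^2.  This package treats stored
values as variances; config files carry a SCALE key ("variance" | "sd") so
tables printed as standard deviations can be loaded by squaring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import yaml

from .core_model import InputError, ParameterError, PDParameters, PKParameters

PK_ETA_NAMES = ("V1", "V2", "V3", "CL", "Q2", "Q3")
PD_ETA_NAMES = ("EC50", "GAMMA")


@dataclass(frozen=True)
class CovariateModel:
    """Power-law covariate model on CL: CL = theta * (WT/ref_wt)^theta_wt * (AGE/ref_age)^theta_age."""

    ref_wt: float = 66.0
    ref_age: float = 72.5
    theta_wt: float = 0.74
    theta_age: float = -0.21

    def __post_init__(self):
        if not (self.ref_wt > 0 and self.ref_age > 0):
            raise ParameterError("covariate reference values must be strictly positive")

    def cl_factor(self, wt: float, age: float) -> float:
        if not (np.all(np.asarray(wt) > 0) and np.all(np.asarray(age) > 0)):
            raise InputError("weight and age must be strictly positive")
        return (wt / self.ref_wt) ** self.theta_wt * (age / self.ref_age) ** self.theta_age


@dataclass(frozen=True)
class OmegaMatrix:
    """Diagonal IIV variances (omega^2) for the PK and PD random effects.

    Off-diagonal elements are structurally zero (diagonal Omega); parameters
    absent here (ke0, E0, Emax) carry no IIV.
    """

    V1: float = 0.0
    V2: float = 0.0
    V3: float = 0.0
    CL: float = 0.0
    Q2: float = 0.0
    Q3: float = 0.0
    EC50: float = 0.0
    GAMMA: float = 0.0

    def __post_init__(self):
        for name in PK_ETA_NAMES + PD_ETA_NAMES:
            if getattr(self, name) < 0:
                raise ParameterError(f"omega^2 for {name} must be >= 0")

    def pk_variances(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PK_ETA_NAMES])

    def pd_variances(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PD_ETA_NAMES])


@dataclass(frozen=True)
class ResidualModel:
    """Residual-error variances: proportional for PK, additive for BIS.

    pk: y = pred * (1 + eps), eps ~ N(0, pk_sigma2)  -> Var = pk_sigma2 * pred^2
    pd: y = pred + eps,       eps ~ N(0, pd_sigma2)  -> Var = pd_sigma2
    """

    pk_sigma2: float = 0.0
    pd_sigma2: float = 0.0

    def __post_init__(self):
        if self.pk_sigma2 < 0 or self.pd_sigma2 < 0:
            raise ParameterError("residual variances must be >= 0")


@dataclass(frozen=True)
class PopulationModel:
    """Typical values + covariate model + IIV + residual error."""

    pk: PKParameters
    pd: PDParameters
    covariates: CovariateModel = field(default_factory=CovariateModel)
    omega: OmegaMatrix = field(default_factory=OmegaMatrix)
    residual: ResidualModel = field(default_factory=ResidualModel)

    def without_variability(self) -> "PopulationModel":
        return replace(self, omega=OmegaMatrix(), residual=ResidualModel())


@dataclass(frozen=True)
class IndividualParameters:
    """Per-subject structural parameters after covariates and eta draws."""

    pk: PKParameters
    pd: PDParameters
    eta: Mapping[str, float]


def reference_population() -> PopulationModel:
    """Final population model for elderly surgical patients (the package default).

    PK: V1 2.95 L, V2 45.15 L, V3 76.79 L, CL 1.01 L/min, Q2 0.76, Q3 0.66
    L/min with CL scaled by (WT/66)^0.74 * (AGE/72.5)^-0.21.  PD: ke0 1.09
    1/min, E0 93.40, Emax 45.77, EC50 233.91 ng/mL, gamma 3.00.

    The published dispersion entries (omega 0.02-0.11, sigma 0.26 and 7.70)
    are standard deviations — the reading under which the reported objective
    function values are reproduced (see docs/methods.md) — so they are
    squared into the variances stored here: e.g. sigma2_pk = 0.26^2 = 0.0676
    (26% proportional CV) and sigma2_pd = 7.70^2 (7.7 BIS units additive SD).
    """
    return PopulationModel(
        pk=PKParameters(V1=2.95, V2=45.15, V3=76.79, CL=1.01, Q2=0.76, Q3=0.66),
        pd=PDParameters(ke0=1.09, E0=93.40, Emax=45.77, EC50=233.91, gamma=3.00),
        covariates=CovariateModel(ref_wt=66.0, ref_age=72.5, theta_wt=0.74, theta_age=-0.21),
        omega=OmegaMatrix(V1=0.06**2, V2=0.11**2, V3=0.11**2, CL=0.03**2, Q2=0.03**2, Q3=0.02**2,
                          EC50=0.09**2, GAMMA=0.02**2),
        residual=ResidualModel(pk_sigma2=0.26**2, pd_sigma2=7.70**2),
    )


def individual_cl(theta_cl: float, cov: CovariateModel, wt: float, age: float, eta_cl: float = 0.0) -> float:
    """Individual clearance: theta_cl * (wt/ref)^theta_wt * (age/ref)^theta_age * exp(eta)."""
    return float(theta_cl * cov.cl_factor(wt, age) * np.exp(eta_cl))


def sample_individual(
    pop: PopulationModel, wt: float, age: float, rng: np.random.Generator
) -> IndividualParameters:
    """Draw one virtual subject's parameters (log-normal IIV, diagonal Omega).

    Reproducible under a fixed-seed generator.  With Omega = 0 the subject
    equals the typical subject at its covariates.
    """
    if not isinstance(rng, np.random.Generator):
        raise InputError("rng must be a seeded numpy Generator")
    om = pop.omega
    eta = {n: rng.normal(0.0, np.sqrt(getattr(om, n))) if getattr(om, n) > 0 else 0.0
           for n in PK_ETA_NAMES + PD_ETA_NAMES}
    t = pop.pk
    pk = PKParameters(
        V1=t.V1 * np.exp(eta["V1"]),
        V2=t.V2 * np.exp(eta["V2"]),
        V3=t.V3 * np.exp(eta["V3"]),
        CL=individual_cl(t.CL, pop.covariates, wt, age, eta["CL"]),
        Q2=t.Q2 * np.exp(eta["Q2"]),
        Q3=t.Q3 * np.exp(eta["Q3"]),
    )
    d = pop.pd
    pd = PDParameters(
        ke0=d.ke0,
        E0=d.E0,
        Emax=d.Emax,
        EC50=d.EC50 * np.exp(eta["EC50"]),
        gamma=d.gamma * np.exp(eta["GAMMA"]),
    )
    return IndividualParameters(pk=pk, pd=pd, eta=eta)


def residual_variance(pred, kind: str, res: ResidualModel):
    """Observation variance the estimator consumes: sigma2*pred^2 (pk) or sigma2 (pd)."""
    pred = np.asarray(pred, dtype=float)
    if kind == "pk":
        return res.pk_sigma2 * pred**2
    if kind == "pd":
        return np.full_like(pred, res.pd_sigma2)
    raise InputError(f"kind must be 'pk' or 'pd', got {kind!r}")


def apply_residual(pred, kind: str, res: ResidualModel, rng: np.random.Generator):
    """Add residual error to predictions: proportional (pk) or additive (pd)."""
    pred = np.asarray(pred, dtype=float)
    if not np.all(np.isfinite(pred)):
        raise InputError("predictions must be finite")
    if kind == "pk":
        if np.any(pred < 0):
            raise InputError("pk predictions must be >= 0")
        eps = rng.normal(0.0, np.sqrt(res.pk_sigma2), size=pred.shape)
        return pred * (1.0 + eps)
    if kind == "pd":
        eps = rng.normal(0.0, np.sqrt(res.pd_sigma2), size=pred.shape)
        return pred + eps
    raise InputError(f"kind must be 'pk' or 'pd', got {kind!r}")


# --------------------------------------------------------------------------
# flat config serialization
# --------------------------------------------------------------------------

_CONFIG_KEYS = (
    "V1", "V2", "V3", "CL", "Q2", "Q3",
    "THETA_WT_CL", "THETA_AGE_CL", "REF_WT", "REF_AGE",
    "KE0", "E0", "EMAX", "EC50", "GAMMA",
    "OMEGA_V1", "OMEGA_V2", "OMEGA_V3", "OMEGA_CL", "OMEGA_Q2", "OMEGA_Q3",
    "OMEGA_EC50", "OMEGA_GAMMA", "SIGMA_PK", "SIGMA_PD", "SCALE",
)


def to_config(pop: PopulationModel) -> dict:
    """Flat key/value mapping of the model (variances on the variance scale)."""
    return {
        "V1": pop.pk.V1, "V2": pop.pk.V2, "V3": pop.pk.V3,
        "CL": pop.pk.CL, "Q2": pop.pk.Q2, "Q3": pop.pk.Q3,
        "THETA_WT_CL": pop.covariates.theta_wt, "THETA_AGE_CL": pop.covariates.theta_age,
        "REF_WT": pop.covariates.ref_wt, "REF_AGE": pop.covariates.ref_age,
        "KE0": pop.pd.ke0, "E0": pop.pd.E0, "EMAX": pop.pd.Emax,
        "EC50": pop.pd.EC50, "GAMMA": pop.pd.gamma,
        "OMEGA_V1": pop.omega.V1, "OMEGA_V2": pop.omega.V2, "OMEGA_V3": pop.omega.V3,
        "OMEGA_CL": pop.omega.CL, "OMEGA_Q2": pop.omega.Q2, "OMEGA_Q3": pop.omega.Q3,
        "OMEGA_EC50": pop.omega.EC50, "OMEGA_GAMMA": pop.omega.GAMMA,
        "SIGMA_PK": pop.residual.pk_sigma2, "SIGMA_PD": pop.residual.pd_sigma2,
        "SCALE": "variance",
    }


def from_config(cfg: Mapping) -> PopulationModel:
    """Build a model from a flat mapping; unknown keys are rejected.

    SCALE="sd" squares the OMEGA_*/SIGMA_* entries on load.
    """
    unknown = set(cfg) - set(_CONFIG_KEYS)
    if unknown:
        raise InputError(f"unknown config keys: {sorted(unknown)}")
    missing = set(_CONFIG_KEYS) - {"SCALE", "REF_WT", "REF_AGE"} - set(cfg)
    if missing:
        raise InputError(f"missing config keys: {sorted(missing)}")
    scale = cfg.get("SCALE", "variance")
    if scale not in ("variance", "sd"):
        raise InputError(f"SCALE must be 'variance' or 'sd', got {scale!r}")
    sq = (lambda v: float(v) ** 2) if scale == "sd" else float
    return PopulationModel(
        pk=PKParameters(V1=cfg["V1"], V2=cfg["V2"], V3=cfg["V3"],
                        CL=cfg["CL"], Q2=cfg["Q2"], Q3=cfg["Q3"]),
        pd=PDParameters(ke0=cfg["KE0"], E0=cfg["E0"], Emax=cfg["EMAX"],
                        EC50=cfg["EC50"], gamma=cfg["GAMMA"]),
        covariates=CovariateModel(
            ref_wt=float(cfg.get("REF_WT", 66.0)), ref_age=float(cfg.get("REF_AGE", 72.5)),
            theta_wt=float(cfg["THETA_WT_CL"]), theta_age=float(cfg["THETA_AGE_CL"]),
        ),
        omega=OmegaMatrix(
            V1=sq(cfg["OMEGA_V1"]), V2=sq(cfg["OMEGA_V2"]), V3=sq(cfg["OMEGA_V3"]),
            CL=sq(cfg["OMEGA_CL"]), Q2=sq(cfg["OMEGA_Q2"]), Q3=sq(cfg["OMEGA_Q3"]),
            EC50=sq(cfg["OMEGA_EC50"]), GAMMA=sq(cfg["OMEGA_GAMMA"]),
        ),
        residual=ResidualModel(pk_sigma2=sq(cfg["SIGMA_PK"]), pd_sigma2=sq(cfg["SIGMA_PD"])),
    )


def save_config(pop: PopulationModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_config(pop), fh, sort_keys=False)


def load_config(path) -> PopulationModel:
    with open(path) as fh:
        return from_config(yaml.safe_load(fh))
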