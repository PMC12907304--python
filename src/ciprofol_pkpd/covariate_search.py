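"""Stepwise covariate modelling (SCM) on the population PK model.

Forward inclusion tests each candidate covariate singly on top of the current
model and keeps the one with the largest objective-function drop of at least
3.84 points (chi-squared, alpha = 0.05, df = 1); the pass repeats until no
candidate qualifies.  Backward elimination then removes included covariates
whose deletion raises the objective by less than 10.82 points (alpha = 0.001,
df = 1), iterating to a fixed point.  Continuous covariates enter as power
functions centered at the cohort median; dichotomous ones as fractional
shifts.  The whole search is a deterministic function of (data, candidates,
settings).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import InputError
from .estimation import (
    CovariateEffect,
    FitResult,
    FitSettings,
    SubjectData,
    ThreeCompartmentModel,
    fit_nlme,
    subjects_from_dataset,
)

log = logging.getLogger(__name__)

#: continuous laboratory/demographic covariates offered to the search by default
DEFAULT_CONTINUOUS = ("WT", "AGE", "BMI", "CREAT", "ALB", "ALT", "AST", "TBIL", "TP")
DEFAULT_CATEGORICAL = ("MALE",)
DEFAULT_TARGETS = ("CL", "V1")


def chi2_threshold(alpha: float, df: int = 1) -> float:
    """Critical OFV change: upper-alpha quantile of chi-squared(df)."""
    if not 0 < alpha < 1:
        raise InputError(f"alpha must be in (0, 1), got {alpha!r}")
    if df < 1:
        raise InputError(f"df must be >= 1, got {df!r}")
    return float(stats.chi2.ppf(1.0 - alpha, df))


FORWARD_ALPHA = 0.05
BACKWARD_ALPHA = 0.001


def default_candidates(
    subjects: Sequence[SubjectData],
    targets: Sequence[str] = DEFAULT_TARGETS,
    continuous: Sequence[str] = DEFAULT_CONTINUOUS,
    categorical: Sequence[str] = DEFAULT_CATEGORICAL,
) -> list[CovariateEffect]:
    """Build the candidate list, centering continuous covariates at the cohort median."""
    cands = []
    for target in targets:
        for cov in continuous:
            vals = [s.covariates[cov] for s in subjects if cov in s.covariates]
            if not vals:
                continue
            cands.append(CovariateEffect(param=target, cov=cov, form="power", ref=float(np.median(vals))))
        for cov in categorical:
            if all(cov in s.covariates for s in subjects):
                cands.append(CovariateEffect(param=target, cov=cov, form="shift"))
    return cands


@dataclass
class ScmStep:
    phase: str  # "forward" | "backward"
    candidate: CovariateEffect
    ofv_before: float
    ofv_after: float
    decision: str  # "tested" | "added" | "removed" | "rejected" | "kept" | "failed"

    @property
    def delta(self) -> float:
        return self.ofv_before - self.ofv_after


@dataclass
class ScmResult:
    steps: list[ScmStep]
    final_fit: FitResult
    final_effects: tuple[CovariateEffect, ...]

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": i + 1,
                    "phase": s.phase,
                    "candidate": s.candidate.theta_name,
                    "OFV_before": s.ofv_before,
                    "OFV_after": s.ofv_after,
                    "dOFV": s.delta,
                    "decision": s.decision,
                }
                for i, s in enumerate(self.steps)
            ]
        )


def _refit_with(subjects, fit: FitResult, model, extra_theta: dict | None, settings) -> FitResult:
    """Refit a modified model warm-started from the current estimates."""
    theta0 = np.array([fit.theta.get(n, (extra_theta or {}).get(n, 0.0)) for n in model.theta_names])
    omega2_0 = np.maximum(fit.omega2_vector, 1e-4)
    return fit_nlme(subjects, model, theta0, omega2_0, max(fit.sigma2, 1e-6), settings)


def forward_step(
    subjects: Sequence[SubjectData],
    current_fit: FitResult,
    candidates: Sequence[CovariateEffect],
    settings: FitSettings | None = None,
    threshold: float | None = None,
) -> tuple[CovariateEffect | None, FitResult, list[ScmStep]]:
    """One forward-inclusion pass: fit each candidate singly, keep the best qualifying one.

    Selection: largest OFV drop >= threshold (default chi2 at alpha=0.05,
    df=1); exact ties broken lexically by covariate name.  Candidates whose
    fit fails are skipped with a warning.
    """
    threshold = chi2_threshold(FORWARD_ALPHA, 1) if threshold is None else threshold
    steps: list[ScmStep] = []
    trials: list[tuple[float, str, CovariateEffect, FitResult]] = []
    for cand in candidates:
        model = current_fit.model.with_covariate(cand)
        try:
            fit = _refit_with(subjects, current_fit, model, {cand.theta_name: 0.0}, settings)
        except Exception as exc:  # noqa: BLE001 - candidate failures must not kill the search
            log.warning("candidate %s failed to fit: %s", cand.theta_name, exc)
            steps.append(ScmStep("forward", cand, current_fit.ofv, float("nan"), "failed"))
            continue
        drop = current_fit.ofv - fit.ofv
        steps.append(ScmStep("forward", cand, current_fit.ofv, fit.ofv, "tested"))
        if drop >= threshold:
            trials.append((drop, cand.theta_name, cand, fit))
    if not trials:
        return None, current_fit, steps
    trials.sort(key=lambda t: (-t[0], t[1]))
    drop, _, selected, best_fit = trials[0]
    for s in steps:
        if s.candidate == selected:
            s.decision = "added"
    return selected, best_fit, steps


def backward_step(
    subjects: Sequence[SubjectData],
    full_fit: FitResult,
    included: Sequence[CovariateEffect],
    settings: FitSettings | None = None,
    threshold: float | None = None,
) -> tuple[tuple[CovariateEffect, ...], FitResult, list[ScmStep]]:
    """Backward elimination to a fixed point.

    Each included covariate is removed singly; if the smallest resulting OFV
    increase is below the threshold (default chi2 at alpha=0.001, df=1) that
    covariate is dropped, and the pass repeats on the reduced model.
    """
    threshold = chi2_threshold(BACKWARD_ALPHA, 1) if threshold is None else threshold
    steps: list[ScmStep] = []
    kept = list(included)
    fit = full_fit
    while kept:
        trials = []
        for eff in kept:
            model = fit.model.without_covariate(eff)
            try:
                red = _refit_with(subjects, fit, model, None, settings)
            except Exception as exc:  # noqa: BLE001
                log.warning("removal fit for %s failed: %s", eff.theta_name, exc)
                steps.append(ScmStep("backward", eff, fit.ofv, float("nan"), "failed"))
                continue
            increase = red.ofv - fit.ofv
            steps.append(ScmStep("backward", eff, fit.ofv, red.ofv, "tested"))
            trials.append((increase, eff.theta_name, eff, red))
        if not trials:
            break
        trials.sort(key=lambda t: (t[0], t[1]))
        increase, _, eff, red = trials[0]
        if increase < threshold:
            for s in steps:
                if s.candidate == eff and s.decision == "tested":
                    s.decision = "removed"
            kept.remove(eff)
            fit = red
        else:
            for s in steps:
                if s.decision == "tested":
                    s.decision = "kept"
            break
    return tuple(kept), fit, steps


def run_scm(
    subjects: Sequence[SubjectData],
    base_fit: FitResult,
    candidates: Sequence[CovariateEffect],
    settings: FitSettings | None = None,
    max_forward_steps: int = 10,
) -> ScmResult:
    """Full greedy forward-inclusion / backward-elimination search."""
    steps: list[ScmStep] = []
    fit = base_fit
    included: list[CovariateEffect] = []
    remaining = list(candidates)
    for _ in range(max_forward_steps):
        selected, fit, st = forward_step(subjects, fit, remaining, settings)
        steps.extend(st)
        if selected is None:
            break
        included.append(selected)
        remaining = [c for c in remaining if c != selected]
    retained, fit, st = backward_step(subjects, fit, included, settings)
    steps.extend(st)
    return ScmResult(steps=steps, final_fit=fit, final_effects=retained)


def scm_pk(
    dataset,
    init_theta: np.ndarray,
    init_omega2: np.ndarray,
    init_sigma2: float,
    candidates: Sequence[CovariateEffect] | None = None,
    settings: FitSettings | None = None,
) -> ScmResult:
    """Convenience driver: SCM on the three-compartment PK model of a study dataset."""
    subjects = subjects_from_dataset(dataset, "pk")
    if candidates is None:
        candidates = default_candidates(subjects)
    base = fit_nlme(subjects, ThreeCompartmentModel(), init_theta, init_omega2, init_sigma2, settings)
    return run_scm(subjects, base, candidates, settings)
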