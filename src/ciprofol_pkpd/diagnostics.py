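"""Model qualification: residual tables, nonparametric bootstrap, pc-VPC.

CWRES follows the FOCE linearization: the model is expanded to first order in
eta around the conditional mode, so the marginal covariance of a subject's
observations is G Omega G' + V with G = df/deta at the mode and V the
(interaction) residual variance; CWRES is the Cholesky-whitened residual
DV - IPRED + G eta_hat under that covariance.  With Omega = 0 and additive
error this collapses to (DV - PRED)/sigma.

The bootstrap resamples *subjects* (the exchangeable unit) with replacement
and refits each replicate; parameter uncertainty is summarized by the
2.5th/50th/97.5th percentiles of the replicate estimates.

The prediction-corrected VPC normalizes each observation and each simulated
observation by its bin's median population prediction — ratio form for
proportional-error concentrations, additive form for the bounded additive-
error BIS scale — and compares observed 5th/50th/95th percentiles per bin
with confidence bands from model simulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core_model import InputError
from .estimation import (
    FitResult,
    FitSettings,
    SubjectData,
    _predict_with_jac,
    _variance,
    fit_pk,
    subjects_from_dataset,
)


# --------------------------------------------------------------------------
# residual table
# --------------------------------------------------------------------------

def _dose_starts(subj: SubjectData) -> np.ndarray:
    """Times at which the input rate increases (dose starts), for TAD."""
    starts = []
    prev = 0.0
    for k, r in enumerate(subj.seg_r):
        if r > prev:
            starts.append(subj.seg_t[k])
        prev = r
    return np.asarray(starts)


def residual_table(fit: FitResult, subjects: Sequence[SubjectData]) -> pd.DataFrame:
    """Per-observation diagnostics: DV, PRED, IPRED, IWRES, CWRES, TAD.

    PRED is the population prediction (eta = 0); IPRED the individual
    prediction at the empirical Bayes eta; CWRES the FOCE-linearized
    standardized residual.
    """
    model = fit.model
    theta = fit.theta_vector
    omega2 = fit.omega2_vector
    active = np.flatnonzero(omega2 > 0)
    rows = []
    for subj in subjects:
        eta = fit.eta_hat.loc[subj.id].to_numpy()
        pred = model.predict(theta, np.zeros_like(eta), subj)
        f, G = _predict_with_jac(model, theta, eta, active, subj)
        v = _variance(f, model.residual_kind, fit.sigma2)
        cov = np.diag(v)
        if len(active):
            om = omega2[active]
            cov = cov + (G * om) @ G.T
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise InputError(f"singular observation covariance for subject {subj.id}") from exc
        res = subj.y - f + (G @ eta[active] if len(active) else 0.0)
        cwres = np.linalg.solve(L, res)
        iwres = (subj.y - f) / np.sqrt(v)
        starts = _dose_starts(subj)
        for j, t in enumerate(subj.times):
            past = starts[starts <= t]
            tad = t - past[-1] if len(past) else t
            rows.append(
                {
                    "ID": subj.id,
                    "TIME": t,
                    "TAD": tad,
                    "DV": subj.y[j],
                    "PRED": pred[j],
                    "IPRED": f[j],
                    "IWRES": iwres[j],
                    "CWRES": cwres[j],
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    replicates: pd.DataFrame  # one row per converged replicate
    summary: pd.DataFrame  # median + 2.5/97.5 percentiles per parameter
    n_requested: int
    n_failed: int

    @property
    def convergence_fraction(self) -> float:
        return 1.0 - self.n_failed / self.n_requested


def resample_dataset(dataset, rng: np.random.Generator):
    """Subject-level resampling with replacement; subjects are relabeled 1..n."""
    from .synthetic_study import StudyDataset

    ids = dataset.subject_ids
    chosen = rng.choice(ids, size=len(ids), replace=True)
    parts = []
    for new_id, sid in enumerate(chosen, start=1):
        sub = dataset.df[dataset.df["ID"] == sid].copy()
        sub["ID"] = new_id
        parts.append(sub)
    return StudyDataset(df=pd.concat(parts, ignore_index=True), design=dataset.design)


def bootstrap(
    dataset,
    n_reps: int,
    seed: int,
    refit: Callable | None = None,
    settings: FitSettings | None = None,
) -> BootstrapResult:
    """Nonparametric bootstrap: resample subjects, refit, summarize percentiles.

    ``refit`` maps a dataset to a FitResult (default: the final-covariate PK
    fit); replicates that raise or fail to converge are excluded and counted.
    Deterministic for a fixed seed.
    """
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    refit = refit or (lambda ds: fit_pk(ds, settings=settings))
    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    for _ in range(n_reps):
        rep = resample_dataset(dataset, rng)
        try:
            fit = refit(rep)
        except Exception:  # noqa: BLE001 - failed replicates are counted, not fatal
            n_failed += 1
            continue
        row = dict(fit.theta)
        row.update({f"omega2_{k}": v for k, v in fit.omega2.items()})
        row["sigma2"] = fit.sigma2
        row["ofv"] = fit.ofv
        rows.append(row)
    if not rows:
        raise InputError("all bootstrap replicates failed")
    reps = pd.DataFrame(rows)
    params = [c for c in reps.columns if c != "ofv"]
    summary = pd.DataFrame(
        {
            "median": reps[params].median(),
            "p2.5": reps[params].quantile(0.025),
            "p97.5": reps[params].quantile(0.975),
        }
    )
    return BootstrapResult(replicates=reps, summary=summary, n_requested=n_reps, n_failed=n_failed)


# --------------------------------------------------------------------------
# prediction-corrected VPC
# --------------------------------------------------------------------------

@dataclass
class VpcResult:
    table: pd.DataFrame  # per bin: observed and simulated-band percentiles + coverage flags
    n_sim: int

    @property
    def coverage_fraction(self) -> float:
        flags = self.table[["cover_5", "cover_50", "cover_95"]].to_numpy()
        return float(flags.mean())


def _bin_edges(times: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.quantile(times, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(qs)
    edges[-1] = edges[-1] + 1e-9
    return edges


def pc_vpc(
    subjects: Sequence[SubjectData],
    fit: FitResult,
    n_sim: int = 200,
    bins: int | Sequence[float] = 8,
    seed: int = 0,
    percentiles: tuple[float, float, float] = (5.0, 50.0, 95.0),
) -> VpcResult:
    """Prediction-corrected visual predictive check of a fitted model.

    Observations and simulations are corrected by the bin-median population
    prediction (ratio form under proportional error, additive form under
    additive error); observed percentiles per time bin are compared with the
    95% band of the same percentiles across ``n_sim`` simulated replicates.
    """
    if n_sim < 2:
        raise InputError("n_sim must be >= 2")
    model = fit.model
    theta = fit.theta_vector
    omega2 = fit.omega2_vector
    rng = np.random.default_rng(seed)

    times = np.concatenate([s.times for s in subjects])
    y = np.concatenate([s.y for s in subjects])
    pred = np.concatenate([model.predict(theta, np.zeros(len(omega2)), s) for s in subjects])

    edges = np.asarray(_bin_edges(times, bins) if np.isscalar(bins) else bins, dtype=float)
    which = np.clip(np.digitize(times, edges) - 1, 0, len(edges) - 2)

    # bin-median population prediction drives the correction
    med_pred = np.array([np.median(pred[which == b]) if np.any(which == b) else np.nan for b in range(len(edges) - 1)])
    # merge empty bins into their left neighbor
    for b in np.flatnonzero(np.isnan(med_pred)):
        which[which == b] = max(b - 1, 0)

    def correct(values: np.ndarray) -> np.ndarray:
        out = np.empty_like(values)
        for b in range(len(edges) - 1):
            m = which == b
            if not np.any(m):
                continue
            if model.residual_kind == "prop":
                out[m] = values[m] * med_pred[b] / pred[m]
            else:
                out[m] = values[m] + (med_pred[b] - pred[m])
        return out

    pc_obs = correct(y)
    obs_pct = {p: np.array([np.percentile(pc_obs[which == b], p) for b in range(len(edges) - 1)]) for p in percentiles}

    sim_pct = {p: np.empty((n_sim, len(edges) - 1)) for p in percentiles}
    for k in range(n_sim):
        sims = []
        for s in subjects:
            eta = np.where(omega2 > 0, rng.normal(0.0, np.sqrt(np.maximum(omega2, 0))), 0.0)
            fsim = model.predict(theta, eta, s)
            if model.residual_kind == "prop":
                ysim = fsim * (1.0 + rng.normal(0.0, np.sqrt(fit.sigma2), len(fsim)))
            else:
                ysim = fsim + rng.normal(0.0, np.sqrt(fit.sigma2), len(fsim))
            sims.append(ysim)
        pc_sim = correct(np.concatenate(sims))
        for p in percentiles:
            sim_pct[p][k] = [np.percentile(pc_sim[which == b], p) for b in range(len(edges) - 1)]

    rows = []
    used = sorted(set(which.tolist()))
    for b in used:
        row = {
            "bin": b,
            "t_lo": edges[b],
            "t_hi": edges[b + 1],
            "n_obs": int(np.sum(which == b)),
        }
        for p, tag in zip(percentiles, ("5", "50", "95")):
            lo, hi = np.percentile(sim_pct[p][:, b], [2.5, 97.5])
            row[f"obs_{tag}"] = obs_pct[p][b]
            row[f"sim_{tag}_lo"] = lo
            row[f"sim_{tag}_hi"] = hi
            row[f"cover_{tag}"] = bool(lo <= obs_pct[p][b] <= hi)
        rows.append(row)
    return VpcResult(table=pd.DataFrame(rows), n_sim=n_sim)


def pc_vpc_dataset(dataset, fit: FitResult, kind: str = "pk", **kwargs) -> VpcResult:
    """pc-VPC convenience wrapper building subjects from a study dataset."""
    subjects = subjects_from_dataset(dataset, kind)
    if kind == "pd":
        from .estimation import individual_pk_parameters

        raise InputError("for PD VPCs pass subjects with pk_params attached to pc_vpc directly")
    return pc_vpc(subjects, fit, **kwargs)


# --------------------------------------------------------------------------
# optional plots
# --------------------------------------------------------------------------

def plot_gof(table: pd.DataFrame, path) -> None:
    """Goodness-of-fit quartet: DV vs PRED/IPRED, CWRES vs PRED/TAD."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    for ax, xcol in zip(axes[0], ("PRED", "IPRED")):
        ax.plot(table[xcol], table["DV"], "o", ms=3, alpha=0.5)
        lim = [0, max(table[xcol].max(), table["DV"].max())]
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel(xcol)
        ax.set_ylabel("DV")
    for ax, xcol in zip(axes[1], ("PRED", "TAD")):
        ax.plot(table[xcol], table["CWRES"], "o", ms=3, alpha=0.5)
        ax.axhline(0, color="k", lw=1)
        for yv in (-2, 2):
            ax.axhline(yv, color="k", ls="--", lw=1)
        ax.set_xlabel(xcol)
        ax.set_ylabel("CWRES")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_vpc(vpc: VpcResult, path, logy: bool = False) -> None:
    """Observed percentile curves over the simulated confidence bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = 0.5 * (vpc.table["t_lo"] + vpc.table["t_hi"])
    fig, ax = plt.subplots(figsize=(7, 5))
    for tag, color in zip(("5", "50", "95"), ("tab:blue", "tab:red", "tab:blue")):
        ax.fill_between(t, vpc.table[f"sim_{tag}_lo"], vpc.table[f"sim_{tag}_hi"], alpha=0.25, color=color)
        ax.plot(t, vpc.table[f"obs_{tag}"], "-o", ms=3, color=color, label=f"obs {tag}th")
    if logy:
        ax.set_yscale("log")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("prediction-corrected DV")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
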