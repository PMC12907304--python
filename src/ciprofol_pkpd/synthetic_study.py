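"""Virtual clinical study generator and event-format dataset I/O.

Emulates the study design behind the reference model: 20 elderly surgical
patients, a 0.4 mg/kg loading infusion over 1 min followed by 0.8 mg/kg/h
maintenance starting at 5 min, arterial PK sampling at protocol offsets
(4 during/after the bolus, 6 during infusion, 9 after cessation — 19 nominal
samples per subject) with BIS recorded synchronously at the same clock times.

Datasets use the standard NLME event-record layout: one row per dose event
(EVID=1) or observation (EVID=0), columns ID, TIME, EVID, AMT, RATE, DV, MDV,
BLQ, CMT, WT, AGE, SEX.  Observed concentrations below the 5 ng/mL LLOQ are
flagged BLQ (kept in the table, excluded from estimation — M1 handling).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import DoseEvent, InputError, Regimen, simulate_profile
from .population import (
    IndividualParameters,
    PopulationModel,
    apply_residual,
    sample_individual,
)

REQUIRED_COLUMNS = ("ID", "TIME", "EVID", "AMT", "RATE", "DV", "MDV", "BLQ", "CMT", "WT", "AGE", "SEX")
#: laboratory covariate columns (optional in files, written by the generator)
OPTIONAL_COLUMNS = ("BMI", "CREAT", "ALB", "ALT", "AST", "TBIL", "TP")

#: cohort summaries used by the demographic sampler: (mean, sd, low, high)
AGE_DIST = (72.95, 4.47, 67.0, 82.0)
WT_DIST = (65.63, 9.34, 49.0, 80.0)
MALE_FRACTION = 0.55

#: laboratory covariates (not in the final model; exercised by covariate screening)
LAB_DISTS = {
    "BMI": (24.7, 2.31, 21.20, 29.38),
    "CREAT": (64.65, 18.43, 37.0, 107.0),
    "ALB": (40.4, 3.02, 36.7, 44.7),
    "ALT": (23.85, 13.62, 8.0, 73.0),
    "AST": (21.25, 3.57, 16.0, 28.0),
    "TBIL": (11.38, 5.7, 5.0, 28.3),
    "TP": (69.30, 4.6, 61.6, 81.6),
}


@dataclass(frozen=True)
class SubjectRecord:
    """One virtual patient: demographics plus optional laboratory covariates."""

    id: int
    age: float
    wt: float
    sex: str  # "M" / "F"
    labs: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (AGE_DIST[2] <= self.age <= AGE_DIST[3]):
            raise InputError(f"age {self.age} outside cohort range {AGE_DIST[2:]}")
        if not (WT_DIST[2] <= self.wt <= WT_DIST[3]):
            raise InputError(f"weight {self.wt} outside cohort range {WT_DIST[2:]}")


@dataclass(frozen=True)
class StudyDesign:
    """Dosing protocol + sampling schedule of the emulated study."""

    n_subjects: int = 20
    bolus_mg_per_kg: float = 0.4
    bolus_duration: float = 1.0
    maintenance_mg_per_kg_h: float = 0.8
    maintenance_start: float = 5.0
    infusion_duration_range: tuple[float, float] = (60.0, 180.0)
    lloq: float = 5.0
    bolus_offsets: tuple[float, ...] = (0.0, 1.0, 3.0, 5.0)  # after bolus start
    infusion_offsets: tuple[float, ...] = (5.0, 10.0, 15.0, 30.0, 45.0, 60.0)  # after infusion start
    post_offsets: tuple[float, ...] = (3.0, 5.0, 10.0, 30.0, 60.0, 90.0, 120.0, 240.0, 360.0)  # after cessation

    def __post_init__(self):
        lo, hi = self.infusion_duration_range
        if not (0 < lo <= hi):
            raise InputError("infusion duration range must be positive and ordered")
        for offs in (self.bolus_offsets, self.infusion_offsets, self.post_offsets):
            arr = np.asarray(offs)
            if np.any(arr < 0) or np.any(np.diff(arr) <= 0):
                raise InputError("sampling offsets must be non-negative and strictly increasing")

    @property
    def n_samples_per_subject(self) -> int:
        return len(self.bolus_offsets) + len(self.infusion_offsets) + len(self.post_offsets)

    def sample_times(self, infusion_duration: float) -> np.ndarray:
        """Absolute sampling clock times for one subject (sorted, unique)."""
        if infusion_duration <= 0:
            raise InputError("infusion duration must be > 0")
        t = np.concatenate(
            [
                np.asarray(self.bolus_offsets),
                self.maintenance_start + np.asarray(self.infusion_offsets),
                self.maintenance_start + infusion_duration + np.asarray(self.post_offsets),
            ]
        )
        return np.sort(t)

    def regimen(self, wt: float, infusion_duration: float) -> Regimen:
        events = [
            DoseEvent(start=0.0, rate=self.bolus_mg_per_kg * wt / self.bolus_duration, duration=self.bolus_duration),
            DoseEvent(
                start=self.maintenance_start,
                rate=self.maintenance_mg_per_kg_h * wt / 60.0,
                duration=infusion_duration,
            ),
        ]
        return Regimen.from_events(events)


@dataclass
class StudyDataset:
    """Event-format table plus (for synthetic data) the generating truth."""

    df: pd.DataFrame
    design: StudyDesign | None = None
    truth: dict | None = None  # id -> {"pk": .., "pd": .., "eta": .., "duration": ..}

    @property
    def subject_ids(self) -> list:
        return sorted(self.df["ID"].unique().tolist())

    def observations(self, kind: str) -> pd.DataFrame:
        cmt = 1 if kind == "pk" else 4
        return self.df[(self.df["EVID"] == 0) & (self.df["CMT"] == cmt)]

    def regimen_for(self, subject_id) -> Regimen:
        rows = self.df[(self.df["ID"] == subject_id) & (self.df["EVID"] == 1)]
        events = [
            DoseEvent(start=float(r.TIME), rate=float(r.RATE), duration=float(r.AMT) / float(r.RATE))
            for r in rows.itertuples()
        ]
        return Regimen.from_events(events)

    def covariates_for(self, subject_id) -> dict:
        row = self.df[self.df["ID"] == subject_id].iloc[0]
        covs = {"WT": float(row.WT), "AGE": float(row.AGE), "SEX": row.SEX}
        for c in OPTIONAL_COLUMNS:
            if c in self.df.columns:
                covs[c] = float(getattr(row, c))
        return covs


def _calibrated_loc(mean, sd, low, high) -> float:
    """Location parameter whose [low, high]-truncated normal has the given mean.

    Asymmetric truncation shifts the mean of a truncated normal away from its
    location; solving for the location reproduces the reported cohort mean.
    """
    from scipy.optimize import brentq

    def shift(loc):
        a, b = (low - loc) / sd, (high - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    lo, hi = mean - 3 * sd, mean + 3 * sd
    return float(brentq(shift, lo, hi))


def _truncnorm_rvs(mean, sd, low, high, size, rng) -> np.ndarray:
    loc = _calibrated_loc(mean, sd, low, high)
    a, b = (low - loc) / sd, (high - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def generate_demographics(n: int, seed_or_rng) -> list[SubjectRecord]:
    """Sample a virtual elderly cohort from the study's demographic summaries.

    Age ~ N(72.95, 4.47^2) truncated to [67, 82]; weight ~ N(65.63, 9.34^2)
    truncated to [49, 80]; sex Bernoulli(0.55 male); laboratory covariates
    from their cohort summaries (truncated to the observed ranges).
    """
    if n < 0:
        raise InputError(f"n must be >= 0, got {n}")
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else np.random.default_rng(seed_or_rng)
    if n == 0:
        return []
    age = _truncnorm_rvs(*AGE_DIST, n, rng)
    wt = _truncnorm_rvs(*WT_DIST, n, rng)
    male = rng.random(n) < MALE_FRACTION
    labs = {k: _truncnorm_rvs(*d, n, rng) for k, d in LAB_DISTS.items()}
    return [
        SubjectRecord(
            id=i + 1,
            age=float(age[i]),
            wt=float(wt[i]),
            sex="M" if male[i] else "F",
            labs={k: float(v[i]) for k, v in labs.items()},
        )
        for i in range(n)
    ]


def generate_study(
    design: StudyDesign, pop: PopulationModel, seed, subjects: Sequence[SubjectRecord] | None = None
) -> StudyDataset:
    """Simulate one virtual study under the given population model.

    Each subject receives the weight-scaled protocol regimen with an
    individual (uniform 60-180 min by default) infusion duration, 19 nominal
    PK samples with proportional error, and synchronized BIS samples with
    additive error.  The generating individual parameters are retained in
    ``truth`` for recovery testing.  Fully reproducible from (design, model,
    seed).
    """
    rng = np.random.default_rng(seed)
    if subjects is None:
        subjects = generate_demographics(design.n_subjects, rng)
    rows = []
    truth = {}
    for s in subjects:
        duration = float(rng.uniform(*design.infusion_duration_range))
        reg = design.regimen(s.wt, duration)
        times = design.sample_times(duration)
        ind = sample_individual(pop, s.wt, s.age, rng)
        traj = simulate_profile(ind.pk, ind.pd, reg, times)
        cp_obs = apply_residual(traj.Cp, "pk", pop.residual, rng)
        bis_obs = apply_residual(traj.BIS, "pd", pop.residual, rng)
        base = {"ID": s.id, "WT": round(s.wt, 3), "AGE": round(s.age, 3), "SEX": s.sex}
        base.update({k: round(v, 3) for k, v in s.labs.items() if k in OPTIONAL_COLUMNS})
        for e in reg.events:
            rows.append(
                {**base, "TIME": e.start, "EVID": 1, "AMT": e.amount, "RATE": e.rate,
                 "DV": np.nan, "MDV": 1, "BLQ": 0, "CMT": 1}
            )
        for t, cp, bis in zip(times, cp_obs, bis_obs):
            blq = int(cp < design.lloq)
            rows.append(
                {**base, "TIME": t, "EVID": 0, "AMT": 0.0, "RATE": 0.0,
                 "DV": cp, "MDV": 0, "BLQ": blq, "CMT": 1}
            )
            rows.append(
                {**base, "TIME": t, "EVID": 0, "AMT": 0.0, "RATE": 0.0,
                 "DV": bis, "MDV": 0, "BLQ": 0, "CMT": 4}
            )
        truth[s.id] = {
            "pk": asdict(ind.pk),
            "pd": asdict(ind.pd),
            "eta": dict(ind.eta),
            "duration": duration,
            "wt": s.wt,
            "age": s.age,
            "labs": dict(s.labs),
        }
    lab_cols = [c for c in OPTIONAL_COLUMNS if subjects and c in subjects[0].labs]
    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + lab_cols)
    df = df.sort_values(["ID", "TIME", "EVID", "CMT"], ascending=[True, True, False, True], kind="stable")
    df = df.reset_index(drop=True)
    return StudyDataset(df=df, design=design, truth=truth)


def write_dataset(ds: StudyDataset, path, truth_path=None) -> None:
    """Write the event table as CSV (and optionally the truth sidecar as JSON)."""
    ds.df.to_csv(path, index=False, float_format="%.10g")
    if truth_path is not None:
        if ds.truth is None:
            raise InputError("dataset has no truth sidecar to write")
        with open(truth_path, "w") as fh:
            json.dump(ds.truth, fh, indent=1)


def read_dataset(path, truth_path=None) -> StudyDataset:
    """Read an event-format CSV with strict header and ordering validation."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"dataset {path} is missing required column(s): {missing}")
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS]
    if extra:
        raise InputError(f"dataset {path} has unknown column(s): {extra}")
    obs = df[df["EVID"] == 0]
    if obs["DV"].isna().any():
        bad = obs[obs["DV"].isna()].index[0]
        raise InputError(f"observation row {bad} has missing DV")
    for sid, g in df.groupby("ID"):
        t = g["TIME"].to_numpy()
        if np.any(np.diff(t) < 0):
            row = g.index[int(np.where(np.diff(t) < 0)[0][0]) + 1]
            raise InputError(f"times not sorted within subject {sid} (row {row})")
    truth = None
    if truth_path is not None:
        with open(truth_path) as fh:
            truth = {int(k): v for k, v in json.load(fh).items()}
    return StudyDataset(df=df, truth=truth)
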