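"""Deterministic structural PK/PD model.

Linear three-compartment (mammillary) pharmacokinetics with zero-order
piecewise-constant infusion input, a first-order effect compartment, and a
sigmoid Emax (Hill) model mapping effect-site concentration to BIS.

Units are fixed package-wide: time in minutes, amounts in mg, volumes in L,
clearances in L/min.  Concentrations are carried internally in mg/L and
exposed in ng/mL through the single conversion constant
:data:`NGML_PER_MGL`; EC50 is handled in ng/mL.

The piecewise-constant-input linear system is solved exactly, segment by
segment, via the eigendecomposition of the (symmetrizable) PK block with the
effect compartment convolved analytically.  A matrix-exponential propagation
path (``method="expm"``) requires no distinct-eigenvalue assumption and
serves as the fallback for (measure-zero) degenerate spectra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap

#: ng/mL per mg/L (the only unit-conversion point in the package).
NGML_PER_MGL = 1000.0


class ParameterError(ValueError):
    """A structural parameter violates its positivity/range invariant."""


class InputError(ValueError):
    """Malformed user input (grids, doses, concentrations)."""


def _require(cond: bool, msg: str, exc=ParameterError) -> None:
    if not cond:
        raise exc(msg)


@dataclass(frozen=True)
class PKParameters:
    """Three-compartment PK fixed effects.

    V1, V2, V3 : central / shallow / deep volumes (L);
    CL : elimination clearance (L/min);
    Q2, Q3 : intercompartmental clearances (L/min).
    """

    V1: float
    V2: float
    V3: float
    CL: float
    Q2: float
    Q3: float

    def __post_init__(self):
        for name in ("V1", "V2", "V3", "CL", "Q2", "Q3"):
            v = getattr(self, name)
            _require(np.isfinite(v) and v > 0, f"{name} must be strictly positive, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.V1, self.V2, self.V3, self.CL, self.Q2, self.Q3])


@dataclass(frozen=True)
class PDParameters:
    """Effect-site / sigmoid-Emax PD fixed effects.

    ke0 : plasma-effect-site equilibration rate (1/min);
    E0 : baseline BIS; Emax : maximal BIS suppression (Emax <= E0);
    EC50 : effect-site concentration at half-maximal suppression (ng/mL);
    gamma : Hill coefficient (steepness).
    """

    ke0: float
    E0: float
    Emax: float
    EC50: float
    gamma: float

    def __post_init__(self):
        _require(self.ke0 > 0, f"ke0 must be > 0, got {self.ke0!r}")
        _require(0 < self.E0 <= 100, f"E0 must be in (0, 100], got {self.E0!r}")
        _require(0 < self.Emax <= self.E0, f"Emax must be in (0, E0], got {self.Emax!r}")
        _require(self.EC50 > 0, f"EC50 must be > 0, got {self.EC50!r}")
        _require(self.gamma > 0, f"gamma must be > 0, got {self.gamma!r}")


@dataclass(frozen=True)
class DoseEvent:
    """One zero-order infusion: ``rate`` mg/min for ``duration`` min from ``start``.

    Boluses are represented as short (1 min, per the dosing protocol)
    infusions; there is no instantaneous-bolus branch.
    """

    start: float
    rate: float
    duration: float

    def __post_init__(self):
        _require(self.start >= 0, f"start must be >= 0, got {self.start!r}", InputError)
        _require(self.rate >= 0, f"rate must be >= 0, got {self.rate!r}", InputError)
        _require(self.duration > 0, f"duration must be > 0, got {self.duration!r}", InputError)

    @property
    def amount(self) -> float:
        """Total mass delivered (mg)."""
        return self.rate * self.duration

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class Regimen:
    """Ordered collection of :class:`DoseEvent` (overlaps allowed; rates add)."""

    events: tuple[DoseEvent, ...]

    def __post_init__(self):
        ev = tuple(self.events)
        starts = [e.start for e in ev]
        _require(list(starts) == sorted(starts), "dose events must be sorted by start time", InputError)
        object.__setattr__(self, "events", ev)

    @classmethod
    def from_events(cls, events: Iterable[DoseEvent]) -> "Regimen":
        return cls(tuple(sorted(events, key=lambda e: e.start)))

    @property
    def total_dose(self) -> float:
        """Total administered mass, sum of rate x duration (mg)."""
        return float(sum(e.amount for e in self.events))

    def segments(self, t_end: float = math.inf) -> tuple[np.ndarray, np.ndarray]:
        """Compile to breakpoints/rates of the piecewise-constant input.

        Returns ``(bounds, rates)`` with ``bounds`` of length ``m+1``
        (``bounds[0] == 0``, ``bounds[-1] == inf``) and ``rates`` of length
        ``m``: total input rate on ``[bounds[k], bounds[k+1])``.
        """
        knots = {0.0}
        for e in self.events:
            knots.add(float(e.start))
            knots.add(float(e.end))
        bounds = sorted(knots) + [math.inf]
        rates = np.zeros(len(bounds) - 1)
        for k in range(len(rates)):
            t0 = bounds[k]
            for e in self.events:
                if e.start <= t0 < e.end:
                    rates[k] += e.rate
        return np.asarray(bounds, dtype=float), rates


def loading_plus_infusion(
    weight_kg: float,
    bolus_mg_per_kg: float = 0.4,
    bolus_duration_min: float = 1.0,
    maintenance_mg_per_kg_h: float = 0.8,
    maintenance_start_min: float = 5.0,
    maintenance_duration_min: float = 120.0,
) -> Regimen:
    """Weight-scaled protocol regimen: 1-min loading infusion + maintenance.

    Defaults mirror the clinical protocol (0.4 mg/kg over 1 min, then
    0.8 mg/kg/h starting at 5 min); the simulation grid uses other values.
    """
    _require(weight_kg > 0, "weight must be positive", InputError)
    events = [DoseEvent(start=0.0, rate=bolus_mg_per_kg * weight_kg / bolus_duration_min, duration=bolus_duration_min)]
    if maintenance_mg_per_kg_h > 0 and maintenance_duration_min > 0:
        events.append(
            DoseEvent(
                start=maintenance_start_min,
                rate=maintenance_mg_per_kg_h * weight_kg / 60.0,
                duration=maintenance_duration_min,
            )
        )
    return Regimen.from_events(events)


@dataclass
class StateTrajectory:
    """Solution grid: compartment amounts (mg), Cp/Ce (ng/mL), predicted BIS."""

    times: np.ndarray
    A1: np.ndarray
    A2: np.ndarray
    A3: np.ndarray
    Cp: np.ndarray
    Ce: np.ndarray
    BIS: np.ndarray
    eliminated: np.ndarray = field(default=None, repr=False)  # cumulative mass cleared (mg)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "A1": self.A1,
                "A2": self.A2,
                "A3": self.A3,
                "Cp": self.Cp,
                "Ce": self.Ce,
                "BIS": self.BIS,
            }
        )


# --------------------------------------------------------------------------
# system matrix
# --------------------------------------------------------------------------

def build_system_matrix(pk: PKParameters, ke0: float) -> np.ndarray:
    """Constant-coefficient matrix of the linear system, state (A1, A2, A3, Ce).

    A1..A3 are amounts (mg); Ce is carried in ng/mL so its row implements
    dCe/dt = ke0 * (A1/V1 * 1000 - Ce).
    """
    _require(np.isfinite(ke0) and ke0 > 0, f"ke0 must be > 0, got {ke0!r}")
    k10 = pk.CL / pk.V1
    k12 = pk.Q2 / pk.V1
    k21 = pk.Q2 / pk.V2
    k13 = pk.Q3 / pk.V1
    k31 = pk.Q3 / pk.V3
    return np.array(
        [
            [-(k10 + k12 + k13), k21, k31, 0.0],
            [k12, -k21, 0.0, 0.0],
            [k13, 0.0, -k31, 0.0],
            [ke0 * NGML_PER_MGL / pk.V1, 0.0, 0.0, -ke0],
        ]
    )


# --------------------------------------------------------------------------
# exact segment-wise solver
# --------------------------------------------------------------------------

@njit(cache=True)
def _profile_kernel(v1, v2, v3, cl, q2, q3, ke0, seg_t, seg_r, times, out):  # pragma: no cover - numba
    """Exact trajectory at ``times`` for piecewise-constant input.

    ``out`` is (n, 6): A1, A2, A3, Cp(ng/mL), Ce(ng/mL), cumulative eliminated
    mass (mg).  The PK block is symmetrized by the diag(1/sqrt(V)) similarity,
    so eigh yields its (real, negative) spectrum; the effect compartment is
    convolved analytically, with the confluent (lambda == -ke0) limit handled
    by its exact limiting form.
    """
    sv1 = math.sqrt(v1)
    sv2 = math.sqrt(v2)
    sv3 = math.sqrt(v3)
    M = np.empty((3, 3))
    M[0, 0] = -(cl + q2 + q3) / v1
    M[1, 1] = -q2 / v2
    M[2, 2] = -q3 / v3
    M[0, 1] = q2 / (sv1 * sv2)
    M[1, 0] = M[0, 1]
    M[0, 2] = q3 / (sv1 * sv3)
    M[2, 0] = M[0, 2]
    M[1, 2] = 0.0
    M[2, 1] = 0.0
    lam, U = np.linalg.eigh(M)
    for j in range(3):
        # the spectrum is strictly negative in exact arithmetic; a rounded-to-zero
        # eigenvalue (degenerate inputs) must not divide by zero — the resulting
        # inf/nan trajectory is rejected by the caller's validity guards
        if lam[j] > -1e-300:
            lam[j] = -1e-300

    z = np.zeros(3)  # transformed state z = U.T @ (A / sqrt(V))
    ce = 0.0
    elim = 0.0
    n = times.shape[0]
    m = seg_r.shape[0]
    idx = 0
    tol = 1e-7 * ke0
    for k in range(m):
        t0 = seg_t[k]
        t1 = seg_t[k + 1]
        r = seg_r[k]
        # input in transformed coordinates: w_j = U[0, j] * r / sqrt(V1)
        # z_j(tau) = p_j * exp(lam_j tau) - w_j / lam_j,  p_j = z0_j + w_j/lam_j
        p = np.empty(3)
        q = np.empty(3)
        for j in range(3):
            wj = U[0, j] * r / sv1
            q[j] = -wj / lam[j]
            p[j] = z[j] + wj / lam[j]
        # Cp in ng/mL: (1000/sv1) * sum_j U[0,j] * z_j(tau)
        c0 = 0.0
        a = np.empty(3)
        for j in range(3):
            a[j] = (NGML_PER_MGL / sv1) * U[0, j] * p[j]
            c0 += (NGML_PER_MGL / sv1) * U[0, j] * q[j]

        while idx < n and (times[idx] < t1 or k == m - 1):
            tau = times[idx] - t0
            ek = math.exp(-ke0 * tau)
            a1 = 0.0
            a2 = 0.0
            a3 = 0.0
            cenow = ce * ek + c0 * (1.0 - ek)
            el = c0 * tau
            for j in range(3):
                e = math.exp(lam[j] * tau)
                zj = p[j] * e + q[j]
                a1 += sv1 * U[0, j] * zj
                a2 += sv2 * U[1, j] * zj
                a3 += sv3 * U[2, j] * zj
                d = lam[j] + ke0
                if abs(d) > tol:
                    cenow += a[j] * ke0 * (e - ek) / d
                else:
                    cenow += a[j] * ke0 * tau * e
                el += a[j] * (e - 1.0) / lam[j]
            out[idx, 0] = a1
            out[idx, 1] = a2
            out[idx, 2] = a3
            out[idx, 3] = (NGML_PER_MGL / v1) * a1
            out[idx, 4] = cenow
            out[idx, 5] = elim + (cl / NGML_PER_MGL) * el
            idx += 1

        if idx >= n:
            break
        # advance state to the end of the segment
        dt = t1 - t0
        ek = math.exp(-ke0 * dt)
        cenext = ce * ek + c0 * (1.0 - ek)
        el = c0 * dt
        for j in range(3):
            e = math.exp(lam[j] * dt)
            d = lam[j] + ke0
            if abs(d) > tol:
                cenext += a[j] * ke0 * (e - ek) / d
            else:
                cenext += a[j] * ke0 * dt * e
            el += a[j] * (e - 1.0) / lam[j]
            z[j] = p[j] * e + q[j]
        ce = cenext
        elim += (cl / NGML_PER_MGL) * el


def _profile_arrays(
    pkvec: np.ndarray, ke0: float, seg_t: np.ndarray, seg_r: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """Low-level exact solver; returns (n, 6) state array (see kernel docstring)."""
    out = np.empty((times.shape[0], 6))
    _profile_kernel(
        pkvec[0], pkvec[1], pkvec[2], pkvec[3], pkvec[4], pkvec[5], ke0, seg_t, seg_r, times, out
    )
    return out


def _profile_expm(
    pkvec: np.ndarray, ke0: float, seg_t: np.ndarray, seg_r: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """Matrix-exponential propagation of the augmented affine system.

    States (A1, A2, A3, Ce, eliminated, 1): exact for any spectrum (no
    distinct-eigenvalue assumption); used as the degenerate-spectrum fallback
    and as an internal cross-check.
    """
    from scipy.linalg import expm

    pk = PKParameters(*pkvec)
    K = build_system_matrix(pk, ke0)
    out = np.empty((times.shape[0], 6))
    x = np.zeros(6)  # A1, A2, A3, Ce, elim, 1
    x[5] = 1.0
    idx = 0
    n = times.shape[0]
    m = seg_r.shape[0]
    A = np.zeros((6, 6))
    A[:4, :4] = K
    A[4, 0] = pk.CL / pk.V1  # d(elim)/dt = CL * A1/V1
    for k in range(m):
        t0, t1, r = seg_t[k], seg_t[k + 1], seg_r[k]
        A[0, 5] = r
        while idx < n and (times[idx] < t1 or k == m - 1):
            y = expm(A * (times[idx] - t0)) @ x
            out[idx, 0:3] = y[0:3]
            out[idx, 3] = NGML_PER_MGL * y[0] / pk.V1
            out[idx, 4] = y[3]
            out[idx, 5] = y[4]
            idx += 1
        if idx >= n:
            break
        x = expm(A * (t1 - t0)) @ x
    return out


def bis_from_ce(pd: PDParameters, ce) -> np.ndarray | float:
    """Sigmoid Emax effect: E(Ce) = E0 - Emax * Ce^gamma / (EC50^gamma + Ce^gamma).

    Strictly decreasing in Ce, bounded in (E0 - Emax, E0].
    """
    ce_arr = np.asarray(ce, dtype=float)
    if np.any(ce_arr < 0) or not np.all(np.isfinite(ce_arr)):
        raise InputError("effect-site concentrations must be finite and >= 0")
    with np.errstate(divide="ignore"):
        # Ce^g / (EC50^g + Ce^g) computed via the ratio (Ce/EC50)^g for stability
        x = np.power(ce_arr / pd.EC50, pd.gamma)
    frac = x / (1.0 + x)
    out = pd.E0 - pd.Emax * frac
    return out if out.ndim else float(out)


def ce_inverse(pd: PDParameters, bis: float) -> float:
    """Effect-site concentration producing a given BIS (inverse Hill); bis in (E0-Emax, E0]."""
    if not (pd.E0 - pd.Emax < bis <= pd.E0):
        raise InputError(f"BIS {bis!r} outside the attainable range ({pd.E0 - pd.Emax}, {pd.E0}]")
    frac = (pd.E0 - bis) / pd.Emax
    if frac == 0:
        return 0.0
    return float(pd.EC50 * (frac / (1.0 - frac)) ** (1.0 / pd.gamma))


def simulate_profile(
    pk: PKParameters,
    pd: PDParameters,
    regimen: Regimen,
    times: Sequence[float],
    method: str = "exact",
) -> StateTrajectory:
    """Simulate the full PK/PD trajectory on a time grid.

    ``method="exact"`` uses the eigendecomposition solver; ``"expm"`` uses
    matrix-exponential propagation (identical result, no spectral assumption).
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise InputError("times must be one-dimensional")
    if t.size and (np.any(np.diff(t) < 0) or t[0] < 0 or not np.all(np.isfinite(t))):
        raise InputError("times must be sorted, finite and non-negative")
    seg_t, seg_r = regimen.segments()
    if method == "exact":
        out = _profile_arrays(pk.as_array(), pd.ke0, seg_t, seg_r, t)
    elif method == "expm":
        out = _profile_expm(pk.as_array(), pd.ke0, seg_t, seg_r, t)
    else:
        raise InputError(f"unknown method {method!r}")
    bis = bis_from_ce(pd, np.maximum(out[:, 4], 0.0))
    return StateTrajectory(
        times=t,
        A1=out[:, 0],
        A2=out[:, 1],
        A3=out[:, 2],
        Cp=out[:, 3],
        Ce=out[:, 4],
        BIS=np.asarray(bis),
        eliminated=out[:, 5],
    )
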