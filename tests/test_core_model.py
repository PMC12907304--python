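"""Structural model: exact solver vs ODE oracle, mass balance, Hill link."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from ciprofol_pkpd import core_model as cm

TYPICAL_PK = dict(V1=2.95, V2=45.15, V3=76.79, CL=1.01, Q2=0.76, Q3=0.66)
TYPICAL_PD = dict(ke0=1.09, E0=93.40, Emax=45.77, EC50=233.91, gamma=3.00)


@pytest.fixture(scope="module")
def pk():
    return cm.PKParameters(**TYPICAL_PK)


@pytest.fixture(scope="module")
def pd():
    return cm.PDParameters(**TYPICAL_PD)


@pytest.fixture(scope="module")
def regimen():
    # 66-kg protocol: 26.4 mg over 1 min, then 0.66 mg/min for 2 h from t=5
    return cm.loading_plus_infusion(66.0, maintenance_duration_min=120.0)


def ode_oracle(pk, ke0, regimen, times, rtol=1e-11):
    """Adaptive numerical integration of the same system (independent oracle)."""
    K = cm.build_system_matrix(pk, ke0)

    def rhs(t, y):
        r = sum(e.rate for e in regimen.events if e.start <= t < e.end)
        dy = K @ y
        dy[0] += r
        return dy

    breaks = sorted({e.start for e in regimen.events} | {e.end for e in regimen.events})
    sol = solve_ivp(
        rhs, (0.0, max(times[-1], 1.0)), np.zeros(4), t_eval=times,
        rtol=rtol, atol=1e-12, max_step=1.0, method="LSODA",
    )
    del breaks
    return sol.y


class TestParameterValidation:
    @pytest.mark.parametrize("field", ["V1", "V2", "V3", "CL", "Q2", "Q3"])
    @pytest.mark.parametrize("bad", [0.0, -1.0, np.nan])
    def test_nonpositive_pk_rejected(self, field, bad):
        params = dict(TYPICAL_PK)
        params[field] = bad
        with pytest.raises(cm.ParameterError):
            cm.PKParameters(**params)

    @pytest.mark.parametrize(
        "field,bad",
        [("ke0", 0.0), ("E0", 0.0), ("E0", 101.0), ("Emax", 0.0), ("Emax", 95.0), ("EC50", -1.0), ("gamma", 0.0)],
    )
    def test_invalid_pd_rejected(self, field, bad):
        params = dict(TYPICAL_PD)
        params[field] = bad
        with pytest.raises(cm.ParameterError):
            cm.PDParameters(**params)

    def test_unsorted_grid_rejected(self, pk, pd, regimen):
        with pytest.raises(cm.InputError):
            cm.simulate_profile(pk, pd, regimen, [5.0, 1.0])
        with pytest.raises(cm.InputError):
            cm.simulate_profile(pk, pd, regimen, [-1.0, 1.0])


class TestSystemMatrix:
    def test_decoupled_when_no_intercompartmental_flow(self):
        pk = cm.PKParameters(V1=5.0, V2=10.0, V3=20.0, CL=2.0, Q2=1e-12, Q3=1e-12)
        K = cm.build_system_matrix(pk, 1.0)[:3, :3]
        offdiag = K - np.diag(np.diag(K))
        assert np.allclose(offdiag, 0.0, atol=1e-10)
        # central compartment then decays mono-exponentially at CL/V1
        assert K[0, 0] == pytest.approx(-2.0 / 5.0)

    def test_typical_values_three_distinct_negative_eigenvalues(self, pk):
        lam = np.linalg.eigvals(cm.build_system_matrix(pk, 1.09)[:3, :3])
        assert np.all(np.abs(lam.imag) < 1e-12)
        lam = np.sort(lam.real)
        assert np.all(lam < 0)
        assert len(np.unique(np.round(lam, 10))) == 3

    @given(
        v=st.tuples(*[st.floats(0.5, 200.0)] * 3),
        c=st.tuples(*[st.floats(0.05, 5.0)] * 3),
    )
    @settings(max_examples=50, deadline=None)
    def test_spectrum_matches_dense_eigensolver(self, v, c):
        """The symmetrized spectrum used by the solver equals the dense one."""
        pk = cm.PKParameters(V1=v[0], V2=v[1], V3=v[2], CL=c[0], Q2=c[1], Q3=c[2])
        K = cm.build_system_matrix(pk, 1.0)[:3, :3]
        dense = np.sort(np.linalg.eigvals(K).real)
        sv = np.sqrt([pk.V1, pk.V2, pk.V3])
        M = np.diag(1.0 / sv) @ K @ np.diag(sv)
        sym = np.sort(np.linalg.eigvalsh((M + M.T) / 2))
        assert np.allclose(dense, sym, rtol=1e-8, atol=1e-12)
        assert np.all(dense < 0)


class TestSimulateProfile:
    def test_empty_regimen_all_zero(self, pk, pd):
        traj = cm.simulate_profile(pk, pd, cm.Regimen(()), np.linspace(0, 100, 11))
        assert np.all(traj.Cp == 0)
        assert np.all(traj.Ce == 0)
        assert np.all(traj.BIS == pd.E0)

    def test_steady_state_rate_over_clearance(self, pk, pd):
        reg = cm.Regimen((cm.DoseEvent(0.0, 0.66, 1e7),))
        traj = cm.simulate_profile(pk, pd, reg, [9e6])
        assert traj.Cp[0] == pytest.approx(1000 * 0.66 / 1.01, rel=1e-6)
        assert traj.Ce[0] == pytest.approx(traj.Cp[0], rel=1e-6)

    def test_against_adaptive_ode_oracle(self, pk, pd, regimen):
        times = np.array([1.0, 3.0, 5.0, 10.0, 30.0, 65.0, 120.0, 126.0, 180.0, 300.0])
        traj = cm.simulate_profile(pk, pd, regimen, times)
        y = ode_oracle(pk, pd.ke0, regimen, times)
        cp = 1000 * y[0] / pk.V1
        assert np.allclose(traj.Cp, cp, rtol=1e-6)
        assert np.allclose(traj.Ce, y[3], rtol=1e-6)

    def test_exact_equals_expm_propagation(self, pk, pd, regimen):
        times = np.array([0.5, 1.0, 4.0, 20.0, 100.0, 124.0, 200.0])
        a = cm.simulate_profile(pk, pd, regimen, times)
        b = cm.simulate_profile(pk, pd, regimen, times, method="expm")
        for field in ("A1", "A2", "A3", "Cp", "Ce"):
            assert np.allclose(getattr(a, field), getattr(b, field), rtol=1e-9)

    def test_confluent_ke0_equals_expm(self, pk, regimen):
        """ke0 colliding with a PK eigenvalue must hit the limiting formula."""
        lam = np.sort(np.linalg.eigvals(cm.build_system_matrix(pk, 1.0)[:3, :3]).real)
        ke0 = -lam[1]
        pd = cm.PDParameters(ke0=float(ke0), **{k: v for k, v in TYPICAL_PD.items() if k != "ke0"})
        times = np.array([1.0, 10.0, 60.0, 200.0])
        a = cm.simulate_profile(pk, pd, regimen, times)
        b = cm.simulate_profile(pk, pd, regimen, times, method="expm")
        assert np.allclose(a.Ce, b.Ce, rtol=1e-9)

    def test_superposition(self, pk, pd):
        r1 = cm.Regimen((cm.DoseEvent(0.0, 10.0, 2.0),))
        r2 = cm.Regimen((cm.DoseEvent(5.0, 3.0, 30.0),))
        both = cm.Regimen.from_events(list(r1.events) + list(r2.events))
        t = np.linspace(0.0, 120.0, 60)
        cp1 = cm.simulate_profile(pk, pd, r1, t).Cp
        cp2 = cm.simulate_profile(pk, pd, r2, t).Cp
        cp12 = cm.simulate_profile(pk, pd, both, t).Cp
        assert np.allclose(cp12, cp1 + cp2, rtol=1e-10, atol=1e-12)

    def test_mass_balance(self, pk, pd, regimen):
        t = np.linspace(1.0, 400.0, 80)
        traj = cm.simulate_profile(pk, pd, regimen, t)
        infused = np.array(
            [sum(e.rate * np.clip(ti - e.start, 0.0, e.duration) for e in regimen.events) for ti in t]
        )
        balance = traj.A1 + traj.A2 + traj.A3 + traj.eliminated
        assert np.allclose(balance, infused, rtol=1e-8)

    def test_ce_lags_cp_after_short_infusion(self, pk, pd):
        reg = cm.Regimen((cm.DoseEvent(0.0, 26.4, 1.0),))
        t = np.linspace(0.0, 30.0, 3001)
        traj = cm.simulate_profile(pk, pd, reg, t)
        assert t[np.argmax(traj.Ce)] > t[np.argmax(traj.Cp)]

    @given(
        v=st.tuples(*[st.floats(1.0, 150.0)] * 3),
        c=st.tuples(*[st.floats(0.1, 3.0)] * 3),
        ke0=st.floats(0.05, 5.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_oracle_equivalence_random_parameters(self, v, c, ke0):
        """Closed form vs adaptive integration at 1e-6 relative, random draws."""
        pk = cm.PKParameters(V1=v[0], V2=v[1], V3=v[2], CL=c[0], Q2=c[1], Q3=c[2])
        pd = cm.PDParameters(ke0=ke0, E0=93.4, Emax=45.77, EC50=233.91, gamma=3.0)
        reg = cm.loading_plus_infusion(66.0, maintenance_duration_min=60.0)
        times = np.array([2.0, 7.0, 20.0, 50.0, 80.0, 150.0])
        traj = cm.simulate_profile(pk, pd, reg, times)
        y = ode_oracle(pk, ke0, reg, times)
        assert np.allclose(traj.Cp, 1000 * y[0] / pk.V1, rtol=1e-6, atol=1e-9)
        assert np.allclose(traj.Ce, y[3], rtol=1e-6, atol=1e-9)
        # mass balance at the final time
        infused = sum(e.rate * np.clip(times[-1] - e.start, 0, e.duration) for e in reg.events)
        assert traj.A1[-1] + traj.A2[-1] + traj.A3[-1] + traj.eliminated[-1] == pytest.approx(infused, rel=1e-8)


class TestHillLink:
    def test_zero_ce_gives_baseline(self, pd):
        assert cm.bis_from_ce(pd, 0.0) == pytest.approx(93.4)

    def test_half_maximum_at_ec50(self, pd):
        assert cm.bis_from_ce(pd, pd.EC50) == pytest.approx(93.40 - 45.77 / 2)

    def test_asymptote_from_above(self, pd):
        hi = cm.bis_from_ce(pd, 100.0 * pd.EC50)
        floor = pd.E0 - pd.Emax
        assert floor < hi < floor + 0.01

    def test_strictly_decreasing_and_invertible(self, pd):
        ce = np.linspace(0.0, 2000.0, 500)
        bis = cm.bis_from_ce(pd, ce)
        assert np.all(np.diff(bis) < 0)
        for target in (90.0, 70.515, 50.0):
            ce_t = cm.ce_inverse(pd, target)
            assert cm.bis_from_ce(pd, ce_t) == pytest.approx(target, abs=1e-9)

    def test_negative_ce_rejected(self, pd):
        with pytest.raises(cm.InputError):
            cm.bis_from_ce(pd, -1.0)


class TestRegimen:
    def test_total_dose_bookkeeping(self, regimen):
        assert regimen.total_dose == pytest.approx(0.4 * 66 + 0.8 * 66 / 60 * 120)

    def test_unsorted_events_rejected(self):
        with pytest.raises(cm.InputError):
            cm.Regimen((cm.DoseEvent(5.0, 1.0, 1.0), cm.DoseEvent(0.0, 1.0, 1.0)))

    def test_segments_cover_line_and_sum_rates(self):
        reg = cm.Regimen.from_events([cm.DoseEvent(0.0, 2.0, 10.0), cm.DoseEvent(5.0, 1.0, 10.0)])
        seg_t, seg_r = reg.segments()
        assert seg_t[0] == 0.0 and np.isinf(seg_t[-1])
        assert np.allclose(seg_r, [2.0, 3.0, 1.0, 0.0])
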