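"""Component right-hand sides, forces, feedback flux and the integrator."""

import numpy as np
import pytest

import cardioloop._rhs as R
from cardioloop.ca_waveforms import make_parametric, record
from cardioloop.model_core import (Mech, ap_rhs, cicr_rhs, coupled_rhs,
                                   forces, integrate, tnc_flux, xb_rhs)
from cardioloop.states import (APState, CalciumState, CrossbridgeState,
                               ModelState, resting_state)


# ---------------------------------------------------------------- AP
def test_ap_resting_state_is_fixed_point(params):
    dv, dr = ap_rhs(APState(v=0.0, r=0.0), 0.0, params, stim=0.0)
    assert abs(dv) < 1e-9 and abs(dr) < 1e-9


def test_ap_nonfinite_state_rejected(params):
    with pytest.raises(ValueError, match="v"):
        ap_rhs(APState(v=np.nan, r=0.0), 0.0, params)


def test_suprathreshold_stimulus_elicits_one_spike(params, iso_lo):
    """One stimulus produces one excitation that recovers within the cycle."""
    res = integrate(iso_lo.final_state, params, 1.0, mech=Mech.fixed())
    # re-derive v from a dense solve to look at the AP itself
    from scipy.integrate import solve_ivp
    p = params.pack()
    E, EC = np.zeros(0), np.zeros((4, 0))
    sol = solve_ivp(lambda t, y: R.rhs(t, y, p, 0, 0, 0.0, E, EC),
                    (0, 1.0), iso_lo.final_state.to_vector(), method="LSODA",
                    rtol=1e-7, atol=1e-10, dense_output=True)
    ts = np.linspace(0, 1, 2001)
    v = sol.sol(ts)[R.IV]
    assert v.max() > 0.7                      # full excursion
    assert abs(v[-1]) < 0.01 * v.max()        # back to rest within the beat
    # exactly one upstroke
    ups = np.sum((v[:-1] < 0.5) & (v[1:] >= 0.5))
    assert ups == 1


def test_paced_ap_is_periodic_at_steady_state(params, iso_lo):
    r1 = integrate(iso_lo.final_state, params, 1.0, mech=Mech.fixed())
    r2 = integrate(r1.final_state, params, 1.0, mech=Mech.fixed())
    # compare consecutive-beat Ca trajectories (driven by the AP)
    assert np.allclose(r1.record.ca_i, r2.record.ca_i, rtol=1e-3)


# ---------------------------------------------------------------- CICR
def test_cicr_diastolic_quasi_steady(params):
    s = resting_state(params)
    d = cicr_rhs(s.ca, s.ap, 0.0, params)
    # diastolic drift is tiny compared with systolic flux scales (~1e3 uM/s)
    assert abs(d.ca_i) < 5.0


def test_cicr_feedback_flux_appears_linearly(params):
    s = resting_state(params)
    d0 = cicr_rhs(s.ca, s.ap, 0.0, params)
    d1 = cicr_rhs(s.ca, s.ap, 7.5, params)
    assert d0.ca_i - d1.ca_i == pytest.approx(7.5, rel=1e-12)
    assert d0.ca_sr == d1.ca_sr


def test_cicr_negative_concentration_rejected(params):
    s = resting_state(params)
    s.ca.ca_i = -0.1
    with pytest.raises(ValueError):
        cicr_rhs(s.ca, s.ap, 0.0, params)


def test_cicr_python_matches_kernel(params):
    """The typed cicr_rhs mirrors the compiled kernel exactly."""
    rng = np.random.default_rng(0)
    for _ in range(5):
        s = resting_state(params)
        s.ca.ca_i = rng.uniform(0.05, 2.0)
        s.ca.ca_sr = rng.uniform(100, 800)
        s.ca.y2 = rng.uniform(0, 0.2)
        s.ca.y3 = rng.uniform(0, 0.3)
        s.ca.y4 = rng.uniform(0, 0.3)
        s.ap.v = rng.uniform(0, 1)
        y = s.to_vector()
        p = params.pack()
        dy = R.rhs(0.5, y, p, R.CA_FREE, R.MECH_FIXED, 0.0,
                   np.zeros(0), np.zeros((4, 0)))
        d = cicr_rhs(s.ca, s.ap, 0.0, params)
        assert d.y2 == pytest.approx(dy[R.IY2], rel=1e-10, abs=1e-12)
        assert d.y3 == pytest.approx(dy[R.IY3], rel=1e-10, abs=1e-12)
        assert d.ca_sr == pytest.approx(dy[R.ICASR], rel=1e-10, abs=1e-10)


# ---------------------------------------------------------------- troponin flux
def test_tnc_flux_zero_without_ca_or_occupancy(params):
    s = CrossbridgeState(trpn_l=0.0, trpn_h=0.0)
    assert tnc_flux(s, 0.0, params) == 0.0


def test_tnc_flux_force_dependence_monotone(params):
    """Higher force shifts troponin to the high-affinity (slow-unbinding)
    regime: net unbinding shrinks monotonically with force."""
    s = CrossbridgeState(trpn_l=0.5, trpn_h=0.5)
    ca = 0.2  # low Ca: net unbinding
    fluxes = [tnc_flux(s, ca, params, active_force=f)
              for f in (0.0, 0.25, 0.5, 0.75, 1.0)]
    assert all(b > a for a, b in zip(fluxes, fluxes[1:]))
    assert fluxes[0] < 0  # net unbinding at force 0


def test_tnc_flux_no_force_dependence_when_feedback_off(params):
    p_off = params.with_(feedback_enabled=False)
    s = CrossbridgeState(trpn_l=0.4, trpn_h=0.7)
    f0 = tnc_flux(s, 0.3, p_off, active_force=0.0)
    f1 = tnc_flux(s, 0.3, p_off, active_force=1.0)
    assert f0 == f1


# ---------------------------------------------------------------- cross-bridges
def test_xb_resting_fixed_point(params):
    s = resting_state(params)
    d = xb_rhs(s.xb, s.ca.ca_i, params.l_o, 0.0, params)
    # occupancies are equilibrated; regulatory/XB drift is slow at diastole
    assert abs(d.trpn_l) < 1e-9
    assert abs(d.xb_postr) < 0.05


def test_xb_ca_step_builds_strong_binding(params):
    """Stepping Ca to systolic levels drives strongly bound fractions up to a
    plateau (reference integration of the xb subsystem alone)."""
    from scipy.integrate import solve_ivp
    p = params.pack()
    s = resting_state(params)
    y0 = s.to_vector()
    E, EC = np.zeros(0), np.zeros((4, 0))

    def fun(t, y):
        dy = R.rhs(0.5, y, p, R.CA_FREE, R.MECH_FIXED, 0.0, E, EC)
        dy[:R.INNO] = 0.0      # freeze AP and Ca handling
        return dy

    y0[R.ICA] = 1.5
    sol = solve_ivp(fun, (0, 2.0), y0, method="LSODA", rtol=1e-8,
                    atol=1e-10, dense_output=True)
    ts = np.linspace(0, 2.0, 400)
    strong = sol.sol(ts)[R.IPRER] + sol.sol(ts)[R.IPOSTR]
    assert strong[50] > 10 * strong[0] + 1e-6      # rises
    assert abs(strong[-1] - strong[-40]) < 1e-3     # plateaus


def test_xb_shortening_lowers_distortion_derivative(params):
    s = CrossbridgeState(n_xb=0.3, p_xb=0.3, xb_prer=0.2, xb_postr=0.2,
                         x_prer=0.0, x_postr=0.007, trpn_l=0.3, trpn_h=0.5)
    d_still = xb_rhs(s, 1.0, 2.2, 0.0, params)
    d_short = xb_rhs(s, 1.0, 2.2, -5.0, params)
    # shortening drags both mean distortions down (force-lowering direction)
    assert d_short.x_prer < d_still.x_prer
    assert d_short.x_postr < d_still.x_postr


def test_xb_fraction_bounds_enforced(params):
    s = CrossbridgeState(xb_prer=1.5)
    with pytest.raises(ValueError):
        xb_rhs(s, 0.1, 2.3, 0.0, params)


# ---------------------------------------------------------------- forces
def test_forces_zero_strong_bridges_gives_passive_only(params):
    s = CrossbridgeState()
    fb = forces(s, 2.2, params)
    assert fb.active == 0.0
    assert fb.total == fb.passive


def test_passive_force_monotone_above_slack(params):
    s = CrossbridgeState()
    sls = np.linspace(params.sl_rest, 2.3, 10)
    ps = [forces(s, sl, params).passive for sl in sls]
    assert all(b > a for a, b in zip(ps, ps[1:]))
    assert all(p >= 0 for p in ps)


def test_peak_lo_twitch_force_is_one_by_construction(params, iso_lo):
    assert np.max(iso_lo.record.f_total) == pytest.approx(1.0, abs=1e-3)


def test_isometric_peak_force_increases_with_length(params, cache,
                                                    iso_lo, iso_short,
                                                    iso_mid):
    p195 = np.max(iso_short.record.f_total)
    p210 = np.max(iso_mid.record.f_total)
    p230 = np.max(iso_lo.record.f_total)
    assert p195 < p210 < p230


# ---------------------------------------------------------------- coupled rhs
def test_coupled_clamped_requires_drive(params):
    s = resting_state(params)
    with pytest.raises(ValueError):
        coupled_rhs(s, 0.0, params, mode="clamped_ca", drive=None)


def test_clamped_constant_diastolic_drive_decays_to_rest(params, iso_lo):
    drv = make_parametric(0.08, 0.0, 1e-3, 2e-3)
    s = iso_lo.final_state
    res = integrate(s, params, 1.0, mode="clamped_ca", drive=drv,
                    mech=Mech.fixed())
    assert res.record.f_active[-1] < 0.02
    assert np.all(np.diff(res.record.f_active[-200:]) <= 1e-6)


def test_free_vs_self_clamped_forces_agree(params, iso_lo):
    """Clamping Ca to the free run's own recorded transient reproduces the
    force trajectory (closed-loop / open-loop self-consistency)."""
    free = integrate(iso_lo.final_state, params, 1.0, mech=Mech.fixed())
    drv = record(free.record, period=params.period)
    clamped = integrate(iso_lo.final_state, params, 1.0, mode="clamped_ca",
                        drive=drv, mech=Mech.fixed())
    peak = np.max(free.record.f_total)
    err = np.max(np.abs(free.record.f_total - clamped.record.f_total))
    assert err < 0.005 * peak


# ---------------------------------------------------------------- integrator
def test_integrate_zero_duration(params):
    s = resting_state(params)
    res = integrate(s, params, 0.0)
    assert res.record.t.size == 0
    assert res.final_state is s


def test_integrate_rejects_negative_duration(params):
    with pytest.raises(ValueError):
        integrate(resting_state(params), params, -1.0)


def test_integrate_bitwise_reproducible(params, iso_lo):
    a = integrate(iso_lo.final_state, params, 0.5, mech=Mech.fixed())
    b = integrate(iso_lo.final_state, params, 0.5, mech=Mech.fixed())
    assert np.array_equal(a.record.f_total, b.record.f_total)
    assert np.array_equal(a.record.ca_i, b.record.ca_i)


def test_tolerance_halving_changes_peak_force_little(params, iso_lo):
    """Headline outputs are converged in solver tolerance."""
    tight = integrate(iso_lo.final_state, params, 1.0, mech=Mech.fixed(),
                      rtol=5e-7)
    loose = integrate(iso_lo.final_state, params, 1.0, mech=Mech.fixed(),
                      rtol=1e-6)
    rel = abs(np.max(tight.record.f_total) - np.max(loose.record.f_total)) \
        / np.max(loose.record.f_total)
    assert rel < 1e-3


def test_force_threshold_event_fires_once_per_beat(params, iso_lo):
    p = params.pack()
    thr = 0.5 * params.force_norm

    def ev(t, y):
        return R.total_force(y, p) - thr
    ev.terminal = False
    ev.direction = 1
    res = integrate(iso_lo.final_state, params, 1.0, mech=Mech.fixed(),
                    events=[ev])
    assert len(res.event_times) == 1
    # event time localized: force at the event equals the threshold closely
    i = np.searchsorted(res.record.t, res.event_times[0])
    assert abs(res.record.f_total[i] - 0.5) < 0.01
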