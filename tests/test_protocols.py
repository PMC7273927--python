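"""Simulation protocols: isometric trains, work-loop phase machine,
quick release, cross-over, steady-state detection, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cardioloop._rhs as R
from cardioloop.analysis import ca_difference, ca_transient_metrics
from cardioloop.model_core import Mech, integrate
from cardioloop.params import ModelParams
from cardioloop.protocols import (ProtocolSpec, SimCache, detect_steady_state,
                                  run_crossover, run_isometric,
                                  run_quick_release, run_workloop)
from cardioloop.states import resting_state


# ------------------------------------------------------- steady-state detector
def test_detect_steady_state_constant_series():
    assert detect_steady_state([1.0, 1.0, 1.0]) == 1


def test_detect_steady_state_requires_two_beats():
    with pytest.raises(ValueError):
        detect_steady_state([1.0])


@settings(deadline=None, max_examples=30)
@given(ratio=st.floats(0.1, 0.9), a0=st.floats(0.01, 1.0),
       rel_tol=st.floats(1e-5, 1e-2))
def test_detect_steady_state_geometric_closed_form(ratio, a0, rel_tol):
    """For p_i = 1 + a0 * ratio**i the first index satisfying the criterion
    follows in closed form from |p_i - p_{i-1}| = a0 (1-ratio) ratio^{i-1}."""
    n = 60
    p = 1.0 + a0 * ratio ** np.arange(n)
    got = detect_steady_state(p, rel_tol)
    expected = next(
        (i for i in range(1, n)
         if abs(p[i] - p[i - 1]) < rel_tol * abs(p[i - 1])), n)
    assert got == expected


def test_default_model_reaches_steady_state_within_20_beats(iso_lo):
    assert detect_steady_state(iso_lo.peaks, 1e-3) <= 19
    assert not iso_lo.warnings


# ------------------------------------------------------- isometric
def test_isometric_rejects_bad_length(params):
    with pytest.raises(ValueError):
        run_isometric(1.0, params)


def test_isometric_records_are_cached(params, cache, iso_lo):
    again = run_isometric(params.l_o, params, cache=cache)
    assert again is iso_lo


def test_ca_width_grows_with_shorter_length(iso_lo, iso_mid, iso_short):
    w = [ca_transient_metrics(r.record).width_50
         for r in (iso_short, iso_mid, iso_lo)]
    assert w[0] > w[1] > w[2]


def test_peak_ca_roughly_length_independent(iso_lo, iso_short):
    """Peak Ca varies far less with length than the transient width does:
    the feedback reshapes the declining phase, not the peak."""
    ma = ca_transient_metrics(iso_short.record)
    mb = ca_transient_metrics(iso_lo.record)
    assert abs(ma.peak - mb.peak) / mb.peak < 0.10
    assert (ma.width_50 - mb.width_50) / mb.width_50 > 0.2


# ------------------------------------------------------- work-loop
def test_workloop_unit_afterload_is_isometric(params, wl_unit, iso_lo):
    """At afterload 1 the loop never shortens: trajectory identical to the
    L_o-isometric contraction."""
    assert wl_unit.end_systolic[0] == params.l_o
    assert np.allclose(wl_unit.record.f_total, iso_lo.record.f_total,
                       atol=1e-9)
    assert np.isnan(wl_unit.t_phase2)


def test_workloop_phase_ordering(wl_mid):
    assert wl_mid.t_phase2 < wl_mid.t_es < wl_mid.t_phase4


def test_workloop_phase2_shortens_monotonically(wl_mid):
    sl = wl_mid.record.sl[wl_mid.record.phase == 2]
    assert np.all(np.diff(sl) <= 1e-9)


def test_workloop_phase2_force_pinned_to_afterload(wl_low, wl_mid, wl_high):
    for wl in (wl_low, wl_mid, wl_high):
        ph2 = wl.record.phase == 2
        assert np.max(np.abs(wl.record.f_total[ph2] - wl.afterload)) < 1e-3


def test_workloop_isometric_phases_hold_length(wl_mid):
    rec = wl_mid.record
    for phase in (1, 3):
        sl = rec.sl[rec.phase == phase]
        assert np.ptp(sl) < 1e-9


def test_workloop_closes_loop(params, wl_mid):
    rec = wl_mid.record
    assert rec.sl[0] == pytest.approx(rec.sl[-1], abs=1e-6)
    assert rec.f_total[0] == pytest.approx(rec.f_total[-1], abs=5e-3)


def test_workloop_end_systole_monotone_in_afterload(wl_low, wl_mid, wl_high):
    assert (wl_low.end_systolic[0] < wl_mid.end_systolic[0]
            < wl_high.end_systolic[0])


def test_workloop_ca_width_grows_with_lower_afterload(wl_low, wl_mid, wl_high,
                                                      iso_lo):
    w = [ca_transient_metrics(r.record).width_50
         for r in (wl_low, wl_mid, wl_high, iso_lo)]
    assert w[0] > w[1] > w[2] >= w[3] * 0.999


def test_workloop_matches_isometric_until_phase2(wl_mid, iso_lo):
    """All loops start at L_o: the Ca transient coincides with the
    L_o-isometric one up to the onset of isotonic shortening."""
    rec, ref = wl_mid.record, iso_lo.record
    mask = rec.t < wl_mid.t_phase2
    ca_ref = np.interp(rec.t[mask], ref.t, ref.ca_i)
    # the two steady states differ slightly at diastole; agreement within a
    # couple of percent of the transient scale
    assert np.allclose(rec.ca_i[mask], ca_ref, rtol=0.02, atol=0.02)


def test_workloop_final_state_satisfies_invariants(wl_low):
    wl_low.final_state.check()


# ------------------------------------------------------- quick release
@pytest.fixture(scope="module")
def quick(params, cache):
    spec = ProtocolSpec(mode="quick_release",
                        release_times=(0.03, 0.06, 0.1, 0.15))
    return run_quick_release(spec, params, cache=cache)


def test_quick_release_time_validation(params, cache):
    spec = ProtocolSpec(mode="quick_release", release_times=(1.5,))
    with pytest.raises(ValueError):
        run_quick_release(spec, params, cache=cache)


def test_quick_release_immediate_force_drop(quick):
    for tr, rec in zip(quick.release_times, quick.releases):
        i0 = np.searchsorted(rec.t, tr) - 1
        i1 = np.searchsorted(rec.t, tr + 2e-3)
        assert rec.f_total[i1] < rec.f_total[i0] - 0.02


def test_quick_release_delta_ca_zero_before_release(quick):
    for tr, rec in zip(quick.release_times, quick.releases):
        d = ca_difference(rec, quick.reference)
        before = d.t < tr - 1e-4
        assert np.max(np.abs(d.delta[before])) < 1e-6


def test_quick_release_ca_surge_after_release(quick):
    """Releasing the muscle lowers troponin affinity and frees Ca: a clear
    positive Ca surge follows the release (any late undershoot stays below
    ~2% of the transient amplitude)."""
    amp = np.max(quick.reference.ca_i) - quick.reference.ca_i[0]
    for tr, rec in zip(quick.release_times, quick.releases):
        d = ca_difference(rec, quick.reference)
        after = (d.t > tr + 5e-3) & (d.t < 0.6)
        assert np.max(d.delta[after]) > 0.02 * amp
        assert np.min(d.delta[after]) > -0.02 * amp


def test_quick_release_ramp_refinement(params, cache):
    """Halving the release-ramp duration barely changes the sustained Ca
    surge (the transient spike during the imposed ramp itself is excluded:
    it scales with the ramp rate by construction)."""
    peaks = []
    for ramp in (0.001, 0.0005):
        spec = ProtocolSpec(mode="quick_release", release_times=(0.06,),
                            release_ramp_duration=ramp)
        qr = run_quick_release(spec, params, cache=cache)
        d = ca_difference(qr.releases[0], qr.reference)
        after = d.t > 0.06 + 5e-3
        peaks.append(np.max(d.delta[after]))
    assert abs(peaks[1] - peaks[0]) / peaks[0] < 0.05


# ------------------------------------------------------- cross-over
def test_crossover_identity_at_unit_afterload(params, cache, iso_lo):
    co = run_crossover(1.0, params, cache=cache)
    assert co.end_systolic[0] == params.l_o
    assert np.allclose(co.record.f_total, iso_lo.record.f_total, atol=5e-3)


def test_crossover_shifts_end_systole_leftward(params, cache, wl_mid):
    co = run_crossover(0.45, params, cache=cache)
    assert co.end_systolic[0] < wl_mid.end_systolic[0]


# ------------------------------------------------------- conservation
def test_total_ca_conserved_without_sarcolemmal_fluxes(params):
    """With LCC/NCX/background off, total Ca over all compartments, buffers
    and troponin is constant over 5 paced beats (0.1%)."""
    p_off = params.with_(sarcolemmal_enabled=False)
    p_off.force_norm = params.force_norm or 1.0
    state = resting_state(p_off)
    parr = p_off.pack()
    amt0 = R.total_ca_amount(state.to_vector(), parr)
    for _ in range(5):
        res = integrate(state, p_off, 1.0, mech=Mech.fixed())
        state = res.final_state
    amt1 = R.total_ca_amount(state.to_vector(), parr)
    assert abs(amt1 - amt0) / amt0 < 1e-3


# ------------------------------------------------------- feedback ablation
def test_feedback_off_makes_ca_insensitive_to_mechanics(params, cache):
    """With the force-dependent troponin affinity disabled, the Ca transient
    is identical across lengths and afterloads: Ca no longer senses
    mechanics."""
    p_off = params.with_(feedback_enabled=False)
    c = SimCache()
    a = run_isometric(1.95, p_off, cache=c)
    b = run_isometric(2.3, p_off, cache=c)
    assert np.allclose(a.record.ca_i, b.record.ca_i, rtol=1e-6, atol=1e-6)
    wl = run_workloop(ProtocolSpec(mode="workloop", afterload=0.45), p_off,
                      cache=c)
    ca_iso = np.interp(wl.record.t, b.record.t, b.record.ca_i)
    assert np.allclose(wl.record.ca_i, ca_iso, rtol=1e-5, atol=1e-5)
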