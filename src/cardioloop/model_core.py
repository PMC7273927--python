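"""Public model operations: component right-hand sides, forces, feedback flux
and the stiff beat integrator.

The coupled system is a phenomenological action potential driving a
local-control CICR Ca2+ unit, coupled to a three-state cross-bridge /
thin-filament model (Rice et al. 2008) whose force-dependent Ca-troponin
binding closes the mechano-calcium feedback loop.  All heavy lifting happens
in the compiled kernels of :mod:`cardioloop._rhs`; this module provides typed
wrappers, the mechanical boundary conditions, and :func:`integrate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _rhs as R
from .ca_waveforms import CaWaveform
from .params import ModelParams
from .states import APState, CalciumState, CrossbridgeState, ModelState

__all__ = ["ForceBreakdown", "Mech", "BeatRecord", "IntegrationResult",
           "ap_rhs", "cicr_rhs", "tnc_flux", "xb_rhs", "forces",
           "coupled_rhs", "integrate", "DEFAULT_RTOL"]

DEFAULT_RTOL = 1e-6

# per-state magnitude scales for the absolute tolerance vector
_ATOL_SCALE = np.array([1.0, 1.0,           # v, r
                        1.0, 1000.0, 1.0,   # ca_i, ca_sr, b_cyt
                        1.0, 1.0, 1.0,      # y2, y3, y4
                        1.0, 1.0, 1.0, 1.0, 1.0, 1.0,  # regulatory/XB fractions
                        0.01, 0.01,         # distortions (um)
                        1.0, 1.0,           # troponin occupancies
                        2.4])               # SL (um)

_EMPTY = np.zeros(0)
_EMPTY_C = np.zeros((4, 0))


@dataclass
class ForceBreakdown:
    """Active, passive and total force; ``normalized`` says whether the values
    are expressed relative to the peak L_o-isometric total force."""
    active: float
    passive: float
    normalized: bool = False

    @property
    def total(self) -> float:
        return self.active + self.passive


@dataclass
class Mech:
    """Mechanical boundary condition for one integration segment."""
    code: int = R.MECH_FIXED
    value: float = 0.0  # raw afterload (isotonic) or velocity um/s (ramp)

    @classmethod
    def fixed(cls) -> "Mech":
        """Hold sarcomere length constant (isometric)."""
        return cls(R.MECH_FIXED, 0.0)

    @classmethod
    def isotonic(cls, afterload_raw: float) -> "Mech":
        """Shorten/lengthen so total force balances the (raw) afterload."""
        return cls(R.MECH_ISOTONIC, afterload_raw)

    @classmethod
    def ramp(cls, velocity: float) -> "Mech":
        """Prescribed constant-velocity length change (um/s)."""
        return cls(R.MECH_RAMP, velocity)


@dataclass
class BeatRecord:
    """Dense time series of one simulated beat (or beat segment).

    Forces are normalized to the peak L_o-isometric total force when the
    parameter set carries a normalization constant; ``j_tnc`` is the net
    Ca-troponin binding flux (uM/s, positive = Ca leaving the cytosol).
    Phase labels: 0 quiescent/isometric twitch, 1-4 the work-loop phases.
    """
    t: np.ndarray
    sl: np.ndarray
    f_active: np.ndarray
    f_passive: np.ndarray
    f_total: np.ndarray
    ca_i: np.ndarray
    j_tnc: np.ndarray
    phase: np.ndarray
    normalized: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def peak_force(self) -> float:
        return float(np.max(self.f_total))

    @property
    def peak_ca(self) -> float:
        return float(np.max(self.ca_i))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_s": self.t, "sl_um": self.sl, "f_active": self.f_active,
            "f_passive": self.f_passive, "f_total": self.f_total,
            "ca_i_uM": self.ca_i, "j_tnc_uM_per_s": self.j_tnc,
            "phase": self.phase,
        })

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("t_s,sl_um,f_active,f_passive,f_total,ca_i_uM,"
                     "j_tnc_uM_per_s,phase\n")
            for i in range(len(self.t)):
                fh.write(f"{self.t[i]:.10g},{self.sl[i]:.10g},"
                         f"{self.f_active[i]:.10g},{self.f_passive[i]:.10g},"
                         f"{self.f_total[i]:.10g},{self.ca_i[i]:.10g},"
                         f"{self.j_tnc[i]:.10g},{int(self.phase[i])}\n")

    @classmethod
    def concatenate(cls, records: Sequence["BeatRecord"]) -> "BeatRecord":
        return cls(*(np.concatenate([getattr(r, f) for r in records])
                     for f in ("t", "sl", "f_active", "f_passive", "f_total",
                               "ca_i", "j_tnc", "phase")),
                   normalized=records[0].normalized,
                   meta=dict(records[0].meta))


@dataclass
class IntegrationResult:
    record: BeatRecord
    final_state: ModelState
    event_times: list


# ----------------------------------------------------------------------
# component right-hand sides (typed views over the compiled kernel math)
# ----------------------------------------------------------------------

def _check_finite(state, names) -> None:
    for name in names:
        if not np.isfinite(getattr(state, name)):
            raise ValueError(f"non-finite state variable {name!r}")


def ap_rhs(state: APState, t: float, params: ModelParams,
           stim: float | Callable[[float], float] = 0.0):
    """Time derivatives (dv/dt, dr/dt) of the action-potential variables."""
    _check_finite(state, ("v", "r"))
    s = stim(t) if callable(stim) else float(stim)
    v, r = state.v, state.r
    dv = (params.ap_c1 * v * (v - params.ap_a) * (1.0 - v)
          - params.ap_c2 * v * r + s)
    dr = params.ap_b * (v - params.ap_d * r)
    return dv, dr


def cicr_rhs(state: CalciumState, ap: APState, j_tnc: float,
             params: ModelParams) -> CalciumState:
    """Time derivatives of the Ca-handling state.

    ``j_tnc`` is the net Ca-troponin binding flux (uM/s, positive = Ca
    leaving the cytosol onto troponin); it appears as ``-j_tnc`` in the
    cytosolic Ca balance.
    """
    if state.ca_i < 0.0 or state.ca_sr < 0.0:
        raise ValueError("negative Ca concentration")
    p = params.pack()
    v_mv = params.v_rest_mv + params.v_amp_mv * ap.v
    sarco = p[R.P_SARCO]
    y1 = state.y1
    phi = R.ghk_drive(v_mv, state.ca_i, p)
    phi_pos = max(phi, 0.0)
    dinf = 1.0 / (1.0 + np.exp(-(v_mv - params.lcc_vhalf) / params.lcc_k))
    alpha = params.lcc_act_max * dinf
    ca_ds = state.ca_i + params.c_ds * phi_pos / params.ca_o
    trig = params.k_trig * ca_ds ** 2 / (params.k_trig_ca ** 2 + ca_ds ** 2)
    rn = (state.ca_i / params.k_trig_ca) ** params.n_trig
    trig_cyto = params.k_cytrig * rn / (1.0 + rn)
    dy2 = alpha * y1 - (params.lcc_close + trig) * state.y2
    dy3 = trig * state.y2 + trig_cyto * y1 - params.k_inact * state.y3
    dy4 = params.k_inact * state.y3 - params.k_recov * state.y4
    j_lcc = sarco * params.p_lcc * dinf * phi
    j_rel = params.g_rel * state.y3 * (state.ca_sr - state.ca_i)
    j_leak = params.g_leak * (state.ca_sr - state.ca_i)
    j_up = (params.vmax_up * state.ca_i ** 2
            / (params.k_up ** 2 + state.ca_i ** 2))
    j_ncx = sarco * params.g_ncx * state.ca_i
    j_bg = sarco * params.j_bg
    d_b = (params.kon_cyt * state.ca_i * (1.0 - state.b_cyt)
           - params.koff_cyt * state.b_cyt)
    d_ca = (j_lcc + j_rel + j_leak - j_up - j_ncx + j_bg
            - params.btot_cyt * d_b - j_tnc)
    beta = 1.0 / (1.0 + params.bsr_tot * params.kd_sr
                  / (params.kd_sr + state.ca_sr) ** 2)
    d_casr = beta * (j_up - j_rel - j_leak) / params.v_sr
    return CalciumState(ca_i=d_ca, ca_sr=d_casr, b_cyt=d_b,
                        y2=dy2, y3=dy3, y4=dy4)


def tnc_flux(state: CrossbridgeState, ca_i: float, params: ModelParams,
             active_force: Optional[float] = None,
             sl: Optional[float] = None) -> float:
    """Net Ca-troponin binding flux (uM/s, positive = Ca leaving cytosol).

    The force-dependent affinity enters through the fraction of overlap-zone
    regulatory sites governed by the high-affinity (strong-cross-bridge)
    off-rate.  By default that fraction is read from the cross-bridge state;
    passing ``active_force`` (normalized to the maximal force) uses it as the
    strongly bound fraction directly, which is convenient for exploring the
    force dependence in isolation.  With ``feedback_enabled`` off the flux
    uses the low-affinity kinetics everywhere and has no force or length
    dependence.
    """
    p = params.pack()
    sl = params.l_o if sl is None else sl
    _, sovf_thin, _ = R.overlap(sl, p)
    if active_force is None:
        fsb = (state.xb_prer + state.xb_postr) / (p[R.P_SS_PRER]
                                                  + p[R.P_SS_POSTR])
    else:
        fsb = min(max(float(active_force), 0.0), 1.0)
    return float(R.tnc_flux_quasistatic(state.trpn_l, state.trpn_h, fsb,
                                        sovf_thin, ca_i, p))


def xb_rhs(state: CrossbridgeState, ca_i: float, sl: float, dsl_dt: float,
           params: ModelParams) -> CrossbridgeState:
    """Time derivatives of the cross-bridge / thin-filament state.

    ``dsl_dt`` is supplied by the active mechanical protocol (0 when
    isometric); shortening feeds the mean-distortion dynamics (shortening
    deactivation).
    """
    eps = 1e-6
    for name in ("n_noxb", "p_noxb", "n_xb", "p_xb", "xb_prer", "xb_postr"):
        f = getattr(state, name)
        if f < -eps or f > 1.0 + eps:
            raise ValueError(f"fraction {name!r} outside [0, 1]")
    p = params.pack()
    y = np.zeros(R.NY)
    y[R.ICA] = ca_i
    y[R.INNO], y[R.IPNO] = state.n_noxb, state.p_noxb
    y[R.IN], y[R.IP] = state.n_xb, state.p_xb
    y[R.IPRER], y[R.IPOSTR] = state.xb_prer, state.xb_postr
    y[R.IXPRER], y[R.IXPOSTR] = state.x_prer, state.x_postr
    y[R.ITRPNL], y[R.ITRPNH] = state.trpn_l, state.trpn_h
    y[R.ISL] = sl
    mech = Mech.ramp(dsl_dt) if dsl_dt != 0.0 else Mech.fixed()
    dy = R.rhs(0.5, y, p, R.CA_FREE, mech.code, mech.value, _EMPTY, _EMPTY_C)
    return CrossbridgeState(
        n_noxb=dy[R.INNO], p_noxb=dy[R.IPNO], n_xb=dy[R.IN], p_xb=dy[R.IP],
        xb_prer=dy[R.IPRER], xb_postr=dy[R.IPOSTR],
        x_prer=dy[R.IXPRER], x_postr=dy[R.IXPOSTR],
        trpn_l=dy[R.ITRPNL], trpn_h=dy[R.ITRPNH])


def forces(state: CrossbridgeState, sl: float, params: ModelParams
           ) -> ForceBreakdown:
    """Active, passive and total force at the given cross-bridge state.

    Values are normalized to the peak L_o-isometric total force when
    ``params.force_norm`` has been computed (see
    ``protocols.ensure_normalization``), otherwise raw model units (maximal
    fully activated force at L_o = 1).
    """
    p = params.pack()
    y = np.zeros(R.NY)
    y[R.IPRER], y[R.IPOSTR] = state.xb_prer, state.xb_postr
    y[R.IXPRER], y[R.IXPOSTR] = state.x_prer, state.x_postr
    y[R.ISL] = sl
    act = float(R.active_force(y, p))
    pas = float(R.passive_force(sl, p))
    if params.force_norm is not None:
        return ForceBreakdown(act / params.force_norm,
                              pas / params.force_norm, normalized=True)
    return ForceBreakdown(act, pas, normalized=False)


def coupled_rhs(state: ModelState, t: float, params: ModelParams,
                mode: str = "free_ca", drive: Optional[CaWaveform] = None,
                mech: Optional[Mech] = None) -> ModelState:
    """Full coupled right-hand side as a ModelState of time derivatives.

    In ``free_ca`` mode the cytosolic Ca balance includes the mechano-calcium
    feedback flux (closed loop); in ``clamped_ca`` mode ``ca_i(t)`` follows
    the drive waveform exactly and the Ca-handling states are bypassed.
    """
    ca_mode = _ca_mode(mode, drive)
    mech = mech or Mech.fixed()
    drive_x, drive_c = _drive_arrays(drive)
    y = state.to_vector()
    if not np.all(np.isfinite(y)):
        bad = int(np.argmin(np.isfinite(y)))
        raise ValueError(f"non-finite state vector entry at index {bad}")
    dy = R.rhs(t, y, params.pack(), ca_mode, mech.code, mech.value,
               drive_x, drive_c)
    return ModelState.from_vector(dy)


def _ca_mode(mode: str, drive) -> int:
    if mode == "free_ca":
        return R.CA_FREE
    if mode == "clamped_ca":
        if drive is None:
            raise ValueError("clamped_ca mode requires a Ca drive waveform")
        return R.CA_CLAMPED
    raise ValueError(f"unknown Ca mode {mode!r}")


def _drive_arrays(drive):
    if drive is None:
        return _EMPTY, _EMPTY_C
    x, c = drive.to_spline_arrays()
    return np.ascontiguousarray(x), np.ascontiguousarray(c)


# ----------------------------------------------------------------------
# integrator
# ----------------------------------------------------------------------

class IntegrationError(RuntimeError):
    """Integration failure; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last valid time {last_time:.6g} s)")
        self.last_time = last_time


def _solve_segment(y0, p, t0, t1, ca_mode, mech, drive_x, drive_c,
                   events, rtol, atol):
    fun = lambda t, y: R.rhs(t, y, p, ca_mode, mech.code, mech.value,
                             drive_x, drive_c)
    sol = solve_ivp(fun, (t0, t1), y0, method="LSODA", rtol=rtol, atol=atol,
                    dense_output=True, events=events)
    if not sol.success:
        raise IntegrationError(sol.message, sol.t[-1] if sol.t.size else t0)
    return sol


def integrate(state0: ModelState, params: ModelParams, duration: float,
              mode: str = "free_ca", drive: Optional[CaWaveform] = None,
              mech: Optional[Mech] = None,
              events: Optional[Sequence[Callable]] = None,
              rtol: float = DEFAULT_RTOL, t0: float = 0.0,
              dt_out: float = 5e-4) -> IntegrationResult:
    """Integrate the coupled model over ``[t0, t0 + duration]``.

    Events are scipy-style callables ``g(t, y)`` (flat state vector, see
    :mod:`cardioloop._rhs` for the layout) with optional ``terminal`` /
    ``direction`` attributes; event times are localized by the solver's
    root finding.  Output is sampled on a uniform grid of step ``dt_out``
    from the dense solution.  Fixed inputs and tolerances give bitwise
    reproducible output.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    mech = mech or Mech.fixed()
    ca_mode = _ca_mode(mode, drive)
    drive_x, drive_c = _drive_arrays(drive)
    p = params.pack()
    f_norm = params.force_norm if params.force_norm is not None else 1.0
    if duration == 0:
        empty = np.zeros(0)
        rec = BeatRecord(empty, empty, empty, empty, empty, empty, empty,
                         np.zeros(0, dtype=np.int8),
                         normalized=params.force_norm is not None)
        return IntegrationResult(rec, state0, [])
    # split at the stimulus-off discontinuity when it falls in the window
    breaks = [t0]
    stim_off = np.floor(t0 / params.period) * params.period + params.stim_dur
    for k in range(int(np.ceil(duration / params.period)) + 1):
        tb = stim_off + k * params.period
        if t0 < tb < t0 + duration:
            breaks.append(tb)
    breaks.append(t0 + duration)
    y = state0.to_vector()
    sols = []
    event_times: list = []
    stopped = False
    for a, b in zip(breaks[:-1], breaks[1:]):
        sol = _solve_segment(y, p, a, b, ca_mode, mech, drive_x, drive_c,
                             events, rtol, rtol * 1e-3 * _ATOL_SCALE)
        sols.append(sol)
        if events is not None:
            for te in sol.t_events:
                event_times.extend(te.tolist())
            if sol.status == 1:  # terminal event fired
                stopped = True
        y = sol.y[:, -1]
        if stopped:
            break
    t_end = sols[-1].t[-1]
    ts = np.arange(t0, t_end - 1e-12, dt_out)
    if ts.size == 0 or t_end - ts[-1] > 1e-9:
        ts = np.append(ts, t_end)
    ys = np.empty((R.NY, ts.size))
    i = 0
    for sol in sols:
        j = np.searchsorted(ts, sol.t[-1], side="right") if sol is not sols[-1] \
            else ts.size
        if j > i:
            ys[:, i:j] = sol.sol(ts[i:j])
        i = j
    f_act, f_pas, ca_out, j_out = R.sample_outputs(
        ts, ys, p, ca_mode, 0, 0.0, drive_x, drive_c)
    rec = BeatRecord(
        t=ts, sl=ys[R.ISL], f_active=f_act / f_norm,
        f_passive=f_pas / f_norm, f_total=(f_act + f_pas) / f_norm,
        ca_i=ca_out, j_tnc=j_out, phase=np.zeros(ts.size, dtype=np.int8),
        normalized=params.force_norm is not None)
    final = ModelState.from_vector(y)
    return IntegrationResult(rec, final, sorted(event_times))
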