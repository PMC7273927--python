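"""Compiled right-hand sides of the coupled excitation-contraction ODE system.

Layout
------
State vector (length ``NY``)::

    0  v          dimensionless excitation variable (action potential)
    1  r          dimensionless recovery variable
    2  ca_i       cytosolic free Ca2+ (uM)
    3  ca_sr      SR free Ca2+ (uM, SR volume)
    4  b_cyt      cytosolic buffer occupancy fraction
    5  y2         release-unit fraction: LCC open, RyR closed
    6  y3         release-unit fraction: RyR open (release)
    7  y4         release-unit fraction: refractory
    8  n_noxb     nonpermissive thin-filament fraction, no-cross-bridge pool
    9  p_noxb     permissive thin-filament fraction, no-cross-bridge pool
    10 n_xb       nonpermissive fraction, cycling pool
    11 p_xb       permissive (no strong cross-bridge) fraction
    12 xb_prer    strongly bound, pre-rotation fraction
    13 xb_postr   strongly bound, post-rotation fraction
    14 x_prer     mean distortion of pre-rotation bridges (um)
    15 x_postr    mean distortion of post-rotation bridges (um)
    16 trpn_l     troponin-C regulatory Ca occupancy, low-affinity regime
    17 trpn_h     troponin-C regulatory Ca occupancy, high-affinity regime
    18 sl         sarcomere length (um)

Mechanical boundary condition codes: 0 = fixed length, 1 = isotonic against a
raw afterload (viscous force-balance velocity), 2 = constant-velocity ramp.
Ca modes: 0 = free (CICR closed loop), 1 = clamped to a drive waveform
(cubic-spline playback, periodic).

All kernels are numba ``njit`` functions over flat float64 arrays so that one
beat integrates in milliseconds; the public API in :mod:`cardioloop.model_core`
wraps them with typed containers.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NY = 19

# state indices
IV, IR, ICA, ICASR, IBCYT, IY2, IY3, IY4 = 0, 1, 2, 3, 4, 5, 6, 7
INNO, IPNO, IN, IP, IPRER, IPOSTR, IXPRER, IXPOSTR = 8, 9, 10, 11, 12, 13, 14, 15
ITRPNL, ITRPNH, ISL = 16, 17, 18

# parameter indices (packed by ModelParams.pack)
(P_AP_C1, P_AP_C2, P_AP_A, P_AP_B, P_AP_D, P_STIM_AMP, P_STIM_DUR, P_PERIOD,
 P_V_REST, P_V_AMP,
 P_CA_O, P_V_SR, P_P_LCC, P_LCC_ACT, P_LCC_VH, P_LCC_K, P_LCC_CLOSE,
 P_K_TRIG, P_K_TRIG_CA, P_C_DS, P_K_INACT, P_K_RECOV, P_G_REL, P_G_LEAK,
 P_VMAX_UP, P_K_UP, P_G_NCX, P_J_BG, P_BTOT, P_KON_B, P_KOFF_B, P_BSR,
 P_KD_SR, P_SARCO,
 P_KONT, P_KOFFLT, P_KOFFHT, P_PERM50, P_NPERM, P_KNPT, P_KPNT,
 P_FAPPT, P_GAPPT, P_HFT, P_HBT, P_GXBT, P_HFMDC, P_HBMDC, P_SIGMAP,
 P_SIGMAN, P_XPSI, P_X0, P_GSLMOD, P_TRPN, P_SS_PRER, P_SS_POSTR,
 P_LEN_THICK, P_LEN_HBARE, P_LEN_THIN, P_SL_REST, P_PCON_T, P_PEXP_T,
 P_SL_COL, P_PCON_C, P_PEXP_C, P_SL_MIN, P_SL_MAX, P_VISC, P_FEEDBACK,
 P_TWOFRT, P_N_TRIG, P_K_CYTRIG) = range(72)

NPAR = 72

MECH_FIXED = 0
MECH_ISOTONIC = 1
MECH_RAMP = 2

CA_FREE = 0
CA_CLAMPED = 1


@njit(cache=True)
def spline_eval(x, c, t):
    """Evaluate a piecewise cubic (scipy ``CubicSpline`` layout) at scalar t."""
    n = x.shape[0]
    if t <= x[0]:
        i = 0
    elif t >= x[n - 1]:
        i = n - 2
    else:
        lo, hi = 0, n - 1
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if x[mid] <= t:
                lo = mid
            else:
                hi = mid
        i = lo
    dt = t - x[i]
    return ((c[0, i] * dt + c[1, i]) * dt + c[2, i]) * dt + c[3, i]


@njit(cache=True)
def drive_ca(t, p, drive_x, drive_c):
    """Clamped-Ca drive: periodic cubic-spline playback of a recorded beat."""
    period = p[P_PERIOD]
    tl = t % period
    return spline_eval(drive_x, drive_c, tl)


@njit(cache=True)
def overlap(sl, p):
    """Single-overlap fractions seen by thick and thin filaments at ``sl``."""
    half_thick = 0.5 * p[P_LEN_THICK]
    sovr_ze = half_thick if 0.5 * sl > half_thick else 0.5 * sl
    cle = p[P_LEN_THIN] - 0.5 * sl
    half_bare = 0.5 * p[P_LEN_HBARE]
    sovr_cle = cle if cle > half_bare else half_bare
    len_sovr = sovr_ze - sovr_cle
    if len_sovr < 0.0:
        len_sovr = 0.0
    sovf_thick = len_sovr * 2.0 / (p[P_LEN_THICK] - p[P_LEN_HBARE])
    sovf_thin = len_sovr / p[P_LEN_THIN]
    # d(len_sovr)/d(sl), needed for the feedback-flux chain rule
    dze = 0.5 if 0.5 * sl < half_thick else 0.0
    dcle = -0.5 if cle > half_bare else 0.0
    dlen = dze - dcle
    dthin_dsl = dlen / p[P_LEN_THIN]
    return sovf_thick, sovf_thin, dthin_dsl


@njit(cache=True)
def passive_force(sl, p):
    """Signed titin force plus collagen engagement (raw normalized units)."""
    dsl = sl - p[P_SL_REST]
    if dsl >= 0.0:
        f = p[P_PCON_T] * (np.exp(p[P_PEXP_T] * dsl) - 1.0)
    else:
        f = -p[P_PCON_T] * (np.exp(-p[P_PEXP_T] * dsl) - 1.0)
    if sl > p[P_SL_COL]:
        f += p[P_PCON_C] * (np.exp(p[P_PEXP_C] * (sl - p[P_SL_COL])) - 1.0)
    return f


@njit(cache=True)
def active_force(y, p):
    """Raw active force: overlap-weighted distortion of strong cross-bridges."""
    sovf_thick, _, _ = overlap(y[ISL], p)
    return (sovf_thick
            * (y[IXPRER] * y[IPRER] + y[IXPOSTR] * y[IPOSTR])
            / (p[P_X0] * p[P_SS_POSTR]))


@njit(cache=True)
def total_force(y, p):
    return active_force(y, p) + passive_force(y[ISL], p)


@njit(cache=True)
def ghk_drive(v_mv, ca_i, p):
    """GHK-type driving concentration for Ca entry through the LCC (uM)."""
    u = p[P_TWOFRT] * v_mv
    if u > 1e-6 or u < -1e-6:
        eu = np.exp(-u)
        return u * (p[P_CA_O] * eu - ca_i) / (1.0 - eu)
    return p[P_CA_O] - ca_i


@njit(cache=True)
def rhs(t, y, p, ca_mode, mech_code, mech_p, drive_x, drive_c):
    """Full coupled right-hand side.  Returns dy/dt (length NY)."""
    dy = np.zeros(NY)

    # ----- action potential (modified FitzHugh-Nagumo) -----
    v = y[IV]
    r = y[IR]
    tl = t % p[P_PERIOD]
    stim = p[P_STIM_AMP] if tl < p[P_STIM_DUR] else 0.0
    dv = p[P_AP_C1] * v * (v - p[P_AP_A]) * (1.0 - v) - p[P_AP_C2] * v * r + stim
    dr = p[P_AP_B] * (v - p[P_AP_D] * r)
    v_mv = p[P_V_REST] + p[P_V_AMP] * v

    # ----- cytosolic Ca seen by the myofilaments -----
    if ca_mode == CA_CLAMPED:
        ca = drive_ca(t, p, drive_x, drive_c)
    else:
        ca = y[ICA]

    # ----- sarcomere geometry -----
    sl = y[ISL]
    sovf_thick, sovf_thin, dthin_dsl = overlap(sl, p)

    # ----- Ca-troponin binding (low/high-affinity regulatory regimes) -----
    trpn_l = y[ITRPNL]
    trpn_h = y[ITRPNH]
    d_trpn_l = p[P_KONT] * ca * (1.0 - trpn_l) - p[P_KOFFLT] * trpn_l
    d_trpn_h = p[P_KONT] * ca * (1.0 - trpn_h) - p[P_KOFFHT] * trpn_h

    # ----- thin-filament permissiveness -----
    trop_reg = (1.0 - sovf_thin) * trpn_l + sovf_thin * trpn_h
    if trop_reg < 1e-12:
        trop_reg = 1e-12
    permtot = np.sqrt(1.0 / (1.0 + (p[P_PERM50] / trop_reg) ** p[P_NPERM]))
    inprmt = 1.0 / permtot
    if inprmt > 100.0:
        inprmt = 100.0
    knp = p[P_KNPT] * permtot
    kpn = p[P_KPNT] * inprmt

    # ----- strain-modulated cross-bridge rates -----
    x_prer = y[IXPRER]
    x_postr = y[IXPOSTR]
    x0 = p[P_X0]
    # strain-modulation exponents saturate at +/-8: far outside the
    # physiological distortion range, but keeps imposed length steps
    # (quick release) from generating astronomically stiff rates
    s = 1.0 if x_prer >= 0.0 else -1.0
    arg = -s * p[P_HFMDC] * (x_prer / x0) * (x_prer / x0)
    hfmd = np.exp(arg if -8.0 < arg < 8.0 else (8.0 if arg > 0 else -8.0))
    dxp = (x_postr - x0) / x0
    s2 = 1.0 if dxp >= 0.0 else -1.0
    arg = s2 * p[P_HBMDC] * dxp * dxp
    hbmd = np.exp(arg if -8.0 < arg < 8.0 else (8.0 if arg > 0 else -8.0))
    if x_postr < x0:
        arg = p[P_SIGMAP] * ((x0 - x_postr) / x0) ** 2
    else:
        arg = p[P_SIGMAN] * ((x_postr - x0) / x0) ** 2
    gxbmd = np.exp(arg if arg < 8.0 else 8.0)
    fapp = p[P_FAPPT]
    gapp = p[P_GAPPT] * (1.0 + (1.0 - sovf_thick) * p[P_GSLMOD])
    hfr = p[P_HFT] * hfmd
    hbr = p[P_HBT] * hbmd
    gxbr = p[P_GXBT] * gxbmd

    # ----- regulatory and cross-bridge state fractions -----
    n_no = y[INNO]
    p_no = y[IPNO]
    n_xb = y[IN]
    p_xb = y[IP]
    prer = y[IPRER]
    postr = y[IPOSTR]
    d_nno = kpn * p_no - knp * n_no
    d_pno = -d_nno
    d_n = kpn * p_xb - knp * n_xb
    d_p = knp * n_xb + gapp * prer + gxbr * postr - (kpn + fapp) * p_xb
    d_prer = fapp * p_xb + hbr * postr - (gapp + hfr) * prer
    d_postr = hfr * prer - (hbr + gxbr) * postr

    # ----- forces and sarcomere-length dynamics -----
    f_active = (sovf_thick * (x_prer * prer + x_postr * postr)
                / (x0 * p[P_SS_POSTR]))
    f_passive = passive_force(sl, p)
    f_total = f_active + f_passive
    if mech_code == MECH_ISOTONIC:
        dsl = (mech_p - f_total) / p[P_VISC]
    elif mech_code == MECH_RAMP:
        dsl = mech_p
    else:
        dsl = 0.0
    if sl <= p[P_SL_MIN] and dsl < 0.0:
        dsl = 0.0
    if sl >= p[P_SL_MAX] and dsl > 0.0:
        dsl = 0.0

    # ----- mean-distortion kinetics (shortening deactivation pathway) -----
    # relaxation coefficients use the strain-free rates: the mean distortion
    # of a (nearly) empty strongly bound pool must stay well-posed, which the
    # strain-modulated rates cannot guarantee at room temperature
    d_xprer = 0.5 * dsl + (p[P_XPSI] / p[P_SS_PRER]) * (
        fapp * (-x_prer) + p[P_HBT] * (x_postr - x0 - x_prer))
    d_xpostr = 0.5 * dsl + (p[P_XPSI] / p[P_SS_POSTR]) * (
        p[P_HFT] * (x_prer + x0 - x_postr))

    # ----- mechano-calcium feedback flux (net Ca binding to troponin) -----
    trpn = p[P_TRPN]
    if p[P_FEEDBACK] != 0.0:
        ss_sum = p[P_SS_PRER] + p[P_SS_POSTR]
        fsb = (prer + postr) / ss_sum
        d_fsb = (d_prer + d_postr) / ss_sum
        occ = fsb * trpn_h + (1.0 - fsb) * trpn_l
        d_occ_partial = fsb * d_trpn_h + (1.0 - fsb) * d_trpn_l
        j_tnc = trpn * (
            (1.0 - sovf_thin) * d_trpn_l
            + sovf_thin * (d_occ_partial + d_fsb * (trpn_h - trpn_l))
            + dthin_dsl * dsl * (occ - trpn_l))
    else:
        j_tnc = trpn * d_trpn_l

    # ----- CICR unit and Ca compartments -----
    sarco = p[P_SARCO]
    y2 = y[IY2]
    y3 = y[IY3]
    y4 = y[IY4]
    y1 = 1.0 - y2 - y3 - y4
    phi = ghk_drive(v_mv, y[ICA], p)
    phi_pos = phi if phi > 0.0 else 0.0
    dinf = 1.0 / (1.0 + np.exp(-(v_mv - p[P_LCC_VH]) / p[P_LCC_K]))
    alpha = p[P_LCC_ACT] * dinf
    ca_ds = y[ICA] + p[P_C_DS] * phi_pos / p[P_CA_O]
    trig = p[P_K_TRIG] * ca_ds * ca_ds / (
        p[P_K_TRIG_CA] * p[P_K_TRIG_CA] + ca_ds * ca_ds)
    # regenerative CICR: available units can also be triggered by cytosolic
    # Ca (steep Hill keeps the resting spark rate negligible)
    rn = (y[ICA] / p[P_K_TRIG_CA]) ** p[P_N_TRIG]
    trig_cyto = p[P_K_CYTRIG] * rn / (1.0 + rn)
    dy2 = alpha * y1 - (p[P_LCC_CLOSE] + trig) * y2
    dy3 = trig * y2 + trig_cyto * y1 - p[P_K_INACT] * y3
    dy4 = p[P_K_INACT] * y3 - p[P_K_RECOV] * y4

    ca_i = y[ICA]
    ca_sr = y[ICASR]
    # whole-cell LCC Ca entry: instantaneous V-gated activation times the
    # GHK driving term (entry lasts for the AP; the y2 trigger state only
    # controls RyR opening)
    j_lcc = sarco * p[P_P_LCC] * dinf * phi
    j_rel = p[P_G_REL] * y3 * (ca_sr - ca_i)
    j_leak = p[P_G_LEAK] * (ca_sr - ca_i)
    j_up = p[P_VMAX_UP] * ca_i * ca_i / (p[P_K_UP] * p[P_K_UP] + ca_i * ca_i)
    j_ncx = sarco * p[P_G_NCX] * ca_i
    j_bg = sarco * p[P_J_BG]
    b = y[IBCYT]
    d_b = p[P_KON_B] * ca_i * (1.0 - b) - p[P_KOFF_B] * b
    j_buf = p[P_BTOT] * d_b

    if ca_mode == CA_FREE:
        d_ca = j_lcc + j_rel + j_leak - j_up - j_ncx + j_bg - j_buf - j_tnc
        kd = p[P_KD_SR]
        beta_sr = 1.0 / (1.0 + p[P_BSR] * kd / ((kd + ca_sr) * (kd + ca_sr)))
        d_casr = beta_sr * (j_up - j_rel - j_leak) / p[P_V_SR]
        dy[IV] = dv
        dy[IR] = dr
        dy[ICA] = d_ca
        dy[ICASR] = d_casr
        dy[IBCYT] = d_b
        dy[IY2] = dy2
        dy[IY3] = dy3
        dy[IY4] = dy4
    # clamped mode: AP and Ca-handling states are bypassed (derivatives 0)

    dy[INNO] = d_nno
    dy[IPNO] = d_pno
    dy[IN] = d_n
    dy[IP] = d_p
    dy[IPRER] = d_prer
    dy[IPOSTR] = d_postr
    dy[IXPRER] = d_xprer
    dy[IXPOSTR] = d_xpostr
    dy[ITRPNL] = d_trpn_l
    dy[ITRPNH] = d_trpn_h
    dy[ISL] = dsl
    return dy


@njit(cache=True)
def tnc_flux_quasistatic(trpn_l, trpn_h, fsb, sovf_thin, ca, p):
    """Instantaneous net Ca-troponin binding flux (uM/s), quasi-static weights.

    The fraction ``fsb`` of overlap-zone regulatory sites experiences the
    high-affinity (strong-cross-bridge) unbinding rate; force dependence of
    the Ca-troponin affinity enters through ``fsb``.
    """
    j_l = p[P_KONT] * ca * (1.0 - trpn_l) - p[P_KOFFLT] * trpn_l
    j_h = p[P_KONT] * ca * (1.0 - trpn_h) - p[P_KOFFHT] * trpn_h
    if p[P_FEEDBACK] == 0.0:
        return p[P_TRPN] * j_l
    return p[P_TRPN] * ((1.0 - sovf_thin) * j_l
                        + sovf_thin * (fsb * j_h + (1.0 - fsb) * j_l))


@njit(cache=True)
def trpn_bound_ca(y, p):
    """Troponin-bound Ca (uM, cytosol volume) consistent with the feedback flux."""
    _, sovf_thin, _ = overlap(y[ISL], p)
    if p[P_FEEDBACK] == 0.0:
        return p[P_TRPN] * y[ITRPNL]
    fsb = (y[IPRER] + y[IPOSTR]) / (p[P_SS_PRER] + p[P_SS_POSTR])
    occ = fsb * y[ITRPNH] + (1.0 - fsb) * y[ITRPNL]
    return p[P_TRPN] * ((1.0 - sovf_thin) * y[ITRPNL] + sovf_thin * occ)


@njit(cache=True)
def total_ca_amount(y, p):
    """Total Ca across cytosol, buffers, troponin and SR (uM, cytosol volume)."""
    ca_sr = y[ICASR]
    sr_bound = p[P_BSR] * ca_sr / (p[P_KD_SR] + ca_sr)
    return (y[ICA]
            + p[P_BTOT] * y[IBCYT]
            + trpn_bound_ca(y, p)
            + p[P_V_SR] * (ca_sr + sr_bound))


@njit(cache=True)
def sample_outputs(ts, ys, p, ca_mode, mech_codes, mech_ps, drive_x, drive_c):
    """Per-sample derived outputs for a dense trajectory.

    Returns (f_active, f_passive, ca, j_tnc) raw arrays; ``j_tnc`` is the
    quasi-static net Ca-troponin binding flux exported in beat records.
    """
    n = ts.shape[0]
    f_act = np.empty(n)
    f_pas = np.empty(n)
    ca_out = np.empty(n)
    j_out = np.empty(n)
    for i in range(n):
        y = ys[:, i]
        f_act[i] = active_force(y, p)
        f_pas[i] = passive_force(y[ISL], p)
        if ca_mode == CA_CLAMPED:
            ca = drive_ca(ts[i], p, drive_x, drive_c)
        else:
            ca = y[ICA]
        ca_out[i] = ca
        _, sovf_thin, _ = overlap(y[ISL], p)
        fsb = (y[IPRER] + y[IPOSTR]) / (p[P_SS_PRER] + p[P_SS_POSTR])
        j_out[i] = tnc_flux_quasistatic(y[ITRPNL], y[ITRPNH], fsb,
                                        sovf_thin, ca, p)
    return f_act, f_pas, ca_out, j_out
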