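"""Model parameters: loading, provenance, and packing for the ODE kernels.

The shipped default parameter file (``data/parameters.yaml``) carries one
entry per parameter with value, unit and provenance string.  ``ModelParams``
is the in-memory container; :meth:`ModelParams.pack` lowers it to the flat
float64 array consumed by the compiled right-hand sides.
"""

from __future__ import annotations

import hashlib
import importlib.resources
from dataclasses import dataclass, field, fields, replace
from typing import Optional

import numpy as np
import yaml

__all__ = ["ModelParams", "load_parameter_file", "PARAM_FILE_FIELDS"]


def _data_path():
    return importlib.resources.files("cardioloop") / "data" / "parameters.yaml"


def load_parameter_file(path=None) -> dict:
    """Read a parameter file and return ``{name: {value, unit, provenance}}``."""
    if path is None:
        text = _data_path().read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    return doc["parameters"]


# Fields that live in the parameter file (physical model constants).
PARAM_FILE_FIELDS = tuple(load_parameter_file().keys())


@dataclass
class ModelParams:
    """Full parameter set of the coupled excitation-contraction model.

    All rates are per second, concentrations in uM, lengths in um, time in s.
    ``feedback_enabled`` switches the force-dependent Ca-troponin affinity
    (mechano-calcium feedback) on or off; ``sarcolemmal_enabled`` switches the
    transmembrane Ca fluxes (LCC, NCX, background) for conservation studies.
    ``force_norm`` is the raw peak total force of the steady-state isometric
    twitch at ``l_o``; it is computed once per parameter set (see
    ``protocols.ensure_normalization``) and used to express all forces in the
    study's normalized units.
    """

    # action potential
    ap_c1: float = 0.0
    ap_c2: float = 0.0
    ap_a: float = 0.0
    ap_b: float = 0.0
    ap_d: float = 0.0
    stim_amp: float = 0.0
    stim_dur: float = 0.0
    period: float = 1.0
    v_rest_mv: float = -80.0
    v_amp_mv: float = 120.0
    # CICR
    ca_o: float = 0.0
    v_sr: float = 0.0
    p_lcc: float = 0.0
    lcc_act_max: float = 0.0
    lcc_vhalf: float = 0.0
    lcc_k: float = 0.0
    lcc_close: float = 0.0
    k_trig: float = 0.0
    k_trig_ca: float = 0.0
    n_trig: float = 2.0
    k_cytrig: float = 0.0
    c_ds: float = 0.0
    k_inact: float = 0.0
    k_recov: float = 0.0
    g_rel: float = 0.0
    g_leak: float = 0.0
    vmax_up: float = 0.0
    k_up: float = 0.0
    g_ncx: float = 0.0
    j_bg: float = 0.0
    btot_cyt: float = 0.0
    kon_cyt: float = 0.0
    koff_cyt: float = 0.0
    bsr_tot: float = 0.0
    kd_sr: float = 0.0
    # cross-bridge / troponin
    kon: float = 0.0
    koffL: float = 0.0
    koffH: float = 0.0
    q_kon: float = 1.0
    q_koff: float = 1.0
    perm50: float = 0.0
    nperm: float = 0.0
    kn_p: float = 0.0
    kp_n: float = 0.0
    q_knp: float = 1.0
    q_kpn: float = 1.0
    fapp: float = 0.0
    gapp: float = 0.0
    hf: float = 0.0
    hb: float = 0.0
    gxb: float = 0.0
    q_fapp: float = 1.0
    q_gapp: float = 1.0
    q_hf: float = 1.0
    q_hb: float = 1.0
    q_gxb: float = 1.0
    hfmdc: float = 0.0
    hbmdc: float = 0.0
    sigma_p: float = 0.0
    sigma_n: float = 0.0
    x_psi: float = 0.0
    x_0: float = 0.007
    gslmod: float = 0.0
    trpn_tot: float = 0.0
    temp_c: float = 23.0
    len_thick: float = 1.65
    len_hbare: float = 0.1
    len_thin: float = 1.2
    sl_rest: float = 1.9
    pcon_titin: float = 0.0
    pexp_titin: float = 0.0
    sl_collagen: float = 2.25
    pcon_collagen: float = 0.0
    pexp_collagen: float = 0.0
    sl_min: float = 1.4
    sl_max: float = 2.4
    l_o: float = 2.3
    visc: float = 5.0e-5
    # flags / derived
    feedback_enabled: bool = True
    sarcolemmal_enabled: bool = True
    force_norm: Optional[float] = None

    # ------------------------------------------------------------------
    @classmethod
    def from_file(cls, path=None, **overrides) -> "ModelParams":
        """Build a parameter set from a parameter file (default: shipped)."""
        entries = load_parameter_file(path)
        kwargs = {name: float(entry["value"]) for name, entry in entries.items()}
        kwargs.update(overrides)
        p = cls(**kwargs)
        p.validate()
        return p

    @classmethod
    def default(cls, **overrides) -> "ModelParams":
        return cls.from_file(None, **overrides)

    def with_(self, **overrides) -> "ModelParams":
        """Return a copy with the given fields replaced (force_norm reset)."""
        p = replace(self, **overrides)
        if any(k not in ("force_norm",) for k in overrides):
            if "force_norm" not in overrides:
                p.force_norm = None
        return p

    # ------------------------------------------------------------------
    def validate(self) -> None:
        rate_fields = (
            "ap_c1", "ap_c2", "lcc_act_max", "lcc_close", "k_trig", "k_inact",
            "k_recov", "g_rel", "vmax_up", "kon", "koffL", "koffH", "kn_p",
            "kp_n", "fapp", "gapp", "hf", "hb", "gxb",
        )
        for name in rate_fields:
            if not getattr(self, name) > 0:
                raise ValueError(f"rate constant {name!r} must be > 0")
        if abs(self.l_o - 2.3) > 1e-12:
            raise ValueError("reference sarcomere length l_o must be 2.3 um")
        if abs(self.temp_c - 23.0) > 1e-12:
            raise ValueError("working temperature must be 23 degC")
        if not (self.sl_min < self.l_o <= self.sl_max):
            raise ValueError("sarcomere-length bounds inconsistent with l_o")

    # ------------------------------------------------------------------
    def param_hash(self) -> str:
        """Hash of the physical parameters (excludes the cached force_norm)."""
        h = hashlib.sha256()
        for f in fields(self):
            if f.name == "force_norm":
                continue
            h.update(f.name.encode())
            h.update(repr(getattr(self, f.name)).encode())
        return h.hexdigest()[:16]

    # ------------------------------------------------------------------
    def pack(self) -> np.ndarray:
        """Lower to the flat array read by the compiled kernels.

        Temperature-adjusted rates (Q10 scaling from the 37 degC reference to
        ``temp_c``) and the steady-state duty fractions used for force
        normalization are precomputed here.
        """
        from . import _rhs as R

        q = lambda Q: Q ** ((self.temp_c - 37.0) / 10.0)
        fappT = self.fapp * q(self.q_fapp)
        gappT = self.gapp * q(self.q_gapp)
        hfT = self.hf * q(self.q_hf)
        hbT = self.hb * q(self.q_hb)
        gxbT = self.gxb * q(self.q_gxb)
        # steady-state duty fractions of the three-state cycle (strain-free
        # rates), used to scale mean-distortion kinetics and to normalize force
        D = (gxbT * hfT + fappT * hfT + gxbT * gappT
             + hbT * fappT + hbT * gappT + gxbT * fappT)
        ss_prer = (hbT * fappT + gxbT * fappT) / D
        ss_postr = fappT * hfT / D

        p = np.zeros(R.NPAR)
        p[R.P_AP_C1] = self.ap_c1
        p[R.P_AP_C2] = self.ap_c2
        p[R.P_AP_A] = self.ap_a
        p[R.P_AP_B] = self.ap_b
        p[R.P_AP_D] = self.ap_d
        p[R.P_STIM_AMP] = self.stim_amp
        p[R.P_STIM_DUR] = self.stim_dur
        p[R.P_PERIOD] = self.period
        p[R.P_V_REST] = self.v_rest_mv
        p[R.P_V_AMP] = self.v_amp_mv
        p[R.P_CA_O] = self.ca_o
        p[R.P_V_SR] = self.v_sr
        p[R.P_P_LCC] = self.p_lcc
        p[R.P_LCC_ACT] = self.lcc_act_max
        p[R.P_LCC_VH] = self.lcc_vhalf
        p[R.P_LCC_K] = self.lcc_k
        p[R.P_LCC_CLOSE] = self.lcc_close
        p[R.P_K_TRIG] = self.k_trig
        p[R.P_K_TRIG_CA] = self.k_trig_ca
        p[R.P_C_DS] = self.c_ds
        p[R.P_K_INACT] = self.k_inact
        p[R.P_K_RECOV] = self.k_recov
        p[R.P_G_REL] = self.g_rel
        p[R.P_G_LEAK] = self.g_leak
        p[R.P_VMAX_UP] = self.vmax_up
        p[R.P_K_UP] = self.k_up
        p[R.P_G_NCX] = self.g_ncx
        p[R.P_J_BG] = self.j_bg
        p[R.P_BTOT] = self.btot_cyt
        p[R.P_KON_B] = self.kon_cyt
        p[R.P_KOFF_B] = self.koff_cyt
        p[R.P_BSR] = self.bsr_tot
        p[R.P_KD_SR] = self.kd_sr
        p[R.P_SARCO] = 1.0 if self.sarcolemmal_enabled else 0.0
        p[R.P_KONT] = self.kon * q(self.q_kon)
        p[R.P_KOFFLT] = self.koffL * q(self.q_koff)
        p[R.P_KOFFHT] = self.koffH * q(self.q_koff)
        p[R.P_PERM50] = self.perm50
        p[R.P_NPERM] = self.nperm
        p[R.P_KNPT] = self.kn_p * q(self.q_knp)
        p[R.P_KPNT] = self.kp_n * q(self.q_kpn)
        p[R.P_FAPPT] = fappT
        p[R.P_GAPPT] = gappT
        p[R.P_HFT] = hfT
        p[R.P_HBT] = hbT
        p[R.P_GXBT] = gxbT
        p[R.P_HFMDC] = self.hfmdc
        p[R.P_HBMDC] = self.hbmdc
        p[R.P_SIGMAP] = self.sigma_p
        p[R.P_SIGMAN] = self.sigma_n
        p[R.P_XPSI] = self.x_psi
        p[R.P_X0] = self.x_0
        p[R.P_GSLMOD] = self.gslmod
        p[R.P_TRPN] = self.trpn_tot
        p[R.P_SS_PRER] = ss_prer
        p[R.P_SS_POSTR] = ss_postr
        p[R.P_LEN_THICK] = self.len_thick
        p[R.P_LEN_HBARE] = self.len_hbare
        p[R.P_LEN_THIN] = self.len_thin
        p[R.P_SL_REST] = self.sl_rest
        p[R.P_PCON_T] = self.pcon_titin
        p[R.P_PEXP_T] = self.pexp_titin
        p[R.P_SL_COL] = self.sl_collagen
        p[R.P_PCON_C] = self.pcon_collagen
        p[R.P_PEXP_C] = self.pexp_collagen
        p[R.P_SL_MIN] = self.sl_min
        p[R.P_SL_MAX] = self.sl_max
        p[R.P_VISC] = self.visc
        p[R.P_FEEDBACK] = 1.0 if self.feedback_enabled else 0.0
        p[R.P_N_TRIG] = self.n_trig
        p[R.P_K_CYTRIG] = self.k_cytrig
        p[R.P_TWOFRT] = 2.0 * 96485.33 / (8.31446 * (273.15 + self.temp_c)) / 1000.0  # 1/mV
        return p
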