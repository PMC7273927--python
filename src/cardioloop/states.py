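"""Typed state containers and their flat-vector packing.

The integrator works on a flat float64 vector (see :mod:`cardioloop._rhs` for
the layout); these dataclasses give the same state a domain-structured view
with invariant checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _rhs as R
from .params import ModelParams

__all__ = ["APState", "CalciumState", "CrossbridgeState", "ModelState",
           "resting_state"]

_FRACTION_TOL = 1e-6


@dataclass
class APState:
    """Phenomenological action-potential state (dimensionless)."""
    v: float = 0.0
    r: float = 0.0

    def check(self) -> None:
        if not (np.isfinite(self.v) and np.isfinite(self.r)):
            raise ValueError("non-finite action-potential state")


@dataclass
class CalciumState:
    """CICR unit state: Ca compartments, buffer and release-unit gating."""
    ca_i: float = 0.1          # cytosolic free Ca2+ (uM)
    ca_sr: float = 1000.0      # SR free Ca2+ (uM)
    b_cyt: float = 0.0         # cytosolic buffer occupancy
    y2: float = 0.0            # LCC open, RyR closed
    y3: float = 0.0            # RyR open (releasing)
    y4: float = 0.0            # refractory

    @property
    def y1(self) -> float:
        """Resting (available) release-unit fraction."""
        return 1.0 - self.y2 - self.y3 - self.y4

    def check(self) -> None:
        if self.ca_i < 0.0 or self.ca_sr < 0.0:
            raise ValueError("negative Ca concentration")
        for name in ("b_cyt", "y2", "y3", "y4"):
            f = getattr(self, name)
            if f < -_FRACTION_TOL or f > 1.0 + _FRACTION_TOL:
                raise ValueError(f"gating/buffer fraction {name!r} outside [0, 1]")
        if self.y1 < -_FRACTION_TOL:
            raise ValueError("release-unit fractions sum above 1")


@dataclass
class CrossbridgeState:
    """Thin-filament activation and cross-bridge cycling state."""
    n_noxb: float = 1.0   # nonpermissive, no-cross-bridge pool
    p_noxb: float = 0.0
    n_xb: float = 1.0     # nonpermissive, cycling pool
    p_xb: float = 0.0     # permissive, no strong cross-bridge
    xb_prer: float = 0.0  # strongly bound, pre-rotation
    xb_postr: float = 0.0  # strongly bound, post-rotation
    x_prer: float = 0.0   # mean distortion (um)
    x_postr: float = 0.007
    trpn_l: float = 0.0   # troponin-C Ca occupancy, low-affinity regime
    trpn_h: float = 0.0   # high-affinity regime

    def check(self) -> None:
        for name in ("n_noxb", "p_noxb", "n_xb", "p_xb", "xb_prer",
                     "xb_postr", "trpn_l", "trpn_h"):
            f = getattr(self, name)
            if f < -_FRACTION_TOL or f > 1.0 + _FRACTION_TOL:
                raise ValueError(f"fraction {name!r} outside [0, 1]")
        if abs(self.n_noxb + self.p_noxb - 1.0) > 1e-3:
            raise ValueError("no-cross-bridge pool does not sum to 1")
        s = self.n_xb + self.p_xb + self.xb_prer + self.xb_postr
        if abs(s - 1.0) > 1e-3:
            raise ValueError("cycling pool does not sum to 1")


@dataclass
class ModelState:
    """Full dynamic state of the coupled model."""
    ap: APState
    ca: CalciumState
    xb: CrossbridgeState
    sl: float = 2.3

    def check(self) -> None:
        self.ap.check()
        self.ca.check()
        self.xb.check()
        if not (1.4 <= self.sl <= 2.4):
            raise ValueError("sarcomere length outside [1.4, 2.4] um")

    # ------------------------------------------------------------------
    def to_vector(self) -> np.ndarray:
        y = np.empty(R.NY)
        y[R.IV], y[R.IR] = self.ap.v, self.ap.r
        y[R.ICA], y[R.ICASR] = self.ca.ca_i, self.ca.ca_sr
        y[R.IBCYT] = self.ca.b_cyt
        y[R.IY2], y[R.IY3], y[R.IY4] = self.ca.y2, self.ca.y3, self.ca.y4
        x = self.xb
        y[R.INNO], y[R.IPNO] = x.n_noxb, x.p_noxb
        y[R.IN], y[R.IP] = x.n_xb, x.p_xb
        y[R.IPRER], y[R.IPOSTR] = x.xb_prer, x.xb_postr
        y[R.IXPRER], y[R.IXPOSTR] = x.x_prer, x.x_postr
        y[R.ITRPNL], y[R.ITRPNH] = x.trpn_l, x.trpn_h
        y[R.ISL] = self.sl
        return y

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "ModelState":
        return cls(
            ap=APState(v=y[R.IV], r=y[R.IR]),
            ca=CalciumState(ca_i=y[R.ICA], ca_sr=y[R.ICASR], b_cyt=y[R.IBCYT],
                            y2=y[R.IY2], y3=y[R.IY3], y4=y[R.IY4]),
            xb=CrossbridgeState(n_noxb=y[R.INNO], p_noxb=y[R.IPNO],
                                n_xb=y[R.IN], p_xb=y[R.IP],
                                xb_prer=y[R.IPRER], xb_postr=y[R.IPOSTR],
                                x_prer=y[R.IXPRER], x_postr=y[R.IXPOSTR],
                                trpn_l=y[R.ITRPNL], trpn_h=y[R.ITRPNH]),
            sl=y[R.ISL],
        )


def resting_state(params: ModelParams, sl: float | None = None,
                  ca_i: float = 0.08228, ca_sr: float = 219.79,
                  y4: float = 0.06272) -> ModelState:
    """Quiescent initial condition: diastolic Ca of the 1-Hz paced steady
    state, troponin/buffer equilibrated, release units partly refractory as
    at the end of a steady-state cycle."""
    sl = params.l_o if sl is None else sl
    q = (params.temp_c - 37.0) / 10.0
    kont = params.kon * params.q_kon ** q
    koffl = params.koffL * params.q_koff ** q
    koffh = params.koffH * params.q_koff ** q
    trpn_l = kont * ca_i / (kont * ca_i + koffl)
    trpn_h = kont * ca_i / (kont * ca_i + koffh)
    b = params.kon_cyt * ca_i / (params.kon_cyt * ca_i + params.koff_cyt)
    return ModelState(
        ap=APState(),
        ca=CalciumState(ca_i=ca_i, ca_sr=ca_sr, b_cyt=b, y4=y4),
        xb=CrossbridgeState(trpn_l=trpn_l, trpn_h=trpn_h,
                            x_postr=params.x_0),
        sl=sl,
    )
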