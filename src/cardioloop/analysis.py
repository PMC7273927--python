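"""ESFLR construction, force-equivalent pairing and Ca2+-transient metrics.

The end-systolic force-length relation (ESFLR) is mode dependent: for
isometric twitches it is the peak total force as a function of sarcomere
length; for work-loop contractions it is the (end-systolic length, afterload)
point where the muscle can no longer shorten.  Forces are normalized to the
peak L_o-isometric force and lengths to L_o.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import BeatRecord, DEFAULT_RTOL
from .params import ModelParams

__all__ = ["ESPoint", "ESFLRTable", "CaMetrics", "TwitchTiming",
           "DifferenceTrace", "esflr", "force_equivalent_length",
           "ca_transient_metrics", "ca_difference", "twitch_timing"]


@dataclass
class ESPoint:
    """One end-systolic point: normalized length and force, per mode."""
    sl_norm: float
    force_norm: float
    mode: str
    sl_um: float = 0.0


@dataclass
class ESFLRTable:
    points: list
    mode: str

    def __iter__(self):
        return iter(self.points)

    def __len__(self):
        return len(self.points)

    @property
    def sl_norm(self) -> np.ndarray:
        return np.array([p.sl_norm for p in self.points])

    @property
    def force_norm(self) -> np.ndarray:
        return np.array([p.force_norm for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mode": [p.mode for p in self.points],
            "sl_um": [p.sl_um for p in self.points],
            "sl_norm": self.sl_norm,
            "force_norm": self.force_norm,
        })

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("mode,sl_um,sl_norm,force_norm\n")
            for p in self.points:
                fh.write(f"{p.mode},{p.sl_um:.10g},{p.sl_norm:.10g},"
                         f"{p.force_norm:.10g}\n")

    def interp_sl_at_force(self, force: float) -> float:
        """Normalized length at the given force, linear interpolation."""
        f = self.force_norm
        s = self.sl_norm
        order = np.argsort(f)
        return float(np.interp(force, f[order], s[order]))


@dataclass
class CaMetrics:
    """Summary metrics of one Ca2+ twitch transient."""
    onset_time: float    # s from record start (diastolic + 5% amplitude crossing)
    peak: float          # uM
    time_to_peak: float  # s from record start
    width_50: float      # s, full width at half amplitude over diastole
    decay_auc: float     # uM*s, area above diastole over the declining phase
    diastolic: float = 0.0


@dataclass
class TwitchTiming:
    t_ca_onset: float
    t_force_onset: float
    delay: float


@dataclass
class DifferenceTrace:
    t: np.ndarray
    delta: np.ndarray


# ----------------------------------------------------------------------
def esflr(records: Sequence, mode: Optional[str] = None) -> ESFLRTable:
    """Build an ESFLR table from per-protocol results.

    ``records`` are :class:`~cardioloop.protocols.IsometricResult` or
    :class:`~cardioloop.protocols.WorkLoopResult` objects of a single mode;
    mixing modes raises.  Isometric points are (length, peak force);
    work-loop and cross-over points are (end-systolic length, afterload).
    """
    modes = {r.mode for r in records}
    if len(modes) != 1:
        raise ValueError(f"records mix contraction modes: {sorted(modes)}")
    rmode = modes.pop()
    if mode is not None and mode != rmode:
        raise ValueError(f"records are {rmode!r}, requested {mode!r}")
    points = []
    for r in records:
        if rmode == "isometric":
            sl = r.sl
            force = float(np.max(r.record.f_total))
        else:
            sl, force = r.end_systolic
        # normalization length L_o = 2.3 um by construction
        l_o = 2.3
        points.append(ESPoint(sl_norm=sl / l_o, force_norm=force,
                              mode=rmode, sl_um=sl))
    points.sort(key=lambda p: p.sl_norm)
    return ESFLRTable(points=points, mode=rmode)


# ----------------------------------------------------------------------
def force_equivalent_length(afterload: float, params: ModelParams,
                            bracket=(1.95, 2.3),
                            cache=None, rtol: float = DEFAULT_RTOL,
                            n_beats: int = 20,
                            force_tol: float = 1e-3) -> float:
    """Sarcomere length whose steady-state isometric peak force equals the
    given normalized afterload, found by bisection over ``bracket``.

    Terminates when the peak-force mismatch is below ``force_tol``
    (normalized units); the peak force is monotone in length over the
    study's range, so the returned length is monotone in the afterload.
    """
    from .protocols import SimCache, run_isometric

    cache = cache or SimCache()

    def peak(sl):
        res = run_isometric(sl, params, n_beats=n_beats, rtol=rtol,
                            cache=cache)
        return float(np.max(res.record.f_total))

    lo, hi = bracket
    f_lo, f_hi = peak(lo) - afterload, peak(hi) - afterload
    if abs(f_lo) < force_tol:
        return lo
    if abs(f_hi) < force_tol:
        return hi
    if f_lo * f_hi > 0:
        raise ValueError(
            f"afterload {afterload} outside the attainable isometric force "
            f"range over the bracket {bracket}")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f_mid = peak(mid) - afterload
        if abs(f_mid) < force_tol or (hi - lo) < 1e-6:
            return mid
        if f_lo * f_mid < 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
    return 0.5 * (lo + hi)


# ----------------------------------------------------------------------
def _cross_up(t, x, level, i_stop):
    """First upward crossing of ``level`` before index ``i_stop`` (interp)."""
    for i in range(1, i_stop + 1):
        if x[i - 1] < level <= x[i]:
            frac = (level - x[i - 1]) / (x[i] - x[i - 1])
            return t[i - 1] + frac * (t[i] - t[i - 1])
    return None


def _cross_down(t, x, level, i_start):
    for i in range(i_start + 1, len(x)):
        if x[i - 1] >= level > x[i]:
            frac = (x[i - 1] - level) / (x[i - 1] - x[i])
            return t[i - 1] + frac * (t[i] - t[i - 1])
    return None


def ca_transient_metrics(record: BeatRecord,
                         onset_fraction: float = 0.05) -> CaMetrics:
    """Onset, peak, time-to-peak, FWHM and decay area of a Ca2+ transient.

    Onset is the first upward crossing of diastolic + ``onset_fraction`` of
    the amplitude; width_50 is the full width at half amplitude over
    diastole; the decay area integrates (ca - diastolic) from the peak to
    the end of the record.  Deterministic for a fixed record.
    """
    t = np.asarray(record.t)
    ca = np.asarray(record.ca_i)
    dia = float(ca[0])
    ipk = int(np.argmax(ca))
    peak = float(ca[ipk])
    amp = peak - dia
    if amp <= max(1e-9, 1e-6 * abs(dia)):
        raise ValueError("flat Ca signal: no transient to measure")
    onset = _cross_up(t, ca, dia + onset_fraction * amp, ipk)
    half = dia + 0.5 * amp
    t_up = _cross_up(t, ca, half, ipk)
    t_down = _cross_down(t, ca, half, ipk)
    if onset is None or t_up is None or t_down is None:
        raise ValueError("transient does not cross the required levels")
    auc = float(np.trapezoid(ca[ipk:] - dia, t[ipk:]))
    return CaMetrics(onset_time=float(onset), peak=peak,
                     time_to_peak=float(t[ipk]),
                     width_50=float(t_down - t_up), decay_auc=auc,
                     diastolic=dia)


def ca_difference(test: BeatRecord, reference: BeatRecord,
                  dt: float = 5e-4) -> DifferenceTrace:
    """Pointwise Ca2+ difference (test - reference) on a shared dense grid."""
    t0 = max(test.t[0], reference.t[0])
    t1 = min(test.t[-1], reference.t[-1])
    tt = np.arange(t0, t1 + dt / 2, dt)
    a = np.interp(tt, test.t, test.ca_i)
    b = np.interp(tt, reference.t, reference.ca_i)
    return DifferenceTrace(t=tt, delta=a - b)


def twitch_timing(record: BeatRecord,
                  onset_fraction: float = 0.05) -> TwitchTiming:
    """Onset of the Ca2+ transient and of active force development.

    Both onsets are crossings of diastolic + 5% of the respective amplitude,
    measured from the record start (the stimulus); the delay is force onset
    minus Ca onset.
    """
    t = np.asarray(record.t)
    ca = np.asarray(record.ca_i)
    f = np.asarray(record.f_active)
    ipk_ca = int(np.argmax(ca))
    ipk_f = int(np.argmax(f))
    dia_ca = float(ca[0])
    dia_f = float(f[0])
    amp_ca = ca[ipk_ca] - dia_ca
    amp_f = f[ipk_f] - dia_f
    if amp_ca <= 0 or amp_f <= 0:
        raise ValueError("record contains no twitch")
    t_ca = _cross_up(t, ca, dia_ca + onset_fraction * amp_ca, ipk_ca)
    t_f = _cross_up(t, f, dia_f + onset_fraction * amp_f, ipk_f)
    if t_ca is None or t_f is None:
        raise ValueError("onset crossing not found")
    return TwitchTiming(t_ca_onset=float(t_ca), t_force_onset=float(t_f),
                        delay=float(t_f - t_ca))
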