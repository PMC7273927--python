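"""Ca2+ drive waveforms: parametric twitch transients and recorded playback.

A :class:`CaWaveform` maps time (s) to cytosolic Ca2+ (uM) and can drive the
myofilament model in clamped-Ca mode.  The parametric family is a
double-exponential twitch transient with closed-form peak time, used both as
a synthetic drive and as the oracle for the transient metrics in
:mod:`cardioloop.analysis`.  Recorded waveforms play back a simulated (or
measured) beat through a periodic cubic spline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["CaWaveform", "make_parametric", "record"]


@dataclass
class CaWaveform:
    """Time-parameterized Ca2+ concentration signal, playable as a model drive.

    ``kind`` is ``"parametric"`` (double-exponential twitch) or ``"recorded"``
    (sampled beat, periodic cubic interpolation).  The support interval is
    ``[0, period)``; evaluation outside wraps periodically.
    """

    kind: str
    period: float = 1.0
    # parametric fields
    diastolic: float = 0.0
    amplitude: float = 0.0
    tau_rise: float = 0.0
    tau_decay: float = 0.0
    offset: float = 0.0
    # recorded fields
    samples_t: Optional[np.ndarray] = None
    samples_ca: Optional[np.ndarray] = None
    _spline: object = field(default=None, repr=False, compare=False)

    # ------------------------------------------------------------------
    @property
    def peak_time(self) -> float:
        """Time of the transient peak (s from beat start)."""
        if self.kind == "parametric":
            if self.amplitude == 0.0:
                return self.offset
            tr, td = self.tau_rise, self.tau_decay
            return self.offset + tr * td / (td - tr) * np.log(td / tr)
        ts = np.asarray(self.samples_t)
        return float(ts[np.argmax(np.asarray(self.samples_ca))])

    @property
    def peak(self) -> float:
        if self.kind == "parametric":
            return self.diastolic + self.amplitude
        return float(np.max(self.samples_ca))

    # ------------------------------------------------------------------
    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        tl = np.mod(t, self.period)
        if self.kind == "parametric":
            if self.amplitude == 0.0:
                return np.broadcast_to(self.diastolic, tl.shape).copy()
            tr, td = self.tau_rise, self.tau_decay
            tp = tr * td / (td - tr) * np.log(td / tr)
            norm = np.exp(-tp / td) - np.exp(-tp / tr)
            x = tl - self.offset
            out = np.where(
                x >= 0.0,
                self.diastolic + self.amplitude / norm
                * (np.exp(-np.clip(x, 0, None) / td)
                   - np.exp(-np.clip(x, 0, None) / tr)),
                self.diastolic,
            )
            return out if out.shape else float(out)
        spl = self._get_spline()
        out = spl(tl)
        return out if out.shape else float(out)

    # ------------------------------------------------------------------
    def _get_spline(self) -> CubicSpline:
        if self._spline is None:
            if self.kind == "recorded":
                t = np.asarray(self.samples_t, dtype=float)
                ca = np.asarray(self.samples_ca, dtype=float)
                if t[-1] < self.period - 1e-12:
                    # close the periodic loop at the beat boundary
                    t = np.append(t, self.period)
                    ca = np.append(ca, ca[0])
                else:
                    ca = ca.copy()
                    ca[-1] = ca[0]
                self._spline = CubicSpline(t, ca, bc_type="periodic")
            else:
                tt = np.arange(0.0, self.period + 1e-12, 2.5e-4)
                self._spline = CubicSpline(tt, self(tt))
        return self._spline

    def to_spline_arrays(self):
        """(breakpoints, coefficients) for the compiled playback kernel."""
        spl = self._get_spline()
        return spl.x, spl.c

    # ------------------------------------------------------------------
    def to_csv(self, path, dt: float = 1e-3) -> None:
        """Write a two-column CSV (t_s, ca_uM) plus a JSON sidecar."""
        tt = np.arange(0.0, self.period, dt)
        vals = self(tt)
        with open(path, "w") as fh:
            fh.write("t_s,ca_uM\n")
            for t, c in zip(tt, vals):
                fh.write(f"{t:.10g},{c:.10g}\n")
        side = {"kind": self.kind, "period": self.period}
        if self.kind == "parametric":
            side.update(diastolic=self.diastolic, amplitude=self.amplitude,
                        tau_rise=self.tau_rise, tau_decay=self.tau_decay,
                        offset=self.offset)
        with open(str(path) + ".json", "w") as fh:
            json.dump(side, fh, indent=1, sort_keys=True)


def make_parametric(diastolic: float, amplitude: float, tau_rise: float,
                    tau_decay: float, offset: float = 0.0,
                    period: float = 1.0) -> CaWaveform:
    """Double-exponential twitch transient.

    ``ca(t) = diastolic + amplitude * (exp(-x/tau_decay) - exp(-x/tau_rise)) / norm``
    with ``x = t - offset`` and ``norm`` chosen so the peak equals
    ``diastolic + amplitude``.  Requires ``tau_decay > tau_rise > 0``.
    """
    if amplitude != 0.0:
        if not (tau_rise > 0.0 and tau_decay > tau_rise):
            raise ValueError("need tau_decay > tau_rise > 0")
    return CaWaveform(kind="parametric", period=period, diastolic=diastolic,
                      amplitude=amplitude, tau_rise=tau_rise,
                      tau_decay=tau_decay, offset=offset)


def record(beat_record, period: float = 1.0) -> CaWaveform:
    """Capture the Ca2+ trace of a beat record as a playable drive.

    The record is assumed to cover one pacing period starting at the
    stimulus; playback extends it periodically.
    """
    t = np.asarray(beat_record.t, dtype=float)
    ca = np.asarray(beat_record.ca_i, dtype=float)
    keep = t < period - 1e-9
    return CaWaveform(kind="recorded", period=period,
                      samples_t=t[keep], samples_ca=ca[keep])
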