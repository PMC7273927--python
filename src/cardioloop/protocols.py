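"""Event-driven simulation protocols.

Four experiments are provided, all paced at 1 Hz to beat-to-beat steady
state (20 beats by default):

* :func:`run_isometric` — fixed sarcomere length throughout the twitch;
* :func:`run_workloop` — the four-phase force-length work-loop (isometric
  contraction, isotonic shortening against a constant afterload, isometric
  relaxation, constant-velocity restretch), the 1-D analogue of the cardiac
  pressure-volume loop;
* :func:`run_quick_release` — rapid length step to a fraction of L_o at a
  prescribed time within the twitch (Ca-surge protocol);
* :func:`run_crossover` — a work-loop driven in clamped-Ca mode by the Ca2+
  transient recorded from its force-equivalent isometric contraction.

Phase transitions are located by the integrator's event root finding.  All
forces are normalized to the peak total force of the steady-state isometric
twitch at L_o; :func:`ensure_normalization` computes that constant once per
parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _rhs as R
from . import ca_waveforms
from .model_core import (BeatRecord, DEFAULT_RTOL, ForceBreakdown,
                         IntegrationResult, Mech, integrate)
from .params import ModelParams
from .states import ModelState, resting_state

__all__ = ["ProtocolSpec", "WorkLoopResult", "IsometricResult",
           "QuickReleaseResult", "SimCache", "detect_steady_state",
           "ensure_normalization", "run_isometric", "run_workloop",
           "run_quick_release", "run_crossover"]


@dataclass
class ProtocolSpec:
    """Declarative description of one simulation experiment."""
    mode: str = "isometric"          # isometric | workloop | quick_release | crossover
    sl_init: float = 2.3             # um
    afterload: float = 1.0           # normalized total force (workloop/crossover)
    release_length_fraction: float = 0.92
    release_times: Sequence[float] = (0.03, 0.06, 0.1, 0.15)
    pacing_hz: float = 1.0
    n_beats_to_steady: int = 20
    restretch_duration: float = 0.05   # s (constant-velocity Phase 4)
    release_ramp_duration: float = 0.001  # s (quick-release length step)
    diastolic_ca_tolerance: float = 0.02  # Phase-3 exit: ca within 2% of diastolic
    ca_drive: Optional[ca_waveforms.CaWaveform] = None
    rtol: float = DEFAULT_RTOL

    def validate(self, params: ModelParams) -> None:
        if self.mode in ("workloop", "crossover") and not (0.0 < self.afterload <= 1.0):
            raise ValueError("afterload must be in (0, 1]")
        if not (1.4 <= self.sl_init <= params.sl_max):
            raise ValueError("sl_init outside the valid sarcomere-length range")


@dataclass
class IsometricResult:
    mode: str
    sl: float
    record: BeatRecord               # steady-state (final) beat
    peak: ForceBreakdown             # at time of peak total force
    peaks: np.ndarray                # per-beat peak total force (normalized)
    steady_index: int
    final_state: ModelState = None
    warnings: list = field(default_factory=list)


@dataclass
class WorkLoopResult:
    mode: str
    afterload: float
    sl_init: float
    record: BeatRecord               # steady-state beat, phase-annotated
    t_phase2: float                  # Phase-1 -> Phase-2 transition (s from stimulus)
    t_es: float                      # end-systole (Phase-2 exit)
    t_phase4: float                  # restretch onset
    end_systolic: tuple              # (sl um, normalized force)
    peaks: np.ndarray
    steady_index: int
    final_state: ModelState = None
    degenerate: bool = False
    warnings: list = field(default_factory=list)


@dataclass
class QuickReleaseResult:
    mode: str
    release_times: Sequence[float]
    releases: list                   # BeatRecord per release time
    reference: BeatRecord            # L_o isometric twitch from the same state
    warnings: list = field(default_factory=list)


# ----------------------------------------------------------------------
class SimCache:
    """Memoization of steady-state simulations for one session.

    Keys include the physical-parameter hash, so a cache can safely be
    shared across parameter variants.
    """

    def __init__(self):
        self._store = {}

    def get_or_run(self, key, fn):
        if key not in self._store:
            self._store[key] = fn()
        return self._store[key]


def _key(params: ModelParams, *rest):
    return (params.param_hash(),) + tuple(
        round(x, 12) if isinstance(x, float) else x for x in rest)


# ----------------------------------------------------------------------
def detect_steady_state(peak_series, rel_tol: float = 1e-3) -> int:
    """First index ``i`` with ``|p[i] - p[i-1]| < rel_tol * |p[i-1]|``.

    The returned index is 0-based into the per-beat series, so the steady
    state is reached within ``i + 1`` beats.  Returns ``len(series)`` as a
    sentinel when the criterion is never met.
    """
    p = np.asarray(peak_series, dtype=float)
    if p.size < 2:
        raise ValueError("need at least two beats")
    for i in range(1, p.size):
        if abs(p[i] - p[i - 1]) < rel_tol * abs(p[i - 1]):
            return i
    return p.size


# ----------------------------------------------------------------------
def ensure_normalization(params: ModelParams, cache: Optional[SimCache] = None,
                         rtol: float = DEFAULT_RTOL,
                         n_beats: int = 20) -> float:
    """Compute (once) the raw peak total force of the steady-state isometric
    twitch at L_o and store it as ``params.force_norm``."""
    if params.force_norm is not None:
        return params.force_norm
    cache = cache or SimCache()

    def run():
        raw = params.with_(l_o=params.l_o)
        raw.force_norm = None
        res = _isometric_train(raw, raw.l_o, n_beats, rtol, f_norm=1.0)
        return float(np.max(res["record_raw_total"]))

    peak = cache.get_or_run(_key(params, "norm", rtol, n_beats), run)
    params.force_norm = peak
    return peak


def _isometric_train(params: ModelParams, sl: float, n_beats: int,
                     rtol: float, f_norm: float,
                     mode: str = "free_ca", drive=None) -> dict:
    """Pace an isometric preparation for ``n_beats``; return the final beat."""
    state = resting_state(params, sl=sl)
    period = params.period
    peaks = []
    last = None
    for _ in range(n_beats):
        res = integrate(state, params, period, mode=mode, drive=drive,
                        mech=Mech.fixed(), rtol=rtol)
        state = res.final_state
        peaks.append(np.max(res.record.f_total))
        last = res.record
    return {
        "record": last,
        "record_raw_total": last.f_total * (params.force_norm or 1.0)
        if last.normalized else last.f_total,
        "peaks": np.asarray(peaks),
        "final_state": state,
    }


def run_isometric(sl: float, params: ModelParams, n_beats: int = 20,
                  rtol: float = DEFAULT_RTOL,
                  cache: Optional[SimCache] = None,
                  mode: str = "free_ca", drive=None) -> IsometricResult:
    """Steady-state isometric twitch at sarcomere length ``sl`` (um)."""
    if not (params.sl_min <= sl <= params.sl_max):
        raise ValueError("sarcomere length outside valid range")
    cache = cache or SimCache()
    ensure_normalization(params, cache, rtol=rtol, n_beats=n_beats)

    def run():
        out = _isometric_train(params, sl, n_beats, rtol,
                               f_norm=params.force_norm, mode=mode,
                               drive=drive)
        rec = out["record"]
        i = int(np.argmax(rec.f_total))
        peak = ForceBreakdown(active=float(rec.f_active[i]),
                              passive=float(rec.f_passive[i]),
                              normalized=True)
        steady = detect_steady_state(out["peaks"], 1e-3)
        warnings = []
        if steady >= len(out["peaks"]):
            warnings.append("beat-to-beat steady state not reached")
        return IsometricResult(mode="isometric", sl=sl, record=rec, peak=peak,
                               peaks=out["peaks"], steady_index=steady,
                               final_state=out["final_state"],
                               warnings=warnings)

    return cache.get_or_run(_key(params, "iso", sl, n_beats, rtol, mode), run)


# ----------------------------------------------------------------------
def _force_event(p, threshold_raw, direction, terminal=True):
    def g(t, y):
        return R.total_force(y, p) - threshold_raw
    g.terminal = terminal
    g.direction = direction
    return g


def _ca_event(p, threshold, direction, drive=None, terminal=True):
    if drive is None:
        def g(t, y):
            return y[R.ICA] - threshold
    else:
        dx, dc = drive.to_spline_arrays()
        dx = np.ascontiguousarray(dx)
        dc = np.ascontiguousarray(dc)

        def g(t, y):
            return R.drive_ca(t, p, dx, dc) - threshold
    g.terminal = terminal
    g.direction = direction
    return g


def _workloop_beat(state: ModelState, params: ModelParams,
                   spec: ProtocolSpec, afterload_raw: float,
                   mode: str, drive) -> dict:
    """Simulate one four-phase work-loop cycle; phases located by events."""
    p = params.pack()
    period = params.period
    restretch = spec.restretch_duration
    t_latest_p1 = period - restretch - 0.02
    rtol = spec.rtol
    sl_init = state.sl
    if mode == "clamped_ca":
        dia_ca = float(drive(0.0))
    else:
        dia_ca = state.ca.ca_i

    segs = []
    # Phase 1: isometric until total force exceeds the afterload
    ev1 = _force_event(p, afterload_raw, +1)
    res1 = integrate(state, params, t_latest_p1, mode=mode, drive=drive,
                     mech=Mech.fixed(), events=[ev1], rtol=rtol)
    segs.append((res1.record, 1))
    if not res1.event_times:
        # afterload never reached within the beat: isometric contraction
        res_rest = integrate(res1.final_state, params, period - res1.record.t[-1],
                             mode=mode, drive=drive, mech=Mech.fixed(),
                             rtol=rtol, t0=res1.record.t[-1])
        segs[-1] = (res1.record, 1)
        segs.append((res_rest.record, 0))
        return {"segs": segs, "t_phase2": np.nan, "t_es": np.nan,
                "t_phase4": np.nan, "sl_es": sl_init,
                "final_state": res_rest.final_state, "fired": False}

    t2 = res1.event_times[0]
    # Phase 2: isotonic shortening at the afterload until the muscle can no
    # longer shorten (force capability falls back to the afterload)
    ev2 = _force_event(p, afterload_raw, -1)
    res2 = integrate(res1.final_state, params, t_latest_p1 - t2, mode=mode,
                     drive=drive, mech=Mech.isotonic(afterload_raw),
                     events=[ev2], rtol=rtol, t0=t2)
    segs.append((res2.record, 2))
    t_es = res2.event_times[0] if res2.event_times else res2.record.t[-1]
    sl_es = res2.final_state.sl

    # Phase 3: isometric relaxation until Ca returns to diastolic levels
    thresh = dia_ca * (1.0 + spec.diastolic_ca_tolerance)
    ev3 = _ca_event(p, thresh, -1, drive=drive if mode == "clamped_ca" else None)
    t_latest_p3 = period - restretch - 0.005
    res3 = integrate(res2.final_state, params, t_latest_p3 - t_es, mode=mode,
                     drive=drive, mech=Mech.fixed(), events=[ev3], rtol=rtol,
                     t0=t_es)
    segs.append((res3.record, 3))
    t4 = res3.event_times[0] if res3.event_times else res3.record.t[-1]

    # Phase 4: constant-velocity restretch to the initial length
    v = (sl_init - sl_es) / spec.restretch_duration
    res4 = integrate(res3.final_state, params, spec.restretch_duration,
                     mode=mode, drive=drive, mech=Mech.ramp(v), rtol=rtol,
                     t0=t4)
    segs.append((res4.record, 4))

    # remainder of the cycle: quiescent at the initial length
    t_end4 = res4.record.t[-1]
    res5 = integrate(res4.final_state, params, period - t_end4, mode=mode,
                     drive=drive, mech=Mech.fixed(), rtol=rtol, t0=t_end4)
    segs.append((res5.record, 0))
    return {"segs": segs, "t_phase2": t2, "t_es": t_es, "t_phase4": t4,
            "sl_es": sl_es, "final_state": res5.final_state, "fired": True}


def _assemble_beat(segs) -> BeatRecord:
    recs = []
    for rec, label in segs:
        rec.phase = np.full(rec.t.size, label, dtype=np.int8)
        recs.append(rec)
    return BeatRecord.concatenate(recs)


def run_workloop(spec: ProtocolSpec, params: ModelParams,
                 cache: Optional[SimCache] = None) -> WorkLoopResult:
    """Steady-state four-phase work-loop contraction.

    At a normalized afterload of 1 the afterload equals the peak isometric
    force at L_o, the shortening threshold is never exceeded, and the
    contraction is identical to the L_o-isometric twitch.
    """
    spec.validate(params)
    cache = cache or SimCache()
    ensure_normalization(params, cache, rtol=spec.rtol,
                         n_beats=spec.n_beats_to_steady)
    mode = "clamped_ca" if spec.ca_drive is not None else "free_ca"
    drive = spec.ca_drive

    def run():
        if spec.afterload >= 1.0 - 1e-9:
            iso = run_isometric(spec.sl_init, params,
                                n_beats=spec.n_beats_to_steady,
                                rtol=spec.rtol, cache=cache, mode=mode,
                                drive=drive)
            return WorkLoopResult(
                mode=spec.mode, afterload=spec.afterload,
                sl_init=spec.sl_init, record=iso.record,
                t_phase2=np.nan, t_es=np.nan, t_phase4=np.nan,
                end_systolic=(spec.sl_init, float(np.max(iso.record.f_total))),
                peaks=iso.peaks, steady_index=iso.steady_index,
                final_state=iso.final_state, warnings=list(iso.warnings))

        afterload_raw = spec.afterload * params.force_norm
        state = resting_state(params, sl=spec.sl_init)
        peaks = []
        beat = None
        for b in range(spec.n_beats_to_steady):
            beat = _workloop_beat(state, params, spec, afterload_raw, mode,
                                  drive)
            state = beat["final_state"]
            peak = max(np.max(rec.f_total) for rec, _ in beat["segs"])
            peaks.append(float(peak))
        record = _assemble_beat(beat["segs"])
        steady = detect_steady_state(peaks, 1e-3)
        warnings = []
        degenerate = not beat["fired"]
        if degenerate:
            warnings.append("afterload never reached: degenerate (isometric) loop")
        if steady >= len(peaks):
            warnings.append("beat-to-beat steady state not reached")
        es_force = spec.afterload if beat["fired"] else peaks[-1]
        return WorkLoopResult(
            mode=spec.mode, afterload=spec.afterload, sl_init=spec.sl_init,
            record=record, t_phase2=beat["t_phase2"], t_es=beat["t_es"],
            t_phase4=beat["t_phase4"],
            end_systolic=(beat["sl_es"], es_force),
            peaks=np.asarray(peaks), steady_index=steady, final_state=state,
            degenerate=degenerate, warnings=warnings)

    drive_id = id(drive) if drive is not None else 0
    return cache.get_or_run(
        _key(params, "wl", spec.mode, spec.afterload, spec.sl_init,
             spec.n_beats_to_steady, spec.rtol, mode, drive_id), run)


# ----------------------------------------------------------------------
def run_quick_release(spec: ProtocolSpec, params: ModelParams,
                      cache: Optional[SimCache] = None) -> QuickReleaseResult:
    """Quick-release protocol: rapid length step from L_o to
    ``release_length_fraction * L_o`` at each requested time after the
    stimulus, compared against the L_o-isometric reference twitch."""
    cache = cache or SimCache()
    ensure_normalization(params, cache, rtol=spec.rtol,
                         n_beats=spec.n_beats_to_steady)
    period = params.period
    ramp = spec.release_ramp_duration
    for tr in spec.release_times:
        if not (0.0 <= tr and tr + ramp < period):
            raise ValueError(f"release time {tr} outside the twitch window")

    # pace to steady state at L_o, keep the pre-beat state
    iso = run_isometric(params.l_o, params, n_beats=spec.n_beats_to_steady,
                        rtol=spec.rtol, cache=cache)
    state0 = iso.final_state
    reference = integrate(state0, params, period, mech=Mech.fixed(),
                          rtol=spec.rtol).record

    sl_target = spec.release_length_fraction * params.l_o
    releases = []
    for tr in spec.release_times:
        res_a = integrate(state0, params, tr, mech=Mech.fixed(),
                          rtol=spec.rtol)
        v = (sl_target - params.l_o) / ramp
        res_b = integrate(res_a.final_state, params, ramp,
                          mech=Mech.ramp(v), rtol=spec.rtol, t0=tr,
                          dt_out=ramp / 10.0)
        res_c = integrate(res_b.final_state, params, period - tr - ramp,
                          mech=Mech.fixed(), rtol=spec.rtol, t0=tr + ramp)
        rec = BeatRecord.concatenate(
            [res_a.record, res_b.record, res_c.record])
        rec.meta["release_time"] = tr
        releases.append(rec)
    return QuickReleaseResult(mode="quick_release",
                              release_times=list(spec.release_times),
                              releases=releases, reference=reference)


# ----------------------------------------------------------------------
def run_crossover(afterload: float, params: ModelParams,
                  cache: Optional[SimCache] = None,
                  spec: Optional[ProtocolSpec] = None) -> WorkLoopResult:
    """Fixed-Ca cross-over experiment.

    The work-loop at ``afterload`` is driven in clamped-Ca mode by the Ca2+
    transient recorded from the force-equivalent isometric contraction (the
    isometric twitch whose steady-state peak force equals the afterload).
    """
    from .analysis import force_equivalent_length

    cache = cache or SimCache()
    spec = spec or ProtocolSpec(mode="crossover", afterload=afterload)
    spec.afterload = afterload
    spec.mode = "crossover"
    ensure_normalization(params, cache, rtol=spec.rtol,
                         n_beats=spec.n_beats_to_steady)

    sl_eq = force_equivalent_length(afterload, params,
                                    bracket=(1.86, params.l_o), cache=cache,
                                    rtol=spec.rtol,
                                    n_beats=spec.n_beats_to_steady)
    iso = run_isometric(sl_eq, params, n_beats=spec.n_beats_to_steady,
                        rtol=spec.rtol, cache=cache)
    drive = ca_waveforms.record(iso.record, period=params.period)
    wl_spec = ProtocolSpec(mode="crossover", sl_init=spec.sl_init,
                           afterload=afterload, ca_drive=drive,
                           n_beats_to_steady=spec.n_beats_to_steady,
                           restretch_duration=spec.restretch_duration,
                           diastolic_ca_tolerance=spec.diastolic_ca_tolerance,
                           rtol=spec.rtol)
    out = run_workloop(wl_spec, params, cache=cache)
    out.mode = "crossover"
    return out
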