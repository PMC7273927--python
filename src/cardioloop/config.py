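"""Run configuration, validation and experiment orchestration.

A :class:`RunConfig` is validated (pydantic schema) before any simulation
starts.  :func:`run_experiment` executes either one of the named experiment
batteries (``fig2`` quick release, ``fig3`` dual ESFLR, ``fig4`` Ca
transients, ``fig5`` force-equivalent pair, ``fig6`` cross-over ESFLR) or an
explicit list of protocol specs, writes CSV/JSON artifacts and returns a run
manifest.  Reruns with the same configuration produce byte-identical CSVs.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path
from typing import List, Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator

from . import __version__ as _version
from .analysis import (ca_difference, ca_transient_metrics, esflr,
                       force_equivalent_length, twitch_timing)
from .ca_waveforms import record as record_waveform
from .params import ModelParams
from .protocols import (ProtocolSpec, SimCache, ensure_normalization,
                        run_crossover, run_isometric, run_quick_release,
                        run_workloop)

__all__ = ["RunConfig", "ProtocolConfig", "run_experiment",
           "ISOMETRIC_LENGTHS", "WORKLOOP_AFTERLOADS"]

# the study grids: six isometric lengths spanning 1.95-2.3 um and five
# work-loop afterloads spanning 0.2-1 (normalized to peak L_o force)
ISOMETRIC_LENGTHS = (1.95, 2.02, 2.09, 2.16, 2.23, 2.3)
WORKLOOP_AFTERLOADS = (0.2, 0.4, 0.6, 0.8, 1.0)


class ProtocolConfig(BaseModel):
    """Schema for one protocol entry in a run configuration."""
    mode: Literal["isometric", "workloop", "quick_release", "crossover"]
    sl: float = 2.3
    afterload: float = 1.0
    release_times: List[float] = [0.03, 0.06, 0.1, 0.15]
    release_length_fraction: float = 0.92

    @field_validator("afterload")
    @classmethod
    def _afterload_range(cls, v):
        if not (0.0 < v <= 1.0):
            raise ValueError("afterload must be in (0, 1]")
        return v

    def to_spec(self, n_beats: int, rtol: float) -> ProtocolSpec:
        return ProtocolSpec(mode=self.mode, sl_init=self.sl,
                            afterload=self.afterload,
                            release_times=tuple(self.release_times),
                            release_length_fraction=self.release_length_fraction,
                            n_beats_to_steady=n_beats, rtol=rtol)


class RunConfig(BaseModel):
    """Validated description of a full run."""
    experiment: Optional[Literal["fig2", "fig3", "fig4", "fig5", "fig6"]] = None
    protocols: List[ProtocolConfig] = Field(default_factory=list)
    params_file: Optional[str] = None
    out_dir: str = "results"
    rtol: float = 1e-6
    n_beats: int = 20
    make_plots: bool = False


def _log(msg: str) -> None:
    print(msg, file=sys.stderr, flush=True)


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _beat_csv(path: Path, rec) -> None:
    rec.to_csv(path)


def run_experiment(config: RunConfig, params: Optional[ModelParams] = None,
                   cache: Optional[SimCache] = None) -> dict:
    """Execute the configured experiment; return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if params is None:
        params = ModelParams.from_file(config.params_file)
    cache = cache or SimCache()
    artifacts: list = []
    events: dict = {}

    def iso_all():
        res = []
        for sl in ISOMETRIC_LENGTHS:
            _log(f"isometric sl={sl}")
            res.append(run_isometric(sl, params, n_beats=config.n_beats,
                                     rtol=config.rtol, cache=cache))
        return res

    def wl_all():
        res = []
        for a in WORKLOOP_AFTERLOADS:
            _log(f"workloop afterload={a}")
            spec = ProtocolSpec(mode="workloop", afterload=a,
                                n_beats_to_steady=config.n_beats,
                                rtol=config.rtol)
            w = run_workloop(spec, params, cache=cache)
            if np.isfinite(w.t_phase2):
                events[f"workloop_{a}"] = {
                    "t_phase2": w.t_phase2, "t_es": w.t_es,
                    "t_phase4": w.t_phase4}
            res.append(w)
        return res

    if config.experiment == "fig3":
        iso = iso_all()
        wl = wl_all()
        for tab, name in ((esflr(iso), "esflr_isometric.csv"),
                          (esflr(wl), "esflr_workloop.csv")):
            tab.to_csv(out / name)
            artifacts.append(name)
    elif config.experiment == "fig4":
        iso = iso_all()
        wl = wl_all()
        metrics = {}
        for r in iso:
            name = f"ca_isometric_sl{r.sl:.2f}.csv"
            _beat_csv(out / name, r.record)
            artifacts.append(name)
            m = ca_transient_metrics(r.record)
            metrics[name] = vars(m)
        for w in wl:
            name = f"ca_workloop_a{w.afterload:.2f}.csv"
            _beat_csv(out / name, w.record)
            artifacts.append(name)
            metrics[name] = vars(ca_transient_metrics(w.record))
        _write_json(out / "ca_metrics.json", metrics)
        artifacts.append("ca_metrics.json")
    elif config.experiment == "fig5":
        afterload = 0.45
        sl_eq = force_equivalent_length(afterload, params, cache=cache,
                                        rtol=config.rtol,
                                        n_beats=config.n_beats)
        iso_lo = run_isometric(params.l_o, params, n_beats=config.n_beats,
                               rtol=config.rtol, cache=cache)
        iso_eq = run_isometric(sl_eq, params, n_beats=config.n_beats,
                               rtol=config.rtol, cache=cache)
        wl = run_workloop(ProtocolSpec(mode="workloop", afterload=afterload,
                                       n_beats_to_steady=config.n_beats,
                                       rtol=config.rtol), params, cache=cache)
        for rec, name in ((iso_lo.record, "beat_isometric_lo.csv"),
                          (iso_eq.record, "beat_isometric_equivalent.csv"),
                          (wl.record, "beat_workloop.csv")):
            _beat_csv(out / name, rec)
            artifacts.append(name)
        timing = {
            "sl_equivalent_um": sl_eq,
            "afterload": afterload,
            "t1_force_onset": vars(twitch_timing(iso_lo.record)),
            "t2_phase2_onset": wl.t_phase2,
        }
        _write_json(out / "timing.json", timing)
        artifacts.append("timing.json")
    elif config.experiment == "fig2":
        spec = ProtocolSpec(mode="quick_release",
                            n_beats_to_steady=config.n_beats,
                            rtol=config.rtol)
        qr = run_quick_release(spec, params, cache=cache)
        _beat_csv(out / "beat_isometric_reference.csv", qr.reference)
        artifacts.append("beat_isometric_reference.csv")
        for tr, rec in zip(qr.release_times, qr.releases):
            name = f"beat_release_{int(round(1e3 * tr))}ms.csv"
            _beat_csv(out / name, rec)
            artifacts.append(name)
            d = ca_difference(rec, qr.reference)
            dname = name.replace("beat_", "delta_ca_")
            with open(out / dname, "w") as fh:
                fh.write("t_s,delta_ca_uM\n")
                for t, v in zip(d.t, d.delta):
                    fh.write(f"{t:.10g},{v:.10g}\n")
            artifacts.append(dname)
    elif config.experiment == "fig6":
        iso = iso_all()
        wl = wl_all()
        co = []
        for a in WORKLOOP_AFTERLOADS:
            _log(f"crossover afterload={a}")
            co.append(run_crossover(a, params, cache=cache,
                                    spec=ProtocolSpec(
                                        mode="crossover", afterload=a,
                                        n_beats_to_steady=config.n_beats,
                                        rtol=config.rtol)))
        for tab, name in ((esflr(iso), "esflr_isometric.csv"),
                          (esflr(wl), "esflr_workloop.csv"),
                          (esflr(co), "esflr_crossover.csv")):
            tab.to_csv(out / name)
            artifacts.append(name)
    elif config.protocols:
        for i, pc in enumerate(config.protocols):
            spec = pc.to_spec(config.n_beats, config.rtol)
            _log(f"protocol {i}: {pc.mode}")
            if pc.mode == "isometric":
                r = run_isometric(pc.sl, params, n_beats=config.n_beats,
                                  rtol=config.rtol, cache=cache)
                rec = r.record
            elif pc.mode == "workloop":
                r = run_workloop(spec, params, cache=cache)
                rec = r.record
            elif pc.mode == "crossover":
                r = run_crossover(pc.afterload, params, cache=cache,
                                  spec=spec)
                rec = r.record
            else:
                r = run_quick_release(spec, params, cache=cache)
                rec = r.releases[0]
            name = f"protocol_{i}_{pc.mode}.csv"
            _beat_csv(out / name, rec)
            artifacts.append(name)

    if config.make_plots and artifacts:
        _plot(out, config, artifacts)

    manifest = {
        "config": json.loads(config.model_dump_json()),
        "param_hash": params.param_hash(),
        "force_norm": params.force_norm,
        "version": _version,
        "events": events,
        "artifacts": sorted(artifacts),
    }
    _write_json(out / "manifest.json", manifest)
    return manifest


def _plot(out: Path, config: RunConfig, artifacts: Sequence[str]) -> None:
    """Quick-look figure for ESFLR experiments (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    esflrs = [a for a in artifacts if a.startswith("esflr_")]
    if not esflrs:
        return
    fig, ax = plt.subplots(figsize=(4, 3.2))
    for name in esflrs:
        df = pd.read_csv(out / name)
        ax.plot(df.sl_norm, df.force_norm, "o-",
                label=name.replace("esflr_", "").replace(".csv", ""))
    ax.set_xlabel("SL / $L_o$")
    ax.set_ylabel("normalized force")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "esflr.png", dpi=150)
    plt.close(fig)
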