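"""Scenario presets, configuration handling and output bundles.

A scenario is fully described by a small mapping (serializable to YAML);
``run_scenario`` executes it and writes a reproducible bundle: the config
snapshot, trace CSVs, an HDF5 container with the full-resolution arrays,
derived reports (flux decomposition, beat metrics, border-zone metrics) and
a run log.  Presets mirror the study design: a 0D control cell, heart-rate
variants, the alternans-suppression and volume-shrinkage interventions, the
1D regional-ischemia control and the conductivity/K+-diffusion sensitivity
grid, plus "fast" profiles for smoke testing.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import time
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import __version__, analysis, params as par
from .cable import CableRun, Scenario1D, run_cable
from .cell import CellRun, Scenario0D, run_single_cell
from .protocol import RegionalLayout

_SC0_KEYS = {f.name for f in dataclasses.fields(Scenario0D)}
_SC1_KEYS = {f.name for f in dataclasses.fields(Scenario1D)} - {"tissue", "layout"}

PRESETS: dict[str, dict] = {
    # --- single cell -----------------------------------------------------
    "0d-control": {"dim": "0d", "normoxia_min": 5.0, "ischemia_min": 30.0},
    "0d-quiescent": {"dim": "0d", "bpm": 0.0, "normoxia_min": 5.0,
                     "ischemia_min": 30.0},
    "0d-30bpm": {"dim": "0d", "bpm": 30.0},
    "0d-120bpm": {"dim": "0d", "bpm": 120.0},
    "0d-180bpm": {"dim": "0d", "bpm": 180.0},
    "0d-alternans-suppressed": {"dim": "0d", "ical_gain": 2.0,
                                "ical_on_min": 3.5, "ical_off_min": 12.0},
    "0d-volume-shrinkage": {"dim": "0d", "shrink_total": 0.09},
    "0d-adp-variant": {"dim": "0d", "adp_variant": "alt"},
    "0d-fast": {"dim": "0d", "normoxia_min": 0.5, "ischemia_min": 3.0},
    # --- tissue ----------------------------------------------------------
    "1d-control": {"dim": "1d", "normoxia_min": 1.0, "ischemia_min": 30.0},
    "1d-dv-x0.8": {"dim": "1d", "dv_factor": 0.8},
    "1d-dv-x0.4": {"dim": "1d", "dv_factor": 0.4},
    "1d-dv-x0.19": {"dim": "1d", "dv_factor": 0.19},
    "1d-dk-x0": {"dim": "1d", "dk_factor": 0.0},
    "1d-dk-x10": {"dim": "1d", "dk_factor": 10.0},
    "1d-dk-x100": {"dim": "1d", "dk_factor": 100.0},
    "1d-tz-0": {"dim": "1d", "tz_cm": 0.0},
    "1d-tz-1.0": {"dim": "1d", "tz_cm": 1.0},
    "1d-adp-variant": {"dim": "1d", "adp_variant": "alt"},
    "1d-fast": {"dim": "1d", "normoxia_min": 0.25, "ischemia_min": 2.0,
                "dx_cm": 0.05},
}


def list_presets() -> list[str]:
    return sorted(PRESETS)


def _build(config: dict):
    cfg = dict(config)
    dim = cfg.pop("dim", "0d")
    if dim == "0d":
        unknown = set(cfg) - _SC0_KEYS
        if unknown:
            raise ValueError(f"unknown 0D scenario keys: {sorted(unknown)}")
        return Scenario0D(**cfg)
    if dim == "1d":
        tz = cfg.pop("tz_cm", 0.5)
        dx = cfg.pop("dx_cm", 0.025)
        unknown = set(cfg) - _SC1_KEYS
        if unknown:
            raise ValueError(f"unknown 1D scenario keys: {sorted(unknown)}")
        tissue = par.TissueParams(dx_cm=dx)
        layout = RegionalLayout(tz_cm=tz)
        return Scenario1D(tissue=tissue, layout=layout, **cfg)
    raise ValueError(f"dim must be '0d' or '1d', got {dim!r}")


def load_config(source: str | Path | dict) -> dict:
    if isinstance(source, dict):
        return dict(source)
    path = Path(source)
    if path.exists():
        with open(path) as fh:
            return yaml.safe_load(fh)
    if str(source) in PRESETS:
        return dict(PRESETS[str(source)])
    raise ValueError(f"{source!r} is neither a preset name nor a config file")


def run_scenario(source: str | Path | dict, out_dir: str | Path | None = None,
                 cp: par.CellParams | None = None):
    """Run a preset or config and (optionally) write an output bundle.

    Returns (run, bundle_path_or_None); the run is a CellRun or CableRun.
    """
    config = load_config(source)
    sc = _build(config)     # validate before any compute
    t0 = time.time()
    if isinstance(sc, Scenario0D):
        run = run_single_cell(sc, cp)
    else:
        run = run_cable(sc, cp)
    elapsed = time.time() - t0
    bundle = None
    if out_dir is not None:
        bundle = Path(out_dir)
        bundle.mkdir(parents=True, exist_ok=True)
        _write_bundle(run, config, bundle, elapsed)
    return run, bundle


def _write_bundle(run, config: dict, out: Path, elapsed_s: float) -> None:
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    log = {"package": "cardiak", "version": __version__,
           "python": platform.python_version(),
           "elapsed_s": round(elapsed_s, 2),
           "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}
    if isinstance(run, CellRun):
        run.to_frame(every_ms=10).to_csv(out / "traces.csv", index=False)
        run.macro_ko().to_csv(out / "macro_ko.csv", index=False)
        analysis.beat_metrics(run).frame().to_csv(out / "beats.csv", index=False)
        if run.scenario.bpm > 0:
            bcl = run.scenario.bcl_ms
            span = run.t_ms[-1]
            marks = tuple(m for m in (0.0, 2.5, 5.0, 10.0, 20.0)
                          if run.t_occ_ms + m * 60000.0 + 2.0 * bcl <= span
                          and run.t_occ_ms + m * 60000.0 >= 2.0 * bcl)
            reports = analysis.decompose_fluxes(run, sample_min=marks)
            with open(out / "flux_reports.json", "w") as fh:
                json.dump([dataclasses.asdict(r) for r in reports], fh, indent=1)
        with h5py.File(out / "fields.h5", "w") as h5:
            h5.create_dataset("rec", data=run.rec, compression="gzip")
            h5.attrs["channels"] = ("t vm ko nai cai cum:"
                                    + " ".join(analysis.KFLUX_CURRENTS))
    else:
        with h5py.File(out / "fields.h5", "w") as h5:
            h5.create_dataset("snap_t_ms", data=run.snap_t_ms)
            h5.create_dataset("vm", data=run.snap_v, compression="gzip")
            h5.create_dataset("ko", data=run.snap_ko, compression="gzip")
            h5.create_dataset("x_cm", data=run.x_cm)
            h5.create_dataset("probe_rec", data=run.rec_probe[::10],
                              compression="gzip")
            h5.create_dataset("act_times", data=run.act_times)
        idx = np.arange(0, run.rec_probe.shape[0], 10)
        cols = {"t_ms": run.t_ms[idx]}
        for q, xi in enumerate(run.x_cm[run.probes_idx]):
            cols[f"vm_x{xi:.2f}"] = run.rec_probe[idx, q, 0]
            cols[f"ko_x{xi:.2f}"] = run.rec_probe[idx, q, 1]
            cols[f"vo_x{xi:.2f}"] = run.rec_probe[idx, q, 2]
        import pandas as pd
        pd.DataFrame(cols).to_csv(out / "probes.csv", index=False)
        rep = analysis.bz_metrics(run.x_cm, run.snap_ko[-1],
                                  border_cm=run.scenario.layout.border_cm)
        with open(out / "bz_report.json", "w") as fh:
            json.dump(dataclasses.asdict(rep), fh, indent=1)
    with open(out / "log.json", "w") as fh:
        json.dump(log, fh, indent=1)
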