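"""Declarative run configuration, task dispatch and fixture generation.

A run is described by one YAML file with sections ``populations``,
``couplings``, ``stimulus``, ``integration``, ``task`` and a top-level
``seed``.  ``run_task`` validates the config, executes the named task
(simulate | reduce | bifurcate | scan | calibrate) and writes its
artifacts plus a metadata sidecar carrying the fully-resolved config and
seeds, so any output directory is reproducible bitwise from the sidecar
alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .bifurcation import BifurcationDiagram, classify_region
from .model import (
    LorentzSpec,
    NetworkSpec,
    PopulationSpec,
    SpecificationError,
    StimulusSpec,
    integrate_full,
    sample_initial_phases,
    sample_natural_frequencies,
)
from .reduced import ReducedParams, integrate_reduced
from .scan import (
    HEALTHY_TARGET,
    PATIENT_TARGET,
    CalibrationTarget,
    calibrate,
    scan,
)
from .sli import default_threshold, sli, sli_timeseries

__all__ = [
    "load_config",
    "network_from_config",
    "run_task",
    "generate_fixture",
    "trajectory_to_frame",
    "reduced_trajectory_to_frame",
]

_TASKS = ("simulate", "reduce", "bifurcate", "scan", "calibrate")


class UsageError(SpecificationError):
    """Invalid configuration; the message names the offending field."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise UsageError(f"config {path} is not a mapping")
    return cfg


def _require(cfg: dict, key: str, where: str = "config") -> Any:
    if key not in cfg:
        raise UsageError(f"missing required field {where}.{key}")
    return cfg[key]


def network_from_config(cfg: dict) -> NetworkSpec:
    pops = _require(cfg, "populations")
    seed = int(cfg.get("seed", 0))
    thal_cfg = _require(pops, "thalamus", "populations")

    def pop(name: str, c: dict, k: int) -> PopulationSpec:
        return PopulationSpec(
            name=name,
            n_oscillators=int(c.get("n", 1000)),
            frequency_law=LorentzSpec(
                center_hz=float(_require(c, "center_hz", f"populations.{name}")),
                half_width_hz=float(c.get("half_width_hz", 0.5)),
            ),
            seed=int(c.get("seed", seed + k)),
        )

    thal = pop("thalamus", thal_cfg, 0)
    cortical_cfg = _require(pops, "cortical", "populations")
    cortical = tuple(
        pop(c.get("name", f"cortex{i}"), c, i + 1) for i, c in enumerate(cortical_cfg)
    )
    coup = _require(cfg, "couplings")
    stim_cfg = _require(cfg, "stimulus")
    stim = StimulusSpec(
        intensity=float(stim_cfg.get("intensity", 100.0)),
        onset_ms=float(stim_cfg.get("onset_ms", 0.0)),
        duration_ms=float(stim_cfg.get("duration_ms", 50.0)),
    )
    return NetworkSpec(
        thalamus=thal,
        cortical=cortical,
        k_thal_to_cortex=tuple(
            float(k) for k in _require(coup, "thal_to_cortex", "couplings")
        ),
        k_cortex_to_thal=tuple(
            float(k) for k in _require(coup, "cortex_to_thal", "couplings")
        ),
        stimulus=stim,
    )


def trajectory_to_frame(traj) -> pd.DataFrame:
    """Tidy mean-field table: time_ms, population, R, Theta."""
    rows = []
    for name, y in traj.iter_populations():
        rows.append(
            pd.DataFrame(
                {
                    "time_ms": traj.times_ms,
                    "population": name,
                    "R": np.abs(y),
                    "Theta": np.angle(y),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def reduced_trajectory_to_frame(tr) -> pd.DataFrame:
    rows = []
    for i, name in enumerate(tr.params.names):
        y = tr.order_parameters[..., i]
        rows.append(
            pd.DataFrame(
                {
                    "time_ms": tr.times_ms,
                    "population": name,
                    "re_Y": y.real,
                    "im_Y": y.imag,
                    "R": np.abs(y),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _axis_from_name(name: str, net: NetworkSpec):
    band_names = [p.name for p in net.cortical]
    direction, _, band = name.partition("_")
    if band not in band_names:
        raise UsageError(f"task.scan axis names unknown band {band!r}")
    attr = {"KC": "k_cortex_to_thal", "KT": "k_thal_to_cortex"}.get(direction)
    if attr is None:
        raise UsageError(f"axis {name!r} must start with KC_ or KT_")
    return (attr, band_names.index(band))


def _target_from_config(tcfg: dict | str) -> CalibrationTarget:
    if tcfg == "healthy":
        return HEALTHY_TARGET
    if tcfg == "patient":
        return PATIENT_TARGET
    if not isinstance(tcfg, dict):
        raise UsageError("task.target must be 'healthy', 'patient' or a mapping")
    return CalibrationTarget(
        sli_targets={k: float(v) for k, v in _require(tcfg, "sli", "task.target").items()},
        freq_intervals_hz={
            k: (float(v[0]), float(v[1]))
            for k, v in tcfg.get("frequency_bands_hz", {}).items()
        },
        sli_tolerance=float(tcfg.get("tolerance", 0.02)),
        label=str(tcfg.get("label", "")),
    )


def run_task(cfg: dict, outdir: str | Path) -> dict:
    """Execute the configured task; write artifacts + metadata sidecar.

    Returns a small summary dict (also written as ``summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    task_cfg = dict(_require(cfg, "task"))
    kind = _require(task_cfg, "kind", "task")
    if kind not in _TASKS:
        raise UsageError(f"task.kind must be one of {_TASKS}, got {kind!r}")
    net = network_from_config(cfg)
    integ = cfg.get("integration", {})
    dt = float(integ.get("dt_ms", 0.1))
    t_end = float(integ.get("t_end_ms", 1100.0))
    store_every = int(integ.get("store_every", 10))
    seed = int(cfg.get("seed", 0))
    summary: dict[str, Any] = {"task": kind}

    if kind == "simulate":
        traj = integrate_full(
            net, (net.stimulus.onset_ms, t_end), dt_ms=dt, seed=seed,
            freq_mode=task_cfg.get("freq_mode", "random"), store_every=store_every,
        )
        trajectory_to_frame(traj).to_csv(outdir / "trajectory.csv", index=False)
        series = sli_timeseries(traj)
        offset = net.stimulus.onset_ms + net.stimulus.duration_ms
        summary["max_sli"] = {
            p.name: float(np.max(series.sli[p.name][traj.times_ms >= offset]))
            for p in net.cortical
        }
    elif kind == "reduce":
        p = ReducedParams.from_network(net)
        y0 = np.zeros(p.n_populations, dtype=complex)
        tr = integrate_reduced(p, y0, (net.stimulus.onset_ms, t_end), dt, store_every)
        reduced_trajectory_to_frame(tr).to_csv(outdir / "reduced_trajectory.csv", index=False)
        summary["final_R"] = {
            name: float(np.abs(tr.order_parameters[-1, i]))
            for i, name in enumerate(p.names)
        }
    elif kind == "bifurcate":
        p = ReducedParams.from_network(net)
        bcfg = task_cfg.get("bifurcation", {})
        grid = np.arange(
            float(bcfg.get("k_min", 0.5)),
            float(bcfg.get("k_max", 20.0)) + 1e-9,
            float(bcfg.get("k_step", 0.5)),
        )
        diagram = BifurcationDiagram.compute(
            p, which=bcfg.get("parameter", "k_thal_to_cortex"),
            band=int(bcfg.get("band", 0)), k_grid=grid, dt_ms=dt,
        )
        pd.DataFrame(
            list(diagram.fixed_points), columns=["k", "x", "stable"]
        ).to_csv(outdir / "fixed_points.csv", index=False)
        pd.DataFrame(
            list(diagram.orbits), columns=["k", "x_min", "x_max", "stable"]
        ).to_csv(outdir / "orbits.csv", index=False)
        summary["hopf_k"] = diagram.hopf_k
        summary["flb_k"] = diagram.flb_k
        summary["region_at_template"] = classify_region(p)
        (outdir / "located_points.json").write_text(
            json.dumps({"hopf_k": diagram.hopf_k, "flb_k": diagram.flb_k}, indent=2)
        )
    elif kind in ("scan", "calibrate"):
        scfg = task_cfg.get("scan", {})
        ax1 = _axis_from_name(scfg.get("axis1", "KC_" + net.cortical[0].name), net)
        ax2_default = (
            "KC_" + net.cortical[1].name if len(net.cortical) > 1
            else "KT_" + net.cortical[0].name
        )
        ax2 = _axis_from_name(scfg.get("axis2", ax2_default), net)
        rng1 = scfg.get("range1", [0.0, 10.0, 0.5])
        rng2 = scfg.get("range2", [0.0, 10.0, 0.5])
        v1 = np.arange(rng1[0], rng1[1] + 1e-9, rng1[2])
        v2 = np.arange(rng2[0], rng2[1] + 1e-9, rng2[2])
        grid = scan(
            net, ax1, v1, ax2, v2,
            engine=scfg.get("engine", "reduced"),
            t_end_ms=t_end, dt_ms=dt, seed=seed,
        )
        grid.table.to_csv(outdir / "scan.csv", index=False)
        summary["cells"] = int(len(v1) * len(v2))
        summary["axes"] = list(grid.axis_names)
        if kind == "calibrate":
            target = _target_from_config(task_cfg.get("target", "patient"))
            pts = calibrate(grid, target, top_k=int(task_cfg.get("top_k", 5)))
            payload = [asdict(pt) for pt in pts]
            (outdir / "calibration.json").write_text(json.dumps(payload, indent=2, default=float))
            summary["n_admissible"] = len(pts)
            if pts:
                summary["best"] = payload[0]

    meta = {
        "version": _version,
        "resolved_config": _resolved(cfg, net, dt, t_end, store_every, seed),
        "summary_keys": sorted(summary),
    }
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2, default=float))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary


def _resolved(cfg, net, dt, t_end, store_every, seed):
    return {
        "seed": seed,
        "integration": {"dt_ms": dt, "t_end_ms": t_end, "store_every": store_every},
        "network": {
            "populations": [
                {
                    "name": p.name,
                    "n": p.n_oscillators,
                    "center_hz": p.frequency_law.center_hz,
                    "half_width_hz": p.frequency_law.half_width_hz,
                    "seed": p.seed,
                }
                for p in net.populations
            ],
            "k_thal_to_cortex": list(net.k_thal_to_cortex),
            "k_cortex_to_thal": list(net.k_cortex_to_thal),
            "stimulus": asdict(net.stimulus),
        },
        "task": cfg.get("task"),
    }


def generate_fixture(kind: str, params: dict, seed: int, path: str | Path) -> Path:
    """Write a small seeded fixture file for tests and examples.

    Kinds: ``uniform-phases`` (CSV of phases, SLI ≈ noise floor),
    ``synced-phases`` (all equal, SLI = 1), ``quantile-freqs``
    (deterministic Lorentzian quantiles in Hz and rad/ms).
    """
    path = Path(path)
    n = int(params.get("n", 1000))
    if kind == "uniform-phases":
        ph = sample_initial_phases(n, seed)
        pd.DataFrame({"phase_rad": ph}).to_csv(path, index=False)
    elif kind == "synced-phases":
        value = float(params.get("phase", 0.0))
        pd.DataFrame({"phase_rad": np.full(n, value)}).to_csv(path, index=False)
    elif kind == "quantile-freqs":
        spec = PopulationSpec(
            "fixture", n,
            LorentzSpec(float(params.get("center_hz", 6.0)),
                        float(params.get("half_width_hz", 0.5))),
            seed=seed,
        )
        w = sample_natural_frequencies(spec, mode="quantile")
        pd.DataFrame(
            {"omega_rad_per_ms": w, "f_hz": w / (2 * np.pi) * 1000.0}
        ).to_csv(path, index=False)
    else:
        raise UsageError(f"unknown fixture kind {kind!r}")
    sidecar = {"kind": kind, "params": params, "seed": seed}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return path
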