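"""Coupling-plane scans and the healthy/patient calibration procedure.

A scan runs the click protocol (by default I = 100 for 50 ms from the
incoherent state) at every cell of a two-coupling grid and records, per
cortical band, the maximum post-stimulus SLI, the synchronisation
duration and the peak frequency of the mean field.  The reduced engine
integrates the Ott-Antonsen system for all cells at once (vectorised over
the grid) and is the default; the full engine runs the N-oscillator model
per cell and is intended for coarse grids or for re-verifying cells the
reduced scan flags as matching a calibration target.

Calibration then selects the grid cells whose per-band maximum SLI and
peak frequency match a stated target — e.g. the θ/α locking levels of
healthy controls (0.37 / 0.26) or of schizophrenia patients (0.30 / 0.19)
with frequencies confined to the 5–7 Hz and 9–12 Hz bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .model import (
    ANGULAR_PER_HZ_MS,
    NetworkSpec,
    SpecificationError,
    integrate_full,
    stimulus_value,
)
from .sli import (
    default_threshold,
    locked_median_frequency,
    max_sli,
    median_oscillator_frequency,
    peak_frequency,
    sli_timeseries,
    sync_duration,
)
from .reduced import ReducedParams

__all__ = [
    "AxisSpec",
    "ScanGrid",
    "CalibrationTarget",
    "CalibrationPoint",
    "scan",
    "calibrate",
    "run_protocol",
    "HEALTHY_TARGET",
    "PATIENT_TARGET",
]

#: coupling axis: (attribute, band index), e.g. ("k_cortex_to_thal", 0)
AxisSpec = tuple[str, int]


def _set_coupling(net: NetworkSpec, axis: AxisSpec, value: float) -> NetworkSpec:
    attr, band = axis
    ks = list(getattr(net, attr))
    ks[band] = float(value)
    return replace(net, **{attr: tuple(ks)})


def _axis_label(net: NetworkSpec, axis: AxisSpec) -> str:
    attr, band = axis
    direction = "KC" if attr == "k_cortex_to_thal" else "KT"
    return f"{direction}_{net.cortical[band].name}"


@dataclass
class ScanGrid:
    """Long-format scan result: one row per (cell, cortical band)."""

    axis_names: tuple[str, str]
    axes: tuple[AxisSpec, AxisSpec]
    values1: np.ndarray
    values2: np.ndarray
    table: pd.DataFrame
    engine: str
    template: NetworkSpec
    threshold: float

    def cell(self, v1: float, v2: float) -> pd.DataFrame:
        t = self.table
        return t[(np.isclose(t["axis1"], v1)) & (np.isclose(t["axis2"], v2))]


@dataclass(frozen=True)
class CalibrationTarget:
    """Per-band SLI levels and admissible frequency windows."""

    sli_targets: dict[str, float]
    freq_intervals_hz: dict[str, tuple[float, float]]
    sli_tolerance: float = 0.02
    label: str = ""

    def __post_init__(self) -> None:
        if self.sli_tolerance <= 0:
            raise SpecificationError("sli_tolerance must be > 0")
        for band, (lo, hi) in self.freq_intervals_hz.items():
            if not lo < hi:
                raise SpecificationError(f"empty frequency interval for {band!r}")


HEALTHY_TARGET = CalibrationTarget(
    sli_targets={"theta": 0.37, "alpha": 0.26},
    freq_intervals_hz={"theta": (5.0, 7.0), "alpha": (9.0, 12.0)},
    label="C",
)
PATIENT_TARGET = CalibrationTarget(
    sli_targets={"theta": 0.30, "alpha": 0.19},
    freq_intervals_hz={"theta": (5.0, 7.0), "alpha": (9.0, 12.0)},
    label="P",
)


@dataclass
class CalibrationPoint:
    """A grid cell meeting a calibration target."""

    label: str
    couplings: dict[str, float]
    achieved_sli: dict[str, float]
    achieved_freq_hz: dict[str, float]
    sli_mismatch: float
    axis_values: tuple[float, float] = (np.nan, np.nan)


# --------------------------------------------------------------------------
# protocol runners


def run_protocol(
    net: NetworkSpec,
    t_end_ms: float = 1100.0,
    dt_ms: float = 0.1,
    seed: int = 0,
    freq_mode: str = "random",
    threshold: float | None = None,
    freq_window_ms: float = 500.0,
):
    """Run the click protocol on the full model and summarise each band.

    Returns ``(trajectory, summary)`` where summary maps band name to a
    dict with max_sli, sync_duration_ms, peak_frequency_hz (mean-field
    DFT peak over the stimulus offset → offset + ``freq_window_ms``
    window) and osc_frequency_hz (median oscillator frequency over the
    locked interval).
    """
    stim = net.stimulus
    offset = stim.onset_ms + stim.duration_ms
    traj = integrate_full(
        net, (stim.onset_ms, t_end_ms), dt_ms=dt_ms, seed=seed,
        freq_mode=freq_mode, store_every=10, store_phases=True,
    )
    if threshold is None:
        threshold = default_threshold(net.cortical[0].n_oscillators)
    series = sli_timeseries(traj)
    out = {}
    for b, pop in enumerate(net.cortical):
        name = pop.name
        dur = sync_duration(series, name, threshold, offset_ms=offset)
        lock_end = offset + max(min(dur, freq_window_ms), 300.0)
        out[name] = {
            "max_sli": max_sli(series, name, (offset, t_end_ms)),
            "sync_duration_ms": dur,
            "peak_frequency_hz": peak_frequency(
                traj, name, (offset, min(offset + freq_window_ms, t_end_ms))
            ),
            "osc_frequency_hz": median_oscillator_frequency(
                traj, name, (offset, min(lock_end, t_end_ms))
            ),
        }
    return traj, out


def _reduced_batch(
    p: ReducedParams,
    kt: np.ndarray,  # (B, nb)
    kc: np.ndarray,  # (B, nb)
    t_end_ms: float,
    dt_ms: float,
    store_every: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the reduced click protocol for a batch of coupling pairs.

    All cells start from the incoherent state Y = 0 at the stimulus onset.
    Returns (times, Y) with Y of shape (n_stored, B, P).
    """
    c = ANGULAR_PER_HZ_MS
    w = c * np.asarray(p.centers_hz)
    d = c * np.asarray(p.half_widths_hz)
    a_lin = 1j * w - d  # (P,)
    stim = p.stimulus
    B, nb = kt.shape
    P = p.n_populations

    def rhs(y: np.ndarray, t: float) -> np.ndarray:
        h = np.empty_like(y)
        h[:, 0] = np.sum(kc * y[:, 1:], axis=1) + 1j * stimulus_value(t, stim)
        h[:, 1:] = kt * y[:, :1]
        return a_lin * y + 0.5 * c * (h - np.conj(h) * y**2)

    t0 = stim.onset_ms
    n_steps = int(round((t_end_ms - t0) / dt_ms))
    store_idx = list(range(0, n_steps + 1, store_every))
    if store_idx[-1] != n_steps:
        store_idx.append(n_steps)
    store_set = set(store_idx)
    times = np.array([t0 + i * dt_ms for i in store_idx])
    out = np.empty((len(store_idx), B, P), dtype=complex)
    y = np.zeros((B, P), dtype=complex)
    row = 0
    out[row] = y
    row += 1
    for i in range(n_steps):
        t = t0 + i * dt_ms
        k1 = rhs(y, t)
        k2 = rhs(y + 0.5 * dt_ms * k1, t + 0.5 * dt_ms)
        k3 = rhs(y + 0.5 * dt_ms * k2, t + 0.5 * dt_ms)
        k4 = rhs(y + dt_ms * k3, t + dt_ms)
        y = y + (dt_ms / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if (i + 1) in store_set:
            out[row] = y
            row += 1
    return times, out


def _band_metrics(
    times: np.ndarray,
    y: np.ndarray,  # (T, B) complex, one band
    offset_ms: float,
    threshold: float,
    guard_ms: float,
    freq_window_ms: float,
    y_thal: np.ndarray | None = None,  # (T, B) thalamic order parameter
    kt_band: np.ndarray | None = None,  # (B,) thalamus->band coupling
    law: tuple[float, float] | None = None,  # band (center_hz, half_width_hz)
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(max_sli, sync_duration_ms, peak_frequency_hz, osc_frequency_hz) per cell."""
    post = times >= offset_ms
    tp = times[post]
    amp = np.abs(y[post])  # (Tp, B)
    maxsli = amp.max(axis=0)

    # duration: first sustained fall below threshold after locking onset
    below = amp < threshold
    n_guard = max(int(round(guard_ms / np.median(np.diff(tp)))), 1)
    dur = np.empty(amp.shape[1])
    for b in range(amp.shape[1]):
        if not np.any(amp[:, b] >= threshold):
            dur[b] = 0.0
            continue
        lock = int(np.argmax(amp[:, b] >= threshold))
        dur[b] = tp[-1] - offset_ms
        for i in np.flatnonzero(below[lock:, b]) + lock:
            if np.all(below[i : i + n_guard, b]):
                dur[b] = tp[i] - offset_ms
                break

    fwin = post & (times <= offset_ms + freq_window_ms)
    x = np.real(y[fwin])  # (Tf, B)
    x = x - x.mean(axis=0)
    x = x * np.hanning(x.shape[0])[:, None]
    n_pad = 4 * x.shape[0]
    spec = np.abs(np.fft.rfft(x, n=n_pad, axis=0))
    spec[0] = 0.0
    dt_s = float(np.median(np.diff(times[fwin]))) / 1000.0
    freqs = np.fft.rfftfreq(n_pad, d=dt_s)
    pf = freqs[np.argmax(spec, axis=0)]

    # oscillator-frequency read-out via the locking-cone formula, using
    # the time-averaged thalamic drive and the band's ring frequency
    of = np.full(amp.shape[1], np.nan)
    if y_thal is not None and kt_band is not None and law is not None:
        span_s = (times[fwin][-1] - times[fwin][0]) / 1000.0
        drive = kt_band * np.mean(np.abs(y_thal[fwin]), axis=0)
        ang = np.unwrap(np.angle(y[fwin]), axis=0)
        ring = (ang[-1] - ang[0]) / span_s / (2.0 * np.pi)
        for b in range(amp.shape[1]):
            of[b] = locked_median_frequency(law[0], law[1], drive[b], ring[b])
    return maxsli, dur, pf, of


def scan(
    net_template: NetworkSpec,
    axis1: AxisSpec,
    values1: np.ndarray,
    axis2: AxisSpec,
    values2: np.ndarray,
    engine: Literal["reduced", "full", "reduced+full-verify"] = "reduced",
    t_end_ms: float = 1100.0,
    dt_ms: float = 0.1,
    seed: int = 0,
    threshold: float | None = None,
    guard_ms: float = 50.0,
    freq_window_ms: float = 500.0,
    verify_target: "CalibrationTarget | None" = None,
    chunk_cells: int = 4000,
    store_every: int = 10,
    progress: bool = False,
) -> ScanGrid:
    """Scan the click protocol over a two-coupling plane.

    ``axis1``/``axis2`` name the couplings, e.g.
    ``("k_cortex_to_thal", 0)`` × ``("k_thal_to_cortex", 0)`` for the
    minimal model or the two feedback couplings for the θ/α model.  With
    ``engine="reduced+full-verify"`` the plane is scanned with the reduced
    system and every cell admissible under ``verify_target`` is re-run
    with the full model, replacing its row (column ``engine`` records
    which route produced each row).
    """
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    if threshold is None:
        threshold = default_threshold(net_template.cortical[0].n_oscillators)
    stim = net_template.stimulus
    offset = stim.onset_ms + stim.duration_ms
    band_names = [p.name for p in net_template.cortical]
    cells = [(a, b) for a in v1 for b in v2]
    rows = []

    if engine == "full":
        for a, b in cells:
            net = _set_coupling(_set_coupling(net_template, axis1, a), axis2, b)
            _, summary = run_protocol(
                net, t_end_ms, dt_ms, seed=seed, threshold=threshold,
                freq_window_ms=freq_window_ms,
            )
            for name in band_names:
                rows.append((a, b, name, summary[name]["max_sli"],
                             summary[name]["sync_duration_ms"],
                             summary[name]["peak_frequency_hz"],
                             summary[name]["osc_frequency_hz"], "full"))
    else:
        p = ReducedParams.from_network(net_template)
        nb = len(band_names)
        kt_base = np.asarray(net_template.k_thal_to_cortex)
        kc_base = np.asarray(net_template.k_cortex_to_thal)
        for start in range(0, len(cells), chunk_cells):
            chunk = cells[start : start + chunk_cells]
            kt = np.tile(kt_base, (len(chunk), 1))
            kc = np.tile(kc_base, (len(chunk), 1))
            for j, (a, b) in enumerate(chunk):
                for axis, val in ((axis1, a), (axis2, b)):
                    (kt if axis[0] == "k_thal_to_cortex" else kc)[j, axis[1]] = val
            times, y = _reduced_batch(p, kt, kc, t_end_ms, dt_ms, store_every)
            for band in range(nb):
                pop = net_template.cortical[band]
                ms, du, pf, of = _band_metrics(
                    times, y[:, :, band + 1], offset, threshold, guard_ms,
                    freq_window_ms, y_thal=y[:, :, 0], kt_band=kt[:, band],
                    law=(pop.frequency_law.center_hz, pop.frequency_law.half_width_hz),
                )
                for j, (a, b) in enumerate(chunk):
                    rows.append((a, b, band_names[band], ms[j], du[j], pf[j],
                                 of[j], "reduced"))
            if progress:
                print(f"scan: {min(start + chunk_cells, len(cells))}/{len(cells)} cells")

    table = pd.DataFrame(
        rows,
        columns=["axis1", "axis2", "population", "max_sli", "sync_duration_ms",
                 "peak_frequency_hz", "osc_frequency_hz", "engine"],
    )
    grid = ScanGrid(
        axis_names=(_axis_label(net_template, axis1), _axis_label(net_template, axis2)),
        axes=(axis1, axis2),
        values1=v1,
        values2=v2,
        table=table,
        engine=engine,
        template=net_template,
        threshold=threshold,
    )

    if engine == "reduced+full-verify":
        if verify_target is None:
            raise SpecificationError(
                "engine 'reduced+full-verify' needs a verify_target"
            )
        for pt in calibrate(grid, verify_target, top_k=None):
            a, b = pt.axis_values
            net = _set_coupling(_set_coupling(net_template, axis1, a), axis2, b)
            _, summary = run_protocol(
                net, t_end_ms, dt_ms, seed=seed, threshold=threshold,
                freq_window_ms=freq_window_ms,
            )
            t = grid.table
            mask = np.isclose(t["axis1"], a) & np.isclose(t["axis2"], b)
            for name in band_names:
                m = mask & (t["population"] == name)
                t.loc[m, ["max_sli", "sync_duration_ms", "peak_frequency_hz",
                          "osc_frequency_hz", "engine"]] = [
                    summary[name]["max_sli"],
                    summary[name]["sync_duration_ms"],
                    summary[name]["peak_frequency_hz"],
                    summary[name]["osc_frequency_hz"],
                    "full",
                ]
    return grid


def calibrate(
    grid: ScanGrid,
    target: CalibrationTarget,
    top_k: int | None = 1,
    require_desync: bool = False,
) -> list[CalibrationPoint]:
    """Grid cells meeting every per-band target, best (smallest total SLI
    mismatch) first.

    A cell is admissible when, for every band named in the target, its
    max SLI lies within ``sli_tolerance`` of the target level and its
    peak frequency inside the admissible interval.  With
    ``require_desync`` the cell must also desynchronise in finite time in
    every band (duration below the record length), which rules out cells
    beyond the Hopf point that lock permanently.  An empty list is a
    valid outcome, not an error.
    """
    wide = grid.table.pivot_table(
        index=["axis1", "axis2"], columns="population",
        values=["max_sli", "sync_duration_ms", "peak_frequency_hz",
                "osc_frequency_hz"],
    )
    record_ms = None
    mask = pd.Series(True, index=wide.index)
    mismatch = pd.Series(0.0, index=wide.index)
    for band, level in target.sli_targets.items():
        s = wide[("max_sli", band)]
        mask &= (s - level).abs() <= target.sli_tolerance
        mismatch += (s - level).abs()
        lo, hi = target.freq_intervals_hz.get(band, (-np.inf, np.inf))
        f = wide[("osc_frequency_hz", band)]
        mask &= (f >= lo) & (f <= hi)
        if require_desync:
            d = wide[("sync_duration_ms", band)]
            if record_ms is None:
                record_ms = d.max()
            mask &= d < 0.98 * record_ms
    hits = wide[mask]
    order = mismatch[mask].sort_values().index
    if top_k is not None:
        order = order[:top_k]
    out = []
    for a, b in order:
        row = hits.loc[(a, b)]
        out.append(
            CalibrationPoint(
                label=target.label,
                couplings={grid.axis_names[0]: float(a), grid.axis_names[1]: float(b)},
                achieved_sli={
                    band: float(row[("max_sli", band)]) for band in target.sli_targets
                },
                achieved_freq_hz={
                    band: float(row[("osc_frequency_hz", band)])
                    for band in target.sli_targets
                },
                sli_mismatch=float(mismatch.loc[(a, b)]),
                axis_values=(float(a), float(b)),
            )
        )
    return out
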