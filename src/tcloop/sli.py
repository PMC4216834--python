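"""Stimulus locking index (SLI) and the derived synchrony read-outs.

The SLI at a time point is the resultant length of the phases across the
ensemble, |n⁻¹ Σ_k e^{iφ_k}| — 0 for uniformly spread phases, 1 for a
perfectly locked ensemble.  In the model the ensemble of differently
initialised oscillators at a single stimulation plays the role of the
repeated experimental trials, so the SLI coincides with the population
mean-field amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .model import SpecificationError, Trajectory

__all__ = [
    "SLISeries",
    "SyncSummary",
    "sli",
    "sli_timeseries",
    "max_sli",
    "sync_duration",
    "peak_frequency",
    "noise_floor",
    "default_threshold",
]


@dataclass
class SLISeries:
    """Per-population SLI time series on a common grid."""

    times_ms: np.ndarray
    sli: dict[str, np.ndarray]

    def window(self, a_ms: float, b_ms: float) -> "SLISeries":
        m = (self.times_ms >= a_ms) & (self.times_ms <= b_ms)
        if not np.any(m):
            raise SpecificationError(f"empty window ({a_ms}, {b_ms}) ms")
        return SLISeries(self.times_ms[m], {k: v[m] for k, v in self.sli.items()})


@dataclass(frozen=True)
class SyncSummary:
    """One row of the synchrony read-out for a (population, parameter) point."""

    population: str
    max_sli: float
    sync_duration_ms: float
    peak_frequency_hz: float


def sli(phases: np.ndarray) -> float:
    """Resultant length of a phase sample."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise SpecificationError("sli of an empty phase array")
    return float(np.abs(np.mean(np.exp(1j * phases))))


def sli_timeseries(traj: Trajectory) -> SLISeries:
    """SLI(t) of every population (= the stored mean-field amplitudes)."""
    return SLISeries(
        times_ms=traj.times_ms,
        sli={name: np.abs(y) for name, y in traj.iter_populations()},
    )


def noise_floor(n: int) -> float:
    """Expected SLI of n uniformly random phases, √(π/4n) ≈ 0.89/√n."""
    return float(np.sqrt(np.pi / (4.0 * n)))


def default_threshold(n: int) -> float:
    """Default synchrony threshold: max(0.15, 3 × noise floor at size n)."""
    return max(0.15, 3.0 * noise_floor(n))


def max_sli(
    series: SLISeries, population: str, window_ms: tuple[float, float]
) -> float:
    """Maximum SLI of one population over a time window."""
    return float(np.max(series.window(*window_ms).sli[population]))


def sync_duration(
    series: SLISeries,
    population: str,
    threshold: float,
    offset_ms: float = 50.0,
    guard_ms: float = 50.0,
) -> float:
    """Time from stimulus offset until the population desynchronises.

    Desynchronisation is the first time at which the SLI, having locked
    (exceeded ``threshold`` at some point after ``offset_ms``), falls
    below the threshold and stays below it for ``guard_ms`` — brief dips
    during otherwise-locked oscillation do not count.  Locking may build
    up only after the stimulus ends (resonant growth), so the search for
    the fall starts at the locking onset, while the duration is still
    counted from the stimulus offset.  Returns 0 if the SLI never exceeds
    the threshold after offset, and the (censored) full remaining window
    if it never falls.
    """
    if not 0.0 < threshold < 1.0:
        raise SpecificationError("threshold must lie in (0, 1)")
    t = series.times_ms
    m = t >= offset_ms
    t = t[m]
    x = series.sli[population][m]
    if t.size == 0 or not np.any(x >= threshold):
        return 0.0
    lock = int(np.argmax(x >= threshold))
    below = x < threshold
    for i in np.flatnonzero(below[lock:]) + lock:
        j = np.searchsorted(t, t[i] + guard_ms, side="left")
        if np.all(below[i:max(j, i + 1)]):
            return float(t[i] - offset_ms)
    return float(t[-1] - offset_ms)


def peak_frequency(
    traj: Trajectory,
    population: str,
    window_ms: tuple[float, float],
    min_periods: float = 2.0,
    nominal_hz: float | None = None,
) -> float:
    """Dominant frequency (Hz) of Re(Y) of one population over a window.

    Detrended, Hann-tapered DFT with 4× zero padding; returns the
    bin-center frequency of the largest non-DC peak.  The window must span
    at least ``min_periods`` periods of the population's nominal frequency
    (taken from the network spec when not given).
    """
    a, b = window_ms
    idx = traj.pop_index(population)
    if nominal_hz is None:
        nominal_hz = traj.net.populations[idx].frequency_law.center_hz
    if (b - a) < min_periods * 1000.0 / nominal_hz:
        raise SpecificationError(
            f"window of {b - a:.0f} ms is shorter than {min_periods} periods at "
            f"{nominal_hz} Hz"
        )
    m = (traj.times_ms >= a) & (traj.times_ms <= b)
    x = np.real(traj.mean_fields[m, idx])
    if x.size < 8:
        raise SpecificationError("window contains too few samples")
    dt_s = float(np.median(np.diff(traj.times_ms[m]))) / 1000.0
    x = _signal.detrend(x) * np.hanning(x.size)
    n_pad = 4 * x.size
    spec = np.abs(np.fft.rfft(x, n=n_pad))
    freqs = np.fft.rfftfreq(n_pad, d=dt_s)
    spec[0] = 0.0
    return float(freqs[np.argmax(spec)])


def median_oscillator_frequency(
    traj: Trajectory, population: str, window_ms: tuple[float, float]
) -> float:
    """Median time-averaged oscillator frequency (Hz) over a window.

    Each oscillator's average frequency is its unwrapped phase advance
    divided by the window length.  The median is the robust location of
    the ensemble's frequency distribution — well defined even for the
    heavy-tailed Lorentzian frequency law — and is the read-out that
    stays near the band's natural center under partial locking, unlike
    the collective ring frequency of the mean field.  Requires the
    trajectory to carry stored phases.
    """
    if traj.phases is None:
        raise SpecificationError(
            "median_oscillator_frequency needs a trajectory with stored phases"
        )
    a, b = window_ms
    m = (traj.times_ms >= a) & (traj.times_ms <= b)
    if np.count_nonzero(m) < 2:
        raise SpecificationError(f"window ({a}, {b}) ms holds fewer than 2 samples")
    ph = np.unwrap(traj.phases[traj.pop_index(population)][m], axis=0)
    span_ms = traj.times_ms[m][-1] - traj.times_ms[m][0]
    f_hz = (ph[-1] - ph[0]) / span_ms / (2.0 * np.pi) * 1000.0
    return float(np.median(f_hz))


def locked_median_frequency(
    center_hz: float,
    half_width_hz: float,
    drive_hz: float,
    collective_hz: float,
    n_quantiles: int = 2001,
) -> float:
    """Median oscillator frequency under a steady rotating drive.

    Infinite-N counterpart of :func:`median_oscillator_frequency` for a
    Lorentzian ensemble forced by a rotating field of strength
    ``drive_hz`` at frequency ``collective_hz``: oscillators within the
    locking cone |f − f_Ω| ≤ F rotate at f_Ω, the rest drift at
    f_Ω ± √(ν² − F²).  Used by the reduced-engine scans, where no
    individual oscillators exist.
    """
    from scipy import stats as _stats

    q = np.arange(1, n_quantiles + 1) / (n_quantiles + 1)
    f = _stats.cauchy.ppf(q, loc=center_hz, scale=half_width_hz)
    nu = f - collective_hz
    drift = np.sqrt(np.maximum(nu**2 - drive_hz**2, 0.0))
    eff = collective_hz + np.sign(nu) * drift
    return float(np.median(eff))
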