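"""Full N-oscillator model of the thalamo-cortical loop.

Each brain area (the thalamic relay and one or two auditory-cortex bands)
is an ensemble of phase oscillators with Lorentzian-distributed natural
frequencies.  Areas interact only through their complex mean fields: a
cortical oscillator is pulled toward the thalamic mean phase with strength
K_T, the thalamic oscillators toward the cortical mean phase(s) with
strength(s) K_C, and an external click stimulus acts on the thalamus as an
additive ``I(t)·cos(φ)`` term that resets phases toward π/2.

Unit convention
---------------
Time is measured in milliseconds.  Natural-frequency centers ``f`` and
half-widths ``Δ`` are quoted in Hz, and the coupling strengths ``K`` and
stimulus intensity ``I`` are quoted in the same frequency units, so the
phase equation reads::

    dφ/dt = (2π/1000) · [ f + K·R·sin(Θ − φ) + I(t)·cos(φ) ]   [rad/ms]

One global angular conversion ``2π/1000`` maps the Hz-valued bracket to
rad/ms.  All parameter values quoted elsewhere in the package (K_T = 16,
I = 100, ...) are on this Hz-equivalent scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ANGULAR_PER_HZ_MS",
    "LorentzSpec",
    "PopulationSpec",
    "StimulusSpec",
    "NetworkSpec",
    "MeanField",
    "Trajectory",
    "SpecificationError",
    "IntegrationError",
    "sample_natural_frequencies",
    "sample_initial_phases",
    "stimulus_value",
    "mean_field",
    "full_rhs",
    "integrate_full",
]

#: rad/ms per Hz-equivalent unit: the single angular conversion of the model.
ANGULAR_PER_HZ_MS: float = 2.0 * np.pi / 1000.0


class SpecificationError(ValueError):
    """An invalid model specification (sizes, signs, missing fields)."""


class IntegrationError(RuntimeError):
    """A numerical failure during time integration."""


@dataclass(frozen=True)
class LorentzSpec:
    """Lorentzian (Cauchy) natural-frequency law of one population.

    Parameters
    ----------
    center_hz : float
        Peak (= median) of the distribution in Hz.
    half_width_hz : float
        Half width at half maximum in Hz; must be positive — the
        mean-field closure requires a genuinely spread ensemble.
    """

    center_hz: float
    half_width_hz: float

    def __post_init__(self) -> None:
        if not self.center_hz > 0:
            raise SpecificationError(f"center_hz must be > 0, got {self.center_hz}")
        if not self.half_width_hz > 0:
            raise SpecificationError(
                f"half_width_hz must be > 0, got {self.half_width_hz}"
            )


@dataclass(frozen=True)
class PopulationSpec:
    """One brain area as an ensemble of phase oscillators."""

    name: str
    n_oscillators: int
    frequency_law: LorentzSpec
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_oscillators < 2:
            raise SpecificationError(
                f"population {self.name!r}: n_oscillators must be >= 2"
            )


@dataclass(frozen=True)
class StimulusSpec:
    """Rectangular stimulus pulse acting on the thalamic population.

    ``intensity`` is dimensionless on the model's Hz-equivalent scale; the
    pulse is on during the half-open window [onset, onset + duration).
    """

    intensity: float = 100.0
    onset_ms: float = 0.0
    duration_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise SpecificationError("stimulus intensity must be >= 0")
        if self.duration_ms < 0:
            raise SpecificationError("stimulus duration must be >= 0")


@dataclass(frozen=True)
class NetworkSpec:
    """Thalamus plus one or two cortical bands with directed couplings.

    ``k_thal_to_cortex[j]`` (K_T) drives cortical band j from the thalamic
    mean field; ``k_cortex_to_thal[j]`` (K_C) feeds band j's mean field
    back to the thalamus.  There is no direct cortex–cortex coupling.
    """

    thalamus: PopulationSpec
    cortical: tuple[PopulationSpec, ...]
    k_thal_to_cortex: tuple[float, ...]
    k_cortex_to_thal: tuple[float, ...]
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cortical", tuple(self.cortical))
        object.__setattr__(self, "k_thal_to_cortex", tuple(float(k) for k in self.k_thal_to_cortex))
        object.__setattr__(self, "k_cortex_to_thal", tuple(float(k) for k in self.k_cortex_to_thal))
        nb = len(self.cortical)
        if nb not in (1, 2):
            raise SpecificationError("need 1 or 2 cortical populations")
        if len(self.k_thal_to_cortex) != nb or len(self.k_cortex_to_thal) != nb:
            raise SpecificationError("coupling lists must match the cortical list")
        if any(k < 0 for k in self.k_thal_to_cortex + self.k_cortex_to_thal):
            raise SpecificationError("coupling strengths must be >= 0")
        names = [self.thalamus.name] + [p.name for p in self.cortical]
        if len(set(names)) != len(names):
            raise SpecificationError(f"population names must be unique, got {names}")

    @property
    def populations(self) -> tuple[PopulationSpec, ...]:
        """All populations, thalamus first."""
        return (self.thalamus,) + self.cortical

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.populations)


@dataclass(frozen=True)
class MeanField:
    """Complex order parameter Y = R·e^{iΘ} of one population."""

    amplitude: float
    phase: float

    @property
    def value(self) -> complex:
        return self.amplitude * np.exp(1j * self.phase)

    @classmethod
    def from_complex(cls, y: complex) -> "MeanField":
        return cls(amplitude=abs(y), phase=float(np.angle(y)))


def sample_natural_frequencies(
    spec: PopulationSpec, mode: Literal["random", "quantile"] = "random"
) -> np.ndarray:
    """Draw the ensemble's natural frequencies, in rad/ms.

    ``random`` gives seeded i.i.d. Cauchy draws (the model's stochastic
    setting); ``quantile`` gives the deterministic k/(N+1) quantiles of the
    Lorentzian in ascending order, which remove sampling noise in tests and
    in full-vs-reduced comparisons.  Draws are not truncated — heavy tails
    are intrinsic to the Lorentzian closure.
    """
    law = spec.frequency_law
    n = spec.n_oscillators
    if mode == "quantile":
        q = np.arange(1, n + 1) / (n + 1)
        f_hz = stats.cauchy.ppf(q, loc=law.center_hz, scale=law.half_width_hz)
    elif mode == "random":
        rng = np.random.default_rng(spec.seed)
        f_hz = law.center_hz + law.half_width_hz * rng.standard_cauchy(n)
    else:
        raise SpecificationError(f"unknown frequency sampling mode {mode!r}")
    return ANGULAR_PER_HZ_MS * f_hz


def sample_initial_phases(n: int, seed: int) -> np.ndarray:
    """Seeded i.i.d. uniform phases on [0, 2π)."""
    if n < 1:
        raise SpecificationError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 2.0 * np.pi, size=n)


def stimulus_value(t_ms: float, s: StimulusSpec) -> float:
    """Stimulus intensity at time t: I inside [onset, onset+duration), else 0."""
    if s.onset_ms <= t_ms < s.onset_ms + s.duration_ms:
        return s.intensity
    return 0.0


def mean_field(phases: np.ndarray) -> MeanField:
    """Complex average of e^{iφ} over one population."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise SpecificationError("mean_field of an empty phase array")
    return MeanField.from_complex(np.mean(np.exp(1j * phases)))


def full_rhs(
    phases: Sequence[np.ndarray],
    t_ms: float,
    net: NetworkSpec,
    freqs: Sequence[np.ndarray],
) -> list[np.ndarray]:
    """Phase velocities dφ/dt (rad/ms) for every oscillator.

    ``phases`` and ``freqs`` are per-population arrays ordered as
    ``net.populations`` (thalamus first).  Cortical band b follows
    dφ = ω + c·K_T^(b)·Im(Y_T e^{−iφ}); the thalamus follows
    dφ = ω + c·Im((Σ_b K_C^(b) Y_b + i·I(t)) e^{−iφ}) with c = 2π/1000,
    the ``i·I`` forcing field being the complex form of I·cos(φ).
    """
    pops = net.populations
    if len(phases) != len(pops) or len(freqs) != len(pops):
        raise SpecificationError("phases/freqs must have one array per population")
    for arr, w, p in zip(phases, freqs, pops):
        if len(arr) != p.n_oscillators or len(w) != p.n_oscillators:
            raise SpecificationError(f"array size mismatch for population {p.name!r}")

    c = ANGULAR_PER_HZ_MS
    e_thal = np.exp(1j * np.asarray(phases[0]))
    y_bands = [np.mean(np.exp(1j * np.asarray(ph))) for ph in phases[1:]]
    y_thal = np.mean(e_thal)

    h_thal = sum(k * y for k, y in zip(net.k_cortex_to_thal, y_bands))
    h_thal = h_thal + 1j * stimulus_value(t_ms, net.stimulus)
    out = [np.asarray(freqs[0]) + c * np.imag(h_thal * np.conj(e_thal))]
    for b, ph in enumerate(phases[1:]):
        e_b = np.exp(1j * np.asarray(ph))
        h_b = net.k_thal_to_cortex[b] * y_thal
        out.append(np.asarray(freqs[b + 1]) + c * np.imag(h_b * np.conj(e_b)))
    return out


@dataclass
class Trajectory:
    """Stored output of a full-model integration.

    ``mean_fields[i, a]`` is the complex order parameter of population a
    (order: thalamus, then cortical bands) at ``times_ms[i]``; the SLI of
    population a is ``abs(mean_fields[:, a])``.  Per-oscillator phases are
    stored on the same grid only when requested (they are large).
    """

    times_ms: np.ndarray
    mean_fields: np.ndarray  # complex, shape (n_times, n_pops)
    pop_names: tuple[str, ...]
    net: NetworkSpec
    dt_ms: float
    seed: int
    freq_mode: str
    frequencies: list[np.ndarray]
    phases: list[np.ndarray] | None = None  # per pop, shape (n_times, n_osc)
    final_phases: list[np.ndarray] | None = None

    def pop_index(self, name: str) -> int:
        return self.pop_names.index(name)

    def sli_of(self, name: str) -> np.ndarray:
        """SLI time series of one population (= mean-field amplitude)."""
        return np.abs(self.mean_fields[:, self.pop_index(name)])

    def iter_populations(self) -> Iterator[tuple[str, np.ndarray]]:
        for i, name in enumerate(self.pop_names):
            yield name, self.mean_fields[:, i]


def _flat_rhs(theta, t_ms, omega, slices, kt, kc, stim, c=ANGULAR_PER_HZ_MS):
    # hot path of the RK4 loop: one flat phase vector, per-pop slices
    e = np.exp(1j * theta)
    y = [np.mean(e[s]) for s in slices]
    h_thal = sum(k * yb for k, yb in zip(kc, y[1:])) + 1j * stimulus_value(t_ms, stim)
    out = np.empty_like(theta)
    out[slices[0]] = omega[slices[0]] + c * np.imag(h_thal * np.conj(e[slices[0]]))
    for b in range(1, len(slices)):
        h_b = kt[b - 1] * y[0]
        out[slices[b]] = omega[slices[b]] + c * np.imag(h_b * np.conj(e[slices[b]]))
    return out


def integrate_full(
    net: NetworkSpec,
    t_span_ms: tuple[float, float],
    dt_ms: float = 0.1,
    seed: int = 0,
    freq_mode: Literal["random", "quantile"] = "random",
    store_every: int = 10,
    store_phases: bool = False,
    initial_phases: Sequence[np.ndarray] | None = None,
) -> Trajectory:
    """Integrate the full model with a fixed-step classical RK4 scheme.

    Initial phases are i.i.d. uniform (one spawned seed per population,
    derived from ``seed``) unless ``initial_phases`` overrides them; the
    frequency draws use each population's own ``seed`` field (or the exact
    Lorentzian quantiles in ``quantile`` mode).  Everything is reproducible
    bitwise from ``(net, seed, dt_ms, freq_mode)``.

    Mean fields are stored every ``store_every`` steps; stored mean fields
    are computed from the state at the stored instant, so recomputing them
    from stored phases reproduces them exactly.
    """
    t0, t1 = t_span_ms
    if not t0 < t1:
        raise SpecificationError("t_span_ms must be increasing")
    if not dt_ms > 0:
        raise SpecificationError("dt_ms must be > 0")

    pops = net.populations
    omega = np.concatenate([sample_natural_frequencies(p, freq_mode) for p in pops])
    sizes = [p.n_oscillators for p in pops]
    bounds = np.cumsum([0] + sizes)
    slices = [slice(bounds[i], bounds[i + 1]) for i in range(len(pops))]

    if initial_phases is None:
        children = np.random.SeedSequence(seed).spawn(len(pops))
        theta = np.concatenate(
            [
                np.random.default_rng(cs).uniform(0.0, 2.0 * np.pi, size=n)
                for cs, n in zip(children, sizes)
            ]
        )
    else:
        if len(initial_phases) != len(pops):
            raise SpecificationError("initial_phases must have one array per population")
        theta = np.concatenate([np.asarray(a, dtype=float) for a in initial_phases])
        if theta.size != bounds[-1]:
            raise SpecificationError("initial_phases sizes do not match populations")

    n_steps = int(round((t1 - t0) / dt_ms))
    kt, kc, stim = net.k_thal_to_cortex, net.k_cortex_to_thal, net.stimulus

    store_idx = list(range(0, n_steps + 1, store_every))
    if store_idx[-1] != n_steps:
        store_idx.append(n_steps)
    store_set = set(store_idx)
    times = np.array([t0 + i * dt_ms for i in store_idx])
    mf = np.empty((len(store_idx), len(pops)), dtype=complex)
    ph_store = (
        [np.empty((len(store_idx), n)) for n in sizes] if store_phases else None
    )

    def record(row: int, th: np.ndarray) -> None:
        e = np.exp(1j * th)
        for a, s in enumerate(slices):
            mf[row, a] = np.mean(e[s])
            if ph_store is not None:
                ph_store[a][row] = np.mod(th[s], 2.0 * np.pi)

    row = 0
    record(row, theta)
    row += 1
    t = t0
    for i in range(n_steps):
        k1 = _flat_rhs(theta, t, omega, slices, kt, kc, stim)
        k2 = _flat_rhs(theta + 0.5 * dt_ms * k1, t + 0.5 * dt_ms, omega, slices, kt, kc, stim)
        k3 = _flat_rhs(theta + 0.5 * dt_ms * k2, t + 0.5 * dt_ms, omega, slices, kt, kc, stim)
        k4 = _flat_rhs(theta + dt_ms * k3, t + dt_ms, omega, slices, kt, kc, stim)
        theta = theta + (dt_ms / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t = t0 + (i + 1) * dt_ms
        if not np.all(np.isfinite(theta)):
            raise IntegrationError(f"non-finite phase encountered at t = {t:.3f} ms")
        if (i + 1) in store_set:
            record(row, theta)
            row += 1

    return Trajectory(
        times_ms=times,
        mean_fields=mf,
        pop_names=net.names,
        net=net,
        dt_ms=dt_ms,
        seed=seed,
        freq_mode=freq_mode,
        frequencies=[omega[s].copy() for s in slices],
        phases=ph_store,
        final_phases=[np.mod(theta[s], 2.0 * np.pi) for s in slices],
    )
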