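"""Bifurcation analysis of the reduced thalamo-cortical system.

With the stimulus off, the incoherent state Y = 0 is always an
equilibrium.  As the thalamus→cortex coupling K_T grows at fixed feedback
K_C, the system passes through three regimes:

* region I   — the origin is the global attractor (desynchrony);
* region II  — the origin is still locally stable but coexists with a
  stable limit cycle (collective oscillation), the two separated by an
  unstable cycle: bistability.  The stable/unstable pair is born at a
  fold-of-limit-cycles (FLB);
* region III — the origin has lost stability at a (subcritical) Hopf
  point (HB) and every trajectory synchronises.

The module locates the HB from the linearisation at the origin, finds the
periodic-orbit pair by Poincaré-section methods (long-run convergence for
the stable cycle, Newton shooting on the return map for the unstable
one), locates the FLB by bisection on orbit existence, and classifies
parameter points into the three regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy import optimize

from .model import ANGULAR_PER_HZ_MS, SpecificationError
from .reduced import (
    ReducedParams,
    from_real_system,
    integrate_reduced,
    reduced_rhs,
    to_real_system,
)

__all__ = [
    "PeriodicOrbit",
    "BifurcationDiagram",
    "jacobian_at_origin",
    "max_growth_rate",
    "hopf_point",
    "hopf_locus",
    "find_periodic_orbit",
    "stable_orbit_exists",
    "flb_point",
    "flb_locus",
    "classify_region",
    "reset_state",
]


def jacobian_at_origin(p: ReducedParams) -> np.ndarray:
    """Exact Jacobian of the real 2P-dimensional reduced system at Y = 0.

    The stimulus must be off (the analysis is post-stimulus).  Diagonal
    blocks are the per-population rotations [[−Δ, −ω̂], [ω̂, −Δ]]; the
    coupling from population b into population a contributes the scalar
    block (c·K/2)·I₂ because the linearised forcing is complex-linear.
    """
    P = p.n_populations
    c = ANGULAR_PER_HZ_MS
    J = np.zeros((2 * P, 2 * P))
    for a in range(P):
        w = c * p.centers_hz[a]
        d = c * p.half_widths_hz[a]
        J[2 * a : 2 * a + 2, 2 * a : 2 * a + 2] = [[-d, -w], [w, -d]]
    for b in range(1, P):
        g_cb = 0.5 * c * p.k_thal_to_cortex[b - 1]  # thalamus -> band b
        g_tb = 0.5 * c * p.k_cortex_to_thal[b - 1]  # band b -> thalamus
        J[2 * b, 0] = J[2 * b + 1, 1] = g_cb
        J[0, 2 * b] = J[1, 2 * b + 1] = g_tb
    return J


def max_growth_rate(p: ReducedParams) -> float:
    """Largest real part (1/ms) of the origin's eigenvalues."""
    return float(np.max(np.real(np.linalg.eigvals(jacobian_at_origin(p)))))


def _coupling_setter(
    p: ReducedParams, which: Literal["k_thal_to_cortex", "k_cortex_to_thal"], band: int
) -> Callable[[float], ReducedParams]:
    def setter(value: float) -> ReducedParams:
        ks = list(getattr(p, which))
        ks[band] = value
        return p.with_couplings(**{which: tuple(ks)})

    return setter


def hopf_point(
    p: ReducedParams,
    which: Literal["k_thal_to_cortex", "k_cortex_to_thal"] = "k_thal_to_cortex",
    band: int = 0,
    bracket: tuple[float, float] = (0.0, 40.0),
    tol: float = 1e-6,
) -> float | None:
    """Coupling value where the origin loses stability, by bisection.

    Returns None when the leading growth rate does not change sign on the
    bracket (no Hopf point in range — not an error).
    """
    setter = _coupling_setter(p.without_stimulus(), which, band)
    lo, hi = bracket
    f = lambda k: max_growth_rate(setter(k))
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        return None
    return float(optimize.brentq(f, lo, hi, xtol=tol))


def hopf_locus(
    p_base: ReducedParams,
    fixed_which: Literal["k_thal_to_cortex", "k_cortex_to_thal"],
    fixed_grid: np.ndarray,
    vary_which: Literal["k_thal_to_cortex", "k_cortex_to_thal"] = "k_thal_to_cortex",
    band: int = 0,
    bracket: tuple[float, float] = (0.0, 40.0),
    tol: float = 1e-6,
) -> list[tuple[float, float]]:
    """Hopf curve in a coupling plane: (fixed value, located crossing) pairs.

    Grid points with no crossing in the bracket are omitted.
    """
    out = []
    for v in np.asarray(fixed_grid, dtype=float):
        p = _coupling_setter(p_base, fixed_which, band)(v)
        k = hopf_point(p, vary_which, band, bracket, tol)
        if k is not None:
            out.append((float(v), k))
    return out


@dataclass(frozen=True)
class PeriodicOrbit:
    """A periodic orbit of the reduced system, anchored on a Poincaré section."""

    period_ms: float
    x_min: float  # extrema of Re(Y) of the section band over one period
    x_max: float
    amplitude: float  # max |Y_band| over one period
    stable: bool
    section_state: np.ndarray  # complex state on the section y_band = 0, dy/dt > 0
    floquet_multipliers: np.ndarray | None = None


def reset_state(p: ReducedParams, dt_ms: float = 0.1) -> np.ndarray:
    """Post-stimulus state: integrate the stimulus window from the origin.

    This is the state the click leaves the system in — the physically
    relevant initial condition for the post-stimulus transient.
    """
    s = p.stimulus
    if s.intensity == 0 or s.duration_ms == 0:
        raise SpecificationError("reset_state needs a nonzero stimulus")
    y0 = np.zeros(p.n_populations, dtype=complex)
    tr = integrate_reduced(
        p, y0, (s.onset_ms, s.onset_ms + s.duration_ms), dt_ms, store_every=10**9
    )
    return tr.order_parameters[-1]


def _section_crossings(times, y_band):
    """Indices i where Im(Y) crosses 0 upward between samples i, i+1."""
    yi = np.imag(y_band)
    return np.flatnonzero((yi[:-1] < 0.0) & (yi[1:] >= 0.0))


def _interp_crossing(t0, t1, y0, y1):
    a = np.imag(y0) / (np.imag(y0) - np.imag(y1))
    return t0 + a * (t1 - t0), y0 + a * (y1 - y0)


def find_periodic_orbit(
    p: ReducedParams,
    init: np.ndarray | None = None,
    branch: Literal["stable", "unstable"] = "stable",
    band: int = 1,
    dt_ms: float = 0.1,
    transient_ms: float = 3000.0,
    settle_tol: float = 1e-4,
    min_amplitude: float = 1e-3,
) -> PeriodicOrbit | None:
    """Locate a periodic orbit of the post-stimulus reduced system.

    Stable branch: integrate past the transient and require successive
    Poincaré-section states (section: Im Y_band = 0 crossed upward) to
    converge.  Unstable branch: Newton shooting on the section return map
    starting from ``init`` (typically a scaled-down stable-orbit state),
    classified afterwards by Floquet multipliers of the return map.
    Returns None when no orbit is found (e.g. the origin attracts).
    """
    p = p.without_stimulus()
    if init is None:
        init = 0.1 * np.ones(p.n_populations, dtype=complex)
    init = np.asarray(init, dtype=complex)

    if branch == "stable":
        tr = integrate_reduced(p, init, (0.0, transient_ms), dt_ms, store_every=1)
        y = tr.order_parameters[..., band]
        n_tail = y.shape[0] // 3
        cross = _section_crossings(tr.times_ms[-n_tail:], y[-n_tail:])
        if len(cross) < 4:
            return None
        cross = cross + (y.shape[0] - n_tail)
        states, tcs = [], []
        for i in cross[-4:]:
            tc, _ = _interp_crossing(
                tr.times_ms[i], tr.times_ms[i + 1], y[i], y[i + 1]
            )
            a = (tc - tr.times_ms[i]) / (tr.times_ms[i + 1] - tr.times_ms[i])
            tcs.append(tc)
            states.append(
                (1.0 - a) * tr.order_parameters[i] + a * tr.order_parameters[i + 1]
            )
        drift = np.max(np.abs(states[-1] - states[-2]))
        amp_here = np.abs(states[-1][band])
        if amp_here < min_amplitude or drift > settle_tol * max(amp_here, 0.05):
            return None
        period = float(tcs[-1] - tcs[-2])
        seg = integrate_reduced(
            p, states[-1], (0.0, 1.05 * period), dt_ms, store_every=1
        ).order_parameters
        xb = np.real(seg[..., band])
        return PeriodicOrbit(
            period_ms=period,
            x_min=float(np.min(xb)),
            x_max=float(np.max(xb)),
            amplitude=float(np.max(np.abs(seg[..., band]))),
            stable=True,
            section_state=states[-1],
        )

    # --- unstable branch: single shooting on the Poincaré return map ---
    def return_map(u: np.ndarray) -> tuple[np.ndarray, float] | None:
        y0 = from_real_system(np.insert(u, 2 * band + 1, 0.0))
        tr = integrate_reduced(
            p, y0, (0.0, 2000.0), dt_ms, store_every=1, check_manifold=False
        )
        y = tr.order_parameters[..., band]
        cross = _section_crossings(tr.times_ms, y)
        cross = cross[cross > 2]  # skip the departure from the section
        if len(cross) == 0:
            return None
        i = cross[0]
        tc, _ = _interp_crossing(tr.times_ms[i], tr.times_ms[i + 1], y[i], y[i + 1])
        # one RK4 step of the right length from the last stored pre-crossing state
        h = tc - tr.times_ms[i]
        ys = tr.order_parameters[i]
        if h > 1e-12:
            k1 = reduced_rhs(ys, tr.times_ms[i], p)
            k2 = reduced_rhs(ys + 0.5 * h * k1, tr.times_ms[i] + 0.5 * h, p)
            k3 = reduced_rhs(ys + 0.5 * h * k2, tr.times_ms[i] + 0.5 * h, p)
            k4 = reduced_rhs(ys + h * k3, tc, p)
            ys = ys + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        return np.delete(to_real_system(ys), 2 * band + 1), float(tc)

    u0 = np.delete(to_real_system(init), 2 * band + 1)

    def residual(u):
        r = return_map(u)
        if r is None:
            return np.full_like(u, 1.0)
        return r[0] - u

    sol = optimize.root(residual, u0, method="hybr", options={"xtol": 1e-10})
    if not sol.success or np.linalg.norm(residual(sol.x)) > 1e-6:
        return None
    r = return_map(sol.x)
    assert r is not None
    _, period = r

    # Floquet multipliers of the section map by central differences
    n = sol.x.size
    eps = 1e-6
    M = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = eps
        rp, rm = return_map(sol.x + e), return_map(sol.x - e)
        if rp is None or rm is None:
            return None
        M[:, j] = (rp[0] - rm[0]) / (2 * eps)
    mults = np.linalg.eigvals(M)
    stable = bool(np.all(np.abs(mults) < 1.0))

    y_sec = from_real_system(np.insert(sol.x, 2 * band + 1, 0.0))
    if np.abs(y_sec[band]) < min_amplitude:
        return None  # converged to the origin, not an orbit
    seg = integrate_reduced(
        p, y_sec, (0.0, 1.05 * period), dt_ms, store_every=1, check_manifold=False
    ).order_parameters
    xb = np.real(seg[..., band])
    return PeriodicOrbit(
        period_ms=float(period),
        x_min=float(np.min(xb)),
        x_max=float(np.max(xb)),
        amplitude=float(np.max(np.abs(seg[..., band]))),
        stable=stable,
        section_state=y_sec,
        floquet_multipliers=mults,
    )


def stable_orbit_exists(
    p: ReducedParams,
    band: int = 1,
    init: np.ndarray | None = None,
    dt_ms: float = 0.1,
    transient_ms: float = 4000.0,
) -> bool:
    """True if long-run integration from ``init`` settles on a limit cycle."""
    orbit = find_periodic_orbit(
        p, init=init, branch="stable", band=band, dt_ms=dt_ms,
        transient_ms=transient_ms,
    )
    return orbit is not None


def flb_point(
    p: ReducedParams,
    which: Literal["k_thal_to_cortex", "k_cortex_to_thal"] = "k_thal_to_cortex",
    band: int = 0,
    bracket: tuple[float, float] = (0.5, 40.0),
    tol: float = 1e-3,
    dt_ms: float = 0.1,
) -> float | None:
    """Fold-of-limit-cycles point, by bisection on stable-orbit existence.

    Continuation is natural: the converged orbit state at one coupling
    value seeds the search at the next, so the existence test does not
    depend on the basin geometry of any particular reset state.  Close to
    the fold the stable orbit is only weakly attracting (its ghost rules
    the transient), so the per-test horizon grows as the bracket shrinks.
    """
    p = p.without_stimulus()
    setter = _coupling_setter(p, which, band)
    sband = 1 if p.n_populations >= 2 else 0
    lo, hi = bracket

    def probe(k, init, horizon):
        orb = find_periodic_orbit(
            setter(k), init=init, branch="stable", band=sband, dt_ms=dt_ms,
            transient_ms=horizon,
        )
        return orb

    orb_hi = probe(hi, None, 4000.0)
    if orb_hi is None:
        return None  # no orbit even at the top of the bracket
    if probe(lo, orb_hi.section_state, 4000.0) is not None:
        return None  # orbit persists across the whole bracket: no fold inside
    seed = orb_hi.section_state
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        horizon = float(np.clip(2000.0 / np.sqrt(max(hi - lo, 1e-6)), 4000.0, 30000.0))
        orb = probe(mid, seed, horizon)
        if orb is not None:
            hi = mid
            seed = orb.section_state
        else:
            lo = mid
    return float(0.5 * (lo + hi))


def flb_locus(
    p_base: ReducedParams,
    fixed_which: Literal["k_thal_to_cortex", "k_cortex_to_thal"],
    fixed_grid: np.ndarray,
    vary_which: Literal["k_thal_to_cortex", "k_cortex_to_thal"] = "k_thal_to_cortex",
    band: int = 0,
    bracket: tuple[float, float] = (0.5, 40.0),
    tol: float = 1e-3,
) -> list[tuple[float, float]]:
    """Fold-of-cycles curve in a coupling plane; points without a fold are omitted."""
    out = []
    for v in np.asarray(fixed_grid, dtype=float):
        p = _coupling_setter(p_base, fixed_which, band)(v)
        k = flb_point(p, vary_which, band, bracket, tol)
        if k is not None:
            out.append((float(v), k))
    return out


def classify_region(
    p: ReducedParams,
    band: int = 1,
    dt_ms: float = 0.1,
    transient_ms: float = 4000.0,
) -> str:
    """Classify a parameter point as region "I", "II" or "III".

    III: the origin is linearly unstable.  Otherwise probe the two states
    the post-stimulus narrative distinguishes — a small perturbation of
    the origin and the stimulus-reset state — plus a large-amplitude
    state; II if any of them settles on a limit cycle, else I.
    """
    ps = p.without_stimulus()
    if max_growth_rate(ps) > 1e-12:
        return "III"
    probes = [1e-3 * np.ones(p.n_populations, dtype=complex)]
    try:
        probes.append(reset_state(p, dt_ms))
    except SpecificationError:
        pass
    probes.append(0.8 * np.ones(p.n_populations, dtype=complex))
    for y0 in probes:
        if stable_orbit_exists(ps, band=band, init=y0, dt_ms=dt_ms,
                               transient_ms=transient_ms):
            return "II"
    return "I"


@dataclass
class BifurcationDiagram:
    """One-parameter diagram: branches and located HB/FLB points.

    ``fixed_points`` rows are (k, x_F, stable); ``orbits`` rows are
    (k, x_min, x_max, stable) for the orbit extrema of Re(Y_band).
    """

    parameter: str
    fixed_points: np.ndarray
    orbits: np.ndarray
    hopf_k: float | None
    flb_k: float | None

    @classmethod
    def compute(
        cls,
        p: ReducedParams,
        which: Literal["k_thal_to_cortex", "k_cortex_to_thal"] = "k_thal_to_cortex",
        band: int = 0,
        k_grid: np.ndarray | None = None,
        dt_ms: float = 0.1,
    ) -> "BifurcationDiagram":
        """Sweep one coupling: origin stability, orbit branches, HB and FLB."""
        if k_grid is None:
            k_grid = np.linspace(0.5, 20.0, 40)
        p = p.without_stimulus()
        setter = _coupling_setter(p, which, band)
        sband = 1 if p.n_populations >= 2 else 0
        hb = hopf_point(p, which, band, (float(k_grid[0]), float(k_grid[-1])))
        flb = flb_point(p, which, band, (float(k_grid[0]), float(k_grid[-1])))

        fps, orbs = [], []
        seed_state = None
        for k in np.asarray(k_grid, dtype=float)[::-1]:  # continue downward
            pk = setter(k)
            fps.append((k, 0.0, max_growth_rate(pk) < 0.0))
            orb = find_periodic_orbit(pk, init=seed_state, branch="stable",
                                      band=sband, dt_ms=dt_ms)
            if orb is not None:
                seed_state = orb.section_state
                orbs.append((k, orb.x_min, orb.x_max, True))
                uns = find_periodic_orbit(
                    pk, init=0.35 * orb.section_state, branch="unstable",
                    band=sband, dt_ms=dt_ms,
                )
                if uns is not None and not uns.stable:
                    orbs.append((k, uns.x_min, uns.x_max, False))
        return cls(
            parameter=which,
            fixed_points=np.array(sorted(fps), dtype=object),
            orbits=np.array(sorted(orbs), dtype=object),
            hopf_k=hb,
            flb_k=flb,
        )
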