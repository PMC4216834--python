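"""Convenience constructors for the standard network layouts.

Default frequency laws: thalamic relay centered at 10 Hz, θ band at 6 Hz,
α band at 10 Hz, all with half-width 0.5 Hz.  The θ and α centers are
pinned by the admissible bands of those rhythms (≈5–7 Hz and ≈9–12 Hz);
the thalamic center is a free model parameter and every value here can be
overridden.
"""

from __future__ import annotations

from .model import LorentzSpec, NetworkSpec, PopulationSpec, StimulusSpec

__all__ = [
    "DEFAULT_THALAMUS_HZ",
    "DEFAULT_THETA_HZ",
    "DEFAULT_ALPHA_HZ",
    "DEFAULT_HALF_WIDTH_HZ",
    "two_population_network",
    "three_population_network",
]

DEFAULT_THALAMUS_HZ = 10.0
DEFAULT_THETA_HZ = 6.0
DEFAULT_ALPHA_HZ = 10.0
DEFAULT_HALF_WIDTH_HZ = 0.5


def two_population_network(
    k_c: float,
    k_t: float,
    n: int = 1000,
    thalamus_hz: float = DEFAULT_THALAMUS_HZ,
    cortex_hz: float = DEFAULT_THETA_HZ,
    half_width_hz: float = DEFAULT_HALF_WIDTH_HZ,
    thalamus_half_width_hz: float | None = None,
    stimulus: StimulusSpec | None = None,
    seed: int = 0,
) -> NetworkSpec:
    """Thalamus + one cortical (θ) band, the minimal loop."""
    if stimulus is None:
        stimulus = StimulusSpec()
    hw_t = thalamus_half_width_hz if thalamus_half_width_hz is not None else half_width_hz
    return NetworkSpec(
        thalamus=PopulationSpec(
            "thalamus", n, LorentzSpec(thalamus_hz, hw_t), seed=seed
        ),
        cortical=(
            PopulationSpec("theta", n, LorentzSpec(cortex_hz, half_width_hz), seed=seed + 1),
        ),
        k_thal_to_cortex=(k_t,),
        k_cortex_to_thal=(k_c,),
        stimulus=stimulus,
    )


def three_population_network(
    k_c_theta: float,
    k_c_alpha: float,
    k_t_theta: float,
    k_t_alpha: float,
    n: int = 1000,
    thalamus_hz: float = DEFAULT_THALAMUS_HZ,
    theta_hz: float = DEFAULT_THETA_HZ,
    alpha_hz: float = DEFAULT_ALPHA_HZ,
    half_width_hz: float = DEFAULT_HALF_WIDTH_HZ,
    stimulus: StimulusSpec | None = None,
    seed: int = 0,
) -> NetworkSpec:
    """Thalamus + θ and α cortical bands (no direct cortex–cortex link)."""
    if stimulus is None:
        stimulus = StimulusSpec()
    return NetworkSpec(
        thalamus=PopulationSpec(
            "thalamus", n, LorentzSpec(thalamus_hz, half_width_hz), seed=seed
        ),
        cortical=(
            PopulationSpec("theta", n, LorentzSpec(theta_hz, half_width_hz), seed=seed + 1),
            PopulationSpec("alpha", n, LorentzSpec(alpha_hz, half_width_hz), seed=seed + 2),
        ),
        k_thal_to_cortex=(k_t_theta, k_t_alpha),
        k_cortex_to_thal=(k_c_theta, k_c_alpha),
        stimulus=stimulus,
    )
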