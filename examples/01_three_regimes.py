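"""The three post-stimulus regimes of the minimal thalamo-cortical loop.

Runs the click protocol (I=100 for 50 ms, N=1000 oscillators per
population) at three thalamus→cortex couplings with fixed feedback
K_C=1.2 and prints what the cortical SLI does afterwards.
"""

import numpy as np

from tcloop import integrate_full
from tcloop.networks import two_population_network
from tcloop.sli import default_threshold, sli_timeseries, sync_duration

for k_t, label in [(1.0, "weak drive"), (5.5, "near the fold"), (16.0, "strong drive")]:
    net = two_population_network(k_c=1.2, k_t=k_t, n=1000)
    traj = integrate_full(net, (0.0, 1600.0), dt_ms=0.1, seed=1, store_every=10)
    t, s = traj.times_ms, traj.sli_of("theta")
    series = sli_timeseries(traj)
    dur = sync_duration(series, "theta", default_threshold(1000), offset_ms=50.0)
    print(f"K_T = {k_t:4.1f} ({label}):")
    print(f"  max post-stimulus SLI   = {s[t >= 50].max():.3f}")
    print(f"  late mean SLI (>600 ms) = {s[t >= 600].mean():.3f}")
    print(f"  sync duration           = {dur:.0f} ms")

print("""
Reading: with weak drive the click never locks the cortex (SLI stays at
the finite-N noise level ~0.03-0.07).  Near the fold of limit cycles the
click resets the phases, the ensemble stays locked for several hundred
milliseconds riding the ghost of the orbit, then desynchronises again --
the regime matching evoked-response recordings.  With strong drive the
ensemble locks onto the stable collective oscillation and never lets go.
""")
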