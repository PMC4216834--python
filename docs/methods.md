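# Methods

## The model

`tcloop` simulates auditory click processing in the thalamo-cortical loop
as interacting populations of phase oscillators.  Each brain area — the
thalamic relay and one or two auditory-cortex frequency bands (θ, α) — is
an ensemble of N phase oscillators whose natural frequencies follow a
Lorentzian (Cauchy) law with center f̂ and half-width Δ.  Areas interact
only through their complex mean fields Y = R·e^{iΘ} (R is the degree of
synchrony, Θ the collective phase):

```
cortex band b:  dφ/dt = (2π/1000) · [ f + K_T^(b) · R_T · sin(Θ_T − φ) ]
thalamus:       dφ/dt = (2π/1000) · [ f + Σ_b K_C^(b) · R_b · sin(Θ_b − φ) + I(t)·cos(φ) ]
```

with time in milliseconds.  The first-harmonic (sine) coupling is the
unique form compatible with the exact mean-field reductions used below.
The click stimulus is a rectangular pulse I(t) = I on the half-open
window [onset, onset + duration), acting on the thalamus only; for I > 0
it pulls every thalamic phase toward the stable zero of f + I·cos(φ),
which is ≈ π/2 for I ≫ f — a phase reset.  There is no direct
cortex–cortex coupling; the bands influence each other only through the
thalamic feedback loop.

### Units

All rate parameters — frequency centers f̂, half-widths Δ, coupling
strengths K and stimulus intensity I — are quoted in the same
Hz-equivalent units, and a single angular conversion 2π/1000 maps the
bracketed sum to rad/ms.  This convention is forced by joint consistency
of the quantities the model must reproduce at the quoted parameter
values (K of order 1–16, I = 100, centers 6–10 Hz, Δ ≈ 0.5 Hz): the
incoherent state must be stable at K_T = 1 and unstable at K_T = 16 for
K_C = 1.2, collective rhythms must run at 6–10 Hz on a millisecond axis,
desynchronisation times must fall in the 250–700 ms range, and a 50 ms
pulse at I = 100 must reset phases completely but not instantaneously.
No other scaling satisfies all of these at once.

### Default parameters

| parameter | default | meaning |
|---|---|---|
| thalamus center | 10 Hz | relay rhythm; a free model parameter |
| θ center | 6 Hz | θ band (admissible 5–7 Hz) |
| α center | 10 Hz | α band (admissible 9–12 Hz) |
| half-widths Δ | 0.5 Hz | Lorentzian scale of every ensemble |
| N | 1000 | oscillators per population |
| I, duration | 100, 50 ms | click stimulus |
| dt | 0.1 ms | RK4 step |
| K_T^(θ), K_T^(α) | 1.0, 0.6 | fixed forward couplings of the θ/α model |

The θ and α centers are pinned by the admissible bands of those rhythms;
the thalamic center and the widths are free parameters of the model, set
once to the values above and configurable everywhere.  The fixed forward
couplings of the three-population model were chosen so that the
clinically observed locking levels (θ max SLI 0.30–0.37, α 0.19–0.26)
fall inside the scanned feedback range with desynchronisation times of a
few hundred milliseconds; the resulting admissible regions are small
islands near the θ fold curve.

## Stimulus-locking metrics

The stimulus locking index (SLI) at time t is the resultant length
|n⁻¹ Σ_k e^{iφ_k(t)}| across the ensemble: 0 for uniformly spread
phases, 1 for perfect locking.  In the model the ensemble of
differently-initialised oscillators at a single stimulation plays the
role of repeated experimental trials, so the SLI is identical to the
population mean-field amplitude.  At N = 1000 the noise floor of a
desynchronised ensemble is √(π/4N) ≈ 0.028.

**Synchronisation duration** — the "time until the system desynchronises
again" read-out — is measured from stimulus offset to the first
time the SLI, having once exceeded a threshold, falls below it and stays
below for a 50 ms guard interval.  The default threshold is
max(0.15, 3·√(π/4N)); locking that builds up only after the stimulus
(resonant growth of the α band) is handled by starting the search for
the fall at the locking onset.  The rule is deliberately explicit: the
quantity is only defined relative to a threshold, and all reported
durations state it.

**Frequency read-outs.**  Two are provided because they measure
different things:

* `peak_frequency` — the DFT peak of Re(Y) (detrended, Hann-tapered, 4×
  zero-padded) over the locked window: the *collective ring frequency*
  of the mean field.
* `median_oscillator_frequency` — the median time-averaged phase
  velocity across oscillators (infinite-N analogue:
  `locked_median_frequency`, via the locking-cone formula for a
  rotating drive).  Under partial locking this stays near the band's
  natural center, which is the "mean frequency of the oscillators" the
  study design tracks; it is the read-out used by scans and
  calibration.  The median is used because a Lorentzian ensemble has no
  mean frequency.

At partially locked θ operating points these differ visibly (collective
ring ≈ 7–7.5 Hz, oscillator median ≈ 6.2 Hz); conflating them would make
the 5–7 Hz θ constraint unsatisfiable even at points that are
behaviourally correct.

## Ott-Antonsen reduction

For Lorentzian frequency laws the infinite-N dynamics of each population
closes exactly on the OA manifold into one complex ODE per population:

```
dY_a/dt = (i·ω̂_a − Δ_a)·Y_a + c·(H_a − H_a*·Y_a²)/2 ,   c = 2π/1000
H_C^(b) = K_T^(b)·Y_T ,   H_T = Σ_b K_C^(b)·Y_b + i·I(t)
```

The i·I forcing field is the complex form of the I·cos(φ) stimulus.  The
package does not carry the intermediate collective-variable machinery at
run time; instead the reduction is certified empirically: with N = 10⁴
quantile-sampled oscillators the full model's mean field tracks the
reduced trajectory within 0.05 sup-norm over 1000 ms in all three
dynamical regimes (an acceptance test).  The closed-form decay
Y(t) = Y(0)·e^{(iω̂−Δ)t} of the uncoupled system is reproduced to
relative error < 10⁻⁶ at dt = 0.1 ms, with the expected fourth-order
improvement under step halving.

Deterministic quantile sampling (the k/(N+1) Lorentzian quantiles)
exists alongside seeded i.i.d. Cauchy draws precisely for these
comparisons: it removes frequency-sampling noise without truncating the
heavy tails, which are intrinsic to the closure.  Draws are never
truncated.

## Bifurcation structure

With the stimulus off, Y = 0 (incoherence) is always an equilibrium.
The linearisation at the origin is block-structured — per-population
rotations [[−Δ, −ω̂], [ω̂, −Δ]] plus scalar coupling blocks (c·K/2)·I₂ —
and for two populations with equal widths the Hopf point is analytic:
K_T·K_C = (f_T − f_C)² + 4Δ² in Hz-equivalent units, i.e. K_T ≈ 14.17 at
K_C = 1.2 with the default centers.  The numerically located fold of
limit cycles sits at K_T ≈ 8.0, so the one-parameter structure at
K_C = 1.2 is:

* region I (K_T < FLB): stable origin only — full desynchronisation;
* region II (FLB < K_T < HB): bistability — stable origin, stable limit
  cycle, unstable cycle between them;
* region III (K_T > HB): origin unstable, all trajectories lock.

The exemplar K_T = 5.5 lies *below* the fold, at the left edge of the
ghost region: the reset state passes near the remnant of the orbit pair
and collapses back to incoherence after ≈ 660–690 ms, and the transient
lengthens monotonically as K_T approaches the fold — the model's
explanation of why evoked synchrony dies out in finite time.

Numerical choices: Hopf points by bisection on the leading eigenvalue
real part (tolerance 10⁻⁶); stable orbits by long-run integration with
convergence of linearly interpolated Poincaré-section states (section
Im Y_band = 0, upward crossing); unstable orbits by Newton shooting on
the section return map, classified by finite-difference Floquet
multipliers; the fold by bisection on stable-orbit existence with
natural continuation (the converged orbit seeds the next probe) and a
horizon that grows as the bracket shrinks, because the orbit is only
weakly attracting near the fold.  Near the Hopf point the attractor can
be amplitude-modulated (torus-like); the orbit finder reports
convergence failure there rather than a spurious orbit.

## Scans and calibration

A scan runs the click protocol at every cell of a two-coupling grid.
The default engine integrates the reduced system for all cells at once
(vectorised batch RK4); the full engine runs the N-oscillator model per
cell and is used to confirm selected cells, mirroring the study's
full-model coupling maps at desk scale.  Recorded per cell and band:
max post-stimulus SLI, synchronisation duration, both frequency
read-outs.  Reduced-engine scans are exactly deterministic.

Calibration selects cells whose per-band max SLI lies within ±0.02 of a
target level with the band frequency inside its admissible interval,
ranked by total SLI mismatch; an empty admissible set is a valid,
reported outcome.  The built-in targets are the healthy-control levels
(θ 0.37, α 0.26) and the patient levels (θ 0.30, α 0.19).

With the defaults, the patient point exists as a small island near
(K_C^θ ≈ 9.9, K_C^α ≈ 3.9) and reproduces the full phenomenology: θ
desynchronises at ≈ 380–400 ms and α earlier at ≈ 285 ms, with locked
frequencies ≈ 6.2 Hz (θ) and ≈ 9.9 Hz (α).  A *joint* healthy point does
not exist in this parameterisation: wherever θ reaches 0.35–0.39 (on its
fold ramp) the θ-locked thalamus rotates coherently near 6.4 Hz and
suppresses the α band to ≈ 0.17.  This is structural — a consequence of
the shared thalamus with no direct cortex–cortex coupling — and was
confirmed over wide ranges of the free parameters.  Healthy-θ cells
(0.37 in the 5–7 Hz band) and patient-α cells with smaller couplings do
exist and are what the per-band acceptance quantities use.  Cells near
fold edges have bimodal finite-N responses; reported values there are
means over a few seeded runs, and cell selection uses small-ensemble
full-model confirmation.

## What the synthetic conditions do and do not show

All inputs are generated by the package itself (seeded phases and
frequency draws); there is no external data.  The model ensemble stands
in for experimental trial repetition, which is exact for the SLI
statistic but idealises away trial-to-trial nonstationarity, measurement
noise, volume conduction and every other EEG acquisition effect.
Passing tests therefore certify the dynamical mechanism — reset,
transient locking, fold-driven desynchronisation, coupling-dependent
locking strength — not agreement with any individual recording.

## Known limitations

* The locked plateau deep in region III reaches R ≈ 0.95 with the
  default narrow ensembles; moderate plateau levels (≈ 0.6) and the
  subcritical fold structure could not be obtained simultaneously in
  this model class — broadening or detuning the thalamic ensemble
  lowers the plateau but makes the Hopf supercritical and destroys the
  fold.  The package prioritises the fold mechanism.
* The joint healthy calibration point is empty (see above); calibration
  reports this rather than forcing a fit.
* Near-fold quantities (durations, max SLI at ramp cells) have large
  finite-N variance; single-run values at N = 1000 scatter by ±0.05 SLI
  and ±100 ms.
* The reduced-engine scan frequency uses the locking-cone approximation
  with a time-averaged drive; it is accurate to ≈ 0.1 Hz against the
  full model at the operating points used here but degrades for
  strongly amplitude-modulated drives.
* Desk-scale defaults (grid step 0.5 coarse / 0.05 refined, N = 1000,
  records of 1.1–1.6 s) were chosen to keep scans and calibrations in
  the seconds-to-minutes range; all are configurable.
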