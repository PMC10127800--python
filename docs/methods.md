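# Methods

## The model

`dakinetics` simulates a stimulated-release fast-scan cyclic voltammetry
(FSCV) experiment: electrical burst stimulation of midbrain dopaminergic
neurons evokes dopamine release in the dorsal striatum, the dopamine
transporter (DAT) clears it, and a carbon-fiber microelectrode — itself a
slow, adsorbing sensor — reports the concentration time course. Three
coupled ODEs on `[0, T]` with zero initial state:

```
d[DA]_S/dt = DAP · I · f · S(t) · L − Vm · [DA]_S / ([DA]_S + Km)
d[DA]_E/dt = kS · [DA]_S − kE · [DA]_E + kΓ · Γ_DA
dΓ_DA/dt   = k1ads · [DA]_E − k2ads · [DA]_E · Γ_DA − k3ads · Γ_DA
```

`[DA]_S` is striatal extracellular dopamine (μM), `[DA]_E` the dopamine
concentration seen at the electrode (the FSCV observable), and `Γ_DA`
dopamine adsorbed to the carbon surface. `S(t)` is the burst indicator: a
sum of Heaviside windows, 1 for `NP/f` seconds from each burst onset.
Release during a burst is a continuous source at rate `DAP·I·f·L` — per-pulse
delta functions are deliberately not modelled. The concentration-coupled
desorption term `k2ads·[DA]_E·Γ_DA` is implemented exactly as the model is
written, without reinterpretation.

Assumptions worth keeping in mind: the traces are background-subtracted
(zero baseline, zero initial state, no tonic dopamine); reuptake is a single
Michaelis–Menten pool (no diffusion, no D2 autoreceptor feedback); the
electrode model is linear apart from the adsorption bilinearity; units are
fixed package-wide (s, μM, mA, Hz) and config readers reject unrecognised
keys rather than converting.

## Parameters

| name | units | default | role |
|---|---|---|---|
| `dap` | μM/mA per pulse | 0.67 (WT) / 0.31 (KO) | release per pulse per unit current; genotype-defining, free in fits |
| `vm` | μM/s | 7.4 (WT) / 2.0 (KO) | maximal DAT reuptake velocity; genotype-defining, free in fits |
| `km` | μM | 0.2 | DAT affinity constant (standard striatal scale) |
| `L` | — | 1.0 | dead-space loss factor, (0, 1] |
| `ks`, `ke` | 1/s | 5.0 | electrode transfer in / out |
| `kgamma` | 1/s | 1.0 | rate transfer of adsorption into `[DA]_E` |
| `k1ads` | 1/s | 0.1 | adsorption rate |
| `k2ads` | 1/(μM·s) | 0.05 | concentration-coupled desorption |
| `k3ads` | 1/s | 0.1 | first-order desorption |

The genotype values of `vm` and `dap` are the published fits. The remaining
defaults are this package's declared implementation choices: the source
analysis reports only that the two genotypes differ in `Vm` and `DAP`, not
the values of the fixed electrode/affinity constants it used. Because the
same fixed values are shared by the simulator and the fitter, they cancel
out of every self-consistent recovery experiment; absolute recovered values
of `Vm`/`DAP` would shift if the true fixed constants differed, but the
WT:KO ratios — the scientific claim — are insensitive to that choice in the
noise-free recovery setting. `kgamma`'s dimensional status is ambiguous in
the source ("= 1"); it is implemented as a rate constant of 1 s⁻¹.

The standard protocol is a single burst of 30 pulses at 50 Hz (0.6 s) and
0.4 mA, onset at 1 s (the onset gives the metrics a pre-stimulus baseline
window; the published methods do not state one).

## Numerics

Fixed-step classical RK4 at `dt = 1e-3` s, chosen over adaptive solvers for
bitwise determinism. The discontinuous source is handled by passing each
step the envelope value at the step midpoint, so RK4 stages never mix the
on/off levels when burst edges coincide with grid nodes — true for the
standard protocol — and the integral of the source (total release
`DAP·I·L·NP` per burst) is then exact. The Heaviside convention is
`θ(0) = 1`: point queries of the envelope are 1 at both the onset and
offset instants (affects at most two grid points). Accuracy is audited in
the tests against an independent fixed-step Euler oracle at `dt = 1e-5` s
(sup-norm agreement on `[DA]_E` below 1e-3 μM for both genotype parameter
sets). States can undershoot zero only at rounding level; nothing is
clamped, and a non-finite state aborts with the first bad time point.

The observable is `[DA]_E` sampled at the acquisition rate (default 10 Hz —
a typical FSCV scan repetition rate; the source does not state its own) by
nearest-grid-point selection.

## Trace metrics

* Baseline: mean of all pre-onset samples (traces start at zero in the
  published figures, so this mostly measures noise).
* Peak amplitude: max of (signal − baseline) at/after onset; first maximum
  on ties.
* Clearance half-time t½: time from the peak to the *first* downward
  crossing of `baseline + amplitude/2`, linearly interpolated between the
  bracketing samples. First crossing, because noise can re-cross; linear
  interpolation, because at 10 Hz a grid-snapped t½ would quantise at
  0.1 s — larger than the genotype effects of interest. No smoothing is
  applied before computing t½ (the published analysis does not state any).
* R²: `1 − SS_res/SS_tot` about the observed mean; undefined for a constant
  trace.
* Group contrast: Welch's unequal-variance t-test (two-sided,
  Welch–Satterthwaite df). Degenerate zero-variance groups are rejected by
  `welch_t` itself; the experiment pipeline maps the all-identical
  noise-free case to `t = 0, p = 1`.

## Fitting

Bounded nonlinear least squares on the residual between the recording and
the simulated observable on the recording's grid, via scipy's
trust-region-reflective `least_squares`, optimising in log10 space (the
parameters are positive scale parameters spanning decades). Default free
set: `{vm, dap}` — mirroring the claim that the genotype contrast is
carried by those two parameters; any other free set must be requested
explicitly. Default bounds: `vm ∈ [0.01, 50]` μM/s, `dap ∈ [0.001, 10]`
μM/mA; default start when none is given: the log-space midpoint of the
bounds. Residuals are unweighted (no noise model is reported for the
averaged traces). Tolerances are set tight (1e-12) so noise-free recovery
is limited by the simulator, not the stopping rule; a single deterministic
start makes fits bit-reproducible. Non-convergence is reported in the
result, never raised.

## Synthetic data

No in vivo recordings are deposited, so cohorts are synthesised with the
statistical structure the analysis assumes:

* additive i.i.d. Gaussian measurement noise on the sampled observable
  (default 0.05 μM, ≈2% of the WT peak — the scale at which the published
  averaged fits reach R² = 0.99);
* between-animal variability as a log-normal on the free parameters with
  median at the cohort value and CV 0.1 (log-normal preserves positivity; a
  10% CV is a conservative reading of the published between-animal spread);
* cohort sizes 4 (WT) and 5 (KO), as in the in vivo experiment; 12 s
  recordings at 10 Hz;
* per-animal randomness derived from `SeedSequence(cohort_seed,
  spawn_key=(animal_index,))`, split into a parameter stream and a noise
  stream — growing a cohort never reshuffles existing animals.

What the generator does *not* emulate: electrode drift, pH transients,
non-dopamine faradaic interferents, correlated noise, or calibration error.
A green recovery test therefore establishes self-consistency of the
pipeline (simulate → sample → fit closes on the generating parameters, and
the genotype contrast survives realistic noise and averaging), not that the
model is identified against every real-world artefact.

## Known limitations

* `Vm` and `Km` are strongly correlated when the transient never leaves the
  saturated regime; the default free set avoids this by fixing `Km`, as the
  published analysis did.
* With heavy noise and only 121 samples, the noisy-recovery error on `dap`
  is several times larger than on `vm` (release and amplitude trade off
  against the electrode gain); the tests assert median, not worst-case,
  recovery.
* The continuous-release approximation makes the within-burst rise linear;
  at 10 Hz sampling this is indistinguishable from pulsed release, but the
  full-resolution `[DA]_S` trace should not be over-interpreted within the
  burst window.
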