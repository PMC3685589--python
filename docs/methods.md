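# Methods

## Model

The axon is a uniform cylinder (length L, diameter diam) discretized
into Nseg equal compartments.  Compartment membrane area is
π·diam·(L/Nseg); adjacent compartment centers are coupled by the axial
conductance (π·diam²/4)/(Ra·Δx).  The ends are sealed (zero axial
flux).  Each compartment carries the canonical squid-axon membrane:
maximum conductances GNa, GK (S/cm²), a leak GL, and gating variables
m, h, n obeying dx/dt = k·[αx(V)(1−x) − βx(V)x] with the standard rate
formulas (αm = 0.1(V+40)/(1−e^(−(V+40)/10)), βm = 4e^(−(V+65)/18),
αh = 0.07e^(−(V+65)/20), βh = 1/(1+e^(−(V+35)/10)),
αn = 0.01(V+55)/(1−e^(−(V+55)/10)), βn = 0.125e^(−(V+65)/80); V in mV,
rest near −65 mV).  The temperature coefficient k = Q10^((T−T0)/10)
multiplies all six rates uniformly (Q10 = 3, T0 = 6.3 °C by default).
ENa and EK are Nernst potentials (natural log) of the configured Na⁺
and K⁺ concentrations at the run temperature; with the squid defaults
(Na 440/50, K 20/400 mM) they are +52.4 and −72.1 mV at 6.3 °C.

### Leak equilibrium potential

Because EK follows the concentrations and temperature, no fixed leak
reversal keeps the membrane quiescent in every configuration: the
classic −54.3 mV constant was tuned for EK = −77 mV and, combined with
the Nernst EK = −72.1 mV, yields a net inward current at −65 mV and
spontaneous firing.  By default EL is therefore *balanced at rest*:
EL = Vinit + (INa∞(Vinit) + IK∞(Vinit))/GL, making Vinit an exact
stationary point (−60.43 mV at 6.3 °C with the defaults).  Supplying a
numeric EL (including −54.3) disables the balancing.

## Numerics

Voltages advance by a theta-method on the tridiagonal system obtained
after freezing the channel conductances over the step: Crank–Nicolson
(θ = 1/2, the default) or fully implicit (θ = 1), both unconditionally
stable, solved with a banded LU factorization per step.  Gating
advances first by the exact exponential update
x ← x∞ + (x − x∞)·e^(−k·dt/τx) with rates evaluated at the pre-step
voltage — the usual staggered arrangement up to the initial half-step
offset.  The stimulus is sampled at each step's midpoint; injected
current enters entirely into the compartment containing the electrode.
The removable singularities of αm (V = −40) and αn (V = −55) are
evaluated through an expm1-based rewriting, accurate to machine
precision arbitrarily close to the singular voltage (verified against
50-digit arithmetic to 1e−10 relative error on a 1000-point grid).
Non-finite voltages abort the run with the offending compartment and
time rather than returning corrupted traces.

Accuracy at the default dt = 0.025 ms, checked against an adaptive
stiff reference (Radau, rtol 1e−10, integrated piecewise between pulse
edges so the solver cannot step over a square pulse): peak-voltage
error 0.07 mV and peak-time error 0.025 ms for a single-compartment
suprathreshold step; spike peak time at the measuring point shifts by
< 0.1 ms under dt-halving or Nseg-doubling.

## Electrodes, recording and analysis

The stimulating electrode sits at normalized position 0.1 and the
measuring point at 0.5; both are fixed named constants.  Recorded per
sample: Vm, INa, IK, IL, the capacitive current Icap = Cm·dV/dt (by
centered differences), the total Im = ionic + capacitive (so the
current balance holds by construction), and m, h, n with the derived
open probabilities m³, m³h, n⁴.  Spikes are upward crossings of 0 mV
debounced at 1 ms — HH spikes overshoot 0 mV robustly and inter-spike
intervals at squid temperatures far exceed 1 ms.  Spike width is the
full width at half maximum, with the height measured from the resting
baseline (Vm at t = 0) and the crossings located by linear
interpolation; peak times for velocity measurements are refined by
parabolic interpolation through the three samples around the maximum.

## Default parameters

GNa = 0.12, GK = 0.036, GL = 0.0003 S/cm²; Cm = 1 µF/cm²;
Ra = 35.4 Ω·cm; L = 10000 µm, diam = 500 µm, Nseg = 101 (odd, so a
compartment center sits exactly at the measuring point); dt = 0.025 ms,
ts = 60 ms, T = 6.3 °C, Vinit = −65 mV.  The default stimulus (one
0.2 ms, 12000 nA pulse at 1 ms, about 3× rheobase for that pulse shape
on the default axon) demonstrates a single propagated spike.

## Scenario calibration

The worked scenarios express amplitudes as multiples of the rheobase
for the pulse shape in use, found by geometric bisection to 1%:

- *frequency* and *temperature* use 3× the brief-pulse (0.2 ms)
  rheobase.  The refractory counts (4 spikes at tintp = 13 ms, 2 at
  5 ms, T = 6.3 °C) are insensitive to this choice across the whole
  2.5–10× range; 2× is already inside the relative-refractory margin
  and drops the fourth spike.
- *amplitude* uses a 50 ms step at (0.5, 1.05, 4, 8)× the long-step
  rheobase, landing in the subthreshold, single-spike and repetitive
  regimes (counts 0, 1, 3, 4 with the defaults).  At 6.3 °C the
  single-spike regime of the HH membrane extends well past rheobase,
  so the repetitive amplitudes sit at 4× and above.

## Scope of the default geometry

With the default L = 1 cm and λ = 1.085 cm, the axon is electrically
compact: it fires nearly synchronously, which is the intended regime
for the spike-counting and spike-width scenarios but leaves no
traveling wave to time.  Conduction-velocity measurements therefore use
a long axon (L = 10 cm), where the measured velocity is 12.9 m/s at
6.3 °C for diam = 500 µm and scales as √diam (×2.04 at 4× diameter) —
distinct from the passive heuristic v = 10·λ/τ, which is reported
alongside and not reconciled with it.

## Limitations

Single unbranched cylinder; no myelin, synapses, extracellular fields
or concentration dynamics; ideal square current pulses only; fixed
electrode positions.  Ionic concentrations are constant in time, so
long high-frequency trains do not deplete gradients as real axons
would.  The gating-rate formulas are fixed at the squid formulation;
other channel families are out of scope.
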