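# qcest

Deuteron (spin-1) quadrupolar **C**hemical **E**xchange **S**aturation
**T**ransfer under magic-angle spinning: a simulator and fitting library for
slow molecular motions in rotating solids.

## The problem

Slow conformational dynamics (rate constants ~5·10² – 5·10⁶ s⁻¹) in solids —
side-chain rotamer flips, transient domain binding in amyloid fibrils —
are invisible to lineshape analysis but leave a clear fingerprint in a CEST
experiment: a weak RF field (ω_RF/2π ≈ 1–5 kHz) saturates the spectrum at a
resonance offset Ω, exchange carries the saturation between conformations,
and the surviving longitudinal magnetization I(T)/I(0), scanned over offsets
spanning the whole quadrupolar pattern (±60 kHz for methyl deuterons), maps
out both the spectra of all exchanging states and the exchange kinetics.
Under MAS, additional intensity dips — *rotary resonances* — appear whenever
|Ω| = n·ω_MAS/2 (the half-integer condition is the analogue of the HORROR
recoupling condition); their width and depth are themselves sensitive
reporters of exchange.

## The model

The spin-1 density matrix is expanded in eight trace-orthonormal operators
(single-quantum Ŝx, Ŝy, Ĵx, Ĵy; double-quantum Ĵz, K̂; Zeeman order Ŝz;
quadrupolar order Q̂), taken in direct product with N exchanging sites.  The
evolution during saturation follows the Liouville–von Neumann equation with
the tilted-frame secular Hamiltonian

    Ĥ = √(2/3)·ω_Q(t)·Q̂ + √2·ω_RF·Ŝx + √2·Ω·Ŝz,

where the site-specific ω_Q(t) is the MAS-modulated secular quadrupolar
frequency of an arbitrarily oriented tensor (C_q, η), exchange enters as a
kinetic generator coupling identical coherences across sites, longitudinal
relaxation is a phenomenological T1 with a Bloch–McConnell-style return of
Ŝz to its site equilibrium, and the propagator over one rotor period is a
time-ordered product of 20 per-step matrix exponentials (exchange and
coherent parts exponentiated together).  Saturation for arbitrary T uses
powers of the rotor-period propagator plus a fractional-period factor.
Detection rotates each site's Ŝz to the transverse plane, evolves only the
single-quantum coherences, and integrates the spectrum in windows of one
rotor frequency per spinning sideband.  Profiles are powder averages over
deterministic orientation sets and weighted averages over the measured RF
inhomogeneity distribution of the probe coil.

Model builders included: two-site rotameric flip (DMS), fast methyl
three-site jumps (explicit or pre-averaged: C_q 165.9 → 55.3 kHz on the
109.47° cone), and 192-site sphere diffusion plus a rigid bound state
(amyloid fibril N-terminal domain).  A Redfield-type calculator maps the
methyl jump rate k₃ to the deuteron T1 (and back) from quadrupolar spectral
densities of the jump correlation functions.  Fitting is a grid search
minimizing the mean absolute difference between measured and simulated
profiles, with the full objective surface and a (D, k_ex) correlation-ridge
diagnostic as outputs.

## Worked example

Simulate a no-motion ²H CEST profile around the first half-integer rotary
resonance and locate the dip:

```python
import numpy as np
from qcest import (ExchangeNetwork, ExperimentParams, QuadrupolarTensor,
                   Site, simulate_cest_profile)

net = ExchangeNetwork([Site(QuadrupolarTensor(cq=55.3e3), 1.0)], np.zeros((1, 1)))
params = ExperimentParams(rf_hz=1300.0, offset_hz=0.0, mas_hz=25e3)
offsets = np.arange(10e3, 15e3 + 1, 250.0)
prof = simulate_cest_profile(net, params, offsets, sat_times=[3e-3], powder_n=300)
print(prof.offsets_hz[prof.intensities[0].argmin()] / 1e3, prof.intensities[0].min())
```

prints

```
12.5 0.2384122559439513
```

— the saturation dip sits exactly at ω_MAS/2 (12.5 kHz at 25 kHz spinning),
with the normalized intensity dropping to 0.24 while neighbouring offsets
stay above 0.95.  The T1 ↔ k₃ map:

```python
from qcest import t1_three_site_jumps
print(t1_three_site_jumps(165.9e3, k3=4.9e9, larmor_hz=115.1e6) * 1e3)
```

```
40.92113510417795
```

i.e. a 41 ms deuteron T1 at 17.6 T for methyl jumps at 4.9·10⁹ s⁻¹.

A CLI covers the same ground (`qcest simulate-profile`, `simulate-spectrum`,
`rcest`, `t1`, `nutation-profile`, `make-fixture`, `fit-grid`); see
`qcest --help`.

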