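# Methods

## State space and operator conventions

The spin-1 density matrix is expanded in eight Hermitian, traceless,
trace-orthonormal operators: Ŝx, Ŝy, Ĵx, Ĵy (single quantum), Ĵz, K̂ (double
quantum), Ŝz (Zeeman order) and Q̂ (quadrupolar order).  Orthonormality
Tr(Ôᵢ Ôⱼ) = δᵢⱼ fixes the prefactors (1/2 on the single-quantum set, 1/√2 on
Ĵz, K̂, Ŝz, 1/√6 on Q̂) and thereby the tilted-frame Hamiltonian coefficients

    Ĥ = √(2/3)·ω_Q·Q̂ + √2·ω_RF·Ŝx + √2·Ω·Ŝz ,

which is verified in the tests against the conventional-operator construction
Ĥ = (ω_Q/3)(3Îz² − 2·1) + ω_RF·Îx + Ω·Îz to 1e−12.  With exchange the state
is the direct product {8 coherences} × {N sites} plus one constant unit slot;
the inhomogeneous equilibrium-return term for Ŝz (see below) then becomes a
column of an augmented generator and the whole evolution a single matrix
exponential per time step.

Conventions, used consistently everywhere:

* ZYZ Euler angles, active rotations; magic angle = acos(1/√3).
* Frequencies are rad/s internally, Hz at every public interface.
* Positive Ω places the carrier above the ²H Larmor frequency.
* The kinetic matrix K is column-stochastic-like: K[i,j] ≥ 0 is the rate
  j → i and columns sum to zero, so K·p_eq = 0; all built-in models satisfy
  detailed balance.  k_ex denotes the *sum* of forward and reverse rate
  constants (two-site flip: k_ex = 2·k_flip at equal populations; bound
  state: k_ex = k_on + k_off with k_on/k_off = p_bound/(1 − p_bound)).

## Quadrupolar frequency under MAS

For an axially symmetric tensor aligned with its crystallite frame,

    ω_Q(t) = (3π/4)·C_q·[ −√2 sin2β cos(ω_MAS t + α) + sin²β cos(2ω_MAS t + 2α) ],

derived from (and tested to 1e−9 against) the explicit second-rank rotation
crystallite → rotor → lab with the magic-angle tilt.  The first-harmonic
coefficient is √2 — this and the phase origin of α follow from the rotation
composition Ry(θ_m)·Rz(ω t)·Rz(α)·Ry(β); only the (physically immaterial)
azimuth origin distinguishes equivalent printed forms.  Tensors with η > 0 or
a tilted principal-axis system are always handled by the explicit rotation
route; with ω_MAS = 0 the orientation angles are read as the polar
coordinates of B₀ in the crystallite frame and no tilt is applied.

## Propagation through the saturation period

The rotor period is divided into n_rotor_steps = 20 sub-steps; within each,
ω_Q is frozen at its mid-step value (mid-point quadrature — the sample point
is validated against 100- and 2000-step references; powder-averaged
saturation observables agree to ~1e−4 even at ω_MAS/2π = 1 kHz, per-
crystallite values to ~1e−3 at 25 kHz).  Exchange and coherent parts are
exponentiated together in each sub-step — no operator splitting.  Saturation
over time T applies the ⌊T·ω_MAS/2π⌋-th power of the rotor-period propagator
followed by a fractional-period factor built from the same sub-steps.
Matrix exponentials are evaluated batched over crystallites.

Longitudinal relaxation is phenomenological: a −1/T1 decay applied by default
to all eight coherences of every site (a switch restricts it to Ŝz), plus the
constant drive returning each site's Ŝz to its equilibrium population.  With
ω_RF = 0 this reproduces Sz(t) = eq + (Sz(0) − eq)·e^(−t/T1) exactly, and
without RF and T1 the secular engine conserves total Zeeman order — CEST
saturation strictly requires the RF field.  The equivalence of this
phenomenological treatment with an explicit fast-methyl-jump frame is tested:
a two-site flip built on the cone-averaged tensor (C_q 165.9 → 55.3 kHz at
109.47°) plus T1 matches the six-site flip ⊗ three-site-jump model carrying
the static tensor (same T1) within 0.2% of normalized intensity.  Note the
explicit fast frame inside a secular Liouvillian supplies tensor averaging
but cannot *generate* T1; the T1 value itself comes from the Redfield
calculator below.

## Detection and band intensities

An ideal 90° pulse converts each site's Ŝz amplitude into Ŝx; the FID is
propagated in the closed single-quantum subspace (no RF, carrier at the
isotropic position) with time step = rotor period / 20 (or the user dwell if
smaller), 2048 points by default.  The spectrum is the real part of the FFT
after exponential apodization (default 500 Hz, chosen so the default FID
length decays to ~2e−3 — narrower apodization on a truncated FID spreads
ringing across band windows) with first-point halving and a ×2 rescale, so
the integral over all frequencies equals Re FID(0) exactly (Parseval).  Band
intensities integrate the signed real spectrum over windows of one rotor
frequency centred at n·ω_MAS/2π; the windows partition the spectral width, so
central + Σ sidebands = total holds to machine precision.  Every profile
point is normalized by a matched T = 0 computation through the identical
pipeline (same orientations, same windows), which cancels pipeline artifacts
such as apodization tails.  For all-bands mode the total equals the
site-summed Ŝz by Parseval.

A measured consequence worth knowing: central-band and all-bands profiles of
the two-site flip model are *not* identical — at k_flip = 9000 s⁻¹, 25 kHz
MAS, ω_RF/2π = 1.3 kHz, T = 3 ms the pointwise difference reaches ~4% at
rotary resonances (mean absolute difference 1.4%), stable against detection
resolution, i.e. genuine differential saturation across the powder rather
than a processing artifact.

## Powder and RF-inhomogeneity averaging

Powder sets are deterministic (golden-section spiral by default; a Fibonacci
variant and a sin β-weighted product grid are provided) — no RNG, so profiles
are bit-reproducible and independent of execution order.  RF inhomogeneity is
a distribution of scale factors s = ω_RF/⟨ω_RF⟩: the two probe coils ship as
built-in six-point grids at s = 0.25…1.5 (weights 0.084, 0.143, 0.126, 0.176,
0.285, 0.187 for the 1.3 mm coil and 0.065, 0.097, 0.103, 0.236, 0.499, 0 for
the 2.5 mm coil); a 30-point grid is obtained by five-fold uniform
subdivision of each six-point bin (exactly mean-preserving) and is used for
|Ω|/2π < 2 kHz where coherent oscillations are strongest.  A ±0.5 kHz
five-point scheme is available as a cheaper alternative.  Nutation decays are
converted to profiles by mean-subtraction, Hann windowing, ×4 zero-padded
Fourier magnitude, a 5%-of-maximum floor, and rescaling by the weighted-mean
frequency; ⟨ω_RF⟩ is reported as the field strength.  Inhomogeneity averaging
raises the apparent intensity at strongly saturated offsets relative to a
homogeneous-field simulation (the homogeneous field overestimates
saturation), which the tests assert.

## R_CEST and the T1 ↔ k₃ map

R_CEST is a least-squares fit of A·e^(−R·T) to the all-bands intensity over
T = 0.25–128 ms (A free); decays with relative fit rms above 5% are flagged
non-exponential (powder decays are intrinsically multi-exponential, so flags
at strong saturation are expected and honest).  For the two-site 106° model
at Ω/2π = 10 kHz and 25 kHz MAS, R_CEST versus k_ex is unimodal with the
half-maximum window ≈ 4·10⁴ – 8·10⁵ s⁻¹ and the maximum near 2·10⁵ s⁻¹.

The deuteron T1 from methyl three-site jumps is computed outside the secular
engine from Redfield-type spectral densities:

    1/T1 = (π C_q)² [ ½ (J₊₁ + J₋₁)(ω₀) + 2 (J₊₂ + J₋₂)(2ω₀) ],

with J_m the cosine transforms of the lab-frame rank-2 EFG fluctuation
correlation functions.  The default route evaluates the correlation functions
numerically from expm of the jump generator on a time grid and integrates;
a closed form (the symmetric three-site generator has a single relaxation
eigenvalue 3k₃, so every J_m is one Lorentzian) agrees to <1% and powers the
fast inverse map T1 → k₃ (Brent root finding on the fast-motion branch).
1/T1 is powder-averaged, then inverted.  The overall constant was fixed from
the second-order master equation and cross-validated against a brute-force
stochastic-jump density-matrix simulation (agreement ~4%, at the Monte-Carlo
noise level).  MAS corrections to T1 are not modelled.

## Fitting

Grid search over named model-builder axes; the objective is the mean absolute
|I_data − I_sim| pooled over all (offset, saturation-time) points, averaged
over datasets for a global fit.  Data offsets match simulated ones by nearest
neighbour within 50 Hz, else linear interpolation.  Ties break toward the
smallest parameters in axis order.  The full objective surface is returned —
minima are shallow and (D, k_ex) are positively correlated (fast diffusion
narrows the pattern, slow exchange widens it), which the correlation
diagnostic exposes as the ridge k_ex*(D).  Node simulations are cached by
(parameters, acquisition settings), so per-dataset fits, global fits and
noise-replicate studies reuse each other's work.

## Synthetic data

The fixture generator simulates a configured model and adds i.i.d. Gaussian
noise (σ default 0.01, clipped at zero intensity), writing generator
parameters and seed into the file header; identical (config, seed) gives
byte-identical files.  It emulates the two-saturation-time, ±60 kHz CEST
design used throughout.  What it does not emulate: probe detuning drifts
(the reason measured offsets are acquired in randomized order),
temperature instability, t-noise correlations, or imperfect 90° detection
pulses — so passing recovery tests demonstrates estimator correctness under
the stated noise model, not robustness to systematic experimental error.

## Default problem sizes

Library defaults aim at production use (300–3000 crystallites, 6/30-point RF
grids).  The test-suite and acceptance runs use reduced sizes chosen once for
convergence of the asserted quantity: 24–128 crystallites for profile
contrasts (profile values converge to ~1e−3 by n ≈ 100), 100 crystallites ×
25 log-spaced k_ex nodes for the sensitivity window, 256 crystallites for T1
(converged to ≪1%), and a 12-surface-site sphere for fibril-type recovery
demonstrations.  The sphere discretization calibrates per-edge rates D/d² so
the initial-slope rank-2 relaxation equals exactly 6D; eigenvalue clusters
then sit within 5% of l(l+1)D for l = 1, 2 (individual eigenvalues spread
±12% on the spiral grid — a known anisotropy of the construction).

## Known limitations

Second-order quadrupolar shifts, chemical-shift anisotropy, dipolar
couplings and relaxation from non-secular quadrupolar fluctuations are not in
the Liouvillian (T1 is phenomenological); nutation-pulse quadrupolar
evolution and rotor-phase-dependent radial RF inhomogeneity are not
modelled; the ensemble-of-D fibril model is out of scope (single-D two-state
model only).  The bound-state tensor orientation is a single fixed axis
(z of the crystallite frame) — the experiment does not constrain it, and
binding is assumed to erase orientational memory.
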