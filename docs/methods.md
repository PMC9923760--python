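# Methods

`chlorosim` simulates the Qy exciton band of chlorosome-like tubular
BChl c aggregates: it builds a synthetic tubular lattice, dresses it with
calibrated static and dynamic disorder, assembles the time-dependent
Frenkel Hamiltonian, propagates wavefunctions numerically (NISE) and
computes linear absorption, zero-waiting-time two-dimensional electronic
spectra (2DES) and exciton delocalization statistics.

## Model

### Exciton Hamiltonian

The single-excitation Frenkel Hamiltonian in the site basis is

    H(t) = sum_n [w0 + dW_n(t)] B_n^+ B_n + sum_{m!=n} J_mn(t) B_m^+ B_n

with `w0 = 15390 cm^-1` (monomer Qy in methanol) and the environmental
shift `dW_n(t)` supplied either directly by the disorder generator or from
ground/excited partial-charge tables via the intermolecular Coulomb sum
(20 Å Mg–Mg cutoff).  Couplings use the point-dipole approximation between
Mg centres with `mu = 5.48 D` and no dielectric screening.  The coupling
strength `S_n(t) = sum_m J_nm(t)` characterizes each molecule's total
excitonic environment; its negative ensemble mean (~ -1350 cm^-1) marks
J-aggregate behaviour.  Unit prefactors (5034.12 cm^-1 Å^3 D^-2 for
dipole–dipole, 116141 cm^-1 Å e^-2 for Coulomb) are derived from CODATA
constants in `constants.py` and unit-tested against hand values.

### Tube geometry

The aggregate is three concentric cylinders rolled from an oblique lattice
(a = 1.48 nm, b = 0.98 nm, gamma = 124.3 deg) at chiral angle
delta = 49.6 deg, radii 5.2/7.3/9.5 nm, length 120 nm (27678 sites in our
construction; a 35-nm window of the middle tube, 2668 sites, is the
spectroscopy subsystem).  Two molecules per cell: *syn* at the cell origin
and *anti* at half a cell diagonal, so rows along `b` are syn–anti
alternating zigzag stacks (nearest Mg–Mg distance 0.616 nm).  This basis
choice is load-bearing: with the anti molecule instead placed in a
separate column, nearest-neighbour couplings are far weaker and the
simulated band comes out ~25% too narrow.

Because `2*pi*R` is generally not a lattice translation, the wrap vector
is snapped to the closest integer lattice vector compatible with the
chiral angle and the effective radius rescaled so the seam closes exactly
(e.g. 7.3 -> 7.266 nm); every adjustment is reported.

The in-plane dipole angle (the N_A->N_C axis direction relative to the
lattice) is not fixed by the lattice constants, so it is calibrated once:
-8.3 deg from the `a` axis gives a bulk-tube mean coupling strength of
-1352 cm^-1 and predominantly axial dipoles (mean |mu_z| = 0.85),
consistent with the strong axial polarization of tubular BChl aggregates.
A second solution of the calibration (-89 deg) was rejected for its less
axial polarization and weaker bright-state coherence.

### Disorder generator

Site energies: per-class mean + one frozen Gaussian draw (static
disorder) + independent stationary Ornstein–Uhlenbeck components, using
the exact OU update (no Euler bias at any step size).  Defaults:

| component | sigma (cm^-1) | tau (fs) |
|---|---|---|
| static | 410 | frozen |
| slow | 230 | 1200 |
| fast | 185 | 50 |

Class means: syn 620, anti 611 cm^-1; hydrogen-bond donors +114,
non-donors -266 cm^-1 about the conformer mean.  The donor/non-donor
split (380 cm^-1) is a calibrated parameter: it reproduces the ~40 cm^-1
separation between the projected donor and non-donor absorption
components (we measure 47 cm^-1) while inflating the total site-energy
spread only mildly (541 vs the 510–514 cm^-1 class spreads).  Donor labels
(70%) are assigned in seeded contiguous runs along stacks (mean run 7
sites), mimicking static hydrogen-bond chains; the global count is
corrected to round(0.7 N) ± 1 by flipping run-boundary sites.

Dipole wobble: each unit dipole diffuses in its local tangent frame with
two OU tilt angles (correlation time 150 fs), confined by a per-class cone.
The exposed cone half-angle maps onto the Gaussian tilt amplitude through
the wobbling-in-cone order parameter `S = cos(t)(1+cos(t))/2` via
`<P2> = 1 - 3 s^2`; the long-time plateau of the renormalized orientational
correlation function `(2/5)<P2(cos Theta(t))>` is then `0.4 S_eff^2`.
Defaults (donor cone 4.84 deg, non-donor 1.25x larger) are calibrated so
the 70:30 ensemble plateaus at 0.395; donors are visibly more restricted
than non-donors.  An optional underdamped low-frequency modulation
(default off, 2 ps period) superimposes a coherent twist without changing
the plateau.

Packing disorder: a frozen Gaussian jitter of the Mg positions
(sigma = 0.045 nm), calibrated so the static coupling-strength spread is
~155 cm^-1; the 1/R^3 nonlinearity then skews the coupling-strength
distribution toward strong coupling, which is what skews the absorption
band's high-frequency flank.  Orientational wobble supplies the dynamic
off-diagonal components (~40–60 cm^-1 on 100–200 fs scales); they are
emergent, not imposed.

All randomness flows from one master seed through counter-based (Philox)
per-site streams, so trajectories are bit-reproducible and adding sites or
frames never correlates existing streams.

### What the generator does and does not emulate

The generator reproduces the target *single-site* statistics: class means
and spreads, the static + two-exponential autocorrelation decomposition
(round-trip fits recover all parameters within 15%), the orientational
plateau, and the off-diagonal static spread.  It deliberately draws the
static field independently per site.  Real structural disorder is
spatially correlated (neighbouring molecules share a local environment);
an iid field with the same variance localizes band-edge excitons somewhat
more strongly.  Two observable consequences, documented here because the
package's own tests exercise them:

* the brightest exciton state carries |mu_exc|/mu_site ~ 7–9.5 (seed
  dependent), i.e. coherence over ~50–90 molecules, at the low end of
  what structurally correlated disorder supports (> 10, i.e. > 100
  molecules);
* in 2DES at the reduced system size, the excited-state-absorption signal
  splits between a near-diagonal derivative-like lobe (from the most
  delocalized states, whose Pauli shift is tiny) and a displaced lobe at
  ~ +450–650 cm^-1; the global-extremum slice metrics then fluctuate
  strongly between realizations (separations ~130–480 cm^-1, intensity
  ratios ~0.3–0.7) instead of settling on a single displaced peak.

Passing tests therefore validate the site-statistics contract and the
spectroscopy machinery; they do not imply the iid field reproduces every
collective observable of spatially structured disorder.

## Spectroscopy

### Propagation (NISE)

The Hamiltonian is held constant within each trajectory frame (default
4 fs) and the wavefunction advanced by the exact per-frame unitary;
longer intervals are time-ordered products.  Small systems use an
eigendecomposition per frame, large ones an adaptive Lanczos exponential
(full reorthogonalization; tolerance 1e-10 default, 1e-7 in spectra
hot paths with complex64 arithmetic).  Unitarity and the composition
property hold to 1e-9–1e-10; both backends satisfy the same tolerance.

Doubly-excited states use the hard-core pair basis |ij>, i<j (no double
occupation).  A pair amplitude is stored as a symmetric N x N matrix with
zero diagonal; the Hamiltonian action `(eps_i+eps_j) C + J C + (J C)^T`
with a zeroed diagonal is algebraically identical to the pair-basis matrix
and costs one dense matrix product per application.  The implementation is
verified against explicit pair-basis enumeration, dense matrix
exponentials, and (for the full 2DES observable) an independent
sum-over-states calculation with complete two-exciton diagonalization on a
108-site system (agreement 6e-3 of the peak).

### Linear absorption

`I(w) ~ Re Int dt e^{iwt} <mu(t) . U(t,0) . mu(0)>`, evaluated in a
rotating frame at the mean site energy, averaged over 10 staggered
configurations of a 10-ps trajectory and the three Cartesian components
(analytic isotropic average), truncated at a 128-fs coherence time.
Apodization multiplies the time-domain response by
`exp(-t/(2 tau_homo))` (Lorentzian, tau_homo = 300 fs) and
`exp(-t^2/(2 tau_inh^2))` (Gaussian, tau_inh = 166 fs); both factors are
configurable since other conventions exist.  The response is zero-padded
and resampled to a fixed 1 cm^-1 grid; widths are measured by linear
interpolation between half-maximum crossings.  Mesoscale disorder (the
ensemble of tube radii and orientations) is a final frequency-domain
Gaussian convolution (sigma = 200 cm^-1), intensity-conserving, applied at
reporting time.  The 1350 cm^-1 red shift used when overlaying experiment
is a display-stage axis shift and never enters the Hamiltonian.
Subensemble projections restrict the detection dipole to a site mask;
complementary masks sum to the total spectrum exactly.

### 2DES at zero waiting time

The absorptive map sums rephasing and nonrephasing ground-state-bleach,
stimulated-emission and excited-state-absorption pathways at t2 = 0, with
the ESA ket propagated in the hard-core pair basis (matrix-free Lanczos)
and apodization applied along both coherence axes.  Coherence times extend
to 192 fs; the response is sampled every 8 fs in the rotating frame
(sampling bandwidth 4170 cm^-1, comfortably covering the optically active
band) while propagation keeps the 4-fs step.  Bleach is positive, ESA
negative, and the output map is normalized to unit peak |amplitude|.

Isotropic parallel (ZZZZ) polarization is approximated by drawing one
random lab polarization per disorder configuration (seeded).  The analytic
isotropic average would require nine distinct two-exciton propagations per
coherence origin (one per Cartesian index pair on the second/third
interactions), a ~9x cost; orientation sampling converges to the same
average with the configuration count and is the only affordable option at
these sizes.  This is the one intentional deviation from the analytic-
average design used for linear absorption.

Slices and metrics: the pump–probe spectrum integrates the map over the
pump axis (trapezoidal); vertical slices interpolate between pump grid
lines at the bright-state pump frequency (or any requested one), the
diagonal slice at w1 = w3.  Extrema are refined by a 3-point parabolic
fit; the fwhm refers to the dominant positive (GSB/SE) feature; curves
lacking a negative extremum return partial metrics rather than failing.

### Exciton statistics and the delocalization length

Snapshots are fully diagonalized; per state we report energy,
participation number `1/sum_i |c_ni|^4` (optionally averaged over a
frequency window — both the per-state and spectrally weighted variants are
exposed), donor character `sum_i donor_i |c_ni|^2`, transition dipole
`mu_exc = sum_i c_ni mu_i` and oscillator strength.  Energy profiles use
fixed-width bins (default 50 cm^-1) weighted by state count.

The exciton delocalization length implied by 2D observables follows the
nearest-neighbour-chain relation between the ESA blue shift and the
effective coupling,

    blue_shift = |S| [cos(pi/(EDL+1)) - cos(2 pi/(EDL+1))],

i.e. the standard `2 J_eff [cos ...]` chain form with per-bond coupling
`J_eff = |S|/2`; the large-EDL limit is `3 pi^2 J_eff/(EDL+1)^2`.  Solved
continuously (bisection) and rounded for a molecule count:
EDL(1350, 350) = 6.26 -> ~6 and EDL(1350, 550) = 4.64 -> ~5.  The inverse
returns both |S| and J_eff; the coupling a 200-molecule delocalization
would demand at a 350 cm^-1 shift is J_eff ~ 4.8e5 cm^-1 (|S| ~ 9.6e5),
orders of magnitude beyond molecular couplings — the quantitative form of
the argument that the chain relation underestimates delocalization in
tubular aggregates.  Note the two conventions differ by exactly a factor
2 in the inverse; we quote J_eff when comparing with chain-model
literature values.

## Problem sizes and runtimes (single CPU)

* geometry builds: seconds (27678 sites).
* linear absorption: 2668-site subsystem, 2500 frames (10 ps), 10
  configurations — ~1.5 min.
* snapshot diagonalization (2668 x 2668): ~5 s.
* 2DES: aspect-preserving scale-down of the subsystem tube (R = 2.6 nm,
  L = 12 nm, 326 sites), 3 disorder configurations — ~10 min.  The
  two-exciton guard refuses > 600 sites unless raised explicitly.
* orientational plateau: 510 sites, 5 ps — ~1 min.

These sizes are the package's defaults for its own reproduction runs;
all are configurable.

## Numerical choices and degenerate inputs

* Frequency grids: fixed 1 cm^-1 output grid (linear absorption) via
  zero-padding + interpolation; 2D maps on the FFT grid (~8 cm^-1) with
  sub-grid extremum refinement.
* Couplings and pair data are float32 (the coupling matrix of 2668 sites
  is 28 MB); wavefunctions complex64 on hot paths, complex128 elsewhere.
  All tolerance-sensitive identities (sum rules, unitarity) are tested at
  the appropriate precision.
* Multiexponential ACF fits: bounded least squares with a deterministic
  multi-start grid of time constants (10 fs – 5 ps, log-spaced), lags
  truncated at 1/3 of the trajectory, components reported slowest first,
  non-convergence flagged in the result.  The static term is the fitted
  additive constant (the plateau-readout alternative is noted in the
  docstring).
* Degenerate inputs: zero-length tubes, empty masks (warn + zero
  spectrum), constant series (flagged zero ACF), flat curves and
  single-site 2DES (no ESA) are all defined behaviours with tests.
* Determinism: every stochastic element is a pure function of
  (parameters, seed); rebuilding bit-identically is tested.

## Known limitations

* Point dipoles only — no extended-dipole or transition-charge couplings,
  no dielectric screening.
* No intramolecular vibronic coupling, charge-transfer states, Qx/Soret
  bands, finite waiting times, or exciton transport.
* The iid static-disorder field's consequences for collective observables
  (above).
* The atomistic path (XYZ frames + charge tables through the Coulomb
  shift) is exercised with small synthetic fixtures only.
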