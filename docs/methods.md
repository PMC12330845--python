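# Methods

`reffmap` maps the effective intra-axonal radius r_eff from ultra-high-b
pulsed-gradient spin-echo (PGSE) diffusion MRI, and provides the synthetic
data, preprocessing, correction, and statistics machinery needed to validate
every stage at desk scale. This note records the models, the numerical
choices, and the known limits of what the synthetic experiments demonstrate.

## Signal model

White matter is modelled as impermeable parallel cylinders with intrinsic
axoplasmic diffusivity D0 = 2.0 um^2/ms (the standard value for tissue at
37 C, configurable). At b >= 7 ms/um^2 extra-axonal water is assumed fully
suppressed, so the powder-averaged (spherical-mean) signal of a stick
(zero-radius cylinder) follows the power law

    S_bar(b) = beta * b^(-1/2),

with beta absorbing the axonal water fraction and parallel diffusivity. A
finite radius adds a small radial diffusivity Da_perp, turning the decay into

    S_bar(b) = beta * b^(-1/2) * exp(-b * Da_perp).

In the long-pulse (Neuman) regime delta >> r^2/D0, Da_perp maps to the
tail-weighted effective radius

    r_eff = ((48/7) * delta * (Delta - delta/3) * D0 * Da_perp)^(1/4),

which for a radius distribution equals (<r^6>/<r^2>)^(1/4) in the
small-attenuation limit (r^2 volume weighting times the r^4 attenuation
sensitivity).

### Cylinder forward models

Three perpendicular-signal implementations are provided and cross-validated:

1. **Neuman closed form** `exp(-2 kappa r^4)` with
   `kappa = (7/96) (gamma g)^2 delta / D0`, valid for `delta*D0/r^2 >> 1`.
2. **van Gelderen Gaussian-phase series** (`gpa_cylinder_perp`), finite
   pulses, roots of J1'; accurate at weak-to-moderate dephasing. At strong
   dephasing (r ~ 5 um at the b=30 gradients) the second-cumulant
   approximation overestimates the signal by tens of percent.
3. **Matrix formalism** (`mcf_cylinder_perp`): exact propagation of the
   Bloch-Torrey equation in the Neumann-Laplacian eigenbasis of the disk
   (cosine sector, default 88 modes, eigenvalues from roots of Jn'). This is
   the reference model used for ensemble signal synthesis; it agrees with a
   2-D reflecting random walk (2e5 walkers, 2e4 steps) to well under 1% of
   the unattenuated signal at all radii tested (1-5 um, both protocol
   configurations).

**A factor-of-two convention.** The attenuation constant under which the
published detectability bounds are defined is kappa = (7/96) (gamma g)^2
delta / D0 with `ln S = -kappa r^4`; the actual long-pulse limit of the
series/matrix/Monte-Carlo models is `ln S = -2 kappa r^4`, i.e. a (7/48)
constant — the same constant implied by the r_eff mapping above. The package
keeps both deliberately: all signal physics and fitting use the (7/48)-
consistent models, while `neuman_kappa`/`resolution_limit` keep the (7/96)
convention so the detectability bounds come out on the published scale
(kappa as half the mean-squared phase). The test suite pins the relationship
(`ln S_GPA -> -2 kappa r^4`) so the convention cannot silently drift.

### Monte-Carlo oracle

The random walk simulates the 2-D cross-section only (the parallel component
factors out analytically). Steps are dichotomous (+/- sigma per axis,
sigma = sqrt(2 D0 dt)) with an inline xorshift64* generator and radial-mirror
reflection; after thousands of steps this converges to Brownian motion and
is ~30x faster than per-step Gaussian draws, which makes the full-scale
oracle affordable inside the test suite. Phase is accumulated during the two
gradient lobes with a midpoint-rule waveform.

### Detectability (resolution) limit

The smallest detectable radius solves `kappa r^4 = z * sigma_sm` with
spherical-mean noise `sigma_sm = 1/(SNR*sqrt(n_dir))`: attenuation must
exceed z times the noise of the spherical mean. Defaults: SNR=20 at b=0, 60
directions, two-sided 99% z = 2.576 (configurable). With the nominal 300
mT/m amplitude and delta = 18.8 ms this gives 1.39 um; with 200 mT/m and
delta = 21.4 ms, 1.65 um. The rule uses the nominal (not b=30-realising)
gradient amplitude; z and the amplitude convention are interpretive choices
documented here because the threshold rule behind the published bounds is
not fully specified.

## Synthetic data

The phantom is a geometric head: a WM ellipsoid core carrying six
left/right-symmetric parcel pairs, a GM shell, and a central CSF blob, with
smooth posterior-probability maps supporting the masking thresholds
(WM > 0.55, GM > 0.8, CSF > 0.9). Per voxel the WM ensemble is a gamma
radius distribution (default shape k = 2, scale s = 0.35 um, truncated to
radii 0.25-5 um, i.e. diameters 0.5-10 um) with cross-section (r^2) signal
weighting; parcels step s over 0.8-1.3x and one pair carries a built-in 5%
left-right asymmetry. Fiber orientations vary smoothly and are dispersed
with a Watson distribution (concentration 16); the powder-averaged estimator
is dispersion-invariant by construction, so dispersion only affects
direction-resolved realism.

Sessions evaluate the tissue mixture per volume at the locally achieved
gradient (amplitude and direction from the coil model), multiply by a smooth
random polynomial phase (order <= 3, amplitude <= pi over the FOV), and add
independent complex Gaussian channel noise with sigma = (mean WM b=0
signal)/SNR (a single global noise level so background statistics are
meaningful). Protocols: `feasibility` b = {7, 11, 13, 16, 21, 25, 30}
ms/um^2 x 60 directions + 8 interspersed b=0 (428 volumes); `retest`
b = {7, 18, 25, 30} x 60 + 5 b=0 (245 volumes); both delta/Delta =
18.8/26.8 ms so diffusion time is constant across shells. Directions come
from seeded electrostatic-repulsion optimisation with antipodal symmetry.
Retest pairs share ground truth; session B optionally applies a
multiplicative lognormal perturbation to the ground-truth Da_perp map
(implemented as the equivalent s-scale change), emulating physiological
change.

Default grid 32x32x12 at 2.2 mm; experiments that exercise gradient
nonlinearity use coarser voxels spanning a 21 cm FOV and/or a superior
offset, because nonlinearity is negligible over a 7 cm slab at isocenter.

What the synthetic data do **not** contain: eddy-current/motion/
susceptibility distortion (their correction is out of scope), coil-array
sensitivity, spatially correlated reconstruction noise, exchange, soma or
extra-axonal compartments. Passing tests therefore demonstrate estimator
correctness under the stated model, not robustness to those confounds.

## Real-valued rectification

Phase is estimated per volume by a magnitude-weighted 3x3x3 boxcar on the
complex image (edge-renormalised), then conjugated away; signal lands in the
real channel and the imaginary channel is kept for QC. The center voxel is
excluded from its own kernel: including it correlates the phase estimate
with the voxel's own noise and re-introduces a reduced noise floor at high b
(measured: +0.11 sigma on high-shell spherical means at SNR 20, enough to
bias median r_eff from 2.29 to 2.00 um on the recovery phantom).
Leave-center-out decorrelates estimate and noise, which is the property the
kernel design optimises; with 26 neighbours the noise penalty is negligible.
The noise-decorrelation hook accepts a whitener for reconstruction chains
with correlated noise (identity here, where channel noise is white).

## Gradient nonlinearity

Coil fields are real regular solid harmonics (no Condon-Shortley phase,
l=1 members exactly x, y, z; coefficients of degree l divided by
reference_radius^(l-1)), generated symbolically with exact analytic
gradients; the local tensor L(x) is the Jacobian of the per-axis fields, and
the per-volume correction is `b_corr = b ||L g||^2`, `g_corr = L g / ||L g||`.
A synthetic head-gradient table ships with >15% amplitude deviation at the
corner of a 21 cm FOV (vendor tables are proprietary; a loader accepts any
(axis, l, m, coefficient) TSV).

Within a nominal shell the corrected b varies across directions, but that
variation is a smooth order-2 function on the sphere and is exactly
collinear with the spherical-harmonic basis — no single-shell binning can
separate it from orientation anisotropy (binned sub-fits were implemented
and produced um-scale artefacts before being removed). Instead each shell's
spherical mean is paired with the *signal-weighted* mean of its local
b-values: directions whose signal has decayed away carry no b-sensitivity,
so weighting by the measured signal is the first-order-correct effective b.
On the edge-bias experiment this reduces gradient-induced r_eff bias 5.9x
versus no correction (plain arithmetic-mean pairing: 4.7x).

## Spherical mean

Per shell, signals are fit to a real symmetric even-order SH basis
(orthonormal; L_max = 6 for 60 directions, 28 coefficients, condition number
reported; optional Laplace-Beltrami regularisation) and the spherical mean
is c00/(2 sqrt(pi)). b=0 volumes are averaged arithmetically for QC only.

## Fitting

Voxelwise bounded nonlinear least squares of (beta, Da_perp) with
Da_perp in [0, 0.5] um^2/ms, initialised from the log-linear regression of
ln(S_bar sqrt(b)) on b; an exact-stick (erf) kernel is available behind a
config switch and is indistinguishable from the b^(-1/2) form at these
b-values. Non-positive spherical means flag the voxel; fits below the
detectability limit are flagged, not zeroed; exact-zero Da_perp reports
r_eff = 0 with the below-limit flag.

**Estimator asymptote for broad distributions.** For the truncated gamma
ensemble (k=2, s=0.5; moment-ratio r_eff 2.54 um truncated / 2.69 um
untruncated) the noiseless estimator converges to 2.29 um — axons with
kappa*r^4 >> 1 contribute essentially no signal, so the fit sees a
tail-trimmed distribution. The same number emerges from the GPA series, the
matrix formalism, and a pure Neuman-limit ensemble: it is a property of the
estimator at these study conditions, not of any implementation. The
moment-ratio equivalence is exact only in the small-attenuation limit, and
the end-to-end recovery test documents the gap honestly rather than tuning
it away. At SNR 20 the real-valued pipeline reproduces the noiseless
asymptote (median 2.29 um); the magnitude pipeline collapses toward zero
because the Rician floor flattens the decay.

## Repeatability statistics

Bland-Altman (LoA = mean +- 1.96 SD of differences, sample SD), RPC =
1.96 x SD of differences (absolute and percent of grand mean), within-
subject CoV = 100*sqrt(mean(d^2)/2)/grand-mean (the RMS test-retest form;
per-parcel SD/mean is also emitted), ICC(2,1) (two-way random effects,
absolute agreement, single measure; cross-checked against an independent
implementation), Spearman rank correlation, and the asymmetry index
2(L-R)/(L+R). Masks use strict thresholds with CSF > GM > WM priority so
they are disjoint.

## Problem sizes in the test suite

Deliberate desk-scale choices: recovery experiments use ~240 WM voxels on a
20x20x6 grid; the gradient-nonlinearity experiment 10x10x10 voxels spanning
the coil FOV; the zero-perturbation retest check 50 replicate pairs on a
10x10x4 grid; the Monte-Carlo oracle runs the full 2e5 walkers x 2e4 steps
per case. These sizes give Monte-Carlo/sampling error comfortably below
each test's tolerance.

## Known limitations

* Single-compartment intra-axonal model: no extra-axonal, soma, dot or
  exchange compartments; no undulation or caliber variation along axons.
* The matrix-formalism table is cached per (radius grid, gradient grid,
  delta, Delta, D0); first use in a session costs ~20 s.
* Gradient corrections are per-volume static PGSE approximations; imaging-
  gradient cross terms and waveform-resolved b-matrix tracking are not
  modelled.
* Phase correction assumes spatially smooth phase; rapid phase from bulk
  motion at ultra-high b is out of scope and would degrade the real-valued
  rectification.
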