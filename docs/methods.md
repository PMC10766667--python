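# Methods

This note documents the models, parameter choices and numerical decisions
behind `tomoelast`, and the limits of what the synthetic data can show.

## Wave physics and phantoms

Tissue is a homogeneous-density (ρ = 1000 kg/m³, the standard soft-tissue
assumption) linear viscoelastic medium described per region by the
magnitude |G\*| (Pa) and loss angle φ (rad, in [0, π/2)) of the complex
shear modulus. The shear wavenumber is k\* = ω√(ρ/G\*) on the branch
Re k\* > 0, Im k\* ≤ 0, so the ground-truth shear wave speed is
SWS = ω / Re k\* = √(|G\*|/ρ) / cos(φ/2), frequency-independent because
G\* is taken constant over the narrow stimulation band (a deliberately
dispersion-free ground truth, which is what makes multifrequency
compounding exactly testable).

**Straight-ray simulator.** The steady-state displacement is a
superposition over source directions d of rays accumulating complex phase
K_d(x) = ∫ k\*(s) ds along the straight line reaching x from the entry
plane; the field is A_d·e^{iφ0}·e^{i Re K}·e^{Im K}. Integration uses the
midpoint rule at half-voxel steps with nearest-neighbour material lookup
(samples beyond the grid clamp to the edge voxel, so a homogeneous phantom
produces an exact plane wave). The simulator deliberately omits
refraction, reflection, mode conversion and boundary resonances: it tests
the *locality* of the inversions — whether the correct k and G\* are read
back from the local field — not full elastodynamics. Phantoms whose
regions do not tile the grid accept a `background_material` so waves reach
interior compartments as plane waves.

**Noise.** Wave fields receive additive complex Gaussian noise with
SD = mean |u| / SNR; magnitude (T2/DWI) stacks receive Rician noise. Both
are seeded. No acquisition SNR is documented for the target protocols, so
defaults are explicit arguments rather than hidden constants.

**Default grids.** Mouse: 90 × 60 voxels at 0.18 mm, single thru-plane
component, frequencies 1000–1400 Hz in 100 Hz steps. Human: 3-component
3D fields at 20, 25, 30, 35 Hz on a 2 mm grid; tests use 32³ volumes —
at 20 Hz a brain-like 1.5 m/s medium has a 7.6 cm wavelength, so smaller
grids hold under half a wavelength and spectral estimates degrade (the
32³ choice keeps the residual bias near 2 %).

## Preprocessing

The mouse chain is Gaussian smoothing (σ = 0.15 mm, mask-aware normalised
convolution) → radial first-order Butterworth low-pass (threshold
600 1/m) → decomposition into 8 in-plane propagation directions → phase
gradient. The human chain is Butterworth (200 1/m) → 3D curl → 20
directions → 3D phase gradient. All operators are linear.

- **Butterworth threshold units.** The cutoff is read as the radial
  spatial frequency in cycles/m: 600 1/m ↔ 1.67 mm wavelength, consistent
  with the 1.4–4 mm shear wavelengths of mouse brain at 1000–1400 Hz, and
  200 1/m ↔ 5 mm for the human band. The filter is zero-phase and purely
  radial, so it rescales amplitudes without touching phase gradients.
- **Directional windows (2D).** Raised-cosine lobes over the signed
  spectral angle: window d is centred at 2πd/n with half-width 2π/n and
  profile cos²(nΔθ/4), so adjacent windows sum as cos² + sin² = 1 — an
  exact partition of unity; the DC sample is shared equally. Signed
  directions (8 over the full circle) are used, so a standing wave splits
  into two opposing travelling components.
- **Directional windows (3D).** 20 directions from a symmetrised
  spherical Fibonacci lattice (10 hemisphere points plus antipodes);
  clipped-cos² lobes normalised sample-wise, again an exact partition.
- **Curl high-pass.** Central-difference curl with spacing in metres
  removes compressional (curl-free) content; for a transverse plane wave
  it preserves the wavenumber. Components that come out identically zero
  (e.g. along the polarisation axis) are skipped downstream.
- **Phase gradient.** k_i = Im(ū ∂_i u)/|u|² per axis equals the phase
  derivative without unwrapping; gradients are central, one-sided at mask
  borders. For a plane wave the central difference returns sin(k_i h)/h —
  an 11 % underestimate at 1400 Hz on the 0.18 mm mouse grid — so the
  inverse transfer function arcsin(k_i h)/h is applied by default
  (exact for plane waves, and the same expression holds at one-sided
  boundary stencils). Voxels below 1 % of the 95th-percentile slice
  amplitude are masked to keep wavenumbers finite near nodes.
- Interslice phase-discontinuity correction is not implemented: synthetic
  fields have none. The pipeline accepts preprocessed fields, so a
  correction stage can be inserted ahead of it.

## Inversion

**k-MDEV.** Per (frequency, direction), c = 2πf/k clipped to
(0, sws_cap] with caps of 10 m/s (mouse) and 5 m/s (human) against
near-node divergence; the compound SWS is the amplitude^p-weighted mean
with p = 2 (inverse-variance heuristic: phase noise scales as 1/amplitude,
so amplitude² weighting approximates minimum-variance compounding). p and
the caps are configuration, not constants.

**MDEV.** |G\*| = ρ Σ ω²|u| / Σ|Δu| and
φ = arccos(−Σ Re(ū Δu) / Σ |u||Δu|) over frequencies and components, on
the smoothed/low-passed (not directionally decomposed) fields. The
Laplacian is the central second difference; its plane-wave transfer
−Σ(2/h_i)² sin²(k_i h_i/2) undershoots −k², biasing |G\*| upward by
(k²)/(Σ(2/h sin(kh/2))²) — about 3–7 % across the mouse band at 0.18 mm.
The bias is asserted in tests at its exactly computed value, and an
optional `dispersion_correction` rescales each Laplacian voxel-wise by the
factor evaluated at the field's own phase-gradient wavenumber components,
bringing |G\*| recovery to < 1 %. φ is clipped into [0, π] by
construction; on physical inputs it stays in [0, π/2], and the fraction
above π/2 (noise) is observable in the map.

Outputs are eroded by one voxel from the mask boundary before any
statistic; reported medians in tests use an additional 3–4 voxel erosion
because the FFT-based filters have no padding (reflection padding was
tried and rejected: reflected waves travel backwards and create spurious
standing waves at the borders, enlarging the error).

## Quantitative MRI

T2 and ADC are fitted per voxel by log-linear least squares weighted by
the squared signal (the maximum-likelihood weighting for Gaussian noise
after the log transform), with one reweighting pass using the fitted
signal — weights taken from the measured signal correlate with the noise
and bias T2 by ~1.4 % at SNR 50; reweighting reduces the discrepancy
against a nonlinear least-squares fit to ~0.5 %. Defaults mirror the
target protocols: 20 echoes at 6.80 ms spacing; b = 0, 400, 1000 s/mm²
in three orthogonal directions, trace ADC = mean of per-direction fits.
T2 outside (1, 2000) ms, voxels with fewer than 3 positive echoes, and
non-positive signals are masked. No noise-floor subtraction is applied;
at the SNRs simulated the Rician floor is negligible before the last
echoes, which the weighting already downweights.

## Synthetic cohorts

The generator emulates a six-phase relapsing–remitting course (baseline,
pre-onset, onset, peak, remission, relapse) on a synthetic 2D parcellation
(elliptical cortical shell; hippocampus, caudoputamen, pallidum, thalamus,
hypothalamus, midbrain, striatum and generic deep parenchyma inside it;
ventricle slots excluded from every mask because fluid supports no shear
wave). Per subject i, phase t and compartment r:

    SWS_itr = α_r · γ_r(t) + b_i + β · score_it + ε_itr

with b_i ~ N(0, τ²), ε ~ N(0, σ²), plus independent voxel noise when maps
are painted. Defaults: cortical trajectory γ = (1.00, 0.95, 0.85, 0.75,
0.92, 0.80) — 25 % softening at peak with partial remission recovery —
and a milder deep-tissue trajectory peaking at 0.90; baselines
α_cortex = 2.0, α_deep = 2.1 m/s; τ = σ = 0.05 m/s; voxel noise
0.05 m/s; phase-level score means (0, 0, 1.5, 3, 0.5, 2.5) on the 0–5
ascending-paralysis scale, drawn with SD 0.5 and rounded to half points.

Two couplings are deliberately kept separate. In trajectory mode
(default, β = 0) the phase means are fixed entirely by γ, so the expected
cortical effect map is −25 % by construction. In score mode
(`simulate_score_observations`, or β ≠ 0) the course is carried by the
score coupling, making the mixed-model slope exactly β and its recovery
testable. Mixing both would confound the two effects and make neither
ground truth clean.

Wave-level mode builds a two-compartment phantom per (subject, phase) and
materialises the five-frequency fields, so the whole inversion chain can
run inside a cohort; map-level mode paints SWS maps directly and is used
for the statistics-focused studies.

## Disease-course statistics

- **Paradigm template** values (1.00, 0.67, 0.33, 0.00, 0.60, 0.20) encode
  linear softening baseline → peak, partial remission recovery and a
  relapse drop. Pearson r is affine-invariant, so only this ordinal shape
  matters; the constants are conventions, not fitted quantities. Missing
  phases are handled by subsetting the template, never by imputation.
- **Paradigm fit** runs on group-averaged maps by default; P values are
  parametric and two-sided from t = r√((T−2)/(1−r²)) with T−2 df. Under
  an iid Gaussian null this is exact (verified against a 10⁵-draw
  Monte-Carlo null and by nominal type-I error at 500 voxels).
- **Mixed model**: value ~ score with a subject random intercept, REML via
  statsmodels MixedLM; slope inference is Wald. With a balanced design
  and zero random-effect variance the slope equals OLS exactly.
- **Group tests**: paired t, and Welch by default for unpaired comparisons
  (no equal-variance assumption is documented for the analyses this
  mirrors; classic Student is a flag). One-way repeated-measures ANOVA is
  an explicit within-subject sum-of-squares partition with
  (T−1, (T−1)(n−1)) df, listwise deletion of incomplete subjects (counted
  in a warning) and defined degenerate behaviour (no timepoint variance →
  F = 0, P = 1); no sphericity correction is applied. Holm–Bonferroni
  adjustment comes from statsmodels with the original order restored.

## Problem sizes

Tests and the acceptance script run at desk scale: 90 × 60 mouse grids,
32³ human grids, 10-subject cohorts, 200 mixed-model replicates,
20 cohort replicates for the discrimination study, 500-voxel null
calibrations. These sizes were chosen so every study completes in seconds
while keeping Monte-Carlo error well inside the asserted tolerances.

## Limitations

- Straight-ray propagation cannot produce the wave interference,
  scattering or slip-interface artifacts of real brains, so passing
  recovery tests demonstrates correctness of the inversion mathematics,
  not robustness to real acquisition physics.
- The synthetic parcellation is geometric, not anatomical; registration,
  distortion and motion correction are out of scope (inputs are assumed
  registered).
- G\* is frequency-independent in the generator; real tissue is
  dispersive, and compound SWS on real data mixes frequencies with
  different intrinsic speeds.
- Rician bias is handled by weighting, not by explicit noise-floor
  modelling; at very low SNR the T2/ADC fits will bias high/low
  respectively.
- The human chain is exercised on analytic transverse waves rather than
  simulated 3D phantom acquisitions; its curl and 20-direction stages are
  unit-tested, but no 3D end-to-end cohort study is included.
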