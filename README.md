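# tomoelast

Multifrequency MR elastography (MRE/tomoelastography) of the brain, end to
end and fully synthetic: digital viscoelastic phantoms and harmonic
shear-wave simulation, the k-MDEV / MDEV inversions that turn wave images
into stiffness and fluidity maps, quantitative T2/ADC mapping, and the
regional plus longitudinal statistics used to track a relapsing–remitting
neuroinflammatory disease course (the EAE mouse model of multiple
sclerosis, and its human counterpart).

The package is aimed at researchers who want to test, calibrate or extend
MRE reconstruction and disease-course analyses without access to scanner
data: every input the pipeline consumes can be generated with known ground
truth.

## The model

Tissue is characterised by a complex shear modulus G\* = |G\*|·e^{iφ} with
loss angle φ ∈ [0, π/2). A harmonic shear wave at angular frequency
ω = 2πf propagates with complex wavenumber

    k* = ω √(ρ / G*),   Re k* > 0, Im k* ≤ 0,   SWS = ω / Re k*

where ρ = 1000 kg/m³ and SWS (m/s) is the shear-wave-speed stiffness
surrogate.

**k-MDEV** (stiffness): each preprocessed wave field (Gaussian smoothing →
radial Butterworth low-pass → decomposition into directional travelling
components) yields local wavenumber maps from the phase gradient,
k(x) = |Im(ū ∇u)| / |u|², without phase unwrapping. Per frequency f and
direction d, c_{f,d} = 2πf / k_{f,d}; the compound map is the
amplitude²-weighted mean over all (f, d).

**MDEV** (fluidity): an algebraic Helmholtz inversion pooling frequencies
and components,

    |G*| = ρ · Σ ω_f² |u_fc| / Σ |Δu_fc|
    φ    = arccos( − Σ Re(ū_fc Δu_fc) / Σ |u_fc| |Δu_fc| )

**Disease course**: regional means over an atlas parcellation feed effect
maps (percent change peak vs baseline), a voxelwise Pearson correlation
against a relapsing–remitting template (baseline → peak softening, partial
remission recovery, relapse drop), a random-intercept linear mixed model
SWS ~ disability score with animal as random effect, and
paired/Welch t tests, repeated-measures ANOVA and Holm–Bonferroni
correction. T2 and ADC maps come from weighted log-linear fits of
multi-echo and multi-b-value stacks.

## Worked example

```python
import numpy as np
import tomoelast as te

# 1. simulate multifrequency shear waves in a homogeneous 4 kPa phantom
material = te.MaterialProps(shear_modulus_magnitude=4000.0)   # SWS = 2.0 m/s
phantom = te.homogeneous_phantom(material)                    # 90 x 60, 0.18 mm
angles = np.deg2rad((10, 100, 205, 295))
cfg = te.WaveSimConfig(frequencies=te.MOUSE_FREQUENCIES,      # 1000-1400 Hz
                       directions=[(np.cos(a), np.sin(a)) for a in angles])
fields = te.simulate_multifrequency(phantom, cfg)

# 2. reconstruct stiffness and fluidity maps (full mouse chain)
maps = te.reconstruct_mouse(fields)
sws = maps["sws"].eroded(3).masked_values()
phi = maps["loss_angle"].eroded(3).masked_values()
print(f"compound SWS: {np.median(sws):.3f} m/s (truth 2.000)")
print(f"loss angle:   {np.median(phi):.4f} rad (truth 0, elastic)")

# 3. longitudinal cohort -> cortical effect map and score mixed model
cohort = te.simulate_cohort(te.CohortSpec(n_subjects=10, seed=1))
peak = te.group_mean_map(cohort.maps_at("peak"))
base = te.group_mean_map(cohort.maps_at("baseline"))
effect = te.percent_change_map(peak, base)
cortex = cohort.atlas.mask_of("cortex") & effect.mask
print(f"cortical softening at peak: {np.median(effect.values[cortex]):.1f} %")

table = te.simulate_score_observations(15, alpha=2.0, beta=-0.0737,
                                       random_intercept_sd=0.05,
                                       residual_sd=0.05, seed=1)
fit = te.mixed_model_fit(table)
print(f"mixed-model slope: {fit.slope:.4f} m/s per score unit "
      f"(P = {fit.slope_p:.4f})")
```

Output:

```
compound SWS: 2.017 m/s (truth 2.000)
loss angle:   0.0041 rad (truth 0, elastic)
cortical softening at peak: -23.9 %
mixed-model slope: -0.0628 m/s per score unit (P = 0.0000)
```

The compound SWS lands within 1 % of the phantom's ground truth, the loss
angle of the purely elastic control is essentially zero, the cortical
effect map reflects the generator's 25 % peak softening, and the mixed
model recovers a slope statistically consistent with the generating
coupling of −0.0737 m/s per score unit.

A command-line interface mirrors the library:
`tomoelast simulate`, `tomoelast reconstruct`, `tomoelast regionstats`,
`tomoelast paradigm`, `tomoelast stats` (see `--help` on each).

## Documentation

`docs/methods.md` describes the simulation and inversion methods, the
default parameters and why they were chosen, the numerical choices
(dispersion corrections, amplitude floors, boundary handling), and what
the synthetic data do and do not capture about real acquisitions.
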