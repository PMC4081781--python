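# vowrhog — blurred-palmprint verification via structure-layer WRHOG features

Palmprints captured by contactless devices are frequently defocused, and the
fine ridge texture that most palmprint matchers rely on is the first thing
blur destroys.  This package implements a verification pipeline built around
the observation that an image's *structure layer* — the cartoon-like component
of a Meyer-type structure/texture decomposition — is nearly invariant to the
amount of defocus, while the oscillatory texture layer is not.  It is aimed at
biometrics researchers who want a complete, self-contained implementation of
the method, including a synthetic palm-ROI generator, so every stage runs and
is testable without access to a licensed palmprint database.

## The method

1. **Blur model.**  Defocus is simulated by the Gaussian degradation model
   `g = h_sigma * f + n`, with `h_sigma` an isotropic Gaussian PSF.  Sharpness is
   tracked by the Robert gradient energy
   `RGE(f) = sum [f(i,j) - f(i+1,j+1)]^2 + [f(i+1,j) - f(i,j+1)]^2`,
   which decreases monotonically with sigma.

2. **Vese–Osher decomposition (p = 1).**  The image is split as `f = u + v`
   with `v = div g` represented through an auxiliary field `g = (g1, g2)`:

       E(u, g) = ∫|∇u| + λ ||f − u − div g||₂² + μ ∫ √(g1² + g2²)

   minimized by alternating majorize–minimize sweeps (Gauss–Seidel for `u`,
   exact coordinate descent for `g`).  `u` keeps principal lines and coarse
   contrast (blur-stable); `v` takes the ridge oscillation (blur-fragile).

3. **WRHOG descriptor.**  On the structure layer, gradients are measured by a
   rotation-invariant gradient operator (RIGO): for each pixel, K = 8 sample
   points on a radius-2 circle each carry a local frame whose x-axis points
   along the radius; gradient components are central differences of
   bilinearly interpolated gray values in that frame.  Accumulating
   magnitude-weighted local angles into N = 12 bins per non-overlapping
   16 × 16 block, concatenating blocks (RHOG), and scaling each block's
   histogram by its differential box-counting fractal dimension D ∈ [2, 3]
   yields the WRHOG feature vector.

4. **Matching and evaluation.**  Features are compared with the normalized
   correlation coefficient (Pearson, population σ).  Sweeping an
   accept-if-score ≥ t threshold gives FAR/FRR curves, their crossing the
   equal error rate (EER), and the decidability index
   `d' = |μ_g − μ_i| / sqrt((σ_g² + σ_i²)/2)` summarizes score separation.

## Worked example

`examples/05_verification_experiment.py` generates 10 synthetic identities
(3 sharp gallery images each, 3 probes blurred with sigma ~ U[1, 7]) and runs
the raw-image and structure-layer pipelines:

```
WRHOG (raw image)       EER = 18.8889%   d' = 1.467   (90 genuine / 810 imposter scores)
VO-WRHOG (structure u)  EER = 4.4444%    d' = 3.250   (90 genuine / 810 imposter scores)
```

Matching raw blurred probes against sharp gallery images fails almost one
time in five at the equal-error operating point; matching the structure
layers instead cuts the error about fourfold and triples the separation
between genuine and imposter score distributions.  The other example scripts
each demonstrate one stage (blur/RGE curve, decomposition stability, rotation
robustness of the descriptor, fractal weights) and print a line explaining
the numbers.

A thin CLI mirrors the library (`vowrhog synth | simulate | decompose |
extract | fractal | match | evaluate | experiment`); see `--help` on each verb.

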