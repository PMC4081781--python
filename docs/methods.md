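# Methods

This note records the models, numerical choices and open design decisions
behind the package, and what the synthetic-data experiments do and do not
establish about real palmprint data.

## Blur simulation and sharpness

Defocus is modeled as convolution with an isotropic Gaussian PSF sampled on
a grid of radius `ceil(3*sigma)` and renormalized (mass lost to truncation
is below 0.3%), followed by optional additive Gaussian noise and clipping to
[0, 255].  The 2-D kernel is an outer product, so the convolution is applied
as two 1-D passes with reflect (symmetric) boundary handling — reflection
avoids the dark frame that zero padding would introduce, which would bias
the Robert gradient energy (RGE) readings near the border.

RGE sums squared Roberts-cross differences over all 2×2 neighborhoods.  It
scales quadratically with contrast and decreases monotonically with blur
width.  On the sharpness-versus-sigma curve the sharp end dominates the
scale (RGE at sigma=1 is two orders of magnitude above the tail), so
"plateau beyond sigma=10" is quantified here as the sigma 10→15 change being
under 1% of the sigma=1 value.  We evaluate that curve on full-size 128 px
ROIs: the sigma scale is defined relative to that ROI size, and halving the
resolution doubles the effective blur.  Truncating the kernel to a small
fixed window would make the tail literally constant, but it also turns the
kernel box-like, re-admits high frequencies as sigma grows, and breaks the
monotone decrease, so the faithful full-support Gaussian is used throughout.

## Vese–Osher decomposition

The texture layer is represented as `v = div g` and the energy

    E(u, g) = Σ (sqrt(|∇u|² + ε²) − ε)
            + λ Σ (f − u − div g)²
            + μ Σ (sqrt(g1² + g2² + ε_g²) − ε_g)

is minimized with forward-difference gradients (homogeneous Neumann
boundaries), the divergence being their exact negative adjoint.  Both
non-smooth terms are smoothed; subtracting the ε offsets makes the energy
of a constant image exactly zero.  ε = 1e-4 (TV term) and ε_g = 1e-2: the
g-term smoothing must be larger because the solver's majorize–minimize
weight is `μ / sqrt(g² + ε_g²)` — with ε_g = 1e-4 the weight at the g = 0
start is ~μ·10⁴ and the texture field never leaves zero.

The solver alternates, per outer iteration: (i) a lagged-diffusivity
quadratic surrogate in `u`, relaxed with two red-black Gauss–Seidel sweeps;
(ii) exact coordinate-descent sweeps for `g1` (even/odd columns) and `g2`
(even/odd rows) on the corresponding surrogate.  Every step minimizes a
convex surrogate that touches the energy at the current iterate, so the
recorded energy trace is non-increasing by construction (a backtracking
guard enforces this even under floating-point edge cases).  Iteration stops
when the L2 change of `u` falls below `tol` times the L2 size of the
mean-removed input — a shift-invariant denominator, so decomposing `f + c`
stops at the same iteration and the decomposition is exactly equivariant
under gray shifts.

Defaults (image scaled to [0, 1] internally): λ = 1.0, μ = 0.01,
max_outer = 100, tol = 1e-3.  λ was chosen so that a known
cartoon-plus-sinusoid pair (period 4 px, amplitude 20 gray levels) has at
least half of its texture energy recovered in `v`; with λ an order of
magnitude smaller the fidelity term is too weak on the unit scale and the
texture stays in neither layer.  All parameters are exposed via `VOParams`.

## Descriptor

Gradients use the `[-1, 0, 1]` mask; angles are gradient vector
orientations on the full circle [0, 2π), with +x along columns and +y along
rows.  Histograms use hard assignment to N half-open bins and L1
normalization (zero histograms stay zero rather than NaN).

The rotation-invariant operator samples K = 8 points at radius r = 2.  Each
sample point carries a local frame with x along the radius; gradient
components are central differences (unit step) of bilinearly interpolated
values in that frame, and each pixel contributes all K (magnitude, local
angle) pairs to the histogram.  The exact difference stencil is a design
choice: three alternatives were evaluated (ring differences across the
circle, a single maximum-magnitude pair, gradient-at-center referenced to
the ring's circular-mean direction) and all separated identities worse on
synthetic ridge data.  Interpolation is exact at integer coordinates, which
makes the descriptor exactly invariant under 90° grid rotations; invariance
under small continuous rotations is approximate and is what the rotation
tests measure.

The plain-HOG baseline is the whole-image N-bin histogram; block division
(non-overlapping 16 × 16, remainder rows/columns dropped) belongs to the
robust blockwise variants.  WRHOG multiplies each block's normalized
histogram by that block's differential box-counting dimension, computed on
the same image the descriptor sees (the structure layer, in the full
pipeline).  Default N = 12 orientation bins; block size 16 with
b ∈ {8, 16, 32, 64} sweepable.

## Fractal dimension

The differential box-counting estimator partitions an M×M block into s×s
cells with box height `s·G/M` (G = 256 gray levels throughout, also for
rescaled structure layers) and counts `floor(max/h) − floor(min/h) + 1`
boxes per cell; D is the least-squares slope of log N_s versus log(M/s)
over scales {2, 4, 8} for 16-px blocks (all divisors leaving at least a
2×2 cell grid).  A flat block gives D = 2 exactly; i.i.d. noise approaches
3.  D is not exactly invariant to gray offsets (box indices shift), but is
invariant to gray-value complement up to ~0.02.

## Matching and evaluation

NCC uses population standard deviations (divide by n); degenerate
zero-variance vectors score 0 with a warning.  The decision rule is accept
iff score ≥ threshold (ties accept).  The threshold grid is all distinct
observed scores plus ±∞ sentinels, so FAR runs 0→1 and FRR 1→0 and a
crossing always exists; the EER is found by linear interpolation of the
FAR−FRR sign change, which is stable for small score sets.  Evaluation is
all-vs-all probe × gallery (the protocol the match-count arithmetic
describes); claimed-identity verification is available separately.

## Synthetic palm ROIs

Each identity is: a ridge orientation field built as a common base
direction (π/2 plus a Gaussian identity offset of 0.15 rad) plus a smooth
identity-specific perturbation of 0.1–0.2 rad; a ridge frequency in 0.1–0.25 cycles/px; a
smooth ridge-contrast field (±60% modulation); and 2–3 principal lines
(quadratic Béziers, Gaussian cross-profile, width 3–5 px, depth 40–80 gray
levels).  The base flow is shared across identities because ROI extraction
anchors the coordinate frame to the hand, making global ridge direction
anatomically stereotyped; identity is carried by the lines, the frequency
and the contrast layout.  Samples add the residual misalignment left after
ROI preprocessing — rotation in ±3°, integer shifts in ±2 px — plus
defocus blur and optional noise; gallery samples are sharp (first-session
captures), probes draw sigma ~ U[1, 7] by default.  Everything is
deterministic given seeds and regenerates bit-identically.

What the generator does *not* emulate: minutiae and ridge branching,
non-rigid skin distortion between sessions, illumination gradients and
sensor vignetting, and the anatomical correlation structure of real palms.
(A per-sample elastic distortion was prototyped and dropped: it degrades
the ring-sampled descriptor as much as the baseline and adds a parameter
with no counterpart in the modeled acquisition chain.)  Consequently,
passing results establish internal consistency of the pipeline and the
*relative* behavior of its variants under controlled blur — not absolute
error rates on real palmprints, which depend on nuisances the generator
omits.

## Problem sizes

Experiments are sized for a desktop single-core run: database experiments
use 128 px ROIs (the size the blur scale refers to) with up to 50
identities × (5 gallery + 5 probe); solver-behavior and stability tests use
64 px images where the blur scale is not at issue.  The verification
experiment in `scripts/acceptance.py` uses 20 identities × (3 + 3) at
128 px.

## Known limitations

- The VO solver is first-order and deliberately simple; for large images a
  preconditioned or primal-dual solver would converge faster.
- RIGO discrimination is intrinsically lower than oriented HOG on images
  whose identity information is carried by absolute orientation; it trades
  that information for rotation robustness.
- The EER interpolation assumes the FAR/FRR step functions are adequately
  sampled at observed scores; with very few scores the reported EER is a
  linear-interpolation convention, not a measured error rate.
- Fractal weights are computed per block independently; no smoothing is
  applied across neighboring blocks.
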