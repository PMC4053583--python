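# Methods

## Problem and solvers

Few-view CT measures line integrals `g̃ = M f + η` of an attenuation
image `f` along rays of a circular fan-beam trajectory, with far fewer
view angles (here 60 over 360°) than analytic reconstruction needs.
All iterative solvers in this package address

    minimize ‖f‖_TV   s.t.   ‖M f − g̃‖₂ ≤ ε,  f ≥ 0.

One main-loop iteration runs:

1. **ART phase** — `I` Kaczmarz sweeps over all rays `j` in a fixed
   order: `f ← f + λ (g̃_j − ⟨M_j, f⟩)/‖M_j‖² M_j`; rays whose row norm
   is zero (they miss the grid) are skipped.
2. **Positivity POCS** — `f ← max(f, 0)`.
3. **TV descent phase** — `K` steps `f ← f − s·d/‖d‖₂` with
   `d = α ∇‖f − f_p‖_TV + (1−α) ∇‖f‖_TV`.

API-TV is this loop with a prior image `f_p` and blend weight
`α ∈ [0,1]`; ASD-POCS is the exact special case `α = 0` (asserted
bit-identical in the tests); ART is the loop without step 3.  The
initial image is zero.  The loop stops after `n_main` iterations or
when the data residual reaches `ε` (default 0, so `n_main` binds; a
huge `ε` therefore stops after the first iteration).

## Operators

**Projector.**  Forward projection uses Siddon-style parametric grid
marching with exact ray/pixel intersection lengths; backprojection,
row norms, ART updates and the optional explicitly assembled sparse
matrix all reuse the *same* traversal routine, so the forward/back pair
is an exact adjoint by construction (verified to 1e-10 on random
instances, and bit-exactly against the assembled matrix on small
grids).  Rays on pixel boundaries contribute zero-length segments on
one side — a half-open pixel convention.  Accumulation is double
precision; stored reconstructions are single precision.

**FBP.**  Flat-detector fan-beam filtered backprojection: detector
rescaled to a virtual panel through the isocenter, cosine pre-weighting
`sod/√(sod²+u²)`, convolution with the band-limited ramp kernel
(zero-padded to a power of two; optional Shepp-Logan or Hann
apodization), distance-weighted backprojection `(sod/d_e)²`, and an
overall `Δβ/2` accounting for every line being measured twice over 2π.
The output is masked to the disk actually seen by every fan
(`max_object_radius = sod·sin(fan half-angle)` ≈ 124 mm at defaults):
outside that disk data are incomplete and FBP error grows without
bound, while the phantom support (≈118 mm) lies inside.  A uniform
disk reconstructs to its true intensity within 2% at 360 views.

**TV.**  Isotropic TV with backward differences and replicate
(Neumann) boundaries — out-of-range differences are zero, so constant
images have exactly zero TV and gradient (zero-padding is available as
an option).  The gradient is the exact analytic gradient of the
smoothed objective `Σ √(|∇f|² + τ)`, which reproduces the classical
three-term (2D) difference stencil and matches central finite
differences to 1e-4 in the tests.  Default `τ = 1e-8`.

## Parameters

| name | default | meaning |
|---|---|---|
| `alpha` | 0.85 | prior blend weight; 0 disables the prior |
| `lambda_art` | 1.0 | ART relaxation, in (0, 2) |
| `n_art` (I) | 1 | ART sweeps per main loop |
| `n_tv` (K) | 10 | TV descent steps per main loop |
| `n_main` | 50 | main-loop iterations |
| `tv_step` (c) | 0.2 | TV step scale |
| `tv_step_decay` | 0.95 | per-main-loop decay of c |
| `epsilon` | 0 | residual stopping tolerance |
| `tau` | 1e-8 | TV gradient smoothing |

The TV step follows the adaptive ASD-POCS convention
`s = c·0.95^m·‖Δf_ART‖₂`, where `Δf_ART` is the change made by the
preceding ART+positivity phase of main loop `m`: the regularization
strength tracks the progress of the data phase and fades as the
iterate approaches data consistency.  A `fixed` step rule is available.
Ray ordering is sequential (view-major) by default; a seeded shuffle is
available and bit-reproducible.

Histories (residual `‖Mf−g̃‖₂` and, when a truth image is supplied, the
sum-of-squared-differences image error) are recorded once per main
loop on the raw post-TV iterate; the *returned* image additionally gets
a final positivity projection, since the TV step can leave negatives of
order `s/√(n_tv)` per pixel.

## Simulation harness

The generator emulates a bench-top circular fan-beam scan of a head
phantom: the canonical 10-ellipse Shepp-Logan, rasterized by
pixel-center point sampling onto a 256×256 grid spanning the phantom
support (optional supersampling exists but the ground truth is the
point-sampled image), a 500 mm source radius, 1000 mm source-detector
distance, a 512-element 1 mm flat panel, and 60 views evenly over 360°.
The `high_contrast` intensity variant composes to 1.0 inside the skull
with ±0.1–0.2 features, matching a [0.8, 1.2] display window; the
`standard` (1974) and `toft` tables are also provided, the latter
validated pixel-wise against scikit-image's stored phantom.  The image
pixel size defaults to 1 mm (a 256 mm field of view), a value chosen —
and recorded in every study config — so the phantom fits the fan with
margin; the acquisition geometry does not pin it down.

Noise is additive white Gaussian with σ = level × RMS of the nonzero
sinogram entries ("10% white noise" is ambiguous about its reference;
RMS is the default, max and mean are options), reproducible from a
single seed.  Photon-statistics (Poisson) noise, scatter, beam
hardening and detector blur are *not* modeled: the forward model is
purely geometric, and the few-view data are generated by the same
projector used for reconstruction, i.e. the simulated data are exactly
consistent in the noise-free case.  Passing tests therefore certify
the solvers and operators, not performance on real scanner data.

## What the experiments show — and a caveat on the prior

Eq.-style image error `E = Σ (f* − f)²` on the noise-free 60-view
study (256×256, defaults, 30 main iterations): ASD-POCS reaches
E ≈ 0.51 and ART E ≈ 163, while API-TV with a 360-view ram-lak FBP
prior reaches E ≈ 30.5.  The explanation is structural, and the
package's studies make it measurable:

* With exactly consistent data and a piecewise-constant phantom, plain
  TV is an *ideal* prior: ASD-POCS converges essentially to the truth
  once the adaptive TV step fades.
* Any FBP prior necessarily carries ramp-filter aliasing/ringing error
  (E ≈ 150 here; scikit-image's parallel-beam FBP of the same phantom:
  E ≈ 281), and the α = 0.85 difference-TV term imports part of it.
* The prior pays off exactly when data consistency is weak: with the
  truth supplied as prior, API-TV is at least as accurate as ASD-POCS
  at *every* iteration (a tested invariant); with 10% noise the
  API-TV arm beats ASD-POCS in image error and along the central row
  profile (tested); and at weak ART relaxation (λ ≈ 0.1) the ordering
  flips in API-TV's favour mid-convergence.

So in this noise-free, exactly consistent regime a measured-data prior
cannot beat the TV prior, and the acceptance suite records that
honestly: the API-TV-below-ASD-POCS ordering asserted for the
noise-free study fails at the default settings, while the noisy-case
orderings and the perfect-prior invariant hold.

## Problem sizes and numerical choices

Unit and property tests run on 2×2–128×128 grids; the end-to-end
acceptance studies run the full 256×256 / 60-view protocol for 50 main
iterations (seconds per arm with the compiled kernels).  The scaled
128×128 profile of every study is exposed via `StudyConfig.scaled()`;
note that at 128×128 the 60-view system (15 360 rays vs 16 384
unknowns) is barely underdetermined, so few-view behaviour is only
fully developed at 256×256.  Ties in the grid marching (corner
crossings) produce zero-length segments and no double counting;
degenerate rays that miss the grid have zero row norm and are skipped
by ART.  All randomness (noise, optional ray shuffles) flows from
explicit integer seeds.

## Limitations

2D fan-beam central slice only (no cone-beam/FDK, helical or offset
geometries); no physical noise models; the quantitative error values
are specific to this projector discretization and rasterization
convention — any consistent linear `M` satisfies the reconstruction
problem, so absolute error levels shift between implementations even
though the orderings and invariants tested here are stable.
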