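# Methods

## Decomposition model

Each color channel of a training stack is decomposed independently by
2DPCA. The channel scatter matrix uses the biased 1/N normalization and
mean-centering; eigendecomposition uses a symmetric solver with eigenvalues
sorted non-increasing and each eigenvector's sign fixed so its first
nonzero entry is non-negative, making bases bit-reproducible across
platforms. Projection multiplies the **raw** image by the basis
(`Y = O·W`) and reconstruction sums `Y_j W_j^T` without re-adding the mean.
This uncentered form is the one the selection objective operates on; with a
full basis it is still exact (`O W W^T = O` for orthonormal `W`). The
conventional centered variant — project `O − Ō`, add `Ō` back — is
available via `centered_reconstruction=True` and matters only when few
components are kept and the stack mean carries most of the intensity.

Because the basis is orthonormal, the residual of a masked reconstruction
equals the sum of the excluded rank-one terms, and its Frobenius norm is
the root-sum of excluded projection-column energies. The swarm's fitness
evaluator precomputes those energies once per stack (`make_fitness`),
reducing each of the thousands of mask evaluations to a masked sum. The
literal reconstruction-based `fitness` function is kept as the public
operation and the test suite asserts the two routes agree to 1e-8.

## Swarm optimization

Both variants share the velocity rule
`v ← ω·v + α·r1·(pbest−x) + β·r2·(gbest−x)` with defaults ω=1.5, α=2, β=1,
swarm 50, 100 iterations, λ=0.001. Defaults reflect the reference
configuration for 640-pixel-wide clinical images; on the 64-wide synthetic
phantoms the same settings run in seconds.

**Traditional:** r1, r2 ~ U[0,1] per dimension; each position bit is
resampled as Bernoulli(sigmoid(v)).

**Improved:** r1, r2 are uniform integers in {0,1}; the velocity is
quantized to {−1,0,1} by the sign function; the position moves additively
and is clamped to {0,1}.

Two design choices here were genuinely open and are worth recording:

* **Boundary handling.** With a clamped binary position and a stored
  velocity of ±1, the inertia term ω·v = ±1.5 outweighs the social pull
  (β=1) forever, so a component pinned at the clamp can never re-enter the
  search; empirically the whole swarm froze within ~10 iterations. The
  velocity carried to the next iteration is therefore the *realized* step
  `x(t+1) − x(t)` — an absorbing boundary, equivalent to reading the
  additive position rule as the definition of what a velocity is. A blocked
  component carries zero velocity forward and stays responsive to its
  neighbours' discoveries.
* **Update order.** Particles are processed in index order with a fixed
  draw order (r1, r2, then any resampling uniforms), and the global best is
  refreshed asynchronously — immediately when a particle improves — so
  later particles in the same sweep exploit fresh information. Both choices
  are deterministic under the run seed.

Personal and global bests replace only on strict improvement (stable under
ties). Velocity initialization is random {−1,0,1} by default with a `zero`
option; with absorbing boundaries the random initialization explores
slightly better on small problems. `BPSOResult.evaluations` counts in-loop
fitness evaluations (N·T); the N initialization evaluations are bookkept
separately.

On a width-4 toy problem where all 4096 tri-channel masks can be
enumerated, the improved variant reaches the exhaustive optimum in ≥ 90% of
seeds at N=20, T=50; the sigmoid variant manages roughly a third of that,
consistent with its known tendency to stall in sparse discrete spaces.

## Selection assembly

B1 is the tri-channel consensus of the best mask: components selected in
all three channels. This is the parameter-free reading of "identical
selection across channels"; any threshold-based similarity would introduce
a tunable the method does not define. B2 ranks components by the ℓ2 norm of
their projected feature vectors, averaged over channels and stack images —
one modality-level ranking rather than per-image or per-channel rankings,
so the final set is a property of the dataset, applied uniformly.
Ties break toward the lower (larger-eigenvalue) index. B = B1 ∪ B2 is
applied to all three channels for reconstruction; since the axes are
orthonormal, enlarging the set can only shrink the residual, so the union
is never worse than either part. m defaults to 100 (matched to d=640
full-scale data) and scales down on small images (the package clamps m to
d; synthetic runs typically use m ≈ d/6).

## Fusion

Fusion is the convex pixelwise blend `F = x·CEUS + (1−x)·conv` of the two
selected reconstructions. Reconstruction is linear in the kept feature
vectors, so blending reconstructions equals blending features under a
shared basis; blending at the reconstruction level keeps the two modality
bases independent. Selection runs once per modality per dataset and the
resulting B is applied to every image of that modality. Endpoints are
returned exactly (no floating-point scaling at x=0 or 1). The grayscale
baseline converts with Rec. 601 luma weights (0.299, 0.587, 0.114) before a
single-channel top-k decomposition.

## Synthetic phantoms

The generator emulates exactly the statistics the pipeline consumes: an
elliptical bright region (uniform-random center jitter, semi-axes and
rotation), multiplicative gamma speckle of mean 1 (shape 30 by default,
i.e. σ ≈ 0.18 — moderate clinical-looking speckle), a conventional channel
replicated to gray, and a CEUS counterpart with stronger region gain
(0.5 vs 0.35 over a 0.15 background) and channel tint (1.0, 0.8, 0.45) —
the warm colormap of contrast-mode displays. Default frame 64×64 keeps
eigendecomposition and swarm runs in seconds while leaving d = 64
components to select from. Everything is a pure function of
(seed, pair index).

What the phantoms do **not** model: ultrasound wave propagation,
attenuation and shadowing, spatially correlated speckle, perfusion time
dynamics, anatomical variability. Passing tests therefore demonstrate the
correctness and internal consistency of the decomposition/selection/fusion
machinery on data with the assumed structure — not clinical detection
performance.

## Numerical choices and degenerate inputs

* Covariance symmetry enforced by averaging with its transpose; inputs
  asymmetric beyond 1e-9 are rejected.
* Empty stacks, shape mismatches, out-of-range masks/indices and non-finite
  fitness values raise immediately with the offending index in the message.
* Images load as float64 in [0,1] (integer inputs rescaled by their type
  maximum); grayscale files are replicated to three channels with a logged
  warning. PNG export clips to [0,1] and quantizes to 8 bits; TIFF export
  writes unclipped float32.
* Reconstruction output is never clipped inside the math; clipping happens
  only at image export.
* Problem sizes in the test and acceptance runs (64×64 phantoms, 10–16
  pairs, d=4 exhaustive toys) were chosen so every stage, including the two
  full-scale swarm invariant runs, completes in seconds on one core.

## Known limitations

* The improved variant has no mutation mechanism; once every particle's
  position, personal best and global best coincide the swarm is stationary.
  On high-dimensional problems run-to-run variability of the selected set
  remains substantial — only the union with B2 stabilizes the result.
* λ interacts with image scale: fitness norms are computed on [0,1]
  intensities, and λ=0.001 charges per selected component across all three
  channels. Rescaled intensities require rescaling λ.
* The fusion ratio is global; no spatially varying blending.
* Benchmark timings are machine-dependent and are reported, never asserted.
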