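# Methods

This note records the model, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## Model

### Image representation

An image is a node-centred lattice of coefficients in [0, 1] with
multilinear interpolation (physical coordinate of node *i* along axis
*a* is `origin[a] + i * spacing[a]`).  Binary masks become crisp {0, 1}
indicator fields; RGB rasters keep three channels and the mismatch sums
over channels.  Out-of-lattice queries return 0 (background) by default,
matching indicator semantics; a clamp mode exists for grayscale volumes.
For optimisation the fields may be Gaussian-smoothed by ~1 px
(`fields.smoothed`): a crisp indicator has intensity gradients only in a
one-pixel band, which starves the mismatch term of gradient signal;
smoothing widens the capture range.  All overlap metrics are computed on
the original crisp fields, never the smoothed ones.

### Flow maps

The transformation is the flow of `dx/dt = NN(x)` under forward Euler
with `n_steps = 15` fixed steps (no adaptive integrators).  The velocity
network has three tanh hidden layers — 40 neurons for 2-D, 60 for 3-D —
with the output layer zero-initialised so the initial map is exactly the
identity and the loss starts from the untransformed mismatch.  tanh is
used because it is smooth with bounded derivative, which helps each
residual step stay contractive; invertibility is monitored through
`min det F` over probe points rather than proved via a Lipschitz bound.
The inverse map uses the reverse-Euler recursion (error O(Δt), measured
to halve when the step count doubles); an optional Newton polish exists
behind a flag but is off by default so that reported Dice reflects the
same approximate inverse the rest of the pipeline uses.

`deformation_gradient` is the exact derivative of the *discrete*
composed map — each Euler step is differentiated analytically, including
the distance-gate factor through its almost-everywhere gradient
`(x − nearest)/D` (subgradient 0 at the cloud, where the gate is not
differentiable).  It matches central finite differences of the forward
transport to ~1e-10 relative error.

### Losses and training

Domain integrals use tensor-product Gauss–Legendre quadrature (2 points
per axis per element); mini-batches sample whole elements uniformly
without replacement each epoch, one Adam step per epoch, fixed epoch
budget, best-checkpoint (periodic dense evaluation on a fixed element
subset) returned.  The S1 factor in both integrands is the interpolated
value — a soft mask restricting the term to the body.

Parameter gradients of F-dependent terms (regularizer, potential
energy) are taken by building F from central finite differences of the
transported positions: the points `X ± h e_j` (h = 1e-3) ride along in
the same batch, so one first-order reverse sweep through the Euler steps
yields the full gradient and no second derivatives of the network are
ever needed.  The O(h²) construction error (~1e-4 on F entries in
float32) is far below the stochastic gradient noise.  Training runs in
float32; exported maps and all diagnostics are float64.

The corrector's F is the gradient of the full composed map
X → corrector(predictor(X)); the predictor is frozen, so its endpoints
and offsets are transported once and cached.  Gate values are treated as
constants when differentiating the training loss (the gate re-evaluates
at each step position; its subgradient at the cloud is zero).  With
growth, `ψ(F^e)` with `F^e = F/θ`, `θ = exp(±κt)`, and κ joins the same
Adam run; its gradient is `∓t Σ w S1 ⟨∂ψ/∂F^e, F^e⟩`.  The growth time
convention is t = 1 per registered frame interval, so θ = exp(±κ).  The
energy integrand is ψ over the reference domain, unweighted by det F^g.

### Materials

Saint Venant–Kirchhoff `ψ = λ/2 (tr E)² + μ tr(E²)`, neo-Hookean
`ψ = μ/2 (tr C − d) − μ log J + λ/2 (log J)²`, and a fixed-coefficient
polynomial in (J, I1, I2) used for ablation work.  μ = λ = 1 Pa
throughout by default.  Two conventions deserve note: the StVK
volumetric term is implemented in its classical squared form (a
`stvk_literal_trace` flag restores a linear-trace variant, which is
dimensionally inconsistent and not a stored-energy function); the
neo-Hookean trace offset is the spatial dimension d, so ψ(I) = 0 in 2-D
as well as 3-D.  The ablation polynomial contains linear invariant
terms, so it is *not* nonnegative near the identity — it is kept exactly
as specified because only its minimisation path matters.

### Sequential registration

For frames I_0 … I_{n−1}, each interval's predictor registers the pair
(I_{j−1}, I_j) — the standard approximation to pulling I_0 through the
accumulated inverse — while the regularizer and the corrector energy act
on the map composed back to frame 0 (the running composed positions and
Jacobians at the quadrature points are cached and chained into the
current interval's F).  One growth rate per interval; the cumulative
growth Jacobian is the product over intervals.  Frames are an ordered
list; running time-reversed is simply passing the reversed list.

## Synthetic benchmarks: what they emulate

The fixtures reproduce displacement-controlled plate problems on
[-1, 1]²: uniaxial extension of a StVK plate with a fixed central hole
(outer edges displaced by ±1), and shear of a neo-Hookean plate
(`u₁ = 0.25(X₂+1)` on the lateral edges) with the hole rim displaced
radially inward by 0.2 (read from "the hole is under contraction"; an
`outward` flag flips the sign).  Targets come from a coarse reference
solve: bilinear elements on a structured grid, total-energy minimisation
(L-BFGS) under ramped Dirichlet data, with the neo-Hookean log barrier
C¹-extended below J₀ = 0.05 so intermediate load steps with locally
inverted cells keep finite energy and useful gradients (the extension is
inactive at converged solutions; the shear solution bottoms out at
J ≈ 0.41).  Restricted to homogeneous problems the solver reproduces
closed-form affine solutions to ~1e-8.  The three-hole bending plate
uses an exact beam-bending diffeomorphism and a documented, parameterised
hole layout, since the original geometry is not published in closed form.

Manufactured diffeomorphisms (translation, rotation, affine stretch,
radial inflation, isotropic exponential growth, bending) carry exact
inverses and gradients; target rasters are generated by exact membership
tests `inside(inverse(x))`, so ground truth is available everywhere.
3-D pairs are balls under exact growth/shrinkage maps.  Besides binary
occupancy, rasters can encode interior depth (`distance`,
`distance_rgb`, `occupancy_distance`): these carry alignment
information throughout the body, which is what makes sub-voxel growth
rates recoverable — the 3-D growth benchmark trains its predictor on
occupancy-plus-distance intensity while scoring overlap on the binary
masks.

What passing these benchmarks does **not** show: performance on real
MRI/confocal intensities (texture, noise, partial-volume effects,
intensity inhomogeneity), behaviour under non-diffeomorphic topology
change, or robustness to mis-specified physical frames.  The synthetic
indicator images carry information only at (or, smoothed, near) the
boundary, which is the harder case for the mismatch term but the easier
case for the physics.

## Reduced problem sizes

The benchmark presets are scaled down from the reference numerics so a
full run fits on a single desktop CPU core: quadrature 100 × 56 and
108 × 90 elements for the 2-D plates (vs 200²), 18³ for the 3-D ball
(vs 45³, raster 44³); mini-batches of 600/400/300–150 elements (vs
4000/2000/1500); and 2 600–3 500 Adam epochs at learning rate 4e-4
(2-D) or 600–1 000 at ~1e-3 (3-D) instead of tens of thousands of
epochs at 5e-5.  The learning rate
is raised in proportion to the reduced epoch count because Adam's
normalised step makes the reachable displacement scale ≈ lr × epochs;
the β weights, material constants, flow steps, and network widths are
unchanged.  At this scale the plate benchmarks reproduce whole-domain
Dice within about ±0.01–0.02 of the full-scale values, and the growth
benchmark recovers κ* ∈ {0.05, 0.2} within 10% with the mean elastic
Jacobian within 0.3% of unity.

## Degenerate inputs, tolerances, tie-breaks

Empty/ non-finite rasters, non-positive spacings, fields with no 0.5
crossing ("no boundary"), empty clouds, and det F ≤ 0 under log-based
energies are rejected with messages; NaN losses abort with the epoch
index.  Dice of two empty masks is defined as 1 to keep the metric
total.  Whole-domain Dice thresholds the fields at 0.5 on the target
lattice and always pulls back through the inverse map (never forward
splatting).  A single run seed drives network init and batch sampling;
the corrector derives its seed from it.  Runs with the same seed and
config reproduce loss traces bit-for-bit on a given platform (BLAS
reduction order may vary across platforms).

## Known limitations

- The reverse-Euler inverse is O(Δt); Dice values inherit a sub-pixel
  bias at strong deformations.  Newton polish removes it but is off by
  default to keep the reported protocol uniform.
- The gate makes the corrector's effective step size vanish near the
  boundary, so interior equilibrium converges faster than the
  near-boundary layer.
- The reference solver is deliberately coarse (structured bilinear
  cells); its rasterised targets carry ~1-cell boundary jitter, which
  bounds the Dice any registration can reach on them.
- Growth is isotropic and homogeneous (θ I); fiber/area growth tensors
  and deformation-dependent growth kinetics are out of scope.
- Oblique NIfTI affines and inter-grid resampling are not supported.
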