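# nodereg

Physics-informed deformable image registration built on neural-ODE flow
maps, for analysts who need a registration map that is not only accurate
but *mechanically admissible*: invertible everywhere, in equilibrium
under a hyperelastic material model, and — for longitudinal biological
data — decomposable into elastic deformation and volumetric
growth/shrinkage.

## The method

Two images are encoded as interpolated indicator fields `S1(X)` (source)
and `S2(x)` (target).  Registration runs in two stages:

**Predictor.**  A transformation `x(X)` is defined as the flow of
`dx/dt = NN(x; w, b)` integrated with `n` forward-Euler steps
(`Δt = 1/n`); small enough residual steps keep the composed map
injective (`det F > 0`).  The network parameters minimise

```
∫_Ω (S1(X) − S2(x(X)))² dΩ  +  β ∫_Ω S1(X) R(F(X)) dΩ
```

with a small β and a regularizer `R` (by default the strain energy
density ψ of a Saint Venant–Kirchhoff or neo-Hookean material,
`F = ∂x/∂X`).  Integrals are evaluated with per-element Gauss–Legendre
quadrature and stochastic mini-batches of elements (Adam).

**Corrector.**  The predictor fixes an implied Dirichlet problem: its
transported boundary is held fixed by a distance gate
`D_p(x) = min‖x − x_boundary‖` that multiplies each velocity increment
of a second flow, which then minimises the total potential energy

```
Π = ∫_Ω S1(X) ψ(F^e) dΩ,      F = F^e F^g,   F^g = θ I,   θ = exp(±κt)
```

so the final map satisfies large-deformation equilibrium in the weak
(energy-minimisation) sense without losing the alignment.  With growth
enabled, the rate κ is co-optimised and only the elastic part `F^e`
stores energy — this separates, e.g., brain-atrophy volume loss or
embryonic growth from elastic shape change.  Ordered frame sequences
are handled by composing per-interval maps while always accounting for
energy relative to the first frame.

Quality is reported as the Dice overlap of the warped source against
the target (pull-back through the approximate inverse flow), alongside
Jacobian statistics and principal stretches.

## Worked example

```python
import nodereg as nr
from nodereg import fixtures as fx
from nodereg.fields import smoothed

pair = fx.disc_translation(resolution=96, shift=(0.2, 0.0))
quad = nr.build_quadrature(pair["frame"], (48, 48), gauss=2)
cfg = nr.PredictorConfig(beta=1/6000, epochs=500, batch_elements=400,
                         learning_rate=1e-3, seed=3, hidden=(20, 20, 20))
res = nr.fit_predictor(smoothed(pair["S1"], 1.0), smoothed(pair["S2"], 1.0),
                       quad, cfg)
dice = nr.whole_domain_dice(pair["S1"], pair["S2"], res.predictor.inverse)
print(f"Dice {dice:.3f}")
print(f"min det F {res.invertibility['min_det']:.3f}, "
      f"fraction det F <= 0: {res.invertibility['fraction_nonpositive']:.3f}")
```

prints (seeded run):

```
Dice 0.988
min det F 0.988, fraction det F <= 0: 0.000
```

i.e. the fitted flow recovers the 0.2-unit translation of the disc with
98.8% overlap and stays invertible everywhere (`det F > 0` at every
probe point).  The same pattern with `fit_corrector` afterwards attaches
the energy-minimising stage; `fit_sequence` chains frame pairs.

A CLI wraps the same pipeline for on-disk images (PNG/`.npy`/NIfTI):

```
nodereg make-fixture disc_translation --out fixtures/
nodereg register config.yaml          # writes checkpoints, traces, summary
nodereg evaluate out/predictor.npz --source S1.png --target S2.png
```

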