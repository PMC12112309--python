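# Methods

## Model

The package implements a two-layer rate model. Layer 1 holds error units
computing `e = x − A s`; layer 2 holds coding units whose responses follow

    ṡ = η_s (Aᵀ e − H(s)),

integrated by explicit Euler with a fixed rate η_s. `Aᵀ` and `A` are the
feedforward and feedback connections; `H` is a per-unit self-regulation
(homeostasis) function, mathematically the scaled derivative of a sparsity
prior, `H = λQ′`. Responses are rectified at zero after every Euler step
(projected dynamics) when the nonnegativity flag is set, which is the default:
responses are interpreted as firing rates. Learning applies one Hebbian step
per batch, `A ← A + η_a · mean(e sᵀ)`, followed by L2 normalization of every
column. The batch-mean convention makes η_a independent of batch size; the
slow-weight/fast-response timescale separation comes from updating weights
once per fully iterated batch, not from the relative magnitudes of η_a and
η_s.

Equilibria solve `−AᵀA s + Aᵀx = H(s)`. In one dimension this is the
intersection of the line `Y(s) = −s + x` with `H(s)`, and
`analytic_response_curve` computes it by bracketed Brent root-finding per
input value. The Jacobian `J(s) = −AᵀA − diag(H′(s))` is symmetric, so its
spectrum is real; with full-column-rank A and monotonically increasing H
every equilibrium is stable.

## Homeostasis families

All families share `H(0) = 0` except the L1 case (`power_prior` with α = 1),
whose constant derivative λ acts as an activation threshold under rectified
dynamics.

| family | H(s) | role |
|---|---|---|
| `zero` | 0 | no regulation; least-squares limit |
| `cauchy_prior` | λ·s/(1+(s/σ)²) | classic sparse-coding prior |
| `gaussian_prior` | λ·s·exp(−(s/σ)²) | classic sparse-coding prior |
| `power_prior` | λ·s^(α−1), s ≥ 0 | α = 1 is L1; learning requires 1 ≤ α < 2 |
| `dn_equivalent` | ρ(γ/s−1)^(−1/n) − s, s < γ | exact single-neuron DN equivalence |
| `concave_convex` | two-branch form with turning point x₀ | learning + saturation |

The published typography of the two classic priors is ambiguous; the forms
above are the conventional sparse-coding ones (the Cauchy form carries σ only
inside the quadratic term, so at σ = 1 all readings coincide).

`dn_equivalent` diverges at s = γ. Evaluation at s ≥ γ(1−10⁻¹²) raises a
domain error rather than clamping — saturating the state is the integrator's
job, and it clamps at (1−10⁻⁹)γ, counting clamp events. The derivative of the
concave–convex form vanishes at x₀ for n ≥ 2, making the concave-to-convex
transition smooth; both branches equal λ at x₀ exactly.

## Numerical choices

- **Response iteration**: explicit Euler, default η_s = 0.002, tol 10⁻⁸ on
  max |Δs|, max 5000 iterations. Oscillation is flagged when the sign of Δs
  alternates over the final 10 iterations for any unit — large η_s with a
  steep H produces this regime.
- **Training iteration**: η_s = 0.02, max 400 iterations, tol 10⁻⁵. At the
  scales used here this reaches the same responses as a 10⁻⁸/8000-iteration
  run to ~4 decimals while keeping a 3000-batch run near two minutes.
- **Analysis iteration**: η_s = 0.005, max 6000 iterations. The
  concave–convex H is stiff near saturation (H′ of order 10²), and explicit
  Euler needs η_s·(λ_max(AᵀA) + H′) < 2 for local stability; 0.005 keeps the
  strongest gratings convergent.
- **Equilibrium solver**: 300 trust-region-limited projected-Euler warm-up
  steps, then damped Newton on the inactive set, treating nonnegativity as a
  complementarity condition (s_i = 0 is accepted when its drive is
  nonpositive). Diverging H′ at a domain boundary is replaced by a 10¹²
  surrogate in the Newton matrix and in stability spectra. A long-horizon
  projected-Euler fallback runs if Newton stalls; failure to reach the
  tolerance raises with the best residual.
- **Naka–Rushton fitting**: bounded trust-region least squares with γ ∈
  (0, 2·max response], ρ ∈ (0, 2·max contrast], n ∈ [0.5, 8], five
  deterministic starts on a coarse grid. Constant curves are flagged
  degenerate, not fitted.
- **Gabor fitting**: eight orientation starts (22.5° grid), center at the
  energy centroid, spatial frequency at the spectral peak; the fit error is
  the relative L2 residual ‖RF − G‖/‖RF‖. A dense 36×3 multistart reproduces
  the 8-start optimum on the models tested here.

## Synthetic images

The generator emulates pre-processed natural scenes: each 128×128 image is a
1/f-filtered Gaussian noise floor (weight 0.35) plus 600 oriented Gaussian
strokes with uniform random position and orientation, length U(1.5, 6) px,
thickness U(0.4, 1.2) px, and Laplace-distributed signed amplitudes; images
are standardized to zero mean, unit variance. Measured on the default set:
radially averaged power-spectrum slope ≈ −1.6 (natural scenes: ≈ −2) and
excess pixel kurtosis > 6 (heavy-tailed, like natural scenes). Whitening uses
the standard radial filter f·exp(−(f/f₀)⁴), f₀ = 0.4 × Nyquist,
peak-normalized so the operation is linear with a fixed gain; whitened pixel
SD comes out near 0.6.

Stroke geometry matters: strokes much longer than a patch produce
image-spanning learned features whose Gabor envelopes never fit inside the
16×16 field, so no cell survives the central-envelope selection rule. The
short-stroke statistics above yield localized receptive fields comparable to
natural-image runs. What the generator does *not* reproduce: occlusion
structure, curvature, long-range contour continuity, luminance gradients, and
the full kurtosis of natural scenes — so passing tests demonstrate that the
pipeline learns localized oriented features from heavy-tailed oriented input,
not that it reproduces any specific natural-image result.

## Training and analysis defaults

Training: M = 64 units, 16×16 patches (L = 256), batches of 100, η_a = 0.2,
3000 batches for the desk-scale runs (5000 by default in the config), seeded
Gaussian weight initialization with unit-norm columns, zero-column rescue by
a fresh seeded draw (counted in the report). With the L1 homeostasis
(λ = 0.3) this yields ≈ 85–90% of units passing the 40% Gabor-error
criterion in about two minutes.

Analysis: Gabor fit on every column of A; selection keeps cells with fit
error < 0.40, center within 3 px margins, and center ± 2·max(envelope SD)
inside the patch. Contrast-response curves use gratings at the fitted
preferred orientation and spatial frequency, 16 phases uniform on [0°, 360°),
contrasts {0.02, 0.05, 0.1, 0.25, 0.5, 0.75, 1.0} (grating amplitude equals
contrast on the whitened-intensity scale; no Michelson normalization). The
"stable response" is the converged value of the iteration, not a time
average; the suboptimal scaling is the ratio of suboptimal (default 30°
offset) to optimal mean response at the highest common contrast.

## Design choices where the design was open

- The response nonlinearity at analysis time is a property of the
  homeostasis, not of the learned dictionary: the equilibrium condition
  depends on A only through AᵀA ≈ I. The saturation/linearity analyses
  therefore equip the trained dictionary with the homeostasis under study
  (concave–convex for saturation, zero for the linearity control) — the same
  manipulation as removing H after learning.
- Training the dictionary *from scratch* under the concave–convex H at desk
  scale does not produce selectable Gabor cells on the synthetic data: that
  H has no activation threshold (H(0) = 0, finite slope), so about half the
  units stay weakly active on every patch, and its convex wall caps
  coefficients near 1.2 so strong components smear across units. Desk-scale
  dictionary learning therefore uses the L1 prior; this is a scale
  limitation, documented rather than hidden.
- Per-unit homeostasis specs are possible in principle but the implementation
  shares one spec across units, since the function depends only on the
  single-neuron homeostatic mechanism.
- Flattening between patches and vectors is column-major everywhere.

## Known limitations

- Only the linear-feedback (f(y) = y) two-layer case is implemented; deeper
  hierarchies, general activation functions, spiking or Dale's-law variants
  are out of scope.
- The multi-neuron DN-to-SPC homeostasis has no closed form; only the
  one-dimensional reduction is provided.
- All implemented homeostasis families give zero spontaneous response at
  x = 0; families with negative values near the origin (nonzero spontaneous
  activity) are not provided.
- Explicit Euler limits how steep a homeostasis the iteration can follow;
  the analytic equilibrium solver has no such limit and should be preferred
  for very stiff H.
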