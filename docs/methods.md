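# Methods

## Forward model and inversion

Oxygen tension maps are estimated from S phase-delayed phosphorescence
intensity images. The chain is: Stern–Volmer quenching
τ(pO₂) = τ₀ / (1 + K_φ τ₀ pO₂); frequency-domain phase lag tan θ = ωτ;
sinusoidal gated intensity I(θₙ) = a₀ + a₁cos θₙ + b₁sin θₙ with
θ = atan2(b₁, a₁). On pO₂ ∈ [0, ∞) the chain is a bijection onto
θ ∈ (0, arctan(ωτ₀)], so recovery is well-posed pixelwise in the noise-free
case; the test suite verifies round trips to 1e−10 relative.

Phase recovery uses the quadrant-aware two-argument arctangent (a
single-argument arctangent of b₁/a₁ is ambiguous by π). A pixel is valid
when θ ∈ (θ_min, π/2 − θ_min) with θ_min = 1e−6 rad; outside that range the
lifetime is non-positive or unbounded and the pixel is flagged invalid
(NaN) rather than raised, so whole-image estimation never aborts. Estimates
are not clipped by default — out-of-range values are a real failure mode of
noisy LS and deliberately stay visible; a [0, 100] mmHg clamp is available
as a flag. Validity gating does allow θ > arctan(ωτ₀), which maps to a
negative pO₂ (finite lifetime longer than τ₀): such values are reported,
not masked, for the same reason.

### Acquisition parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| S (phases) | 10, equally spaced on [0, 2π) | — | standard phase-delayed acquisition count |
| Δt | 74 | µs | phase-delay increment of the modelled instrument |
| ω | 2π/(S·Δt) ≈ 8491 | rad/s | modulation period inferred as S·Δt (one full cycle); an implementation choice, configurable |
| τ₀ | 637 | µs | literature zero-oxygen lifetime of Pd-porphyrin |
| K_φ | 381 | (mmHg·s)⁻¹ | literature quenching constant of Pd-porphyrin |

ω, τ₀ and K_φ are configuration parameters, not measured constants of this
package; all results scale through the bijection above, so estimator
comparisons (LS vs RLS vs fast RLS) are insensitive to their exact values.
With these defaults, pO₂ = 60 mmHg gives τ ≈ 40.9 µs and θ ≈ 0.334 rad.

Equal spacing over a full cycle makes AᵀA = diag(S, S/2, S/2), the
structural fact the closed-form regularized estimates substitute into; the
LS pseudo-inverse is computed once per acquisition by Cholesky on the
normal equations (AᵀA is SPD at full column rank) and applied to all pixels
as one matrix product.

## Regularization

Maps are vectorized column-major: pixel (r, c) (1-based) → index
(c−1)R + r, so the 3×3 neighbourhood sits on linear-index offsets
{0, ±1, ±R, ±(R−1), ±(R+1)}. K carries weights l (self), p (edge-adjacent),
q (diagonal) on those bands with l + 4p + 4q = 1. Defaults l = 0.5,
p = 0.1, q = 0.025: a center-weighted averaging kernel satisfying the
constraint; by Gershgorin the spectrum of K then lies in [0, 1], so K is
positive semidefinite and I − K is a proper smoothing penalty. All three
are configurable.

K is by default the literal Toeplitz band, which couples the last pixel of
a column to the first pixel of the next. This "wrap" artifact is retained
deliberately: the boundary error analysis of the fast method (first/last
2R+2 rows of KᵀK are non-Toeplitz) presumes exactly this construction, and
the artifact only affects two rows per column at the map border. A
graph-exact variant (`wrap=False`) that zeroes cross-column couplings is
provided; interior rows are identical.

L = I + β(I−K)ᵀ(I−K) is symmetric with every eigenvalue ≥ 1 for any β ≥ 0
(a quadratic form plus the identity), hence always invertible — stronger
than positive definiteness of K. The exact RLS solve factorizes L once
(sparse LU with fill-reducing ordering; L⁻¹ is never formed) and solves for
a₁ and b₁; a₀ passes through unregularized because pO₂ depends only on
b₁/a₁ and the closed form is derived for a₁, b₁.

The per-pixel regularization coefficient γ of the cost relates to β as
γ = S·β/2, forced by matching the gradient of the expanded global cost to
the closed-form normal equations; the implementation is parameterized by β
throughout.

## The fast window method

For an R_s×R_s map (default R_s = 13, odd so the middle row is centrally
symmetric), L_s is an R_s²×R_s² matrix. Its inverse is near-Toeplitz:
shifting the middle row reconstructs the other interior rows. The window is
the middle row of L_s⁻¹ (obtained by one sparse solve L_s w = e_mid),
reshaped column-major to R_s×R_s and renormalized to sum exactly 1 (the raw
sum, ~0.9999 at β = 5, differs from 1 only through the boundary rows of
K_s; renormalization makes constant maps exact fixed points). The window is
applied to the LS a₁ and b₁ maps by cross-correlation with symmetric
(mirror) border padding — chosen because it avoids darkening at edges and
approximately preserves the sum-to-one property; equivalence with the exact
solve is only claimed for interior pixels (margin ≥ (R_s−1)/2 + 2), where
it holds to ≤1% relative and typically to ~1e−4 on noisy LS maps.

Two quantitative caveats, both measured by the test suite:

- The window has small negative side-lobes (min entry ≈ −3×10⁻³ at β = 5):
  L has positive off-diagonals through β(I−K)², so L⁻¹ is not elementwise
  non-negative. The side-lobes are two orders below the center weight and
  harmless in practice.
- The shifted-middle-row reconstruction of L_s⁻¹ is accurate to ~1e−3
  absolute over all interior rows (≈5e−5 away from boundary columns) at
  β = 5 — small relative to the significant entries (~1e−1) but not exact.
  The fast-vs-exact agreement (≤1% interior, ~0.5% on vessel-MAE) is the
  operative measure of this approximation.

Window extraction is independent of the target map size: a 13×13-derived
window reused on 50×50 and 60×90 maps keeps the same interior agreement
with the exact solve.

## Iterative reference solver

The global cost is a strictly convex quadratic, so a literal Newton step is
one exact linear solve — the closed-form solution itself. To preserve the
structure of the runtime comparison (iteration count growing with β versus
a β-independent window pass), the iterative solver implements fixed-step
gradient descent from the LS initialization, with a₀ held at its LS value.
The default step is δ = 2/(S(1 + β·λ_max((I−K)²)) + ε) with ε = S: the
Hessian is S(I + β(I−K)ᵀ(I−K)) with spectrum in [S, S(1+β·λ_max)], so this
is the optimal fixed step 2/(λ_min+λ_max) — monotone descent with
worst-case contraction (κ−1)/(κ+1). With ε → 0 the step sits at the bare
stability bound and the top mode contracts by only ~0.998 per iteration;
that variant is not offered. A second interpretation, δ = 1/(S(1+β)) under
the weight constraint (the printed step-size rule rescaled by 1/S because
the summed gradient carries a factor S), is available as
`step_size="paper"`; both are checked against the stability bound
δ < 2/λ_max(Hessian) and converge to the closed-form solution to ≤1e−6
relative on the test problems. Descent stops when the joint gradient norm
falls below `grad_tol` times its initial value; non-convergence returns the
best iterate with a RuntimeWarning, never silently.

## Synthetic retina phantom

The generator emulates the vascular oxygenation pattern of the rat retina
under normoxia: straight artery/vein spokes radiating from the optic disc
at seed-jittered angles (default 6 + 6, alternating), arterial pO₂
60 mmHg at the disc rim declining linearly by 15 mmHg to the farthest map
corner (floored at the venous level), venous pO₂ constant at 35 mmHg,
background tissue at 25 mmHg. Default map 485×600 px at a nominal 5 µm/px;
disc diameter and vessel width default to min(R,C)/8 and min(R,C)/48 px
(≈300 µm and ≈50 µm on the default map) so smaller validation phantoms
keep proportionate geometry. Generation is deterministic given the seed.

Noise is i.i.d. white Gaussian on the phase images with variance
σ² = P_signal/10^(SNR_dB/10), where P_signal is the mean squared intensity
over all pixels and frames (power definition, stated explicitly because
SNR-on-variance would differ by the DC term a₀). Study levels are
15/20/25 dB.

What the phantom does **not** emulate: vessel curvature and branching,
optical blur/PSF, photobleaching, shot noise, spatially varying probe
concentration, eye motion. Passing tests therefore demonstrate estimator
correctness and the LS-vs-RLS noise behaviour under the modelled
conditions, not robustness to those real-data effects; in particular the
smoothing prior's benefit depends on pO₂ varying slowly within the window,
which the straight-vessel phantom satisfies by construction.

## Evaluation

MAE/RMSE/bias are computed over vessel pixels by default (full-map
evaluation via flag): background pixels would dilute the clinically
relevant error, and the evaluation mask is otherwise unspecified in this
problem domain. Pixels whose phase recovery failed are excluded from the
error and counted separately — including them would either hide LS
artifacts (if clamped) or let a few infinities dominate. Wall-clock times
are reported in pipeline output for context, never asserted.

## Problem sizes

Validation uses 50×50 phantoms for solver-equivalence checks, 100×100
phantoms with 100 noise replicates for the LS-dominance statistics, and
structural checks on matrices up to 307200² (640×480 maps, sparse
construction only). These sizes give stable statistics (the dominance
margin is ~6 mmHg MAE against a replicate spread well under 1 mmHg) while
keeping the full suite around a minute of compute. The exact solve itself
handles M ≈ 3×10⁵ through sparse LU; the fast method has no practical size
limit.
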