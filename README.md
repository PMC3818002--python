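# plimox

Estimation of retinal vascular oxygen tension (pO₂, mmHg) from
phase-resolved phosphorescence lifetime image stacks, for researchers in
retinal oximetry and frequency-domain lifetime imaging (PLIM/FLIM). The
package provides the conventional least-squares (LS) estimator, the exact
closed-form regularized least-squares (RLS) estimator, a fast RLS variant
that reduces the global regularized solve to a single weighted-averaging
window, an iterative reference solver, and a synthetic retina simulator for
validation.

## The model

An oxygen-sensitive phosphor (e.g. Pd-porphyrin) injected into the retinal
circulation is quenched by oxygen following the Stern–Volmer relation

    τ₀/τ = 1 + K_φ τ₀ pO₂,

where τ is the phosphorescence lifetime, τ₀ the zero-oxygen lifetime and
K_φ the quenching constant. In frequency-domain imaging the lifetime
appears as a phase lag θ between modulated excitation and emission,
tan θ = ωτ. Each pixel is imaged at S gain-modulation phases θₙ, and the
recorded intensity follows a three-parameter sinusoid

    I(θₙ) = a₀ + a₁ cos θₙ + b₁ sin θₙ,   θ = tan⁻¹(b₁/a₁),

so per-pixel LS on the S×3 design matrix A (rows (1, cos θₙ, sin θₙ))
recovers (a₀, a₁, b₁) and hence pO₂. LS is noisy: it produces high-variance
maps with values outside the physiological range.

Because pO₂ varies negligibly within a 3×3-pixel neighbourhood (~15×15 µm²),
a regularizer couples each pixel to its neighbours through a sparse banded
weighting matrix K (self weight l, edge-adjacent p, diagonal-adjacent q,
with l + 4p + 4q = 1). The regularized cost

    C(X) = ‖Y − AX‖²_F + γ ‖X − KXᵀᵀ‖²_F

is a strictly convex quadratic whose exact minimizer is a sparse solve
applied to the LS maps:

    â₁ᴿᴸˢ = L⁻¹ â₁,  b̂₁ᴿᴸˢ = L⁻¹ b̂₁,  L = I + β (I − K)ᵀ(I − K).

The fast method exploits the near-Toeplitz structure of L⁻¹: its interior
rows are shifts of one row, and that row barely changes with map size. So
L_s⁻¹ is computed once on a small R_s×R_s map (an R_s²×R_s² system), its
middle row is reshaped into an R_s×R_s window, and the window is applied to
the LS maps by 2-D cross-correlation — O(M R_s²) instead of a global
M×M solve, with negligible accuracy loss away from map borders.

## Worked example

```
plimox simulate --rows 80 --cols 80 --snr-db 20 --seed 4 --outdir sim
plimox estimate sim/stack_noisy.tif --method rls-fast --beta 5 --out po2_fast.tif
plimox estimate sim/stack_noisy.tif --method ls --out po2_ls.tif
plimox evaluate --truth sim/truth_po2.tif --est po2_fast.tif --mask sim/truth_po2_labels.tif
plimox evaluate --truth sim/truth_po2.tif --est po2_ls.tif --mask sim/truth_po2_labels.tif
```

prints

```
MAE 6.7467 mmHg  RMSE 8.8518 mmHg  bias -4.5666 mmHg  (930 valid, 0 invalid)
MAE 12.7172 mmHg  RMSE 52.9370 mmHg  bias +3.7458 mmHg  (928 valid, 2 invalid)
```

The first line is the fast RLS estimate, the second plain LS, both scored
over vessel pixels of the synthetic retina (arteries 60 mmHg at the optic
disc declining linearly, veins constant 35 mmHg, 20 dB white Gaussian noise
on the 10 phase images). Regularization halves the mean absolute error and
collapses the RMSE six-fold — the huge LS RMSE comes from the artifact
pixels whose recovered phase leaves the physical range (2 pixels here are
flagged invalid outright). The same computation is available from Python via
`plimox.run_pipeline` or the individual functions (`ls_estimate`,
`rls_direct`, `extract_window`, `rls_fast`, `rls_iterate`).

`plimox window --beta 5 --window-size 13 --out win.csv` exports the 13×13
averaging window itself (its raw middle-row sum, 0.999897 here, is printed
before renormalization).

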