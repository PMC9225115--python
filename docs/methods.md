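# Methods

## The reconstruction problem

Spin-lock (T1ρ) mapping acquires one k-space data set per spin-lock time
TSL_c.  The pixel-wise signal magnitude follows the mono-exponential model

    S_c = S0 · exp(−TSL_c / T1ρ),

with S0 the baseline (TSL = 0) intensity and T1ρ the rotating-frame
relaxation time in milliseconds.  Writing θ for the image phase (shared
across contrasts, since the spin-lock preparation is separate from the
imaging segment), the measurement model is

    m = K(S0, T1ρ, θ) + e,        K = A ∘ B ∘ D,

where D maps the parameter maps to per-contrast magnitude images
r_c = S0 ⊙ exp(−TSL_c/T1ρ), B embeds magnitude and phase into complex
images r_c e^{iθ}, and A is the block-diagonal Fourier encoding —
undersampled centred unitary FFT for cartesian row sampling, or a
Kaiser–Bessel gridding NUFFT for golden-angle radial trajectories —
normalized to unit operator norm by power iteration (30 iterations,
tolerance 1e−6).

The **embedded** reconstruction estimates the three real maps directly:

    min_{S0,T1ρ,θ} ‖K(S0,T1ρ,θ) − m‖² + α₁ TV(S0) + α₂ TV(T1ρ)
                    + α₃ ‖∇θ‖² + δ_{S0 ≥ a₁} + δ_{T1ρ ≥ a₂},

a non-convex, non-smooth problem solved by non-linear primal–dual
proximal splitting: each iteration takes a primal step through the
Jacobian adjoint of the stacked map H = [K; ∇S0; ∇T1ρ; ∇θ], projects
onto the box constraints, over-relaxes with ω = 1, and applies the dual
resolvents (a linear resolvent for the squared data term, pixel-wise disc
projections for the TV duals, a linear shrink for the phase-smoothness
dual).  For C contrasts this parameterization carries 3N real unknowns
versus 2NC for a per-contrast complex image series — a 79% reduction at
C = 7 and 70% at C = 5 — and lets the regularization act on the map of
interest itself.

Two **compressed-sensing references** reconstruct the complex image
series u first and fit the signal model afterwards:

* S1+C1: ‖Au − m‖² + α TV_S(u) + β TV_C(u) (isotropic spatial TV per
  contrast plus an L1 penalty on first contrast differences);
* S1C2: ‖Au − m‖² + α TV_SC(u), with TV_SC the pixel-wise root of the
  squared spatial differences plus the squared second-order contrast
  difference (interior contrasts only).

Both are convex and solved by Chambolle–Pock with steps
τ = σ = 0.99/‖[A; differences]‖ (power iteration).  Complex TV uses the
modulus of the complex differences.  A zero-filled inverse FFT is the
non-iterative reference for cartesian data.

The **pixel fit** converting image series to maps is bounded non-linear
least squares on S0·exp(−TSL/T1ρ) per pixel (trust-region reflective,
analytic Jacobian), started from the closed-form log-linear fit of
log |u| against TSL.  Bounds are T1ρ ∈ [0.1, 1000] ms and S0 ≥ 0; pixels
whose magnitudes never exceed 1e−3 of the series maximum are flagged
unfittable and carry the lower-bound values.  S0 is taken from this fit,
not from the TSL = 0 image.  An optional `tsl_max` drops contrasts whose
signal sits at the noise floor (the experimental protocol dropped
TSL = 128 ms this way).

## Step sizes of the embedded solver

The Jacobian of B ∘ D is diagonal per pixel, so the three parameter
blocks have cheap squared sup-norm sums

    L₁² = Σ_c ‖exp(−TSL_c/T1ρ)‖∞², L₂² = Σ_c ‖r_c TSL_c/T1ρ²‖∞²,
    L₃² = Σ_c ‖S0 ⊙ exp(−TSL_c/T1ρ)‖∞².

The primal block steps are **inverse** to these, τ_i = scale/L_i²: this
is the per-block curvature scale, and it is what gives the weakly coupled
T1ρ block (whose Jacobian entries carry the small factor TSL/T1ρ²) the
large steps — order 10²–10³ ms per unit gradient at unit image intensity
— that it needs to traverse its 20–120 ms range.  A `tau2_multiplier`
can boost τ₂ further; with the inverse rule the default 1 is adequate,
and multipliers ≳ 5 combined with an active T1ρ-TV dual were observed to
destabilize the non-convex iteration, so the presets leave it at 1.

A single dual step cannot serve both the data block (row norm ≈ 1 after
normalization) and the T1ρ-TV block (which needs σ·8τ₂ < 1 with τ₂
large), so each dual block receives its own step in the standard
diagonally preconditioned fashion:

    σ_data = 0.5 / Σ_i τ_i L_i²,   σ_TV,i = 0.15 / (8 τ_i),

whose budgets sum to 0.95 < 1, guaranteeing the convergence criterion
‖Σ^{1/2} ∇H(x) T^{1/2}‖² < 1 (the generalization of τσ‖∇H‖² < 1 to
per-block steps).  Because the sup-norm bounds are loose for radial
encodings (the per-block maxima sit at different pixels), σ_data is
tightened against the measured data-row norm ‖A·J·T^{1/2}‖² obtained by
power iteration.  The criterion itself is re-estimated numerically at
every logged iteration (default every 50) and the primal steps are
rescaled globally if it is ever found violated; all block norms are
refreshed at every iterate and both τ and σ are kept non-increasing.

Initialization: S0⁰ = max(|z|, a₁) and θ⁰ = arg z from the zero-filled
(cartesian) or ramp-density-compensated adjoint (radial) reconstruction
of the TSL = 0 contrast, with the radial adjoint amplitude calibrated on
a centred point source; T1ρ⁰ ≡ 20 ms; dual variables zero.  Constant-S0
initializations are known to strand the non-convex iteration, while the
T1ρ constant mainly affects speed.  Because the phase map is shared by
all contrasts, `phase_init="composite"` reads θ⁰ from the adjoint of the
pooled data of every contrast instead — under complementary sampling the
pool has the union k-space coverage, and the better-conditioned phase
start was measured to halve the iterations the radial problems need
(π-flipped pixels in a streaky single-contrast adjoint seed local minima
that the magnitude-nonnegative parameterization cannot cross).  Two
further robustness options, `phase_init_smooth` (read θ⁰ from a
low-passed adjoint) and `phase_warmup_iters` (hold θ for the first
iterations), default off.  Stopping: relative primal change below
`rel_tol` (default 1e−6) or `max_iters` (default 10 000); the test and
acceptance presets cap iterations well below convergence-to-tolerance
(see below).  Degenerate air pixels are clamped to the box bounds and
carried along — no masking.  a₁ = a₂ = 1e−6 (signal units / ms).

A note on the regularization scales: all three weights multiply
penalties whose data-term counterweight scales with the squared image
intensity, so usable values depend on the intensity normalization.  At
this package's unit-peak phantom scaling the phase weight α₃ must sit
near 1e−5 — at 0.01 the penalty's curvature (≈8α₃) rivals the data
term's phase curvature (2Σ_c r_c² ≈ 0.1 where S0 ≈ 0.2) and the
minimizer audibly flattens the true phase ramp.  Values quoted for
raw-scanner-intensity data (S0 ~ 10³–10⁴), where 0.01 is relatively
~10⁶ times weaker, do not transfer.

## NUFFT

No NUFFT library ships with the package's dependency set, so the
operator is implemented directly: min–max-style Kaiser–Bessel
interpolation of width 4 on a 2× oversampled FFT grid, with Beatty's
shape parameter and the analytic kernel transform as de-apodization.
The interpolation matrix is assembled sparse (scipy CSR) once per
trajectory, making the adjoint exact to machine precision by
construction; forward accuracy against a direct discrete Fourier sum is
≈ 8e−4 relative on a 16×16 image with 8 spokes.  Trajectory units are
cycles/FOV in [−0.5, 0.5); radial readouts carry `matrix_size` samples
spanning the full k-space diameter, so a 192 matrix is fully sampled by
round(192·π/2) = 302 golden-angle spokes (increment 111.246°).  Ramp
density compensation is used only to initialize the embedded solver,
never inside the forward/adjoint pair.

## Synthetic data

The phantom is the classic head-phantom ellipse table rasterised at
`base_size` (default 128) and zero-filled to `matrix_size` (default 192):
S0 is the additive ellipse image rescaled to a peak of 1; each ellipse
(in table order, later ellipses overwriting) carries a distinct T1ρ
evenly spaced over 20–120 ms — the exact per-ellipse assignment is a
package choice, made so that parameter-recovery tests have structured,
known ground truth; the phase is the ramp 2πx/192 per pixel column.
Spin-lock times default to 0, 4, 8, 16, 32, 64, 128 ms.

Sampling: radial subsets take consecutive golden-angle blocks of
round(total/AF) spokes per contrast (the sequence continues past the
full-sampling count where needed, so blocks never overlap — complementary
by construction; AF = 1 gives every contrast the full set).  Cartesian
subsets take round(N/AF) full rows per contrast: a centred quarter-block
always containing the zero-frequency row, the rest split evenly between
top and bottom and drawn in seeded random order without replacement
across contrasts.

Noise: complex Gaussian with total std equal to `noise_fraction` (default
0.05) of the mean magnitude of the noiseless samples; real and imaginary
parts are independent with std σ/√2.  All randomness is seeded.

What the simulation does **not** emulate: coil sensitivities and parallel
imaging, off-resonance and gradient imperfections, Rician magnitude bias,
3-D geometry, or anatomical structure.  Passing tests therefore
demonstrate correctness of the operators and solvers under the stated
noise model, not robustness to scanner physics beyond it.

## Problem sizes, presets and the evaluation metric

The packaged comparison preset (`reduced_radial_plan`) runs the radial
phantom at 48×48 (base 32) with the full 7-spin-lock protocol (0, 4, 8,
16, 32, 64, 128 ms), AF ∈ {1, 5, 10}, 5% noise, embedded runs capped at
7000 iterations and CS at 2500, with small per-model weight grids that
bracket each model's optimum as located by a wider development sweep.
The matrix is reduced but the contrast count is not: the embedded
model's unknown-count advantage is 1 − 3/(2C), i.e. 79% at C = 7 but
only 50% at C = 3, and dropping contrasts was measured to invert the
model ordering the comparison exists to probe.  The preset's phase
weight is α₃ = 1e−5 and the embedded runs use the pooled-contrast
("composite") phase initialization; both choices are unit-intensity
rescalings discussed above.  These sizes keep the whole comparison in
the ~10-minute range; the full study conditions (192×192, AF up to 101,
7-point log grids, 40k/10k iteration caps) are available as
`full_radial_plan` and are an overnight computation, consistent with
the hours-per-run cost of the embedded model at full size.

What the reduced comparison does and does not show: at this scale the
embedded reconstruction beats the combined spatial/second-order-contrast
TV model (S1C2) at the undersampled AFs with a margin that grows with
AF, and its standing against both CS models improves monotonically with
AF — the expected robustness-to-undersampling trend of the direct
parameterization.  It does not beat the S1+C1 model here: first-order
contrast TV is an almost perfectly matched prior for a phantom whose
contrast images are structurally identical up to the decay, and at
full sampling the two-step pipelines denoise more efficiently than
direct T1ρ TV can (the T1ρ–data coupling carries the small factor
TSL/T1ρ²).  The unknown-count advantage that drives the direct model's
reported dominance grows with both the contrast count and the
undersampling severity, so the balance at 192×192 with AF up to 101
need not match the desk-scale balance; the full-size plan exists to
measure exactly that.

RMSE against ground truth is evaluated on the phantom support for the
reduced preset.  At 48×48 the zero-padded background occupies most of
the field of view, and on background pixels the mono-exponential fit of
pure noise returns essentially arbitrary values inside its [0.1, 1000] ms
bounds; a full-field RMSE would then measure the fit bounds rather than
reconstruction quality and would scale with an arbitrary choice.  The
full field of view remains the default elsewhere and both options are
exposed (`rmse_mask`).

## Known limitations

* The embedded objective is non-convex; convergence is to a stationary
  point and depends on the initialization described above.
* Step sizes assume the encoding is normalized; feeding unnormalized
  operators would change the balance between the data and regularizer
  duals.
* Single-coil encoding only; a shared phase map across contrasts (a
  per-contrast phase would need the documented model extension).
* The S1C2 contrast stencil needs C ≥ 3; with fewer contrasts it reduces
  to pure spatial TV and the solver refuses rather than silently
  degrading.
* Radial "full sampling" covers the inscribed k-space disc: for
  sharp-edged objects a substantial share of spectral energy lies in the
  unsampled corners, so even noiseless AF = 1 radial reconstructions rely
  on the regularizer to extrapolate — full-data RMSEs are therefore
  nonzero for every model.
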