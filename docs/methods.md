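# Methods

This note documents the models, algorithms and design choices behind
`renalmdr`, in the spirit of a methods appendix: what is computed, under
which assumptions, with which defaults, and what the synthetic validation
does and does not demonstrate.

## Signal and kinetic models

**Linearity in concentration.** The DCE-MRI signal is taken as
`S(x,t) = S0(x) + C(x,t)`. The proportionality between signal and
concentration (relaxivity, pre-contrast T1, scanner gain) is absorbed into
the kinetic amplitude parameters, so `C` is carried in signal units and no
absolute calibration is attempted. This is sufficient for motion correction
and keeps the fitting linear; absolute quantification is out of scope.

**Two-compartment filtration model (2CFM).** Tissue concentration is the
arterial input `c_a(t)` convolved with a bi-exponential impulse response: a
plasma compartment with flow `FP` and mean transit time `TP` drains into a
tubular compartment with flow `FT` and mean transit time `TT`. Flows are
carried in mL/min/100mL and converted internally to 1/s (divide by 6000);
transit times are in seconds. The forward simulation uses the
bi-exponential convolution with trapezoid weights (second-order accurate; a
confluent branch avoids cancellation when `TP ≈ TT`), and an independent
stiff-safe ODE integration of the compartment equations is kept solely as a
cross-check oracle in the tests.

**Linearised fitting.** Integrating the compartment ODEs twice gives the
identity

    y(t) = α₁ I[y](t) + α₂ I²[y](t) + β₁ I[c_a](t) + β₂ I²[c_a](t)

for the baseline-subtracted signal `y = S − S0`, with
`α₁ = −(1/TP + 1/TT)`, `α₂ = −1/(TP·TT)`, `β₁ = FP` and
`β₂ = FP/TT + FT/TP` (rates in 1/s). `I` denotes the running integral,
implemented as the cumulative trapezoid with `out[0] = 0`; the identical
quadrature is used everywhere (fitting, diagnostics). `S0` is the mean of
the first `n0` frames (default 15; the digital reference object uses
`⌊baseline/frame interval⌋ = 13`). The per-pixel ordinary-least-squares
problem is solved batched over pixels via column-equilibrated normal
equations; rank-deficient pixels (flat time courses, or degenerate
regressors) are flagged and returned with zero coefficients and a
baseline-only prediction, so whole-image fitting never aborts. The fit only
aborts — deliberately — when more than half of all pixels fail the solve,
which indicates corrupt inputs rather than difficult pixels.

Transit-time rates are recovered as the roots of `z² + α₁ z − α₂ = 0`, the
larger root being `1/TP` (plasma transit is faster than tubular transit in
kidney tissue; the inverted ordering only warns). Complex or non-positive
roots are flagged invalid (NaN); the one-compartment limit
(`α₂ = β₂ = 0`) returns a single transit time with `TT` flagged absent.
Invalid pixels enter exported parameter maps as 0 with a separate validity
mask, so downstream error statistics remain finite.

**Modified Tofts (model-bias experiments only).** The 3-parameter model
`C = vp·c_a + Ktrans·exp(−kep t) ⊗ c_a` is fitted by a deterministic
linearised search: for each `kep` on a 128-point log-spaced grid
(10⁻⁴…1 s⁻¹) the two amplitudes follow in closed form; the best grid point
is refined by parabolic interpolation of the residual in `log(kep)` and the
amplitudes re-solved, with negative amplitudes projected to zero. Noise-free
round trips recover all three parameters to better than 1% without any
non-linear optimiser or starting values.

## Free-form deformation model

Coordinates are voxel-centre, 0-based, in pixel units. The deformation maps
corrected-frame coordinates to source-frame coordinates (backward warping).
Displacement vectors live on a rectangular control lattice whose first node
sits at the image corner and whose outermost nodes lie on or beyond the
opposite corner; the dense field is the separable tent-kernel (linear)
interpolation of the node vectors, and images are resampled with the same
tent kernel between voxel centres. Anisotropic per-axis spacings are
supported for 3D data. Out-of-bounds samples clamp to the edge: with
uniform background and shifts of ten or more pixels, zero-filling would
inject false edges into the kinetic fit, clamping does not. Halving the
lattice spacing reproduces the dense field exactly (piecewise-linear fields
are closed under midpoint refinement), which is what carries solutions
between resolution levels.

**Gradient convention.** The analytical cost gradient over control points
sums `W_j(x) · R(x,t) · ∇S(D(x,t))` over each kernel support, where `∇S` is
the *exact* derivative of the tent-kernel interpolant (one-sided cell
differences sampled at the deformed coordinates, zero where clamped). A
smoothed central-difference image gradient is also provided as a utility,
but the optimiser uses the interpolant-consistent derivative: it is the true
derivative of the implemented cost, so the analytical gradient matches
finite differences to rounding error, and descent directions are never
corrupted by an O(h) gradient-model mismatch at tissue edges.

## The registration engine

The joint cost `χ²(D,P) = ½ Σ (S_D − Σ)²` is optimised by alternating

1. **model fit** — pixelwise linearised 2CFM (or modified Tofts) on the
   currently deformed series, producing the target stack `Σ`, and
2. **deformation fit** — per-frame gradient descent on the control-point
   displacements against the frozen target,

inside a multi-resolution loop that starts with one control cell spanning
the field of view and halves the spacing until the configured minimum
(defaults: 32 px for 2D data and the reference object, 4 px intended for
3D). Deformations start at the identity, so before any iteration the
corrected series equals the input bit for bit. Everything is deterministic;
per-frame problems are independent under the identity approximation, and
results do not depend on the frame processing order (tested).

**Line search.** Each descent step uses back-tracking: the trial step is the
previously accepted step for that frame (preconditioning), expanded ×2 for
the next search after a first-try success and contracted ×0.5 on failure,
at most 20 trials. Steps are additionally capped so that no control point
moves more than 10× the convergence tolerance in a single update. This
trust-region-style cap matters because the target is *moving*: it keeps the
deformations co-evolving with the progressively sharpening model target
instead of jumping across lobes of the (initially motion-blurred,
multi-modal) cost landscape. A frame stops when its line search fails or
when a curvature-limited (back-tracked) step changes no control point by
more than the tolerance `δ_min` (default 0.3 px; 0.2 px for the reference
object); a resolution level stops when no frame produced a change above
`δ_min`, with safety caps of 200 descent steps per frame per sweep and 50
outer iterations per level (never reached in practice).

**Moving target and monotonicity.** With the linearised model the target
depends on the data, so re-fitting it after a deformation sweep is not
mathematically guaranteed to lower the joint cost. The engine therefore
accepts a refitted target only if it does not increase `χ²` and otherwise
keeps the previous one; combined with descent-only deformation updates this
makes the cost trace non-increasing within every resolution level by
construction. The exact generalised residual — the residual propagated
through the derivative `∂R = (I − α₁ΔtM − α₂(ΔtM)²)(I − M₀)` of the
linearised fit with respect to the data (`M` the integration operator, `M₀`
baseline averaging) — is implemented as a diagnostic of the identity
approximation, not as an optimiser mode: the correction terms are of order
`Δt/TP`, `Δt/TT` and `1/n0`, all small at typical frame rates.

## The digital reference object

The DRO emulates a coronal renography slice: two kidneys, each three
concentric ellipses (cortex, medulla, pelvis), on a uniform background with
`S0 = 1`. Geometry is specified as fractions of the matrix (cortex
semi-axes 0.20 × 0.12) so the phantom scales; region parameters sit at the
ends/midpoints of physiological ranges — cortex `FP=300, TP=6, FT=60,
TT=90`, medulla `150, 13, 50, 180`, pelvis `30, 20, 40, 300` (flows in
mL/min/100mL, times in s). Signals are simulated region-wise at 0.1 s
resolution with a population AIF — a gamma-variate bolus (peak 8 s after
arrival, normalised to 1) with a biexponential washout tail, padded with a
15 s zero baseline; any tabulated AIF can be injected instead — and
block-averaged (11 fine samples per frame, frame times at window centres)
to the default 135 × 135 × 120-frame series at 1.1 s.

Motion corrupts the series by backward warping each frame: rigid
vertical sinusoidal shifts (default amplitude 12 px, period 4 s) or a
synthetic non-rigid field — per-node sinusoids of seeded random amplitude
and phase on a coarse lattice, checked for a positive Jacobian — standing in
for fields measured on clinical data, with amplitudes larger than typical
renal displacement. The ground-truth parameter maps are warped with the
*same* per-frame fields. Gaussian noise with `SD = max(c_a)/CNR` is added
after motion corruption (within-frame motion/noise interaction is not
modelled, consistent with not modelling acquisition physics at all: no
saturation-recovery signal equation, k-space sampling or within-frame
artefacts). Zero amplitude and no noise reproduce the motion-free phantom
bit for bit.

**Ground truth under motion.** A registration that freezes breathing in any
natural breathing state is correct, so error quantification selects as
reference the breathing state whose moving plasma-flow map is closest (sum
of squared differences) to the reconstruction, ties to the earliest frame.

## Evaluation metrics

Percent error is `E_P = (P_r − P)/max_x P × 100` with the denominator the
maximum of the ground-truth map over the whole field. Bias is the median of
`E_P` over all pixels; precision is the width of its equal-tailed 90%
confidence interval (95th minus 5th percentile, linear interpolation — the
rule matters at small n and is fixed here). The Hausdorff distance between
binary masks uses boundary voxels (mask minus its erosion) and the
classical symmetric max–min definition in voxel units. Time cuts extract
one spatial line per frame as a space × time image for visual motion
assessment.

Because the phantom's baseline is uniform (`S0 = 1`), pre-contrast frames
carry no registerable anatomy; mask-overlap statistics are therefore
evaluated over frames whose kidney-mean enhancement exceeds 5% of its peak,
and the reference mask is the moving truth mask at the selected reference
breathing state.

## Validation problem sizes

The test suite and `scripts/acceptance.py` run the pipeline at two phantom
scales, chosen as the package's validation conditions: a scaled 64 × 64,
60-frame DRO (rigid amplitude 6 px, CNR 10³) for the motion-recovery and
monotonicity checks, and the full-size 135 × 135, 120-frame DRO (rigid
amplitude 12 px) for the segmentation-overlap and error-distribution
checks. The model-bias experiment runs the modified Tofts model on
motion-free 2CFM data at CNR 10³ with a 16 px minimum grid spacing — the
low noise isolates model-error-driven deformations from noise-driven ones,
and 16 px at the 64² scale preserves the spacing-to-matrix ratio of the
full-size configuration, the regime in which an oversimplified model
visibly deforms the first-pass frames.

## Known limitations

- **Edge interpolation bias at small scales.** The phantom's tissue
  interfaces are binary-sharp, and both the motion corruption and the
  correction resample them with linear kernels. A mixture of two kinetic
  curves at a blurred edge is not itself a 2CFM curve, so the joint cost is
  insensitive to — and can even prefer — sub-pixel edge misalignments. At
  the full phantom size the affected pixel ring is thin and the 90% CI
  metric is barely touched; at the scaled 64² size the edge ring is a much
  larger pixel fraction and dominates the CI width even for a perfect
  registration. Scaled-phantom precision numbers therefore measure an
  edge-resampling floor as much as registration quality; conclusions about
  registration fidelity should be drawn from the full-size configuration.
- **Soft temporal modes.** Slow drifts of the frozen breathing state over
  the series are weakly penalised because the kinetic model can absorb
  low-frequency trends; the reference-state selection compensates only for
  a global offset.
- **Frames without contrast** (uniform baseline in the DRO) cannot be and
  are not registered; real data with anatomical baseline contrast do not
  share this degeneracy.
- The identity approximation to the residual derivative is adopted, not
  exact; its correction terms are available only as a diagnostic.
- The DRO does not emulate acquisition physics, within-frame motion, or
  measured breathing traces; passing its checks demonstrates correctness of
  the algorithmic chain under the stated phantom assumptions, not clinical
  performance.
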