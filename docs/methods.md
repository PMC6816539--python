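# Methods

## The problem

Electrical impedance tomography (EIT) drives small currents through surface
electrodes and measures the resulting voltages; the inverse problem is to
recover the interior conductivity `sigma(z)` governed by
`div(sigma grad u) = 0`. Absolute (single-frame) EIT is severely ill-posed,
and reconstruction quality is limited both by noise and by how much prior
knowledge is available. This package implements a two-stage pipeline:

1. a **regularized direct reconstruction** (the D-bar method): scattering
   data — a nonlinear Fourier transform of the conductivity — is computed,
   truncated to `|k| <= R` (the regularization step), and inverted through a
   `dbar_k` integral equation, producing a stable but low-pass (blurred)
   image `sigma_DB`;
2. a **learned post-processing step**: a small U-Net `G_Theta` trained on
   simulated pairs `{sigma, sigma_DB}` sharpens the blurred image.

The distinguishing choice is how the training data is simulated. Instead of
solving the physical boundary-value problem on a fixed domain (which bakes
the domain shape and electrode layout into the network), training
reconstructions are generated through the **Beltrami equation**

    dbar_z f = mu dbar-conjugate(d_z f),    mu = (1 - sigma) / (1 + sigma),

whose exponentially-behaving solutions `f = e^{ikz} M(z, k)`, `M -> 1`,
yield the scattering transform

    conj(tau(k)) = (1/2pi) int dbar_z [M_+mu - M_-mu] dA.

Because `sigma` is scaled to 1 near the boundary, `mu` vanishes outside the
inclusions and *no boundary information enters the simulation at all*.
Measured data from any tank or body shape is mapped into the same setting by
scaling its Neumann-to-Dirichlet (ND) matrix by the radius of the smallest
circle containing the domain and by the near-boundary conductivity
`sigma_0`.

## Pipeline in detail

**Step 1 (simulation route).** For a phantom scaled to unit boundary value,
both Beltrami solutions (`+mu` and `-mu`) are computed for every node of a
uniform k-grid with `|k| <= R` (`R = 5` for the thoracic family, `5.5` for
the generic family), and `tau(k)` is read off. Schrödinger-type data is
obtained as `t(k) = -4 pi i conj(k) tau(k)`, with `t(0) = 0`.

**Step 2 (regularized inversion).** A truncation radius `R_n` is drawn
uniformly from `[3.5, 5]` (thoracic) or `[4, 5.5]` (generic) — varying the
cutoff during training-data production teaches the post-processor to handle
reconstructions at different noise-dictated regularization levels. `t` is
spline-interpolated to a fresh grid on `[-R_n, R_n]^2`, then a non-uniform
cutoff zeroes nodes with `|Re t| > 24`, `|Im t| > 24`, or `|k| > R_n`
(interpolate first, then threshold; the order is exposed as an argument).
For each image point `z` the integral form

    m(z, kappa) = 1 + (1/4pi^2) int t(k) e(z, -k) / ((kappa - k) conj(k))
                                  conj(m(z, k)) dk,

with `e(z, k) = exp(i(kz + conj(kz)))`, is solved and
`sigma_DB(z) = sigma_b * Re[(m(z, 0))^2]`. The imaginary part of `m^2` is
discretization noise; its median relative size is recorded as a diagnostic
(typically < 1e-3).

**Measurement route.** From per-pattern currents and voltages the ND matrix
`R(m, n) = sum_l phi_l^m v_l^n |e_l|` is assembled on width-orthonormalized
current patterns, scaled to the unit disc (`ND -> ND * sigma_0 / r_max`,
with pattern vectors renormalized to the shrunk widths), inverted to the DN
matrix, and fed into the 'exp' scattering integral

    t_exp(k) = oint e^{i conj(kz)} [Lambda_sigma(e^{ikz}) - i k nu e^{ikz}] ds,

where the homogeneous term uses the continuum DN map of the disc. The final
image is rescaled by `sigma_0`; when `sigma_0` is unknown it is estimated as
the best constant-conductivity fit to the measured ND matrix in Frobenius
norm. `t_exp` is a Born-type approximation of the true `t`: exact in the
low-contrast limit, but with a systematic magnitude bias growing with
contrast and `|k|` (see *Known limitations*).

## Numerical scheme

Both integral equations are real-linear (they conjugate the unknown). Each
is reduced to a compactly supported unknown and solved by FFT-accelerated
Krylov iteration:

* **Beltrami solve.** With `M = 1 + P u`, `u = dbar_z M` is supported on
  `supp mu` and satisfies
  `u = nu_k (conj(S u) - i conj(k) conj(P u) - i conj(k))`,
  `nu_k = (+/-mu) e(z, -k)`, where `P` is the solid Cauchy transform
  (kernel `1/(pi z)`, evaluated exactly on a doubled grid) and `S` the
  Beurling transform (Fourier multiplier `conj(xi)/xi` on the doubled
  grid). Because the unknown vanishes outside the 0.95 disc, the solver
  square only needs to contain the support: it is `[-1.05, 1.05)^2`, not a
  larger square — the same spatial resolution at a quarter of the cost.
* **dbar_k solve.** The convolution with `1/kappa` is evaluated by FFT on a
  doubled k-grid; `t(k)/conj(k)` carries 0 at `k = 0`, and the k-grid is
  node-centered so `k = 0` (where `sigma_DB` is read off) is a grid node.
* **Antilinear squaring.** For antilinear `A`, `(I - A)(I + A) = I - A^2`
  with `A^2` complex-linear; GMRES is applied to `I - A^2` and the solution
  recovered as `x = w + A w`. The residual of the squared system equals the
  residual of the original system exactly.
* **Batching.** All spectral nodes (Beltrami) or image points (dbar) are
  independent systems; a hand-rolled batched GMRES runs one Krylov
  iteration for the whole stack with FFTs and inner products vectorized
  over the batch, keeping per-system Hessenberg data so iterates equal
  standard GMRES per system. Results are independent of batch partition
  (tested). Arithmetic is complex64; Krylov tolerances (1e-6 Beltrami, 1e-5
  dbar) sit well above single-precision round-off.
* **Conjugate symmetry.** For real coefficients,
  `tau(-conj k) = conj(tau(k))` (verified numerically in the suite); sweeps
  solve one half-plane and fill the other by conjugation.

## Phantom families and their parameters

*Thoracic (high prior).* Five reference organs — two lungs, heart, aorta,
spine — are included independently with probabilities 0.90/0.90/0.95/0.95/
1.00; conductivities (S/m) are drawn uniformly from per-tissue windows
(heart/aorta `[0.5, 0.8]`, lungs/spine `[0.01, 0.2]`, background
`[0.29, 0.31]`, injured lung regions `[0.01, 1.5]`). Each included lung is
injured with probability 1/2 by a horizontal dividing line at a uniform
height, the injured side (top/bottom, 50-50) taking the wide-window value.
Organ boundaries are jittered with additive white Gaussian noise on the
vertex coordinates. The noise level is not published; the default is SNR
20 dB relative to the mean coordinate power, redrawn when the perturbed
polygon self-intersects, and jittered organs are clipped to the 0.95 disc
so the Beltrami coefficient always vanishes near the boundary. The organ
polygons shipped in `_synthetic_organs.py` are a synthetic, illustrative
layout (the original boundaries were digitized from an unpublished
photograph); they are user-overridable.

*Generic ellipses (low prior).* One to three ellipses, semi-axes
`U[0.2, 0.35]`, centers `rho e^{i theta}` with `rho ~ U[0, 0.6]`, uniform
orientation, rejection-sampled until pairwise disjoint and inside the 0.95
disc. Background `U[0.13, 0.145]` S/m; each inclusion conductive
(`U[0.29, 0.34]`) or resistive (`U[0.05, 0.075]`) with equal chance; split
in two by a random chord with probability 1/3, no part smaller than 1/4 of
the inclusion, the two parts either (background, inclusion value) or
(conductive, resistive) — each option with probability 1/2, the paper-side
convention leaving the choice frequency unstated.

Unstated micro-decisions, fixed once: grid nodes exactly on an inclusion
boundary belong to the inclusion (closed regions, deterministic); when
several inclusions contain a node the smallest-area one wins; injuries with
values close to the background are not redrawn.

## What the generator emulates — and does not

The synthetic families emulate the *statistical structure* of the two
experimental settings (organ-like high-prior phantoms with injuries;
generic piecewise-constant ellipse phantoms), on the same conductivity
scales, with the same randomized truncation radii. They do not emulate:
electrode contact impedance or 3D current spreading (the analytic disc
forward model is a 2D continuum model), instrument noise spectra, real
organ boundary shapes, or non-circular tank geometry on the measurement
side. Passing tests therefore demonstrate internal consistency of the
mathematical pipeline and the direction of the learned improvement at desk
scale — not clinical performance on tank or patient data.

## Desk-scale versus production settings

Full-scale training-data production uses a `2^5 x 2^5` k-grid for `tau`,
regridding to `2^6 x 2^6`, and a `2^6 x 2^6` image grid solved directly
(`PipelineConfig.production()`); reference networks are trained on
thousands of pairs for 200k iterations. The defaults used by the tests,
examples and the acceptance script (`PipelineConfig.desk()`) are sized for
minutes-scale runs on one CPU and are the package's own desk-scale choices:

* Beltrami solver square 40 nodes (generic family; 64 for the thoracic
  family with its small aorta), `tau` on a `2^4` k-grid, dbar on a `2^5`
  k-grid, `m(z, 0)` solved on a 24x24 grid and spline-upsampled to 64x64
  (the image is low-pass; the upsampling error is ~1% and tested);
* post-processor width `base_channels = 2` (doubling over four pooling
  levels to 32 at the bottom), trained for 2000 iterations with the study
  optimizer settings (Adam, lr 1e-4, batch 16, ~5% validation split).
  Channel widths are not prescribed by the underlying architecture
  description; 16 is the library default for quality, 2 the desk-scale
  training width.

Resolution-sensitivity measurements behind these choices: `tau` on the
40-node solver square differs from a 128-node reference by ~4% rel l2 over
the generic family (2.4% at 64 nodes); the coarse-solve/upsample image path
differs from the direct solve by <2%.

## Robustness probes

The adversarial probe maximizes `||G(x + d) - G(x)||^2 - alpha ||d||^2` by
gradient ascent from `d = 0` (the objective and its gradient both vanish
there, so the first step is seeded with a tiny uniform perturbation);
a backtracking step keeps the objective trace non-decreasing, and
perturbation snapshots are returned at early ("small") and late ("large")
stages. Defaults `alpha = 1`, 200 steps, initial step 1e-2 — the original
optimization schedule is unpublished; these are package choices. The
garbage-in probe feeds uniform noise spanning the training D-bar range and
zero-mean Gaussian noise (with negative values, outside the range) and
returns the outputs for inspection.

## Metrics

SSIM uses a 7x7 uniform window, `C1 = (0.01 L)^2`, `C2 = (0.03 L)^2` with
data range `L` defaulting to the truth maximum, sample-covariance
normalization, and full-window cropping (verified to 1e-6 against
scikit-image). Relative errors are `100 ||r - t||_p / ||t||_p`, `p = 1, 2`,
over the full square by default (a unit-disc mask is available); the
normalization is by the truth norm. The exact window/mask conventions used
in the original tank-data evaluations are unpublished; these defaults are
recorded in every report.

## Known limitations

* The 'exp' scattering data is a linearization: on the concentric-disc
  oracle at contrast 2 it overestimates `|t|` by ~25% rel l2 over
  `|k| <= 4` (0.7% at contrast 1.05), and the resulting images differ by
  ~7% rel l2 from the Beltrami-route images. This is the approximation's
  documented systematic error, not a numerical artifact: the implementation
  matches an exact closed-form series for `t_exp` on that geometry to 1e-5.
* Reconstructions of *discontinuous* phantoms exhibit Gibbs-type ringing:
  a sharp disc of contrast 2 truncated at `R = 4` reconstructs with a
  center value *above* 2 (the linear low-pass of the disc indicator
  overshoots by a factor `1 - J_0(2 R rho) ~ 1.4` at the center). Monotone
  error decrease in the truncation radius holds for smooth phantoms.
* The analytic forward model is a concentric disc; non-circular boundaries
  are supported on the measurement side (spline normals of a parameterized
  curve) but have no synthetic forward solver in-package.
* The post-processor is trained at desk scale in the tests; quality
  (sharpness of recovered edges) is far below what the full-scale regime
  produces, and only the direction of improvement is asserted.
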