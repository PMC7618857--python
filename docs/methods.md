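# Methods

`ptxb1map` implements an accelerated calibration chain for multi-channel
transmit (pTx) B1+ mapping at ultrahigh field: simulated multi-channel
acquisitions, incoherent undersampling, joint calibrationless structured
low-rank k-space completion, eigenvalue-based sensitivity estimation,
saturation-recovery flip-angle inversion, and the combination of relative
per-channel maps with two absolute shim-mode maps into absolute per-channel
maps. This note records the model, the parameters that matter, the numerical
choices, and the limitations.

## Signal model

A field set holds, on a uniform grid, the per-channel complex transmit
fields `B1+_c` (magnitude stored directly as the saturation flip angle in
degrees at the reference drive), per-channel complex receive sensitivities
`B1-_r` (arbitrary units), and a proton-density phantom `ρ`. The simulated
acquisition follows the ideal saturation ("sandwich") model:

- relative image, channel c:  `ρ · B1+_c`
- reference image, shim j:    `ρ · S_j`,   `S_j = Σ_c w_jc B1+_c`
- prepared image, shim j:     `ρ · S_j · cos(α_j)`,  `α_j = |S_j| · α_nom/90°`

with every image additionally multiplied by each receive sensitivity. The
two absolute shim modes default to the first- and second-order circularly
polarized modes, `w_c = exp(−i 2π p c / N_tx)/√N_tx` for order p ∈ {1, 2};
the phase sign is a fixed, documented convention. The nominal saturation
angle defaults to 90°.

Proton density is derived from a tissue-density map: densities above
1200 kg/m³ (bone) or below 400 kg/m³ (lung) are replaced by 80 so the
phantom resembles an MR magnitude image; the inequalities are strict.

K-space noise is channel-independent complex Gaussian at a peak SNR of
60 dB by default: the per-component standard deviation satisfies
`20·log10(peak image magnitude / σ) = psnr_db`. Because all transforms are
unitary, σ is identical in the image and k-space domains, so the definition
needs no domain qualifier.

## Array and transform conventions

Arrays are `(x, y[, z], rx, mode)` with spatial axes first. All centered
transforms put DC at index `N // 2` for both odd and even `N`, which makes
the odd-to-even crop (e.g. a 139-sample axis to 24) unambiguous; cropping
and zero-padding always align source DC to target DC. FFTs are unitary
(`norm="ortho"`), so Parseval holds to machine precision and noise variances
match across domains. Apodization windows are separable per-axis tapered
cosines defined on `x = (i − N//2)/(N/2)` with gain exactly 1 at DC;
`cosine_fraction = 0` is rectangular and `1` is the Hann window.

## Undersampling masks

Per-transmit-mode binary masks over the phase-encode plane are generated by
uniform-density Poisson-disc (blue-noise) sampling: grid points are accepted
in a seeded random order subject to a minimum pairwise distance, the radius
descending a short ladder from the density-matched spacing
`r_target = (N_total/n)^(1/d)` with a hard floor at `0.7·r_target`, after
which a random excess is pruned. The achieved sample count is therefore
within 10% of `N_total/R` by construction, and the minimum distance among
accepted (non-calibration) points never drops below the floor. An optional
centered calibration block (default 4×4) is always fully sampled. The
reference and prepared images of an absolute mode share one mask; every
other mode gets its own mask (seeds derived as `seed + mode index`). In 3D,
masks cover the ky–kz plane only; the frequency-encode axis is fully
sampled.

## Joint structured low-rank completion

All receive channels and transmit modes (e.g. 8 relative + 2 reference + 2
prepared modes × 8 receivers = 96 channels) are completed jointly. Sliding
kernel windows (default 5×5) of the phase-encode plane are stacked into a
multi-channel block-Hankel matrix (rows = window positions, columns = kernel
elements × channels; 400 × 2400 for a 24×24 grid). Because each channel is,
to good approximation, a smooth complex field times one common object, every
window lies in a low-dimensional subspace and the matrix is strongly
rank-deficient.

Completion alternates three projections: hard truncation to the top `rank`
(default 50) singular values; projection back onto the structured set by
anti-diagonal averaging (each k-space sample becomes the mean of all matrix
entries referencing it — the Frobenius-nearest consistent matrix); and exact
replacement of measured samples. Measured entries are re-imposed after every
iteration and once more after the last, so data consistency is bit-exact.

Two numerical choices matter:

- The truncation is computed from the eigendecomposition of the Gram matrix
  on the smaller side, equivalent to a truncated SVD but much cheaper for
  the wide matrices that arise here.
- The iteration uses an inertial (heavy-ball) extrapolation,
  `v_k = x_k + β(x_k − x_{k−1})` with `β = 0.85` by default, before the
  projection steps. Plain alternating projection (`β = 0`) converges to the
  same fixed point but needs several hundred iterations to complete exactly
  structured data to sub-percent error; with inertia the default 50
  iterations suffice (median unmeasured-entry error ≈ 0.6% on exactly
  structured test problems, with occasional random instances converging
  more slowly — 1–5% at the same budget). The monotone-residual property of
  the plain scheme is asserted in the test suite with `β = 0`.

The default iteration budget is fixed (50 iterations, no early stop); an
optional relative-change tolerance exists for fast paths. A rank above the
matrix's minimum dimension is clamped with a warning. The calibration block
receives no special treatment inside the solver — it is simply measured
data, and its benefit emerges through data consistency. Channels are not
normalized before the joint decomposition.

For 3D data the volume is inverse-transformed along the fully sampled
frequency-encode axis and each x-slice is completed independently in hybrid
x–k_y–k_z space (slices commute; execution order is irrelevant), then
transformed back.

## Sensitivity estimation and combination

Receive sensitivities are estimated with ESPIRiT from a centered calibration
block (default 12×12) of the *reconstructed* relative-map k-space, with all
relative transmit modes contributing rows to the calibration matrix. The
right singular vectors whose singular values reach `0.02` of the maximum
span the local signal subspace; the conjugated kernels are transformed to
image space (scaled so per-voxel eigenvalues land in [0, 1]) and the
per-voxel top eigenvector of the kernel Gram operator is the sensitivity,
phase-referenced to receive channel 0. The named threshold (0.02) is the
calibration-matrix singular-value threshold; the image-space eigenvalue crop
that defines the support mask is a second, separate parameter defaulting to
0.9 (configurable). One eigen-map is used (no soft-SENSE second map).
Receive combination is the per-voxel matched filter
`Σ_r conj(S_r) I_r / Σ_r |S_r|²` inside the support, zero outside.

Transmit relative profiles are unit-norm per-voxel channel vectors,
phase-referenced to transmit channel 0. The default method is the per-voxel
image-domain eigen-analysis of the receive-combined relative images — for a
single image set this is the normalized channel vector, and it is exact on
noiseless model data (the completion stage has already suppressed noise and
filled k-space). The k-space ESPIRiT pathway, with the transmit-mode axis
playing the channel role, is available as `tx_maps_method="espirit"`; it is
approximate for fields that are not band-limited to the kernel size, which
is why it is not the default.

SVD coil compression projects the receive axis onto the top singular
subspace of the channel × sample matrix and reports the retained energy
fraction; geometric-decomposition ("aligned") compression is out of scope.

## Flip-angle inversion

The per-mode flip angle comes from the reference/prepared ratio. The ratio
uses the real projection `Re(prep·conj(ref))/|ref|²` rather than a magnitude
ratio: the shared receive phase drops out and the noise-floor bias of
magnitudes is avoided. The default inversion is the arccosine (exact under
the ideal cosine saturation model used throughout the simulation study).

For shaped saturation pulses the package provides a Bloch-simulated lookup
table. The hyperbolic-secant family `A(t) = A0·sech(β τ^n)`, `τ = 2t/T − 1`
(default HS8: n = 8, β = 5.3, 1 kHz sweep, 5 ms) is integrated as a
hard-pulse train (Rodrigues rotations per sample; relaxation neglected —
milliseconds versus tissue T1). `A0` is calibrated so the amplitude integral
equals the nominal flip angle; the deviation of the achieved saturation from
`cos(α)` is exactly the nonlinearity the table corrects. The table maps the
simulated residual longitudinal fraction Mz/M0 to the flip angle over its
maximal strictly monotone domain (truncated with a warning otherwise); for a
rectangular pulse it reproduces the arccosine to < 0.01°. Out-of-domain
voxels are masked and filled by linear spatial interpolation from valid
neighbours (nearest-value fallback outside the convex hull). Readout-train
relaxation corrections (extended-phase-graph modelling) are not included;
the table corrects saturation nonlinearity only.

## Absolute per-channel combination

With relative profiles `rel_c`, two absolute mode maps `α_j`, and the
reference-image magnitudes `I_j`, the combination is, per voxel:

    R_j = |Σ_c w_jc rel_c|
    λ_j = I_j^m / Σ_k I_k^m          (total scaling exponent m, default 4)
    C   = Σ_j λ_j (α_j / R_j)
    map_c = rel_c · C                (magnitude now in degrees)

Each absolute mode proposes the common per-voxel scale `α_j/R_j`; the blend
weights favour the brighter (higher-B1+) mode, overcoming the limited
dynamic range of a single shim. Modes with vanishing `R_j` are dropped from
the blend; voxels with no usable mode are invalid. The combination is
equivariant to a global complex scale of the relative maps, and as m → ∞ it
selects the brighter mode voxelwise. The exponent is applied to the
reference-image magnitudes; this concretization is confined to this one
operation.

Output masking combines a value threshold — root-sum-of-squares of the
fully sampled relative images at or above `value_frac` (default 0.1, a
package choice) of its 95th percentile — with a shim-efficiency floor: the
best of the two modes must reach efficiency `|Σ w_c rel_c| / Σ |w_c||rel_c|`
of at least 0.30, since voxels dark in both modes yield unreliable absolute
values.

## The surrogate field generator

The generator provides study inputs without any electromagnetic simulation
data: transmit elements evenly spaced on an ellipse around the FOV, with
per-channel magnitude decaying with distance from the element
(`(d0/(d0+d))^decay`, default exponent 1.0) and phase advancing with
distance plus the element's azimuthal angle, so the CP+ mode is
constructive near the centre. Receive elements share the geometry with
independent random perturbations and phases. The phantom is an elliptical
body with a soft-tissue gradient, a low-density lung pocket and a
high-density rim, passed through the tissue-density rule; elliptical body
and heart ROI masks are included. Transmit magnitudes are scaled once so the
CP+ mean flip angle over the heart ROI is 66° (the study condition for the
body simulations).

The default phase-advance wavelength is 300 mm — deliberately longer than
the ~11 cm in-tissue RF wavelength at 7 T. The premise of small-matrix pTx
calibration is that body transmit fields are dominated by a few low-order
spatial modes; with the longer wavelength the joint 96-channel block-Hankel
matrix of the simulated acquisition retains 99.9% of its energy in the top
50 singular values, matching that premise. With literal 11 cm phase advance
from every element the surrogate's joint matrix is *not* rank-50
compressible and the completion stage fails at any acceleration — a
property of the surrogate's crude geometry, not of real body fields.
Consequences worth knowing: the surrogate's heart ROI shows milder CP+
heterogeneity (CV ≈ 10%) than real body data, it has no cardiac or
respiratory motion, no B0 off-resonance, no T1 weighting of the readout
train, and its receive fields share the transmit geometry. Passing tests on
the surrogate therefore demonstrate the correctness and convergence of the
processing chain under the stated model, not in-vivo image quality.

The default native grid is 64×64 at 4 mm (256 mm FOV), cropped to the
24×24 scan matrix for reconstruction and zero-padded back after Hann
filtering; these sizes keep the default Monte-Carlo study (5 acceleration
factors × 10 repeats) to a few minutes of CPU time while preserving the
structure of the protocol (the acquisition-side matrix, kernel, rank,
iteration count, calibration size, noise level and exponent are the
protocol values: 24×24, 5×5, 50, 50, 4×4, 60 dB, m = 4).

## Evaluation

Error metrics operate on complex maps in degree-magnitude representation
(phase from the channel-0-referenced combined map): complex RMSE over an
ROI; relative-map RMSE normalized by the ROI mean of `Σ_c |ref_c|` (the
total available B1+), reported in percent; and ROI summaries
(mean/min/max/CV). The sweep experiment runs the full pipeline per
(acceleration, repeat) cell with seed `base_seed + 1009·R_index + repeat`,
each repeat drawing unique noise and masks; the seed schedule is stored in
the results table so any cell can be replayed in isolation. Comparisons are
against the native-resolution noiseless ground truth. Sweep runs use
complex64 arithmetic inside the completion solver (the measured-entry
replacement is exact in either precision); everything else runs in
complex128.

## Known limitations

- The pipeline's evaluation path is 2D (the simulation study); 3D data are
  reconstructed slice-wise in hybrid space, but the full 3D map-combination
  workflow is exercised only through the hybrid reconstruction operator.
- The lookup path models the saturation pulse only; TurboFLASH readout
  relaxation and RF spoiling are out of scope.
- ESPIRiT transmit-profile estimation (the non-default pathway) is biased
  for fields with spectral content beyond the kernel size.
- ISMRMRD containers are supported through their HDF5 layout (h5py), not
  through a dedicated ISMRMRD dependency.
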