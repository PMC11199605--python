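# Methods

## Models

**Nonlocal interaction-redistribution model.** Biomass b(r, t) grows
logistically, enhanced by a facilitation feedback M_f and suppressed by an
aridity-weighted competition feedback M_c, with diffusive seed dispersal:

    ∂t b = b(1 − b) M_f[b] − μ b M_c[b] + D ∇²b,
    M_i[b] = exp(χ_i ∫ φ_i(r, r′) b(r′) dr′).

The influence kernels φ_i are unit-mass anisotropic Gaussians with widths
(l_ix, l_iy) and spatial offsets (x_i0, y_i0). Offsets along the fog
direction x encode nonreciprocity — φ(r, r′) ≠ φ(r′, r) — which is the
directional-fog mechanism: facilitation and competition reach differently
up- and downwind. All quantities are dimensionless; lengths are in the
model's kernel-length units, time in inverse growth-rate units. Assumptions
worth keeping in mind: feedbacks are exponential in the convolved biomass
(growth must stay in the guarded regime, exponent magnitude < 50), the fog
direction is uniform and steady, and terrain enters only through the
boundary conditions, not through an explicit water or droplet field.

**Reduced equation.** Near the nascent-bistability point (μ = 1,
χ_f − χ_c = 1, b = 0), a weak-gradient expansion collapses the model to

    ∂t b = −η b + κ b² − b³/2 + d ∇²b − b(α ∂x + γ ∂x² + ∂x⁴) b,

with η = μ − 1 the aridity balance, κ = χ_f − χ_c − 1 the cooperativity,
α the nonreciprocity intensity, and γ the facilitation/competition range
balance; x is rescaled by σ^¼ with σ = 3 l_fx² l_cx². The mapping formulas
are implemented in `map_parameters`. The reduction fixes only the
*combination* d/σ^½ as the seed-dispersion coefficient, so d is kept as an
independent input and the mapping does not emit it. Validity requires
|η| ≪ 1 and long-wavelength patterns; at the reference aridity η = −0.02
used throughout, the expansion is stretched but the phenomenology (band
coexistence, drift) is intact, which is the regime the package targets.

**Boundary conditions.** Both simulators pin b = 0 at x = 0 and x = L_x
(bare ground beyond a fog-limited range; two ghost layers of zeros feed the
fourth x-derivative) and wrap periodically in y. This discretizes the
admissible wavevectors as sine columns k_x = πm/L_x and Fourier rows
k_y = 2πn/L_y; modes with n = 0 are horizontal bands (H), n ≷ 0 the
oblique pair (O_l / O_r).

**Linear stability.** About the vegetated state b₊ = κ + √(κ² − 2η),

    Re λ(k) = b₊(κ − b₊) − d|k|² + b₊(γ k_x² − k_x⁴),
    Im λ(k) = −b₊ α k_x,

so the real spectrum is α-independent and the bands drift at phase speed
b₊α. The critical point solves Re λ = ∂Re λ/∂k_x = 0 with
k_c² = (b₊γ − d)/(2b₊), by bracketed root-finding in η (residuals below
1e-10; the bracket is scanned over 400 points before `brentq`).

**Amplitude equations.** The three-mode truncation of the Ginzburg–Landau
envelope couples H, O_l, O_r with the cross-coupling terms 2O_lO_r·conj(H)
and H²·conj(O_∓). At β = 0 the flow is gradient (`potential` implements the
Lyapunov function; dV/dt = −2Σ|∂t·|² is checked in the tests to machine
precision). Branches: |H|² = μ̂; single oblique |O|² = μ̂ − Δk²; rhombic
pair |O|² = (μ̂ − Δk²)/3 (always unstable to stripe selection, eigenvalue
+2q²); symmetric mixed state h² = (μ̂ − 2Δk²)/5, q² = (2μ̂ + Δk²)/15 at
β = 0, continued numerically in the modulus/relative-phase reduction
(Φ = 2θ_H − θ_l − θ_r) for β ≠ 0, with natural continuation from the
previous μ̂. Stability: at β = 0 the 6-dimensional real Jacobian is
diagonalized and the global-phase zero modes (|λ| < 1e-7, at most two) are
projected out; for β ≠ 0 the closed-form leading rates are used where they
are β-independent (trivial, H, single oblique, pair asymmetry mode) and the
4-dimensional reduced Jacobian for the mixed state. The two routes are
cross-checked against each other in the test suite. μ̂, β, α̂, Δk are free
inputs (the normal-form coefficients of the reduced equation are not
derived here); `params_from_linear` offers the convenience choice
μ̂ = max_k Re λ, α̂ = −b₊α.

## Numerics

**Discretization.** Central differences: 3-point first and second
derivatives, 5-point fourth derivative and Laplacian. Explicit RK4 in time.
The quartic term dominates stability; `stable_dt` implements
dt ≲ 1.4 dx⁴ / (16 b_max) with a safety factor, plus diffusive and
antidiffusive corrections. Reference grids use dx = 0.5 (k_c dx ≈ 0.46)
with dt = 2.5e-3; oracle comparisons against the continuous dispersion use
dx = 0.15–0.2, where the finite-difference symbol is within a fraction of
a percent of k² and k⁴ over the unstable band.

**Kernels and convolutions.** Kernels are sampled on the wrap grid with
±1 periodic images summed, so the discrete mass equals the unit integral
to near machine precision (the build refuses grids narrower than 6 kernel
widths per axis). Dirichlet-x convolution zero-pads b by
max(4 l_ix + |x_i0|) before the FFT; the padded kernel FFTs are precomputed
per run. A brute-force quadruple-sum oracle in the tests agrees with the
FFT path to 1e-8 on small grids.

**Pattern classification.** The dominant mode is read from the 2-D FFT on
the k_x > 0 half-plane; Dirichlet boxes get a Hann window in x and the
lowest wavenumbers (below 2.5 box fundamentals) are excluded, because the
wall-confined cover itself — including its stationary fringe oscillations,
which the advective term amplifies at the downwind wall — carries spectral
weight there. Labels: H when k_y = 0 on the discrete grid, O_l/O_r by the
sign of k_y (matching the e^{±iΔk y} ansatz), `mixed` when a second
non-adjacent mode is within 3 dB of the peak, `none` when the peak is
under 5× the median background or under an absolute floor of 0.01. Bulk
measures for wall-bounded fields (scan amplitudes, labels) are taken on
the central half of the box (`interior_crop`) for the same reason.

**Drift measurement.** Phase of the dominant x-mode of the y-averaged
profile, unwrapped and fitted linearly over the record; speed = −dφ/dt / k.
The transverse drift of oblique patterns is measured the same way on the
centre-column record b(x_mid, y, t).

**Orientation pipeline.** Gradients are derivative-of-Gaussian filters
(σ = 1 px): their spectral attenuation is isotropic, so the gradient
direction of any plane wave — and hence of each harmonic that the
rolling-ball step generates — is exact, where plain central differences
bias the angle by ~(k²/6)·sin 2φ (≈ 0.3° at wavelength 16 px, above the
1° pipeline budget once harmonics are involved). The structure tensor is
smoothed with a Gaussian window σ_w = 4 px (configurable; the named
plugin's default is not published). Rolling-ball background subtraction is
scikit-image's `rolling_ball` (the standard algorithm behind the FIJI
tool; bit-equality with FIJI is not claimed, and the test oracle is
synthetic ground truth). Histogram modes are local maxima of the
180°-periodic histogram with prominence ≥ 25% of the peak, refined by a
±3-bin circular centroid. Conventions: orientations are axial angles in
[0°, 180°) CCW from east; histogram differences are folded to [0°, 180°);
the alignment correlation uses the band-normal γ_⊥ = γ_pattern − 90° and
signed differences folded to [−90°, 90°), so perpendicular bands score 1
and parallel bands 0. Coherence threshold for inclusion: 0.3. Default wind
direction Γ = 30° CCW from east.

## Synthetic data

The generators emulate what the pipeline needs and nothing more: sinusoidal
stripes (near onset the biomass modulation is harmonic, and a pure cosine
gives closed-form structure-tensor ground truth) in rectangular orientation
domains, additive linear backgrounds, Gaussian pixel noise, dislocations as
seeded π phase jumps along a cut, planar-ramp DEMs with optional sinusoidal
ridge modulation, and uniform-noise initial conditions (the distribution is
a free choice — only "noisy" is specified upstream — with amplitude 0.1
about the homogeneous state, small enough to start in the linear regime).
They do not emulate georeferencing, radiometric or atmospheric effects,
binary/patchy vegetation textures, curved or branching bands, or spatially
correlated noise, so passing tests demonstrate the correctness of the
algorithms on their idealized model, not performance on real imagery; the
empirical correlations reported for real Atacama scenes are outside the
package's scope.

## Reference problem sizes

Chosen as the package's standard configurations; the acceptance script and
tests use them (or smaller versions of them):

- Discrete-mode box: L_x = 85, L_y = 100 at η = −0.219 — the box whose
  sine/Fourier grid holds exactly one unstable horizontal column and the
  n = ±1 oblique pair; `admissible_box_window` reports the window of
  equivalent boxes.
- Dispersion oracle: periodic box, 256 × 4 at dx = 0.15, five probe modes
  spanning decay and growth, chosen away from the neutral crossing where a
  relative comparison is ill-conditioned.
- Drift: periodic 128 × 8 at dx = 0.5; saturation for 60 time units, speed
  measured over 30.
- Coexistence / aridity scan: Dirichlet box L_x = 40, L_y = 32 (81 × 32,
  dy = 1) — the transverse size keeps the oblique tilt gentle (~12°);
  steeper tilts are eroded by the walls, the confinement dependence of the
  oblique threshold. Scan points η = −0.40 / −0.215 / −0.02 for 40 / 250 /
  120 time units (near-threshold dynamics are slow, ~1/μ̂).
- Nonlocal run: 161 × 96 at dx = 0.375 (box 60 × 36), dt = 0.02, 120 time
  units; the emerging band wavelength is ≈ 20 length units, set by the
  competition range through the rescaling σ^¼ ≈ 2.79.
- Orientation scenes: 256² px, wavelength 16 px, contrast 1, noise σ = 0.3
  (SNR ≈ 3.3), three y-strips at the wind-perpendicular angle and ±7°.

## Limitations

- No linear analysis of the nonlocal equation itself (its dispersion
  relation is transcendental); the reduced equation is the analysis
  vehicle, and the nonlocal model is verified through its uniform states,
  symmetries, and simulated patterns.
- Small boxes make thresholds box-dependent (wall fringes, oblique
  erosion); quantitative threshold values quoted here are for the stated
  boxes.
- The amplitude-equation stability analysis at β ≠ 0 covers the branches
  listed above; secondary (sideband) instabilities of the envelope are out
  of scope, as are defect dynamics and sloped-terrain water transport.
- TIFF output quantizes to 16 bits; CSV is the lossless interchange format.
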