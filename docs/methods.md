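# Methods

## Image-formation model

A DIC micrograph is modelled as the local correlation of the specimen's
optical-path-length (OPL) map `I` with a finite derivative-type kernel `K`
on the window `W = [−d, d]²` (side `2d + 1` pixels),

    G(x, y) = Σ_{(ξ,η) ∈ W} K(η, ξ) · I(y + η, x + ξ),

with mirror (reflect, no edge repeat) boundary handling. Arrays are indexed
`(row, col) = (y, x)`, x rightward, y downward, window origin at the centre
pixel; every module shares this convention. The model ignores diffraction,
partial coherence and bias retardation: `K` sums to zero, so constant
regions map to zero and the uninformative mid-gray bias of real positive
bias DIC is simply omitted. Kernels are oriented so that correlation with
an image computes the image's directional derivative along `+shear`; the
Dirac-difference kernel therefore carries `+1` at `+offset·u` and `−1` at
`−offset·u` (sub-pixel positions deposited bilinearly over the four nearest
cells, preserving the zero sum exactly).

## The variational reconstruction

The reconstruction minimizes

    E(I) = Σ_Ω (L I − G)² + λ Σ_Ω ( √(Ix² + Iy² + ε²) − ε )

by explicit gradient descent, where `L` is one of three discretizations of
the forward operator and the smoothed isotropic TV term (`ε > 0`) keeps the
Euler–Lagrange curvature `div(∇I/|∇I|_ε)` defined at zero gradient. The
`−ε` offset makes the TV of a constant image exactly zero without changing
the gradient.

A single design rule governs the whole module: **every descent direction is
the exact gradient of the discrete energy it descends.** All spatial
operators are built from mirror-padded correlation `C∘P` and its exact
adjoint `Pᵀ∘Cᵀ` (full convolution followed by folding the padded border
back onto its sources), so analytic gradients agree with central finite
differences of the energies to rounding error — the master oracle of the
test suite. Because the data energies are quadratic, that agreement is
exact, not approximate.

The three data-term schemes:

* **bilinear** — Taylor expansion of `I` inside the window up to the mixed
  term collapses the local integral onto kernel moments:
  `L = m00 + m10·Dx + m01·Dy + m11·Dx·Dy` (central differences, mirror
  boundary). Fast; exact only for kernels fully captured by those moments
  (e.g. the grid-aligned Dirac difference).
* **piecewise_constant** — for kernels mirror-symmetric about the shear
  axis (checked, with an informative error otherwise) the mixed moment
  vanishes and `L = μ·D_u` with `μ` the first moment along the shear. The
  descent direction then involves only `∇G` and the shear-direction second
  derivative of `I` — the cheapest scheme.
* **kernel_form** (default) — the derivative is moved onto the kernel: the
  integral kernel `K₀` is the exclusive cumulative sum of the PSF along the
  grid direction nearest the shear, built on a window enlarged by 3 with the
  outer two rings forced to zero, so all boundary first differences vanish.
  Differencing `K₀` back along the shear step reproduces the PSF exactly on
  the original window (a test invariant up to `d = 4`), and the scheme
  correlates with that reconstructed kernel and its exact adjoint. This is
  the default because it represents an arbitrary, asymmetric PSF exactly.

Numerical choices: initialization `I₀ = 0` (background = no path
difference, and reproducible); step control is a monotone line search —
halve on any energy increase (up to 20 times, after which the iterate is
declared stationary), grow by 1.1× on success up to 10× the initial step.
Pure halving can let the step collapse at a TV kink and stall the slowly
converging low-frequency modes; the capped growth restores progress while
keeping the logged energy trace non-increasing by construction. Stopping:
relative total-energy decrease below `rel_tol = 1e-6` over 10 iterations,
or `max_iter = 3000`. Defaults: `λ = 0.1` (the one value the method fixes),
`ε = 1e-3 ×` the dynamic range of `G`, step 0.2. The returned image is
clipped to nonnegative values, matching the evaluation convention that
negative path lengths are meaningless.

The **Feineigle** variant ties the shear-direction derivative of `I`
directly to `G` and adds `λ₁ Σ (D_n I)²` (n ⟂ shear; suppresses streaks
along the shear) and `λ₂ Σ b (I − I_db)²` (a tether pulling estimated
background pixels `b` — local-variance filter → Gaussian smoothing → Otsu
threshold — to the desired background value `I_db`). Same descent loop,
same exactness property. Defaults `λ₁ = λ₂ = 0.1`, `I_db = 0`.

## Fourier baselines

Wiener: `Î = F⁻¹[ conj(H)·Ĝ / (|H|² + N/S) ]`; Yin replaces the constant by
`smooth·|A|² + sparse` with `A` the spectrum of the 5-point Laplacian (the
multi-shear formulation is reduced to the single-image case). The kernel is
embedded at image size, centred on the frequency origin, and the transfer of
*correlation* is `H = conj(F K)`. Spectra are taken on the plain periodic
grid: a derivative-type kernel is antisymmetric along the shear, so a
mirror extension of `G` would equal the *negative* of the circular forward
model on the extended domain and break the convolution theorem; periodic
embedding agrees exactly with the spatial (mirror-boundary) model whenever
objects stay away from the image border, which the synthetic phantoms do.
Two spectral facts matter for interpretation: any directional-derivative
kernel annihilates the entire frequency line perpendicular to the shear
(not just DC) plus the Nyquist line, so "noiseless inversion" statements
are made with a zero-sum difference-of-Gaussians kernel whose spectrum is
nonzero away from DC; and reconstructions are defined only up to the lost
content, which min-max normalization absorbs in evaluation. The Hilbert
transform multiplies the spectrum by `−i·sgn(u·k)` (zero on the `s = 0`
line), a pure phase filter chosen so a positive-bias edge doublet maps to a
single-signed ridge; `--invert` flips the sign, since both signs are valid
reconstructions with inverted contrast. Defaults `N/S = 1e-3`,
`smooth = 1e-3`, `sparse = 1e-4`, set once on the phantom fixture.

## Algebraic solvers

`H` is never materialized (at 256² it would be 65536²); both solvers work
matrix-free through the correlation operator and its exact adjoint, which
passes a 50-pair dot-product test per configuration.

**SEMU** minimizes `‖Hf − g‖² + α‖Rf‖² + β‖Wf‖₁` over `f ≥ 0` (`R` the
5-point Laplacian, `W` positive diagonal) with the multiplicative update for
nonnegative quadratic programs: writing the objective as
`½ fᵀA f + bᵀf` with `A = 2(HᵀH + αRᵀR)`, `b = −2Hᵀg + βw`, and splitting
`A = A⁺ − A⁻` via the kernel sign split (entrywise nonnegative parts),

    f_i ← f_i · ( −b_i + √(b_i² + 4 (A⁺f)_i (A⁻f)_i) ) / ( 2 (A⁺f)_i ).

This update keeps every iterate nonnegative (zeros are absorbing), handles
signed `g` natively, and decreases the objective monotonically — the
standard auxiliary-function argument needs only symmetric entrywise
nonnegative splits, which the operator split provides. Optional log-sum
reweighting `w_i ← 1/(f_i + ε)` per iteration. Defaults `α = 1e-2`,
`β = 1e-3`, `ε = 1e-2·max f`.

**SOCP** minimizes `‖Hf − g‖² + tv·TV_iso(f) + sparse·‖f‖₁` over `f ≥ 0`
(isotropic forward-difference TV, matching the variational term) by
primal–dual splitting: dual variables for the data term (closed-form prox
of the conjugate of `‖z − g‖²`) and the TV term (projection onto the
tv-radius ball), primal prox = shift by `τ·sparse` and clip at zero; steps
`σ = τ = 0.95/√(‖K‖₁² + 8)`; termination on primal–dual residuals every 50
iterations. A pixel-count guard (default 64², overridable with `force`)
reflects the method's cost at realistic sizes. A cross-check path
materializes `H` densely on ≤16² instances and re-solves the program (TV
and L1 kinks smoothed by `1e-7`, perturbing the optimum by at most
`~1e-7·n`) with bound-constrained L-BFGS-B — an optimizer wholly
independent of the splitting solver, used as the test oracle.

## Synthetic data

The generator emulates the benchmark conditions the solvers are evaluated
under: 20 ground-truth images — 5 binary base shapes (ellipse, rectangle,
pentagon, triangle, cross) × 3 rotations = 15 strictly two-valued images,
plus 5 multi-level images (ramp ellipse, step pyramid, radial disk, ramp
pentagon, two-level annulus) — each paired with its simulated DIC image.
Binary shapes are rasterized by exact pixel-centre inclusion tests with the
geometry (not the image) rotated, so the two-valued cardinality invariant
holds exactly. Default image size is 128×128, a desk-scale choice (the
benchmark literature states no size). The default PSF is the Dirac
difference at one-pixel offset — a close approximation of the σ = 0.5
Gaussian derivative — at 45° shear; the shear is never hard-coded and every
entry point accepts an angle. Noise is additive white Gaussian at a stated
SNR referenced to the *variance* of `G` (DIC images carry a large DC bias,
so mean-square referencing would understate the degradation); 20 dB is the
benchmark's noisy condition. The bead phantom is the chord-length profile
`OPL(ρ) = Δn · 2√(r² − ρ²)` of a 9 µm polystyrene bead (n = 1.595) in
index oil (n = 1.515), sampled at 0.25 µm/px on a 53² grid — a
mid-magnification sampling chosen once, as the physical pixel size of such
acquisitions varies by instrument.

What the generator does *not* emulate: diffraction and partial coherence
(the linear model's own scope), bias retardation and flat-field structure,
camera noise statistics (Poisson, fixed-pattern), and the irregular
morphology of cells. Passing tests therefore establish correctness of the
*solvers under the linear model*, not photometric accuracy on real
micrographs; on real data the PSF is imperfect and the recovered OPL is
meaningful only after bead calibration.

## Evaluation and calibration

Negative reconstruction values are clipped first, then both reconstruction
and truth are independently min-max scaled to [0, 1] (clip-then-scale, in
that order) before the MSE. ROC sweeps every unique reconstruction value
plus a sentinel above the maximum, counts threshold ties as foreground, and
integrates trapezoidally — which makes the AUC identical to the
Mann–Whitney U statistic with half-weighted ties (a brute-force test
invariant). Benchmark summaries weight base shapes equally regardless of
rotation count: rotation MSEs are averaged first, then shapes.

Calibration averages four centre-line profiles (horizontal, vertical, both
diagonals; diagonals resampled by linear interpolation to one-pixel
physical spacing) and fits `theory ≈ scale·measured + offset` by least
squares. An affine fit (not scale-only) is the default because
reconstructions are defined only up to the background level; scale-only is
available via a flag. The profile agrees with the closed form to well under
1% of peak over the disc interior; at the rim the chord profile has
infinite slope and any finite-pixel interpolation errs at the few-percent
level — an intrinsic sampling property, not a solver artifact. Bead centres
on real images are located by Otsu threshold + centroid; synthetic tests
pass the known centre.

## Problem sizes and limitations

Test and acceptance runs use 128² benchmark images (20 phantoms), 48²
fixtures for monotonicity, 12²–16² instances for the dense cone-program
oracle, and the 53² bead; these sizes exercise every code path while
keeping a full run in minutes on one CPU. Known limitations: plain explicit
descent converges slowly in the kernel's near-null low-frequency directions
(visible as reduced amplitude that calibration absorbs); the TV term
flattens gentle interior gradients (the flat-top signature on the bead) and
shrinks peak amplitude by several percent at λ = 0.1; all Fourier methods
assume content stays away from image borders; and nothing here corrects
diffraction blur of thick, curved objects, which the linear model cannot
represent.
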