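# Methods

This note records the models behind `spisort`, the defaults that matter,
and the places where a genuinely open design choice was fixed.

## The synthetic experiment

The generator emulates a single-particle imaging run on an icosahedral
virus at small scattering angles.

**Particle.** A regular icosahedron of configurable inradius (default 10
voxels on a 32³ grid, 2.2 nm voxels → ~50 nm across, roughly a small
bacteriophage) with `capsid_density` 1 and an interior core sphere of
density 1.6 mimicking the packaged genome. The core is centred by default;
a `core_offset` preset displaces it toward a vertex to demonstrate
asymmetric interiors. Edges are softened by a Gaussian of σ = 0.8 voxels.
Voxelization is by the face-plane test max_n(v·n̂) ≤ r over the 20 face
normals (the dual dodecahedron vertices).

**Reciprocal space.** The ground-truth intensity is |F|² of the zero-padded
density (default linear oversampling 3; phasing requires ≥ 2). One volume
voxel spans Δq = 2π/(N·Δr) nm⁻¹ in the angular convention
q = (4π/λ)sin(θ/2); real-space lengths are reported as 1/q, matching the
way small-angle SPI work pairs its q values with nanometre resolutions.

**Rendering.** Flat-Ewald (central-slice) approximation: a frame is a
trilinear central-plane sample of the rotated intensity volume. At the
small-angle resolutions this targets, Ewald curvature is far below a voxel
and is deliberately ignored. Orientations are uniform quaternions
(normalized 4-Gaussians). Multi-particle frames combine complex amplitudes
F₁(R₁q) + e^{−iq·d}F₂(R₂q) before squaring, so they carry fringes of period
2π/|d_xy|; the displacement's in-plane magnitude is drawn from
`multi_hit_separation_range` because the axial component is invisible to a
flat detector — a "multi" hit displaced along the beam is physically
indistinguishable from a single hit and would be unlabelable even by eye.
Non-hits are uniform-sphere droplets (form factor
[3(sin x − x cos x)/x³]², x = qR) plus flat Poisson background.

**Detection.** Per-pixel Poisson counts at the requested expected photon
number, gain 28 ADU/photon, Gaussian read noise σ = 4 ADU, masked pixels
set to a sentinel. The gain/noise values are fixed, arbitrary calibrations;
preprocessing inverts exactly this model.

**Defaults as study conditions.** 50 000 photons per particle per frame and
in-plane separations of 12–32 voxels were chosen once, during design, so
that the three classifiers face a separable but non-trivial task (fringe
periods of 3–8 detector pixels against a speckle background); they are not
calibrated to any particular beamline, and photon-starved settings (≲ 10⁴
photons/frame) make all three classifiers collapse toward chance. The
bundled labelled split — 200 patterns at 79:121 single:non-single — mirrors
the hand-labelled training sets this kind of pipeline is built around.
Class counts follow deterministic largest-remainder rounding, so printed
fractions map to exact counts.

What the generator does **not** model: Ewald curvature, detector panel
gaps and tiling, pulse-intensity jitter, hydration/solvent contrast, or
particle heterogeneity. Passing classifier tests on these synthetics shows
the methods separate interference-fringed from single-particle speckle at
realistic photon budgets; it does not certify accuracy on any real
beamtime's artefact mix.

## Preprocessing

Binning **sums** 4×4 blocks (photon conservation; an output pixel is masked
only if all 16 inputs were). Friedel repair copies the value of the
nearest-pixel point reflection through the (possibly fractional) beam
centre; pixels whose mate is also bad stay masked at 0; the operation never
touches valid pixels and is idempotent. ADU→photon conversion divides by
the gain, rounds half-to-even, and zeroes anything below one photon —
sub-photon analogue signal is indistinguishable from noise. Classifier
inputs are ln(1 + n) scaled and normalized to a common mean (default 1.0);
the logarithm base is immaterial once means are equalized. The photon
branch used for orientation analysis bypasses the log/normalization
entirely.

## Graph-cut classifier

Vertices are patterns; each connects to its k = 10 nearest neighbours
(Euclidean distance on flattened 64×64 feature images) with
w_ij = exp(−d²_ij/σ_iσ_j). **Local scale:** σ_i is the distance to the k-th
neighbour (Zelnik-Manor–Perona local scaling). The alternative "standard
deviation of the k neighbour distances" reading is implemented as
`sigma_mode="std"` but is not the default: on concentrated high-dimensional
data the spread of the neighbour distances is two orders of magnitude below
the distances themselves, every exponent is ≈ −10³, and all weights
underflow — the k-th-distance convention keeps exponents O(1) by
construction.

The region force is a similarity-weighted vote of the labelled seeds,
prior₁(x) = Σ_{s∈class 1} w(x,s) / Σ_s w(x,s), evaluated in log space
(softmax) so the ratio survives even where individual exponentials
underflow; seed vertices are pinned to their own label, priors are clipped
to [10⁻⁶, 1−10⁻⁶], and unary costs are −log prior. The relaxed Potts
functional (unary + λ·weighted graph TV, λ = 1.0 chosen by a coarse grid
search on synthetic data) is minimized by a Chambolle–Pock primal–dual
scheme: dual ascent on edge variables capped at λw_e, primal descent
projected to [0,1], steps τ = σ = 0.99/‖K‖ with the incidence-operator norm
from power iteration, relative duality gap ≤ 10⁻⁶ or 2000 iterations
(best iterate returned with a warning on non-convergence). Thresholding at
u > 0.5 (ties → class 0) recovers the exact discrete min-cut on instances
with a unique optimum — verified against exhaustive enumeration in the
tests. Scores are invariant under global feature rescaling because the
local σ absorbs the scale.

## CNN classifier

Input 64×64 → three blocks of [3×3 conv (no bias) → batch norm → ReLU →
2×2 max-pool → dropout 0.2] with channels 1→2→2→3 → flatten (192) → one
hidden dense unit (with bias, identity activation) → one sigmoid output
unit (no bias). Parameter budget: conv 18+36+54, batch-norm 4+4+6, dense
193, output 1 — **316 total**, a deliberate bottleneck against overfitting
200-image training sets. The hidden unit carries no ReLU: a rectified
bottleneck of width one can die irreversibly (observed as training pinned
at ln 2), while the conv stack already supplies the nonlinearity.

Training: binary cross-entropy, Adam (lr 3·10⁻³, batches of 32, 200
epochs), all randomness from one seeded generator, so identical seeds give
bitwise-identical weights. A learning rate of 10⁻³ underfits this
architecture within 200 epochs. Batch-norm running statistics (momentum
0.1) are frozen at inference and dropout is disabled, making prediction
deterministic.

## Diffusion-map classifier

Dense Gaussian affinity A_ij = exp(−d²/ε), ε = median squared k-NN distance
when "auto". The diffusion operator P = D⁻¹A is diagonalized through its
symmetric conjugate D^{-1/2}AD^{-1/2} (dense below 2000 patterns, ARPACK
above); the trivial constant eigenvector is dropped and the next m = 5
eigenvectors, scaled by eigenvalue^t with t = 1, are the coordinates
(sign-fixed for reproducibility). Classification is nearest class centroid
of the labelled seeds with score d₀²/(d₀² + d₁²) — plain row normalization
(no density correction), and a centroid rule where fancier cluster-shape
rules would need problem-specific tuning.

## Phase retrieval

Constraints: modulus (replace |F| by √I on measured voxels, keep phases;
unmeasured voxels float) and support-plus-positivity (density is real,
non-negative, confined to n voxels). A run starts from uniformly random
phases and executes 100 ER + 200 difference-map (β = 1) + 200 ER
iterations; each iteration re-selects the support as the `support_size`
voxels of largest density (ties broken by voxel index). Because selecting
the n largest non-negative values is an exact projection onto
{x ≥ 0, |supp| ≤ n}, ER is a true alternating projection and its relative
modulus error ‖|F(ρ)|−√I‖/‖√I‖ is non-increasing from the first recorded
iterate; traces therefore describe post-update iterates, not the random
start. 2000 support voxels is the production default; desk-scale tests set
`support_size` to the true particle volume (~600 voxels on a 32³ grid), as
one would estimate it from particle size and oversampling.

Ensembles run 40 independent seeds (spawned deterministically from one
seed). Runs are aligned to the first by the integer circular shift and
Friedel-twin inversion maximizing cross-correlation — rotations are not an
ambiguity since all runs phase the same volume — then averaged voxelwise.
The PRTF is the radially averaged magnitude of the mean reciprocal unit
phasor; identical runs give exactly 1, independent phases give
O(N^{-1/2}) ≈ 0.14 at N = 40, and the 1/e crossing is the reported
resolution. Convergence is ‖ρ_k − ρ_{k−1}‖₂/‖ρ_k‖₂; both error norms are
plain L2 ratios over measured voxels — a documented convention, with 0/0
defined as 0.

## Metrics

Shell statistics bin by |q| with empty shells flagged NaN rather than zero.
The R factor uses the symmetrized denominator
R = Σ||F_a|−|F_b|| / Σ(|F_a|+|F_b|)/2 (making it symmetric; scaling one
volume by 2 gives the closed form 2(√2−1)/(√2+1) ≈ 0.343 in every shell).
FSC is Re ΣF_aF̄_b/√(Σ|F_a|²Σ|F_b|²) with resolution 1/q at the 0.5
crossing. Orientation probabilities are one expectation step of
orientation recovery: model slices rendered per grid orientation, scaled to
each pattern's total counts, floored at 10⁻¹², Poisson log-likelihood
Σ K log W − W, softmax rows under a uniform prior. The grid is Fibonacci
directions × in-plane angles with quaternions built so the slice normal is
the Fibonacci direction; the orientation sphere map therefore collapses
in-plane angles exactly. Desk grids use 10²–10³ directions × a few in-plane
angles; 50 100 orientations is kept as the production preset and its
uniform baseline 1/50100 ≈ 2·10⁻⁵ is exact by construction.

Cross-section eccentricity samples central planes along Fibonacci normals
and fits the contour at `contour_level` (default 0.5) × section max by
sub-pixel radial crossings plus least squares on the centred-ellipse form
1/r(θ)² = x̂ᵀMx̂; e = √(1 − (b/a)²). Second-moment fitting of the
thresholded region is provided (`fit_ellipse_moments`) but is not used by
the analysis: e amplifies the moment ratio so strongly near circularity
that pixelation bias alone fakes e ≈ 0.1, an order of magnitude above the
contour fit's error. Even the contour fit inherits the target's own
digitization: a voxelized ball carries genuine lattice anisotropy, so
near-zero eccentricities are only resolvable for smoothly sampled (or
pre-smoothed) maps.

## Numerical notes and limitations

* Similarity weights are floored at 10⁻³⁰ so distant neighbour pairs keep
  their edges instead of vanishing by underflow.
* Trilinear slice interpolation low-passes sharp diffraction rings; the
  orientation-averaged radial profile of rendered frames tracks the
  spherical average of the volume to ~1% (median) but single shells at
  sharp ring edges deviate by up to ~6%.
* Relative form-factor errors explode in the immediate neighbourhood of
  diffraction minima of digitized spheres (the binned average cannot reach
  zero); profile agreement is asserted away from the zeros, and minima
  positions are checked separately.
* Test problem sizes (700-pattern datasets, 32³ phasing grids, 40-run
  ensembles, 10²–10³-orientation grids) are the package's chosen desk
  scale: large enough for the statistics being tested, small enough to run
  on a single CPU.
* The full iterative orientation-recovery merge (expectation maximization
  over many iterations) is out of scope by design; only its expectation
  step and the downstream probability analyses are implemented here.
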