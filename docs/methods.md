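# Methods

## The generative model

flexrec models a continuously flexible macromolecule as deformations of a
single canonical density map. For particle image *i* with known pose
φ<sub>i</sub> and CTF C<sub>i</sub>,

    I_i = C_i P(φ_i) D(f_θ(z_i), V) + η,

where V is the canonical map (a real-space voxel grid N³), z<sub>i</sub> ∈
R<sup>K</sup> is that particle's conformational coordinate, f<sub>θ</sub> is
a small fully connected network (the *flow generator*) producing one 3-vector
displacement per vertex of a tetrahedral mesh, D is a density-conserving
convection operator, P(φ) projects along the viewing direction, and η is
white Gaussian noise. Fitting minimizes

    L = E_data + λ E_rigid,    E_data = ½ Σ_i ||I_i − C_i P(φ_i) D(f_θ(z_i), V)||²,

plus a unit-variance Gaussian prior ½||z<sub>i</sub>||² per particle. All
three groups of unknowns — V, θ and z<sub>1:M</sub> — are learned jointly
from the images.

Assumptions: poses and CTFs are known (from an upstream consensus
refinement) and are not re-optimized; the noise is white with the dataset
scale absorbed into λ; conformations are related by *motion* (density
transport), not by composition changes — appearing/disappearing density is
outside the model.

### Deformation parameterization and rigidity prior

The mesh is a lattice of cubes (element size a user parameter, typically a
few voxels) covering the molecular envelope, each cube split into 5
tetrahedra with parity-alternating orientation so neighboring faces are
compatible. Vertex displacements are interpolated to voxel centers with
linear shape functions (barycentric weights); voxels outside the mesh do not
move. A custom construction accepts a coarse segmentation of the map into
subdomains, expands each segment to its nearest voxels, builds one submesh
per subdomain and shares vertices only across interfaces the user declares
continuous — the remaining interfaces are "cuts" along which adjacent
domains may shear independently.

Within element *j* the deformation is affine, u(x) = A x + b, with A solved
exactly from the four vertex rest/displaced positions. Local nonrigidity is
penalized as

    E_rigid = Σ_i Σ_j w_j Σ_ℓ (s_ijℓ − 1)²,

the squared deviation from 1 of the singular values of A<sub>ij</sub>. The
per-element weights w<sub>j</sub> interpolate linearly in mean element
density from w_min = 0.5 (empty elements) to 1.0 (densest element), so empty
space around the molecule may compress and stretch more freely. The gradient
uses the analytic SVD form U diag(2(s−1)) Vᵀ, which is well defined for this
symmetric spectral function also at repeated singular values.

### Convection

The flow is a forward map from canonical to deformed coordinates: each
source voxel deposits its density at its mapped position through an
interpolation kernel (a "splat"), W(x) = Σ<sub>y</sub> k(x − y − d(y)) V(y).
This conserves total mass by construction — the kernel weights of each
deposit sum to 1 — without computing Jacobian determinants, exactly so
whenever the deposit stays inside the grid. Both trilinear (default, 8
taps) and Keys tricubic (64 taps, a = −0.5) kernels are implemented; the
tricubic kernel gives smoother gradients at about 4× the cost.

### Projection and CTF

Projection is performed in real space: the convected map is resampled onto
the rotated microscope frame about the center voxel N//2 and summed along
the viewing axis, then shifted in-plane. Resampling is trilinear by default;
an optional tricubic path reduces the interpolation error from ~1% to ~0.03%
(measured against analytic Gaussian projections) where accuracy matters more
than speed. A constant map of value c projects to N·c per interior pixel.
The convected map is a scratch buffer inside the fused prediction; it is
materialized only by the explicit `convect`/`convected_series` paths.

The CTF follows the weak-phase model, CTF(s) = −(√(1−w²) sin χ + w cos χ)
with χ(s) = πλ Δf(α) s² − (π/2) Cs λ³ s⁴ + phase shift, relativistic
wavelength λ(V₀), astigmatic defocus Δf(α) and underfocus positive (CTF
negative at low frequency). It is applied as a real, even multiplier on the
image spectrum, so the operator is self-adjoint and the backward pass reuses
the forward multiplier. On the half-spectrum (rfft) grid the aliased
±Nyquist column is averaged so the multiplier stays exactly Hermitian under
astigmatism.

All gradients (through CTF, projection, splat, shape-function interpolation,
the MLP, and the SVD of the rigidity term) are hand-derived adjoints in
numpy/numba and are verified against central differences in the test suite
at relative error < 1e-3 end to end (typically ~1e-7 per stage).

## Inference and training

**Auto-decoder latents.** Per-particle coordinates are inferred directly
against the generative model, with no encoder network: with V and θ fixed,
each image's objective ½||I − pred(z)||² + ½||z||² is minimized by cyclic
per-dimension golden-section search on [−4, 4] (default) or by backtracking
gradient descent. The search always keeps the best point evaluated, so the
per-image objective never increases; a probe that drives the deformation
beyond the divergence guard (displacement > N/2) scores +∞.

**Noise injection.** During generator updates, Gaussian noise is added to
the latent point estimates (σ decaying linearly from 0.1 to 0.02 over
training, in units of the unit-variance prior). This smooths the
latent-to-deformation map; it is never applied at evaluation time.

**Block coordinate descent.** When latents start at zero, the first 5
epochs (warmup) update θ and z with V fixed at the (band-limited) consensus
map; when latents are supplied externally (e.g. from a linear-subspace
method), warmup updates θ with z fixed. Subsequent epochs alternate between
updating V and updating (θ, z). Updates use Adam (default) or Nesterov SGD
on minibatches; latents in a minibatch are inferred before its gradient
step. λ defaults to 2.0 (useful range about 0.5–5; larger λ yields stiffer,
more nearly rigid flows).

**Frequency marching.** V is constrained low-pass with a band-limit ramping
linearly from N/8 to N/2 shells over the first half of training (2-shell
cosine rolloff, re-applied after every V update together with the optional
solvent mask, and idempotent at a fixed shell). The zero-deformation mask is
honored exactly: vertices inside it are pinned to zero displacement in the
generator output and their gradients are zeroed.

**Checkpoints.** Training state snapshots (generator weights, latents, map,
loss trace, RNG state, optimizer moments and early-stop bookkeeping) are
taken every epoch and serialize to a single npz; resuming from a checkpoint
reproduces the uninterrupted run bitwise. Because the latent-noise schedule
is defined over the configured epoch budget, an interrupted run is one
stopped early under the same configuration, not one configured shorter.

**Learning rates and budgets.** None of these are physically constrained;
the defaults (Adam, θ at 1e-4 for production-size problems, V at 0.1, epoch
budget 40 with early stop when the loss improves < 0.1% three times) are
exposed in `TrainConfig`. On the small synthetic problems used in the tests
the flow generator must grow displacements by two orders of magnitude from
its near-identity initialization within a few dozen Adam steps, so those
runs use a larger θ rate (3e-3–5e-3); with minibatch counts in the
thousands-of-particles regime this is stable.

**Initialization.** Hidden layers use He initialization; the final (linear,
bias-free) layer is scaled by 1e-2 so training starts near the identity
deformation and the consensus map explains the data initially. The default
architecture is a six-layer MLP with 64 hidden units (ReLU), K = 2 latent
dimensions (1–8 exposed; the hinge fixtures use K = 1).

## High-resolution refinement and validation

Training uses a small box N_L (Fourier-cropped images) and a band-limit well
below its Nyquist. Afterwards θ and z are frozen, mesh vertex positions and
displacements are rescaled by N_H/N_L (the physical deformation is
scale-invariant in Å), and the canonical map is re-estimated at full box
size for each half-set by full-batch L-BFGS (memory 10, strong Wolfe line
search, from V = 0, until the gradient infinity-norm drops 1000× or an
iteration cap). The objective is quadratic in V; an optional small Tikhonov
ridge pins the weakly observed corner frequencies and makes the minimizer
unique (used when comparing solvers, not needed for FSC validation).

The two half-maps are compared by Fourier shell correlation (per-shell
normalized cross-spectral correlation, optional real-space mask, resolution
read at a threshold — 0.143 by default, 0.5 also reported — by linear
interpolation between shells; no noise-substitution mask correction).
Correlation in shells beyond the training band-limit is signal the motion
model recovered independently in both half-sets — the central validation
logic. Cn symmetrization (trilinear rotation averaging about a chosen axis)
is available post hoc for molecules whose canonical density is symmetric.

## The synthetic data generator

The toy molecule is a sum of Gaussian blobs in a static domain and a mobile
domain joined by a connector blob. The ground-truth motion rotates the
mobile domain rigidly about a hinge axis by z·(max angle)/3 degrees,
blended smoothly (smoothstep over 4 voxels across the connector) to zero on
the static side; the true deformation is therefore exactly rigid inside the
mobile core and exactly zero in the static domain, so the true E_rigid
vanishes on core elements — a known floor the fitted model should approach.
Defaults: box 32, voxel 3 Å, one latent dimension, 20° hinge range at
|z| = 3, M = 2000 particles, SNR 0.5, defocus 8,000–20,000 Å, 300 kV,
Cs 2.7 mm, amplitude contrast 0.07, uniform SO(3) poses, ±2 Å shifts,
latents standard normal (clipped to ±3 to stay inside the hinge range).

Clean images are rendered through the same physics as the fitted model but
with the *analytic* deformation field on a 2× oversampled grid, then
Fourier-cropped to the dataset box (amplitudes scaled by 1/oversample so the
cropped projection matches the native projection scale). Fitting a model
whose discretization differs from the one that made the data avoids the
inverse crime. Noise is white Gaussian with variance set so that the clean
signal variance inside the central disk divided by the noise variance equals
the requested SNR.

What the generator does *not* emulate: structured noise (micelle, ice
gradients), beam-induced motion, pose/CTF estimation error, compositional
heterogeneity, and non-rigid internal motion of the domains themselves.
Passing tests on these fixtures therefore demonstrate correctness of the
estimator under its own model assumptions at desk scale, not performance on
experimental micrographs.

## Problem sizes used in the test suite

The validation experiments are sized to run comfortably on one CPU core:

- Latent/motion recovery: the default hinge fixture (N = 32, M = 2000,
  SNR 0.5), trained on the Fourier-cropped 24 box (the hinge signal is
  low-frequency; the crop preserves it and cuts kernel cost ~2.4×) at batch
  500, θ rate 5e-3, 24 epochs, band-limit ramping to shell 9 (≈ shell 12 of
  the 32 box). Success criteria: |Pearson r| ≥ 0.9 between learned and true
  latents after sign alignment, and per-vertex displacement RMSE < 1.5
  voxels at ±1 latent standard deviation inside the mobile core. The θ rate
  is larger than a production default because at desk scale an epoch holds
  only 4 minibatches: the generator must traverse two orders of magnitude
  in flow amplitude within ~60 Adam steps.
- Beyond-band-limit signal: the fine-featured validation phantom
  (`make_validation_spec`: 64 box, σ ≈ 1.3-voxel blobs so the molecule
  carries spectral power well past half-Nyquist, 40° hinge range so the
  motion is large relative to the feature size, M = 240, SNR 2), trained on
  its Fourier-cropped 32 box at a fixed shell-8 band-limit, then half-maps
  reconstructed at N_H = 64 by L-BFGS (35 iterations) and compared by
  masked FSC over the mobile domain against a rigid reconstruction of the
  same half-sets. Two notes on the design. First, the per-shell SNR of a
  reconstruction scales with the particle count: a desk-scale experiment
  with ~120 particles per half-set needs individually cleaner images to
  reach the aggregate per-shell SNR that a real dataset achieves with 10⁵
  particles at per-image SNR ~0.01, hence SNR 2 here. Second, a hinge
  produces purely tangential rotational smear; with small angles a rigid
  reconstruction retains most of an isotropic FSC shell, so the motion
  range must be large in feature units for the rigid baseline to degrade
  visibly — which is exactly the regime the method targets.
- λ sweep: reduced datasets (M = 500, shortened epoch budget) at
  λ ∈ {0.5, 2, 5}, checking that mean element nonrigidity is non-increasing
  in λ.

## Known limitations

- Single-threaded numba kernels; production cryo-EM box sizes (256+) would
  need a GPU backend.
- The white-noise likelihood ignores frequency-dependent noise; λ therefore
  absorbs an arbitrary per-dataset scale.
- Latent inference cost scales linearly in K with coordinate descent; the
  gradient method is available for larger K but needs per-image backward
  passes.
- Mesh quality is not optimized (no remeshing); very coarse meshes bias the
  recovered motion toward piecewise-linear fields.
- With a cold start and weak per-image signal the auto-decoder can converge
  to a sign-flipped or rescaled latent axis; this is the expected gauge
  freedom of the model, and downstream analyses treat latents up to sign
  and scale.
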