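# Methods

`elunet` solves quasistatic inverse problems in 3D linear elasticity: given a
measured 6-channel strain volume (and, for anisotropic materials, the fiber
orientation field) together with the normal tractions prescribed on the six
faces of a block specimen, it recovers the voxel-wise material parameters by
training a volumetric encoder–decoder network against physics residuals.  No
ground-truth parameters or stresses enter the training loss; the inversion is
driven entirely by the constitutive law, static equilibrium and the boundary
conditions.

## Model

**Forward physics.** Small-strain linear elasticity without body forces:
σ = C ε in Voigt form (order xx, yy, zz, xy, yz, xz; engineering shears carry
the factor 2) and ∇·σ = 0.  Two material classes are supported:

* isotropic, parameterized by the Lamé pair (λ, μ) with
  E = μ(3λ+2μ)/(λ+μ), ν = λ/(2(λ+μ));
* transversely isotropic, parameterized by the five local stiffness terms
  (C′₁₁, C′₁₂, C′₂₂, C′₂₃, C′₄₄) in the fiber frame (x′ longitudinal, y′z′
  the isotropy plane; the (yz,yz) entry is (C′₂₂−C′₂₃)/2).  The lab-frame
  stiffness is C = Bᵀ C′ B, where B is the Bond matrix of the direction-cosine
  matrix built from Z–Y′–Z″ Euler angles.  Engineering constants
  (Exx, Eyy, ν_xy, ν_yz, Gxy; Gyz dependent) are recovered from the stiffness
  terms after inversion, not estimated directly — the constitutive residual is
  then *linear* in the quantities the network outputs, which in our experience
  (and in the linearized-parameterization argument for this family of methods)
  is decisive for convergence.

**Networks.** A three-level UNet (double 3×3×3 convolutions, ReLU, same
padding, 2× max-pool, trilinear-upsample + convolution decoder, skip
connections, 1×1×1 head).  Reference widths are 64/128/256; reduced presets
(16/32/64 and 8/16/32) are first-class for CPU-scale problems.  Isotropic
mode: one network, strain (6 ch) → (Λ, M, six stresses).  TI mode: a
Parameter UNet maps the mean of the normalized strains over the three
loadings to the five stiffness channels, and a weight-shared Stress UNet maps
each loading's strains to that loading's stresses.  Material-parameter heads
pass through softplus, keeping stiffness outputs strictly positive; stress
heads are linear.  The network stack (convolutions via cached-index im2col +
BLAS, explicit layer-wise backward passes, Adam) is implemented in numpy
inside `elunet.nn`; the backward pass is verified against central finite
differences to ~1e-7 relative in the test suite.

**Losses.** Three mean-squared families, summed with unit coefficients:

* constitutive: C(outputs)·ε − σ_net per voxel.  The per-voxel coefficient
  tensors (A ε, Bm ε for isotropic; Bᵀ Eₖ B ε for TI, with B fixed by the
  known orientation) are precomputed once, so gradients with respect to all
  network outputs are analytic and exact;
* equilibrium: the finite-difference divergence of σ_net, central differences
  inside and second-order one-sided stencils on the boundary layers (the loss
  is defined volume-wide, no cropping);
* boundary: per-face traction mismatch.  A loaded face prescribes the normal
  traction and zero shears, a frictionless (roller) face prescribes zero
  shears only, and a free face prescribes all three traction components zero.

Trainable self-adaptive spatial weights (one volume for the constitutive
term, one map per face for the boundary term) are parameterized as w = s² —
non-negative by construction, initialized at one — and updated by gradient
*ascent* with the same learning rate as the main optimizer, so they grow
wherever residuals persist.  The exact update rule of the mechanism this
mirrors is published separately and not restated here; plain simultaneous
ascent is our reconstruction of it.

**Nondimensionalization.** Strains are divided by the maximum strain
magnitude ε*, tractions by the largest prescribed traction σ*; a recovered
dimensionless stiffness P maps back as p = P σ*/ε*.  In TI mode all three
loadings share one (σ*, ε*) pair so a single dimensionless stiffness field is
consistent across loadings; the Parameter UNet input is the per-channel mean
of the so-normalized strains (normalize-then-average).

**FD conditioning (important numerical choice).**  Inside the training losses
the derivative operators use voxel-normalized spacing h/min(h) rather than
physical spacing.  With physical spacing the 1/h factors make the equilibrium
gradients dominate by ~(1/h)²; the optimizer then keeps the stress field
divergence-free but approaches the prescribed boundary tractions extremely
slowly (we observed the volume error plateau at ~20% for thousands of
epochs).  With per-voxel derivatives the three loss families compete on
comparable scales and the same problems converge one order of magnitude
faster.  The zero set is unchanged — axis ratios are preserved — and the
public `equilibrium_residual` / `equilibrium_loss` functions keep physical
units.

**Training.** Full-volume batches, Adam at learning rate 1e-3, a fixed epoch
budget (no early stopping), single optimizer over all network parameters.
Runs are deterministic given (config, seed): initialization, noise and the
weight updates all derive from the seed.  Divergent losses (NaN) abort with a
diagnostic.  Reference protocol is 40 000 epochs at full widths; the desk
presets used throughout the tests are 2 000–5 000 epochs at reduced widths on
12³–16³ grids, chosen so that a full inversion completes in minutes on one
CPU core.

## Synthetic phantoms

The generator family replaces an imaging + commercial-FEM pipeline and
defines the study conditions:

* **Manufactured phantom** (isotropic): built from the displacement field
  u = (x g(z), y g(z), −(x²+y²) g′(z)/2 + h(z)) with g linear, giving linear
  lateral strains, shear-free kinematics and a constant uniaxial stress
  σ_zz = −σ₀ — *exactly* divergence-free and compatible at any grid size.
  Defaults: E(z) linear from 1 to 2 kPa, ν(z) between 0.35 and ~0.45,
  σ₀ = 0.035 kPa so the peak axial strain is −0.035.
* **Homogeneous blocks** (isotropic or rotated-TI): uniform-stress exact
  solutions via the 6×6 compliance.
* **FEM phantoms**: trilinear hexahedral elements (one per voxel, 2×2×2
  Gauss), per-voxel stiffness, uniform traction on the loaded face
  (force/area), roller support opposite (zero normal displacement, in-plane
  rigid modes pinned at two corner nodes), free lateral faces; sparse direct
  solve, strains at voxel centers.  The solver passes homogeneous patch tests
  to ~1e-12 and balances global forces to ~1e-13.
* **Inclusion phantom**: two seeded ellipsoidal inclusions (E = 2 kPa/ν = 0.35
  and 1.5/0.40) in a soft background (1/0.45) under z-compression — the
  brain-like contrast set on procedural geometry.
* **Cartilage phantom**: a 2 mm cube with three equal layers stacked along z
  (deep at the bottom), per-layer TI constants in MPa — superficial
  (35°, Exx 2, Eyy 0.4, Gxy 0.3, ν_xy 0.35, ν_yz 0.3), intermediate
  (60°, 3, 0.6, 0.4, 0.4, 0.35), deep (80°, 5, 1, 0.5, 0.45, 0.4) — the single
  fiber angle interpreted as the tilt θ of the longitudinal axis about the
  global Y axis (ψ = φ = 0, recorded in the dataset metadata so alternative
  conventions remain switchable).  Compression of 0.05 N (0.0125 MPa) applied
  along X, Y and Z in three separate forward solves.

Optional measurement noise adds zero-mean Gaussians per strain channel with
standard deviation = fraction × that channel's standard deviation (default
fraction 0.05 when enabled); tractions are never perturbed.

**What the phantoms do not emulate:** real segmented anatomy with curved
interfaces, unstructured-mesh discretization error and interpolation to the
voxel grid, correlated (speckle-like) measurement noise, and boundary
imperfections of physical experiments.  Passing recovery tests on these
phantoms demonstrates the correctness and conditioning of the inversion
machinery, not field performance on imaging data.

## Accuracy expectations and limitations

On exact analytic data the isotropic inversion at 16³ with the 16/32/64
preset reaches a volume MARE in E below 1% within a few thousand epochs,
though the epoch budget needed varies noticeably with the weight
initialization (some seeds need ~10 000 epochs where others need 4 000; Adam
occasionally produces transient error spikes that subsequent epochs undo).
On FEM-generated data the achievable error is bounded below by the mismatch
between the FEM strain field and the voxel FD equilibrium operator, which is
O(h²) — desk-scale grids therefore cannot reach the sub-2% errors attainable
at 160³, and layer/inclusion interfaces concentrate the residual error (the
evaluation reports transition-zone voxels separately for this reason).  The
TI problem with five unknown fields converges markedly more slowly than the
isotropic one: with the 16/32/64 preset the mean error over the five
parameters crosses 5% after roughly 4 500–5 000 epochs (12³ floors near
4.7%, 16³ reaches ~4.4% by 6 000 epochs).  Minibatch training, GPU
execution, other symmetry handling, and hyperelastic or viscoelastic laws
are out of scope.
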