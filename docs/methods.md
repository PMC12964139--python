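# Methods

## Scientific setting

White matter behaves mechanically as a fibrous composite: aligned,
myelinated axon bundles make both the shear and the tensile response
direction dependent. Magnetic resonance elastography (MRE) drives
~50 Hz shear waves through the skull, encodes the resulting micron-scale
displacements in MR phase, and inverts the wave field for viscoelastic
moduli. An isotropic inversion confounds the fiber-parallel and
fiber-perpendicular responses; this package implements the
transversely isotropic alternative end to end on synthetic data: a
three-parameter, nearly incompressible transversely isotropic (NITI)
material model, a multi-excitation time-harmonic forward solver, the
phase pre-processing chain, an adjoint-based nonlinear inversion, and
the group statistics (skeleton-based voxelwise permutation tests,
tract-ROI t-tests, added-value logistic regression) used to contrast a
young-adult and an older-adult group.

## The NITI material model

Each voxel carries

* `G2 = G' + iG''` — complex substrate shear modulus (shear
  perpendicular to the fiber axis), Pa;
* `phi = G1/G2 - 1` — shear anisotropy (fiber-parallel shear excess);
* `zeta = E1/E2 - 1` — tensile anisotropy (fiber-parallel Young's
  modulus excess);
* a unit fiber axis (in a study this comes from the principal diffusion
  eigenvector).

Damping is *isotropic*: `phi` and `zeta` are real and scale storage and
loss identically, so a single loss ratio `G''/G'` applies to the whole
deviatoric response.

The full stiffness tensor is not uniquely determined by the three
parameters; this package constructs it from engineering constants
through the standard transversely isotropic compliance matrix:

* the axial Poisson ratio is `nu31 = (3K - 2G')/(2(3K + G'))`, the
  isotropic value implied by the bulk modulus `K`;
* the in-plane Poisson ratio `nu12` is solved in closed form from the
  requirement that the volumetric compliance under hydrostatic stress
  equal exactly `1/K` for every `zeta` — this keeps the material
  nearly incompressible for all admissible anisotropies and makes
  `phi = zeta = 0` reduce *exactly* to isotropic elasticity with
  moduli `(G2, K)`;
* `E2 = 2 G2 (1 + nu12)` ties the transverse Young's modulus to the
  substrate shear modulus, `E1 = E2 (1 + zeta)`, `G1 = G2 (1 + phi)`;
* the storage compliance is inverted and the deviatoric part
  `C - C_vol` is scaled by `1 + i G''/G'` (lossless bulk response);
* the tensor is rotated so its symmetry axis matches the voxel fiber.

**Admissible domain.** Near-incompressibility forces
`E2 = 2 G2 (1 + nu12)` with `nu12 ~ 1 - 1/(2(1+zeta))`; the tensor
loses positive definiteness as `zeta -> -3/4`. The package therefore
bounds `zeta > -0.7` everywhere (generator clip, inversion bounds,
type validation). Observed white-matter values lie in roughly
`[0.2, 1.4]`, far from the bound. `phi > -1` keeps `G1` positive.

Derived scalar stiffness measures follow the elastography convention:
`mu2 = 2|G|^2/(G' + |G|)` (proportional to squared shear-wave speed;
equals `G'` when lossless, and bounded by `2G'` for loss ratios below
`(1+sqrt(5))/2` — always true for brain tissue), and the fiber-parallel
counterpart `mu1 = mu2 (1 + phi)`. Plane-wave phase speeds come from
the Christoffel (acoustic) tensor `n . C . n` of the storage stiffness.

Defaults: density 1000 kg/m^3 (soft-tissue convention), frequency
50 Hz, bulk modulus 1e7 Pa (>= 1000x the shear-modulus magnitude;
a near-incompressibility surrogate rather than a mixed formulation).

## Digital phantom and synthetic cohort

No raw images are publicly deposited for studies of this kind, so all
inputs are synthesized. A deterministic box phantom (default 32^3
voxels at 2 mm) contains an ellipsoidal brain with a gray-matter
shell, background white matter, and eight mutually exclusive tract
ROIs — CCB, FMAJ, FMIN, CR, CST, ATR, PTR, SLF — built from bars,
columns and sheets whose unit fiber fields follow the tract tangents.
Every tract keeps >= 50 voxels on any grid of >= 24 voxels per axis.

Subjects are drawn in two groups (20 young, 18 older by default).
For each tract and parameter one **tract-level** value is drawn from
the group's Normal(mean, SD) — between-subject variability, which is
what published tract tables report — and voxel noise (SD 0.08 kPa for
stiffness, 0.02/0.04 for phi/zeta, small DTI noise) models within-tract
heterogeneity. Draws are clipped to physical bounds (`mu2 > 0.5 kPa`,
`phi, zeta > -0.65`, `FA` in [0, 1]) with clip counts recorded.
Mechanical group means/SDs default to the published young/old tract
summaries; the DTI-like maps (FA, MD, RD, MK) default to plausible
assumed values (lower FA/MK, higher MD/RD in the older group) because
tract-wise DTI group tables are not part of the main text — these are
assumptions, configurable, not literature values. Background white
matter keeps FA = 0.15, below the skeleton threshold, so the mean-FA
skeleton tracks the tract cores.

Ground-truth complex moduli are realized from the stiffness draw by
inverting `mu2 = 2|G|^2/(G'+|G|)` at a fixed loss ratio
`G''/G' = 0.3`, a typical brain value at 50 Hz.

Seeding is counter-based: each subject's substream derives from
(master seed, subject id), so cohorts reproduce under reordering and
group-size changes.

What the generator does **not** emulate: realistic neuroanatomy,
inter-subject registration error (all subjects share the atlas grid),
crossing fibers, diffusion signal formation, scanner artifacts.
Passing tests therefore demonstrate correctness of the estimation and
statistics machinery under the stated statistical conditions, not
robustness to real-data confounds.

## Forward wave model

The steady-state equation `div(C(x):grad u) + rho omega^2 u = 0` is
discretized with trilinear hexahedral voxel elements on the property
grid (displacements on the node grid). The volumetric (bulk) term is
integrated with a single central point and the deviatoric term with
2x2x2 Gauss points — selective reduced integration, the standard cure
for volumetric locking of low-order elements near incompressibility.
Mass is lumped. Actuation is a Dirichlet patch on the domain boundary
(AP pillow on the anterior face, LR bottle on the temporal face);
remaining boundaries are traction free (natural). Each default drive
carries a 40% superior-inferior component: skull-coupled actuators are
never purely uniaxial, and the oblique polarization excites
fiber-parallel shear, which is what makes `phi` identifiable.

The complex symmetric system is solved by direct sparse LU. Verified
accuracy: the damped 1-D plane wave `exp(ik*x)`,
`k* = omega sqrt(rho/G)`, is reproduced within 0.9% at 16 elements and
0.1% at 24 (second-order convergence). Iterative alternatives (ILU
preconditioning, two-grid Jacobi/Galerkin) were evaluated and rejected:
the indefinite, nearly incompressible operator defeats both. Direct
factorization cost rises steeply with grid size (about 2 s at 12^3,
8 s at 16^3, 40 s at 20^3 on one CPU), which sets the problem sizes
used below.

The drive amplitude (default 10 um) is irrelevant to all results by
linearity.

## Phase pipeline and quality control

Scanner phase is synthesized as
`phase(t_j) = +/- s * Re[u exp(i omega t_j)] + N(0, sigma)` at four
offsets spanning one period, two polarities, three encoding directions,
wrapped to (-pi, pi]. The inverse chain is: polarity subtraction,
spatial unwrapping (reliability-sorted algorithm from scikit-image;
each unwrapped volume is re-anchored so its mean lies nearest zero,
since unwrapping is defined only up to a global 2-pi shift which would
otherwise leak into the temporal transform), temporal DFT across
offsets, first-harmonic coefficient divided by `2s`. The chain is an
exact inverse in the wrap-free noiseless regime (< 1e-10 relative) and
recovers fields with several deliberate 2-pi wraps to < 1e-6, provided
the per-voxel phase step stays below pi (the Nyquist limit of any
unwrapper).

Data quality is gated by the octahedral-shear-strain SNR: the mean
octahedral shear strain of the measured field (complex strain
magnitudes, central differences, one-voxel boundary rind excluded
because its one-sided stencils carry 4x the noise variance) divided by
the closed-form expected octahedral strain of pure displacement noise
at the stated noise SD. The reference uses the square root of the
expected squared octahedral sum; the Jensen gap (~2.5% at these
degrees of freedom) is absorbed by the Monte-Carlo calibration
tolerance. Fields with OSS-SNR below 3.0 are rejected by the inversion
unless explicitly waived. Whether published QC referenced motion
amplitude or an estimated strain-noise floor is not stated anywhere;
the noise-referenced definition here is a documented choice.

## Nonlinear inversion

The inversion minimizes the summed relative displacement misfit of the
available excitations plus a Tikhonov penalty on spatial gradients of
each parameter field, over voxelwise `theta = (mu2', mu2'', phi,
zeta)`. The forward model inside the objective imposes the *measured*
displacements on the whole domain boundary (any boundary data
consistent with the interior physics leaves the true parameters a
fixed point — the standard nonlinear-inversion boundary treatment), so
no knowledge of the actuators is needed. Gradients are adjoint-based
(one extra solve with the conjugate-transposed operator per
excitation); stiffness-tensor parameter derivatives use central finite
differences on the 6x6 Voigt matrix, vectorized over voxels.
Optimization is box-constrained L-BFGS with the moduli in log space
(`mu2'` in [0.1, 10] kPa, `mu2''` in [1 Pa, 10 kPa], `phi` in
[-0.65, 2], `zeta` in [-0.65, 4]); the recorded objective history is
non-increasing across accepted iterates. Initial guess: 2.5 kPa /
1 kPa / 0 / 0.5 uniform. The isotropic variant fixes `phi = zeta = 0`
and uses the AP field alone, yielding `mu_iso`; on a strongly
anisotropic phantom it is measurably biased away from the substrate
stiffness, which is exactly the motivation for the anisotropic model.

Subzone decomposition (a scalability device of the original
finite-element implementation) is out of scope at this problem size;
the objective is the same.

Measured recovery (noiseless two-compartment phantom, 10^3 voxels at
3 mm, 150 iterations, ~80 s): inclusion medians within 1.4% for
`mu2'`, 0.020 for `phi`, 0.039 for `zeta`; an isotropic phantom yields
`|phi|`, `|zeta|` medians ~0.01 and `mu_iso` within 0.3% of the
composite stiffness.

## Skeleton and ROI statistics

The white-matter skeleton is the medial sheet of the mean-FA > 0.2
mask: a voxel survives when the distance-to-edge transform is a local
maximum along the local sheet normal (gradient of the smoothed
distance map). Subject maps are projected by searching +/- 2 voxels
along that normal for each subject's maximal-FA position (ties resolve
to the nearest offset, so an identical subject reduces to direct
sampling); all-subthreshold windows are flagged missing and handled
listwise, and voxels with < 80% subject coverage are dropped.

Voxelwise inference is a pooled-variance two-sample t statistic with
p-values from the group-label permutation null (label shuffles shared
across voxels, add-one correction, both contrast directions).
Uncorrected voxelwise p at alpha = 0.05 is reported, matching the
published maps' display convention; TFCE/FWE cluster correction is out
of scope. Zero-variance voxels return p = 1. Percent-significant is
the significant fraction of evaluated skeleton voxels per direction,
and MRE-vs-DTI overlap classifies each skeleton voxel as
MRE-only / DTI-only / both / neither.

ROI analysis averages each map over (tract AND skeleton), compares
groups with pooled Student t-tests (the published tables use Student
t-tests; Welch is available via scipy directly), and applies strict
Bonferroni `p < 0.05/8`. The added-value logistic model
`P(old) ~ base DTI covariate + added MRE covariate` is fit per tract
by maximum likelihood with internally standardized covariates;
coefficients are reported on the raw scale (consistent with the large
printed anisotropy betas). The added term's p-value defaults to the
likelihood-ratio test: the Wald test measured a null rejection rate of
0.02 at n = 20+18 over 500 synthetic cohorts (small-sample
conservatism) versus 0.062 for the LRT; Wald remains available.
Exact collinearity and (quasi-)separation — including an added
covariate that alone separates the groups — are flagged instead of
reported as estimates.

**A calibration caveat established by simulation.** With the default
group parameterization, the containment "every tract Bonferroni-
significant for `mu2` is also significant for `zeta`" fails with
probability ~0.19 per cohort (20,000-replicate Monte Carlo on the
tract summary statistics): the borderline stiffness effects in PTR and
FMAJ cross the threshold by chance while their tensile counterparts
occasionally miss. The corresponding test documents this; the weaker
ordering — `zeta` differences are more widespread on the skeleton than
`mu2` differences — holds in 10/10 seeded cohorts.

## Pipeline

`run_pipeline` chains cohort synthesis, forward solves, phase
encode/decode, QC, TI + isotropic inversion, derived maps, skeleton
statistics, and ROI statistics into a report (QC table, tract summary
table, percent-significant table, overlap counts, regression table),
with every output file name carrying a hash of the configuration.
The statistics grid and the wave/inversion grid are decoupled:
properties are block-averaged by `wave_downsample` (default 2) before
simulation and inversion, and recovered maps are upsampled back —
mirroring the resolution gap between elastography acquisition and
standard-space voxelwise analysis, and keeping the nonlinear inversion
affordable. The pipeline's default iteration cap (10) yields usable
but under-converged maps; increase `inversion_max_iterations` to
~100+ for quantitative per-voxel accuracy.

Problem sizes used by the shipped tests: wave/inversion grids of
8-16^3 voxels at 2-4 mm, a 24^3 atlas for the ten-seed group-ordering
experiment and the end-to-end smoke run (3+3 subjects, 200
permutations), 32^3 for atlas/cohort unit tests. Reruns with the same
configuration and master seed reproduce every table exactly.

## Known limitations

* The stiffness-tensor parameterization is a documented stand-in: the
  three-parameter description does not pin down how `zeta` couples to
  the volumetric part, and other implementations may differ there.
* Inverse-crime validation: recovery tests generate data with the same
  discretization used by the inversion. This isolates the estimation
  machinery but does not measure model-form error.
* Single fiber per voxel; no orthotropy, no multi-frequency rheology,
  no poroelasticity, no registration/warping step.
* The phase chain models ideal sampling; no k-space artifacts, motion,
  or slice effects.
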