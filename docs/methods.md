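# Methods

`flairseg` segments sub-acute ischemic stroke lesions from single-channel
FLAIR MRI. The method is a two-stage classifier: a Bayesian maximum-a-
posteriori decision on multi-window Gabor texture features produces an
initial lesion estimate, which a customized four-class Markov random
field (CSF, GM, WM, lesion) refines using voxel intensities, texture,
neighborhood intensity differences, and learned clique statistics.
This note records the model, its assumptions, the parameters that
matter, and the design choices made where the design was genuinely open.

## Intensity standardization

Multi-center FLAIR intensities are not comparable across scanners, so
every volume is mapped to a standard scale by a piecewise-linear map
through histogram landmarks of the brain-masked foreground: the
quartiles Q1, Q2, Q3 as control points, anchored at the 1st and 99th
percentiles. Quartiles alone leave the tails of the map undefined;
the percentile anchors make it well-posed without letting single
extreme voxels drive the range. The target scale is fixed to [0, 1] so
that the bias-mask thresholds below are absolute numbers.

Bias-field handling is pluggable. The built-in estimator smooths the
log-intensities inside a *bias mask* — brain voxels in [0.12, 0.65] of
the standardized scale, excluding the hyperintense lesions and the
background that would distort the estimate — with an anisotropic
Gaussian (default bandwidth 20 mm) using normalized convolution, and
divides the field out. It is a deliberately simple smooth-field
estimator; externally corrected volumes can be supplied instead
(`--bias external`). Order of operations: standardize, mask, correct,
re-standardize, so downstream models always see one scale. When the
estimator bandwidth is close to the true field's length scale the
estimate is attenuated; choose the bandwidth below the field scale you
expect to remove.

## Multi-window Gabor features

Each axial slice is convolved with a bank of complex Gabor kernels

    g_r[x, y] = exp(-(x²/σ_x,r² + y²/σ_y,r²)) · exp(-j2π(m1·b·x/L1 + m2·b·y/L2)),

evaluated densely (spatial shift a = 1) on a support truncated at
3·max(σ); slice boundaries are reflection-padded. 2-D rather than 3-D
filtering is used because clinical FLAIR slice spacing is several times
the in-plane resolution. The per-voxel feature is the modulus of each
complex coefficient (sign-free, and it feeds Gaussian class models
naturally); the complex coefficients themselves are available
(`modulus=False`) and are strictly linear in the image.

The default bank has R = 3 windows at octave-spaced spreads
σ = (1.5, 3, 6) voxels. Frequency shifts are assigned per window at the
window's own octave — the largest window carries the m = 1 shifts
{(1,0), (0,1), (1,1), (1,−1)}, the middle window the m = 2 shifts, and
the finest window only its local-mean channel (its octave would sit at
the Nyquist rate). The rationale is the classic bandwidth pairing
σ·f ≈ 0.5–0.75: with a shared low-frequency lattice a small window's
oriented channels pass the local mean almost unattenuated
(exp(−(πfσ)²) ≈ 0.7 at σ = 1.5, f = 0.125 cy/voxel) and would mostly
re-encode brightness; at the octave-matched assignment the DC leakage
is below 0.5%, so oriented channels measure orientation. This yields
D = 11 features per voxel.

Window spreads are tuned by maximizing the total pairwise distance
Σ‖c_t − c_h‖ between lesion and non-lesion coefficient vectors over
labelled data, scanned exhaustively over a grid of base spreads (each
candidate scales the whole octave ladder) with a seeded subsample of at
most `pairs_budget` voxel pairs per volume. The scan is exact on the
declared grid and reproducible; the same subsample is used for every
candidate. The raw objective is scale-dependent (coefficient magnitudes
grow with window area), so it is most meaningful when the two classes
share mean intensity and differ in texture; spread optimization should
use data disjoint from the training set, and the CLI refuses overlaps.

## Bayesian initialization

The initial estimate treats each brain voxel's feature vector as a draw
from one of two multivariate Gaussians (lesion / non-lesion) with full
covariances (ridge-regularized, default 1e-6) and class-frequency
priors; the posterior is normalized over the two classes and computed
in the log domain. Ties resolve to non-lesion: the initialization is
deliberately conservative because the MRF stage refines it. Modelling
the pooled non-lesion class (CSF + GM + WM) with a single Gaussian is a
known simplification — its covariance is broad, which costs specificity
against bright untextured tissue (see Limitations).

## The Markov random field

Each brain voxel i carries a label C_i ∈ {CSF, GM, WM, Les}. The
conditional energy minimized per voxel is

    U(C_i | I) = −log P(I_i | C_i) − log P(T_i | C_i) − log P(C_i)
                 − Σ_{j∈N_i} log P(ΔI_ij | C_i, C_j)
                 + α · Σ_{cliques k ∋ i} m(C_k)

with:

* `P(I_i|C_i)` — per-class 1-D intensity Gaussian;
* `P(T_i|C_i)` — per-class multivariate texture Gaussian over the Gabor
  features (covariance ridge: max(ridge, 1e-6 · mean diagonal));
* `P(C_i)` — registered tissue priors. The atlas has no lesion channel,
  so a constant lesion prior π_les (default 0.05) is mixed in and the
  tissue priors rescaled by 1 − π_les; probabilities are floored at
  1e-12 before logs;
* `P(ΔI_ij|C_i,C_j)` — a Gaussian on the center-minus-neighbor intensity
  difference per ordered class pair. The neighborhood difference vector
  is a single factor of the observation model, so each in-brain
  neighbor pair contributes exactly once (replicating it per clique
  would weight the pairwise term ~5-fold and let it overwhelm the unary
  evidence — in practice the lesion class then grows across flat white
  matter until the next intensity edge). Fitting pools both directions
  of every neighbor relation, making the means exactly antisymmetric
  and the variances symmetric in the class pair;
* `m(C_k)` — the negative log Laplace-smoothed training frequency of the
  clique's label multiset (center included). Defining the potential on
  the joint multiset makes it identical from every member's viewpoint;
  a center-conditioned variant is role-asymmetric and breaks the
  descent property below. The same tables realize the label-transition
  term of the factored posterior;
* `α` — the in-plane / through-plane distance ratio (dx/dz, e.g. 0.14
  at 0.7 × 0.7 × 5 mm), down-weighting the spatial term on coarse
  slices. In-plane spacing must be isotropic within 5%.

**Neighborhood and cliques.** Default: the 8 in-plane neighbors plus
the same-(x, y) voxels in the slices above and below. Cliques are all
mutually adjacent subsets of sizes 2–4 containing the voxel; adjacency
means sharing an edge or a vertex. Under the minimal reading the
through-plane neighbors touch only the center, so the default clique
census per interior voxel is 10 pairs, 12 triples and 4 quadruples
(2 × 2 in-plane squares); a full 26-neighborhood is available
(`through_plane="full"`). Cliques extending outside the brain mask or
the volume are dropped, not padded.

**Training.** All Gaussians are sample statistics over in-mask voxels
of the quaternary ground truth; class pairs that never co-occur fall
back to the pooled difference variance (an error if the ridge is zero).
Clique configuration tables count each physical clique once (via the
lexicographically-minimal-center convention) with add-one smoothing
over the multisets.

**Inference.** Asynchronous iterated conditional modes: brain voxels
are visited in a fresh seeded random permutation each sweep (randomized
order avoids raster artifacts and is reproducible) and set to the label
minimizing the conditional energy given the current neighbors, keeping
the current label on exact ties. The tracked total energy sums unary
terms per voxel and counts each neighbor pair and each clique potential
once; the conditional above is exactly the part of that total depending
on C_i, so every accepted update strictly decreases it — the energy
trace is non-increasing by construction, and termination is guaranteed.
The iteration cap is 10 sweeps; convergence (a sweep with no change) is
typically reached in 5–7 on the synthetic cohort. The final lesion mask
is the Les class with no morphological post-processing.

Initialization maps the two-class output onto four classes: lesion
voxels become Les; other brain voxels take the argmax of the tissue
priors (ties break CSF < GM < WM); voxels outside the brain carry a
background sentinel (−1) excluded from inference.

## Evaluation metrics

Dice 2|A∩M|/(|A|+|M|), PPV |A∩M|/|A|, sensitivity |A∩M|/|M|
(Dice(∅,∅) = 1; PPV/sensitivity reported missing for empty masks).
Surface distances use border voxels (mask voxels with a non-mask face
neighbor), distances in mm under the anisotropic spacing; ASD is the
symmetric mean of the two directed mean border distances and HD the
full (100th percentile) Hausdorff, the conventions of the public stroke
segmentation challenges. Volumes are voxel counts × voxel volume in mL;
volume agreement uses Spearman rank correlation (average ranks on
ties). Small-lesion counting: connected components under
26-connectivity; a manual component under 1 mL is a true positive if at
least three of its voxels are auto-segmented, and an automatic
component under 1 mL is a false positive if it covers fewer than three
manually segmented voxels ("in that area" is read as: within the
automatic component's voxel set).

## The synthetic cohort

The phantom generator provides the study conditions for all end-to-end
tests; it is schematic, not a physics simulation. One case is an
ellipsoidal brain (CSF rim, central CSF "ventricle", GM shell, WM
interior) on a 48 × 48 × 16 grid at (2, 2, 6) mm spacing — a scaled-down
brain of ≈ 310 mL that keeps clinical in-plane/through-plane anisotropy
while letting a full leave-one-out experiment run in about a minute.
Class means on the standardized scale are (0.12, 0.42, 0.55, 0.85) for
(CSF, GM, WM, Les) with per-class SD 0.03 — the FLAIR-like ordering with
CSF suppressed and the lesion hyperintense. Each case carries one
irregular WM lesion with a 15 mL target volume (jittered by ×0.6–1.4
across a cohort; the volume is hit within 10% by thresholding a
perturbed radial field at the target voxel count), textured by an
oriented sinusoidal grating (45°, |f| = √2/8 cy/voxel, contrast 0.10) so
the Gabor features are discriminative by construction. Three
white-matter-hyperintensity confounders (0.35 mL each) share the lesion
peak intensity but carry no oriented texture: they have smooth 2.5 mm
shoulders, because a hard-edged small blob is spectrally broadband and
would itself light up the oriented channels. Confounders are labelled
WM in the truth. A multiplicative bias field (log-amplitude 0.10, 40 mm
scale) and additive noise (SD 0.02) complete the image, clipped to
[0, 1]. Tissue priors come from the smoothed (6 mm), lesion-free truth,
so the lesion region has WM-dominant priors — an atlas that knows
nothing of the lesion.

What the phantom does **not** emulate: real anatomy and partial-volume
mixing at tissue boundaries, multi-center intensity variation beyond an
affine change, spatially varying noise, and lesions whose texture is
not a single coherent grating. Passing the end-to-end tests shows the
pipeline recovers lesions whose texture matches its feature model under
controlled conditions; it does not certify performance on clinical
data.

## Numerical choices

Probability floor 1e-12 before every log; covariance ridges as above;
Cholesky factorization for all multivariate Gaussian evaluations;
log-domain posteriors with log-sum-exp normalization; ICM ties keep the
current label; prior argmax ties break by fixed class order; convolution
via FFT (verified against direct summation at 1e-8); reflection padding
at slice borders. All randomness (ICM visit order, pair subsampling,
phantom synthesis) flows from explicit integer seeds.

## Known limitations

* Bright but untextured structures whose intensity matches the lesion
  class (confluent WM hyperintensity cores) can survive into the final
  mask: the pooled single-Gaussian non-lesion model of the initializer
  seeds them, and single-site ICM cannot dissolve a compact seeded blob
  because the learned lesion-boundary intensity-step statistics
  penalize placing a Les/WM interface where no step exists. On
  confounder-only phantoms this leaves roughly 0.2–0.3% of brain voxels
  falsely labelled (the confounder load itself is 0.34%) — the shoulders
  are rejected, the cores are not.
* The window-spread grid optimization is exact only on its grid, and its raw
  objective is scale-biased when classes differ in mean intensity.
* The fallback bias estimator removes smooth multiplicative fields only;
  it is not a replacement for a dedicated non-uniformity correction.
* 2-D features ignore through-plane texture by design (coarse slices);
  volumes with near-isotropic high resolution would leave information
  unused.
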