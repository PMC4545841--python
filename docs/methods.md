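# Methods

## Model

Each voxel of a dual-echo UTE acquisition provides a pair of magnitude
intensities (I_TE1, I_TE2), in arbitrary units, sampled at echo times
TE1 = 30 μs and TE2 = 1.7 ms. Tissue classes occupy overlapping
clusters in this 2D space: soft tissue near a dominant peak (canonically
placed at (4,000, 4,000)), bone at lower intensity with a strongly
reduced second echo (fast T2* decay), air at background-noise level.

The classifier is the empirical posterior P(class | echo pair): with a
co-registered CT volume, voxels are labeled air / soft / bone by HU
thresholding, echo pairs are discretized on a fixed lattice, and the
per-bin class counts are normalized by the per-bin total. Per-patient
maps are averaged (unweighted) over the training cohort, and a priori
rules prune physically implausible assignments. At inference a voxel is
assigned the argmax class of its bin; the evaluated bone mask is
P(bone) > 0.5.

### Processing order

1. **Background estimation** (per case, per echo, on raw intensities):
   seed on voxels with echo1 < 1,000 a.u.; re-estimate the mean/sd on
   the interval (0, μ + 3σ) of each echo to center on the background
   peak. If the refinement interval is empty (exactly constant
   background) the seed statistics are kept. μ + 3σ is the air/tissue
   reference level. The refinement interval is applied per echo (the
   alternative — using echo1's interval for both — is ambiguous in the
   method's description; per-echo is the symmetric choice).
2. **Prescaling**: the joint histogram of voxels above the reference
   level is smoothed (Gaussian, σ = 1.5 bins of 50 a.u.) and its argmax
   is the soft-tissue peak; each echo is multiplied by 4,000/peak_k.
   Smoothing is an estimator choice: raw bin counts carry Poisson noise
   that lets the argmax wander across the flat top of the soft cluster;
   the smoothed argmax re-detects within one bin after prescaling.
   Ties break to the lexicographically smallest bin center.
3. **CT labels**: HU ≤ −400 → air, HU ≥ +100 → bone, else soft tissue.
   +100 HU matches the usual non-contrast soft-tissue ceiling; both
   cutpoints are configuration, and no shipped result depends on their
   precise values. CT is resampled to the MR grid (trilinear) when the
   grids differ; labels, when resampled, always use nearest-neighbor.
4. **Histograms and posteriors**: echo pairs are binned on a 240×240
   lattice of 50 a.u. bins over [0, 12,000]² (half-open bins, edge bins
   absorb out-of-range values). 50 a.u. is far below any cluster width,
   so the discretization does not limit the classifier. The posterior
   divides class counts by max(total, 10): bins backed by fewer than 10
   voxels are damped rather than trusted, and a reliability mask marks
   them so callers can exclude them outright. On reliable bins the
   three probabilities sum to 1 (±1e-9); on clipped bins to less.
5. **Averaging and constraints**: per-patient maps are averaged
   unweighted; a bin of the average is reliable if reliable in at least
   half the inputs. The a priori rules are imposed once, on the final
   averaged map, at bin centers: echo1+echo2 > 4,000 → never air;
   echo2 > echo1, echo1 > 8,000, echo2 > 5,000 or echo1−echo2 > 4,000 →
   never bone. Probability mass removed by a rule moves to soft tissue
   (the fallback class for uncertain regions), so per-bin mass is
   conserved. The rules compare post-prescaling (canonical-space)
   intensities. Applying constraints twice is an error.
6. **Classification**: bin lookup + argmax; exact ties and unreliable
   bins resolve to soft tissue. The constraint rules are re-checked on
   each voxel's own intensities, because a voxel near a rule boundary
   can fall in a bin whose center lies on the other side; this
   guarantees that no classified voxel violates a rule.

### Baselines

R₂ = ln(I_TE1/I_TE2)/(TE2−TE1), in ms⁻¹ so that the operating point
0.35 ms⁻¹ equals the 350 s⁻¹ member of the straight-cut family
e₂ = e₁·exp(−t·ΔTE). N = (I_TE1−I_TE2)/I_TE2², operating point 5×10⁻⁴
(the pair (4,000, 2,000) lies exactly on this boundary). "Higher than"
is strict; voxels with a non-positive echo carry a NaN sentinel and are
never bone. Neither baseline defines an air/soft split, and only bone
masks are scored; air is assigned where echo1 falls below the
background reference level, and this assignment overrides a bone vote —
at the noise floor the echo ratio is random, and without the override
the background floods the bone mask. The ndiff boundary solves
t·e₂² + e₂ − e₁ = 0 via the cancellation-free root
2e₁/(1 + √(1+4te₁)), accurate to ~1e-15 even at t = 10⁻⁶.

### Evaluation

Jaccard distance in percent, 100·(1 − |A∩B|/|A∪B|); two empty masks
are 0% by convention. Cohort summaries report mean, median, sd (n−1),
min and max per method — central tendencies are always reported as both
mean and median — and two-tailed Welch t-tests (unequal variances,
Welch–Satterthwaite degrees of freedom) of the posterior method against
each baseline. Agreement maps use the four states TN/TP/FP/FN with the
conventional coloring (green TP, red FP, blue FN, black TN).

## The phantom generator

The generator stands in for a tri-modality patient cohort. Geometry is
a deterministic nested-ellipsoid head: outer soft ellipsoid (semi-axes
55×50×55 mm, "scalp" margin 6 mm), a skull shell of 7 mm (an
anatomically typical adult calvarial thickness), an inner soft "brain",
and a 10 mm air cavity ("sinus"). The default grid is 64³ voxels at
2 mm — large enough that the skull is several voxels thick and each
class contributes tens of thousands of training voxels, small enough
that a 10-case cohort runs in seconds.

Intensities (defaults; units a.u. for MR, HU for CT, ms⁻¹ for R2):

| class | CT (HU)      | echo model                                        |
|-------|--------------|---------------------------------------------------|
| air   | −1000 ± 30   | 2D Gaussian at (60, 60), sd 30                    |
| soft  | +30 ± 40     | mixture at (4,000, 4,000): 45% sharp core (sd 250) + 55% broad tail (sd 900, ρ = 0.6) |
| bone  | +1200 ± 150  | echo1 ~ N(2,200, 700²); echo2 = echo1·e^(−R2·ΔTE), R2 ~ N(0.55, 0.18²) |

plus additive acquisition noise of sd 120 a.u. per echo (Gaussian by
default; a Rician option exists since magnitude images are
non-negative) and clamping at 0. CT anchors follow the standard HU
references (air −1,000, water 0, brain +20..+45, cortical bone
+700..+3,000). Bone echoes are generated mechanistically through T2*
decay — not as a free 2D Gaussian — so the R2 baseline's physical
assumption is true of the data and its behavior interpretable; the R2
spread places the 0.35 ms⁻¹ threshold inside the lower bone tail, as an
empirically tuned threshold would sit. The soft cluster is a
core-plus-tail mixture because a single broad Gaussian yields a
histogram maximum no sharper than the bone cluster's, while the method
requires a distinct dominant soft-tissue peak for prescaling; the
correlated broad tail supplies the soft/bone overlap that makes the
classification problem non-trivial. No quantitative cluster covariances
are published for clinical data; these values are a qualitative
calibration and must not be read as measured.

`generate_cohort` draws per-case rendering seeds from one master seed
and applies a per-case, per-echo global gain exp(N(0, 0.1)) — the
inter-patient receive-gain variation that gives prescaling and
cross-patient averaging real work to do.

**What the phantoms do not model**: anatomy beyond nested ellipsoids,
partial-volume mixing at interfaces, motion, metal and dental
artifacts, bias fields, coil structures in the background, and
misregistration between CT and MR. Consequently the absolute Jaccard
distances on phantoms (≈14–24%) are far better than clinical values,
and passing tests demonstrate correctness of the machinery and the
qualitative ranking of methods — not clinical performance.

## Numerical choices

* Binning: half-open [low, high) bins, final bin closed, out-of-range
  clamps to edge bins; identical 50 a.u./[0, 12,000] lattice for peak
  detection and posterior maps.
* Boundary HU values label to the denser class (≤ air cutpoint → air,
  ≥ bone cutpoint → bone).
* Ties in the posterior argmax, and unreliable bins, go to soft tissue.
* Resampling fills out-of-field voxels with −1,000 HU (CT) or 0 (MR);
  nearest-neighbor for categorical volumes, trilinear for intensities.
* All randomness flows through `numpy.random.Generator` seeded from the
  spec/cohort seed; identical configuration is bitwise reproducible.
* Degenerate inputs: empty background seed set, background-only
  volumes, non-positive peaks, mismatched grids or binnings, and
  double-applied constraints raise typed exceptions
  (`utebone.errors`), never silent fallbacks.

## Problem sizes used by the shipped checks

The test suite and the reproduction script use 64³-voxel phantoms,
cohorts of 10 cases (6 for the Bayes-agreement check, which compares
the trained map with an analytic Bayes rule integrated numerically over
the generating mixtures on the reliable, unconstrained part of the bin
lattice), and 24³–48³ grids for geometry unit tests. These sizes give
every class ≥10⁴ training voxels per case and leave the whole pipeline
fast enough to iterate on a laptop.

## Known limitations

* The posterior map is a raw lookup table: no smoothing or parametric
  (e.g. ellipsoidal-cluster) modeling of the maps, and no morphological
  post-processing of the segmentations.
* Inputs are assumed co-registered; there is no registration step.
* The HU thresholds ignore contrast agent, and bone is a binary class —
  no continuous bone-density estimation.
* Baselines need an air/soft split that their original formulations do
  not define; the background-reference rule used here only matters for
  unscored classes.
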