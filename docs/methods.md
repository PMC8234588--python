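# Methods

## The measurement problem

After an intracerebral hemorrhage (ICH), white matter (WM) is destroyed
within the hematoma and disrupted in the surrounding (perilesional) tissue.
`ichwm` quantifies both from diffusion tensor MRI using a deliberately
simple index: the volume of tissue whose fractional anisotropy (FA)
strictly exceeds 0.5. FA varies strongly with location in the brain, so raw
FA averages are biased by where a lesion happens to sit; the package
instead compares three compartments inside a constant-radius analysis
sphere centered on the lesion against a mirror-image sphere in the
unaffected hemisphere, which serves as each subject's internal control.

## Core quantities

For an FA map and a sphere of radius *R* (20–25 mm band by default, held
constant across a subject's timepoints):

* **lesion** — the segmented hematoma; FA>0.5 volume measured directly;
* **ipsilateral sphere** — measured directly;
* **perilesion** — ipsilateral sphere minus lesion; its FA>0.5 volume is
  the difference of the two direct measurements (floored at zero with a
  logged warning if a noisy lesion mask makes it negative);
* **contralateral sphere** — the midsagittal reflection of the ipsilateral
  sphere, measured directly.

The perilesional deficit compares the measurement with the volume expected
if the perilesional zone matched the contralateral WM fraction:

    deficit = (ipsi FA>0.5 − lesion FA>0.5)
              − perilesion volume × (contra FA>0.5 / contra sphere volume)   [mL]

This raw expression is negative when WM is missing. The package reports
both it (`deficit_printed_ml`) and its negation (`loss_ml`, positive =
tissue lost); the sign convention is stated explicitly because the raw
expression reads as measured-minus-expected while the quantity is discussed
as a loss.

NaN voxels (ill-defined tensor fits) never count toward an FA>0.5 volume.
By default they remain in the geometric denominators, so percentages are
fractions of compartment volume; `nan_in_denominator=False` switches to
fractions of well-fitted volume.

## Tensor estimation

Single-shell DTI: one b=0 volume plus 32 directions at b = 800 s/mm²
(electrostatically spread half-sphere table; design-matrix condition number
≈ 1.6). Per voxel, the tensor solves ``log(S/S0) = −b gᵀDg`` by ordinary
(unweighted) log-linear least squares — the simplest defensible estimator;
weighted and nonlinear fits change nothing qualitative at the SNR
simulated here. Multiple b=0 volumes are averaged into S0. Voxels with
non-positive S0 or weighted signal are flagged invalid and carry NaN in
every derived map. Negative eigenvalues (noise floor) are clamped to zero
with a logged count before FA/Westin/MD computation, keeping FA in [0, 1]
without discarding voxels.

FA is `sqrt(3/2)·sqrt(Σ(λᵢ−λ̄)²)/sqrt(Σλᵢ²)`; Westin measures use the
trace-normalised convention cl = (λ1−λ2)/T, cp = 2(λ2−λ3)/T, cs = 3λ3/T,
so cl+cp+cs = 1.

## ROI construction

Coordinates are world millimetres with voxel centers at index × spacing,
0-based, identity orientation only (rotated affines are refused at load).
The first voxel axis is left–right; the midsagittal plane is the geometric
center plane of that axis. The lesion is segmented from the b=0 image as
the largest 26-connected component darker than half the robust background
median (subacute blood is hypointense on T2-weighted EPI), subject to a
minimum size (0.3 mL), then morphologically closed. The ipsilateral sphere
is centered on the lesion centroid, its radius escalated within the
configured band until every lesion voxel center is enclosed; a sphere that
would cross the midline is an error, with tangency allowed ("not crossing"
read literally). Voxelisation uses the voxel-center-in-sphere rule, making
every volume bit-reproducible. The contralateral sphere is the exact
reflection (x → 2·x_mid − x), radius unchanged.

## Synthetic cohort

No patient images are distributed with the study this design follows, so
the package ships a ground-truthed generator that every downstream stage is
validated against.

**Geometry.** Each phantom is a 96×96×44 grid at 1×1×2.3 mm (a miniature
56×56×26 "small" layout, geometrically similar with 11 mm spheres, serves
the many-replicate tests). White matter is a mirror-symmetric square
lattice of cranio-caudal tubes (radius 2.4 mm, spacing 10.3 mm in the
standard layout) at packing fraction πr²/s² = 0.17, so any analysis sphere
holds ≈ 17% WM by volume. A distributed lattice, rather than one central
tract, makes destroyed/disrupted WM scale with the *volume* of the lesion
and shell — with a single tube the deficit saturates as soon as the
hematoma swallows the tract, and the deficit-versus-volume regression the
statistics layer tests for would have no slope to find.

**Tissue model.** Bundle tensors are cigar-shaped with eigenvalues
(1.7, 0.3, 0.3)×10⁻³ mm²/s (FA 0.80) aligned with the tube axis;
background is isotropic 0.8×10⁻³ mm²/s. The hematoma core is an axially
symmetric tensor solved in closed form to hit a target FA of 0.15 (the
0.1–0.2 band reported for clotting blood in vitro) at mean diffusivity
0.8×10⁻³; its b=0 signal is 40% of background, which is what the
segmentation exploits. In the perilesional shell, bundle tensors are
interpolated toward their isotropic part, ``D′ = f·D + (1−f)·(trace/3)·I``
with attenuation factor f (1 = intact, 0 = isotropic); FA is strictly
monotone in f, and f ≈ 0.55 is where bundle FA crosses the 0.5 cut.

**Acquisition.** ``S = S0·exp(−b gᵀDg)`` with Rician noise — the magnitude
of (S+N(0,σ), N(0,σ)) — at default σ = S0/20 (SNR₀ 20). Noise and cohort
draws derive from `numpy` SeedSequence spawns of a single design seed, so a
cohort is byte-reproducible.

**Longitudinal model.** Per subject: baseline hematoma volume drawn
log-uniform (stratified, then shuffled) across the design range 0.3–39 mL —
hematoma volumes in real cohorts are right-skewed; a disruption shell of
thickness 0.4× the baseline radius (min 2 mm) with attenuation 0.35 at
day 3; exponential recovery of the attenuation toward 1 at a per-subject
lognormal rate (median 0.04/day, log-SD 0.6 — the heterogeneity dial); and
exponential hematoma radius decay (median 0.015/day, log-SD 0.5), so small
bleeds largely resolve by day 30. The default 13-subject design applies a
missing-timepoint pattern with 11/10/9 scans at days 3/14/30 and 7 complete
subjects. Table-level simulators (`simulate_loss_table`,
`simulate_location_table`) generate measurement tables directly from the
additive models the statistics assume, for calibration experiments needing
hundreds of replicate cohorts.

**What the phantom does not model:** partial-volume averaging, CSF, EPI
distortion, motion, eddy currents, gyral anatomy, crossing fibers, or any
T1/T2 contrast beyond the single b=0 hypointensity. Passing tests therefore
demonstrate correctness of the measurement chain and calibration of the
statistics under the stated generative model — not robustness to scanner
physics.

## Statistics

Summaries are mean ± SD (n−1; SD undefined, not zero, for singleton
cells). Paired t-tests are complete-case, two-tailed. Loss-versus-volume
uses OLS with a two-tailed slope test; slope homogeneity across days is the
ANCOVA F-test of the group×covariate interaction (full vs common-slope
model). The mixed model is ``fa_gt_pct ~ location (+ day (+ location:day))``
with day categorical, a random intercept per subject (variance-components
covariance), REML estimation, and C(4,2) = 6 Bonferroni-adjusted pairwise
location contrasts (per-comparison threshold 0.05/6 = 0.0083). Fixed-effect
tests are Wald F with containment denominator df (nobs − k_fe −
(subjects − 1)); the asymptotic chi-square alternative is anti-conservative
at a dozen subjects, and the containment version measures a 5.5% location
type-I error over 400 null cohorts. Fits whose random-intercept variance
collapses are flagged singular rather than silently accepted.

## Numerical and scale choices

* Tensor fits use one pseudo-inverse shared across voxels (exact for the
  common design); noiseless round trips recover tensors to ~1e-15.
* Eigenvalue-only paths use `eigvalsh`; the eigenvector-bearing
  `eigen_spectrum` is reserved for principal-direction queries.
* Heavy tests run on the small layout (≈ 0.4 s per subject-timepoint);
  standard-layout subjects cost ≈ 2.5 s, and the full 13-subject,
  30-record default pipeline ≈ 3 minutes. Replicate counts in the
  calibration tests (100 regression cohorts, 400 null mixed-model cohorts)
  use the table-level simulators.
* The default pipeline holds sphere center and radius fixed from each
  subject's first acquired timepoint; a hematoma that resolved below the
  segmentation floor anchors the sphere at the known lesion site instead.
* Whether late-timepoint lesion voxels rejoin the perilesion follows the
  lesion mask policy: `per_day` (default — the shrinking segmented mask is
  used as-is, so resolved voxels are perilesional) or `baseline` (the
  first-day mask is frozen).

## Known limitations

The contralateral hemisphere is exactly symmetric, so between-subject
variance of the control sphere is unrealistically small; percent deficits
against contralateral are correspondingly cleaner than in patients. The
deficit saturates when lesion + shell approach the sphere volume (large
bleeds), which flattens the loss-volume relation at the top of the range —
visible in real data too, where the analysis sphere barely exceeds the
largest hematomas. Lesional FA>0.5 volumes in noisy simulations arise from
Rician FA inflation at low SNR inside the clot, standing in for — but not
mechanistically modelling — surviving intralesional fibers.
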