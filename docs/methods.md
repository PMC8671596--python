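# Methods

## Problem and model

Amyloid-PET burden is quantified as a standardized uptake value ratio
(SUVR): mean tracer uptake in a global cortical target region (CTX)
divided by mean uptake in a whole-cerebellum reference region (WhlCbl),
both defined as masks in a standard template space. For
^18F-flutemetamol with this reference the SUVR is mapped to the
Centiloid scale by the direct conversion

    CL = 121.42 · SUVR − 121.16,

an affine map anchored at CL 0 (young amyloid-negative controls) and
CL 100 (typical Alzheimer's disease). Because the masks live in template
space, the decisive step is *anatomic standardization*: warping the
subject's PET into the template frame. `centipet` implements four
interchangeable routes and the statistics used to compare them:

* **MRI route** — affine registration of a T1 MRI to the template,
  rigid PET-to-MRI coregistration, tissue-prior segmentation of the MRI,
  demons estimation of the residual nonlinear warp, single-interpolation
  normalization of the PET.
* **CT route** — the same pipeline driven by the low-dose CT acquired
  with the PET on a hybrid scanner.
* **mPET route** — PET-only normalization against a mean PET atlas.
* **aPET route** — PET-only normalization with an adaptive atlas:
  normalize against the amyloid-negative template, compute a provisional
  CL, and re-normalize against the positive template when the
  provisional CL reaches the positivity cutoff of CL 16 (a provisional
  CL exactly at the cutoff selects the positive template; starting from
  the negative template avoids biasing low-burden subjects toward the
  positive atlas).

All spatial mappings are pull-backs (template/fixed frame to
subject/moving frame), the world frame is RAS millimetres, and chains of
mappings are composed before a single trilinear interpolation so the
four routes differ only in how the mapping was estimated, not in how
much blur resampling added.

## Registration

Rigid and 12-parameter affine registration maximize normalized mutual
information (32×32 joint histogram, Parzen linear binning, samples from
a bounding box around the fixed-image head) for cross-modality pairs, or
normalized cross-correlation within modality. Optimization is a
deterministic Powell search over a 3-level pyramid (factors 4/2/1) with
fixed iteration caps, initialized by centre-of-mass alignment; the
reported metric at the solution is never worse than at the identity.
Parameters are expressed in comparable units (degrees, mm, percent
scale/shear) so the unscaled Powell directions are well conditioned.

## Segmentation and nonlinear warp

Tissue classification is a Gaussian-mixture EM with spatial priors:
posterior ∝ prior × class likelihood, with class means/variances
re-estimated each iteration and convergence declared when the relative
log-likelihood change falls below 1e-5 (cap 50 iterations). For MRI a
degree-2 polynomial multiplicative bias field is re-fitted each
iteration by weighted least squares. For CT, the image is first
denoised (4-mm FWHM) and windowed (shifted-HU 900–1200 → [0, 1], bone
and air saturated); GM and WM share one intensity class whose posterior
is split by the prior ratio, and class means are anchored on
high-confidence prior cores (prior > 0.9) and held fixed — the
partial-volumed CSF rim would otherwise drag the CSF mean across the
~25 HU CSF/parenchyma contrast and invert it. With flat priors
(uninformative), initial means fall back to intensity quantiles.

The residual nonlinear warp is a multi-resolution (factors 2/1) demons
match between the template GM+WM prior and the subject GM+WM posterior,
which is first smoothed to the intrinsic smoothness of the priors so
the force vanishes for a subject identical to the template. The update
and accumulated field are smoothed with Gaussian kernels of σ = 2 mm
("fluid") and σ = 3 mm ("elastic") per iteration — σ, not FWHM: at the
default 3-mm grid an FWHM reading would give sub-voxel kernels and the
field folds under realistic noise. Steps are capped at 2 mm and the
Jacobian determinant of the final field must stay positive on the brain
mask (GM+WM prior > 0.1), otherwise a `WarpError` advises stronger
regularization. PET-only normalization uses the same demons on
intensity-scaled, additionally smoothed (4-mm) PET images with doubled
elastic width, because a subject whose binding pattern disagrees with
the atlas produces conflicting boundary forces.

## Digital head phantom

The synthetic-data generator emulates the study conditions. The
template (64×76×64 voxels at 3 mm) is a nested-ellipsoid head: skull
shell, subarachnoid CSF, an ~18-mm supratentorial cortical GM ribbon
around a WM body with ventricular CSF, and a separate cerebellar
compartment with its own GM shell/WM core separated from the cerebrum
by a CSF gap. Tissue priors are the blurred (4-mm FWHM) hard masks
renormalized to sum to 1. The CTX VOI is the supratentorial cortical
ribbon kept ≥ 12 mm from the cerebellum and eroded (3× 6-connected);
WhlCbl is the cerebellar compartment eroded (2× 26-connected); the
margins keep PSF contamination of the VOI means below 0.2 CL at CL 140.

Per subject, a smooth random deformation (white noise smoothed to a
12-mm correlation length, scaled to a chosen peak amplitude, redrawn if
the Jacobian is not everywhere positive) and a rigid offset (defaults:
±4 mm, ±3°) displace the anatomy; the PET additionally carries a small
extra offset (≤ ±2 mm/±1°) that the rigid coregistration stage must
recover. Renderings: T1-like MRI (GM 90, WM 130, CSF 35, skull 20,
air 5), low-dose CT in shifted Hounsfield units (HU + 1024: air 24,
CSF 1034, WM 1056, GM 1062, skull 2024 — GM/WM nearly iso-intense by
design, and the shift makes the universal 0-fill on resampling
innocuous), and PET whose cerebellar compartment is fixed at 1.0 and
whose cortical GM equals `centiloid_to_suvr(target_cl)`, with cerebral
WM at 1.45 for amyloid-negative and 1.15 for amyloid-positive binding
patterns and 0.05 background. The PET is blurred with a 6-mm FWHM PSF
before noise; default noise SDs are MRI 4, CT 10 (HU), PET 0.05 —
values chosen to be realistic for 3D T1 imaging, 40-mAs low-dose CT and
a 20-min flutemetamol acquisition. The CT additionally carries a
deterministic per-subject low-frequency posterior-fossa artifact
(15 HU), emulating petrous-bone beam hardening; this is the mechanism
that makes CT-guided normalization measurably weaker in the posterior
fossa, as it is in practice.

What the phantom does *not* model: attenuation/scatter physics, motion,
partial-volume effects beyond the Gaussian PSF, cortical folding,
atrophy, or left-right asymmetric binding. Passing recovery tests on
these phantoms therefore demonstrates internal consistency of the
pipeline under known geometry and noise, not clinical accuracy on real
heads.

## Statistics

Agreement between routes is reported as Bland-Altman summaries of
differences (test − reference, so a negative bias means the test route
underestimates): bias, SD of differences (N−1), conventional 95% limits
of agreement (bias ± 1.96 SD) *and* the 95% CI of the mean difference
(bias ± t·SD/√n) — both carried explicitly because published
method-comparison tables sometimes print the CI under the LoA name (for
bias −1.7, SD 2.4, n 24, the CI is −2.7..−0.7 while the ±1.96 SD limits
are −6.4..+3.0). Pearson/Spearman correlations and the paired t-test
are computed from their defining formulas (p-values from scipy's t
distribution); scipy's own implementations serve as independent oracles
in the test suite. Spearman load-dependence correlates the differences
with the pairwise means by default (reference-only axis available).
Two-tailed tests throughout, no multiple-testing correction.

A related algebraic fact the implementation documents: applying the CL
conversion to both axes of a SUVR-space regression leaves slope and
Pearson r unchanged and maps the intercept affinely; published
SUVR-space and CL-space fits of the same data are therefore consistent
only up to rounding of the printed coefficients (1.027·x − 0.020 in
SUVR space implies intercept 0.843 in CL space, whichever CL-space
intercept the source table prints).

Voxel-wise comparison smooths each normalized PET with an 8-mm FWHM
Gaussian, computes a paired t per voxel inside the GM+WM > 0.1 mask,
thresholds one-sided at uncorrected p < 0.001 (two directions, df =
n−1), labels 26-connected components and discards clusters below 300
voxels; peaks are reported in world mm.

## Atlases and cohort bookkeeping

PET-only atlases are voxel-wise means of template-frame PET volumes
(addends sorted per voxel so the result is bitwise
permutation-invariant), with a cohort record (n, mean CL, SD CL with
N−1) from the member tags. Synthetic atlas cohorts are drawn around
CL 92 ± 21.6 (positive) and CL −1 ± 3.5 (negative), matching the
adaptive-atlas design sizes; the mean atlas pools both. Pooled cohort
means are size-weighted (Σnᵢmᵢ/Σnᵢ); the pooled SD uses the N−1
mixture formula and is informational only, since reconstructing it from
rounded subgroup summaries does not recover a printed pooled SD exactly.

## Problem sizes and numerical choices

The default recovery experiment uses 10 subjects on the 64×76×64 @ 3 mm
grid with ground-truth CL in {−10, 0, 15, 16, 30, 50, 75, 100, 120,
140}, 4-mm peak deformations and default noise — large enough to span
the clinically relevant CL range around the cutoff while keeping a full
two-route cohort run in the tens of minutes on one CPU. Registration
iteration caps (Powell maxfev 600/400/200 per pyramid level), demons
iterations (40/15) and EM caps (50) were fixed once for this grid
scale. Degenerate inputs fail loudly: constant images refuse to
register, empty or non-positive reference VOIs refuse to quantify,
zero-variance difference vectors set explicit degenerate flags rather
than NaNs.

## Known limitations

* The segmentation-normalization is sequential (affine, then EM, then
  demons), not a joint generative optimization; it reproduces the data
  flow and failure modes of unified segmentation, not its estimator.
* VOI masks are binary with unweighted means.
* The CT conditioning window (900–1200 shifted HU) is a fixed choice;
  scanner-specific calibration is out of scope.
* Only the single flutemetamol whole-cerebellum conversion equation is
  provided; other tracers/references need their own anchor constants.
* Phantom realism limits are listed above; in particular the
  posterior-fossa CT artifact is a stylized stand-in for beam
  hardening, not a CT physics simulation.
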