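"""Digital head phantoms with known ground-truth Centiloid.

The template is a smooth geometric head built from nested ellipsoids: a
skull shell, a subarachnoid CSF layer, a supratentorial cortical GM ribbon
around a central WM body with ventricular CSF, and a separate
posterior-fossa cerebellar compartment with its own GM/WM microstructure.
Per-subject data are produced by warping this anatomy with a smooth random
deformation plus a rigid offset and rendering three modalities:

* a T1-like MRI (strong GM/WM contrast),
* a low-dose-CT-like image in *shifted* Hounsfield units (HU + 1024, so
  air is a small positive number and out-of-field zero-fill is innocuous),
  with near-iso-intense GM/WM by design,
* an amyloid-PET image whose cortical-to-cerebellar uptake ratio encodes a
  chosen ground-truth Centiloid through the direct conversion equation,
  blurred with a 6-mm FWHM PSF to emulate scanner resolution.

Amyloid-negative subjects have relatively high white-matter uptake
(WM 1.45 vs cortex near 1.0) and positive subjects low WM relative to
cortex (WM 1.15), reproducing the binding patterns that make PET-only
normalization template choice matter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage

from .errors import DomainError, GeometryError
from .image_core import (
    DeformationField,
    RigidTransform,
    Volume,
    fwhm_to_sigma,
    gaussian_smooth,
)
from .quantification import VOISet, centiloid_to_suvr

TISSUES = ("GM", "WM", "CSF", "skull", "air")

#: mean tissue intensities for the T1-like rendering
MRI_INTENSITY = {"GM": 90.0, "WM": 130.0, "CSF": 35.0, "skull": 20.0, "air": 5.0}
#: shifted Hounsfield units (HU + 1024); GM/WM nearly iso-intense
CT_INTENSITY = {"GM": 1062.0, "WM": 1056.0, "CSF": 1034.0, "skull": 2024.0, "air": 24.0}
#: PET uptake by compartment; cortical GM is set per subject from target CL
PET_BACKGROUND = 0.05
PET_WM_NEGATIVE = 1.45
PET_WM_POSITIVE = 1.15
PET_PSF_FWHM_MM = 6.0
#: amplitude (HU) of the posterior-fossa beam-hardening-like CT artifact
CT_FOSSA_ARTIFACT_HU = 15.0

#: default per-modality Gaussian noise SD (image units)
DEFAULT_NOISE_SD = {"mri": 4.0, "ct": 10.0, "pet": 0.05}

DEFAULT_GRID = ((64, 76, 64), 3.0)

# head-model geometry, world mm, RAS, centred at the origin
_OUTER_SKULL = (70.0, 88.0, 75.0)
_INNER_SKULL = (62.0, 80.0, 67.0)
_BRAIN_SURFACE = (58.0, 76.0, 63.0)
_RIBBON_INNER = (40.0, 56.0, 44.0)
_VENTRICLE_C, _VENTRICLE_A = (0.0, -8.0, 6.0), (14.0, 26.0, 12.0)
_CEREB_C, _CEREB_A = (0.0, -44.0, -36.0), (38.0, 24.0, 22.0)
_CEREB_GAP_MM = 8.0  # CSF gap between cerebrum and cerebellum (tentorium)
_CTX_MARGIN_MM = 12.0  # cortical VOI keeps this distance from the cerebellum
_SUPRATENT_Z = -20.0


@dataclass
class PhantomTemplate:
    """Template anatomy: T1 rendering, tissue priors, VOIs and hard masks."""

    t1: Volume
    priors: Dict[str, Volume]
    vois: VOISet
    tissue_masks: Dict[str, np.ndarray]
    compartments: Dict[str, np.ndarray]
    seed: int = 0

    @property
    def grid(self) -> Volume:
        return self.t1

    @property
    def brain_mask(self) -> np.ndarray:
        """GM+WM+internal CSF support (the intracranial brain)."""
        return (
            self.tissue_masks["GM"] | self.tissue_masks["WM"]
        ) | self.compartments["ventricle"]


@dataclass
class SubjectTruth:
    """Ground truth for one simulated subject."""

    seed: int
    rigid_offset: RigidTransform
    pet_offset: RigidTransform
    warp_truth: DeformationField
    target_cl: float
    pattern: str
    noise_sd: Dict[str, float]


def _ellipsoid_rho(coords, center, semi) -> np.ndarray:
    """Normalized ellipsoidal radius (<=1 inside)."""
    x, y, z = coords
    cx, cy, cz = center
    ax, ay, az = semi
    return np.sqrt(((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2)


def make_template(
    grid_shape: Tuple[int, int, int] = DEFAULT_GRID[0],
    voxel_mm: float = DEFAULT_GRID[1],
    seed: int = 0,
) -> PhantomTemplate:
    """Build the deterministic template anatomy on the requested grid."""
    shape = tuple(int(s) for s in grid_shape)
    affine = np.eye(4)
    affine[:3, :3] *= voxel_mm
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel_mm

    half_fov = np.asarray(shape) * voxel_mm / 2.0
    needed = np.asarray(_OUTER_SKULL) + 2 * voxel_mm
    if np.any(half_fov < needed):
        raise GeometryError(
            f"grid {shape} at {voxel_mm} mm cannot contain the head model "
            f"(needs half-FOV >= {needed.tolist()} mm, has {half_fov.tolist()})"
        )

    idx = np.indices(shape, dtype=np.float64)
    world = (
        affine[:3, :3] @ idx.reshape(3, -1) + affine[:3, 3:4]
    ).reshape((3,) + shape)

    rho_outer = _ellipsoid_rho(world, (0, 0, 0), _OUTER_SKULL)
    rho_cavity = _ellipsoid_rho(world, (0, 0, 0), _INNER_SKULL)
    rho_brain = _ellipsoid_rho(world, (0, 0, 0), _BRAIN_SURFACE)
    rho_ribbon = _ellipsoid_rho(world, (0, 0, 0), _RIBBON_INNER)
    rho_vent = _ellipsoid_rho(world, _VENTRICLE_C, _VENTRICLE_A)
    rho_cereb = _ellipsoid_rho(world, _CEREB_C, _CEREB_A)
    gap_semi = tuple(a + _CEREB_GAP_MM for a in _CEREB_A)
    rho_cereb_gap = _ellipsoid_rho(world, _CEREB_C, gap_semi)
    margin_semi = tuple(a + _CTX_MARGIN_MM for a in _CEREB_A)
    rho_cereb_margin = _ellipsoid_rho(world, _CEREB_C, margin_semi)
    rho_cereb_core = _ellipsoid_rho(
        world, _CEREB_C, tuple(0.55 * a for a in _CEREB_A)
    )

    air = rho_outer > 1
    skull = (rho_outer <= 1) & (rho_cavity > 1)
    brain = rho_brain <= 1
    subarachnoid = (rho_cavity <= 1) & ~brain

    cerebellum = (rho_cereb <= 1) & brain
    cereb_wm = cerebellum & (rho_cereb_core <= 1)
    cereb_gm = cerebellum & ~cereb_wm

    cerebrum = brain & (rho_cereb_gap > 1)
    tentorial_gap = brain & ~cerebrum & ~cerebellum
    ventricle = cerebrum & (rho_vent <= 1)
    cortical_gm = cerebrum & (rho_ribbon > 1) & ~ventricle
    cerebral_wm = cerebrum & (rho_ribbon <= 1) & ~ventricle

    tissue_masks = {
        "GM": cortical_gm | cereb_gm,
        "WM": cerebral_wm | cereb_wm,
        "CSF": subarachnoid | tentorial_gap | ventricle,
        "skull": skull,
        "air": air,
    }
    total = np.zeros(shape, dtype=np.int64)
    for m in tissue_masks.values():
        total += m.astype(np.int64)
    assert np.all(total == 1), "tissue masks must partition the grid"

    compartments = {
        "cortical_gm": cortical_gm,
        "cerebral_wm": cerebral_wm,
        "cerebellum": cerebellum,
        "ventricle": ventricle,
        "csf": tissue_masks["CSF"],
        "skull": skull,
        "air": air,
    }

    # soft tissue priors: blurred hard masks, renormalized to sum to 1
    sigma_vox = fwhm_to_sigma(4.0) / voxel_mm
    prior_arrays = {
        t: ndimage.gaussian_filter(m.astype(np.float64), sigma_vox, mode="nearest")
        for t, m in tissue_masks.items()
    }
    norm = sum(prior_arrays.values())
    priors = {
        t: Volume(a / norm, affine, modality="PRIOR", frame="template")
        for t, a in prior_arrays.items()
    }

    t1_arr = np.zeros(shape)
    for t, m in tissue_masks.items():
        t1_arr[m] = MRI_INTENSITY[t]
    t1_arr = ndimage.gaussian_filter(t1_arr, fwhm_to_sigma(2.0) / voxel_mm,
                                     mode="nearest")
    t1 = Volume(t1_arr, affine, modality="MRI", frame="template")

    # VOIs keep a safety margin from every compartment boundary so that the
    # 6-mm PET PSF barely contaminates their means (<0.2 CL at CL 140)
    ctx = cortical_gm & (world[2] > _SUPRATENT_Z) & (rho_cereb_margin > 1)
    ctx = ndimage.binary_erosion(
        ctx, structure=ndimage.generate_binary_structure(3, 1), iterations=3
    )
    whlcbl = ndimage.binary_erosion(
        cerebellum, structure=np.ones((3, 3, 3), dtype=bool), iterations=2
    )
    if not ctx.any() or not whlcbl.any():
        raise GeometryError("grid too coarse: VOI masks are empty after erosion")
    assert not (ctx & whlcbl).any()
    vois = VOISet(
        {
            "CTX": Volume(ctx.astype(float), affine, modality="MASK",
                          frame="template"),
            "WhlCbl": Volume(whlcbl.astype(float), affine, modality="MASK",
                             frame="template"),
        }
    )
    return PhantomTemplate(
        t1=t1,
        priors=priors,
        vois=vois,
        tissue_masks=tissue_masks,
        compartments=compartments,
        seed=seed,
    )


def _pet_compartment_values(target_cl: float, pattern: str) -> Dict[str, float]:
    suvr = float(centiloid_to_suvr(target_cl))
    if suvr <= 0:
        raise DomainError(
            f"target CL {target_cl} implies non-positive SUVR {suvr:.4f}"
        )
    if pattern not in ("positive", "negative"):
        raise DomainError(f"unknown binding pattern {pattern!r}")
    wm = PET_WM_NEGATIVE if pattern == "negative" else PET_WM_POSITIVE
    return {
        "cortical_gm": suvr,
        "cerebral_wm": wm,
        "cerebellum": 1.0,
        "ventricle": PET_BACKGROUND,
        "csf": PET_BACKGROUND,
        "skull": PET_BACKGROUND,
        "air": PET_BACKGROUND,
    }


def _pet_template_array(tmpl: PhantomTemplate, target_cl: float,
                        pattern: str) -> np.ndarray:
    values = _pet_compartment_values(target_cl, pattern)
    arr = np.full(tmpl.grid.shape, PET_BACKGROUND)
    for name in ("csf", "skull", "air", "cerebral_wm", "cerebellum",
                 "ventricle", "cortical_gm"):
        arr[tmpl.compartments[name]] = values[name]
    return arr


def true_suvr(truth: "SubjectTruth", tmpl: PhantomTemplate) -> float:
    """Cortical/cerebellar mean ratio on the noise-free undeformed tissue maps."""
    arr = _pet_template_array(tmpl, truth.target_cl, truth.pattern)
    ctx = tmpl.vois["CTX"].data > 0.5
    ref = tmpl.vois["WhlCbl"].data > 0.5
    return float(arr[ctx].mean() / arr[ref].mean())


def synthesize_subject(
    tmpl: PhantomTemplate,
    seed: int,
    deform_amp_mm: float = 4.0,
    rigid_amp: Tuple[float, float] = (4.0, 3.0),
    target_cl: Optional[float] = None,
    pattern: Optional[str] = None,
    noise_sd: Optional[Dict[str, float]] = None,
) -> SubjectTruth:
    """Draw a subject: smooth random warp, rigid offset and target Centiloid.

    ``rigid_amp`` is (max |translation| mm, max |rotation| degrees); the
    warp is band-limited noise smoothed to a 12-mm correlation length with
    peak magnitude ``deform_amp_mm`` and everywhere-positive Jacobian
    (fields that fold are rejected and redrawn).
    """
    if deform_amp_mm < 0:
        raise DomainError("deform_amp_mm must be >= 0")
    rng = np.random.default_rng(seed)
    if target_cl is None:
        target_cl = float(rng.uniform(-10.0, 120.0))
    if pattern is None:
        pattern = "positive" if target_cl >= 16.0 else "negative"
    _ = _pet_compartment_values(target_cl, pattern)  # validates domain
    sd = dict(DEFAULT_NOISE_SD)
    if noise_sd:
        sd.update(noise_sd)

    trans_amp, rot_amp_deg = rigid_amp
    rigid = RigidTransform(
        rotation=np.deg2rad(rng.uniform(-rot_amp_deg, rot_amp_deg, 3)),
        translation=rng.uniform(-trans_amp, trans_amp, 3),
        center=np.zeros(3),
    )
    pet_trans = min(trans_amp, 2.0)
    pet_rot = min(rot_amp_deg, 1.0)
    pet_offset = RigidTransform(
        rotation=np.deg2rad(rng.uniform(-pet_rot, pet_rot, 3)),
        translation=rng.uniform(-pet_trans, pet_trans, 3),
        center=np.zeros(3),
    )

    shape = tmpl.grid.shape
    voxel_mm = float(tmpl.grid.voxel_sizes[0])
    sigma_vox = 12.0 / voxel_mm  # correlation length >= 12 mm
    for _attempt in range(20):
        disp = rng.standard_normal(shape + (3,))
        for c in range(3):
            disp[..., c] = ndimage.gaussian_filter(
                disp[..., c], sigma_vox, mode="nearest"
            )
        mag = np.sqrt((disp**2).sum(axis=-1))
        peak = mag.max()
        if deform_amp_mm == 0 or peak == 0:
            disp[:] = 0.0
        else:
            disp *= deform_amp_mm / peak
        field = DeformationField(disp, tmpl.grid.affine.copy())
        if deform_amp_mm == 0 or field.jacobian_determinant().min() > 0:
            break
    else:  # pragma: no cover - astronomically unlikely at sane amplitudes
        raise DomainError("could not draw a fold-free deformation field")

    return SubjectTruth(
        seed=seed,
        rigid_offset=rigid,
        pet_offset=pet_offset,
        warp_truth=field,
        target_cl=float(target_cl),
        pattern=pattern,
        noise_sd=sd,
    )


def _invert_forward_map(
    points: np.ndarray,
    rigid: RigidTransform,
    field: DeformationField,
    n_iter: int = 15,
) -> np.ndarray:
    """Solve s = rigid(x + u(x)) for x at the given native points s."""
    p = rigid.inverse().apply(points)
    if field.max_magnitude() == 0:
        return p
    x = p.copy()
    for _ in range(n_iter):
        x = p - field.sample(x)
    return x


def _render_from_template(
    arr: np.ndarray,
    tmpl: PhantomTemplate,
    template_points: np.ndarray,
    cval: float,
) -> np.ndarray:
    inv = tmpl.grid.inv_affine
    vox = inv[:3, :3] @ template_points + inv[:3, 3:4]
    out = ndimage.map_coordinates(arr, vox, order=1, mode="constant", cval=cval)
    return out.reshape(tmpl.grid.shape)


def render_modalities(
    truth: SubjectTruth, tmpl: PhantomTemplate
) -> Dict[str, Volume]:
    """Render native-frame MRI, low-dose-CT and PET volumes for a subject.

    All three carry the subject's warp and rigid offset; the PET is blurred
    with the 6-mm PSF before noise and additionally carries a small extra
    PET-to-anatomy offset (the misalignment the rigid coregistration stage
    has to recover).
    """
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 2024]))
    grid = tmpl.grid
    native_points = grid.world_grid()

    mri_t = np.zeros(grid.shape)
    ct_t = np.zeros(grid.shape)
    for t, m in tmpl.tissue_masks.items():
        mri_t[m] = MRI_INTENSITY[t]
        ct_t[m] = CT_INTENSITY[t]
    pet_t = _pet_template_array(tmpl, truth.target_cl, truth.pattern)

    x_anat = _invert_forward_map(native_points, truth.rigid_offset,
                                 truth.warp_truth)
    pet_total = RigidTransform(
        rotation=truth.pet_offset.rotation,
        translation=truth.pet_offset.translation,
        center=truth.pet_offset.center,
    )
    pet_points = pet_total.inverse().apply(native_points)
    x_pet = _invert_forward_map(pet_points, truth.rigid_offset, truth.warp_truth)

    mri_arr = _render_from_template(mri_t, tmpl, x_anat, MRI_INTENSITY["air"])
    ct_arr = _render_from_template(ct_t, tmpl, x_anat, CT_INTENSITY["air"])
    pet_arr = _render_from_template(pet_t, tmpl, x_pet, PET_BACKGROUND)

    # beam-hardening-like low-frequency artifact between the petrous bones:
    # low-dose CT soft-tissue values in the posterior fossa are unreliable,
    # which is the physical reason CT-guided normalization is weakest there
    art_rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 31]))
    voxel_mm = float(grid.voxel_sizes.mean())
    art = art_rng.standard_normal(grid.shape)
    art = ndimage.gaussian_filter(art, 15.0 / voxel_mm, mode="nearest")
    art *= CT_FOSSA_ARTIFACT_HU / max(art.std(), 1e-12)
    # bounded artifact: edge replication in the smoothing inflates a few
    # boundary voxels far beyond the nominal amplitude
    art = np.clip(art, -3.0 * CT_FOSSA_ARTIFACT_HU, 3.0 * CT_FOSSA_ARTIFACT_HU)
    z_world = native_points[2].reshape(grid.shape)
    fossa_weight = np.clip((-z_world - 10.0) / 20.0, 0.0, 1.0)
    soft = ct_arr < 1500.0  # bone itself stays bright
    ct_arr = ct_arr + art * fossa_weight * soft

    pet_vol = Volume(pet_arr, grid.affine.copy(), modality="PET", frame="native")
    pet_vol = gaussian_smooth(pet_vol, PET_PSF_FWHM_MM)
    pet_arr = pet_vol.data
    if truth.noise_sd["pet"] > 0:
        pet_arr = pet_arr + rng.normal(0, truth.noise_sd["pet"], grid.shape)
    if truth.noise_sd["mri"] > 0:
        mri_arr = mri_arr + rng.normal(0, truth.noise_sd["mri"], grid.shape)
    if truth.noise_sd["ct"] > 0:
        ct_arr = ct_arr + rng.normal(0, truth.noise_sd["ct"], grid.shape)

    return {
        "mri": Volume(mri_arr, grid.affine.copy(), modality="MRI", frame="native"),
        "ct": Volume(ct_arr, grid.affine.copy(), modality="CT", frame="native"),
        "pet": Volume(pet_arr, grid.affine.copy(), modality="PET", frame="native"),
    }


def render_template_pet(
    tmpl: PhantomTemplate,
    target_cl: float,
    pattern: str,
    psf_fwhm_mm: float = PET_PSF_FWHM_MM,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Volume:
    """Noise-controlled template-frame PET rendering (no warp, no offset).

    Used to build PET-only normalization atlases from synthetic cohorts and
    for PSF-only error-budget checks.
    """
    arr = _pet_template_array(tmpl, target_cl, pattern)
    vol = Volume(arr, tmpl.grid.affine.copy(), modality="PET", frame="template")
    if psf_fwhm_mm > 0:
        vol = gaussian_smooth(vol, psf_fwhm_mm)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
        vol = vol.with_data(vol.data + rng.normal(0, noise_sd, vol.shape))
    return vol
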