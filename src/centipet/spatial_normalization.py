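"""Tissue-prior segmentation and nonlinear normalization to template space.

This is a simplified stand-in for joint ("unified") segmentation-
normalization: the affine pre-alignment is estimated separately
(:mod:`centipet.rigid_registration`), tissue classification is a Gaussian
mixture EM with spatial priors (plus a smooth polynomial bias field for
MRI), and the residual nonlinear deformation is a multi-resolution demons
match between the subject GM+WM posterior and the template GM+WM prior.
The CT route fits GM and WM as a single intensity class (they are nearly
iso-intense on low-dose CT) whose posterior is split by the spatial prior
ratio — which is exactly why CT-guided normalization is driven by CSF and
skull boundaries, and where its weakness in the posterior fossa comes from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import ContractViolation, SegmentationError, WarpError
from .image_core import (
    DeformationField,
    RigidTransform,
    Volume,
    fwhm_to_sigma,
    resample,
)
from .rigid_registration import AffineTransform, register_affine

#: shifted-HU soft-tissue window applied to CT before segmentation
CT_WINDOW = (900.0, 1200.0)

#: demons regularization: Gaussian sigma (mm) applied to the update
#: ("fluid", 2 mm) and to the accumulated field ("elastic", 3 mm) per level
FLUID_SIGMA_MM = 2.0
ELASTIC_SIGMA_MM = 3.0


@dataclass
class TissuePosteriors:
    """Per-tissue posterior maps plus the fitted mixture parameters."""

    posteriors: Dict[str, Volume]
    means: Dict[str, float]
    variances: Dict[str, float]
    bias: Optional[np.ndarray] = None
    loglik_trace: list = field(default_factory=list)
    converged: bool = False

    def gm_wm(self) -> np.ndarray:
        out = np.zeros(next(iter(self.posteriors.values())).shape)
        for t in ("GM", "WM"):
            if t in self.posteriors:
                out += self.posteriors[t].data
        return out


def condition_ct(ct: Volume, presmooth_fwhm_mm: float = 4.0) -> Volume:
    """Denoise and rescale shifted-HU CT over the soft-tissue window.

    Low-dose CT carries only ~20-30 HU of CSF/parenchyma contrast against
    comparable noise, so the image is first smoothed (4-mm FWHM default),
    then windowed to [0, 1]; bone and air saturate at 1 and 0 so the
    mixture fit concentrates its dynamic range on the boundaries that
    low-dose CT actually delineates.
    """
    data = ct.data
    if presmooth_fwhm_mm > 0:
        sigma = fwhm_to_sigma(presmooth_fwhm_mm) / ct.voxel_sizes
        data = ndimage.gaussian_filter(data, sigma, mode="nearest")
    lo, hi = CT_WINDOW
    data = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    return ct.with_data(data)


def _polynomial_basis(shape, order: int = 2) -> np.ndarray:
    """Low-frequency 3-D polynomial basis, coords normalized to [-1, 1]."""
    grids = [np.linspace(-1, 1, n) for n in shape]
    x, y, z = np.meshgrid(*grids, indexing="ij")
    cols = []
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                cols.append((x**i) * (y**j) * (z**k))
    return np.stack([c.ravel() for c in cols], axis=1)


def segment_tissues(
    anat: Volume,
    priors: Dict[str, Volume],
    modality: str = "MRI",
    max_iter: int = 50,
    tol: float = 1e-5,
    bias_order: int = 2,
) -> TissuePosteriors:
    """EM on a Gaussian mixture with spatial priors.

    E-step: posterior ∝ prior x class likelihood; M-step updates class
    means/variances and, for MRI, a low-frequency multiplicative bias
    field. For CT the image is windowed first, the bias field is disabled,
    and GM/WM share a tied intensity class split by the prior ratio.
    Iterates until the relative log-likelihood change is below ``tol``.
    """
    classes = list(priors)
    grid = anat
    for t, p in priors.items():
        if p.shape != anat.shape:
            raise ContractViolation(
                f"prior {t!r} shape {p.shape} != anatomy shape {anat.shape}"
            )

    if modality == "CT":
        work = condition_ct(anat)
        use_bias = False
    elif modality == "MRI":
        work = anat
        use_bias = True
    else:
        raise ContractViolation(f"segmentation supports MRI or CT, got {modality!r}")

    tied: Dict[str, Sequence[str]] = {}
    if modality == "CT" and "GM" in classes and "WM" in classes:
        tied = {"soft": ("GM", "WM")}

    y = work.data.reshape(-1)
    n = y.size
    pri = {t: np.clip(priors[t].data.reshape(-1), 1e-6, None) for t in classes}

    # intensity groups: tied classes share one Gaussian
    groups: Dict[str, Sequence[str]] = {t: (t,) for t in classes}
    for gname, members in tied.items():
        for m in members:
            groups.pop(m)
        groups[gname] = tuple(members)

    def group_prior(members):
        out = np.zeros(n)
        for m in members:
            out += pri[m]
        return out

    gp = {g: group_prior(members) for g, members in groups.items()}
    mu = {}
    var = {}
    yvar_floor = max(np.var(y), 1e-12) * 1e-6
    # prior-dominated CT update: class means are anchored on high-confidence
    # prior cores and not re-estimated, because the partial-volumed CSF rim
    # would otherwise drag the CSF mean across the (tiny) soft-tissue
    # contrast and invert it; EM then only adapts variances/posteriors.
    fix_means = modality == "CT"
    for g, w in gp.items():
        core = w > 0.9
        wc = np.where(core, w, 0.0) if (fix_means and core.sum() > 50) else w
        wsum = wc.sum()
        mu[g] = float((wc * y).sum() / wsum)
        var[g] = float(max((wc * (y - mu[g]) ** 2).sum() / wsum, yvar_floor))

    # flat (uninformative) priors make all prior-weighted initial means
    # coincide; fall back to intensity quantiles so EM can separate classes
    mus = np.array(list(mu.values()))
    if len(mu) > 1 and np.ptp(mus) < 0.05 * (y.std() + 1e-300):
        qs = np.quantile(y, np.linspace(0.1, 0.9, len(mu)))
        for g, q in zip(mu, qs):
            mu[g] = float(q)
            var[g] = float(max(y.var() / len(mu) ** 2, yvar_floor))

    bias = np.ones(n)
    basis = _polynomial_basis(anat.shape, bias_order) if use_bias else None

    loglik_trace = []
    converged = False
    resp = None
    for it in range(max_iter):
        yc = y / bias
        # E-step over intensity groups
        lik = {}
        for g in groups:
            lik[g] = np.exp(-0.5 * (yc - mu[g]) ** 2 / var[g]) / np.sqrt(
                2 * np.pi * var[g]
            )
        num = {g: gp[g] * lik[g] for g in groups}
        denom = sum(num.values()) + 1e-300
        loglik = float(np.log(denom).sum())
        if not np.isfinite(loglik):
            raise SegmentationError(
                f"EM diverged at iteration {it}; trace={loglik_trace}"
            )
        resp = {g: num[g] / denom for g in groups}
        loglik_trace.append(loglik)
        if it > 0:
            rel = abs(loglik - loglik_trace[-2]) / (abs(loglik_trace[-2]) + 1e-300)
            if rel < tol:
                converged = True
                break
        # M-step
        for g in groups:
            w = resp[g]
            wsum = w.sum() + 1e-300
            if not fix_means:
                mu[g] = float((w * yc).sum() / wsum)
            var[g] = float(max((w * (yc - mu[g]) ** 2).sum() / wsum, yvar_floor))
        if use_bias:
            pred = sum(resp[g] * mu[g] for g in groups)
            weight = pred**2
            target = np.where(pred > 1e-6, y / np.clip(pred, 1e-6, None), 1.0)
            wts = weight
            bw = basis * wts[:, None]
            coef, *_ = np.linalg.lstsq(
                basis.T @ bw, (bw * target[:, None]).sum(axis=0), rcond=None
            )
            bias = basis @ coef
            bias = np.clip(bias, 0.2, 5.0)
            bias /= bias.mean()

    # split tied groups by prior ratio
    post_arrays: Dict[str, np.ndarray] = {}
    for g, members in groups.items():
        if len(members) == 1:
            post_arrays[members[0]] = resp[g]
        else:
            total = sum(pri[m] for m in members)
            for m in members:
                post_arrays[m] = resp[g] * pri[m] / total

    posteriors = {
        t: Volume(
            post_arrays[t].reshape(anat.shape),
            grid.affine.copy(),
            modality="PRIOR",
            frame=grid.frame,
        )
        for t in classes
    }
    means = {}
    variances = {}
    for g, members in groups.items():
        for m in members:
            means[m] = mu[g]
            variances[m] = var[g]
    return TissuePosteriors(
        posteriors=posteriors,
        means=means,
        variances=variances,
        bias=bias.reshape(anat.shape) if use_bias else None,
        loglik_trace=loglik_trace,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# demons deformation


def _demons_level(
    fixed: np.ndarray,
    moving: np.ndarray,
    spacing: np.ndarray,
    u: np.ndarray,
    n_iter: int,
    fluid_sigma_vox: np.ndarray,
    elastic_sigma_vox: np.ndarray,
    max_step_mm: float = 2.0,
) -> np.ndarray:
    shape = fixed.shape
    idx = np.indices(shape, dtype=np.float64)
    grad_f = np.stack(np.gradient(fixed, *spacing))
    norm2_scale = float((spacing**2).mean())
    for _ in range(n_iter):
        coords = [idx[c] + u[..., c] / spacing[c] for c in range(3)]
        warped = ndimage.map_coordinates(
            moving, coords, order=1, mode="nearest"
        )
        diff = warped - fixed
        grad_w = np.stack(np.gradient(warped, *spacing))
        g = 0.5 * (grad_f + grad_w)
        g2 = (g**2).sum(axis=0)
        denom = g2 + diff**2 / norm2_scale
        factor = np.where(denom > 1e-12, diff / np.where(denom > 1e-12, denom, 1.0), 0.0)
        du = -np.stack([factor * g[c] for c in range(3)], axis=-1)
        step = np.sqrt((du**2).sum(axis=-1))
        cap = np.where(step > max_step_mm, max_step_mm / np.where(step > 0, step, 1.0), 1.0)
        du *= cap[..., None]
        for c in range(3):
            du[..., c] = ndimage.gaussian_filter(
                du[..., c], fluid_sigma_vox, mode="nearest"
            )
        u = u + du
        for c in range(3):
            u[..., c] = ndimage.gaussian_filter(
                u[..., c], elastic_sigma_vox, mode="nearest"
            )
    return u


def demons_warp(
    fixed: Volume,
    moving: Volume,
    iters=(40, 15),
    fluid_sigma_mm: float = FLUID_SIGMA_MM,
    elastic_sigma_mm: float = ELASTIC_SIGMA_MM,
    brain_mask: Optional[np.ndarray] = None,
) -> DeformationField:
    """Multi-resolution demons estimate of the map fixed -> moving.

    Both images live on the same (template) grid; the returned field maps a
    fixed-grid point x to x + u(x) where the moving image matches. The
    Jacobian determinant must stay positive on the brain mask.
    """
    if fixed.shape != moving.shape:
        raise ContractViolation("demons requires a common grid")
    spacing = fixed.voxel_sizes
    factors = (2, 1) if len(iters) == 2 else (4, 2, 1)

    u = None
    for factor, n_iter in zip(factors, iters):
        if factor > 1:
            sl = (slice(None, None, factor),) * 3
            fx = ndimage.gaussian_filter(fixed.data, factor / 2.0, mode="nearest")[sl]
            mv = ndimage.gaussian_filter(moving.data, factor / 2.0, mode="nearest")[sl]
        else:
            fx, mv = fixed.data, moving.data
        sp = spacing * factor
        if u is None:
            u_level = np.zeros(fx.shape + (3,))
        else:
            u_level = np.stack(
                [ndimage.zoom(u[..., c], np.array(fx.shape) / np.array(u.shape[:3]),
                              order=1, mode="nearest") for c in range(3)],
                axis=-1,
            )
        fluid_sigma = fluid_sigma_mm / sp
        elastic_sigma = elastic_sigma_mm / sp
        u = _demons_level(fx, mv, sp, u_level, n_iter, fluid_sigma, elastic_sigma)

    field = DeformationField(u, fixed.affine.copy())
    jac = field.jacobian_determinant()
    mask = brain_mask if brain_mask is not None else np.ones(fixed.shape, bool)
    if jac[mask].min() <= 0:
        raise WarpError(
            "deformation field folds (Jacobian <= 0) on the brain mask; "
            "increase the fluid/elastic regularization widths"
        )
    return field


def estimate_warp(
    post: TissuePosteriors, tmpl, posterior_smoothing_fwhm_mm: float = 4.0
) -> DeformationField:
    """Demons warp from the template GM+WM prior to the subject posterior.

    ``post`` must come from an anatomy already affinely aligned to and
    resampled on the template grid; the result maps template points to the
    (affinely aligned) subject, i.e. the residual nonlinear deformation.
    The near-binary subject posterior is smoothed to the intrinsic
    smoothness of the template priors so the demons force vanishes when
    subject and template coincide.
    """
    tmpl_gmwm = tmpl.priors["GM"].data + tmpl.priors["WM"].data
    subj_gmwm = post.gm_wm()
    if posterior_smoothing_fwhm_mm > 0:
        sigma = fwhm_to_sigma(posterior_smoothing_fwhm_mm) / tmpl.grid.voxel_sizes
        subj_gmwm = ndimage.gaussian_filter(subj_gmwm, sigma, mode="nearest")
    fixed = Volume(tmpl_gmwm, tmpl.grid.affine.copy(), modality="PRIOR",
                   frame="template")
    moving = fixed.with_data(subj_gmwm)
    brain = tmpl_gmwm > 0.1
    return demons_warp(fixed, moving, brain_mask=brain)


def save_deformation(field: DeformationField, path) -> None:
    """Serialize as a 3-component NIfTI (mm displacement per voxel)."""
    import nibabel as nib

    img = nib.Nifti1Image(field.displacement.astype(np.float32),
                          field.grid_affine)
    img.set_sform(field.grid_affine, code=1)
    img.set_qform(field.grid_affine, code=1)
    nib.save(img, str(path))


def load_deformation(path) -> DeformationField:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(dtype=np.float64))
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ContractViolation(
            f"{path}: expected a 3-component displacement NIfTI"
        )
    return DeformationField(data, img.affine)


def normalize_pet(
    pet: Volume,
    pet2anat: Optional[RigidTransform],
    anat2tmpl_affine,
    warp: Optional[DeformationField],
    tmpl_grid: Volume,
) -> Volume:
    """Warp a native PET into template space with a single interpolation.

    The mapping chain (template voxel -> PET voxel) is: nonlinear warp,
    then the anatomy-to-template affine (template world -> anatomy world),
    then the PET-to-anatomy rigid (anatomy world -> PET world).
    """
    if tmpl_grid.frame != "template":
        raise ContractViolation("tmpl_grid must be in the template frame")
    if isinstance(anat2tmpl_affine, AffineTransform):
        anat2tmpl_affine = anat2tmpl_affine.as_matrix()
    chain = [m for m in (warp, anat2tmpl_affine, pet2anat) if m is not None]
    out = resample(pet, chain if chain else None, tmpl_grid, interp="trilinear")
    out.frame = "template"
    return out


def normalize_pet_only(pet: Volume, template_pet: Volume) -> Volume:
    """PET-only anatomic standardization against a PET atlas.

    Affine (NCC) registration to the atlas followed by the same demons
    warp driven directly by PET intensities; the original PET is then
    pulled onto the template grid with a single interpolation.
    """
    if template_pet.frame != "template":
        raise ContractViolation("template_pet must be in the template frame")
    aff = register_affine(pet, template_pet, metric="NCC")
    pet_aff = resample(pet, aff.as_matrix(), template_pet, interp="trilinear")
    # estimation-only conditioning: intensity-scale match plus extra
    # smoothing, because a subject whose binding pattern disagrees with the
    # atlas (e.g. positive subject vs mean atlas) produces strong
    # conflicting forces at the GM/WM boundary
    mask = template_pet.data > template_pet.data.min() + 0.1 * np.ptp(template_pet.data)
    scale = float(template_pet.data[mask].mean()) / max(
        float(pet_aff.data[mask].mean()), 1e-12
    )
    sigma = fwhm_to_sigma(4.0) / template_pet.voxel_sizes
    fixed_sm = template_pet.with_data(
        ndimage.gaussian_filter(template_pet.data, sigma, mode="nearest")
    )
    moving_sm = pet_aff.with_data(
        ndimage.gaussian_filter(pet_aff.data * scale, sigma, mode="nearest")
    )
    warp = demons_warp(fixed_sm, moving_sm, brain_mask=mask,
                       elastic_sigma_mm=2.0 * ELASTIC_SIGMA_MM)
    out = resample(pet, [warp, aff.as_matrix()], template_pet, interp="trilinear")
    out.frame = "template"
    return out
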