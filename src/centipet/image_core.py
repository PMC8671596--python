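"""Volume container, NIfTI-1 I/O, world/voxel geometry, resampling and smoothing.

Conventions used throughout the package:

* world frame is RAS, millimetres; voxel indices are 0-based;
* every spatial mapping is a *pull-back*: it maps points in the frame of the
  target (fixed) image to points in the frame of the source (moving) image,
  so resampling evaluates the source at mapped target-voxel centres;
* sampling outside the source field of view yields 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .errors import ContractViolation, DimensionalityError, DomainError, FormatError

#: full width at half maximum of a unit-variance Gaussian
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

MODALITIES = ("MRI", "CT", "PET", "MASK", "TMAP", "PRIOR")
FRAMES = ("native", "template")


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian FWHM to the equivalent standard deviation."""
    return fwhm / FWHM_PER_SIGMA


@dataclass
class Volume:
    """A 3-D scalar image with voxel-to-world geometry.

    Parameters
    ----------
    data:
        3-D array of intensities (any units; converted to float64).
    affine:
        4x4 voxel-index -> world-mm map (RAS).
    modality:
        One of ``MRI, CT, PET, MASK, TMAP, PRIOR``.
    frame:
        ``native`` (subject space) or ``template`` (standard space).
    """

    data: np.ndarray
    affine: np.ndarray
    modality: str = "PET"
    frame: str = "native"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"Volume requires 3-D data, got {self.data.ndim}-D"
            )
        if self.affine.shape != (4, 4):
            raise ContractViolation("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ContractViolation("affine is singular")
        if self.modality not in MODALITIES:
            raise ContractViolation(f"unknown modality {self.modality!r}")
        if self.frame not in FRAMES:
            raise ContractViolation(f"unknown frame {self.frame!r}")
        if not np.all(np.isfinite(self.data)):
            raise ContractViolation("volume data contains non-finite values")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the 3x3 block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def inv_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    def voxel_to_world(self, vox: np.ndarray) -> np.ndarray:
        """Map (3, N) voxel indices to (3, N) world-mm coordinates."""
        vox = np.asarray(vox, dtype=np.float64)
        return self.affine[:3, :3] @ vox + self.affine[:3, 3:4]

    def world_to_voxel(self, world: np.ndarray) -> np.ndarray:
        world = np.asarray(world, dtype=np.float64)
        inv = self.inv_affine
        return inv[:3, :3] @ world + inv[:3, 3:4]

    def world_grid(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (3, n_voxels)."""
        idx = np.indices(self.shape, dtype=np.float64).reshape(3, -1)
        return self.voxel_to_world(idx)

    def center_of_mass_world(self) -> np.ndarray:
        """Intensity-weighted centre of mass in world mm."""
        w = np.clip(self.data, 0, None)
        total = w.sum()
        if total <= 0:
            com_vox = (np.asarray(self.shape, dtype=float) - 1) / 2.0
        else:
            com_vox = np.array(ndimage.center_of_mass(w))
        return self.voxel_to_world(com_vox.reshape(3, 1)).ravel()

    def with_data(self, data: np.ndarray, **kwargs) -> "Volume":
        """Copy of this volume with new data (and optional field overrides)."""
        out = replace(self, data=np.asarray(data, dtype=np.float64))
        for k, v in kwargs.items():
            setattr(out, k, v)
        return out

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class RigidTransform:
    """Six-parameter rigid-body map of world coordinates.

    ``apply`` computes ``y = R (x - c) + c + t`` with ``R`` built from
    extrinsic x-y-z Euler angles. In registration results the transform maps
    fixed-image world points to moving-image world points (pull-back).
    """

    rotation: np.ndarray  # 3 Euler angles, radians
    translation: np.ndarray  # mm
    center: np.ndarray  # world mm
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        self.center = np.asarray(self.center, dtype=np.float64).reshape(3)

    @classmethod
    def identity(cls, center: Sequence[float] = (0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(np.zeros(3), np.zeros(3), np.asarray(center, dtype=float))

    @property
    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation).as_matrix()

    def as_matrix(self) -> np.ndarray:
        R = self.rotation_matrix
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = self.center + self.translation - R @ self.center
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        R = self.rotation_matrix
        return R @ (points - self.center[:, None]) + (
            self.center + self.translation
        )[:, None]

    def inverse(self) -> "RigidTransform":
        R = self.rotation_matrix
        rot = Rotation.from_matrix(R.T).as_euler("xyz")
        return RigidTransform(rot, -(R.T @ self.translation), self.center.copy())

    def compose(self, other: "RigidTransform") -> np.ndarray:
        """Matrix of self∘other (apply ``other`` first)."""
        return self.as_matrix() @ other.as_matrix()

    def to_dict(self) -> dict:
        return {
            "convention": "euler-xyz-extrinsic/world-mm",
            "rotation_rad": self.rotation.tolist(),
            "translation_mm": self.translation.tolist(),
            "center_mm": self.center.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            np.asarray(d["rotation_rad"]),
            np.asarray(d["translation_mm"]),
            np.asarray(d["center_mm"]),
        )


@dataclass
class DeformationField:
    """Dense displacement field on the template lattice.

    ``displacement[i, j, k]`` is the world-mm displacement vector at lattice
    point (i, j, k); the field maps a template-space point ``x`` to
    ``x + u(x)`` (trilinear interpolation of ``u`` between lattice points).
    """

    displacement: np.ndarray  # (X, Y, Z, 3), mm
    grid_affine: np.ndarray  # 4x4 lattice voxel -> world

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        self.grid_affine = np.asarray(self.grid_affine, dtype=np.float64)
        if self.displacement.ndim != 4 or self.displacement.shape[-1] != 3:
            raise ContractViolation("displacement must have shape (X, Y, Z, 3)")
        if not np.all(np.isfinite(self.displacement)):
            raise ContractViolation("displacement field contains non-finite values")

    @classmethod
    def zero(cls, shape: tuple, grid_affine: np.ndarray) -> "DeformationField":
        return cls(np.zeros(tuple(shape) + (3,)), grid_affine)

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Interpolate the displacement (mm) at world points (3, N)."""
        inv = np.linalg.inv(self.grid_affine)
        vox = inv[:3, :3] @ points + inv[:3, 3:4]
        out = np.empty_like(points)
        for c in range(3):
            out[c] = ndimage.map_coordinates(
                self.displacement[..., c], vox, order=1, mode="nearest"
            )
        return out

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points + self.sample(points)

    def jacobian_determinant(self) -> np.ndarray:
        """Voxel-wise det of the Jacobian of x -> x + u(x) on the lattice."""
        spacing = np.linalg.norm(self.grid_affine[:3, :3], axis=0)
        jac = np.empty(self.displacement.shape[:3] + (3, 3))
        for i in range(3):
            grads = np.gradient(self.displacement[..., i], *spacing)
            for j in range(3):
                jac[..., i, j] = grads[j] + (1.0 if i == j else 0.0)
        return np.linalg.det(jac)

    def max_magnitude(self) -> float:
        return float(np.sqrt((self.displacement**2).sum(axis=-1)).max())


Mapping = Union[RigidTransform, DeformationField, np.ndarray, None]


def _apply_mapping(points: np.ndarray, mapping: Mapping) -> np.ndarray:
    if mapping is None:
        return points
    if isinstance(mapping, RigidTransform):
        return mapping.apply(points)
    if isinstance(mapping, DeformationField):
        return mapping.apply(points)
    m = np.asarray(mapping, dtype=np.float64)
    if m.shape != (4, 4):
        raise ContractViolation("array mapping must be a 4x4 affine")
    return m[:3, :3] @ points + m[:3, 3:4]


def resample(
    source: Volume,
    mapping: Union[Mapping, Sequence[Mapping]] = None,
    target_grid: Volume | None = None,
    interp: str = "trilinear",
) -> Volume:
    """Pull the source volume onto the target grid through a mapping chain.

    ``mapping`` may be a single transform or a sequence applied left to
    right to target-world points, ending in source-world points; passing a
    sequence performs the whole composition with a single interpolation.
    Samples outside the source field of view are set to 0.
    """
    if target_grid is None:
        target_grid = source
    if interp not in ("trilinear", "nearest"):
        raise ContractViolation(f"unknown interpolation {interp!r}")
    if source.modality == "MASK" and interp != "nearest":
        raise ContractViolation("MASK volumes must be resampled with nearest")

    points = target_grid.world_grid()
    chain: Iterable[Mapping]
    if mapping is None or isinstance(
        mapping, (RigidTransform, DeformationField, np.ndarray)
    ):
        chain = [mapping]
    else:
        chain = mapping
    for m in chain:
        points = _apply_mapping(points, m)
    vox = source.world_to_voxel(points)
    order = 1 if interp == "trilinear" else 0
    out = ndimage.map_coordinates(
        source.data, vox, order=order, mode="constant", cval=0.0
    ).reshape(target_grid.shape)
    return Volume(
        out, target_grid.affine.copy(), modality=source.modality, frame=target_grid.frame
    )


def gaussian_smooth(v: Volume, fwhm_mm: float) -> Volume:
    """Smooth with an isotropic-in-mm Gaussian kernel of the given FWHM.

    Anisotropic voxel sizes are honoured (per-axis sigma in voxels is
    ``fwhm / (voxel_size * 2 sqrt(2 ln 2))``); boundaries use nearest-edge
    replication so constant images are exactly preserved.
    """
    if not fwhm_mm > 0:
        raise DomainError(f"fwhm_mm must be positive, got {fwhm_mm}")
    sigma_vox = fwhm_to_sigma(fwhm_mm) / v.voxel_sizes
    out = ndimage.gaussian_filter(v.data, sigma=sigma_vox, mode="nearest")
    return v.with_data(out)


def read_volume(path, modality: str = "PET", frame: str = "native") -> Volume:
    """Read a NIfTI-1 volume (.nii / .nii.gz).

    The affine is taken from the s-form when its code is valid, otherwise
    from the q-form; scl_slope/scl_inter scaling is applied by nibabel.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        hdr = img.header
        data = np.asarray(img.get_fdata(dtype=np.float64))
    except DimensionalityError:
        raise
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected a 3-D volume, got {data.ndim}-D"
        )
    sform_code = int(hdr["sform_code"])
    affine = img.get_sform() if sform_code > 0 else img.get_qform()
    if affine is None or abs(np.linalg.det(np.asarray(affine)[:3, :3])) < 1e-12:
        raise FormatError(f"{path}: degenerate sform/qform affine")
    if not np.all(np.isfinite(data)):
        data = np.nan_to_num(data, nan=0.0, posinf=0.0, neginf=0.0)
    return Volume(data, affine, modality=modality, frame=frame)


def write_volume(v: Volume, path) -> None:
    """Write as NIfTI-1, float32 data, s-form set and preferred."""
    path = Path(path)
    img = nib.Nifti1Image(v.data.astype(np.float32), v.affine)
    img.set_sform(v.affine, code=1)
    img.set_qform(v.affine, code=1)
    nib.save(img, str(path))
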