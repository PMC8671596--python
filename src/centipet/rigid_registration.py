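"""Multimodal rigid and affine registration.

Orientation is initialized by centre-of-mass alignment; the similarity
metric (normalized mutual information for cross-modality pairs, normalized
cross-correlation within modality) is then maximized by a deterministic
derivative-free Powell search over a 3-level multi-resolution pyramid
(downsampling factors 4/2/1). NMI uses a 32x32 joint histogram with Parzen
linear binning over a bounding box around the fixed-image head.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .errors import RegistrationError
from .image_core import RigidTransform, Volume

NMI_BINS = 32
_LEVELS = (4, 2, 1)
_MAXFEV = {4: 600, 2: 400, 1: 200}


@dataclass
class AffineTransform:
    """12-parameter affine world map: rotation, translation, scale, shear.

    ``apply`` computes ``y = T(c+t) R S K T(-c) x``; in registration results
    it maps fixed-image world points to moving-image world points.
    """

    params: np.ndarray  # rx,ry,rz deg; tx,ty,tz mm; sx,sy,sz %; kxy,kxz,kyz %
    center: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=np.float64).reshape(12)
        self.center = np.asarray(self.center, dtype=np.float64).reshape(3)

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "AffineTransform":
        return cls(np.zeros(12), np.asarray(center, dtype=float))

    def as_matrix(self) -> np.ndarray:
        rot = Rotation.from_euler("xyz", np.deg2rad(self.params[:3])).as_matrix()
        scale = np.diag(1.0 + self.params[6:9] / 100.0)
        shear = np.eye(3)
        shear[0, 1], shear[0, 2], shear[1, 2] = self.params[9:12] / 100.0
        lin = rot @ scale @ shear
        m = np.eye(4)
        m[:3, :3] = lin
        m[:3, 3] = self.center + self.params[3:6] - lin @ self.center
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        m = self.as_matrix()
        return m[:3, :3] @ points + m[:3, 3:4]

    @property
    def scales(self) -> np.ndarray:
        return 1.0 + self.params[6:9] / 100.0

    def to_dict(self) -> dict:
        return {
            "convention": "rot-deg/trans-mm/scale-pct/shear-pct, world-mm",
            "params": self.params.tolist(),
            "center_mm": self.center.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        return cls(np.asarray(d["params"]), np.asarray(d["center_mm"]))


# ---------------------------------------------------------------------------
# similarity metrics


def joint_histogram(a: np.ndarray, b: np.ndarray, bins: int = NMI_BINS) -> np.ndarray:
    """Joint intensity histogram with Parzen linear binning."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    ar = np.ptp(a) or 1.0
    br = np.ptp(b) or 1.0
    fa = (a - a.min()) / ar * (bins - 1)
    fb = (b - b.min()) / br * (bins - 1)
    ia = np.clip(np.floor(fa).astype(np.intp), 0, bins - 2)
    ib = np.clip(np.floor(fb).astype(np.intp), 0, bins - 2)
    wa = fa - ia
    wb = fb - ib
    hist = np.zeros((bins, bins))
    for da, pa in ((0, 1.0 - wa), (1, wa)):
        for db, pb in ((0, 1.0 - wb), (1, wb)):
            np.add.at(hist, (ia + da, ib + db), pa * pb)
    return hist


def normalized_mutual_information(a, b, bins: int = NMI_BINS) -> float:
    """Studholme NMI: (H(A) + H(B)) / H(A, B); 2 for identical images."""
    hist = joint_histogram(a, b, bins)
    p = hist / hist.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)

    def _entropy(q):
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    h_ab = _entropy(p.ravel())
    if h_ab == 0:
        return 2.0
    return (_entropy(pa) + _entropy(pb)) / h_ab


def normalized_cross_correlation(a, b) -> float:
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


_METRICS = {
    "NMI": normalized_mutual_information,
    "NCC": normalized_cross_correlation,
}


# ---------------------------------------------------------------------------
# pyramid and sampling helpers


def _downsample(vol: Volume, factor: int) -> Volume:
    if factor == 1:
        return vol
    sm = ndimage.gaussian_filter(vol.data, sigma=factor / 2.0, mode="nearest")
    data = sm[::factor, ::factor, ::factor]
    scale = np.diag([factor, factor, factor, 1.0])
    return Volume(data, vol.affine @ scale, modality=vol.modality, frame=vol.frame)


def _head_bbox_points(fixed: Volume) -> Tuple[np.ndarray, np.ndarray]:
    """Fixed-image samples inside the head bounding box (values, world pts)."""
    data = fixed.data
    thr = data.min() + 0.05 * (np.ptp(data) or 1.0)
    mask = data > thr
    if not mask.any():
        mask = np.ones_like(data, dtype=bool)
    slices = ndimage.find_objects(mask.astype(np.int8))[0]
    sub = data[slices]
    idx = np.indices(sub.shape, dtype=np.float64).reshape(3, -1)
    idx += np.array([[s.start] for s in slices], dtype=np.float64)
    return sub.ravel(), fixed.voxel_to_world(idx)


def _sample_moving(moving: Volume, points_world: np.ndarray) -> np.ndarray:
    vox = moving.world_to_voxel(points_world)
    return ndimage.map_coordinates(
        moving.data, vox, order=1, mode="constant", cval=float(moving.data.min())
    )


def _check_degenerate(moving: Volume, fixed: Volume) -> None:
    for name, v in (("moving", moving), ("fixed", fixed)):
        if np.ptp(v.data) == 0:
            raise RegistrationError(f"{name} image is constant; cannot register")


# ---------------------------------------------------------------------------
# registration drivers


def _optimize(
    moving: Volume,
    fixed: Volume,
    metric: str,
    p0: np.ndarray,
    make_transform,
    levels=_LEVELS,
):
    metric_fn = _METRICS[metric]
    p = np.asarray(p0, dtype=np.float64)
    for factor in levels:
        fx = _downsample(fixed, factor)
        mv = _downsample(moving, factor)
        fixed_vals, points = _head_bbox_points(fx)

        def cost(q):
            vals = _sample_moving(mv, make_transform(q).apply(points))
            return -metric_fn(fixed_vals, vals)

        res = optimize.minimize(
            cost,
            p,
            method="Powell",
            options={
                "xtol": 1e-3,
                "ftol": 1e-6,
                "maxfev": _MAXFEV[factor],
                "maxiter": 6,
            },
        )
        p = np.asarray(res.x, dtype=np.float64)

    # full-resolution metric bookkeeping; never report worse than identity
    fixed_vals, points = _head_bbox_points(fixed)

    def full_metric(q):
        return metric_fn(fixed_vals, _sample_moving(moving, make_transform(q).apply(points)))

    candidates = [p, np.asarray(p0, dtype=np.float64), np.zeros_like(p)]
    values = [full_metric(q) for q in candidates]
    best = int(np.argmax(values))
    tf = make_transform(candidates[best])
    tf.meta["metric"] = metric
    tf.meta["metric_value"] = values[best]
    tf.meta["metric_at_identity"] = full_metric(np.zeros_like(p))
    return tf


def register_rigid(
    moving: Volume, fixed: Volume, metric: str = "NMI"
) -> RigidTransform:
    """Estimate the rigid map (fixed world -> moving world) aligning the pair.

    Use ``metric="NMI"`` for cross-modality pairs (PET<->MRI, PET<->CT,
    CT<->template T1); NCC is appropriate within modality.
    """
    _check_degenerate(moving, fixed)
    center = fixed.center_of_mass_world()
    t0 = moving.center_of_mass_world() - center

    def make(q):
        return RigidTransform(
            rotation=np.deg2rad(q[:3]), translation=q[3:6], center=center.copy()
        )

    p0 = np.concatenate([np.zeros(3), t0])
    return _optimize(moving, fixed, metric, p0, make)


def register_affine(
    moving: Volume,
    fixed: Volume,
    metric: str = "NMI",
    init: Optional[RigidTransform] = None,
) -> AffineTransform:
    """12-parameter affine registration initialized from the rigid solution."""
    _check_degenerate(moving, fixed)
    if init is None:
        init = register_rigid(moving, fixed, metric=metric)
    center = init.center

    def make(q):
        return AffineTransform(params=q, center=center.copy())

    p0 = np.concatenate(
        [np.rad2deg(init.rotation), init.translation, np.zeros(6)]
    )
    return _optimize(moving, fixed, metric, p0, make, levels=(2, 1))
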