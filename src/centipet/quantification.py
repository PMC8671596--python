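"""SUVR computation, Centiloid conversion and the adaptive-template rule.

The Centiloid (CL) scale is a linear standardization of amyloid burden
anchored at 0 (young amyloid-negative controls) and 100 (typical AD). For
^18F-flutemetamol with a whole-cerebellum reference the direct conversion is

    CL = 121.42 * SUVR - 121.16

where SUVR is the mean uptake in the global cortical target VOI (CTX)
divided by the mean uptake in the whole-cerebellum VOI (WhlCbl).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .errors import ContractViolation, QuantificationError
from .image_core import Volume

#: slope / intercept of the flutemetamol direct conversion equation
CL_SLOPE = 121.42
CL_INTERCEPT = -121.16

#: amyloid-positivity cutoff on the Centiloid scale used by the adaptive atlas
POSITIVITY_CUTOFF_CL = 16.0

ROUTES = ("MRI", "CT", "mPET", "aPET")


def suvr_to_centiloid(suvr):
    """CL = 121.42 * SUVR - 121.16 (exact affine map)."""
    return CL_SLOPE * np.asarray(suvr, dtype=np.float64) + CL_INTERCEPT


def centiloid_to_suvr(cl):
    """Exact inverse of :func:`suvr_to_centiloid` (total on the reals)."""
    return (np.asarray(cl, dtype=np.float64) - CL_INTERCEPT) / CL_SLOPE


@dataclass
class VOISet:
    """Named binary masks on the template grid (target CTX, reference WhlCbl)."""

    masks: Dict[str, Volume]

    def __post_init__(self) -> None:
        for name, m in self.masks.items():
            vals = np.unique(m.data)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ContractViolation(f"VOI {name!r} is not binary")
            if m.modality != "MASK":
                raise ContractViolation(f"VOI {name!r} must have MASK modality")

    def __getitem__(self, name: str) -> Volume:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    @property
    def names(self):
        return list(self.masks)


@dataclass
class QuantResult:
    """One subject x route quantification record."""

    subject_id: str
    route: str
    suvr: float
    cl: float
    template_used: str = "none"
    provisional_cl: Optional[float] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ContractViolation(f"unknown route {self.route!r}")
        if not self.suvr > 0:
            raise ContractViolation(f"SUVR must be positive, got {self.suvr}")
        if abs(self.cl - float(suvr_to_centiloid(self.suvr))) > 1e-9:
            raise ContractViolation("cl does not match 121.42*suvr - 121.16")
        if self.template_used not in ("none", "mean", "positive", "negative"):
            raise ContractViolation(f"unknown template {self.template_used!r}")


def compute_suvr(
    pet_tmpl: Volume, vois: VOISet, target: str = "CTX", reference: str = "WhlCbl"
) -> float:
    """Mean uptake over the target mask divided by mean over the reference.

    Masks are binary and unweighted; the PET volume must live on the VOI
    grid in the template frame.
    """
    tgt, ref = vois[target], vois[reference]
    if not (pet_tmpl.same_grid(tgt) and pet_tmpl.same_grid(ref)):
        raise ContractViolation("PET volume and VOI masks are on different grids")
    if pet_tmpl.frame != "template":
        raise ContractViolation("compute_suvr requires a template-frame PET")
    tmask = tgt.data > 0.5
    rmask = ref.data > 0.5
    if not tmask.any() or not rmask.any():
        raise QuantificationError("empty VOI mask")
    ref_mean = float(pet_tmpl.data[rmask].mean())
    if ref_mean <= 0:
        raise QuantificationError(f"non-positive reference mean ({ref_mean})")
    return float(pet_tmpl.data[tmask].mean()) / ref_mean


def make_result(subject_id: str, route: str, suvr: float, **kwargs) -> QuantResult:
    return QuantResult(
        subject_id=subject_id,
        route=route,
        suvr=float(suvr),
        cl=float(suvr_to_centiloid(suvr)),
        **kwargs,
    )


def quantify_adaptive(
    pet: Volume,
    templates: Dict[str, Volume],
    vois: VOISet,
    cutoff: float = POSITIVITY_CUTOFF_CL,
    subject_id: str = "",
) -> QuantResult:
    """Adaptive-atlas quantification (route ``aPET``).

    Two-pass rule: normalize with the *negative* template and compute a
    provisional CL; if it is at or above the positivity cutoff (CL 16),
    re-normalize with the *positive* template and report that result,
    otherwise keep the negative-template result. The provisional CL is
    always recorded.
    """
    from .spatial_normalization import normalize_pet_only

    for key in ("negative", "positive"):
        if key not in templates:
            raise ContractViolation(f"adaptive quantification needs a {key!r} template")

    pet_neg = normalize_pet_only(pet, templates["negative"])
    provisional_suvr = compute_suvr(pet_neg, vois)
    provisional_cl = float(suvr_to_centiloid(provisional_suvr))
    if provisional_cl >= cutoff:
        pet_pos = normalize_pet_only(pet, templates["positive"])
        suvr = compute_suvr(pet_pos, vois)
        used = "positive"
    else:
        suvr = provisional_suvr
        used = "negative"
    return make_result(
        subject_id,
        "aPET",
        suvr,
        template_used=used,
        provisional_cl=provisional_cl,
    )
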