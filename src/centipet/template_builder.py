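"""PET-only normalization atlases built from normalized PET cohorts.

The mean atlas averages amyloid-positive and amyloid-negative subjects
together; the adaptive-atlas pair keeps the two groups separate so the
normalization target can match the subject's binding pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np

from .errors import ContractViolation, DomainError
from .image_core import Volume


@dataclass
class CohortRecord:
    """Summary of the Centiloid tags of the volumes averaged into an atlas."""

    n: int
    mean_cl: float
    sd_cl: float

    def to_dict(self) -> dict:
        return {"n": self.n, "mean_cl": self.mean_cl, "sd_cl": self.sd_cl}


def build_atlas(volumes: Sequence[Volume], cl_tags: Sequence[float]):
    """Voxel-wise arithmetic mean of template-frame PET volumes.

    Returns the atlas Volume plus a :class:`CohortRecord` computed from the
    supplied per-volume CL tags (SD with N-1 normalization; 0 for n < 2
    would be ill-defined, so at least two volumes are required).
    """
    volumes = list(volumes)
    cl_tags = [float(c) for c in cl_tags]
    if len(volumes) < 2:
        raise ContractViolation("build_atlas needs at least 2 volumes")
    if len(volumes) != len(cl_tags):
        raise ContractViolation("each volume needs a CL tag")
    first = volumes[0]
    for v in volumes[1:]:
        if not v.same_grid(first):
            raise ContractViolation("atlas inputs must share one grid")
    # sort addends voxel-wise so the average is bitwise permutation-invariant
    stack = np.sort(np.stack([v.data for v in volumes]), axis=0)
    mean = stack.sum(axis=0) / len(volumes)
    atlas = Volume(mean, first.affine.copy(), modality="PET", frame="template")
    record = CohortRecord(
        n=len(volumes),
        mean_cl=float(np.mean(cl_tags)),
        sd_cl=float(np.std(cl_tags, ddof=1)),
    )
    return atlas, record


def save_atlas(atlas: Volume, record: CohortRecord, path) -> None:
    """Write the atlas as NIfTI plus a sidecar JSON cohort record."""
    import json
    from pathlib import Path

    from .image_core import write_volume

    path = Path(path)
    write_volume(atlas, path)
    sidecar = path.with_name(path.name.split(".")[0] + ".json")
    sidecar.write_text(json.dumps(record.to_dict(), indent=2))


def pooled_cohort_mean(groups: List[Dict[str, float]]) -> float:
    """Size-weighted mean of group means: sum(n_i m_i) / sum(n_i)."""
    if not groups:
        raise DomainError("pooled_cohort_mean needs at least one group")
    n_total = 0.0
    acc = 0.0
    for g in groups:
        n = float(g["n"])
        if n < 1:
            raise DomainError("group sizes must be >= 1")
        n_total += n
        acc += n * float(g["mean"])
    return acc / n_total


def pooled_cohort_sd(groups: List[Dict[str, float]]) -> float:
    """Mixture SD of group summaries with N-1 normalization.

    Informational output: reconstructing a pooled SD from rounded printed
    subgroup summaries does not in general recover the printed pooled SD
    to its last digit.
    """
    if not groups:
        raise DomainError("pooled_cohort_sd needs at least one group")
    n_total = sum(float(g["n"]) for g in groups)
    grand = pooled_cohort_mean(groups)
    ss = 0.0
    for g in groups:
        n, m, sd = float(g["n"]), float(g["mean"]), float(g.get("sd", 0.0))
        ss += (n - 1) * sd**2 + n * (m - grand) ** 2
    return float(np.sqrt(ss / (n_total - 1)))
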