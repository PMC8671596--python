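"""Voxel-wise paired t-maps and cluster-extent reporting.

Two normalized, smoothed PET stacks (paired by index) are compared voxel
by voxel with a paired t-test inside a brain mask; the resulting t-map is
thresholded one-sided at an uncorrected p-value and connected components
(26-connectivity) smaller than an extent threshold are discarded —
the standard uncorrected-p / cluster-extent reporting convention.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .errors import ContractViolation
from .image_core import Volume, gaussian_smooth

DEFAULT_P = 0.001
DEFAULT_EXTENT = 300
DIRECTIONS = ("A_gt_B", "B_gt_A")


def paired_t_map(
    stack_a: Sequence[Volume],
    stack_b: Sequence[Volume],
    fwhm_mm: float = 8.0,
    mask: Optional[np.ndarray] = None,
) -> Volume:
    """Voxel-wise paired t statistic of (a - b) after Gaussian smoothing.

    ``fwhm_mm=0`` skips smoothing. Voxels with zero difference variance get
    t = 0; voxels outside the mask are 0.
    """
    stack_a, stack_b = list(stack_a), list(stack_b)
    if len(stack_a) != len(stack_b):
        raise ContractViolation("stacks must have equal length (paired)")
    n = len(stack_a)
    if n < 3:
        raise ContractViolation("paired t-map needs at least 3 pairs")
    grid = stack_a[0]
    for v in stack_a + stack_b:
        if not v.same_grid(grid):
            raise ContractViolation("all volumes must share one grid")

    diffs = np.empty((n,) + grid.shape)
    for i, (a, b) in enumerate(zip(stack_a, stack_b)):
        if fwhm_mm > 0:
            a = gaussian_smooth(a, fwhm_mm)
            b = gaussian_smooth(b, fwhm_mm)
        diffs[i] = a.data - b.data

    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    if mask is not None:
        t = np.where(mask, t, 0.0)
    return Volume(t, grid.affine.copy(), modality="TMAP", frame=grid.frame)


def threshold_clusters(
    tmap: Volume,
    df: int,
    p_threshold: float = DEFAULT_P,
    extent: int = DEFAULT_EXTENT,
    direction: str = "A_gt_B",
) -> pd.DataFrame:
    """Supra-threshold clusters of a t-map, one-sided, 26-connected.

    Returns a table with one row per surviving cluster: voxel count, peak
    t value and the world-mm coordinates of the peak voxel, sorted by
    cluster size descending.
    """
    if df < 2:
        raise ContractViolation("df must be >= 2")
    if direction not in DIRECTIONS:
        raise ContractViolation(f"direction must be one of {DIRECTIONS}")
    cutoff = float(sps.t.isf(p_threshold, df))
    signed = tmap.data if direction == "A_gt_B" else -tmap.data
    supra = signed > cutoff
    labels, n_labels = ndimage.label(supra, structure=np.ones((3, 3, 3)))
    rows: List[dict] = []
    for lab in range(1, n_labels + 1):
        idx = np.nonzero(labels == lab)
        size = idx[0].size
        if size < extent:
            continue
        vals = signed[idx]
        peak = int(np.argmax(vals))
        peak_vox = np.array([[idx[0][peak]], [idx[1][peak]], [idx[2][peak]]],
                            dtype=np.float64)
        xyz = tmap.voxel_to_world(peak_vox).ravel()
        rows.append(
            {
                "cluster_size": int(size),
                "peak_t": float(vals[peak]),  # magnitude in the tested direction
                "peak_x": float(xyz[0]),
                "peak_y": float(xyz[1]),
                "peak_z": float(xyz[2]),
                "direction": direction,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["cluster_size", "peak_t", "peak_x", "peak_y", "peak_z",
                 "direction"],
    )
    if len(table):
        table = table.sort_values(
            "cluster_size", ascending=False, kind="mergesort"
        ).reset_index(drop=True)
    return table


def cluster_table(
    tmap: Volume,
    df: int,
    p_threshold: float = DEFAULT_P,
    extent: int = DEFAULT_EXTENT,
) -> pd.DataFrame:
    """Both one-sided cluster tables (A>B and B>A) concatenated."""
    parts = [
        threshold_clusters(tmap, df, p_threshold, extent, direction)
        for direction in DIRECTIONS
    ]
    non_empty = [p for p in parts if len(p)]
    if not non_empty:
        return parts[0]
    return pd.concat(non_empty, ignore_index=True)
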