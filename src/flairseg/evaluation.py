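"""Segmentation evaluation: overlap, surface distances, volumes, and
small-lesion counting.

Surface distances use border voxels (mask voxels with at least one
non-mask face neighbor), distances in mm under anisotropic spacing;
ASD is the symmetric mean of the two directed mean border-to-border
distances and HD the full (100th percentile) Hausdorff, matching the
conventions of the public stroke-lesion segmentation challenges.

Small-lesion counting: connected components under 26-connectivity;
a manual component smaller than 1 mL counts as detected (TP) when at
least three of its voxels are auto-segmented, and an automatic
component smaller than 1 mL counts as a false positive when it covers
fewer than three manually segmented voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from .volume import LabelMap

#: "Small" lesion component threshold, millilitres.
SMALL_LESION_ML = 1.0
#: Minimum segmented voxels inside a component for TP / against FP status.
MIN_VOXELS = 3


def _binary(mask: LabelMap) -> np.ndarray:
    return mask.labels > 0


def _check_grids(a: LabelMap, b: LabelMap) -> None:
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")


def overlap_metrics(auto: LabelMap, manual: LabelMap):
    """(Dice, PPV, sensitivity) of the automatic vs. the manual mask.

    Empty-set conventions: Dice(empty, empty) = 1; PPV is None for an
    empty automatic mask, sensitivity None for an empty manual mask.
    """
    _check_grids(auto, manual)
    a = _binary(auto)
    m = _binary(manual)
    tp = int(np.count_nonzero(a & m))
    na, nm = int(a.sum()), int(m.sum())
    dice = 1.0 if na + nm == 0 else 2.0 * tp / (na + nm)
    ppv = None if na == 0 else tp / na
    sensitivity = None if nm == 0 else tp / nm
    return dice, ppv, sensitivity


def _border_coords(mask: np.ndarray, spacing) -> np.ndarray:
    face = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask, structure=face, border_value=0)
    border = mask & ~interior
    coords = np.argwhere(border).astype(np.float64)
    return coords * np.asarray(spacing)


def surface_distances(auto: LabelMap, manual: LabelMap, spacing=None):
    """(ASD, Hausdorff) in mm between the borders of two nonempty masks."""
    _check_grids(auto, manual)
    spacing = auto.spacing if spacing is None else spacing
    a = _binary(auto)
    m = _binary(manual)
    if not a.any() or not m.any():
        raise ValueError("surface distances require two nonempty masks")
    pa = _border_coords(a, spacing)
    pm = _border_coords(m, spacing)
    d_am, _ = cKDTree(pm).query(pa)
    d_ma, _ = cKDTree(pa).query(pm)
    asd = 0.5 * (float(d_am.mean()) + float(d_ma.mean()))
    hd = max(float(d_am.max()), float(d_ma.max()))
    return asd, hd


def volume_ml(mask: LabelMap, spacing=None) -> float:
    """Mask volume in millilitres."""
    spacing = mask.spacing if spacing is None else spacing
    dx, dy, dz = spacing
    return float(np.count_nonzero(mask.labels > 0)) * dx * dy * dz / 1000.0


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("spearman_rho needs two equal-length lists of >= 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank variance is zero")
    rho, _ = spearmanr(x, y)
    return float(rho)


def _components(mask: np.ndarray):
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    lab, n = ndimage.label(mask, structure=structure)
    return lab, n


def small_lesion_counts(auto: LabelMap, manual: LabelMap, spacing=None):
    """Small-component detection counts: (n_small, n_tp, n_fp).

    ``n_small`` is the number of manual components below 1 mL; ``n_tp``
    how many of them contain at least 3 auto-segmented voxels; ``n_fp``
    the number of sub-1-mL automatic components containing fewer than 3
    manually segmented voxels.
    """
    _check_grids(auto, manual)
    spacing = auto.spacing if spacing is None else spacing
    vox_ml = spacing[0] * spacing[1] * spacing[2] / 1000.0
    a = _binary(auto)
    m = _binary(manual)

    man_lab, n_man = _components(m)
    n_small = n_tp = 0
    for comp in range(1, n_man + 1):
        sel = man_lab == comp
        if sel.sum() * vox_ml >= SMALL_LESION_ML:
            continue
        n_small += 1
        if int(np.count_nonzero(a & sel)) >= MIN_VOXELS:
            n_tp += 1

    auto_lab, n_auto = _components(a)
    n_fp = 0
    for comp in range(1, n_auto + 1):
        sel = auto_lab == comp
        if sel.sum() * vox_ml >= SMALL_LESION_ML:
            continue
        if int(np.count_nonzero(m & sel)) < MIN_VOXELS:
            n_fp += 1
    return n_small, n_tp, n_fp


@dataclass
class CaseMetrics:
    """Per-case evaluation summary."""

    case: str
    dice: float
    ppv: float | None
    sensitivity: float | None
    asd_mm: float | None
    hd_mm: float | None
    vol_manual_ml: float
    vol_auto_ml: float

    @classmethod
    def compute(cls, case: str, auto: LabelMap, manual: LabelMap) -> "CaseMetrics":
        dice, ppv, sens = overlap_metrics(auto, manual)
        if (auto.labels > 0).any() and (manual.labels > 0).any():
            asd, hd = surface_distances(auto, manual)
        else:
            asd = hd = None
        return cls(
            case=case,
            dice=dice,
            ppv=ppv,
            sensitivity=sens,
            asd_mm=asd,
            hd_mm=hd,
            vol_manual_ml=volume_ml(manual),
            vol_auto_ml=volume_ml(auto),
        )
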