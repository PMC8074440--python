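"""Segmentation-agreement metrics and parameter-agreement statistics.

Geometric metrics (Dice, Hausdorff distance, mean surface distance) are
computed in 3D on physical coordinates.  Surfaces are the structure
voxels with at least one face-adjacent non-structure neighbor (array
borders count as outside); distances are measured between boundary
voxel centers with anisotropic spacing applied.

Parameter agreement follows the convention of reporting Pearson's R,
mean errors — absolute differences for percentage-based parameters (EF,
scar %), absolute relative differences for numerical ones — and
Bland–Altman bias with ±1.96 sd limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from cmrseg.core import LabelMask

#: parameters whose errors are absolute differences (all others relative)
PERCENTAGE_PARAMS = frozenset(
    {"lv_ef_pct", "rv_ef_pct", "scar_pct", "ef", "ef_pct", "scar"}
)


# ---------------------------------------------------------------------------
# geometric metrics


def _binary(mask: LabelMask | np.ndarray, label: int) -> np.ndarray:
    arr = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    return arr == label


def _check_grids(a, b) -> None:
    arr_a = a.labels if isinstance(a, LabelMask) else np.asarray(a)
    arr_b = b.labels if isinstance(b, LabelMask) else np.asarray(b)
    if arr_a.shape != arr_b.shape:
        raise ValueError("grid mismatch")
    if isinstance(a, LabelMask) and isinstance(b, LabelMask):
        if (
            a.in_plane_spacing_mm != b.in_plane_spacing_mm
            or a.slice_thickness_mm != b.slice_thickness_mm
        ):
            raise ValueError("grid mismatch: spacings differ")


def dice3d(a: LabelMask | np.ndarray, b: LabelMask | np.ndarray, label: int) -> float:
    """Dice overlap ``2|A∩B| / (|A|+|B|)``; both-empty -> 1, one-empty -> 0."""
    _check_grids(a, b)
    abin, bbin = _binary(a, label), _binary(b, label)
    na, nb = int(abin.sum()), int(bbin.sum())
    if na == 0 and nb == 0:
        return 1.0
    return 2.0 * int((abin & bbin).sum()) / (na + nb)


def boundary_voxels(binary: np.ndarray) -> np.ndarray:
    """Structure voxels with >= 1 face-adjacent outside neighbor."""
    if binary.ndim != 3:
        raise ValueError("boundary extraction expects a 3D volume")
    structure = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(binary, structure=structure, border_value=0)
    return binary & ~interior


def _surface_points_mm(binary: np.ndarray, spacing: tuple[float, float, float]) -> np.ndarray:
    pts = np.argwhere(boundary_voxels(binary)).astype(np.float64)
    pts *= np.asarray(spacing)
    return pts


def _surface_distances(
    a, b, label: int, spacing_mm: Optional[tuple[float, float, float]]
) -> Optional[tuple[np.ndarray, np.ndarray]]:
    _check_grids(a, b)
    if spacing_mm is None:
        if not isinstance(a, LabelMask):
            raise ValueError("spacing required for plain arrays")
        spacing_mm = (
            a.slice_thickness_mm,
            a.in_plane_spacing_mm[0],
            a.in_plane_spacing_mm[1],
        )
    abin, bbin = _binary(a, label), _binary(b, label)
    if not abin.any() or not bbin.any():
        return None
    pa = _surface_points_mm(abin, spacing_mm)
    pb = _surface_points_mm(bbin, spacing_mm)
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return d_ab, d_ba


def hausdorff3d(
    a: LabelMask | np.ndarray,
    b: LabelMask | np.ndarray,
    label: int,
    spacing_mm: Optional[tuple[float, float, float]] = None,
) -> float:
    """Symmetric Hausdorff distance (mm) between boundary voxel sets.

    NaN (metric missing) when either side lacks the structure."""
    d = _surface_distances(a, b, label, spacing_mm)
    if d is None:
        return float("nan")
    return float(max(d[0].max(), d[1].max()))


def mean_surface_distance(
    a: LabelMask | np.ndarray,
    b: LabelMask | np.ndarray,
    label: int,
    spacing_mm: Optional[tuple[float, float, float]] = None,
) -> float:
    """Symmetric mean surface distance (mm): average of the two directed
    boundary-to-boundary mean distances.  NaN when either side is empty."""
    d = _surface_distances(a, b, label, spacing_mm)
    if d is None:
        return float("nan")
    return float((d[0].mean() + d[1].mean()) / 2.0)


@dataclass
class StructureEval:
    """Per-structure segmentation agreement."""

    label: int
    dice: float
    hd_mm: float
    msd_mm: float
    n_voxels_a: int
    n_voxels_b: int


def evaluate_structures(
    pred: LabelMask, truth: LabelMask, labels: Optional[list[int]] = None
) -> list[StructureEval]:
    """Dice/HD/MSD per structure.  Temporal stacks: Dice over all frames,
    HD as the max and MSD as the mean over per-frame 3D surfaces."""
    _check_grids(pred, truth)
    if labels is None:
        labels = sorted((set(pred.kind.legal_labels) - {0}))
    out = []
    for lab in labels:
        dice = dice3d(pred, truth, lab)
        if pred.has_time:
            hds, msds = [], []
            for f in range(pred.n_frames):
                pa, ta = pred.frame(f), truth.frame(f)
                spacing = (
                    pred.slice_thickness_mm,
                    pred.in_plane_spacing_mm[0],
                    pred.in_plane_spacing_mm[1],
                )
                hds.append(hausdorff3d(pa, ta, lab, spacing))
                msds.append(mean_surface_distance(pa, ta, lab, spacing))
            hds, msds = np.asarray(hds), np.asarray(msds)
            hd = float(np.nanmax(hds)) if not np.all(np.isnan(hds)) else float("nan")
            msd = float(np.nanmean(msds)) if not np.all(np.isnan(msds)) else float("nan")
        else:
            hd = hausdorff3d(pred, truth, lab)
            msd = mean_surface_distance(pred, truth, lab)
        out.append(
            StructureEval(
                label=lab,
                dice=dice,
                hd_mm=hd,
                msd_mm=msd,
                n_voxels_a=int(_binary(pred, lab).sum()),
                n_voxels_b=int(_binary(truth, lab).sum()),
            )
        )
    return out


# ---------------------------------------------------------------------------
# parameter agreement


@dataclass
class AgreementStats:
    """Pearson R, mean error and Bland–Altman summary of paired values."""

    pearson_r: Optional[float]
    mean_error: float
    bias: float
    loa_low: float
    loa_high: float
    n: int
    error_rule: str  # "absolute" or "relative"


def agreement(auto: np.ndarray, ref: np.ndarray, param: str) -> AgreementStats:
    """Agreement between automatic and reference parameter vectors.

    Percentage-based parameters (EF, scar %) use mean absolute
    differences; numerical parameters use mean absolute relative
    differences, reported in percent.  Bland–Altman limits are
    ``bias ± 1.96 sd`` of the differences.  Pearson's R is omitted
    (None) when either vector has zero variance.
    """
    auto = np.asarray(auto, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if auto.shape != ref.shape or auto.ndim != 1:
        raise ValueError("paired 1D vectors required")
    if auto.size < 3:
        raise ValueError("need >= 3 pairs")
    is_pct = param.lower() in PERCENTAGE_PARAMS or param.lower().endswith(("_pct", "_percent"))
    diff = auto - ref
    if is_pct:
        mean_error = float(np.abs(diff).mean())
        rule = "absolute"
    else:
        nonzero = ref != 0
        if not nonzero.any():
            raise ValueError("relative error undefined: all reference values zero")
        mean_error = float((np.abs(diff[nonzero] / ref[nonzero])).mean() * 100.0)
        rule = "relative"
    if np.std(auto) == 0 or np.std(ref) == 0:
        r = None
    else:
        r = float(pearsonr(auto, ref)[0])
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementStats(
        pearson_r=r,
        mean_error=mean_error,
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=int(auto.size),
        error_rule=rule,
    )
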