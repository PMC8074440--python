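"""Clinical parameter extraction from final label masks.

Volumes are voxel summations (equivalent to slice-wise Simpson
summation on these per-slice masks).  LV mass uses the conventional
myocardial density of 1.05 g/mL at end-diastole.  The scar percentage
counts scar as diseased myocardium, i.e. the denominator is
myocardium + scar.  Flow amplitudes integrate through-plane velocity
over the segmented aorta: ``Q_f = sum_px v * a``; net flow is
``sum_f Q_f * dt`` and backward flow the magnitude of the negative
per-frame contributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.filters import threshold_otsu

from cmrseg.core import (
    AORTA,
    LV_CAVITY,
    LV_MYO,
    RV_CAVITY,
    SCAR,
    ImageStack,
    LabelMask,
    SequenceKind,
)

MYOCARDIAL_DENSITY_G_PER_ML = 1.05


@dataclass
class CardiacParams:
    """The extracted clinical measurements of one subject/sequence."""

    kind: SequenceKind
    lv_edv_ml: Optional[float] = None
    lv_esv_ml: Optional[float] = None
    lv_sv_ml: Optional[float] = None
    lv_ef_pct: Optional[float] = None
    lv_mass_g: Optional[float] = None
    rv_edv_ml: Optional[float] = None
    rv_esv_ml: Optional[float] = None
    rv_sv_ml: Optional[float] = None
    rv_ef_pct: Optional[float] = None
    ed_frame: Optional[int] = None
    es_frame: Optional[int] = None
    scar_pct: Optional[float] = None
    mean_t1_ms: Optional[float] = None
    mean_t1post_ms: Optional[float] = None
    mean_t2_ms: Optional[float] = None
    net_flow_ml: Optional[float] = None
    backward_flow_ml: Optional[float] = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {"kind": self.kind.value}
        for k, v in self.__dict__.items():
            if k in ("kind", "warnings") or v is None:
                continue
            out[k] = int(v) if k in ("ed_frame", "es_frame") else float(v)
        if self.warnings:
            out["warnings"] = list(self.warnings)
        return out


# ---------------------------------------------------------------------------
# primitives


def structure_volume(mask: LabelMask, label: int, frame: Optional[int] = None) -> float:
    """Volume of ``label`` in mL: voxel count x voxel volume."""
    labels = mask.frame(frame) if (mask.has_time and frame is not None) else mask.labels
    return float((labels == label).sum() * mask.voxel_volume_mm3 / 1000.0)


def volume_per_frame(mask: LabelMask, label: int) -> np.ndarray:
    if not mask.has_time:
        return np.array([structure_volume(mask, label)])
    return np.array([structure_volume(mask, label, f) for f in range(mask.n_frames)])


def find_ed_es(mask: LabelMask) -> tuple[int, int]:
    """ED = frame of maximum LV-cavity volume, ES = minimum; ties ->
    earliest frame."""
    if not mask.has_time:
        raise ValueError("ED/ES detection needs a temporal stack")
    vols = volume_per_frame(mask, LV_CAVITY)
    if not np.any(vols > 0):
        raise ValueError("LV cavity empty on every frame")
    return int(np.argmax(vols)), int(np.argmin(vols))


def ejection_fraction(edv_ml: float, esv_ml: float) -> float:
    """``100 * (EDV - ESV) / EDV``; ESV > EDV clamps to 0 with a warning."""
    if edv_ml <= 0:
        raise ValueError("EDV must be positive")
    if esv_ml > edv_ml:
        warnings.warn("ESV exceeds EDV; EF clamped to 0", stacklevel=2)
        return 0.0
    return 100.0 * (edv_ml - esv_ml) / edv_ml


def lv_mass(mask: LabelMask, frame: Optional[int] = None) -> float:
    """Myocardial mass in grams: myocardium volume x 1.05 g/mL.

    For temporal stacks pass the ED frame."""
    myo_ml = structure_volume(mask, LV_MYO, frame)
    scar_ml = structure_volume(mask, SCAR, frame) if SCAR in mask.kind.legal_labels else 0.0
    return (myo_ml + scar_ml) * MYOCARDIAL_DENSITY_G_PER_ML


def scar_percentage(mask: LabelMask) -> float:
    """Scar volume as a percentage of total myocardium (healthy + scar)."""
    myo = structure_volume(mask, LV_MYO)
    scar = structure_volume(mask, SCAR)
    if myo + scar == 0:
        raise ValueError("empty myocardium")
    return 100.0 * scar / (myo + scar)


def otsu_scar_from_intensity(image: np.ndarray, myo_mask: np.ndarray) -> np.ndarray:
    """Scar mask by Otsu thresholding within the myocardium.

    Hyperenhanced (bright) pixels above the Otsu threshold of the
    within-myocardium intensity histogram are labeled scar."""
    image = np.asarray(image)
    myo_mask = np.asarray(myo_mask, dtype=bool)
    if image.shape != myo_mask.shape:
        raise ValueError("image / mask shape mismatch")
    values = image[myo_mask]
    if values.size == 0 or np.unique(values).size < 2:
        raise ValueError("Otsu thresholding needs >= 2 distinct myocardial intensities")
    thr = threshold_otsu(values)
    return myo_mask & (image > thr)


def map_mean(image: np.ndarray, myo_mask: np.ndarray) -> float:
    """Arithmetic mean of raw map values (ms) over myocardium voxels."""
    myo_mask = np.asarray(myo_mask, dtype=bool)
    if not myo_mask.any():
        raise ValueError("empty myocardium")
    return float(np.asarray(image)[myo_mask].mean())


def flow_amplitudes(
    velocity: np.ndarray,
    aorta_mask: np.ndarray,
    pixel_area_mm2: float,
    frame_duration_ms: Optional[float],
) -> tuple[float, float]:
    """Net and backward aortic flow in mL.

    ``velocity`` (cm/s) and ``aorta_mask`` are ``[frame, ...]`` on the
    same grid; each frame's flux is ``Q_f = sum_px v * a`` and the net /
    backward amplitudes integrate positive-signed / negative-only flux
    over the cycle."""
    if frame_duration_ms is None:
        raise ValueError("frame duration required for flow integration")
    velocity = np.asarray(velocity, dtype=np.float64)
    aorta_mask = np.asarray(aorta_mask, dtype=bool)
    if velocity.shape != aorta_mask.shape:
        raise ValueError("velocity / mask shape mismatch")
    area_cm2 = pixel_area_mm2 / 100.0
    dt_s = frame_duration_ms / 1000.0
    q = np.array([velocity[f][aorta_mask[f]].sum() * area_cm2 for f in range(velocity.shape[0])])
    net = float((q * dt_s).sum())
    backward = float(abs((np.minimum(q, 0.0) * dt_s).sum()))
    return net, backward


# ---------------------------------------------------------------------------
# per-kind dispatch


def extract_params(stack: ImageStack, mask: LabelMask) -> CardiacParams:
    """All clinical parameters a sequence kind supports, from its mask.

    ``stack`` supplies intensities (map values, velocities); ``mask`` the
    anatomy.  Both must share kind and grid."""
    if stack.kind is not mask.kind:
        raise ValueError("stack and mask kinds differ")
    if stack.voxels.shape != mask.labels.shape:
        raise ValueError("stack and mask grids differ")
    kind = stack.kind
    p = CardiacParams(kind=kind)

    if kind is SequenceKind.CINE:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            ed, es = find_ed_es(mask)
            p.ed_frame, p.es_frame = ed, es
            p.lv_edv_ml = structure_volume(mask, LV_CAVITY, ed)
            p.lv_esv_ml = structure_volume(mask, LV_CAVITY, es)
            p.lv_sv_ml = p.lv_edv_ml - p.lv_esv_ml
            p.lv_ef_pct = ejection_fraction(p.lv_edv_ml, p.lv_esv_ml)
            p.lv_mass_g = lv_mass(mask, ed)
            rv = volume_per_frame(mask, RV_CAVITY)
            if np.any(rv > 0):
                p.rv_edv_ml = float(rv.max())
                p.rv_esv_ml = float(rv.min())
                p.rv_sv_ml = p.rv_edv_ml - p.rv_esv_ml
                p.rv_ef_pct = ejection_fraction(p.rv_edv_ml, p.rv_esv_ml)
            p.warnings.extend(str(w.message) for w in caught)
    elif kind is SequenceKind.LGE:
        p.scar_pct = scar_percentage(mask)
        p.lv_mass_g = lv_mass(mask)
    elif kind.is_map:
        myo = mask.labels == LV_MYO
        value = map_mean(stack.voxels, myo)
        if kind is SequenceKind.T1_NATIVE:
            p.mean_t1_ms = value
        elif kind is SequenceKind.T1_POST:
            p.mean_t1post_ms = value
        else:
            p.mean_t2_ms = value
    elif kind is SequenceKind.FLOW:
        p.net_flow_ml, p.backward_flow_ml = flow_amplitudes(
            stack.voxels,
            mask.labels == AORTA,
            stack.pixel_area_mm2,
            stack.frame_duration_ms,
        )
    return p
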