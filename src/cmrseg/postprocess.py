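"""From per-slice softmax maps to a clean 3D label mask.

Fixed pipeline order: argmax -> inverse resample & stack -> largest
connected component -> convex-hull regularization -> Random-Forest
rejection of over-segmented slices (LGE and relaxation maps only).

The Random Forest (6 trees, depth 6) classifies each slice from three
features: mean softmax of the predicted myocardium, its mean normalized
intensity, and the normalized slice position in the stack.  Slices
classified as spurious are cleared to background; slices with no
predicted myocardium at all are cleared without consulting the forest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image
from sklearn.ensemble import RandomForestClassifier

from cmrseg.core import (
    AORTA,
    BACKGROUND,
    LV_CAVITY,
    LV_MYO,
    SCAR,
    ImageStack,
    LabelMask,
    SequenceKind,
    class_to_label,
)
from cmrseg.preprocess import ResampleRecord, from_network_grid, to_network_grid


# ---------------------------------------------------------------------------
# argmax and stacking


def argmax_labels(softmax_map: np.ndarray, kind: Optional[SequenceKind] = None) -> np.ndarray:
    """Per-pixel class of maximum probability; ties -> lowest class index.

    ``softmax_map`` is ``(n_classes, H, W)``.  With ``kind`` given, class
    indices are mapped to codebook labels.
    """
    softmax_map = np.asarray(softmax_map)
    if softmax_map.ndim != 3:
        raise ValueError("softmax map must be (n_classes, H, W)")
    cls = softmax_map.argmax(axis=0)
    if kind is None:
        return cls
    lut = np.asarray(class_to_label(kind), dtype=np.int16)
    return lut[cls]


def stack_to_3d(
    slice_labels: Sequence[np.ndarray],
    records: Sequence[ResampleRecord],
    kind: SequenceKind,
    slice_thickness_mm: float,
    frame_duration_ms: Optional[float] = None,
) -> LabelMask:
    """Inverse-resample per-slice label maps and stack them into a 3D mask."""
    if len(slice_labels) != len(records):
        raise ValueError("one resample record per slice required")
    shapes = {r.original_shape for r in records}
    spacings = {r.original_spacing_mm for r in records}
    if len(shapes) != 1 or len(spacings) != 1:
        raise ValueError("inconsistent slice grids")
    planes = [from_network_grid(lab, rec) for lab, rec in zip(slice_labels, records)]
    labels = np.stack(planes).astype(np.int16)
    if kind.is_temporal:
        labels = labels[None]  # single-frame temporal stack
    return LabelMask(
        labels=labels,
        in_plane_spacing_mm=spacings.pop(),
        slice_thickness_mm=slice_thickness_mm,
        kind=kind,
        frame_duration_ms=frame_duration_ms,
    )


# ---------------------------------------------------------------------------
# geometric cleanup


def _keep_largest_binary(binary: np.ndarray, structure: np.ndarray) -> np.ndarray:
    labeled, n = ndimage.label(binary, structure=structure)
    if n <= 1:
        return binary
    sizes = np.bincount(labeled.ravel())[1:]
    best = sizes.max()
    candidates = np.flatnonzero(sizes == best) + 1
    if len(candidates) == 1:
        keep = candidates[0]
    else:
        # tie-break: component whose first voxel in scan order (lexico-
        # graphically smallest index) comes first
        flat = labeled.ravel()
        keep = min(candidates, key=lambda c: int(np.argmax(flat == c)))
    return labeled == keep


def largest_component(mask: LabelMask, label: int) -> LabelMask:
    """Keep only the largest connected component of ``label``.

    26-connectivity in 3D, applied per frame for temporal stacks; the
    aorta (single-plane flow acquisitions) uses 8-connectivity in 2D.
    """
    if label not in mask.kind.legal_labels:
        raise ValueError(f"label {label} illegal for kind {mask.kind.value}")
    out = mask.labels.copy()
    frames = out if mask.has_time else out[None]
    for fr in frames:
        binary = fr == label
        if not binary.any():
            continue
        if label == AORTA:
            for z in range(fr.shape[0]):
                plane = binary[z]
                if plane.any():
                    kept = _keep_largest_binary(plane, np.ones((3, 3), dtype=bool))
                    fr[z][plane & ~kept] = BACKGROUND
        else:
            kept = _keep_largest_binary(binary, np.ones((3, 3, 3), dtype=bool))
            fr[binary & ~kept] = BACKGROUND
    return mask.with_labels(out)


def _hull(binary2d: np.ndarray) -> np.ndarray:
    if not binary2d.any():
        return binary2d
    # pixel-center vertices make the hull exactly idempotent
    return convex_hull_image(binary2d, offset_coordinates=False)


def convexify(mask: LabelMask) -> LabelMask:
    """Convex-hull regularization, per 2D slice.

    The endocardial contour becomes the hull of the cavity; the
    epicardial contour becomes the hull of cavity plus myocardium (plus
    scar, which is part of the muscle); the myocardium is the epicardial
    hull minus the cavity hull — an annulus itself is not convex, so
    convexity is imposed on its two contours.  Scar is exempt from
    hulling but clipped to the final myocardium.  The aorta is hulled
    directly.  Empty structures pass through.
    """
    out = mask.labels.copy()
    frames = out if mask.has_time else out[None]
    for fr in frames:
        for z in range(fr.shape[0]):
            plane = fr[z]
            if mask.kind is SequenceKind.FLOW:
                hull = _hull(plane == AORTA)
                plane[hull] = AORTA
                continue
            cav = plane == LV_CAVITY
            myo = (plane == LV_MYO) | (plane == SCAR)
            if not (cav.any() or myo.any()):
                continue
            cav_hull = _hull(cav)
            epi_hull = _hull(cav | myo)
            scar = plane == SCAR
            ring = epi_hull & ~cav_hull
            plane[epi_hull] = LV_MYO
            plane[cav_hull] = LV_CAVITY
            plane[ring & scar] = SCAR
    return mask.with_labels(out)


# ---------------------------------------------------------------------------
# Random-Forest slice rejection

REJECTABLE_KINDS = (
    SequenceKind.LGE,
    SequenceKind.T1_NATIVE,
    SequenceKind.T1_POST,
    SequenceKind.T2,
)


@dataclass(frozen=True)
class SliceFeatures:
    """Per-slice features consumed by the rejector."""

    mean_softmax_myo: float
    mean_intensity_myo: float
    norm_slice_pos: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mean_softmax_myo, self.mean_intensity_myo, self.norm_slice_pos],
            dtype=np.float64,
        )


@dataclass
class RFConfig:
    n_trees: int = 6
    max_depth: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.max_depth < 1:
            raise ValueError("n_trees and max_depth must be >= 1")


def extract_slice_features(
    softmax_map: np.ndarray,
    image_slice: np.ndarray,
    slice_index: int,
    n_slices: int,
    kind: SequenceKind,
) -> Optional[SliceFeatures]:
    """Features of one slice, or ``None`` when no myocardium is predicted.

    ``image_slice`` is the z-scored slice on the same grid as the
    softmax map; the intensity feature is the normalized intensity.
    """
    classes = class_to_label(kind)
    if LV_MYO not in classes:
        raise ValueError(f"kind {kind.value} has no myocardium class")
    myo_ch = classes.index(LV_MYO)
    pred_myo = softmax_map.argmax(axis=0) == myo_ch
    if not pred_myo.any():
        return None
    pos = 0.0 if n_slices <= 1 else slice_index / (n_slices - 1)
    return SliceFeatures(
        mean_softmax_myo=float(softmax_map[myo_ch][pred_myo].mean()),
        mean_intensity_myo=float(np.asarray(image_slice)[pred_myo].mean()),
        norm_slice_pos=float(pos),
    )


def train_slice_rejector(
    features: np.ndarray, discard: np.ndarray, cfg: RFConfig
) -> RandomForestClassifier:
    """Fit the slice rejector on ``(n_slices, 3)`` features.

    ``discard`` is 1 for slices the model segmented but the ground truth
    leaves empty (over-segmentation), 0 for genuine slices.
    """
    features = np.asarray(features, dtype=np.float64)
    discard = np.asarray(discard).astype(int)
    if features.ndim != 2 or features.shape[1] != 3:
        raise ValueError("features must be (n, 3)")
    if len(np.unique(discard)) < 2:
        raise ValueError("rejector training needs both keep and discard examples")
    rf = RandomForestClassifier(
        n_estimators=cfg.n_trees, max_depth=cfg.max_depth, random_state=cfg.seed
    )
    rf.fit(features, discard)
    return rf


def save_rejector(rejector: RandomForestClassifier, cfg: RFConfig, path) -> None:
    """Persist a trained rejector (joblib binary + JSON config sidecar)."""
    import json
    from pathlib import Path

    import joblib

    path = Path(path)
    joblib.dump(rejector, path)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"n_trees": cfg.n_trees, "max_depth": cfg.max_depth, "seed": cfg.seed})
    )


def load_rejector(path) -> tuple[RandomForestClassifier, RFConfig]:
    import json
    from pathlib import Path

    import joblib

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return joblib.load(path), RFConfig(**meta)


def rejector_labels_from_truth(pred_mask: np.ndarray, truth_mask: np.ndarray) -> np.ndarray:
    """Per-slice discard labels: slice segmented by the model but empty in
    the ground truth => discard (1)."""
    if pred_mask.shape != truth_mask.shape:
        raise ValueError("grid mismatch")
    n = pred_mask.shape[0]
    out = np.zeros(n, dtype=int)
    for z in range(n):
        if (pred_mask[z] != BACKGROUND).any() and not (truth_mask[z] != BACKGROUND).any():
            out[z] = 1
    return out


def apply_slice_rejector(
    mask: LabelMask,
    rejector: RandomForestClassifier,
    softmax_stack: np.ndarray,
    norm_image_stack: np.ndarray,
) -> LabelMask:
    """Clear slices the rejector classifies as over-segmented.

    Only LGE and relaxation-map stacks are eligible; cine and flow
    stacks are rejected with an error.  ``softmax_stack`` is
    ``(n_slices, n_classes, H, W)`` and ``norm_image_stack`` the z-scored
    image slices on the same grid.
    """
    if mask.kind not in REJECTABLE_KINDS:
        raise ValueError(f"slice rejector does not apply to kind {mask.kind.value}")
    out = mask.labels.copy()
    n = out.shape[0]
    for z in range(n):
        if not (out[z] != BACKGROUND).any():
            continue
        feats = extract_slice_features(
            softmax_stack[z], norm_image_stack[z], z, n, mask.kind
        )
        if feats is None or rejector.predict(feats.as_array()[None])[0] == 1:
            out[z] = BACKGROUND
    return mask.with_labels(out)


@dataclass
class RejectorExample:
    """One over-segmented stack prepared for rejector training/evaluation."""

    norm_image: np.ndarray  # (n_slices, H, W) z-scored
    softmax: np.ndarray  # (n_slices, n_classes, H, W)
    corrupted: LabelMask
    truth: LabelMask
    features: list[Optional[SliceFeatures]]
    discard: np.ndarray  # per-slice labels derived from the ground truth


def build_rejector_corpus(
    kind: SequenceKind,
    n_stacks: int,
    seed: int,
    n_slices: int = 8,
    empty_basal_slices: int = 2,
    grid: tuple[int, int] = (64, 64),
) -> list[RejectorExample]:
    """Phantom over-segmentation corpus for the slice rejector.

    Each stack carries 1-2 deliberately over-segmented basal slices.
    Softmax maps are synthesized from the corrupted masks with higher
    confidence on genuine heart slices than on the spurious ones,
    emulating a network that is less certain off the heart.
    """
    from cmrseg.phantom import make_oversegmentation_fixture, mask_to_softmax, random_spec
    from cmrseg.preprocess import zscore

    if kind not in REJECTABLE_KINDS:
        raise ValueError(f"rejector corpus only for kinds {[k.value for k in REJECTABLE_KINDS]}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_stacks):
        spec = random_spec(
            kind, rng, n_slices=n_slices, empty_basal_slices=empty_basal_slices, grid=grid
        )
        n_extra = int(rng.integers(1, empty_basal_slices + 1))
        image, gt, corrupted = make_oversegmentation_fixture(spec, n_extra)
        sm, norm = [], []
        for z in range(n_slices):
            genuine = bool((gt.labels[z] != BACKGROUND).any())
            conf = rng.uniform(0.85, 0.98) if genuine else rng.uniform(0.55, 0.80)
            sm.append(mask_to_softmax(corrupted.labels[z], kind, conf))
            norm.append(zscore(image.voxels[z]))
        softmax_stack = np.stack(sm)
        norm_stack = np.stack(norm)
        feats = [
            extract_slice_features(softmax_stack[z], norm_stack[z], z, n_slices, kind)
            for z in range(n_slices)
        ]
        out.append(
            RejectorExample(
                norm_image=norm_stack,
                softmax=softmax_stack,
                corrupted=corrupted,
                truth=gt,
                features=feats,
                discard=rejector_labels_from_truth(corrupted.labels, gt.labels),
            )
        )
    return out


def corpus_features(examples: list[RejectorExample]) -> tuple[np.ndarray, np.ndarray]:
    """Stacked (features, discard-labels) of all slices with defined features."""
    X, y = [], []
    for ex in examples:
        for z, f in enumerate(ex.features):
            if f is not None:
                X.append(f.as_array())
                y.append(ex.discard[z])
    return np.asarray(X), np.asarray(y)


# ---------------------------------------------------------------------------
# end-to-end segmentation of one stack


def segment_stack(
    stack: ImageStack,
    model,
    rejector: Optional[RandomForestClassifier] = None,
    target_shape: Optional[tuple[int, int]] = None,
    target_spacing_mm: Optional[tuple[float, float]] = None,
) -> LabelMask:
    """Run the full segmentation pipeline on one image stack.

    ``model`` is a trained U-Net whose input grid is given by
    ``target_shape``/``target_spacing_mm`` (defaults: the 212 x 212 @
    1.37 mm network grid).  Returns the cleaned 3D (or 3D+t) label mask
    on the acquisition grid.
    """
    from cmrseg.preprocess import TARGET_SHAPE, TARGET_SPACING_MM
    from cmrseg.segmenter import predict_batch

    tshape = target_shape or TARGET_SHAPE
    tspace = target_spacing_mm or TARGET_SPACING_MM
    kind = stack.kind
    vox = stack.voxels if stack.has_time else stack.voxels[None]
    n_frames, n_slices = vox.shape[0], vox.shape[1]

    frame_masks = []
    softmax_per_frame = []
    norm_per_frame = []
    for f in range(n_frames):
        norm_slices, records = [], []
        for z in range(n_slices):
            img, rec = to_network_grid(vox[f, z], stack.in_plane_spacing_mm, tshape, tspace)
            norm_slices.append(img)
            records.append(rec)
        norm = np.stack(norm_slices)
        sm = predict_batch(model, norm)  # (n_slices, C, h, w)
        labels2d = [argmax_labels(sm[z], kind) for z in range(n_slices)]
        planes = [from_network_grid(lab, rec) for lab, rec in zip(labels2d, records)]
        frame_masks.append(np.stack(planes).astype(np.int16))
        softmax_per_frame.append(sm)
        norm_per_frame.append(norm)

    labels = np.stack(frame_masks) if stack.has_time else frame_masks[0]
    mask = LabelMask(
        labels=labels,
        in_plane_spacing_mm=stack.in_plane_spacing_mm,
        slice_thickness_mm=stack.slice_thickness_mm,
        kind=kind,
        frame_duration_ms=stack.frame_duration_ms,
    )
    for lab in sorted(kind.legal_labels - {BACKGROUND, SCAR}):
        mask = largest_component(mask, lab)
    mask = convexify(mask)
    if rejector is not None and kind in REJECTABLE_KINDS:
        mask = apply_slice_rejector(mask, rejector, softmax_per_frame[0], norm_per_frame[0])
    return mask
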