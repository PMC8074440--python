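"""Domain types, label conventions and NIfTI I/O shared by all stages.

Conventions
-----------
* Voxel arrays are indexed ``[frame?, slice, row, col]``; the temporal
  axis exists only for cine and phase-contrast flow stacks.
* Slice index 0 is the most basal slice; the normalized slice position
  used by the slice rejector is ``slice_index / (n_slices - 1)``.
* The label codebook is fixed for the whole pipeline:
  0 background, 1 LV cavity, 2 LV myocardium, 3 RV cavity, 4 scar,
  5 aorta.  Each sequence kind may only carry a subset of it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# label codebook

BACKGROUND = 0
LV_CAVITY = 1
LV_MYO = 2
RV_CAVITY = 3
SCAR = 4
AORTA = 5

CODEBOOK = {
    "background": BACKGROUND,
    "lv_cavity": LV_CAVITY,
    "lv_myo": LV_MYO,
    "rv_cavity": RV_CAVITY,
    "scar": SCAR,
    "aorta": AORTA,
}

LABEL_NAMES = {v: k for k, v in CODEBOOK.items()}

#: default cardiac cycle length used when a temporal stack arrives
#: without frame-duration metadata
DEFAULT_CYCLE_MS = 800.0


class SequenceKind(str, enum.Enum):
    """The six CMR sequence kinds the pipeline dispatches on."""

    CINE = "cine"
    LGE = "lge"
    T1_NATIVE = "t1_native"
    T1_POST = "t1_post"
    T2 = "t2"
    FLOW = "flow"

    @property
    def is_temporal(self) -> bool:
        return self in (SequenceKind.CINE, SequenceKind.FLOW)

    @property
    def is_map(self) -> bool:
        return self in (SequenceKind.T1_NATIVE, SequenceKind.T1_POST, SequenceKind.T2)

    @property
    def legal_labels(self) -> frozenset[int]:
        return LEGAL_LABELS[self]

    @property
    def n_classes(self) -> int:
        """Number of segmentation classes (background included)."""
        return len(LEGAL_LABELS[self])

    @property
    def intensity_units(self) -> str:
        if self.is_map:
            return "milliseconds"
        if self is SequenceKind.FLOW:
            return "cm_per_s"
        return "arbitrary"


LEGAL_LABELS: dict[SequenceKind, frozenset[int]] = {
    SequenceKind.CINE: frozenset({BACKGROUND, LV_CAVITY, LV_MYO, RV_CAVITY}),
    SequenceKind.LGE: frozenset({BACKGROUND, LV_CAVITY, LV_MYO, SCAR}),
    SequenceKind.T1_NATIVE: frozenset({BACKGROUND, LV_CAVITY, LV_MYO}),
    SequenceKind.T1_POST: frozenset({BACKGROUND, LV_CAVITY, LV_MYO}),
    SequenceKind.T2: frozenset({BACKGROUND, LV_CAVITY, LV_MYO}),
    SequenceKind.FLOW: frozenset({BACKGROUND, AORTA}),
}

#: class index (contiguous, 0-based) <-> codebook label, per kind.  The
#: network emits contiguous class channels; the pipeline speaks codebook
#: labels everywhere else.
def class_to_label(kind: SequenceKind) -> list[int]:
    return sorted(LEGAL_LABELS[kind])


def label_to_class(kind: SequenceKind) -> dict[int, int]:
    return {lab: i for i, lab in enumerate(class_to_label(kind))}


# ---------------------------------------------------------------------------
# containers


@dataclass
class ImageStack:
    """A spatially calibrated 3D (or 3D+time) voxel array.

    ``voxels`` is ``[slice, row, col]`` for static kinds and
    ``[frame, slice, row, col]`` for cine/flow.
    """

    voxels: np.ndarray
    in_plane_spacing_mm: tuple[float, float]
    slice_thickness_mm: float
    kind: SequenceKind
    frame_duration_ms: Optional[float] = None
    intensity_units: str = "arbitrary"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        self.in_plane_spacing_mm = (
            float(self.in_plane_spacing_mm[0]),
            float(self.in_plane_spacing_mm[1]),
        )
        self.slice_thickness_mm = float(self.slice_thickness_mm)
        if min(self.in_plane_spacing_mm) <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("non-positive spacing")
        want = 4 if self.kind.is_temporal else 3
        if self.voxels.ndim != want:
            raise ValueError(
                f"{self.kind.value} stack must be {want}D, got {self.voxels.ndim}D"
            )
        if self.kind.is_temporal and self.frame_duration_ms is None:
            self.frame_duration_ms = DEFAULT_CYCLE_MS / self.voxels.shape[0]
        if self.frame_duration_ms is not None and self.frame_duration_ms <= 0:
            raise ValueError("non-positive frame duration")
        if self.intensity_units not in ("arbitrary", "milliseconds", "cm_per_s"):
            raise ValueError(f"unknown intensity units {self.intensity_units!r}")

    @property
    def has_time(self) -> bool:
        return self.voxels.ndim == 4

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[0] if self.has_time else 1

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[-3]

    @property
    def voxel_volume_mm3(self) -> float:
        return (
            self.in_plane_spacing_mm[0]
            * self.in_plane_spacing_mm[1]
            * self.slice_thickness_mm
        )

    @property
    def pixel_area_mm2(self) -> float:
        return self.in_plane_spacing_mm[0] * self.in_plane_spacing_mm[1]

    def frame(self, f: int) -> np.ndarray:
        """The 3D ``[slice, row, col]`` volume of frame ``f``."""
        return self.voxels[f] if self.has_time else self.voxels


@dataclass
class LabelMask:
    """Integer anatomical labels on the same grid as an :class:`ImageStack`."""

    labels: np.ndarray
    in_plane_spacing_mm: tuple[float, float]
    slice_thickness_mm: float
    kind: SequenceKind
    frame_duration_ms: Optional[float] = None

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int16)
        self.in_plane_spacing_mm = (
            float(self.in_plane_spacing_mm[0]),
            float(self.in_plane_spacing_mm[1]),
        )
        self.slice_thickness_mm = float(self.slice_thickness_mm)
        if min(self.in_plane_spacing_mm) <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("non-positive spacing")
        want = 4 if self.kind.is_temporal else 3
        if self.labels.ndim != want:
            raise ValueError(
                f"{self.kind.value} mask must be {want}D, got {self.labels.ndim}D"
            )
        if self.kind.is_temporal and self.frame_duration_ms is None:
            self.frame_duration_ms = DEFAULT_CYCLE_MS / self.labels.shape[0]
        present = set(np.unique(self.labels).tolist())
        illegal = present - LEGAL_LABELS[self.kind]
        if illegal:
            raise ValueError(
                f"labels {sorted(illegal)} are illegal for kind {self.kind.value}"
            )

    @property
    def has_time(self) -> bool:
        return self.labels.ndim == 4

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0] if self.has_time else 1

    @property
    def n_slices(self) -> int:
        return self.labels.shape[-3]

    @property
    def voxel_volume_mm3(self) -> float:
        return (
            self.in_plane_spacing_mm[0]
            * self.in_plane_spacing_mm[1]
            * self.slice_thickness_mm
        )

    def frame(self, f: int) -> np.ndarray:
        return self.labels[f] if self.has_time else self.labels

    def with_labels(self, labels: np.ndarray) -> "LabelMask":
        """A copy of this mask carrying a new label array."""
        return LabelMask(
            labels=labels,
            in_plane_spacing_mm=self.in_plane_spacing_mm,
            slice_thickness_mm=self.slice_thickness_mm,
            kind=self.kind,
            frame_duration_ms=self.frame_duration_ms,
        )


# ---------------------------------------------------------------------------
# NIfTI I/O
#
# Arrays are stored in NIfTI data order (col, row, slice[, frame]) so that
# pixdim carries (col spacing, row spacing, slice thickness, frame duration).
# Sequence kind and intensity units travel in the 80-byte descrip field.


def _to_nifti_order(a: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.transpose(a))


def _from_nifti_order(a: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.transpose(a))


def _descrip(kind: SequenceKind, units: str) -> bytes:
    return f"cmrseg;kind={kind.value};units={units}".encode()


def _parse_descrip(hdr) -> tuple[Optional[SequenceKind], Optional[str]]:
    try:
        text = bytes(hdr["descrip"]).split(b"\x00")[0].decode()
    except Exception:
        return None, None
    kind = units = None
    for part in text.split(";"):
        if part.startswith("kind="):
            try:
                kind = SequenceKind(part[5:])
            except ValueError:
                pass
        elif part.startswith("units="):
            units = part[6:]
    return kind, units


def _raw_zooms(path: Path) -> np.ndarray:
    """pixdim[1:4] as stored on disk, bypassing nibabel's auto-repair of
    zero voxel sizes (a corrupt header must be an error, not a guess)."""
    from nibabel.openers import ImageOpener

    with ImageOpener(str(path), "rb") as f:
        hdr = nib.Nifti1Header.from_fileobj(f, check=False)
    return np.asarray(hdr["pixdim"][1:4], dtype=float)


def _sidecar_frame_duration(path: Path) -> Optional[float]:
    """frame_duration_ms from a YAML sidecar (``<stem>.yaml``), for
    temporal stacks whose NIfTI header lacks a time step."""
    import yaml

    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    sidecar = path.parent / (name + ".yaml")
    if not sidecar.exists():
        return None
    meta = yaml.safe_load(sidecar.read_text()) or {}
    value = meta.get("frame_duration_ms")
    return None if value is None else float(value)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as a NIfTI-1 file."""
    data = _to_nifti_order(stack.voxels.astype(np.float32))
    sr, sc = stack.in_plane_spacing_mm
    affine = np.diag([sc, sr, stack.slice_thickness_mm, 1.0])
    img = nib.Nifti1Image(data, affine)
    zooms = [sc, sr, stack.slice_thickness_mm]
    if stack.has_time:
        zooms.append(stack.frame_duration_ms)
        img.header.set_xyzt_units("mm", "msec")
    else:
        img.header.set_xyzt_units("mm")
    img.header.set_zooms(zooms)
    img.header["descrip"] = _descrip(stack.kind, stack.intensity_units)
    nib.save(img, str(path))


def read_stack(
    path: str | Path,
    kind: Optional[SequenceKind] = None,
    frame_duration_ms: Optional[float] = None,
) -> ImageStack:
    """Read a NIfTI file written by :func:`write_stack`.

    ``kind`` (normally supplied by the study manifest) overrides the kind
    recorded in the header; at least one of the two must be present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    hdr_kind, hdr_units = _parse_descrip(img.header)
    kind = kind or hdr_kind
    if kind is None:
        raise ValueError(f"sequence kind for {path} not in header nor supplied")
    zooms = img.header.get_zooms()
    sc, sr, thick = float(zooms[0]), float(zooms[1]), float(zooms[2])
    if min(sc, sr, thick) <= 0 or np.any(_raw_zooms(path) <= 0):
        raise ValueError("non-positive spacing")
    data = _from_nifti_order(np.asanyarray(img.dataobj).astype(np.float32))
    if frame_duration_ms is None and data.ndim == 4 and len(zooms) >= 4 and zooms[3] > 0:
        frame_duration_ms = float(zooms[3])
    if frame_duration_ms is None:
        frame_duration_ms = _sidecar_frame_duration(path)
    return ImageStack(
        voxels=data,
        in_plane_spacing_mm=(sr, sc),
        slice_thickness_mm=thick,
        kind=kind,
        frame_duration_ms=frame_duration_ms,
        intensity_units=hdr_units or kind.intensity_units,
    )


def write_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a :class:`LabelMask` as an integer-typed NIfTI-1 file."""
    data = _to_nifti_order(mask.labels.astype(np.int16))
    sr, sc = mask.in_plane_spacing_mm
    affine = np.diag([sc, sr, mask.slice_thickness_mm, 1.0])
    img = nib.Nifti1Image(data, affine)
    zooms = [sc, sr, mask.slice_thickness_mm]
    if mask.has_time:
        zooms.append(mask.frame_duration_ms)
        img.header.set_xyzt_units("mm", "msec")
    else:
        img.header.set_xyzt_units("mm")
    img.header.set_zooms(zooms)
    img.header["descrip"] = _descrip(mask.kind, "labels")
    nib.save(img, str(path))


def read_mask(path: str | Path, kind: Optional[SequenceKind] = None) -> LabelMask:
    """Read a label mask written by :func:`write_mask`; exact round-trip."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    hdr_kind, _ = _parse_descrip(img.header)
    kind = kind or hdr_kind
    if kind is None:
        raise ValueError(f"sequence kind for {path} not in header nor supplied")
    zooms = img.header.get_zooms()
    sc, sr, thick = float(zooms[0]), float(zooms[1]), float(zooms[2])
    if min(sc, sr, thick) <= 0 or np.any(_raw_zooms(path) <= 0):
        raise ValueError("non-positive spacing")
    data = _from_nifti_order(np.asanyarray(img.dataobj))
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded):
            raise ValueError(f"{path} does not contain integer labels")
        data = rounded
    frame_duration = None
    if data.ndim == 4 and len(zooms) >= 4 and zooms[3] > 0:
        frame_duration = float(zooms[3])
    return LabelMask(
        labels=data.astype(np.int16),
        in_plane_spacing_mm=(sr, sc),
        slice_thickness_mm=thick,
        kind=kind,
        frame_duration_ms=frame_duration,
    )


# ---------------------------------------------------------------------------
# study manifest


@dataclass
class ManifestEntry:
    subject_id: str
    kind: SequenceKind
    image_path: Path
    mask_path: Optional[Path] = None


@dataclass
class StudyManifest:
    """One entry per subject/sequence pair, read from a CSV file."""

    entries: list[ManifestEntry] = field(default_factory=list)

    @classmethod
    def read_csv(cls, path: str | Path, check_exists: bool = True) -> "StudyManifest":
        path = Path(path)
        df = pd.read_csv(path, dtype=str)
        required = {"subject_id", "kind", "image_path"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"manifest missing columns {sorted(missing)}")
        entries = []
        seen = set()
        for _, row in df.iterrows():
            key = (row["subject_id"], row["kind"])
            if key in seen:
                raise ValueError(f"duplicate manifest entry {key}")
            seen.add(key)
            mask = row.get("mask_path")
            mask_path = (
                path.parent / mask if isinstance(mask, str) and mask.strip() else None
            )
            entry = ManifestEntry(
                subject_id=row["subject_id"],
                kind=SequenceKind(row["kind"]),
                image_path=path.parent / row["image_path"],
                mask_path=mask_path,
            )
            if check_exists:
                if not entry.image_path.exists():
                    raise FileNotFoundError(str(entry.image_path))
                if entry.mask_path is not None and not entry.mask_path.exists():
                    raise FileNotFoundError(str(entry.mask_path))
            entries.append(entry)
        return cls(entries=entries)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "subject_id": e.subject_id,
                    "kind": e.kind.value,
                    "image_path": str(e.image_path),
                    "mask_path": "" if e.mask_path is None else str(e.mask_path),
                }
            )
        pd.DataFrame(rows).to_csv(path, index=False)

    def subjects(self) -> list[str]:
        out = []
        for e in self.entries:
            if e.subject_id not in out:
                out.append(e.subject_id)
        return out
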