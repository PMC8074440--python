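"""Synthetic short-axis cardiac phantom with analytically known truth.

The phantom emulates the geometry the pipeline segments — an annular LV
myocardium around a circular LV cavity, a crescent-shaped RV cavity, a
within-myocardium hyperintense scar sector, relaxation maps with known
tissue values, and an aortic disk carrying a time-varying through-plane
velocity profile.  Every structure is an analytic shape voxelized by the
voxel-center rule, so ground-truth volumes are exact voxel counts and
every clinical parameter (EF, scar %, map means, net/backward flow) is
known by construction.

The generator is a pure function of ``(spec, seed)``.  Deliberate
over-segmentation fixtures (extra basal slices labeled over non-cardiac
tissue) provide training corpora for the Random-Forest slice rejector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from cmrseg.core import (
    AORTA,
    BACKGROUND,
    LV_CAVITY,
    LV_MYO,
    RV_CAVITY,
    SCAR,
    ImageStack,
    LabelMask,
    SequenceKind,
    class_to_label,
)

# default per-kind tissue intensity means.  Maps are in milliseconds
# (plausible 1.5 T myocardium/blood values); cine and LGE are arbitrary
# units; flow is peak velocity in cm/s handled separately.
DEFAULT_TISSUE_MEANS: dict[SequenceKind, dict[int, float]] = {
    SequenceKind.CINE: {BACKGROUND: 60.0, LV_CAVITY: 400.0, LV_MYO: 180.0, RV_CAVITY: 400.0},
    SequenceKind.LGE: {BACKGROUND: 60.0, LV_CAVITY: 300.0, LV_MYO: 100.0, SCAR: 280.0},
    SequenceKind.T1_NATIVE: {BACKGROUND: 300.0, LV_CAVITY: 1600.0, LV_MYO: 1000.0},
    SequenceKind.T1_POST: {BACKGROUND: 200.0, LV_CAVITY: 300.0, LV_MYO: 450.0},
    SequenceKind.T2: {BACKGROUND: 20.0, LV_CAVITY: 180.0, LV_MYO: 50.0},
    SequenceKind.FLOW: {BACKGROUND: 0.0, AORTA: 0.0},
}

DEFAULT_NOISE_SD: dict[SequenceKind, float] = {
    SequenceKind.CINE: 20.0,
    SequenceKind.LGE: 15.0,
    SequenceKind.T1_NATIVE: 60.0,
    SequenceKind.T1_POST: 25.0,
    SequenceKind.T2: 5.0,
    SequenceKind.FLOW: 4.0,
}


@dataclass
class PhantomSpec:
    """Geometry, tissue and acquisition parameters of one phantom."""

    kind: SequenceKind
    n_slices: int = 6
    grid: tuple[int, int] = (64, 64)
    in_plane_spacing_mm: tuple[float, float] = (1.37, 1.37)
    slice_thickness_mm: float = 10.0
    n_frames: int = 12
    lv_radius_ed_mm: float = 22.0
    lv_radius_es_mm: float = 14.0
    myo_thickness_mm: float = 8.0
    apical_taper: float = 0.35
    es_frame_frac: float = 0.4
    center_offset_mm: tuple[float, float] = (0.0, 6.0)
    rv_enabled: bool = True
    rv_radius_scale: float = 0.65
    rv_gap_mm: float = 1.0
    scar_angular_extent_deg: float = 90.0
    scar_start_angle_deg: float = -30.0
    scar_transmurality: float = 0.6
    aorta_radius_mm: float = 12.0
    flow_peak_cm_s: float = 80.0
    flow_offset_cm_s: float = 30.0
    empty_basal_slices: int = 0
    tissue_means: dict[int, float] = field(default_factory=dict)
    noise_sd: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tissue_means:
            self.tissue_means = dict(DEFAULT_TISSUE_MEANS[self.kind])
        if self.noise_sd is None:
            self.noise_sd = DEFAULT_NOISE_SD[self.kind]
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.kind is not SequenceKind.FLOW:
            if not (0.0 < self.scar_transmurality <= 1.0):
                raise ValueError("scar_transmurality must lie in (0, 1]")
            if not (0.0 < self.scar_angular_extent_deg < 360.0):
                raise ValueError("scar sector must be a strict sector")
            if self.lv_radius_es_mm >= self.lv_radius_ed_mm:
                raise ValueError("ES radius must be smaller than ED radius")
        if not (0.0 <= self.apical_taper < 1.0):
            raise ValueError("apical_taper must lie in [0, 1)")
        if self.n_slices < 1 or min(self.grid) < 8:
            raise ValueError("degenerate grid")

    # -- schedules ----------------------------------------------------------

    @property
    def n_heart_slices(self) -> int:
        return self.n_slices - self.empty_basal_slices

    def contraction_schedule(self) -> np.ndarray:
        """Per-frame factor in [0, 1]; 1 at ED (frame 0), 0 at ES.

        Piecewise linear with a unique maximum at frame 0 and a unique
        minimum at the ES frame, so end-diastole and end-systole are
        well-defined.
        """
        n = self.n_frames
        if n == 1:
            return np.ones(1)
        f_es = max(1, int(round(self.es_frame_frac * n)))
        f_es = min(f_es, n - 1)
        u = np.empty(n)
        u[: f_es + 1] = 1.0 - np.arange(f_es + 1) / f_es
        tail = np.arange(n - f_es)  # 0 .. n-1-f_es
        u[f_es:] = tail / (n - f_es)
        return u

    def taper_schedule(self) -> np.ndarray:
        """Per-heart-slice radius factor; 1 basal, tapering toward apex."""
        m = self.n_heart_slices
        if m == 1:
            return np.ones(1)
        return 1.0 - self.apical_taper * np.arange(m) / (m - 1)

    def cavity_radius_mm(self) -> np.ndarray:
        """LV cavity radius schedule, shape (n_frames_or_1, n_heart_slices)."""
        taper = self.taper_schedule()
        if self.kind is SequenceKind.CINE:
            u = self.contraction_schedule()
            r_frame = self.lv_radius_es_mm + (self.lv_radius_ed_mm - self.lv_radius_es_mm) * u
            return np.outer(r_frame, taper)
        return np.outer([self.lv_radius_ed_mm], taper)


@dataclass
class PhantomTruth:
    """Exact ground truth accompanying one generated phantom."""

    mask: LabelMask
    true_volumes_ml: dict[int, np.ndarray]  # label -> per-frame volume
    ed_frame: int = 0
    es_frame: int = 0
    true_lv_ef_pct: Optional[float] = None
    true_rv_ef_pct: Optional[float] = None
    true_scar_pct: Optional[float] = None
    true_map_mean_ms: Optional[float] = None
    true_net_flow_ml: Optional[float] = None
    true_backward_flow_ml: Optional[float] = None

    def summary(self) -> dict:
        out = {
            "kind": self.mask.kind.value,
            "ed_frame": int(self.ed_frame),
            "es_frame": int(self.es_frame),
            "true_volumes_ml": {
                str(k): [float(x) for x in v] for k, v in self.true_volumes_ml.items()
            },
        }
        for name in (
            "true_lv_ef_pct",
            "true_rv_ef_pct",
            "true_scar_pct",
            "true_map_mean_ms",
            "true_net_flow_ml",
            "true_backward_flow_ml",
        ):
            val = getattr(self, name)
            if val is not None:
                out[name] = float(val)
        return out

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


# ---------------------------------------------------------------------------
# geometry helpers


def _grid_coords_mm(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Row/col voxel-center coordinates in mm, origin at grid center."""
    nr, nc = spec.grid
    sr, sc = spec.in_plane_spacing_mm
    rows = (np.arange(nr) - (nr - 1) / 2.0) * sr
    cols = (np.arange(nc) - (nc - 1) / 2.0) * sc
    return np.meshgrid(rows, cols, indexing="ij")


def _cardiac_slice_labels(spec: PhantomSpec, r_cavity: float, r_epi: float) -> np.ndarray:
    """Label one short-axis slice of the heart from analytic shapes."""
    rr, cc = _grid_coords_mm(spec)
    orow, ocol = spec.center_offset_mm
    d_lv = np.hypot(rr - orow, cc - ocol)
    labels = np.zeros(spec.grid, dtype=np.int16)
    labels[d_lv <= r_epi] = LV_MYO
    labels[d_lv <= r_cavity] = LV_CAVITY

    if spec.kind is SequenceKind.LGE:
        ang = np.degrees(np.arctan2(rr - orow, cc - ocol))
        start = spec.scar_start_angle_deg
        width = spec.scar_angular_extent_deg
        in_sector = np.mod(ang - start, 360.0) <= width
        depth = r_cavity + spec.scar_transmurality * (r_epi - r_cavity)
        scar = (labels == LV_MYO) & in_sector & (d_lv <= depth)
        labels[scar] = SCAR

    if spec.kind is SequenceKind.CINE and spec.rv_enabled:
        rv_r = spec.rv_radius_scale * r_cavity
        rv_col = ocol - (r_epi + spec.rv_gap_mm + 0.35 * rv_r)
        d_rv = np.hypot(rr - orow, cc - rv_col)
        rv = (d_rv <= rv_r) & (d_lv > r_epi + spec.rv_gap_mm)
        labels[rv] = RV_CAVITY
    return labels


def _flow_velocity_frame(spec: PhantomSpec, f: int) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless velocity field (cm/s) and aorta mask of one flow frame."""
    rr, cc = _grid_coords_mm(spec)
    orow, ocol = spec.center_offset_mm
    d = np.hypot(rr - orow, cc - ocol)
    aorta = d <= spec.aorta_radius_mm
    v_peak = spec.flow_peak_cm_s * np.sin(2.0 * np.pi * f / spec.n_frames) + spec.flow_offset_cm_s
    v = np.zeros(spec.grid, dtype=np.float64)
    v[aorta] = v_peak * (1.0 - (d[aorta] / spec.aorta_radius_mm) ** 2)
    return v, aorta


# ---------------------------------------------------------------------------
# generators


def make_phantom(spec: PhantomSpec) -> tuple[ImageStack, PhantomTruth]:
    """Generate one phantom stack with its exact ground truth.

    The image is per-label tissue mean plus Gaussian noise; the mask is
    the voxelized analytic geometry.  Deterministic given ``spec.seed``.
    """
    if spec.kind is SequenceKind.FLOW:
        return make_flow_phantom(spec)

    rng = np.random.default_rng(spec.seed)
    n_frames = spec.n_frames if spec.kind is SequenceKind.CINE else 1
    radii = spec.cavity_radius_mm()  # (n_frames_or_1, n_heart_slices)
    taper = spec.taper_schedule()
    r_epi = spec.lv_radius_ed_mm * taper + spec.myo_thickness_mm  # constant over time

    frames = []
    for f in range(n_frames):
        vol = np.zeros((spec.n_slices, *spec.grid), dtype=np.int16)
        for s in range(spec.n_heart_slices):
            z = spec.empty_basal_slices + s
            vol[z] = _cardiac_slice_labels(spec, radii[min(f, radii.shape[0] - 1), s], r_epi[s])
            if not np.any((vol[z] == LV_MYO) | (vol[z] == SCAR)):
                raise ValueError(f"geometry leaves zero myocardium voxels on slice {z}")
        frames.append(vol)
    labels = np.stack(frames) if spec.kind is SequenceKind.CINE else frames[0]

    means = spec.tissue_means
    image = np.empty(labels.shape, dtype=np.float32)
    for lab in np.unique(labels):
        image[labels == lab] = means.get(int(lab), means[BACKGROUND])
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, labels.shape).astype(np.float32)

    frame_ms = None
    if spec.kind is SequenceKind.CINE:
        frame_ms = 800.0 / spec.n_frames
    mask = LabelMask(
        labels=labels,
        in_plane_spacing_mm=spec.in_plane_spacing_mm,
        slice_thickness_mm=spec.slice_thickness_mm,
        kind=spec.kind,
        frame_duration_ms=frame_ms,
    )
    stack = ImageStack(
        voxels=image.astype(np.float32),
        in_plane_spacing_mm=spec.in_plane_spacing_mm,
        slice_thickness_mm=spec.slice_thickness_mm,
        kind=spec.kind,
        frame_duration_ms=frame_ms,
        intensity_units=spec.kind.intensity_units,
    )
    truth = _truth_from_mask(spec, mask)
    return stack, truth


def _truth_from_mask(spec: PhantomSpec, mask: LabelMask) -> PhantomTruth:
    vox_ml = mask.voxel_volume_mm3 / 1000.0
    labels = mask.labels if mask.has_time else mask.labels[None]
    vols: dict[int, np.ndarray] = {}
    for lab in sorted(spec.kind.legal_labels - {BACKGROUND}):
        vols[lab] = np.array([(fr == lab).sum() * vox_ml for fr in labels])

    truth = PhantomTruth(mask=mask, true_volumes_ml=vols)
    if spec.kind is SequenceKind.CINE:
        lv = vols[LV_CAVITY]
        truth.ed_frame = int(np.argmax(lv))
        truth.es_frame = int(np.argmin(lv))
        truth.true_lv_ef_pct = 100.0 * (lv[truth.ed_frame] - lv[truth.es_frame]) / lv[truth.ed_frame]
        if spec.rv_enabled:
            rv = vols[RV_CAVITY]
            truth.true_rv_ef_pct = 100.0 * (rv.max() - rv.min()) / rv.max()
    if spec.kind is SequenceKind.LGE:
        myo, scar = vols[LV_MYO][0], vols[SCAR][0]
        truth.true_scar_pct = 100.0 * scar / (myo + scar)
    if spec.kind.is_map:
        truth.true_map_mean_ms = float(spec.tissue_means[LV_MYO])
    return truth


def make_flow_phantom(spec: PhantomSpec) -> tuple[ImageStack, PhantomTruth]:
    """Aortic phase-contrast phantom: parabolic in-plane velocity profile,
    sinusoidal-with-offset temporal modulation (some frames net-negative).

    Truth flows are integrals of the noiseless voxelized velocity field:
    ``net = sum_f sum_px v * a * dt``, ``backward = |sum of negative
    per-frame contributions|``.
    """
    if spec.kind is not SequenceKind.FLOW:
        raise ValueError("make_flow_phantom requires kind=flow")
    rng = np.random.default_rng(spec.seed)
    frame_ms = 800.0 / spec.n_frames
    area_cm2 = spec.in_plane_spacing_mm[0] * spec.in_plane_spacing_mm[1] / 100.0
    dt_s = frame_ms / 1000.0

    # phase-contrast flow is a single-plane acquisition: one slice per frame
    vels, masks, q_ml = [], [], []
    for f in range(spec.n_frames):
        v, aorta = _flow_velocity_frame(spec, f)
        lab = np.zeros((1, *spec.grid), dtype=np.int16)
        lab[0, aorta] = AORTA
        q_ml.append(v[aorta].sum() * area_cm2 * dt_s)  # cm/s * cm^2 * s = mL
        vels.append(v[None])
        masks.append(lab)

    q_ml = np.asarray(q_ml)
    image = np.stack(vels).astype(np.float32)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, image.shape).astype(np.float32)
    labels = np.stack(masks)

    mask = LabelMask(
        labels=labels,
        in_plane_spacing_mm=spec.in_plane_spacing_mm,
        slice_thickness_mm=spec.slice_thickness_mm,
        kind=spec.kind,
        frame_duration_ms=frame_ms,
    )
    stack = ImageStack(
        voxels=image,
        in_plane_spacing_mm=spec.in_plane_spacing_mm,
        slice_thickness_mm=spec.slice_thickness_mm,
        kind=spec.kind,
        frame_duration_ms=frame_ms,
        intensity_units="cm_per_s",
    )
    vox_ml = mask.voxel_volume_mm3 / 1000.0
    truth = PhantomTruth(
        mask=mask,
        true_volumes_ml={AORTA: np.array([(fr == AORTA).sum() * vox_ml for fr in labels])},
        true_net_flow_ml=float(q_ml.sum()),
        true_backward_flow_ml=float(abs(q_ml[q_ml < 0].sum())),
    )
    return stack, truth


def analytic_net_flow_ml(spec: PhantomSpec) -> float:
    """Closed-form net flow: per frame v_peak * pi R^2 / 2 integrated in time."""
    f = np.arange(spec.n_frames)
    v_peak = spec.flow_peak_cm_s * np.sin(2.0 * np.pi * f / spec.n_frames) + spec.flow_offset_cm_s
    area_cm2 = np.pi * (spec.aorta_radius_mm / 10.0) ** 2
    dt_s = 800.0 / spec.n_frames / 1000.0
    return float((v_peak * area_cm2 / 2.0 * dt_s).sum())


def solve_radius_for_volume(
    target_ml: float, n_slices: int, thickness_mm: float, apical_taper: float
) -> float:
    """Basal cavity radius whose disk-summation volume equals ``target_ml``.

    Inverts ``V = pi * t * r^2 * sum taper_s^2`` (disk summation over the
    slice stack); voxelization introduces a small additional error.
    """
    if n_slices == 1:
        taper_sq = 1.0
    else:
        taper = 1.0 - apical_taper * np.arange(n_slices) / (n_slices - 1)
        taper_sq = float((taper**2).sum())
    return float(np.sqrt(target_ml * 1000.0 / (np.pi * thickness_mm * taper_sq)))


# ---------------------------------------------------------------------------
# over-segmentation fixtures for the slice rejector


def make_oversegmentation_fixture(
    spec: PhantomSpec, n_extra: int
) -> tuple[ImageStack, LabelMask, LabelMask]:
    """A phantom whose corrupted mask labels ``n_extra`` slices beyond the
    true basal extent, painted over non-cardiac tissue — the failure mode
    the Random-Forest rejector is trained to discard.

    Returns ``(image, ground_truth_mask, corrupted_mask)``.
    """
    if n_extra < 0:
        raise ValueError("n_extra must be >= 0")
    if n_extra > spec.empty_basal_slices:
        raise ValueError(
            f"n_extra={n_extra} exceeds the {spec.empty_basal_slices} empty basal slices"
        )
    stack, truth = make_phantom(spec)
    gt = truth.mask
    corrupted = gt.labels.copy()
    first_heart = spec.empty_basal_slices
    for k in range(1, n_extra + 1):
        corrupted[..., first_heart - k, :, :] = gt.labels[..., first_heart, :, :]
    return stack, gt, gt.with_labels(corrupted)


def mask_to_softmax(labels2d: np.ndarray, kind: SequenceKind, confidence: float) -> np.ndarray:
    """Synthetic softmax map for a 2D label slice: probability
    ``confidence`` on the labeled class, remainder spread uniformly.

    Used to emulate network output when building rejector corpora from
    constructed masks.
    """
    classes = class_to_label(kind)
    n = len(classes)
    if not (1.0 / n) <= confidence <= 1.0:
        raise ValueError("confidence must lie in [1/n_classes, 1]")
    out = np.full((n, *labels2d.shape), (1.0 - confidence) / (n - 1), dtype=np.float32)
    for ci, lab in enumerate(classes):
        out[ci][labels2d == lab] = confidence
    return out


def random_spec(kind: SequenceKind, rng: np.random.Generator, **overrides) -> PhantomSpec:
    """A randomized phantom spec emulating anatomical variability:
    cavity size, wall thickness, heart position, scar geometry and
    aorta size all jitter around their defaults."""
    base = PhantomSpec(kind=kind)
    r_ed = base.lv_radius_ed_mm * rng.uniform(0.8, 1.15)
    params = dict(
        kind=kind,
        seed=int(rng.integers(0, 2**31 - 1)),
        lv_radius_ed_mm=r_ed,
        lv_radius_es_mm=r_ed * rng.uniform(0.55, 0.75),
        myo_thickness_mm=base.myo_thickness_mm * rng.uniform(0.8, 1.2),
        center_offset_mm=(float(rng.uniform(-4, 4)), float(rng.uniform(2, 9))),
        apical_taper=float(rng.uniform(0.25, 0.45)),
        scar_start_angle_deg=float(rng.uniform(0, 360)),
        scar_angular_extent_deg=float(rng.uniform(60, 120)),
        scar_transmurality=float(rng.uniform(0.4, 0.9)),
        aorta_radius_mm=base.aorta_radius_mm * rng.uniform(0.8, 1.2),
        flow_peak_cm_s=base.flow_peak_cm_s * rng.uniform(0.8, 1.2),
    )
    params.update(overrides)
    return PhantomSpec(**params)


def make_training_slices(
    kind: SequenceKind,
    n_slices_total: int,
    seed: int,
    grid: tuple[int, int] = (64, 64),
    **spec_overrides,
) -> tuple[np.ndarray, np.ndarray]:
    """A training corpus of 2D slices: z-scored images and class-index
    targets (contiguous class channels in codebook order).

    Phantom geometry is re-randomized until ``n_slices_total`` slices are
    collected.  Returns ``(images [N,H,W] float32, classes [N,H,W] int)``.
    """
    from cmrseg.preprocess import zscore

    rng = np.random.default_rng(seed)
    lab2class = {lab: i for i, lab in enumerate(class_to_label(kind))}
    imgs, targets = [], []
    while len(imgs) < n_slices_total:
        spec = random_spec(kind, rng, grid=grid, **spec_overrides)
        stack, truth = make_phantom(spec)
        vox = stack.voxels if stack.has_time else stack.voxels[None]
        lab = truth.mask.labels if truth.mask.has_time else truth.mask.labels[None]
        # subsample frames of temporal stacks to diversify geometry faster
        f_idx = rng.permutation(vox.shape[0])[:3] if vox.shape[0] > 1 else [0]
        for f in f_idx:
            for z in range(vox.shape[1]):
                imgs.append(zscore(vox[f, z]))
                cls = np.zeros(lab.shape[2:], dtype=np.int64)
                for l, c in lab2class.items():
                    cls[lab[f, z] == l] = c
                targets.append(cls)
                if len(imgs) >= n_slices_total:
                    break
            if len(imgs) >= n_slices_total:
                break
    return np.stack(imgs).astype(np.float32), np.stack(targets)
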