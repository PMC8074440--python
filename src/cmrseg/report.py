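"""Study-level batch processing and reporting.

Runs a manifest of subjects end-to-end (segmentation when models are
supplied, otherwise the manifest's reference masks), tabulates the
extracted parameters, flags rows whose values fall outside configured
physiological ranges for human review, and — once corrected analyses
exist for a subset — summarizes confidence as per-parameter agreement
statistics.

Per-subject failures are logged and skipped; one bad scan never aborts
a batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from cmrseg.core import LabelMask, SequenceKind, StudyManifest, read_mask, read_stack
from cmrseg.evalmetrics import AgreementStats, agreement
from cmrseg.params import extract_params

#: shipped default ranges — documented conventions meant to be overridden
#: per study, not clinical reference values
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "lv_ef_pct": (20.0, 80.0),
    "rv_ef_pct": (20.0, 80.0),
    "lv_edv_ml": (20.0, 400.0),
    "lv_esv_ml": (5.0, 300.0),
    "lv_mass_g": (20.0, 400.0),
    "scar_pct": (0.0, 60.0),
    "mean_t1_ms": (600.0, 1600.0),
    "mean_t1post_ms": (150.0, 800.0),
    "mean_t2_ms": (20.0, 120.0),
    "net_flow_ml": (20.0, 180.0),
    "backward_flow_ml": (0.0, 40.0),
}


@dataclass
class PhysioRanges:
    """Inclusive [low, high] plausibility bounds per parameter."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"range for {name} must have low < high")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhysioRanges":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(bounds={k: (float(v[0]), float(v[1])) for k, v in raw.items()})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump({k: [float(a), float(b)] for k, (a, b) in self.bounds.items()})
        )

    def violations(self, row: dict) -> list[str]:
        out = []
        for name, (lo, hi) in self.bounds.items():
            val = row.get(name)
            if val is None:
                continue
            if not lo <= val <= hi:
                out.append(f"{name}={val:.3g} outside [{lo:g}, {hi:g}]")
        return out


@dataclass
class StudyReport:
    """Batch output: one parameter row per processed subject/sequence."""

    params: pd.DataFrame
    flags: pd.DataFrame
    failures: list[str] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.params.to_csv(out_dir / "report.csv", index=False)
        self.flags.to_csv(out_dir / "flags.csv", index=False)
        (out_dir / "run.log").write_text("\n".join(self.failures) + ("\n" if self.failures else ""))


def run_study(
    manifest: StudyManifest,
    models: Optional[dict[SequenceKind, object]] = None,
    ranges: Optional[PhysioRanges] = None,
    rejectors: Optional[dict[SequenceKind, object]] = None,
    target_shape: Optional[tuple[int, int]] = None,
    target_spacing_mm: Optional[tuple[float, float]] = None,
) -> StudyReport:
    """Process every manifest entry and tabulate parameters and flags.

    With ``models`` given, each stack is segmented by its sequence-kind
    model (plus optional slice rejector); otherwise the manifest must
    reference masks.  Deterministic given models and inputs.
    """
    from cmrseg.postprocess import segment_stack

    ranges = ranges or PhysioRanges()
    rows, flag_rows, failures = [], [], []
    for entry in manifest.entries:
        try:
            stack = read_stack(entry.image_path, kind=entry.kind)
            if models is not None:
                if entry.kind not in models:
                    raise KeyError(f"no model for kind {entry.kind.value}")
                trained = models[entry.kind]
                model = getattr(trained, "model", trained)
                rej = (rejectors or {}).get(entry.kind)
                mask = segment_stack(
                    stack,
                    model,
                    rejector=rej,
                    target_shape=target_shape,
                    target_spacing_mm=target_spacing_mm,
                )
            else:
                if entry.mask_path is None:
                    raise ValueError("no models supplied and manifest has no mask")
                mask = read_mask(entry.mask_path, kind=entry.kind)
            p = extract_params(stack, mask)
            row = {"subject_id": entry.subject_id, **p.to_dict()}
            row.pop("warnings", None)
            violated = ranges.violations(row)
            row["flagged"] = bool(violated)
            rows.append(row)
            for v in violated:
                flag_rows.append(
                    {"subject_id": entry.subject_id, "kind": entry.kind.value, "violation": v}
                )
        except Exception as exc:  # skip-and-log failure policy
            failures.append(f"{entry.subject_id}/{entry.kind.value}: {exc}")
    params_df = pd.DataFrame(rows)
    flags_df = pd.DataFrame(flag_rows, columns=["subject_id", "kind", "violation"])
    return StudyReport(params=params_df, flags=flags_df, failures=failures)


def confidence(
    auto: pd.DataFrame, corrected: pd.DataFrame, parameters: Optional[list[str]] = None
) -> dict[str, AgreementStats]:
    """Agreement between automatic and corrected analyses, per parameter.

    ``auto`` and ``corrected`` are report tables sharing ``subject_id``;
    only subjects present in both are compared (>= 3 required)."""
    merged = auto.merge(corrected, on="subject_id", suffixes=("_auto", "_ref"))
    if len(merged) < 3:
        raise ValueError("need >= 3 corrected subjects")
    if parameters is None:
        parameters = [
            c for c in auto.columns
            if c not in ("subject_id", "kind", "flagged", "ed_frame", "es_frame")
            and pd.api.types.is_numeric_dtype(auto[c])
        ]
    out = {}
    for p in parameters:
        pa, pr = f"{p}_auto", f"{p}_ref"
        if pa not in merged or pr not in merged:
            continue
        sub = merged[[pa, pr]].dropna()
        if len(sub) < 3:
            continue
        out[p] = agreement(sub[pa].to_numpy(), sub[pr].to_numpy(), p)
    return out
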