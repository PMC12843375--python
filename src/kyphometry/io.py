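"""File formats and run configuration.

Plain-text formats only: centroid tables and paired angles as CSV, detection
annotations as YOLO-format text (one ``class x_center y_center width height``
line per box, coordinates normalized to [0, 1] by the image dimensions,
class indices 0–8 mapping to Th4–Th12), reports as JSON, phantom renderings
as PNG.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .agreement import AgreementReport, DiagnosticReport, PairedAngles
from .detection import BoundingBox, DetectionEvalReport
from .geometry import (
    THORACIC_LEVELS,
    KyphosisMeasurement,
    Point2D,
    VertebraLevel,
    VertebralCentroidSet,
)

__all__ = [
    "RunConfig",
    "read_centroids_csv",
    "write_centroids_csv",
    "read_paired_csv",
    "write_paired_csv",
    "read_yolo_annotations",
    "write_yolo_annotations",
    "write_image_png",
    "read_image_png",
    "measurement_to_dict",
    "agreement_report_to_dict",
    "diagnostic_report_to_dict",
    "detection_report_to_dict",
]

_CENTROID_COLUMNS = ["scan_id", "level", "x", "y", "confidence"]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline-wide thresholds and seeds; serializes round-trip losslessly."""

    threshold_deg: float = 40.0
    iou_threshold: float = 0.5
    fit_method: str = "algebraic"
    consensus_threshold_deg: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold_deg <= 0 or self.iou_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.consensus_threshold_deg < 0:
            raise ValueError("consensus threshold must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        """Load from a JSON or TOML file (by extension)."""
        p = Path(path)
        if p.suffix.lower() == ".toml":
            with open(p, "rb") as fh:
                return cls.from_dict(tomllib.load(fh))
        return cls.from_dict(json.loads(p.read_text()))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def write_centroids_csv(
    sets: Iterable[VertebralCentroidSet], path: str | Path
) -> None:
    rows = []
    for cs in sets:
        for lvl in cs:
            obs = cs.entries[lvl]
            rows.append(
                {
                    "scan_id": cs.scan_id,
                    "level": lvl.label,
                    "x": obs.point.x,
                    "y": obs.point.y,
                    "confidence": obs.confidence,
                }
            )
    pd.DataFrame(rows, columns=_CENTROID_COLUMNS).to_csv(path, index=False)


def read_centroids_csv(path: str | Path) -> list[VertebralCentroidSet]:
    """Read a centroid table (columns scan_id, level, x, y, confidence) into
    per-scan centroid sets, in file order of first appearance."""
    df = pd.read_csv(path)
    missing = set(_CENTROID_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"centroid CSV lacks columns: {sorted(missing)}")
    out: dict[str, VertebralCentroidSet] = {}
    for _, row in df.iterrows():
        sid = str(row["scan_id"])
        cs = out.setdefault(sid, VertebralCentroidSet(scan_id=sid))
        cs.add(
            VertebraLevel.parse(row["level"]),
            Point2D(float(row["x"]), float(row["y"])),
            float(row["confidence"]),
        )
    return list(out.values())


def write_paired_csv(pairs: PairedAngles, path: str | Path) -> None:
    pd.DataFrame(
        {
            "scan_id": pairs.scan_ids,
            "automated_deg": pairs.automated,
            "manual_deg": pairs.manual,
        }
    ).to_csv(path, index=False)


def read_paired_csv(path: str | Path) -> PairedAngles:
    df = pd.read_csv(path)
    missing = {"scan_id", "automated_deg", "manual_deg"} - set(df.columns)
    if missing:
        raise ValueError(f"paired CSV lacks columns: {sorted(missing)}")
    return PairedAngles.from_dataframe(df)


def write_yolo_annotations(
    boxes: Sequence[BoundingBox],
    path: str | Path,
    image_size: tuple[int, int],
    include_confidence: bool = False,
) -> None:
    """Write YOLO-format annotation text (normalized center/size per line).

    Boxes without a level are written with class index −1 so predictions of
    unknown level survive a round trip.
    """
    w, h = image_size
    lines = []
    for b in boxes:
        cls = b.level.value - THORACIC_LEVELS[0].value if b.level is not None else -1
        cx = (b.x_min + b.x_max) / 2.0 / w
        cy = (b.y_min + b.y_max) / 2.0 / h
        bw = (b.x_max - b.x_min) / w
        bh = (b.y_max - b.y_min) / h
        parts = [str(cls)] + [f"{v:.6f}" for v in (cx, cy, bw, bh)]
        if include_confidence:
            parts.append(f"{b.confidence:.6f}")
        lines.append(" ".join(parts))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_annotations(
    path: str | Path, image_size: tuple[int, int]
) -> list[BoundingBox]:
    """Read YOLO-format annotations back into pixel-coordinate boxes; a fifth
    numeric column, when present, is the confidence."""
    w, h = image_size
    boxes = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if len(parts) not in (5, 6):
            raise ValueError(f"malformed YOLO line: {line!r}")
        cls = int(parts[0])
        cx, cy, bw, bh = (float(v) for v in parts[1:5])
        conf = float(parts[5]) if len(parts) == 6 else 1.0
        level = (
            VertebraLevel(THORACIC_LEVELS[0].value + cls)
            if 0 <= cls < len(THORACIC_LEVELS)
            else None
        )
        boxes.append(
            BoundingBox(
                x_min=(cx - bw / 2.0) * w,
                y_min=(cy - bh / 2.0) * h,
                x_max=(cx + bw / 2.0) * w,
                y_max=(cy + bh / 2.0) * h,
                level=level,
                confidence=conf,
            )
        )
    return boxes


def write_image_png(image: np.ndarray, path: str | Path) -> None:
    """Save a float image in [0, 1] as 8-bit grayscale PNG."""
    from PIL import Image

    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 255).round().astype(np.uint8), mode="L").save(path)


def read_image_png(path: str | Path) -> np.ndarray:
    """Load an 8-bit grayscale PNG as a float image in [0, 1]."""
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=float) / 255.0


def measurement_to_dict(m: KyphosisMeasurement) -> dict:
    d = {
        "scan_id": m.scan_id,
        "qc_flag": m.qc_flag,
        "qc_reason": m.qc_reason,
        "central_angle_deg": m.central_angle_deg,
        "cobb_equiv_deg": m.cobb_equiv_deg,
        "levels_used": [lvl.label for lvl in m.levels_used],
        "circle": None,
    }
    if m.circle is not None:
        d["circle"] = {
            "cx": m.circle.center.x,
            "cy": m.circle.center.y,
            "r": m.circle.radius,
            "rms_residual": m.circle.rms_residual,
        }
    return d


def _pct(v: float | None) -> int | None:
    return None if v is None else int(round(100 * v))


def agreement_report_to_dict(r: AgreementReport) -> dict:
    d = dataclasses.asdict(r)
    # display rounding: angles to 0.1 degree
    for key in (
        "rmse_deg",
        "mae_deg",
        "median_ae_deg",
        "p95_ae_deg",
        "ba_mean_diff_deg",
        "ba_loa_low_deg",
        "ba_loa_high_deg",
    ):
        d[f"{key}_display"] = round(d[key], 1)
    return d


def diagnostic_report_to_dict(r: DiagnosticReport) -> dict:
    d = dataclasses.asdict(r)
    d["n"] = r.n
    for key in ("sensitivity", "specificity", "ppv", "npv", "prevalence"):
        d[f"{key}_pct"] = _pct(getattr(r, key))
    for key in ("sensitivity_ci", "specificity_ci", "ppv_ci", "npv_ci"):
        ci = getattr(r, key)
        d[f"{key}_pct"] = None if ci is None else [_pct(ci[0]), _pct(ci[1])]
    return d


def detection_report_to_dict(r: DetectionEvalReport) -> dict:
    return {
        "n_images": r.n_images,
        "precision": r.precision,
        "recall": r.recall,
        "f1": r.f1,
        "ap50": r.ap50,
        "ap50_95": r.ap50_95,
        "mean_iou": r.mean_iou,
        "iou_sd": r.iou_sd,
        "image_success_rate": r.image_success_rate,
        "tp": r.tp,
        "fp": r.fp,
        "fn": r.fn,
        "per_level": {
            lvl.label: {
                "precision": m.precision,
                "recall": m.recall,
                "f1": m.f1,
                "mean_iou": m.mean_iou,
                "missed_count": m.missed_count,
            }
            for lvl, m in r.per_level.items()
        },
    }
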