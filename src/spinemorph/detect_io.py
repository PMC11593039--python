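"""Detector-output handling: YOLO-style text records, box matching, per-vertebra scores.

Detections arrive as normalized boxes ``class cx cy w h conf`` (one per
line, coordinates relative to the image).  Each detection is attributed to
the vertebra whose reference box it overlaps most (intersection over union),
and every vertebra is reduced to a single confidence score: the maximum over
its matched boxes, zero when nothing matched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

from .errors import InvalidInputError, ParseError

__all__ = [
    "DetectionBox",
    "VertebraScore",
    "box_iou",
    "read_yolo_file",
    "write_yolo_file",
    "match_boxes",
]

Corners = tuple[float, float, float, float]  # x0, y0, x1, y1 (normalized)


@dataclass(frozen=True)
class DetectionBox:
    """A detector box in normalized center/size form with a confidence score."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise InvalidInputError(f"box center ({self.cx}, {self.cy}) outside [0,1]")
        if self.w <= 0 or self.h <= 0:
            raise InvalidInputError(f"box size ({self.w}, {self.h}) must be positive")
        if not 0.0 <= self.confidence <= 1.0:
            raise InvalidInputError(f"confidence {self.confidence} outside [0,1]")

    def corners(self) -> Corners:
        return (
            self.cx - self.w / 2.0,
            self.cy - self.h / 2.0,
            self.cx + self.w / 2.0,
            self.cy + self.h / 2.0,
        )

    @classmethod
    def from_corners(
        cls, x0: float, y0: float, x1: float, y1: float,
        confidence: float, class_id: int = 0,
    ) -> "DetectionBox":
        return cls(
            class_id=class_id,
            cx=(x0 + x1) / 2.0, cy=(y0 + y1) / 2.0,
            w=x1 - x0, h=y1 - y0, confidence=confidence,
        )


@dataclass(frozen=True)
class VertebraScore:
    """One detector confidence per vertebra (0 when no box matched)."""

    vertebra_id: Hashable
    dl_confidence: float
    matched_box: DetectionBox | None = None

    @property
    def has_detection(self) -> bool:
        return self.matched_box is not None


def box_iou(a: Corners | DetectionBox, b: Corners | DetectionBox) -> float:
    """Intersection over union of two axis-aligned boxes; symmetric, in [0,1]."""
    ca = a.corners() if isinstance(a, DetectionBox) else a
    cb = b.corners() if isinstance(b, DetectionBox) else b
    ix = max(0.0, min(ca[2], cb[2]) - max(ca[0], cb[0]))
    iy = max(0.0, min(ca[3], cb[3]) - max(ca[1], cb[1]))
    inter = ix * iy
    area_a = (ca[2] - ca[0]) * (ca[3] - ca[1])
    area_b = (cb[2] - cb[0]) * (cb[3] - cb[1])
    union = area_a + area_b - inter
    if union <= 0:
        return 0.0
    return inter / union


def read_yolo_file(
    path: str | Path, image_shape: tuple[int, int] | None = None
) -> list[DetectionBox]:
    """Parse a YOLO-style detection file: rows of ``class cx cy w h conf``.

    Coordinates are normalized to the image; ``image_shape`` is accepted for
    interface symmetry with pixel-space callers and not needed for parsing.
    Rows failing range checks are rejected with their line number.
    """
    boxes: list[DetectionBox] = []
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 6:
            raise ParseError(f"expected 6 fields, got {len(fields)}: {raw!r}", line=lineno)
        try:
            class_id = int(fields[0])
            cx, cy, w, h, conf = (float(v) for v in fields[1:])
        except ValueError as exc:
            raise ParseError(f"non-numeric field in {raw!r}", line=lineno) from exc
        try:
            boxes.append(DetectionBox(class_id, cx, cy, w, h, conf))
        except InvalidInputError as exc:
            raise ParseError(str(exc), line=lineno) from exc
    return boxes


def write_yolo_file(path: str | Path, boxes: Iterable[DetectionBox]) -> None:
    lines = [
        f"{b.class_id} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f} {b.confidence:.6f}"
        for b in boxes
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def match_boxes(
    boxes: Sequence[DetectionBox],
    truth_boxes: Mapping[Hashable, Corners],
    iou_min: float = 0.25,
) -> tuple[list[VertebraScore], list[DetectionBox]]:
    """Attribute detections to vertebrae by maximal IoU.

    Each detection goes to the single vertebra with the highest IoU if that
    IoU reaches ``iou_min``, otherwise it is returned in the unmatched side
    list.  Per-vertebra confidence is the maximum over assigned boxes, 0 when
    none matched.  The default ``iou_min`` of 0.25 reflects vertebra-level
    attribution rather than localization quality.
    """
    import numpy as np

    vids = list(truth_boxes)
    best: dict[Hashable, DetectionBox] = {}
    unmatched: list[DetectionBox] = []
    if vids:
        t = np.asarray([truth_boxes[v] for v in vids], dtype=float)  # (n, 4)
        t_area = (t[:, 2] - t[:, 0]) * (t[:, 3] - t[:, 1])
        for box in boxes:
            x0, y0, x1, y1 = box.corners()
            ix = np.clip(np.minimum(x1, t[:, 2]) - np.maximum(x0, t[:, 0]), 0.0, None)
            iy = np.clip(np.minimum(y1, t[:, 3]) - np.maximum(y0, t[:, 1]), 0.0, None)
            inter = ix * iy
            union = (x1 - x0) * (y1 - y0) + t_area - inter
            with np.errstate(invalid="ignore", divide="ignore"):
                ious = np.where(union > 0, inter / union, 0.0)
            k = int(np.argmax(ious))
            if ious[k] < iou_min:
                unmatched.append(box)
                continue
            bid = vids[k]
            prev = best.get(bid)
            if prev is None or box.confidence > prev.confidence:
                best[bid] = box
    else:
        unmatched.extend(boxes)
    scores = [
        VertebraScore(vid, best[vid].confidence, best[vid])
        if vid in best else VertebraScore(vid, 0.0, None)
        for vid in truth_boxes
    ]
    return scores, unmatched


def max_score_over_slices(per_slice: Iterable[VertebraScore]) -> VertebraScore:
    """Aggregate one vertebra's scores across slices: keep the maximum.

    A fracture visible on any sagittal slice counts for the vertebra.
    """
    items = list(per_slice)
    if not items:
        raise InvalidInputError("no scores to aggregate")
    ids = {s.vertebra_id for s in items}
    if len(ids) != 1:
        raise InvalidInputError(f"scores belong to different vertebrae: {sorted(map(str, ids))}")
    return max(items, key=lambda s: s.dl_confidence)
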