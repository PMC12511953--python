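"""Axis-aligned box algebra: IoU and the corner-distance-penalised MPDIoU.

MPDIoU augments plain IoU with the squared Euclidean distances between
corresponding top-left and bottom-right corners of the two boxes, normalised
by the squared image diagonal (w**2 + h**2).  Unlike IoU it distinguishes
predictions that overlap a target equally well but sit at different corner
offsets, which is what makes its complement usable as a regression loss for
boxes that must follow an animal's contour tightly.

Coordinates are continuous and corner-based (x1, y1, x2, y2) with the origin
at the top-left of the image, x rightward and y downward.  MOT-style
(left, top, width, height) records are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidArgumentError, InvalidDataError

__all__ = ["Box", "Detection", "iou", "mpdiou", "mpdiou_loss"]


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle in pixel coordinates.

    ``x2 >= x1`` and ``y2 >= y1`` are enforced.  Zero-area boxes are legal —
    a tracker can momentarily produce them — but the aspect ratio is defined
    only for positive height.
    """

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        if not (self.x2 >= self.x1 and self.y2 >= self.y1):
            raise InvalidArgumentError(
                f"box corners must satisfy x2 >= x1 and y2 >= y1, got {self!r}"
            )

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def cx(self) -> float:
        return 0.5 * (self.x1 + self.x2)

    @property
    def cy(self) -> float:
        return 0.5 * (self.y1 + self.y2)

    @property
    def aspect(self) -> float:
        """Aspect-ratio coefficient width/height; requires positive height."""
        if self.height <= 0:
            raise InvalidDataError(f"aspect ratio undefined for zero-height box {self!r}")
        return self.width / self.height

    @classmethod
    def from_ltwh(cls, left: float, top: float, width: float, height: float) -> "Box":
        return cls(left, top, left + width, top + height)

    def to_ltwh(self) -> tuple[float, float, float, float]:
        return (self.x1, self.y1, self.width, self.height)

    @classmethod
    def from_xyah(cls, cx: float, cy: float, a: float, h: float) -> "Box":
        """Build from center, aspect ratio a = w/h and height (tracker state)."""
        w = a * h
        return cls(cx - w / 2.0, cy - h / 2.0, cx + w / 2.0, cy + h / 2.0)

    def to_xyah(self) -> tuple[float, float, float, float]:
        return (self.cx, self.cy, self.aspect, self.height)


@dataclass(frozen=True)
class Detection:
    """One detector output: a frame index (0-based internally), a box and a
    confidence score in [0, 1]."""

    frame: int
    box: Box
    confidence: float

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise InvalidArgumentError(f"frame index must be >= 0, got {self.frame}")
        if not 0.0 <= self.confidence <= 1.0:
            raise InvalidArgumentError(
                f"confidence must lie in [0, 1], got {self.confidence}"
            )


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes.

    Returns 0.0 for disjoint boxes and, by convention, when both boxes have
    zero area (the union is empty).  Symmetric in its arguments.
    """
    iw = min(a.x2, b.x2) - max(a.x1, b.x1)
    ih = min(a.y2, b.y2) - max(a.y1, b.y1)
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    inter = iw * ih
    union = a.area + b.area - inter
    if union <= 0.0:
        return 0.0
    return inter / union


def mpdiou(pred: Box, gt: Box, img_w: float, img_h: float) -> float:
    """IoU penalised by normalised squared corner distances.

        MPDIoU = IoU - (d1^2 + d2^2) / (w^2 + h^2)

    where d1, d2 are the Euclidean distances between the top-left and the
    bottom-right corners of the two boxes and (w, h) is the size of the
    *image*, passed explicitly.  For boxes inside the image the value lies in
    [-2, 1], with 1 iff the boxes coincide.
    """
    if img_w <= 0 or img_h <= 0:
        raise InvalidArgumentError(
            f"image dimensions must be positive, got {img_w} x {img_h}"
        )
    d1_sq = (pred.x1 - gt.x1) ** 2 + (pred.y1 - gt.y1) ** 2
    d2_sq = (pred.x2 - gt.x2) ** 2 + (pred.y2 - gt.y2) ** 2
    return iou(pred, gt) - (d1_sq + d2_sq) / (img_w**2 + img_h**2)


def mpdiou_loss(pred: Box, gt: Box, img_w: float, img_h: float) -> float:
    """Bounding-box regression loss 1 - MPDIoU; zero iff the boxes coincide."""
    return 1.0 - mpdiou(pred, gt, img_w, img_h)


def corner_distances_sq(a: Box, b: Box) -> tuple[float, float]:
    """Squared distances between corresponding top-left / bottom-right corners."""
    d1 = (a.x1 - b.x1) ** 2 + (a.y1 - b.y1) ** 2
    d2 = (a.x2 - b.x2) ** 2 + (a.y2 - b.y2) ** 2
    return d1, d2
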