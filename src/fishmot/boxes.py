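"""Core geometric types shared across the tracker, metrics and simulator.

Boxes are axis-aligned, in continuous pixel coordinates with a 0-based
origin at the top-left of the image.  File I/O (which uses the 1-based
MOTChallenge convention) converts at the boundary; see
:mod:`fishmot.motchallenge`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box with strictly positive dimensions."""

    left: float
    top: float
    width: float
    height: float

    def __post_init__(self) -> None:
        for name in ("left", "top", "width", "height"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite box field {name}={v!r}")
        if not (self.width > 0 and self.height > 0):
            raise ValueError(
                f"degenerate box: width={self.width}, height={self.height}"
            )

    @property
    def right(self) -> float:
        return self.left + self.width

    @property
    def bottom(self) -> float:
        return self.top + self.height

    @property
    def cx(self) -> float:
        return self.left + self.width / 2.0

    @property
    def cy(self) -> float:
        return self.top + self.height / 2.0

    @property
    def aspect(self) -> float:
        """Width / height ratio (the Kalman state's shape component)."""
        return self.width / self.height

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def diagonal(self) -> float:
        return math.hypot(self.width, self.height)

    def to_cah(self) -> tuple[float, float, float, float]:
        """(center-x, center-y, aspect, height) measurement vector."""
        return (self.cx, self.cy, self.aspect, self.height)

    @classmethod
    def from_cah(cls, cx: float, cy: float, a: float, h: float) -> "BoundingBox":
        w = a * h
        return cls(cx - w / 2.0, cy - h / 2.0, w, h)


@dataclass(frozen=True)
class Detection:
    """A detector output on one frame: a box plus a confidence score."""

    frame: int
    box: BoundingBox
    score: float

    def __post_init__(self) -> None:
        if self.frame < 1:
            raise ValueError(f"frame index must be >= 1, got {self.frame}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")


@dataclass
class Trajectory:
    """An identity-bearing sequence of boxes, at most one per frame."""

    identity: int
    boxes: dict[int, BoundingBox] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.identity < 1:
            raise ValueError(f"identity must be positive, got {self.identity}")

    @property
    def frames(self) -> list[int]:
        return sorted(self.boxes)

    def __len__(self) -> int:
        return len(self.boxes)
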