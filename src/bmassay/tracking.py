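"""Single-fish videotracking: blob segmentation and head/centroid/tail detection.

The tracker follows a three-step pipeline per frame: (1) the fish is searched
for inside a predefined rectangular region of the grayscale frame (the
tracked 12 x 12 cm inner area of the tank) by automatic intensity
thresholding, keeping the largest connected component; (2) the blob's center
of mass and its two extremities along the principal (second-moment) axis give
the centroid, head and tail -- the head is the endpoint on the half of the
blob with the greater area (fish are front-heavy), overridden by temporal
continuity when the implied heading would flip by more than 90 degrees
between consecutive frames; (3) the per-frame body points are assembled into
a :class:`Trajectory` in which failed frames are flagged, never dropped.

Coordinates are region-local pixels with y increasing upward: for a region
``(x0, y0, w, h)`` in image (row/col) convention, ``x = col - x0`` and
``y = (y0 + h - 1) - row``.  The synthetic renderer uses the same transform,
so tracker output is directly comparable with its ground truth and with the
arena coordinate frame used by the preference metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label

from .errors import GeometryError, StructureError

__all__ = [
    "BodyPoints",
    "Trajectory",
    "segment_fish",
    "body_points",
    "track_video",
    "heading",
]


@dataclass(frozen=True)
class BodyPoints:
    """Head/centroid/tail pixel coordinates for one frame (y up)."""

    frame_index: int
    ok: bool
    head: tuple[float, float] | None = None
    centroid: tuple[float, float] | None = None
    tail: tuple[float, float] | None = None


@dataclass
class Trajectory:
    """Per-frame body points of one fish, stored as dense arrays.

    ``head``, ``centroid`` and ``tail`` have shape ``(n_frames, 2)`` with NaN
    where ``ok`` is False.  ``fps`` is the recording rate (2 in the assay);
    ``arena`` optionally carries the pixel-to-cm mapping.
    """

    head: np.ndarray
    centroid: np.ndarray
    tail: np.ndarray
    ok: np.ndarray
    fps: float = 2.0
    arena: object | None = None

    def __post_init__(self) -> None:
        self.head = np.asarray(self.head, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.tail = np.asarray(self.tail, dtype=float)
        self.ok = np.asarray(self.ok, dtype=bool)
        n = len(self.ok)
        for name in ("head", "centroid", "tail"):
            arr = getattr(self, name)
            if arr.shape != (n, 2):
                raise StructureError(f"{name} must have shape ({n}, 2), got {arr.shape}")
        if not self.fps > 0:
            raise StructureError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.ok)

    @property
    def missing_count(self) -> int:
        return int((~self.ok).sum())

    def point(self, i: int) -> BodyPoints:
        if not self.ok[i]:
            return BodyPoints(frame_index=i, ok=False)
        return BodyPoints(
            frame_index=i,
            ok=True,
            head=tuple(self.head[i]),
            centroid=tuple(self.centroid[i]),
            tail=tuple(self.tail[i]),
        )

    @classmethod
    def from_points(
        cls, points: Sequence[BodyPoints], fps: float = 2.0, arena: object | None = None
    ) -> "Trajectory":
        n = len(points)
        head = np.full((n, 2), np.nan)
        cent = np.full((n, 2), np.nan)
        tail = np.full((n, 2), np.nan)
        ok = np.zeros(n, dtype=bool)
        for i, bp in enumerate(points):
            if bp.ok:
                ok[i] = True
                head[i] = bp.head
                cent[i] = bp.centroid
                tail[i] = bp.tail
        return cls(head=head, centroid=cent, tail=tail, ok=ok, fps=fps, arena=arena)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "ok": self.ok.astype(int),
                "head_x": self.head[:, 0],
                "head_y": self.head[:, 1],
                "cent_x": self.centroid[:, 0],
                "cent_y": self.centroid[:, 1],
                "tail_x": self.tail[:, 0],
                "tail_y": self.tail[:, 1],
            }
        )
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path: str | Path, fps: float = 2.0, arena: object | None = None) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(
            head=df[["head_x", "head_y"]].to_numpy(),
            centroid=df[["cent_x", "cent_y"]].to_numpy(),
            tail=df[["tail_x", "tail_y"]].to_numpy(),
            ok=df["ok"].to_numpy().astype(bool),
            fps=fps,
            arena=arena,
        )


def segment_fish(
    frame: np.ndarray,
    region: tuple[int, int, int, int],
    min_area: int = 30,
    min_contrast: float = 20.0,
) -> np.ndarray:
    """Largest thresholded connected component inside ``region``.

    ``region`` is ``(x0, y0, w, h)`` in image coordinates.  The threshold is
    Otsu's; polarity (dark fish on bright background or the reverse) is
    auto-detected by taking the minority side as foreground.  A frame whose
    foreground/background mean separation falls below ``min_contrast``
    intensity units is treated as fish-absent (Otsu always splits something,
    even pure sensor noise).  Returns a bool mask of shape ``(h, w)``;
    all-False when nothing qualifies or exceeds ``min_area``.
    """
    frame = np.asarray(frame)
    x0, y0, w, h = (int(v) for v in region)
    H, W = frame.shape[:2]
    if x0 < 0 or y0 < 0 or x0 + w > W or y0 + h > H or w <= 0 or h <= 0:
        raise GeometryError(f"region {region} outside image of shape {frame.shape}")
    crop = frame[y0 : y0 + h, x0 : x0 + w].astype(float)

    empty = np.zeros((h, w), dtype=bool)
    if crop.max() - crop.min() < 1e-9:
        return empty
    thr = threshold_otsu(crop)
    hi = crop > thr
    fg = hi if hi.sum() <= hi.size - hi.sum() else ~hi
    if not fg.any() or abs(crop[fg].mean() - crop[~fg].mean()) < min_contrast:
        return empty
    labels, n_cc = _cc_label(fg, return_num=True)
    if n_cc == 0:
        return empty
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    best = int(areas.argmax())
    if areas[best] < min_area:
        return empty
    return labels == best


def _mask_xy(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mask pixel coordinates in region-local y-up convention."""
    rows, cols = np.nonzero(mask)
    h = mask.shape[0]
    return cols.astype(float), (h - 1 - rows).astype(float)


def body_points(
    mask: np.ndarray,
    prev: Optional[BodyPoints] = None,
    frame_index: int = 0,
    tip_depth: float = 1.5,
) -> BodyPoints:
    """Centroid, head and tail of a blob mask (region-local y-up pixels).

    The head/tail axis is the principal eigenvector of the blob's second
    moments; each endpoint is estimated as the mean of the pixels within
    ``tip_depth`` px of the extreme projection (robust against single
    off-axis tip pixels).  Head = endpoint on the heavier (front-heavy) end,
    identified by the third moment of the axial projection: mass concentrated
    near the head leaves the long thin tail as the skew lobe, so the head
    lies opposite the skew.  Swapped if a previous detection implies a
    > 90 degree heading jump.
    """
    if mask is None or not np.asarray(mask).any():
        return BodyPoints(frame_index=frame_index, ok=False)
    x, y = _mask_xy(np.asarray(mask, dtype=bool))
    cx, cy = float(x.mean()), float(y.mean())
    xc, yc = x - cx, y - cy
    cov = np.array([[np.mean(xc * xc), np.mean(xc * yc)], [np.mean(xc * yc), np.mean(yc * yc)]])
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, int(np.argmax(evals))]
    proj = xc * axis[0] + yc * axis[1]

    skew = float(np.mean(proj**3))
    head_sign = 1.0 if skew <= 0 else -1.0

    def _tip(sign: float) -> tuple[float, float]:
        p = proj * sign
        sel = p >= p.max() - tip_depth
        return float(x[sel].mean()), float(y[sel].mean())

    head = _tip(head_sign)
    tail = _tip(-head_sign)

    if prev is not None and prev.ok and prev.head is not None and prev.centroid is not None:
        prev_dir = (prev.head[0] - prev.centroid[0], prev.head[1] - prev.centroid[1])
        new_dir = (head[0] - cx, head[1] - cy)
        if prev_dir[0] * new_dir[0] + prev_dir[1] * new_dir[1] < 0:
            head, tail = tail, head
    return BodyPoints(frame_index=frame_index, ok=True, head=head, centroid=(cx, cy), tail=tail)


def track_video(
    frames: Iterable[np.ndarray],
    region: tuple[int, int, int, int],
    arena: object | None = None,
    fps: float = 2.0,
    min_area: int = 30,
) -> Trajectory:
    """Run the per-frame pipeline over an image stream.

    Failed frames (no blob above ``min_area``) are recorded with ``ok=False``;
    the output length always equals the input length.
    """
    points: list[BodyPoints] = []
    prev: Optional[BodyPoints] = None
    for i, frame in enumerate(frames):
        mask = segment_fish(frame, region, min_area=min_area)
        bp = body_points(mask, prev=prev, frame_index=i)
        points.append(bp)
        if bp.ok:
            prev = bp
    if not points:
        raise StructureError("empty frame stream")
    return Trajectory.from_points(points, fps=fps, arena=arena)


def heading(bp: BodyPoints) -> float:
    """Heading angle of head minus centroid, degrees in [-180, 180), CCW from +x."""
    if not bp.ok or bp.head is None or bp.centroid is None:
        raise GeometryError("cannot compute heading of a failed detection")
    dx = bp.head[0] - bp.centroid[0]
    dy = bp.head[1] - bp.centroid[1]
    if dx == 0 and dy == 0:
        raise GeometryError("degenerate pose: head coincides with centroid")
    ang = math.degrees(math.atan2(dy, dx))
    return -180.0 if ang >= 180.0 else ang
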