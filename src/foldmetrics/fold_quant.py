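"""Per-fold morphometry from a binarized, blob-filtered fold mask.

Each 8-connected component of the mask is treated as one fold.  A
minimum-area rotated bounding rectangle is fitted to its pixel centres
(rotating calipers over the convex hull); the long and short rectangle
sides are the fold's length and width, and the slope of the rectangle's
diagonal (dY/dX, in a bottom-left-origin, Y-up frame) classifies the fold
as *vertical* (|slope| > 1) or *horizontal* (|slope| < 1).

Conventions
-----------
* Images are stored top-left origin (row, col); all rectangle geometry is
  converted to the bottom-left-origin X-right / Y-up frame before slopes
  are computed: ``X = col``, ``Y = (H - 1) - row``.
* Rectangle side lengths are distances between pixel centres, so an
  N-pixel axis-aligned run measures N - 1; reported fold lengths/widths
  add 1 to restore pixel counts.
* A diagonal slope of exactly +/-1 is classified horizontal (the interval
  rule "over 1 / under -1" assigns it to neither side); configurable via
  ``tie``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

__all__ = [
    "RotatedRect",
    "Fold",
    "FoldSummary",
    "min_area_rect",
    "fold_gradient",
    "classify_orientation",
    "extract_folds",
    "summarize",
]


@dataclass(frozen=True)
class RotatedRect:
    """Minimum-area bounding rectangle in the bottom-left-origin frame.

    ``corners`` are ordered around the rectangle, so opposite corners are
    two apart.  ``length_px >= width_px`` are the geometric side lengths
    (pixel-centre distances); ``angle_deg`` is the orientation of the long
    side in degrees measured counter-clockwise from the +X axis.
    """

    corners: np.ndarray  # (4, 2) float, sequential order
    length_px: float
    width_px: float
    angle_deg: float


@dataclass(frozen=True)
class Fold:
    """One connected component with its fitted rectangle and metrics."""

    component_id: int
    pixel_count: int
    rect: RotatedRect
    gradient: float  # dY/dX of the rectangle diagonal; +inf if vertical
    orientation: str  # 'vertical' | 'horizontal'

    @property
    def length_px(self) -> float:
        """Fold length in pixels (rect long side + 1, pixel convention)."""
        return self.rect.length_px + 1.0

    @property
    def width_px(self) -> float:
        """Fold width in pixels (rect short side + 1, pixel convention)."""
        return self.rect.width_px + 1.0


@dataclass(frozen=True)
class FoldSummary:
    """Per-image fold metrics (one row of the longitudinal cohort table)."""

    density_pct: float
    n_total: int
    n_vertical: int
    n_horizontal: int
    mean_length_px: float
    mean_width_px: float
    is_empty: bool = field(default=False)


def min_area_rect(points) -> RotatedRect:
    """Minimum-area rectangle enclosing ``points`` ((X, Y) pairs).

    Uses the rotating-calipers property: some side of the optimal rectangle
    is collinear with an edge of the convex hull, so only hull-edge
    orientations need to be scanned.  Collinear point sets yield a
    degenerate rectangle with ``width_px = 0``; a single point degenerates
    to four equal corners.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("min_area_rect requires at least one point")
    if pts.shape[1] != 2:
        raise ValueError("points must be (X, Y) pairs")

    uniq = np.unique(pts, axis=0)
    if len(uniq) == 1:
        c = np.repeat(uniq, 4, axis=0)
        return RotatedRect(corners=c, length_px=0.0, width_px=0.0, angle_deg=0.0)

    try:
        hull = ConvexHull(uniq)
        hp = uniq[hull.vertices]
    except QhullError:
        # all points collinear: rectangle degenerates to the spanning segment
        d = uniq[-1] - uniq[0]
        d = d / np.linalg.norm(d)
        proj = uniq @ d
        lo, hi = uniq[np.argmin(proj)], uniq[np.argmax(proj)]
        corners = np.array([lo, hi, hi, lo])
        return RotatedRect(
            corners=corners,
            length_px=float(np.linalg.norm(hi - lo)),
            width_px=0.0,
            angle_deg=float(np.degrees(math.atan2(d[1], d[0]))),
        )

    edges = np.roll(hp, -1, axis=0) - hp
    norms = np.linalg.norm(edges, axis=1)
    u = edges[norms > 0] / norms[norms > 0, None]  # unit edge directions
    v = np.stack([-u[:, 1], u[:, 0]], axis=1)  # normals

    s = hp @ u.T  # projections along each candidate orientation
    t = hp @ v.T
    ws = s.max(axis=0) - s.min(axis=0)
    wt = t.max(axis=0) - t.min(axis=0)
    areas = ws * wt
    k = int(np.argmin(areas))

    s0, s1 = s[:, k].min(), s[:, k].max()
    t0, t1 = t[:, k].min(), t[:, k].max()
    uk, vk = u[k], v[k]
    corners = np.array(
        [
            s0 * uk + t0 * vk,
            s1 * uk + t0 * vk,
            s1 * uk + t1 * vk,
            s0 * uk + t1 * vk,
        ]
    )
    side_u, side_v = float(s1 - s0), float(t1 - t0)
    if side_u >= side_v:
        length, width, long_dir = side_u, side_v, uk
    else:
        length, width, long_dir = side_v, side_u, vk
    angle = math.degrees(math.atan2(long_dir[1], long_dir[0]))
    return RotatedRect(
        corners=corners, length_px=length, width_px=width, angle_deg=angle
    )


def fold_gradient(rect: RotatedRect) -> float:
    """Slope dY/dX of the rectangle diagonal.

    The diagonal runs from the corner with minimal X + Y to its opposite
    corner (deterministic choice; for elongated folds both diagonals fall
    on the same side of the +/-1 classification boundary).  A vertical
    diagonal returns +inf; a degenerate point rectangle has no orientation
    and returns NaN with a warning (classified horizontal downstream).
    """
    c = rect.corners
    i = int(np.argmin(c.sum(axis=1)))
    j = (i + 2) % 4
    dx = c[j, 0] - c[i, 0]
    dy = c[j, 1] - c[i, 1]
    if dx == 0.0 and dy == 0.0:
        warnings.warn(
            "degenerate point rectangle has undefined orientation; "
            "classified horizontal",
            stacklevel=2,
        )
        return math.nan
    if dx == 0.0:
        return math.inf
    return dy / dx


def classify_orientation(gradient: float, tie: str = "horizontal") -> str:
    """Interval rule: vertical iff slope > 1 or < -1, horizontal iff within.

    A slope of exactly +/-1 belongs to neither open interval; it is assigned
    per ``tie`` (default 'horizontal').  +/-inf is vertical; NaN (undefined
    orientation) is horizontal.
    """
    if tie not in ("horizontal", "vertical"):
        raise ValueError("tie must be 'horizontal' or 'vertical'")
    if math.isnan(gradient):
        return "horizontal"
    if math.isinf(gradient):
        return "vertical"
    if gradient > 1.0 or gradient < -1.0:
        return "vertical"
    if -1.0 < gradient < 1.0:
        return "horizontal"
    return tie  # gradient exactly +1 or -1


def extract_folds(
    mask: np.ndarray,
    connectivity: int = 8,
    tie: str = "horizontal",
) -> list[Fold]:
    """One :class:`Fold` per connected component of a blob-filtered mask.

    Components are ordered deterministically by their topmost-then-leftmost
    pixel.  Component ids are 1-based in that order.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        return []
    h = mask.shape[0]
    labels = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    regions = measure.regionprops(labels)
    # coords are emitted in row-major scan order, so coords[0] is the
    # lexicographic (row, col) minimum of the component
    regions.sort(key=lambda r: tuple(r.coords[0]))

    folds = []
    for cid, region in enumerate(regions, start=1):
        rows = region.coords[:, 0]
        cols = region.coords[:, 1]
        pts = np.stack([cols, (h - 1) - rows], axis=1).astype(float)
        rect = min_area_rect(pts)
        with warnings.catch_warnings():
            if len(region.coords) == 1:
                warnings.simplefilter("ignore")
            grad = fold_gradient(rect)
        folds.append(
            Fold(
                component_id=cid,
                pixel_count=int(region.area),
                rect=rect,
                gradient=grad,
                orientation=classify_orientation(grad, tie=tie),
            )
        )
    return folds


def summarize(mask: np.ndarray, folds: list[Fold]) -> FoldSummary:
    """Per-image summary: density, orientation counts, mean length/width.

    Density is the white-pixel fraction of the image x 100.  With no folds
    the means are reported as 0 with ``is_empty`` set.
    """
    mask = np.asarray(mask, dtype=bool)
    density = 100.0 * float(mask.sum()) / mask.size
    n_v = sum(1 for f in folds if f.orientation == "vertical")
    n_h = sum(1 for f in folds if f.orientation == "horizontal")
    if folds:
        mean_len = float(np.mean([f.length_px for f in folds]))
        mean_wid = float(np.mean([f.width_px for f in folds]))
    else:
        mean_len = mean_wid = 0.0
    return FoldSummary(
        density_pct=density,
        n_total=len(folds),
        n_vertical=n_v,
        n_horizontal=n_h,
        mean_length_px=mean_len,
        mean_width_px=mean_wid,
        is_empty=not folds,
    )
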