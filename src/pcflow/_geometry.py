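"""Shared polygon geometry on the pixel grid.

One convention used everywhere: coordinates are 0-based (x = column,
y = row) with pixel centers at integer positions; a pixel belongs to a
contour when its center lies inside the polygon (even-odd rule); areas
are signed shoelace areas, positive for counter-clockwise orientation
in (x, y).
"""

from __future__ import annotations

import numpy as np
from matplotlib.path import Path
from shapely.geometry import Polygon


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon given as (N, 2) vertices."""
    x = points[:, 0]
    y = points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_centroid(points: np.ndarray) -> tuple[float, float]:
    """Area centroid of a simple polygon (shoelace formula)."""
    x = points[:, 0]
    y = points[:, 1]
    xn = np.roll(x, -1)
    yn = np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-12:
        # degenerate: fall back to vertex mean
        return float(np.mean(x)), float(np.mean(y))
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return float(cx), float(cy)


def is_simple_polygon(points: np.ndarray) -> bool:
    """True when the closed polygon does not self-intersect."""
    if len(points) < 3:
        return False
    return Polygon(points).is_valid


def interior_mask(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean (H, W) mask of pixels whose centers fall inside the polygon."""
    h, w = shape
    # restrict the point-in-polygon test to the bounding box
    x0 = max(int(np.floor(points[:, 0].min())), 0)
    x1 = min(int(np.ceil(points[:, 0].max())), w - 1)
    y0 = max(int(np.floor(points[:, 1].min())), 0)
    y1 = min(int(np.ceil(points[:, 1].max())), h - 1)
    mask = np.zeros((h, w), dtype=bool)
    if x1 < x0 or y1 < y0:
        return mask
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    inside = Path(points).contains_points(pts)  # implicitly closed
    mask[y0:y1 + 1, x0:x1 + 1] = inside.reshape(ys.shape)
    return mask


def circle_polygon(cx: float, cy: float, r: float, n: int = 64,
                   phase_index: int = 0):
    """Regular n-gon approximation of a circle, as a Contour."""
    from .pcmr_io import Contour

    t = 2.0 * np.pi * np.arange(n) / n
    pts = np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])
    return Contour(points=pts, phase_index=phase_index)


def resample_closed_curve(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon to n vertices at uniform arc length."""
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return np.repeat(points[:1], n, axis=0)
    targets = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(targets, s, closed[:, 0])
    y = np.interp(targets, s, closed[:, 1])
    return np.column_stack([x, y])
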