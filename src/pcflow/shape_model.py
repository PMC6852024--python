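"""Statistical shape model of vessel cross-sections.

Great-vessel lumina in 2D PC-MR are near-convex, star-shaped blobs.
Each contour is parameterized by the radial distances from its area
centroid to the boundary along ``n_points`` equiangular rays,
normalized by the mean radius so that translation and isotropic scale
are removed before statistics.  Principal component analysis of the
pooled normalized radius vectors (all phases of all training subjects,
per vessel) yields a mean shape and a small set of orthonormal
variation modes.  Shape-constrained reconstruction projects a
candidate contour onto the retained modes and clips each coefficient
to ``clip_sd`` standard deviations, then rebuilds the contour with the
original centroid and scale — so the constraint acts on shape only,
never on position or size.

No rotational alignment is performed: vessel orientation in the
imaging plane is anatomically consistent under a fixed scan protocol,
so orientation is an informative part of the shape.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .pcmr_io import Contour, SegmentationResult

__all__ = ["ShapeVector", "ShapeModel", "parameterize_contour",
           "shape_vector_to_contour", "fit_shape_model", "reconstruct_shape"]

_EIGENVALUE_FLOOR = 1e-12  # below this a mode is treated as degenerate


@dataclass
class ShapeVector:
    """Normalized radial parameterization of one contour.

    radii     : (n_points,) radial distances / mean radius (unitless).
    scale     : the mean radius that was divided out (pixels).
    centroid  : (x, y) ray origin in pixel coordinates.
    """

    radii: np.ndarray
    scale: float
    centroid: tuple[float, float]

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")


@dataclass
class ShapeModel:
    """PCA shape constraints for one vessel type."""

    mean_shape: np.ndarray           # (n_points,), mean normalized radii
    modes: np.ndarray                # (n_points, n_modes_retained), orthonormal
    eigenvalues: np.ndarray          # (n_modes_retained,), non-increasing
    n_modes_retained: int
    clip_sd: float = 3.0
    vessel_label: str = "other"

    def __post_init__(self):
        self.mean_shape = np.asarray(self.mean_shape, dtype=float)
        self.modes = np.asarray(self.modes, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        k = self.n_modes_retained
        if self.modes.shape != (len(self.mean_shape), k):
            raise ValueError("modes must be (n_points, n_modes_retained)")
        if k > len(self.mean_shape):
            raise ValueError("cannot retain more modes than points")
        gram = self.modes.T @ self.modes
        if k and not np.allclose(gram, np.eye(k), atol=1e-8):
            raise ValueError("modes are not orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be non-increasing")

    @property
    def n_points(self) -> int:
        return len(self.mean_shape)

    def save(self, path: str | os.PathLike) -> None:
        np.savez(path, schema_version=np.int64(1),
                 mean_shape=self.mean_shape, modes=self.modes,
                 eigenvalues=self.eigenvalues,
                 n_modes_retained=np.int64(self.n_modes_retained),
                 clip_sd=np.float64(self.clip_sd),
                 vessel_label=np.str_(self.vessel_label))

    @classmethod
    def load(cls, path: str | os.PathLike) -> "ShapeModel":
        with np.load(path, allow_pickle=False) as z:
            return cls(mean_shape=z["mean_shape"], modes=z["modes"],
                       eigenvalues=z["eigenvalues"],
                       n_modes_retained=int(z["n_modes_retained"]),
                       clip_sd=float(z["clip_sd"]),
                       vessel_label=str(z["vessel_label"]))


def _ray_angles(n_points: int) -> np.ndarray:
    return 2.0 * np.pi * np.arange(n_points) / n_points


def _radial_distances(points: np.ndarray, origin: tuple[float, float],
                      angles: np.ndarray) -> np.ndarray:
    """Distances from origin to the polygon boundary along given ray angles.

    Requires the polygon to be star-shaped with respect to the origin,
    i.e. every ray from the origin crosses the boundary exactly once;
    equivalently the vertex polar angles are monotone along the
    (counter-clockwise) traversal.
    """
    rel = points - np.asarray(origin)
    r_v = np.hypot(rel[:, 0], rel[:, 1])
    if np.any(r_v < 1e-9):
        raise ValueError("parameterization origin lies on the boundary")
    phi = np.arctan2(rel[:, 1], rel[:, 0])
    dphi = np.diff(phi, append=phi[:1])
    dphi = np.mod(dphi + np.pi, 2 * np.pi) - np.pi
    back = dphi < -1e-12
    if np.any(back):
        i = int(np.argmin(dphi))
        raise ValueError(
            "contour is not star-shaped about its centroid: boundary "
            f"backtracks near ray angle {np.degrees(phi[i]) % 360:.1f} deg")
    if not np.isclose(np.sum(dphi), 2 * np.pi, atol=1e-6):
        raise ValueError("contour does not wind once about the origin")

    # unwrapped vertex angles, increasing from phi[0]
    cum = phi[0] + np.concatenate([[0.0], np.cumsum(dphi[:-1])])
    n = len(points)
    out = np.empty(len(angles))
    for k, theta in enumerate(angles):
        # bring theta into [cum[0], cum[0] + 2*pi)
        t = cum[0] + np.mod(theta - cum[0], 2 * np.pi)
        # vertex hit: reuse the vertex distance exactly
        hit = np.where(np.abs(cum - t) < 1e-12)[0]
        if hit.size:
            out[k] = r_v[hit[0]]
            continue
        i = int(np.searchsorted(cum, t, side="right") - 1)
        j = (i + 1) % n
        a = rel[i]
        d = rel[j] - rel[i]
        u = np.array([np.cos(t), np.sin(t)])
        denom = u[0] * d[1] - u[1] * d[0]
        if abs(denom) < 1e-15:
            out[k] = r_v[i]
            continue
        s = -(u[0] * a[1] - u[1] * a[0]) / denom
        p = a + s * d
        out[k] = float(u @ p)
    if np.any(out <= 0):
        raise ValueError("ray intersection produced a non-positive radius")
    return out


def parameterize_contour(c: Contour, n_points: int = 48) -> ShapeVector:
    """Radial shape vector of a star-shaped contour.

    Rays are cast at ``n_points`` equiangular directions from the
    contour's area centroid (or, for contours produced by
    :func:`shape_vector_to_contour`, from the recorded build origin so
    that parameterize/rebuild round-trips are exact).
    """
    origin = c.radial_origin if c.radial_origin is not None else c.centroid()
    radii = _radial_distances(c.points, origin, _ray_angles(n_points))
    scale = float(np.mean(radii))
    return ShapeVector(radii=radii / scale, scale=scale,
                       centroid=(float(origin[0]), float(origin[1])))


def shape_vector_to_contour(sv: ShapeVector, phase_index: int = 0) -> Contour:
    """Inverse of :func:`parameterize_contour` (up to ray sampling)."""
    theta = _ray_angles(len(sv.radii))
    r = sv.radii * sv.scale
    pts = np.column_stack([sv.centroid[0] + r * np.cos(theta),
                           sv.centroid[1] + r * np.sin(theta)])
    return Contour(points=pts, phase_index=phase_index,
                   radial_origin=sv.centroid)


def fit_shape_model(training: list[SegmentationResult], n_points: int = 48,
                    variance_kept: float = 0.95, clip_sd: float = 3.0,
                    vessel_label: str = "other") -> ShapeModel:
    """Fit PCA shape constraints from time-resolved reference delineations.

    All phases of all training subjects are pooled; the model then
    applies at any point of the cardiac cycle.  ``n_modes_retained`` is
    the smallest number of modes whose cumulative explained variance
    reaches ``variance_kept``.
    """
    rows = []
    for seg in training:
        for c in seg.contours:
            rows.append(parameterize_contour(c, n_points).radii)
    if len(rows) < 2:
        raise ValueError("need at least 2 training contours")
    x = np.asarray(rows)
    mean = x.mean(axis=0)
    xc = x - mean
    # PCA by thin SVD; eigenvalues are sample variances (ddof=1)
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s**2 / (len(rows) - 1)
    total = float(eig.sum())
    if total < _EIGENVALUE_FLOOR:
        # all training shapes identical after normalization
        k = 1
        modes = vt[:1].T
        eig = eig[:1]
    else:
        cum = np.cumsum(eig) / total
        k = int(np.searchsorted(cum, variance_kept - 1e-12) + 1)
        k = min(k, len(eig))
        modes = vt[:k].T
        eig = eig[:k]
    # deterministic sign: largest-magnitude entry of each mode positive
    for j in range(modes.shape[1]):
        i = int(np.argmax(np.abs(modes[:, j])))
        if modes[i, j] < 0:
            modes[:, j] = -modes[:, j]
    return ShapeModel(mean_shape=mean, modes=modes, eigenvalues=eig,
                      n_modes_retained=modes.shape[1], clip_sd=clip_sd,
                      vessel_label=vessel_label)


def reconstruct_shape(c: Contour, model: ShapeModel) -> Contour:
    """Project a contour onto the shape model and clip mode coefficients.

    The output keeps the input's centroid and mean radius exactly;
    only the normalized radial profile is constrained.  Coefficients
    along degenerate (zero-variance) modes are forced to zero.
    """
    sv = parameterize_contour(c, model.n_points)
    b = model.modes.T @ (sv.radii - model.mean_shape)
    bound = model.clip_sd * np.sqrt(np.maximum(model.eigenvalues, 0.0))
    bound[model.eigenvalues < _EIGENVALUE_FLOOR] = 0.0
    b = np.clip(b, -bound, bound)
    radii = model.mean_shape + model.modes @ b
    if np.any(radii <= 0):
        raise ValueError("shape reconstruction produced non-positive radii")
    return shape_vector_to_contour(
        ShapeVector(radii=radii, scale=sv.scale, centroid=sv.centroid),
        phase_index=c.phase_index)
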