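"""I/O and core containers for 2D phase-contrast MR (PC-MR) series.

A PC-MR acquisition delivers a time-resolved pair of image stacks over
one cardiac cycle: a magnitude stack (anatomy) and a phase stack whose
pixel values encode through-plane velocity.  Phase pi maps to +VENC
(the velocity-encoding limit, cm/s) and -pi to -VENC.

Units throughout the package: lengths mm, velocities cm/s, times ms,
volumes ml.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

from ._geometry import (interior_mask, is_simple_polygon, polygon_centroid,
                        signed_area)

__all__ = [
    "ImageSeries", "Contour", "VelocityMap", "SegmentationResult",
    "read_series", "write_series", "phase_to_velocity",
    "read_contours", "write_contours",
]

CONTOUR_SCHEMA_VERSION = 1


@dataclass
class Contour:
    """Closed simple polygon outlining a vessel lumen in one time phase.

    Points are (x, y) pixel coordinates (0-based, pixel centers at
    integers), stored counter-clockwise (positive shoelace area).

    ``radial_origin`` optionally records the centroid a radially
    parameterized contour was built around, so that re-parameterization
    samples the identical rays (used by the shape model for exact
    round-trips); it is not part of the serialized schema.
    """

    points: np.ndarray
    phase_index: int = 0
    radial_origin: tuple[float, float] | None = field(default=None,
                                                      compare=False)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("contour points must be an (N, 2) array")
        if len(pts) < 3:
            raise ValueError(
                f"contour needs >= 3 points, got {len(pts)} "
                f"(phase {self.phase_index})")
        if not is_simple_polygon(pts):
            raise ValueError(
                f"contour is self-intersecting (phase {self.phase_index})")
        if signed_area(pts) < 0:
            pts = pts[::-1].copy()
        self.points = pts

    @property
    def n_points(self) -> int:
        return len(self.points)

    def area(self) -> float:
        """Enclosed area in pixel^2 (shoelace)."""
        return signed_area(self.points)

    def centroid(self) -> tuple[float, float]:
        return polygon_centroid(self.points)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Pixel-center interior mask on an (H, W) grid."""
        return interior_mask(self.points, shape)

    def shifted(self, dx: float, dy: float, phase_index: int | None = None) -> "Contour":
        origin = None
        if self.radial_origin is not None:
            origin = (self.radial_origin[0] + dx, self.radial_origin[1] + dy)
        return Contour(points=self.points + np.array([dx, dy]),
                       phase_index=self.phase_index if phase_index is None
                       else phase_index,
                       radial_origin=origin)


@dataclass
class ImageSeries:
    """Paired magnitude and phase stacks with acquisition metadata.

    magnitude, phase : (T, H, W) arrays; phase in radians in [-pi, pi).
    pixel_spacing : (dy, dx) mm/pixel.
    temporal_resolution : ms per cardiac phase.
    venc : velocity-encoding limit, cm/s.
    rr_interval : cardiac cycle length, ms.
    """

    magnitude: np.ndarray
    phase: np.ndarray
    pixel_spacing: tuple[float, float]
    temporal_resolution: float
    venc: float
    rr_interval: float
    vessel_label: str = "other"

    def __post_init__(self):
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.magnitude.shape != self.phase.shape:
            raise ValueError(
                f"magnitude shape {self.magnitude.shape} != phase shape "
                f"{self.phase.shape}")
        if self.magnitude.ndim != 3 or self.magnitude.shape[0] < 2:
            raise ValueError("need a (T, H, W) stack with T >= 2")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be non-negative")
        if min(self.pixel_spacing) <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if self.temporal_resolution <= 0 or self.rr_interval <= 0:
            raise ValueError("temporal_resolution and rr_interval must be positive")
        t = self.magnitude.shape[0]
        if t * self.temporal_resolution > self.rr_interval * 1.10:
            raise ValueError(
                "T x temporal_resolution exceeds the RR interval by more "
                "than the 10% gating tolerance")
        if self.phase.min() < -np.pi - 1e-9 or self.phase.max() >= np.pi + 1e-9:
            raise ValueError("phase must lie in [-pi, pi) radians")
        if self.vessel_label not in ("aorta", "pulmonary", "other"):
            raise ValueError(f"unknown vessel_label {self.vessel_label!r}")

    @property
    def n_phases(self) -> int:
        return self.magnitude.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.magnitude.shape[1:]

    def phase_times_ms(self) -> np.ndarray:
        """Mid-phase acquisition times relative to the R wave."""
        return (np.arange(self.n_phases) + 0.5) * self.temporal_resolution


@dataclass
class VelocityMap:
    """Through-plane velocity field, cm/s, one frame per cardiac phase."""

    velocity: np.ndarray
    venc: float
    corrected: bool = False

    def __post_init__(self):
        self.velocity = np.asarray(self.velocity, dtype=float)
        # allow a whisker of slack for background-corrected data
        if np.any(np.abs(self.velocity) > self.venc * (1 + 1e-9)) and not self.corrected:
            raise ValueError("velocity exceeds VENC (aliasing is out of scope)")


@dataclass
class SegmentationResult:
    """Time-resolved segmentation: one contour per cardiac phase.

    Carries full provenance of the processing loop: the order in which
    phases were segmented, the rigid shift applied when each phase was
    initialized from its neighbour, and the high-velocity class.
    """

    contours: list[Contour]
    seed_phase: int = 0
    processing_order: list[int] | None = None
    shifts: list[tuple[float, float]] | None = None
    high_velocity_phases: frozenset[int] = frozenset()

    def __post_init__(self):
        t = len(self.contours)
        if t < 1:
            raise ValueError("need at least one contour")
        for i, c in enumerate(self.contours):
            if c.phase_index != i:
                raise ValueError(
                    f"contour {i} has phase_index {c.phase_index}; expected "
                    "exactly one contour per phase, in order")
        if self.processing_order is None:
            self.processing_order = list(range(t))
        if self.shifts is None:
            self.shifts = [(0.0, 0.0)] * t
        order = self.processing_order
        if sorted(order) != list(range(t)):
            raise ValueError("processing_order must be a permutation of 0..T-1")
        seen = {order[0]}
        for p in order[1:]:
            if (p - 1) not in seen and (p + 1) not in seen:
                raise ValueError(
                    f"phase {p} processed before any temporal neighbour")
            seen.add(p)
        self.high_velocity_phases = frozenset(self.high_velocity_phases)

    @property
    def n_phases(self) -> int:
        return len(self.contours)


def phase_to_velocity(series: ImageSeries) -> VelocityMap:
    """Convert the phase stack to velocity: v = phase / pi * VENC (cm/s)."""
    return VelocityMap(velocity=series.phase / np.pi * series.venc,
                       venc=series.venc, corrected=False)


# ---------------------------------------------------------------------------
# Array container (.npz): the canonical on-disk format for tests/phantoms.
# ---------------------------------------------------------------------------

def write_series(series: ImageSeries, path: str | os.PathLike) -> None:
    """Write an ImageSeries to the package's .npz array container."""
    np.savez(path,
             magnitude=series.magnitude,
             phase=series.phase,
             pixel_spacing=np.asarray(series.pixel_spacing, dtype=float),
             temporal_resolution=np.float64(series.temporal_resolution),
             venc=np.float64(series.venc),
             rr_interval=np.float64(series.rr_interval),
             vessel_label=np.str_(series.vessel_label))


def _read_series_npz(path) -> ImageSeries:
    with np.load(path, allow_pickle=False) as z:
        for key in ("magnitude", "phase", "pixel_spacing",
                    "temporal_resolution", "venc", "rr_interval"):
            if key not in z:
                raise ValueError(f"array container is missing field {key!r}")
        return ImageSeries(
            magnitude=z["magnitude"],
            phase=z["phase"],
            pixel_spacing=tuple(z["pixel_spacing"]),
            temporal_resolution=float(z["temporal_resolution"]),
            venc=float(z["venc"]),
            rr_interval=float(z["rr_interval"]),
            vessel_label=str(z["vessel_label"]) if "vessel_label" in z else "other",
        )


def _read_series_dicom(path, venc: float | None = None,
                       vessel_label: str = "other") -> ImageSeries:
    """Best-effort reader for the common magnitude + phase two-series layout.

    Phase pixel values are mapped to radians with the stored rescale
    slope/intercept, assuming the vendor's linear [-pi, pi) convention.
    VENC is taken from the private/sequence metadata when recognizable,
    else it must be supplied by the caller.
    """
    import pydicom

    files = sorted(
        os.path.join(path, f) for f in os.listdir(path)
        if not f.startswith("."))
    mags, phases = [], []
    spacing = None
    trigger_dt = None
    rr = None
    found_venc = venc
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        itype = "\\".join(getattr(ds, "ImageType", []) or []).upper()
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        trig = float(getattr(ds, "TriggerTime", len(mags) + len(phases)))
        if spacing is None and hasattr(ds, "PixelSpacing"):
            spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
        if rr is None and hasattr(ds, "NominalInterval"):
            rr = float(ds.NominalInterval)
        if found_venc is None and hasattr(ds, "SequenceName"):
            # Siemens convention: sequence name like 'fl2d1_v200in'
            import re
            m = re.search(r"[vV](\d+)", str(ds.SequenceName))
            if m:
                found_venc = float(m.group(1))
        if "\\P\\" in f"\\{itype}\\" or "PHASE" in itype:
            phases.append((trig, arr * slope + intercept))
        else:
            mags.append((trig, arr * slope + intercept))
    if not phases:
        raise ValueError("phase series not found in DICOM directory")
    if not mags:
        raise ValueError("magnitude series not found in DICOM directory")
    if len(mags) != len(phases):
        raise ValueError(
            f"mismatched magnitude/phase geometry: {len(mags)} magnitude vs "
            f"{len(phases)} phase frames")
    mags.sort(key=lambda p: p[0])
    phases.sort(key=lambda p: p[0])
    mag = np.stack([a for _, a in mags])
    pha = np.stack([a for _, a in phases])
    if mag.shape != pha.shape:
        raise ValueError("mismatched magnitude/phase geometry")
    if spacing is None:
        raise ValueError("missing metadata: PixelSpacing")
    if found_venc is None:
        raise ValueError("missing metadata: VENC (pass venc= explicitly)")
    times = np.array([t for t, _ in mags])
    if trigger_dt is None:
        trigger_dt = float(np.median(np.diff(times))) if len(times) > 1 else 30.0
    if rr is None:
        rr = trigger_dt * len(mags)
    # clamp the representable extreme exactly onto [-pi, pi)
    pha = np.clip(pha, -np.pi, np.pi * (1 - 1e-12))
    return ImageSeries(magnitude=np.clip(mag, 0, None), phase=pha,
                       pixel_spacing=spacing, temporal_resolution=trigger_dt,
                       venc=found_venc, rr_interval=rr,
                       vessel_label=vessel_label)


def read_series(path: str | os.PathLike, format: str = "auto",
                venc: float | None = None,
                vessel_label: str = "other") -> ImageSeries:
    """Read an ImageSeries from the array container or a DICOM directory."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "auto":
        format = "dicom" if os.path.isdir(path) else "array-container"
    if format == "array-container":
        return _read_series_npz(path)
    if format == "dicom":
        return _read_series_dicom(path, venc=venc, vessel_label=vessel_label)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Contour JSON
# ---------------------------------------------------------------------------

def write_contours(seg: SegmentationResult, path: str | os.PathLike) -> None:
    """Serialize a SegmentationResult to the documented JSON schema."""
    doc = {
        "schema_version": CONTOUR_SCHEMA_VERSION,
        "seed_phase": int(seg.seed_phase),
        "processing_order": [int(i) for i in seg.processing_order],
        "shifts": [[float(dx), float(dy)] for dx, dy in seg.shifts],
        "high_velocity_phases": sorted(int(i) for i in seg.high_velocity_phases),
        "contours": [
            {"phase_index": int(c.phase_index),
             "points": np.asarray(c.points, dtype=float).tolist()}
            for c in seg.contours
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_contours(path: str | os.PathLike) -> SegmentationResult:
    with open(path) as fh:
        doc = json.load(fh)
    contours = []
    for entry in doc["contours"]:
        idx = entry.get("phase_index", len(contours))
        pts = np.asarray(entry["points"], dtype=float)
        try:
            contours.append(Contour(points=pts, phase_index=int(idx)))
        except ValueError as e:
            raise ValueError(f"invalid contour at phase {idx}: {e}") from e
    contours.sort(key=lambda c: c.phase_index)
    return SegmentationResult(
        contours=contours,
        seed_phase=int(doc.get("seed_phase", 0)),
        processing_order=doc.get("processing_order"),
        shifts=[tuple(s) for s in doc["shifts"]] if "shifts" in doc else None,
        high_velocity_phases=frozenset(doc.get("high_velocity_phases", [])),
    )
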