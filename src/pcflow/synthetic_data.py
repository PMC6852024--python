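"""Synthetic pulsatile-vessel phantoms with analytic ground truth.

The generator emulates a 2D PC-MR acquisition of a single great-vessel
cross-section over one cardiac cycle: a near-elliptical lumen that pulsates in
size, translates in-plane, carries a parabolic (or plug) through-plane
velocity profile with a systolic pulse and small diastolic flow, and —
crucially for segmentation robustness — loses most of its
lumen/background magnitude contrast during diastole.  Because lumen
geometry and velocity profile are analytic, per-phase flow and the net
flow volume are known in closed form, playing the role of the
timer-and-beaker reference of a physical pump phantom.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ._geometry import circle_polygon
from .pcmr_io import Contour, ImageSeries, SegmentationResult

__all__ = ["PhantomSpec", "default_phantom_spec", "generate_phantom_series",
           "generate_training_set", "stroke_volume_sweep"]

BACKGROUND_LEVEL = 100.0  # arbitrary magnitude units


@dataclass
class PhantomSpec:
    """Full description of one synthetic PC-MR acquisition."""

    grid: tuple[int, int] = (80, 80)
    pixel_spacing: float = 1.0            # mm, isotropic
    temporal_resolution: float = 30.0     # ms
    venc: float = 200.0                   # cm/s
    base_radius: float = 13.0             # mm (26 mm inner diameter tube)
    aspect: float = 0.92                  # minor/major axis ratio of the lumen
    tilt: float = 0.1                     # lumen orientation, radians
    radius_waveform: np.ndarray = None    # per-phase multiplicative factor
    center_path: np.ndarray = None        # per-phase (x, y), mm
    flow_waveform: np.ndarray = None      # per-phase peak velocity, cm/s
    contrast_waveform: np.ndarray = None  # per-phase lumen/background ratio
    velocity_profile: str = "parabolic"   # "parabolic" | "plug"
    noise_sigma_magnitude: float = 8.0
    noise_sigma_phase: float = 0.04       # radians
    rician_noise: bool = False
    # static bright neighbours (e.g. the descending aorta next to the
    # ascending aorta): centers (K, 2) mm, radii (K,) mm, magnitude ratio
    adjacent_centers: np.ndarray | None = None
    adjacent_radii: np.ndarray | None = None
    adjacent_level: float = 2.2
    background_plane: tuple[float, float, float] = (0.2, 0.005, -0.004)  # cm/s
    vessel_label: str = "aorta"
    seed: int = 0

    def __post_init__(self):
        for name in ("radius_waveform", "center_path", "flow_waveform",
                     "contrast_waveform", "adjacent_centers",
                     "adjacent_radii"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        t = self.n_phases
        if t < 2:
            raise ValueError("need at least 2 cardiac phases")
        for name in ("radius_waveform", "center_path", "contrast_waveform"):
            v = getattr(self, name)
            if v is None or len(v) != t:
                raise ValueError(f"{name} must have one entry per phase")
        if np.any(self.radius_waveform <= 0):
            raise ValueError("radius_waveform must be positive")
        if np.max(np.abs(self.flow_waveform)) > self.venc:
            raise ValueError(
                "peak velocity exceeds VENC: the phantom would alias")
        if self.velocity_profile not in ("parabolic", "plug"):
            raise ValueError(f"unknown profile {self.velocity_profile!r}")
        if not 0 < self.aspect <= 1:
            raise ValueError("aspect must lie in (0, 1]")
        # lumen must stay >= 2 px away from the image border at all times
        h, w = self.grid
        r_px = (self.base_radius * self.radius_waveform
                / (self.pixel_spacing * np.sqrt(self.aspect)))
        cx = self.center_path[:, 0] / self.pixel_spacing
        cy = self.center_path[:, 1] / self.pixel_spacing
        if (np.any(cx - r_px < 2) or np.any(cx + r_px > w - 3)
                or np.any(cy - r_px < 2) or np.any(cy + r_px > h - 3)):
            raise ValueError("lumen comes within 2 px of the image border")
        if self.adjacent_centers is not None:
            if self.adjacent_radii is None or len(self.adjacent_radii) != len(
                    self.adjacent_centers):
                raise ValueError("adjacent_centers/adjacent_radii mismatch")
            for (acx, acy), ar in zip(self.adjacent_centers,
                                      self.adjacent_radii):
                gap = (np.hypot(self.center_path[:, 0] - acx,
                                self.center_path[:, 1] - acy)
                       - r_px * self.pixel_spacing - ar)
                if np.any(gap < 1.0 * self.pixel_spacing):
                    raise ValueError(
                        "adjacent structure overlaps or touches the lumen")

    @property
    def n_phases(self) -> int:
        return len(self.flow_waveform)

    @property
    def rr_interval(self) -> float:
        return self.n_phases * self.temporal_resolution


def _systolic_bump(T: int, width: float = 0.45) -> np.ndarray:
    """Smooth 0..1 ejection waveform occupying the first ``width`` of RR."""
    f = np.arange(T) / T
    w = np.zeros(T)
    sel = f < width
    w[sel] = np.sin(np.pi * f[sel] / width) ** 2
    return w


def default_phantom_spec(peak_velocity: float = 100.0, n_phases: int = 30,
                         seed: int = 0, **overrides) -> PhantomSpec:
    """Study-default phantom: 26 mm tube, pulsating and moving lumen,
    parabolic flow with a systolic pulse and 3 cm/s diastolic baseline,
    and diastolic contrast drop to a 1.15 lumen/background ratio.
    """
    w = _systolic_bump(n_phases)
    f = np.arange(n_phases) / n_phases
    center = np.column_stack([
        40.0 + 2.0 * np.sin(2 * np.pi * f),
        40.0 + 1.2 * (1 - np.cos(2 * np.pi * f)) / 2,
    ])
    spec = dict(
        radius_waveform=1.0 + 0.06 * w,
        center_path=center,
        flow_waveform=peak_velocity * w + 3.0,
        contrast_waveform=1.1 + (2.8 - 1.1) * w,
        # a bright static neighbour a few px from the lumen, the structure
        # an unconstrained contour leaks into when diastolic contrast fades
        adjacent_centers=np.array([[14.0, 40.0]]),
        adjacent_radii=np.array([6.5]),
        seed=seed,
    )
    spec.update(overrides)
    return PhantomSpec(**spec)


def stroke_volume_sweep(n: int = 5, seed: int = 0) -> list[PhantomSpec]:
    """Specs whose analytic stroke volumes span roughly 12-90 ml,
    mirroring a pump phantom swept over its stroke-volume settings."""
    peaks = np.linspace(8.0, 140.0, n)
    return [default_phantom_spec(peak_velocity=p, seed=seed + i)
            for i, p in enumerate(peaks)]


def _analytic_flow(spec: PhantomSpec) -> np.ndarray:
    """Closed-form flow (ml/s) per phase.

    Parabolic profile over an ellipse with semi-axes (a, b): the
    integral of v_peak (1 - rho^2) is v_peak/2 * pi a b; the semi-axes
    are chosen with a b = R^2, so the flow equals that of a circular
    lumen of radius R.  Plug profile: v_peak * pi R^2.
    """
    r_cm = spec.base_radius * spec.radius_waveform / 10.0
    area = np.pi * r_cm**2
    if spec.velocity_profile == "parabolic":
        return spec.flow_waveform / 2.0 * area
    return spec.flow_waveform * area


def generate_phantom_series(spec: PhantomSpec):
    """Render the phantom into an ImageSeries with analytic ground truth.

    Returns ``(series, truth, true_flow_per_phase, true_net_volume)``
    where ``truth`` is a SegmentationResult holding the exact lumen
    boundary per phase.  The magnitude stack gets a 1 px Gaussian blur
    (partial-volume effect) and additive noise; the velocity map is the
    ideal profile plus the background plane and phase noise.  Fully
    reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    T = spec.n_phases
    h, w = spec.grid
    gx, gy = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    a, b, c = spec.background_plane

    magnitude = np.empty((T, h, w))
    phase = np.empty((T, h, w))
    truth_contours = []
    cos_t, sin_t = np.cos(spec.tilt), np.sin(spec.tilt)
    for t in range(T):
        cx = spec.center_path[t, 0] / spec.pixel_spacing
        cy = spec.center_path[t, 1] / spec.pixel_spacing
        r_px = spec.base_radius * spec.radius_waveform[t] / spec.pixel_spacing
        # semi-axes with the same enclosed area as a circle of radius r_px
        ax_px = r_px / np.sqrt(spec.aspect)
        bx_px = r_px * np.sqrt(spec.aspect)
        u = (gx - cx) * cos_t + (gy - cy) * sin_t
        v_ = -(gx - cx) * sin_t + (gy - cy) * cos_t
        rho2 = (u / ax_px) ** 2 + (v_ / bx_px) ** 2
        inside = rho2 <= 1.0

        mag = np.full((h, w), BACKGROUND_LEVEL)
        if spec.adjacent_centers is not None:
            for (acx, acy), ar in zip(spec.adjacent_centers,
                                      spec.adjacent_radii):
                adj = ((gx - acx / spec.pixel_spacing) ** 2
                       + (gy - acy / spec.pixel_spacing) ** 2
                       <= (ar / spec.pixel_spacing) ** 2)
                mag[adj] = BACKGROUND_LEVEL * spec.adjacent_level
        mag[inside] = BACKGROUND_LEVEL * spec.contrast_waveform[t]
        mag = ndimage.gaussian_filter(mag, 1.0)
        if spec.noise_sigma_magnitude > 0:
            if spec.rician_noise:
                n1 = rng.normal(0, spec.noise_sigma_magnitude, (h, w))
                n2 = rng.normal(0, spec.noise_sigma_magnitude, (h, w))
                mag = np.hypot(mag + n1, n2)
            else:
                mag = mag + rng.normal(0, spec.noise_sigma_magnitude, (h, w))
        magnitude[t] = np.clip(mag, 0, None)

        vmap = np.zeros((h, w))
        if spec.velocity_profile == "parabolic":
            vmap[inside] = spec.flow_waveform[t] * (1 - rho2[inside])
        else:
            vmap[inside] = spec.flow_waveform[t]
        vmap = vmap + a + b * gx + c * gy
        ph = np.pi * vmap / spec.venc
        if spec.noise_sigma_phase > 0:
            ph = ph + rng.normal(0, spec.noise_sigma_phase, (h, w))
        phase[t] = np.clip(ph, -np.pi, np.pi * (1 - 1e-12))

        th = 2 * np.pi * np.arange(96) / 96
        bx = ax_px * np.cos(th)
        by = bx_px * np.sin(th)
        pts = np.column_stack([cx + bx * cos_t - by * sin_t,
                               cy + bx * sin_t + by * cos_t])
        truth_contours.append(Contour(points=pts, phase_index=t))

    series = ImageSeries(magnitude=magnitude, phase=phase,
                         pixel_spacing=(spec.pixel_spacing,
                                        spec.pixel_spacing),
                         temporal_resolution=spec.temporal_resolution,
                         venc=spec.venc, rr_interval=spec.rr_interval,
                         vessel_label=spec.vessel_label)
    truth = SegmentationResult(contours=truth_contours, seed_phase=0)
    true_flow = _analytic_flow(spec)
    true_volume = float(np.sum(true_flow) * spec.temporal_resolution / 1000.0)
    return series, truth, true_flow, true_volume


def generate_training_set(n_subjects: int, vessel_label: str = "aorta",
                          seed: int = 0, n_phases: int = 25,
                          n_boundary_points: int = 64,
                          aspect_range: tuple[float, float] = (0.85, 1.0),
                          harmonic_sd: float = 0.015,
                          tilt_sd: float = 0.08
                          ) -> list[SegmentationResult]:
    """Time-resolved reference delineations for shape-model training.

    Each synthetic subject is an ellipse-like lumen (aspect ratio drawn
    from ``aspect_range``, small orientation jitter, mild 3rd/4th
    boundary harmonics) whose size pulses over the cardiac cycle —
    a stand-in family for manually delineated great-vessel contours.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 training subjects")
    rng = np.random.default_rng(seed)
    theta = 2 * np.pi * np.arange(n_boundary_points) / n_boundary_points
    subjects = []
    bump = _systolic_bump(n_phases)
    for _ in range(n_subjects):
        r0 = rng.uniform(10.0, 14.0)
        aspect = rng.uniform(*aspect_range)
        tilt = rng.normal(0.0, tilt_sd)
        pulsation = rng.uniform(0.03, 0.09)
        amp = rng.normal(0.0, harmonic_sd, size=4)  # cos3, sin3, cos4, sin4
        th = theta - tilt
        radial = (aspect /
                  np.sqrt((aspect * np.cos(th)) ** 2 + np.sin(th) ** 2))
        radial = radial * (1 + amp[0] * np.cos(3 * th) + amp[1] * np.sin(3 * th)
                           + amp[2] * np.cos(4 * th) + amp[3] * np.sin(4 * th))
        contours = []
        for t in range(n_phases):
            r = r0 * (1 + pulsation * bump[t]) * radial
            pts = np.column_stack([40.0 + r * np.cos(theta),
                                   40.0 + r * np.sin(theta)])
            contours.append(Contour(points=pts, phase_index=t))
        subjects.append(SegmentationResult(contours=contours, seed_phase=0))
    return subjects
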