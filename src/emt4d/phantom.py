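"""Seeded synthetic 4D phantom: anatomy, analytic respiratory deformation,
per-tick beam dose and a breathing trace.

The phantom emulates a phase-binned 4D lung acquisition:

* a reference anatomy with a low-density ellipsoidal "lung" containing a
  soft-tissue "tumour" sphere, embedded in tissue (HU ~ 0), plus seeded
  noise;
* ``n_phases`` respiratory states produced by an analytic superior-inferior
  compression field ``u_i(x) = A sin(pi z / L) s_i zhat`` with per-phase
  scale ``s_i = sin(2 pi i / P)`` — phase 0 is the reference (s = 0), and
  the field is invertible for the default amplitude (positive Jacobian);
* per-phase displacement fields in the direction the compiler needs
  (moving voxel centre -> reference-space point), obtained by fixed-point
  inversion of the forward map;
* per-tick Gaussian "beam" dose cubes centred on the phase target position;
* an elliptical target trajectory sampled at the 40 ms (25 Hz) machine-log
  tick.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .volumes_io import (
    BreathingTrace,
    DisplacementField,
    Grid3D,
    ScalarVolume,
)

__all__ = [
    "PhantomSpec",
    "generate_reference",
    "generate_phase",
    "generate_tick_dose",
    "generate_trace",
    "phase_centroids",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic 4D set.

    Defaults mirror a clinical phase-binned lung protocol at reduced grid
    size: image voxels 1 x 1 x 2 mm (the clinical in-plane/slice anisotropy),
    dose/energy voxels 2 x 2 x 2 mm (one dose voxel per 2 x 2 x 1 image
    block), 10 respiratory phases.  The 64 x 64 x 40 image grid keeps the
    full pipeline in seconds; clinical sizes remain reachable through the
    fields.
    """

    image_shape: tuple = (64, 64, 40)
    image_spacing: tuple = (1.0, 1.0, 2.0)  # mm
    dose_spacing: tuple = (2.0, 2.0, 2.0)  # mm
    n_phases: int = 10
    amplitude_mm: float = 8.0  # peak superior-inferior compression
    trajectory_semi_axes_mm: tuple = (3.0, 1.0, 8.0)
    breathing_period_s: float = 4.0
    tick_interval_s: float = 0.040  # 25 Hz machine-log rate
    beam_sigma_mm: float = 5.0
    dose_per_tick_gy: float = 0.02  # peak dose of one tick's beam cube
    noise_hu: float = 15.0
    lung_hu: float = -700.0
    tissue_hu: float = 0.0
    tumour_hu: float = 0.0
    tumour_radius_mm: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.n_phases < 2:
            raise ValueError("need at least 2 phases")
        extent_z = self.image_shape[2] * self.image_spacing[2]
        if self.amplitude_mm >= extent_z / 4:
            raise ValueError(
                f"amplitude {self.amplitude_mm} mm must stay below a quarter "
                f"of the z extent ({extent_z} mm)"
            )
        ratio = np.asarray(self.dose_spacing) / np.asarray(self.image_spacing)
        if not np.allclose(ratio, np.round(ratio)):
            raise ValueError("dose spacing must be an integer multiple of image spacing")
        if np.any(np.asarray(self.image_shape) % np.round(ratio).astype(int)):
            raise ValueError("image shape must tile the dose grid exactly")

    @property
    def image_grid(self) -> Grid3D:
        return Grid3D(
            origin=np.asarray(self.image_spacing) / 2.0,
            spacing=self.image_spacing,
            shape=self.image_shape,
        )

    @property
    def grid_ratio(self) -> tuple:
        r = np.asarray(self.dose_spacing) / np.asarray(self.image_spacing)
        return tuple(int(v) for v in np.round(r))

    @property
    def dose_grid(self) -> Grid3D:
        ratio = self.grid_ratio
        shape = tuple(n // r for n, r in zip(self.image_shape, ratio))
        return Grid3D(
            origin=np.asarray(self.dose_spacing) / 2.0,
            spacing=self.dose_spacing,
            shape=shape,
        )

    @property
    def centre_mm(self) -> np.ndarray:
        """Physical centre of the volume (also the tumour/trajectory centre)."""
        return self.image_grid.extent / 2.0

    def phase_scale(self, i: int) -> float:
        """Per-phase deformation scale ``s_i = sin(2 pi i / P)``."""
        if not 0 <= i < self.n_phases:
            raise ValueError(f"phase index {i} outside [0, {self.n_phases})")
        return float(np.sin(2.0 * np.pi * i / self.n_phases))


def generate_reference(spec: PhantomSpec) -> ScalarVolume:
    """Reference-phase HU volume: tissue background (~0 HU), ellipsoidal lung
    (~ -700 HU) holding a soft-tissue tumour sphere (~0 HU), plus seeded
    Gaussian noise."""
    grid = spec.image_grid
    centres = grid.voxel_centers()
    centre = spec.centre_mm
    lung_semi = grid.extent * np.array([0.38, 0.38, 0.40])
    if spec.tumour_radius_mm >= lung_semi.min():
        raise ValueError("tumour does not fit inside the lung region")
    rel = (centres - centre) / lung_semi
    lung = (rel**2).sum(axis=-1) <= 1.0
    r2 = ((centres - centre) ** 2).sum(axis=-1)
    tumour = r2 <= spec.tumour_radius_mm**2

    hu = np.full(grid.shape, spec.tissue_hu, dtype=np.float64)
    hu[lung] = spec.lung_hu
    hu[tumour] = spec.tumour_hu
    rng = np.random.default_rng(spec.seed)
    hu += rng.normal(0.0, spec.noise_hu, size=grid.shape)
    return ScalarVolume(grid=grid, values=hu, role="hu")


def _forward_shift(z_mm: np.ndarray, scale: float, spec: PhantomSpec) -> np.ndarray:
    """Superior-inferior displacement (mm) of tissue at reference height z:
    ``u = A sin(pi z / L) * s``."""
    length = spec.image_shape[2] * spec.image_spacing[2]
    return spec.amplitude_mm * scale * np.sin(np.pi * z_mm / length)


def _invert_forward_map(z_query_mm: np.ndarray, scale: float, spec: PhantomSpec,
                        tol_voxel: float = 1e-3, max_iter: int = 200) -> np.ndarray:
    """Solve ``Z + u(Z) = z`` for reference height Z by fixed-point iteration.

    Converges because ``|du/dZ| = A |s| pi / L < 1`` for any admissible
    amplitude; tolerance is in voxel units of the image z-spacing.
    """
    tol_mm = tol_voxel * spec.image_spacing[2]
    z_ref = z_query_mm.copy()
    for _ in range(max_iter):
        new = z_query_mm - _forward_shift(z_ref, scale, spec)
        if np.max(np.abs(new - z_ref)) < tol_mm:
            return new
        z_ref = new
    raise RuntimeError(
        "fixed-point inversion of the deformation did not converge; "
        "amplitude too large"
    )


def generate_phase(spec: PhantomSpec, i: int):
    """Phase-``i`` HU image and displacement field.

    The phase image is the reference resampled through the inverse of the
    analytic forward map (trilinear along z, the only deformed axis).  The
    returned DVF maps moving-phase voxel centres to reference-space points,
    the direction the push compiler consumes.
    """
    scale = spec.phase_scale(i)
    grid = spec.image_grid
    reference = generate_reference(spec)

    nz = grid.shape[2]
    z_centres = grid.origin[2] + grid.spacing[2] * np.arange(nz)
    if scale == 0.0:
        z_ref = z_centres.copy()
    else:
        z_ref = _invert_forward_map(z_centres, scale, spec)

    # resample reference at (x, y, Z(z)): only the z-coordinate moves
    zi = (z_ref - grid.origin[2]) / grid.spacing[2]
    coords = np.meshgrid(
        np.arange(grid.shape[0]),
        np.arange(grid.shape[1]),
        zi,
        indexing="ij",
    )
    values = map_coordinates(
        reference.values, coords, order=1, mode="nearest"
    )
    image = ScalarVolume(grid=grid, values=values, role="hu")

    vectors = np.zeros(grid.shape + (3,), dtype=np.float64)
    vectors[..., 2] = (z_ref - z_centres)[None, None, :]
    dvf = DisplacementField(grid=grid, vectors=vectors)
    return image, dvf


def phase_centroids(spec: PhantomSpec) -> np.ndarray:
    """Centre-of-target position of each phase on the breathing ellipse,
    shape ``(P, 3)`` mm."""
    theta = 2.0 * np.pi * np.arange(spec.n_phases) / spec.n_phases
    return _ellipse(theta, spec)


def _ellipse(theta: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    a = np.asarray(spec.trajectory_semi_axes_mm, dtype=np.float64)
    centre = spec.centre_mm
    pos = np.empty(np.shape(theta) + (3,), dtype=np.float64)
    pos[..., 0] = centre[0] + a[0] * np.cos(theta)
    pos[..., 1] = centre[1] + a[1] * np.cos(theta)
    pos[..., 2] = centre[2] + a[2] * np.sin(theta)
    return pos


def generate_tick_dose(spec: PhantomSpec, i: int, t: int = 0) -> ScalarVolume:
    """One tick's dose cube: an isotropic 3D Gaussian beam of peak
    ``dose_per_tick_gy`` centred on the phase-``i`` target position, on the
    dose grid.  Deterministic; ``t`` is accepted for interface symmetry with
    a time-varying delivery but does not alter the cube."""
    scale_angle = 2.0 * np.pi * i / spec.n_phases
    centre = _ellipse(np.asarray(scale_angle), spec)
    grid = spec.dose_grid
    r2 = ((grid.voxel_centers() - centre) ** 2).sum(axis=-1)
    dose = spec.dose_per_tick_gy * np.exp(-0.5 * r2 / spec.beam_sigma_mm**2)
    return ScalarVolume(grid=grid, values=dose, role="dose")


def generate_trace(spec: PhantomSpec, duration_s: float) -> BreathingTrace:
    """Elliptical target trajectory sampled every ``tick_interval_s`` over
    ``duration_s`` (one revolution per breathing period);
    ``floor(duration / tick) + 1`` samples."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(np.floor(duration_s / spec.tick_interval_s)) + 1
    t = spec.tick_interval_s * np.arange(n)
    theta = 2.0 * np.pi * t / spec.breathing_period_s
    return BreathingTrace(timestamps=t, positions=_ellipse(theta, spec))
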