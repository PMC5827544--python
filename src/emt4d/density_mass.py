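"""HU-to-density conversion, per-voxel mass, and the image/dose grid relation.

The image grid (fine, e.g. 1x1x2 mm) and the dose/energy grid (coarse, e.g.
2x2x2 mm) are rectilinear and mutually aligned so that an integer block of
image voxels tiles each dose voxel.  Dose is sampled piecewise-constant: each
image voxel takes the dose of its containing coarse voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes_io import Grid3D, ScalarVolume

__all__ = [
    "GridAlignment",
    "hu_to_density",
    "image_voxel_mass",
    "containing_dose_voxel",
    "dose_on_image_grid",
]


@dataclass(frozen=True)
class GridAlignment:
    """Integer block relation between a fine image grid and a coarse dose grid.

    ``ratio`` gives the number of image voxels per dose voxel per axis; the
    image block ``(0..ratio-1)^3`` lies inside dose voxel 0 (shared origin
    convention: both grids cover the same physical box).
    """

    image_grid: Grid3D
    dose_grid: Grid3D
    ratio: tuple

    def __post_init__(self):
        ratio = tuple(int(r) for r in self.ratio)
        if len(ratio) != 3 or any(r < 1 for r in ratio):
            raise ValueError(f"ratio must be 3 positive integers, got {self.ratio}")
        expected_spacing = self.image_grid.spacing * np.asarray(ratio)
        if not np.allclose(self.dose_grid.spacing, expected_spacing, rtol=1e-9):
            raise ValueError(
                f"dose spacing {self.dose_grid.spacing} is not image spacing "
                f"{self.image_grid.spacing} times ratio {ratio}"
            )
        expected_shape = tuple(
            n * r for n, r in zip(self.dose_grid.shape, ratio)
        )
        if self.image_grid.shape != expected_shape:
            raise ValueError(
                f"image shape {self.image_grid.shape} is not dose shape "
                f"{self.dose_grid.shape} times ratio {ratio}"
            )
        # both lattices must cover the same physical box: the corner of image
        # voxel (0,0,0) coincides with the corner of dose voxel (0,0,0)
        image_corner = self.image_grid.origin - self.image_grid.spacing / 2
        dose_corner = self.dose_grid.origin - self.dose_grid.spacing / 2
        if not np.allclose(image_corner, dose_corner, atol=1e-6):
            raise ValueError(
                "image and dose grids do not share the same physical corner"
            )
        object.__setattr__(self, "ratio", ratio)

    @classmethod
    def identity(cls, grid: Grid3D) -> "GridAlignment":
        """1:1 alignment of a grid with itself."""
        return cls(image_grid=grid, dose_grid=grid, ratio=(1, 1, 1))


def hu_to_density(hu_volume: ScalarVolume) -> ScalarVolume:
    """Convert CT numbers to mass density via the linear ramp
    ``rho = max(0, 1 + HU/1000)`` g/cm^3.

    HU = 0 maps to water (1 g/cm^3) and HU = -1000 to air (0); values below
    -1000 clamp to zero.  The ramp is a deliberate simplification — any
    scanner-specific calibration curve can be substituted, the mapping
    pipeline is agnostic to it.
    """
    if hu_volume.role != "hu":
        raise ValueError(f"expected an hu volume, got role {hu_volume.role!r}")
    rho = np.maximum(0.0, 1.0 + hu_volume.values / 1000.0)
    return ScalarVolume(grid=hu_volume.grid, values=rho, role="density")


def image_voxel_mass(density_volume: ScalarVolume) -> ScalarVolume:
    """Per-image-voxel mass ``m = rho * V_A`` in g, with ``V_A`` the image
    voxel volume in cm^3 (spacings are mm: ``V_A = prod(spacing) / 1000``)."""
    if density_volume.role != "density":
        raise ValueError(
            f"expected a density volume, got role {density_volume.role!r}"
        )
    voxel_volume_cm3 = float(np.prod(density_volume.grid.spacing)) / 1000.0
    return ScalarVolume(
        grid=density_volume.grid,
        values=density_volume.values * voxel_volume_cm3,
        role="mass",
    )


def containing_dose_voxel(image_index, alignment: GridAlignment) -> np.ndarray:
    """Dose-grid index of the coarse voxel containing an image voxel:
    ``floor(image_index / ratio)`` per axis."""
    idx = np.asarray(image_index, dtype=np.int64)
    shape = np.asarray(alignment.image_grid.shape)
    if np.any(idx < 0) or np.any(idx >= shape):
        raise IndexError(f"image index {image_index} outside image shape {tuple(shape)}")
    return idx // np.asarray(alignment.ratio, dtype=np.int64)


def dose_on_image_grid(dose_volume: ScalarVolume, alignment: GridAlignment) -> np.ndarray:
    """Dose sampled onto the image grid, piecewise-constant per coarse voxel.

    Returns an ``(nx, ny, nz)`` array on the image grid; no interpolation.
    """
    if not dose_volume.grid.same_geometry(alignment.dose_grid):
        raise ValueError("dose volume is not on the alignment's dose grid")
    rx, ry, rz = alignment.ratio
    return np.repeat(
        np.repeat(np.repeat(dose_volume.values, rx, axis=0), ry, axis=1),
        rz,
        axis=2,
    )
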