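"""Grids, volumes, displacement fields, breathing traces and all file I/O.

Conventions
-----------
Volumes live on axis-aligned rectilinear lattices (:class:`Grid3D`).  Values
are stored as ``(nx, ny, nz)`` arrays; the flat index of voxel ``(i, j, k)``
is ``i + nx * (j + ny * k)`` (first axis fastest), i.e. Fortran ravel order,
which matches the on-disk layout of NIfTI.  Voxel indices are 0-based and the
centre of voxel ``(0, 0, 0)`` sits at the grid origin.

File formats: NIfTI (.nii / .nii.gz) for scalar volumes and displacement-field
components, CSV for breathing traces, and a bespoke little-endian ``.dvs``
binary container for compiled displacement-vector-structure tables.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Grid3D",
    "ScalarVolume",
    "DisplacementField",
    "BreathingTrace",
    "VOLUME_ROLES",
    "read_volume",
    "write_volume",
    "read_trace",
    "write_trace",
    "read_dvs_container",
    "write_dvs_container",
    "DVS_HEADER_SIZE",
    "PUSH_RECORD_SIZE",
    "PULL_RECORD_SIZE",
]

VOLUME_ROLES = ("hu", "density", "dose", "energy", "mass")

#: roles whose values must be non-negative everywhere
_NONNEGATIVE_ROLES = ("density", "energy", "mass")


@dataclass(frozen=True)
class Grid3D:
    """Geometry of an axis-aligned voxel lattice.

    Parameters
    ----------
    origin : (3,) array, mm
        World position of the centre of voxel ``(0, 0, 0)``.
    spacing : (3,) array, mm/voxel
        Strictly positive voxel pitch per axis.
    shape : (3,) int tuple
        Voxel counts per axis.
    """

    origin: np.ndarray
    spacing: np.ndarray
    shape: tuple

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        shape = tuple(int(n) for n in self.shape)
        if len(shape) != 3 or any(n <= 0 for n in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if not np.all(np.isfinite(origin)):
            raise ValueError("grid origin must be finite")
        if not (np.all(np.isfinite(spacing)) and np.all(spacing > 0)):
            raise ValueError("grid spacing must be finite and strictly positive")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "shape", shape)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def extent(self) -> np.ndarray:
        """Physical size of the lattice per axis (mm), shape * spacing."""
        return np.asarray(self.shape) * self.spacing

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centres, shape ``(nx, ny, nz, 3)``."""
        axes = [
            self.origin[i] + self.spacing[i] * np.arange(self.shape[i])
            for i in range(3)
        ]
        grids = np.meshgrid(*axes, indexing="ij")
        return np.stack(grids, axis=-1)

    def flat_index(self, ijk: np.ndarray) -> np.ndarray:
        """Flat index of voxel triplets, first axis fastest."""
        ijk = np.asarray(ijk)
        nx, ny, _ = self.shape
        return ijk[..., 0] + nx * (ijk[..., 1] + ny * ijk[..., 2])

    def unravel(self, flat: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`flat_index`; returns ``(..., 3)`` int array."""
        flat = np.asarray(flat)
        nx, ny, _ = self.shape
        i = flat % nx
        j = (flat // nx) % ny
        k = flat // (nx * ny)
        return np.stack([i, j, k], axis=-1)

    def same_geometry(self, other: "Grid3D", rtol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, rtol=rtol, atol=1e-9)
            and np.allclose(self.spacing, other.spacing, rtol=rtol, atol=0)
        )


@dataclass
class ScalarVolume:
    """A :class:`Grid3D` plus one finite value per voxel and a role tag.

    Roles: ``hu`` (CT numbers), ``density`` (g/cm^3), ``dose`` (Gy),
    ``energy`` (Gy*g) and ``mass`` (g).  Density, energy and mass must be
    non-negative everywhere.
    """

    grid: Grid3D
    values: np.ndarray
    role: str = "hu"

    def __post_init__(self):
        if self.role not in VOLUME_ROLES:
            raise ValueError(f"unknown volume role {self.role!r}")
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != self.grid.shape:
            raise ValueError(
                f"value array shape {values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("volume values must all be finite")
        if self.role in _NONNEGATIVE_ROLES and np.any(values < 0):
            raise ValueError(f"{self.role} volume must be non-negative everywhere")
        self.values = values

    @property
    def flat(self) -> np.ndarray:
        """Values in flat-index order (first axis fastest)."""
        return self.values.reshape(-1, order="F")


@dataclass
class DisplacementField:
    """Per-voxel displacement vectors of a moving-phase image grid.

    ``vectors[i, j, k]`` (mm) maps the centre of moving image voxel
    ``(i, j, k)`` to a point in reference space:
    ``target = centre + vector``.
    """

    grid: Grid3D
    vectors: np.ndarray

    def __post_init__(self):
        vectors = np.asarray(self.vectors, dtype=np.float64)
        if vectors.shape != self.grid.shape + (3,):
            raise ValueError(
                f"vector array shape {vectors.shape} does not match grid "
                f"{self.grid.shape} + (3,)"
            )
        if not np.all(np.isfinite(vectors)):
            raise ValueError("displacement vectors must all be finite")
        self.vectors = vectors

    def target_points(self) -> np.ndarray:
        """Displaced voxel centres in reference space, ``(nx, ny, nz, 3)`` mm."""
        return self.grid.voxel_centers() + self.vectors


@dataclass
class BreathingTrace:
    """Target-position time series: strictly increasing timestamps (s) and
    3-vector positions (mm)."""

    timestamps: np.ndarray
    positions: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.timestamps, dtype=np.float64).reshape(-1)
        p = np.asarray(self.positions, dtype=np.float64)
        if t.size < 1:
            raise ValueError("trace needs at least one sample")
        if p.shape != (t.size, 3):
            raise ValueError(f"positions must be ({t.size}, 3), got {p.shape}")
        if np.any(np.diff(t) <= 0):
            raise ValueError("trace timestamps must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(p))):
            raise ValueError("trace values must be finite")
        self.timestamps = t
        self.positions = p

    def __len__(self) -> int:
        return self.timestamps.size


# ---------------------------------------------------------------------------
# NIfTI I/O


def _grid_from_affine(affine: np.ndarray, shape: tuple) -> Grid3D:
    rot = affine[:3, :3]
    # accept only axis-aligned, unsheared, positively-oriented affines
    off_diag = rot - np.diag(np.diag(rot))
    if np.any(np.abs(off_diag) > 1e-9 * max(1.0, np.abs(rot).max())):
        raise ValueError("only axis-aligned (unsheared, unrotated) affines are supported")
    spacing = np.diag(rot).copy()
    if np.any(spacing <= 0):
        raise ValueError("affine must have strictly positive diagonal spacing")
    return Grid3D(origin=affine[:3, 3].copy(), spacing=spacing, shape=shape)


def _affine_from_grid(grid: Grid3D) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(grid.spacing)
    affine[:3, 3] = grid.origin
    return affine


def read_volume(path, role: str = "hu") -> ScalarVolume:
    """Read a 3D scalar NIfTI volume.

    The grid geometry is taken from the file's affine; only axis-aligned
    affines are accepted.  Non-3D payloads and non-finite values are rejected.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D payload, got {data.ndim}D in {path}")
    grid = _grid_from_affine(np.asarray(img.affine), data.shape)
    return ScalarVolume(grid=grid, values=data, role=role)


def write_volume(volume: ScalarVolume, path) -> None:
    """Write a :class:`ScalarVolume` as NIfTI; :func:`read_volume` inverts it
    bit-for-bit at double precision."""
    # NIfTI-2: the header stores the affine at float64, so grid geometry
    # round-trips losslessly (NIfTI-1 truncates srow to float32)
    img = nib.Nifti2Image(volume.values, _affine_from_grid(volume.grid))
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))


def read_displacement_field(paths) -> DisplacementField:
    """Read a DVF stored as three scalar NIfTI components (x, y, z in mm)."""
    comps = [read_volume(p, role="hu") for p in paths]
    grid = comps[0].grid
    for c in comps[1:]:
        if not grid.same_geometry(c.grid):
            raise ValueError("DVF component grids disagree")
    vectors = np.stack([c.values for c in comps], axis=-1)
    return DisplacementField(grid=grid, vectors=vectors)


def write_displacement_field(dvf: DisplacementField, paths) -> None:
    """Write a DVF as three scalar NIfTI components."""
    if len(paths) != 3:
        raise ValueError("need exactly three component paths")
    for axis, p in enumerate(paths):
        comp = ScalarVolume(grid=dvf.grid, values=dvf.vectors[..., axis], role="hu")
        write_volume(comp, p)


# ---------------------------------------------------------------------------
# Trace CSV I/O

_TRACE_COLUMNS = ["time_s", "x_mm", "y_mm", "z_mm"]


def read_trace(path) -> BreathingTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV missing columns {missing}")
    return BreathingTrace(
        timestamps=df["time_s"].to_numpy(dtype=np.float64),
        positions=df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=np.float64),
    )


def write_trace(trace: BreathingTrace, path) -> None:
    df = pd.DataFrame(
        {
            "time_s": trace.timestamps,
            "x_mm": trace.positions[:, 0],
            "y_mm": trace.positions[:, 1],
            "z_mm": trace.positions[:, 2],
        }
    )
    # repr-round-trip float formatting keeps the CSV lossless at double precision
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# DVS binary container
#
# Layout (little endian):
#   header, 32 bytes fixed:
#     0   4s   magic b"DVS1"
#     4   B    format version (1)
#     5   B    layout tag: 1 = push, 2 = pull, 3 = unified
#     6   H    reserved (0)
#     8   I    record count N
#     12  3H   moving image grid shape
#     18  3H   reference grid shape
#     24  8x   padding
#   for pull/unified layouts: range index, (n_ref + 1) u32 cumulative offsets
#   records:
#     push:          u32 targetIndex, 3 x i8 quantized offsets, u8 isUsed  (8 B)
#     pull/unified:  u32 sourceIndex, 3 x i8 quantized values             (7 B)

DVS_MAGIC = b"DVS1"
DVS_VERSION = 1
DVS_HEADER_SIZE = 32
PUSH_RECORD_SIZE = 8
PULL_RECORD_SIZE = 7

_LAYOUT_TAGS = {"push": 1, "pull": 2, "unified": 3}
_TAG_LAYOUTS = {v: k for k, v in _LAYOUT_TAGS.items()}

_HEADER_STRUCT = struct.Struct("<4sBBHI3H3H8x")

_PUSH_DTYPE = np.dtype(
    [("index", "<u4"), ("q", "i1", (3,)), ("used", "u1")]
)
_PULL_DTYPE = np.dtype([("index", "<u4"), ("q", "i1", (3,))])


@dataclass
class DVSTable:
    """In-memory compiled displacement-vector-structure table.

    ``layout`` is one of ``push``, ``pull``, ``unified``.

    push
        One record per moving image voxel (``index`` = targetIndex, the
        nearest reference voxel to the displaced point; ``q`` = quantized
        relative offsets; ``used`` = status byte).
    pull
        Records re-keyed by reference voxel: ``ranges`` holds cumulative
        per-reference-voxel record offsets (length n_ref + 1); ``index`` =
        sourceIndex into the image grid; ``q`` = quantized offsets.
    unified
        Like pull but keyed by the minimum-index ("voxel 1") corner of the
        8-voxel overlap ensemble, with ``q`` holding quantized weight
        factors w0 instead of offsets.

    ``exact`` optionally carries the pre-quantization offsets/weights for
    in-memory pipelines; it is never serialized.
    """

    layout: str
    image_shape: tuple
    ref_shape: tuple
    index: np.ndarray
    q: np.ndarray
    used: np.ndarray | None = None
    ranges: np.ndarray | None = None
    exact: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.layout not in _LAYOUT_TAGS:
            raise ValueError(f"unknown DVS layout {self.layout!r}")
        self.index = np.asarray(self.index, dtype=np.uint32)
        self.q = np.asarray(self.q, dtype=np.int8)
        if self.q.shape != (self.index.size, 3):
            raise ValueError("q must have shape (n_records, 3)")
        self.image_shape = tuple(int(n) for n in self.image_shape)
        self.ref_shape = tuple(int(n) for n in self.ref_shape)
        n_ref = int(np.prod(self.ref_shape))
        if self.layout == "push":
            if self.used is None:
                raise ValueError("push layout requires a status byte array")
            self.used = np.asarray(self.used, dtype=np.uint8)
            if self.used.shape != (self.index.size,):
                raise ValueError("used must have one byte per record")
        else:
            if self.ranges is None:
                raise ValueError(f"{self.layout} layout requires a range index")
            self.ranges = np.asarray(self.ranges, dtype=np.int64)
            if self.ranges.shape != (n_ref + 1,):
                raise ValueError("ranges must have length n_ref + 1")
            if self.ranges[0] != 0 or self.ranges[-1] != self.index.size:
                raise ValueError("ranges must start at 0 and end at record count")
            if np.any(np.diff(self.ranges) < 0):
                raise ValueError("ranges must be non-decreasing")

    @property
    def n_records(self) -> int:
        return int(self.index.size)

    @property
    def record_size(self) -> int:
        return PUSH_RECORD_SIZE if self.layout == "push" else PULL_RECORD_SIZE

    def __eq__(self, other) -> bool:
        if not isinstance(other, DVSTable):
            return NotImplemented
        if (
            self.layout != other.layout
            or self.image_shape != other.image_shape
            or self.ref_shape != other.ref_shape
        ):
            return False
        if not (
            np.array_equal(self.index, other.index)
            and np.array_equal(self.q, other.q)
        ):
            return False
        if self.layout == "push":
            return np.array_equal(self.used, other.used)
        return np.array_equal(self.ranges, other.ranges)


def write_dvs_container(table: DVSTable, path) -> None:
    """Serialize a :class:`DVSTable` bit-exactly (little endian)."""
    header = _HEADER_STRUCT.pack(
        DVS_MAGIC,
        DVS_VERSION,
        _LAYOUT_TAGS[table.layout],
        0,
        table.n_records,
        *table.image_shape,
        *table.ref_shape,
    )
    with open(path, "wb") as fh:
        fh.write(header)
        if table.layout == "push":
            rec = np.empty(table.n_records, dtype=_PUSH_DTYPE)
            rec["index"] = table.index
            rec["q"] = table.q
            rec["used"] = table.used
        else:
            fh.write(table.ranges.astype("<u4").tobytes())
            rec = np.empty(table.n_records, dtype=_PULL_DTYPE)
            rec["index"] = table.index
            rec["q"] = table.q
        fh.write(rec.tobytes())


def read_dvs_container(path) -> DVSTable:
    """Inverse of :func:`write_dvs_container`; validates header and sizes."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < DVS_HEADER_SIZE:
        raise ValueError("truncated DVS container: incomplete header")
    magic, version, tag, _, count, *dims = _HEADER_STRUCT.unpack(
        raw[:DVS_HEADER_SIZE]
    )
    if magic != DVS_MAGIC:
        raise ValueError("not a DVS container (bad magic)")
    if version != DVS_VERSION:
        raise ValueError(f"unsupported DVS container version {version}")
    if tag not in _TAG_LAYOUTS:
        raise ValueError(f"unknown DVS layout tag {tag}")
    layout = _TAG_LAYOUTS[tag]
    image_shape = tuple(dims[:3])
    ref_shape = tuple(dims[3:])
    offset = DVS_HEADER_SIZE
    ranges = None
    if layout != "push":
        n_ref = int(np.prod(ref_shape))
        idx_bytes = 4 * (n_ref + 1)
        if len(raw) < offset + idx_bytes:
            raise ValueError("truncated DVS container: incomplete range index")
        ranges = np.frombuffer(raw, dtype="<u4", count=n_ref + 1, offset=offset)
        ranges = ranges.astype(np.int64)
        offset += idx_bytes
    rec_size = PUSH_RECORD_SIZE if layout == "push" else PULL_RECORD_SIZE
    expected = offset + rec_size * count
    if len(raw) != expected:
        raise ValueError(
            f"DVS container size mismatch: header says {count} records "
            f"({expected} bytes), file has {len(raw)} bytes"
        )
    if layout == "push":
        rec = np.frombuffer(raw, dtype=_PUSH_DTYPE, count=count, offset=offset)
        return DVSTable(
            layout=layout,
            image_shape=image_shape,
            ref_shape=ref_shape,
            index=rec["index"].copy(),
            q=rec["q"].copy(),
            used=rec["used"].copy(),
        )
    rec = np.frombuffer(raw, dtype=_PULL_DTYPE, count=count, offset=offset)
    return DVSTable(
        layout=layout,
        image_shape=image_shape,
        ref_shape=ref_shape,
        index=rec["index"].copy(),
        q=rec["q"].copy(),
        ranges=ranges,
    )
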