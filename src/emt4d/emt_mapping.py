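"""Energy/mass transfer (EMT) mapping kernels and the direct-dose-mapping
(DDM) baseline.

The physical picture: dose delivered on a moving respiratory phase must be
accumulated onto a common reference grid.  Because tissue deforms, several
source voxels can be compressed into one reference voxel, which makes the
dose value ambiguous under naive averaging.  EMT resolves this by the
physical definition of dose: it transports *energy* (dose x mass) and *mass*
separately along the displacement field and divides the accumulated energy
by the accumulated mass per reference voxel.

Each displaced image-voxel centre lands at a continuous point in reference
space.  A unit virtual voxel spanned around that point overlaps (at most)
8 reference voxels; each receives the fraction of the transferred energy
equal to its overlap volume in relative coordinates, dE_j = Vbar_j * E_T
with sum_j Vbar_j = 1.

Three arrangements of the same arithmetic are provided:

* ``map_energy_push`` — serial sweep over image voxels, scattering each
  contribution (race-prone if parallelised naively);
* ``map_energy_pull`` — sweep over reference voxels owning contiguous record
  ranges; slab-decomposable along z with deterministic halo merging;
* ``map_energy_unified`` — the branch-free variant: weights come as per-axis
  factor pairs (w0, 1-w0) combined along one fixed 8-step traversal pattern
  starting at the minimum-index corner.

All three produce the same contribution multiset; per-voxel results agree to
summation-order rounding only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density_mass import GridAlignment, dose_on_image_grid
from .dvs_compile import dequantize_offset, unified_weights_from_offset
from .volumes_io import DVSTable, Grid3D, ScalarVolume

__all__ = [
    "PATTERN_OFFSETS",
    "OverlapWeights",
    "overlap_weights",
    "box_intersection_oracle",
    "map_energy_push",
    "map_energy_pull",
    "map_energy_unified",
    "map_mass",
    "divide_energy_by_mass",
    "ddm_map",
    "used_record_count",
]

#: fixed traversal pattern of the 8-voxel overlap ensemble relative to the
#: minimum-index corner: base, +x, +y, +xy, +z, +xz, +yz, +xyz
PATTERN_OFFSETS = np.array(
    [
        (0, 0, 0),
        (1, 0, 0),
        (0, 1, 0),
        (1, 1, 0),
        (0, 0, 1),
        (1, 0, 1),
        (0, 1, 1),
        (1, 1, 1),
    ],
    dtype=np.int64,
)


@dataclass
class OverlapWeights:
    """The 8 overlap voxels of one displacement and their volume shares.

    ``voxels`` holds the absolute voxel triplets in fixed pattern order
    (base, +x, +y, +xy, +z, +xz, +yz, +xyz); ``weights`` are the relative
    overlap volumes, each in [0, 1] and summing to 1.
    """

    voxels: np.ndarray
    weights: np.ndarray


def overlap_weights(offset, nearest_voxel=(0, 0, 0)) -> OverlapWeights:
    """Overlap volumes between the unit virtual voxel centred at
    ``nearest_voxel + offset`` (relative coordinates) and its 8 surrounding
    reference voxels.

    ``offset`` must lie in (-0.5, 0.5] per axis (the relative coordinate of a
    displaced point with respect to its nearest reference voxel centre).
    """
    offset = np.asarray(offset, dtype=np.float64).reshape(3)
    if np.any(offset <= -0.5) or np.any(offset > 0.5):
        raise ValueError(f"offsets must lie in (-0.5, 0.5] per axis, got {offset}")
    nearest = np.asarray(nearest_voxel, dtype=np.int64).reshape(3)
    shift, w0 = unified_weights_from_offset(offset)
    base = nearest - shift
    voxels = base[None, :] + PATTERN_OFFSETS
    factors = np.where(PATTERN_OFFSETS == 0, w0[None, :], 1.0 - w0[None, :])
    return OverlapWeights(voxels=voxels, weights=factors.prod(axis=1))


def box_intersection_oracle(offset, nearest_voxel=(0, 0, 0)) -> OverlapWeights:
    """Reference computation of the overlap volumes by explicit axis-aligned
    box intersection (independent of the factor-pair shortcut; used for
    cross-checking).

    The virtual voxel occupies ``[offset - 0.5, offset + 0.5]`` per axis in
    coordinates centred on the nearest voxel; neighbour ``d`` occupies
    ``[d - 0.5, d + 0.5]``.  Each weight is the product over axes of the
    interval-overlap lengths.  All 27 neighbours are scanned and the 8 with
    the ensemble's sign pattern are returned in pattern order.
    """
    offset = np.asarray(offset, dtype=np.float64).reshape(3)
    nearest = np.asarray(nearest_voxel, dtype=np.int64).reshape(3)

    def axis_overlap(x, d):
        lo = max(x - 0.5, d - 0.5)
        hi = min(x + 0.5, d + 0.5)
        return max(0.0, hi - lo)

    # ensemble corner: one voxel down when the offset is negative
    base_d = np.where(offset < 0, -1, 0)
    voxels = []
    weights = []
    for step in PATTERN_OFFSETS:
        d = base_d + step
        w = 1.0
        for axis in range(3):
            w *= axis_overlap(offset[axis], d[axis])
        voxels.append(nearest + d)
        weights.append(w)
    return OverlapWeights(
        voxels=np.asarray(voxels, dtype=np.int64),
        weights=np.asarray(weights, dtype=np.float64),
    )


# ---------------------------------------------------------------------------
# record decoding


def _push_contributions(table: DVSTable, ref_grid: Grid3D):
    """(source flat index, base corner triplets, w0 factors) of used push
    records, in ascending image-voxel order."""
    used = table.used.astype(bool)
    source = np.nonzero(used)[0]
    offsets = dequantize_offset(table.q[used])
    shift, w0 = unified_weights_from_offset(offsets)
    nearest = ref_grid.unravel(table.index[used].astype(np.int64))
    return source, nearest - shift, w0


def _keyed_contributions(table: DVSTable, ref_grid: Grid3D):
    """(source flat index, base corner triplets, w0 factors, key z-plane
    record boundaries) for pull/unified tables, in stored (key-ascending)
    order."""
    source = table.index.astype(np.int64)
    counts = np.diff(table.ranges)
    keys = np.repeat(np.arange(ref_grid.n_voxels, dtype=np.int64), counts)
    key3 = ref_grid.unravel(keys)
    if table.layout == "pull":
        offsets = dequantize_offset(table.q)
        shift, w0 = unified_weights_from_offset(offsets)
        base = key3 - shift
    elif table.layout == "unified":
        w0 = dequantize_offset(table.q)
        base = key3
    else:
        raise ValueError(f"expected a pull or unified table, got {table.layout!r}")
    nx, ny, nz = ref_grid.shape
    plane_bounds = table.ranges[:: nx * ny].copy()  # record offset of each key z-plane
    return source, base, w0, plane_bounds


# ---------------------------------------------------------------------------
# scatter engines


def _pattern_scatter(acc, base, w0, values, ref_grid, dtype, index_offset=0):
    """Scatter ``values`` with the 8 fixed-pattern weights into ``acc``.

    The 8 pattern positions are processed in fixed order; within each
    position, records accumulate in their given (ascending) order, so the
    result is bitwise reproducible.
    """
    single = np.dtype(dtype) == np.float32
    n = acc.size
    for step in PATTERN_OFFSETS:
        idx = ref_grid.flat_index(base + step) - index_offset
        w = np.where(step == 0, w0, 1.0 - w0).prod(axis=1)
        contrib = values * w
        if single:
            np.add.at(acc, idx, contrib.astype(np.float32))
        else:
            acc += np.bincount(idx, weights=contrib, minlength=n)


def _scatter_push(source, base, w0, values, ref_grid, dtype):
    acc = np.zeros(ref_grid.n_voxels, dtype=dtype)
    _pattern_scatter(acc, base, w0, values, ref_grid, dtype)
    return acc


def _scatter_keyed(source, base, w0, plane_bounds, values, ref_grid, n_slabs, dtype):
    """Keyed (pull/unified) scatter with z-slab decomposition.

    Each key z-plane's contributions are accumulated into a private window
    covering the planes its 8-voxel ensembles can touch; windows are merged
    afterwards in ascending key-plane order.  Because partial accumulators
    are per key-plane and the merge order is fixed, the result is bitwise
    independent of ``n_slabs`` — slabs only assign contiguous plane ranges to
    (conceptual) workers, and no reference voxel is touched by two workers
    before the merge.
    """
    nx, ny, nz = ref_grid.shape
    plane = nx * ny
    if not 1 <= n_slabs <= nz:
        raise ValueError(f"n_slabs must be in [1, {nz}], got {n_slabs}")
    slab_edges = np.linspace(0, nz, n_slabs + 1).astype(int)

    partials = [None] * nz  # (window start plane, window accumulator)
    for s in range(n_slabs):
        for z in range(slab_edges[s], slab_edges[s + 1]):
            lo, hi = plane_bounds[z], plane_bounds[z + 1]
            if lo == hi:
                continue
            zmin = max(z - 1, 0)
            zmax = min(z + 1, nz - 1)
            win = np.zeros((zmax - zmin + 1) * plane, dtype=dtype)
            _pattern_scatter(
                win,
                base[lo:hi],
                w0[lo:hi],
                values[lo:hi],
                ref_grid,
                dtype,
                index_offset=zmin * plane,
            )
            partials[z] = (zmin, win)

    acc = np.zeros(ref_grid.n_voxels, dtype=dtype)
    for z in range(nz):  # fixed merge order: ascending key plane
        if partials[z] is None:
            continue
        zmin, win = partials[z]
        start = zmin * plane
        acc[start : start + win.size] += win
    return acc


# ---------------------------------------------------------------------------
# public mapping operations


def _check_ref(ref_grid: Grid3D, table: DVSTable):
    if table.ref_shape != ref_grid.shape:
        raise ValueError(
            f"table reference shape {table.ref_shape} does not match grid "
            f"{ref_grid.shape}"
        )


def _energy_per_record(dose_moving, mass_image, alignment, table, source):
    if not dose_moving.grid.same_geometry(alignment.dose_grid):
        raise ValueError("moving dose is not on the alignment's dose grid")
    if not mass_image.grid.same_geometry(alignment.image_grid):
        raise ValueError("image mass is not on the alignment's image grid")
    if tuple(alignment.image_grid.shape) != table.image_shape:
        raise ValueError("table was compiled against a different image grid")
    dose_flat = dose_on_image_grid(dose_moving, alignment).reshape(-1, order="F")
    mass_flat = mass_image.flat
    return dose_flat[source] * mass_flat[source]


def _as_volume(acc, ref_grid, role):
    values = np.maximum(acc, 0.0).astype(np.float64).reshape(ref_grid.shape, order="F")
    return ScalarVolume(grid=ref_grid, values=values, role=role)


def map_energy_push(
    dose_moving: ScalarVolume,
    mass_image: ScalarVolume,
    push_table: DVSTable,
    alignment: GridAlignment,
    ref_grid: Grid3D,
    dtype=np.float64,
) -> ScalarVolume:
    """Serial-layout energy mapping.

    For each used record with image voxel ``a``, the transferred energy is
    ``E_T = d(containing dose voxel of a) * m(a)`` (Gy*g), distributed over
    the 8 overlap voxels by their relative overlap volumes.  Records are
    processed in ascending image index; total scattered energy equals the
    sum of all E_T exactly (boundary records were excluded at compile time).
    """
    if push_table.layout != "push":
        raise ValueError("map_energy_push expects a push-layout table")
    _check_ref(ref_grid, push_table)
    source, base, w0 = _push_contributions(push_table, ref_grid)
    e_t = _energy_per_record(dose_moving, mass_image, alignment, push_table, source)
    acc = _scatter_push(source, base, w0, e_t, ref_grid, dtype)
    return _as_volume(acc, ref_grid, "energy")


def map_energy_pull(
    dose_moving: ScalarVolume,
    mass_image: ScalarVolume,
    pull_table: DVSTable,
    alignment: GridAlignment,
    ref_grid: Grid3D,
    n_slabs: int = 1,
    dtype=np.float64,
) -> ScalarVolume:
    """Pull-layout energy mapping (parallel-safe arrangement).

    Iterates reference voxels and gathers their assigned records; the
    reference grid is decomposed into ``n_slabs`` z-slabs with separate halo
    accumulators merged deterministically, so the result is bitwise
    independent of ``n_slabs``.
    """
    if pull_table.layout != "pull":
        raise ValueError("map_energy_pull expects a pull-layout table")
    _check_ref(ref_grid, pull_table)
    source, base, w0, bounds = _keyed_contributions(pull_table, ref_grid)
    e_t = _energy_per_record(dose_moving, mass_image, alignment, pull_table, source)
    acc = _scatter_keyed(source, base, w0, bounds, e_t, ref_grid, n_slabs, dtype)
    return _as_volume(acc, ref_grid, "energy")


def map_energy_unified(
    dose_moving: ScalarVolume,
    mass_image: ScalarVolume,
    unified_table: DVSTable,
    alignment: GridAlignment,
    ref_grid: Grid3D,
    n_slabs: int = 1,
    dtype=np.float64,
) -> ScalarVolume:
    """Branch-free unified-pattern energy mapping.

    The 8 weights are the ordered products over the per-axis factor pairs
    ``(w0, 1-w0)`` along the fixed traversal pattern; the 8 absolute indices
    are the base ("voxel 1") index plus a fixed relative-offset vector.
    Same slab/halo-merge contract as the pull variant.
    """
    if unified_table.layout != "unified":
        raise ValueError("map_energy_unified expects a unified-layout table")
    _check_ref(ref_grid, unified_table)
    source, base, w0, bounds = _keyed_contributions(unified_table, ref_grid)
    e_t = _energy_per_record(dose_moving, mass_image, alignment, unified_table, source)
    acc = _scatter_keyed(source, base, w0, bounds, e_t, ref_grid, n_slabs, dtype)
    return _as_volume(acc, ref_grid, "energy")


def map_mass(
    mass_image: ScalarVolume,
    table: DVSTable,
    ref_grid: Grid3D,
    n_slabs: int = 1,
    dtype=np.float64,
) -> ScalarVolume:
    """Scatter per-image-voxel mass to the reference grid with any layout.

    The transferred-mass volume depends only on the anatomy and the DVF, so
    it is computed once per phase and cached; total scattered mass equals the
    sum of the used image-voxel masses.
    """
    _check_ref(ref_grid, table)
    if mass_image.role != "mass":
        raise ValueError(f"expected a mass volume, got role {mass_image.role!r}")
    if tuple(mass_image.grid.shape) != table.image_shape:
        raise ValueError("table was compiled against a different image grid")
    mass_flat = mass_image.flat
    if table.layout == "push":
        source, base, w0 = _push_contributions(table, ref_grid)
        acc = _scatter_push(source, base, w0, mass_flat[source], ref_grid, dtype)
    else:
        source, base, w0, bounds = _keyed_contributions(table, ref_grid)
        acc = _scatter_keyed(
            source, base, w0, bounds, mass_flat[source], ref_grid, n_slabs, dtype
        )
    return _as_volume(acc, ref_grid, "mass")


def divide_energy_by_mass(
    energy: ScalarVolume,
    mass: ScalarVolume,
    mass_floor: float = 1e-6,
):
    """Accumulated dose ``D = E / M`` (Gy) where the transferred mass reaches
    ``mass_floor`` (g); voxels below the floor get zero dose.

    Returns ``(dose volume, number of floored voxels)``.
    """
    if energy.role != "energy" or mass.role != "mass":
        raise ValueError("divide_energy_by_mass expects energy and mass volumes")
    if not energy.grid.same_geometry(mass.grid):
        raise ValueError("energy and mass must share the reference grid")
    if mass_floor <= 0:
        raise ValueError("mass_floor must be positive")
    ok = mass.values >= mass_floor
    dose = np.zeros_like(energy.values)
    np.divide(energy.values, mass.values, out=dose, where=ok)
    n_floored = int(np.count_nonzero(~ok))
    return ScalarVolume(grid=energy.grid, values=dose, role="dose"), n_floored


def ddm_map(
    dose_moving: ScalarVolume,
    push_table: DVSTable,
    alignment: GridAlignment,
    ref_grid: Grid3D,
    dtype=np.float64,
) -> ScalarVolume:
    """Direct dose mapping baseline: per reference voxel, the overlap-weighted
    *mean* of contributing source doses, ``D(v) = sum(w d) / sum(w)``.

    Uses the same trilinear overlap weights as EMT so that the difference to
    EMT isolates the averaging-vs-energy/mass question: under compression EMT
    yields the mass-weighted mean while DDM ignores mass.  Voxels receiving
    no weight get zero.
    """
    if push_table.layout != "push":
        raise ValueError("ddm_map expects a push-layout table")
    _check_ref(ref_grid, push_table)
    source, base, w0 = _push_contributions(push_table, ref_grid)
    dose_flat = dose_on_image_grid(dose_moving, alignment).reshape(-1, order="F")
    d = dose_flat[source]
    num = _scatter_push(source, base, w0, d, ref_grid, dtype)
    den = _scatter_push(source, base, w0, np.ones_like(d), ref_grid, dtype)
    out = np.zeros(ref_grid.n_voxels, dtype=np.float64)
    np.divide(num, den, out=out, where=den > 0)
    return ScalarVolume(
        grid=ref_grid,
        values=np.maximum(out, 0.0).reshape(ref_grid.shape, order="F"),
        role="dose",
    )


def used_record_count(table: DVSTable) -> int:
    """Number of records actually scattered by a mapping sweep (the per-tick
    operation count is this, independent of the field's shape)."""
    if table.layout == "push":
        return int(np.count_nonzero(table.used))
    return table.n_records
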