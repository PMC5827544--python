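"""Compile a displacement field into compact displacement-vector-structure
(DVS) tables.

Three layouts are produced:

push
    One record per moving image voxel, keyed by the *target*: the reference
    voxel nearest to the displaced voxel centre, plus the quantized relative
    offset of the target point from that voxel's centre and a status byte.
    Natural for a serial sweep over the image; scattering is race-prone in
    parallel.
pull
    The same records re-keyed by reference voxel, so every reference voxel
    owns a contiguous record range and can be updated by exactly one worker.
pull-unified
    Records re-keyed by the minimum-index corner ("voxel 1") of the 8-voxel
    overlap ensemble, carrying three per-axis weight factors ``w0`` instead of
    signed offsets.  The 8 overlap weights then follow one fixed, branch-free
    traversal pattern (base, +x, +y, +xy, +z, +xz, +yz, +xyz) with the pair
    ``(w0, 1 - w0)`` per axis.

Offsets and weights are stored as signed 8-bit codes with dequantization
``x = b / (2^7 - 1)``; quantization rounds half away from zero so the sign of
the code always equals the sign of the offset.
"""

from __future__ import annotations

import numpy as np

from .volumes_io import DisplacementField, DVSTable, Grid3D

__all__ = [
    "QUANT_SCALE",
    "quantize_offset",
    "dequantize_offset",
    "compile_push",
    "compile_pull",
    "compile_unified",
]

#: dequantization divisor 2^7 - 1
QUANT_SCALE = 127


def quantize_offset(x):
    """Quantize a value in [-1, 1] to a signed 8-bit code,
    ``b = round_half_away_from_zero(x * 127)``."""
    x = np.asarray(x, dtype=np.float64)
    if np.any(np.abs(x) > 1.0):
        raise ValueError("offsets must lie in [-1, 1]")
    b = np.sign(x) * np.floor(np.abs(x) * QUANT_SCALE + 0.5)
    return b.astype(np.int8)


def dequantize_offset(b):
    """Inverse map ``x = b / (2^7 - 1)``; round-trip error is at most 1/254."""
    return np.asarray(b, dtype=np.float64) / QUANT_SCALE


def _nearest_and_offset(points: np.ndarray, ref_grid: Grid3D):
    """Nearest reference voxel and relative offset of displaced points.

    Offsets are expressed in reference-voxel units (relative coordinates,
    so the reference voxel volume is 1).  Ties at half-voxel are broken
    upward: the lower voxel is kept and the offset stays at +0.5, giving
    offsets in (-0.5, 0.5] per axis.
    """
    rel = (points - ref_grid.origin) / ref_grid.spacing
    nearest = np.ceil(rel - 0.5).astype(np.int64)
    offset = rel - nearest
    return nearest, offset


def compile_push(
    dvf: DisplacementField,
    ref_grid: Grid3D,
    mask: np.ndarray | None = None,
) -> DVSTable:
    """Compile push-layout records: one per image voxel, in flat-index order.

    A record is flagged unused when its mask value is zero or when the full
    8-voxel overlap ensemble around the displaced point is not contained in
    the reference grid (boundary records are excluded, not clipped, so
    energy/mass conservation over used records is exact).

    The returned table carries the pre-quantization offsets in ``exact`` for
    in-memory pipelines; only the quantized codes are ever serialized.
    """
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != dvf.grid.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match image grid {dvf.grid.shape}"
            )
    points = dvf.target_points().reshape(-1, 3, order="F")
    nearest, offset = _nearest_and_offset(points, ref_grid)

    # minimum-index corner of the 8-voxel overlap ensemble
    base = nearest - (offset < 0)
    ref_shape = np.asarray(ref_grid.shape)
    inside = np.all((base >= 0) & (base + 1 <= ref_shape - 1), axis=1)

    used = inside
    if mask is not None:
        used = used & (mask.reshape(-1, order="F") != 0)

    # clip out-of-grid targets to a valid flat index; their records are unused
    clipped = np.clip(nearest, 0, ref_shape - 1)
    target = ref_grid.flat_index(clipped).astype(np.uint32)
    q = quantize_offset(np.clip(offset, -1.0, 1.0))
    return DVSTable(
        layout="push",
        image_shape=dvf.grid.shape,
        ref_shape=ref_grid.shape,
        index=target,
        q=q,
        used=used.astype(np.uint8),
        exact=offset,
    )


def _rekey(keys: np.ndarray, push: DVSTable, q: np.ndarray, n_ref: int,
           exact: np.ndarray | None, layout: str, ref_shape) -> DVSTable:
    """Group used records by reference-voxel key into contiguous ranges,
    ordered by (key, sourceIndex) — stable and reproducible."""
    used = push.used.astype(bool)
    source = np.nonzero(used)[0].astype(np.uint32)
    keys = keys[used]
    q = q[used]
    if exact is not None:
        exact = exact[used]
    order = np.argsort(keys, kind="stable")  # sources already ascending
    counts = np.bincount(keys, minlength=n_ref)
    ranges = np.zeros(n_ref + 1, dtype=np.int64)
    np.cumsum(counts, out=ranges[1:])
    return DVSTable(
        layout=layout,
        image_shape=push.image_shape,
        ref_shape=ref_shape,
        index=source[order],
        q=q[order],
        ranges=ranges,
        exact=None if exact is None else exact[order],
    )


def compile_pull(push: DVSTable, ref_grid: Grid3D) -> DVSTable:
    """Re-key push records by their target reference voxel.

    Unused records are dropped; the surviving (sourceIndex, targetIndex,
    quantized offset) triples are preserved verbatim, arranged into
    contiguous per-reference-voxel ranges with ascending sourceIndex inside
    each range.
    """
    if push.layout != "push":
        raise ValueError("compile_pull expects a push-layout table")
    if push.ref_shape != ref_grid.shape:
        raise ValueError("push table was compiled against a different reference grid")
    return _rekey(
        push.index.astype(np.int64),
        push,
        push.q,
        ref_grid.n_voxels,
        push.exact,
        "pull",
        ref_grid.shape,
    )


def unified_weights_from_offset(offset: np.ndarray):
    """Base-corner shift and w0 weight factors for given relative offsets.

    Per axis: the base ("voxel 1") is the nearest voxel shifted down by one
    when the offset is negative, and the base weight is
    ``w0 = |dx|`` if ``dx < 0`` else ``1 - dx``, so voxel 1's overlap volume
    is always ``w0_1 * w0_2 * w0_3`` and a +1 step along axis i swaps in
    ``w+ = 1 - w0``.
    """
    offset = np.asarray(offset, dtype=np.float64)
    neg = offset < 0
    shift = neg.astype(np.int64)
    w0 = np.where(neg, -offset, 1.0 - offset)
    return shift, w0


def compile_unified(push: DVSTable, ref_grid: Grid3D) -> DVSTable:
    """Re-key push records by the minimum-index overlap corner and store
    quantized w0 weight factors.

    Weights are computed from the pre-quantization offsets when the push
    table carries them (freshly compiled), falling back to dequantized codes
    for tables loaded from disk; quantization happens after the w0 transform
    so unified precision matches push precision.
    """
    if push.layout != "push":
        raise ValueError("compile_unified expects a push-layout table")
    if push.ref_shape != ref_grid.shape:
        raise ValueError("push table was compiled against a different reference grid")
    offsets = push.exact if push.exact is not None else dequantize_offset(push.q)
    shift, w0 = unified_weights_from_offset(offsets)
    nearest = ref_grid.unravel(push.index.astype(np.int64))
    base = np.clip(nearest - shift, 0, np.asarray(ref_grid.shape) - 1)
    keys = ref_grid.flat_index(base)
    wq = quantize_offset(np.clip(w0, 0.0, 1.0))
    return _rekey(keys, push, wq, ref_grid.n_voxels, w0, "unified", ref_grid.shape)
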