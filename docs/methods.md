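# Methods

## Dose accumulation model

Dose delivered on a moving respiratory phase is accumulated onto a reference
anatomy by transporting energy and mass separately (EMT).  For image voxel
`a` of the moving phase, the transferred energy is `E_T = d(a) · m(a)` where
`d(a)` is the dose of the coarse dose voxel containing `a` (piecewise-
constant sampling, no interpolation) and `m(a) = ρ(a) · V_A` its mass
(`V_A` = image voxel volume in cm³).  The displacement vector of `a` maps its
centre to a continuous point in reference space; a unit virtual voxel
spanned around that point overlaps 8 reference voxels, and voxel `j`
receives `ΔE_j = V̄_j E_T`, with `V̄_j` the fractional overlap volume in
relative coordinates (reference voxel volume ≡ 1).  `Σ_j V̄_j = 1` holds
identically, so energy and mass are conserved exactly over used records
(asserted at 1e-12 relative in the tests).  The accumulated dose is
`D(v) = E(v)/M(v)` per reference voxel.

Voxels are translated rigidly — rotations/deformations of individual voxels
are not modelled; at ~1 mm voxels a deformation is well approximated by a
field of per-voxel translations.  The DDM baseline shares the same overlap
weights but averages dose (`Σ wd / Σ w`), so any EMT–DDM difference isolates
the averaging-vs-transport question: under a two-voxel compression EMT gives
the mass-weighted mean, DDM the plain mean.

## Displacement tables and quantization

A compiled record stores the nearest reference voxel (4-byte flat index,
first axis fastest) and the relative offset of the displaced point as three
signed 8-bit codes, dequantized by `2⁷−1 = 127`; quantization rounds half
away from zero so the code sign always equals the offset sign (the sign
selects the overlap quadrant).  The literal `b/127` map is used — the code
range is not rescaled to the occupied `[−0.5, 0.5]` offset band — so the
worst-case round-trip error is `1/254` per axis.

Rounding ties at exactly half a voxel keep the *lower* voxel and an offset
of `+0.5`, so offsets live in `(−0.5, 0.5]` deterministically.  Records whose
8-voxel overlap ensemble is not fully inside the reference grid are excluded
(status byte 0), not clipped: conservation over used records stays exact and
the excluded count is reported.  The ensemble is defined uniformly as the
minimum-index corner plus a `(+1,+1,+1)` neighbourhood, also when an axis
offset is exactly zero (that neighbour's weight is zero but it must still be
in bounds) — slightly conservative at the grid faces, branch-free everywhere.

Layouts:

* **push**: one 8-byte record per image voxel (index, 3 offsets, status),
  keyed by the moving image;
* **pull**: used records re-keyed into contiguous per-reference-voxel ranges
  (ascending source index inside a range), 7-byte records — the status byte
  is unnecessary because regions of interest live on the reference grid;
* **unified**: keyed by the minimum-index corner, storing quantized weight
  factors `w⁰_i` (`w⁰ = |Δx̄|` for negative offsets, `1 − Δx̄` otherwise);
  the 8 weights are the ordered products over `(w⁰, 1−w⁰)` along the fixed
  pattern base, +x, +y, +xy, +z, +xz, +yz, +xyz.

`w⁰` is computed from the pre-quantization offsets and quantized afterwards.
Because `x ↦ 1−x` and `x ↦ |x|` map code points to code points, this is
equivalent (up to exact rounding ties) to deriving `w⁰` from the quantized
offsets, and unified-layout precision matches push-layout precision; the
residual push/unified dose deviation is pure summation-order rounding.

The on-disk container is little-endian: a fixed 32-byte header (magic,
version, layout tag, record count, image and reference shapes), then for
pull/unified a `u32` cumulative range index (reference voxel count + 1
entries — required to reconstruct the per-voxel ranges, since 7-byte records
do not encode their key), then the bit-exact records (8·N or 7·N bytes).

## Parallel contract (slab decomposition)

The pull/unified sweep decomposes the reference grid along z into `n_slabs`
contiguous plane ranges.  An 8-voxel ensemble keyed at plane `z` can touch
planes `z−1 … z+1`, crossing slab boundaries; each key plane therefore
accumulates into a private window covering exactly those planes, and windows
are merged after the sweep in ascending key-plane order.  No reference voxel
is updated by two workers before the merge, and because partial accumulators
are per key plane with a fixed merge order, the result is **bitwise**
independent of `n_slabs`.  Accumulation order is fixed throughout (records
ascending within each of the 8 pattern passes), so every run is bitwise
reproducible at a given precision.  Both double (default) and single
precision accumulation modes exist; single precision exhibits the ~1e-5 %
layout-deviation scale typical of reordered float32 summation.

## HU → density

`ρ = max(0, 1 + HU/1000)` g/cm³ (water at HU 0, air at −1000, clamped
below).  No scanner calibration curve is assumed; the mapping pipeline is
agnostic to the conversion law, which is a single pluggable function.

## Dual-resolution grids

The image grid (default 1×1×2 mm) and the dose/energy grid (2×2×2 mm) are
rectilinear, share the same physical box, and relate by an integer per-axis
ratio (here 2×2×1 image voxels per dose voxel), so block sums are exact.
An image voxel takes the dose of its containing coarse voxel.

## Synthetic 4D phantom

The phantom emulates a phase-binned 4D lung set on a reduced grid
(64×64×40 image voxels; the clinical 512×512×173 remains reachable through
the spec):

* anatomy: tissue background (0 HU) with an ellipsoidal lung (−700 HU)
  holding an 8 mm-radius soft-tissue tumour sphere, plus seeded Gaussian
  noise (σ = 15 HU);
* deformation: superior–inferior compression
  `u_i(x) = A sin(πz/L) s_i ẑ`, `s_i = sin(2πi/P)`, `P = 10` phases,
  `A = 8 mm`.  Phase 0 is the reference (`s = 0`); the Jacobian
  `1 + A s π/L cos(πz/L)` stays positive (no folding) for any admissible
  amplitude (`A < L/4 < L/π`), and the forward map is inverted by fixed-point
  iteration to 10⁻³ voxel.  The gradient of `u` genuinely compresses tissue,
  producing many-to-one mappings that exercise the EMT/DDM difference;
* delivery: per-tick isotropic Gaussian beam (σ = 5 mm, peak 0.02 Gy)
  centred on the phase target; target trajectory an ellipse (semi-axes
  3, 1, 8 mm about the tumour centre, dominant superior–inferior axis
  matching the deformation amplitude), sampled every 40 ms (25 Hz) with a
  4 s breathing period.

These defaults were chosen once as representative of a lung SBRT-like
motion scenario at a grid size that keeps the full loop in seconds.  The
phantom is fully deterministic given its seed.  What it does *not* emulate:
realistic CT texture, hysteresis in the breathing loop, lateral/rotational
deformation components, MLC aperture shapes, or registration error — the
DVFs are analytic and exact, so passing tests demonstrate the correctness of
the mapping machinery, not robustness to imperfect deformable registration,
which bounds the accuracy of any dose-warping method on real data.

## Reconstruction loop

Per 40 ms tick: nearest-centroid phase selection from the target position
(ties to the lower index; whole-tick phase assignment — sub-tick phase
changes are not weighted), tick dose cube, energy mapping with the phase's
compiled table, division by the phase's cached transferred mass (a per-phase,
not per-tick, quantity), and addition of the per-tick dose increment.  The
per-tick scatter operation count equals the phase's used-record count —
independent of the deformation's shape.  Wall-clock latency is logged but
never asserted: runtime claims are hardware-bound.

## Numerical choices

* mass floor 10⁻⁶ g: below it the accumulated dose is defined as 0 (the
  behaviour at vanishing transferred mass is otherwise undefined); floored
  voxel counts are reported so the choice is auditable;
* conservation gate at bundle precompute: 10⁻⁹ relative on transferred mass;
* NIfTI-2 is written (not NIfTI-1) so grid geometry round-trips at float64;
* trace CSVs are written with `%.17g` and parsed in round-trip mode, making
  CSV I/O lossless at double precision.

## Known limitations

Axis-aligned grids only (no oblique acquisitions); integer image/dose grid
ratios; no DVF inversion or composition across phases; the slab
decomposition simulates the parallel contract deterministically on one
thread rather than spawning workers; DDM is implemented only in the push
arrangement (it is a baseline, not an optimisation target).
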