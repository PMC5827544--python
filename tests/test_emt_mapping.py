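"""Overlap weights, energy/mass scatter in all layouts, E/m division, DDM."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import emt4d as e

offsets_strategy = st.tuples(
    st.floats(-0.499999, 0.5), st.floats(-0.499999, 0.5), st.floats(-0.499999, 0.5)
)


class TestOverlapWeights:
    def test_coincident_centres(self):
        ow = e.overlap_weights((0, 0, 0), (2, 2, 2))
        assert ow.weights[0] == 1.0
        assert np.all(ow.weights[1:] == 0.0)
        assert tuple(ow.voxels[0]) == (2, 2, 2)

    def test_half_offset_symmetry(self):
        ow = e.overlap_weights((0.5, 0.5, 0.5), (2, 2, 2))
        assert np.allclose(ow.weights, 0.125)

    def test_2d_slice_example(self):
        """Printed product formulas for offsets (0.25, 0.4, 0): nearest voxel
        0.45, axis neighbours 0.15/0.30, diagonal 0.10, far z-layer zero."""
        ow = e.overlap_weights((0.25, 0.4, 0.0), (5, 5, 5))
        by_voxel = {tuple(v): w for v, w in zip(ow.voxels, ow.weights)}
        assert by_voxel[(5, 5, 5)] == pytest.approx(0.45)
        assert by_voxel[(6, 5, 5)] == pytest.approx(0.15)
        assert by_voxel[(5, 6, 5)] == pytest.approx(0.30)
        assert by_voxel[(6, 6, 5)] == pytest.approx(0.10)
        assert sorted(ow.weights)[:4] == pytest.approx([0, 0, 0, 0])

    def test_single_axis_half_offset(self):
        ow = e.box_intersection_oracle((0.5, 0.0, 0.0))
        nonzero = ow.weights[ow.weights > 0]
        assert len(nonzero) == 2 and np.allclose(nonzero, 0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            e.overlap_weights((0.7, 0, 0))

    @given(offsets_strategy)
    def test_matches_box_intersection_oracle(self, offset):
        """The factor-pair shortcut equals explicit box intersection."""
        ow = e.overlap_weights(offset, (3, 3, 3))
        oracle = e.box_intersection_oracle(offset, (3, 3, 3))
        assert np.array_equal(ow.voxels, oracle.voxels)
        assert np.allclose(ow.weights, oracle.weights, atol=1e-12)
        assert ow.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all((ow.weights >= 0) & (ow.weights <= 1))


def tiny_setup(shape=(6, 6, 6)):
    grid = e.Grid3D(origin=(0.5, 0.5, 0.5), spacing=(1, 1, 1), shape=shape)
    alignment = e.GridAlignment.identity(grid)
    return grid, alignment


def volume(grid, values, role):
    return e.ScalarVolume(grid=grid, values=values, role=role)


def single_displacement_setup(vector, dose_gy=2.0, hu=0.0):
    """One used record at voxel (2,2,2) of a 1 mm^3 unit grid: mass
    rho(hu) * 0.001 g, dose ``dose_gy``."""
    grid, alignment = tiny_setup()
    vectors = np.zeros(grid.shape + (3,))
    vectors[2, 2, 2] = vector
    dvf = e.DisplacementField(grid=grid, vectors=vectors)
    mask = np.zeros(grid.shape, dtype=bool)
    mask[2, 2, 2] = True
    push = e.compile_push(dvf, grid, mask=mask)
    dose = volume(grid, np.full(grid.shape, dose_gy), "dose")
    mass = e.image_voxel_mass(e.hu_to_density(volume(grid, np.full(grid.shape, hu), "hu")))
    return grid, alignment, push, dose, mass


class TestMapEnergyPush:
    def test_single_identity_displacement(self):
        """d = 2 Gy on a 0.001 g voxel concentrates 0.002 Gy*g in one
        reference voxel."""
        grid, alignment, push, dose, mass = single_displacement_setup((0, 0, 0))
        energy = e.map_energy_push(dose, mass, push, alignment, grid)
        assert energy.values[2, 2, 2] == pytest.approx(0.002)
        assert energy.values.sum() == pytest.approx(0.002)

    def test_half_offset_splits_eightfold(self):
        """A +half-voxel offset on all axes spreads the energy over the 8
        ensemble voxels in equal shares, up to the stored-offset quantization
        (each per-axis factor is within 1/254 of 0.5, i.e. within a relative
        1/127, so each eighth is within (1 + 1/127)^3 - 1 of 0.00025)."""
        grid, alignment, push, dose, mass = single_displacement_setup((0.5, 0.5, 0.5))
        energy = e.map_energy_push(dose, mass, push, alignment, grid)
        block = energy.values[2:4, 2:4, 2:4]
        assert np.allclose(block, 0.00025, rtol=(1 + 1 / 127) ** 3 - 1)
        assert energy.values.sum() == pytest.approx(0.002)
        assert np.count_nonzero(energy.values) == 8

    def test_zero_dose_zero_energy(self):
        grid, alignment, push, dose, mass = single_displacement_setup((0, 0, 0),
                                                                      dose_gy=0.0)
        energy = e.map_energy_push(dose, mass, push, alignment, grid)
        assert np.all(energy.values == 0)

    def test_energy_conservation_on_phantom(self, small_spec, small_alignment,
                                            compiled_tables, phase_inputs):
        push, _, _ = compiled_tables
        dose, mass = phase_inputs
        energy = e.map_energy_push(dose, mass, push, small_alignment,
                                   small_spec.dose_grid)
        from emt4d.density_mass import dose_on_image_grid

        used = push.used.astype(bool)
        e_t = (dose_on_image_grid(dose, small_alignment).reshape(-1, order="F")
               * mass.flat)[used].sum()
        assert energy.values.sum() == pytest.approx(e_t, rel=1e-12)


class TestLayoutEquivalence:
    def test_pull_matches_push(self, small_spec, small_alignment, compiled_tables,
                               phase_inputs):
        push, pull, _ = compiled_tables
        dose, mass = phase_inputs
        ref = small_spec.dose_grid
        e_push = e.map_energy_push(dose, mass, push, small_alignment, ref)
        e_pull = e.map_energy_pull(dose, mass, pull, small_alignment, ref, n_slabs=1)
        nz = e_push.values != 0
        rel = np.abs(e_pull.values[nz] - e_push.values[nz]) / e_push.values[nz]
        assert rel.max() <= 1e-12

    def test_unified_matches_push(self, small_spec, small_alignment, compiled_tables,
                                  phase_inputs):
        push, _, unified = compiled_tables
        dose, mass = phase_inputs
        ref = small_spec.dose_grid
        e_push = e.map_energy_push(dose, mass, push, small_alignment, ref)
        e_uni = e.map_energy_unified(dose, mass, unified, small_alignment, ref,
                                     n_slabs=3)
        nz = e_push.values != 0
        rel = np.abs(e_uni.values[nz] - e_push.values[nz]) / e_push.values[nz]
        assert rel.max() <= 1e-12

    def test_slab_count_invariance_bitwise(self, small_spec, small_alignment,
                                           compiled_tables, phase_inputs):
        _, pull, _ = compiled_tables
        dose, mass = phase_inputs
        ref = small_spec.dose_grid
        ref_result = e.map_energy_pull(dose, mass, pull, small_alignment, ref,
                                       n_slabs=1)
        for n_slabs in (2, 4, 7):
            other = e.map_energy_pull(dose, mass, pull, small_alignment, ref,
                                      n_slabs=n_slabs)
            assert np.array_equal(other.values, ref_result.values)

    def test_invalid_slab_count_rejected(self, small_spec, small_alignment,
                                         compiled_tables, phase_inputs):
        _, pull, _ = compiled_tables
        dose, mass = phase_inputs
        with pytest.raises(ValueError, match="n_slabs"):
            e.map_energy_pull(dose, mass, pull, small_alignment,
                              small_spec.dose_grid, n_slabs=1000)

    def test_single_precision_mean_deviation(self, small_spec, small_alignment,
                                             compiled_tables, phase_inputs):
        """At float32 accumulation the pull/push deviation stays below
        1e-4 % mean per voxel (the reordered-float32-summation scale)."""
        push, pull, _ = compiled_tables
        dose, mass = phase_inputs
        ref = small_spec.dose_grid
        e_push = e.map_energy_push(dose, mass, push, small_alignment, ref,
                                   dtype=np.float32)
        e_pull = e.map_energy_pull(dose, mass, pull, small_alignment, ref,
                                   n_slabs=4, dtype=np.float32)
        nz = e_push.values > 0
        rel = np.abs(e_pull.values[nz] - e_push.values[nz]) / e_push.values[nz]
        assert rel.mean() * 100 <= 1e-4


class TestMapMass:
    def test_identity_dvf_preserves_mass_field(self):
        grid, alignment = tiny_setup()
        dvf = e.DisplacementField(grid=grid, vectors=np.zeros(grid.shape + (3,)))
        push = e.compile_push(dvf, grid)
        hu = volume(grid, np.random.default_rng(0).uniform(-500, 500, grid.shape), "hu")
        mass = e.image_voxel_mass(e.hu_to_density(hu))
        mass_ref = e.map_mass(mass, push, grid)
        used = push.used.reshape(grid.shape, order="F").astype(bool)
        assert np.allclose(mass_ref.values[used], mass.values[used], rtol=1e-12)

    def test_total_mass_conserved_per_layout(self, small_spec, compiled_tables,
                                             phase_inputs):
        _, mass = phase_inputs
        push, pull, unified = compiled_tables
        used = push.used.astype(bool)
        total_in = mass.flat[used].sum()
        for table in (push, pull, unified):
            out = e.map_mass(mass, table, small_spec.dose_grid)
            assert out.values.sum() == pytest.approx(total_in, rel=1e-12)

    def test_compression_masses_add(self):
        grid, alignment = tiny_setup()
        vectors = np.zeros(grid.shape + (3,))
        vectors[3, 2, 2] = (-1.0, 0, 0)  # (3,2,2) lands on (2,2,2)
        dvf = e.DisplacementField(grid=grid, vectors=vectors)
        mask = np.zeros(grid.shape, dtype=bool)
        mask[2, 2, 2] = mask[3, 2, 2] = True
        push = e.compile_push(dvf, grid, mask=mask)
        hu = np.zeros(grid.shape)
        hu[2, 2, 2] = 0.0      # rho 1 -> 0.001 g
        hu[3, 2, 2] = 2000.0   # rho 3 -> 0.003 g
        mass = e.image_voxel_mass(e.hu_to_density(volume(grid, hu, "hu")))
        mass_ref = e.map_mass(mass, push, grid)
        assert mass_ref.values[2, 2, 2] == pytest.approx(0.004)


class TestDivideEnergyByMass:
    def test_plain_division(self):
        grid, _ = tiny_setup((2, 2, 2))
        energy = volume(grid, np.full(grid.shape, 0.002), "energy")
        mass = volume(grid, np.full(grid.shape, 0.001), "mass")
        dose, n_floored = e.divide_energy_by_mass(energy, mass)
        assert np.allclose(dose.values, 2.0)
        assert n_floored == 0

    def test_zero_mass_floors_to_zero_dose(self):
        grid, _ = tiny_setup((2, 2, 2))
        energy = volume(grid, np.full(grid.shape, 0.002), "energy")
        mass = volume(grid, np.zeros(grid.shape), "mass")
        dose, n_floored = e.divide_energy_by_mass(energy, mass)
        assert np.all(dose.values == 0)
        assert n_floored == 8

    def test_role_mixup_rejected(self):
        grid, _ = tiny_setup((2, 2, 2))
        dose = volume(grid, np.ones(grid.shape), "dose")
        mass = volume(grid, np.ones(grid.shape), "mass")
        with pytest.raises(ValueError):
            e.divide_energy_by_mass(dose, mass)


def compression_pair(grid, masses=(0.001, 0.003), doses=(1.0, 2.0)):
    """Two image voxels pushed onto reference voxel (2,2,2) with zero offsets."""
    vectors = np.zeros(grid.shape + (3,))
    vectors[3, 2, 2] = (-1.0, 0, 0)
    dvf = e.DisplacementField(grid=grid, vectors=vectors)
    mask = np.zeros(grid.shape, dtype=bool)
    mask[2, 2, 2] = mask[3, 2, 2] = True
    push = e.compile_push(dvf, grid, mask=mask)
    dose_vals = np.zeros(grid.shape)
    dose_vals[2, 2, 2], dose_vals[3, 2, 2] = doses
    mass_vals = np.zeros(grid.shape)
    mass_vals[2, 2, 2], mass_vals[3, 2, 2] = masses
    dose = e.ScalarVolume(grid=grid, values=dose_vals, role="dose")
    mass = e.ScalarVolume(grid=grid, values=mass_vals, role="mass")
    return push, dose, mass


class TestEmtVsDdm:
    def test_canonical_compression_case(self):
        """Masses (0.001, 0.003) g with doses (1, 2) Gy into one voxel:
        EMT = 1.75 Gy (mass-weighted), DDM = 1.5 Gy (plain average)."""
        grid, alignment = tiny_setup()
        push, dose, mass = compression_pair(grid)
        energy = e.map_energy_push(dose, mass, push, alignment, grid)
        mass_ref = e.map_mass(mass, push, grid)
        emt, _ = e.divide_energy_by_mass(energy, mass_ref)
        ddm = e.ddm_map(dose, push, alignment, grid)
        assert emt.values[2, 2, 2] == pytest.approx(1.75)
        assert ddm.values[2, 2, 2] == pytest.approx(1.5)

    def test_identity_dvf_ddm_reproduces_source(self):
        grid, alignment = tiny_setup()
        dvf = e.DisplacementField(grid=grid, vectors=np.zeros(grid.shape + (3,)))
        push = e.compile_push(dvf, grid)
        rng = np.random.default_rng(9)
        dose = volume(grid, rng.uniform(0, 3, grid.shape), "dose")
        ddm = e.ddm_map(dose, push, alignment, grid)
        used = push.used.reshape(grid.shape, order="F").astype(bool)
        assert np.allclose(ddm.values[used], dose.values[used], rtol=1e-12)

    def test_uniform_dose_maps_to_uniform(self):
        grid, alignment = tiny_setup()
        rng = np.random.default_rng(10)
        vectors = rng.uniform(-0.8, 0.8, grid.shape + (3,))
        dvf = e.DisplacementField(grid=grid, vectors=vectors)
        push = e.compile_push(dvf, grid)
        dose = volume(grid, np.full(grid.shape, 2.5), "dose")
        ddm = e.ddm_map(dose, push, alignment, grid)
        mapped = ddm.values[ddm.values != 0]
        assert np.allclose(mapped, 2.5, rtol=1e-12)

    @given(
        st.floats(1e-4, 1e-2), st.floats(1e-4, 1e-2),
        st.floats(0.1, 5.0), st.floats(0.1, 5.0),
    )
    def test_emt_is_mass_weighted_mean(self, m1, m2, d1, d2):
        """On any two-voxel compression EMT equals the mass-weighted mean of
        the source doses, DDM the plain mean; they differ whenever masses and
        doses both differ."""
        grid, alignment = tiny_setup()
        push, dose, mass = compression_pair(grid, masses=(m1, m2), doses=(d1, d2))
        energy = e.map_energy_push(dose, mass, push, alignment, grid)
        mass_ref = e.map_mass(mass, push, grid)
        emt, _ = e.divide_energy_by_mass(energy, mass_ref, mass_floor=1e-9)
        ddm = e.ddm_map(dose, push, alignment, grid)
        expected_emt = (m1 * d1 + m2 * d2) / (m1 + m2)
        expected_ddm = (d1 + d2) / 2
        assert emt.values[2, 2, 2] == pytest.approx(expected_emt, rel=1e-10)
        assert ddm.values[2, 2, 2] == pytest.approx(expected_ddm, rel=1e-10)


class TestClosedForms:
    def test_identity_dvf_returns_moving_dose(self):
        """Identity DVF on 1:1 grids: E/m mapping reproduces the moving dose
        wherever transferred mass clears the floor."""
        grid, alignment = tiny_setup()
        dvf = e.DisplacementField(grid=grid, vectors=np.zeros(grid.shape + (3,)))
        push = e.compile_push(dvf, grid)
        rng = np.random.default_rng(12)
        dose = volume(grid, rng.uniform(0, 4, grid.shape), "dose")
        hu = volume(grid, rng.uniform(-300, 300, grid.shape), "hu")
        mass = e.image_voxel_mass(e.hu_to_density(hu))
        energy = e.map_energy_push(dose, mass, push, alignment, grid)
        mass_ref = e.map_mass(mass, push, grid)
        out, _ = e.divide_energy_by_mass(energy, mass_ref)
        solid = (mass_ref.values >= 1e-6)
        assert np.allclose(out.values[solid], dose.values[solid], rtol=1e-12)

    def test_integer_translation_shifts_dose(self):
        """A constant integer-voxel translation accumulates the translated
        moving dose on the overlap region."""
        grid, alignment = tiny_setup((7, 7, 7))
        shift = np.array([1, 2, 0])
        vectors = np.broadcast_to(shift.astype(float), grid.shape + (3,)).copy()
        dvf = e.DisplacementField(grid=grid, vectors=vectors)
        push = e.compile_push(dvf, grid)
        rng = np.random.default_rng(13)
        dose = volume(grid, rng.uniform(0.5, 4, grid.shape), "dose")
        mass = e.image_voxel_mass(
            e.hu_to_density(volume(grid, np.zeros(grid.shape), "hu"))
        )
        energy = e.map_energy_push(dose, mass, push, alignment, grid)
        mass_ref = e.map_mass(mass, push, grid)
        out, _ = e.divide_energy_by_mass(energy, mass_ref)
        used = push.used.reshape(grid.shape, order="F").astype(bool)
        src = np.argwhere(used)
        dst = src + shift
        assert np.allclose(
            out.values[dst[:, 0], dst[:, 1], dst[:, 2]],
            dose.values[src[:, 0], src[:, 1], src[:, 2]],
            rtol=1e-12,
        )


class TestQuantizationSensitivity:
    def test_energy_error_bounded_by_quantization_step(self, small_spec,
                                                       small_alignment,
                                                       compressing_phase,
                                                       phase_inputs):
        """Scattering with quantized vs exact offsets changes total absolute
        energy by at most 6/254 of the transferred energy (each of the three
        per-axis weight factors moves by <= 1/254, and the 8 products absorb
        each axis error twice)."""
        _, _, dvf = compressing_phase
        dose, mass = phase_inputs
        ref = small_spec.dose_grid
        push = e.compile_push(dvf, ref)
        energy_q = e.map_energy_push(dose, mass, push, small_alignment, ref)

        # exact-offset result: re-quantize at (effectively) infinite precision
        # by scattering from the stored exact offsets
        from emt4d.dvs_compile import unified_weights_from_offset
        from emt4d.emt_mapping import _scatter_push
        from emt4d.density_mass import dose_on_image_grid

        used = push.used.astype(bool)
        source = np.nonzero(used)[0]
        shift, w0 = unified_weights_from_offset(push.exact[used])
        nearest = ref.unravel(push.index[used].astype(np.int64))
        e_t = (dose_on_image_grid(dose, small_alignment).reshape(-1, order="F")
               * mass.flat)[source]
        exact = _scatter_push(source, nearest - shift, w0, e_t, ref, np.float64)
        exact = exact.reshape(ref.shape, order="F")

        l1 = np.abs(energy_q.values - exact).sum()
        assert l1 <= (6 / 254) * e_t.sum()
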