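"""BEV pipeline: dose extraction, resampling, rotation, projection,
normalization, and aperture-stack construction."""
import numpy as np
import pytest

from leafseq.core import (Beam, Dose3D, Grid3, PreprocessingError, Segment,
                          aperture_mask)
from leafseq import preprocessing as pp
from leafseq import simulation as sim


@pytest.fixture(scope="module")
def beam_doses(machine, phantom, plan):
    total, per = sim.forward_dose_3d(plan, phantom, machine, per_beam=True)
    return total, per


class TestExtractBeamDose:
    def test_beam_doses_sum_to_plan(self, beam_doses):
        total, per = beam_doses
        d = sum(pp.extract_beam_dose(per, k).values for k in per)
        assert np.allclose(d, total.values, atol=1e-9)

    def test_unknown_beam_lists_available(self, beam_doses):
        with pytest.raises(PreprocessingError, match="B00"):
            pp.extract_beam_dose(beam_doses[1], "B99")


class TestResample:
    def test_identity_on_same_grid(self, beam_doses):
        d = beam_doses[0]
        out = pp.resample_to_planning_grid(d, d.grid)
        assert np.array_equal(out.values, d.values)

    def test_constant_field_preserved(self, small_grid):
        fine = Grid3((63, 63, 63), (3.0,) * 3, small_grid.origin)
        d = Dose3D(np.full(small_grid.shape, 7.5), small_grid)
        out = pp.resample_to_planning_grid(d, fine)
        assert np.allclose(out.values, 7.5)

    def test_integral_preserved_on_upsampling(self, beam_doses):
        d = beam_doses[0]
        g = d.grid
        fine = Grid3(tuple(2 * n - 1 for n in g.shape),
                     tuple(s / 2 for s in g.spacing), g.origin)
        out = pp.resample_to_planning_grid(d, fine)
        coarse_int = d.values.sum() * np.prod(g.spacing)
        fine_int = out.values.sum() * np.prod(fine.spacing)
        assert fine_int == pytest.approx(coarse_int, rel=0.03)

    def test_disjoint_grids_rejected(self, beam_doses):
        d = beam_doses[0]
        far = Grid3(d.grid.shape, d.grid.spacing, (1e4, 1e4, 1e4))
        with pytest.raises(PreprocessingError, match="disjoint"):
            pp.resample_to_planning_grid(d, far)


class TestShiftToIsocenter:
    def test_centered_isocenter_is_identity(self, beam_doses):
        d = beam_doses[0]
        out = pp.shift_to_isocenter(d, d.grid.center_mm)
        assert np.array_equal(out.values, d.values)

    def test_integer_voxel_shift_is_exact_roll(self, small_grid):
        rng = np.random.default_rng(0)
        vals = rng.random(small_grid.shape)
        d = Dose3D(vals, small_grid)
        iso = small_grid.center_mm - np.array([2 * 6.0, 0.0, 0.0])
        out = pp.shift_to_isocenter(d, iso)
        expected = np.zeros_like(vals)
        expected[2:] = vals[:-2]
        assert np.allclose(out.values, expected, atol=1e-9)

    def test_shift_then_inverse_is_identity(self, small_grid):
        rng = np.random.default_rng(1)
        d = Dose3D(rng.random(small_grid.shape), small_grid)
        iso = small_grid.center_mm - np.array([6.0, -12.0, 6.0])
        there = pp.shift_to_isocenter(d, iso)
        back = pp.shift_to_isocenter(
            there, 2 * np.asarray(small_grid.center_mm) - iso)
        inner = (slice(4, -4),) * 3
        assert np.abs(back.values[inner] - d.values[inner]).max() \
            < 1e-6 * d.values.max()

    def test_isocenter_outside_grid_rejected(self, beam_doses):
        with pytest.raises(PreprocessingError):
            pp.shift_to_isocenter(beam_doses[0], (1e5, 0, 0))


class TestRotateToBev:
    def test_zero_angle_identity(self, beam_doses):
        d = beam_doses[0]
        out = pp.rotate_to_bev(d, 0.0)
        assert np.allclose(out.values, d.values, atol=1e-12)

    def test_four_right_angles_identity(self, small_grid, rng):
        d = Dose3D(rng.random(small_grid.shape), small_grid)
        out = d
        for _ in range(4):
            out = pp.rotate_to_bev(out, 90.0)
        assert np.abs(out.values - d.values).max() < 1e-9

    def test_cylindrical_dose_invariant(self, small_grid):
        coords = [small_grid.axis_coords(a) for a in range(3)]
        x, y, z = np.meshgrid(*coords, indexing="ij")
        vals = np.exp(-(x ** 2 + y ** 2) / (2 * 40.0 ** 2))
        d = Dose3D(vals, small_grid)
        out = pp.rotate_to_bev(d, 37.0)
        inner = (slice(6, -6),) * 3
        assert np.abs(out.values[inner] - vals[inner]).max() < 0.02


class TestProjectBev:
    def test_slab_projects_to_thickness(self, small_grid):
        vals = np.zeros(small_grid.shape)
        vals[:, 10:15, :] = 1.0     # 5-voxel slab along the beam axis
        bev = pp.project_bev(Dose3D(vals, small_grid))
        assert np.allclose(bev.values, 5.0)

    def test_zero_dose_projects_to_zero(self, small_grid):
        bev = pp.project_bev(Dose3D(np.zeros(small_grid.shape), small_grid))
        assert not np.any(bev.values)

    def test_projection_commutes_with_transverse_shift(self, small_grid,
                                                       rng):
        vals = np.zeros(small_grid.shape)
        vals[8:24, 8:24, 8:24] = rng.random((16, 16, 16))
        d = Dose3D(vals, small_grid)
        shifted = np.roll(vals, 3, axis=0)   # transverse (linac Y) shift
        proj_then_shift = np.roll(pp.project_bev(d).values, 3, axis=1)
        shift_then_proj = pp.project_bev(
            Dose3D(shifted, small_grid)).values
        assert np.allclose(proj_then_shift, shift_then_proj, atol=1e-12)


class TestNormalizeResample:
    def test_constant_map_becomes_ones(self, machine):
        out = pp.normalize_resample(np.full((128, 128), 4.2), machine)
        assert np.allclose(out.pixels, 1.0)
        assert out.scale == pytest.approx(4.2)

    def test_max_is_exactly_one(self, machine, rng):
        out = pp.normalize_resample(rng.random((64, 64)), machine)
        assert out.pixels.max() == 1.0

    def test_all_zero_stays_zero_with_flagged_scale(self, machine):
        out = pp.normalize_resample(np.zeros((64, 64)), machine)
        assert out.scale == 0.0
        assert not np.any(out.pixels)

    def test_negative_input_rejected(self, machine):
        with pytest.raises(PreprocessingError, match="negative"):
            pp.normalize_resample(np.full((32, 32), -1.0), machine)

    def test_denormalization_recovers_smooth_map(self, machine):
        yy, xx = np.meshgrid(np.linspace(-1, 1, 128),
                             np.linspace(-1, 1, 128), indexing="ij")
        smooth = np.exp(-(xx ** 2 + yy ** 2) * 3.0) * 50.0
        out = pp.normalize_resample(smooth, machine)
        assert np.abs(out.denormalized() - smooth).max() \
            < 0.02 * smooth.max()


class TestApertureStack:
    def test_full_open_single_segment(self, machine):
        iv = np.tile([-machine.y_half, machine.y_half],
                     (machine.n_leaf_rows, 1))
        beam = Beam(5.0, [Segment(iv, 1.0)], np.zeros(3))
        st = pp.segments_from_controlpoints(beam, machine, mu_scale=1.0)
        assert st.channels.shape == (128, 128, 6)
        assert np.allclose(st.channels[:, :, 0], 1.0)
        assert not np.any(st.channels[:, :, 1:])

    def test_closed_segment_rejected(self, machine):
        iv = np.zeros((machine.n_leaf_rows, 2))
        with pytest.raises(ValueError, match="open"):
            beam = Beam(5.0, [Segment(iv, 1.0)], np.zeros(3))
            pp.segments_from_controlpoints(beam, machine)

    def test_three_segments_zero_padded(self, machine, rng):
        segs = [sim.sample_segment(rng, machine, (0.0, 0.0), 25.0)
                for _ in range(3)]
        beam = Beam(5.0, segs, np.zeros(3))
        st = pp.segments_from_controlpoints(beam, machine)
        assert st.n_real_segments == 3
        assert not np.any(st.channels[:, :, 3:])
        for c in range(3):
            ch = st.channels[:, :, c]
            nz = ch[ch > 0]
            assert nz.size and np.allclose(nz, nz[0])  # one MU per channel

    def test_overflow_policies(self, machine, rng):
        segs = [sim.sample_segment(rng, machine, (0.0, 0.0), 25.0)
                for _ in range(8)]
        beam = Beam(5.0, segs, np.zeros(3))
        with pytest.raises(PreprocessingError, match="6 channels"):
            pp.segments_from_controlpoints(beam, machine, overflow="error")
        st = pp.segments_from_controlpoints(beam, machine, overflow="merge")
        assert st.n_real_segments == 6
        total_mu = sum(s.mu_weight for s in segs)
        chan_mus = [st.channels[:, :, c].max() * st.mu_scale
                    for c in range(6)]
        assert sum(chan_mus) == pytest.approx(total_mu)

    def test_rasterized_area_matches_interval_lengths(self, machine):
        seg = sim.sample_segment(5, machine, (0.0, 0.0), 30.0)
        mask = aperture_mask(seg, machine, (128, 128))
        dy = machine.field_y_extent / 128
        dx = machine.field_x_extent / 128
        analytic = np.sum(np.diff(seg.open_intervals, axis=1)
                          * machine.leaf_width)
        pixel_area = mask.sum() * dx * dy
        # boundary quantization: one pixel column per open row
        slack = (len(seg.open_rows) + 2) * machine.leaf_width * dy
        assert abs(pixel_area - analytic) <= slack


class TestWellPosedness:
    def test_bev_dose_correlates_with_aperture_sum(self, machine):
        """The normalized BEV projection of each beam's 3D dose must
        correlate strongly (cohort-mean Pearson r >= 0.95 on a 64^3 grid)
        with the MU-weighted aperture channel sum — the property that
        makes dose -> segments learnable."""
        half = 63 * 3.0 / 2.0
        grid = Grid3((64, 64, 64), (3.0,) * 3, (-half,) * 3)
        ph = sim.sample_phantom(21, grid)
        p = sim.sample_plan(22, machine, ph)
        _, per = sim.forward_dose_3d(p, ph, machine, per_beam=True)
        mu_scale = pp.plan_mu_scale(p)
        rs = []
        for bi, beam in enumerate(p.beams):
            dm = pp.bev_dose_input(per[sim.beam_key(bi)], beam, machine)
            st = pp.segments_from_controlpoints(beam, machine, mu_scale)
            rs.append(np.corrcoef(dm.pixels.ravel(),
                                  st.channel_sum().ravel())[0, 1])
        assert np.mean(rs) >= 0.95

    def test_training_pairs_roundtrip_h5(self, tmp_path, machine,
                                         small_grid):
        cohort = sim.sample_cohort(5, machine, n_patients=1, n_fractions=1,
                                   grid_spec=small_grid)
        ts = pp.build_training_pairs(cohort, shape=(32, 32))
        assert ts.inputs.shape == (11, 32, 32, 1)
        assert ts.targets.shape == (11, 32, 32, 6)
        ts.save_h5(tmp_path / "pairs.h5")
        back = pp.TrainingSet.load_h5(tmp_path / "pairs.h5")
        assert np.array_equal(back.inputs, ts.inputs)
        assert np.array_equal(back.targets, ts.targets)
        assert list(back.meta["patient"]) == list(ts.meta["patient"])
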