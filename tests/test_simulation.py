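"""Simulator: samplers, their invariants, and the idealized dose engine."""
import copy

import numpy as np
import pytest

from leafseq.core import (GANTRY_ANGLES, Grid3, MachineModel, Segment,
                          SimulationError, aperture_mask)
from leafseq import simulation as sim


class TestMachineModel:
    def test_leaf_rows_cover_field_exactly(self, machine):
        assert machine.n_leaf_rows == 80
        assert machine.n_leaf_rows * machine.leaf_width == machine.field_x_extent

    def test_inconsistent_geometry_rejected(self):
        with pytest.raises(ValueError):
            MachineModel(leaf_width=7.0)  # 572 not a multiple of 7
        with pytest.raises(ValueError):
            MachineModel(leaf_travel_axis="X", diaphragm_axis="X")


class TestSampleSegment:
    def test_same_seed_identical(self, machine):
        s1 = sim.sample_segment(42, machine, (10.0, -5.0), 30.0)
        s2 = sim.sample_segment(42, machine, (10.0, -5.0), 30.0)
        assert np.array_equal(s1.open_intervals, s2.open_intervals)
        assert s1.mu_weight == s2.mu_weight

    def test_degenerate_target_opens_single_row(self, machine):
        seg = sim.sample_segment(0, machine, (3.0, 7.0), 0.0)
        open_rows = seg.open_rows
        assert open_rows.size == 1
        # the single open row is the one covering the target centre
        leaf = int((3.0 + machine.x_half) // machine.leaf_width)
        assert open_rows[0] == leaf
        lo, up = seg.open_intervals[leaf]
        assert up - lo == pytest.approx(sim.MIN_OPENING_MM)

    def test_target_outside_field_rejected(self, machine):
        with pytest.raises(SimulationError, match="does not fit"):
            sim.sample_segment(0, machine, (0.0, 100.0), 30.0)

    def test_sampled_segments_connected_and_within_field(self, machine):
        """Every sampled aperture is a contiguous run of open rows whose
        edges move by at most two leaf widths between adjacent rows and
        stay inside the field extents."""
        rng = np.random.default_rng(99)
        for _ in range(1000):
            cx = rng.uniform(-60, 60)
            cy = rng.uniform(-40, 40)
            r = rng.uniform(1.0, 50.0)
            seg = sim.sample_segment(rng, machine, (cx, cy), r)
            seg.validate(machine)
            rows = seg.open_rows
            assert np.array_equal(rows, np.arange(rows[0], rows[-1] + 1)), \
                "open rows must be contiguous"
            iv = seg.open_intervals[rows]
            if len(rows) > 1:
                jumps = np.abs(np.diff(iv, axis=0))
                assert jumps.max() <= 2 * machine.leaf_width + 1e-9
            assert iv.min() >= -machine.y_half - 1e-9
            assert iv.max() <= machine.y_half + 1e-9


class TestSamplePlan:
    def test_eleven_fixed_beam_angles(self, plan):
        assert len(plan.beams) == 11
        assert tuple(b.gantry_angle for b in plan.beams) == GANTRY_ANGLES

    def test_segment_range_respected(self, machine, phantom):
        p = sim.sample_plan(5, machine, phantom, n_segments_range=(1, 1))
        assert all(len(b.segments) == 1 for b in p.beams)

    def test_empty_ptv_rejected(self, machine, phantom):
        empty = copy.deepcopy(phantom)
        empty.ptv_mask = np.zeros_like(empty.ptv_mask)
        with pytest.raises(SimulationError, match="PTV"):
            sim.sample_plan(5, machine, empty)

    def test_cohort_counts(self, small_grid):
        cohort = sim.sample_cohort(3, n_patients=2, n_fractions=5,
                                   grid_spec=small_grid)
        assert len(cohort.plans) == 10
        assert cohort.n_beams == 110
        assert len(cohort.phantoms) == 2


class TestSamplePhantom:
    def test_deterministic(self, small_grid):
        p1 = sim.sample_phantom(7, small_grid)
        p2 = sim.sample_phantom(7, small_grid)
        assert np.array_equal(p1.ptv_mask, p2.ptv_mask)
        assert np.array_equal(p1.body_mask, p2.body_mask)

    def test_ptv_inside_body_and_oars_disjoint_from_ptv(self, phantom):
        assert not np.any(phantom.ptv_mask & ~phantom.body_mask)
        assert len(phantom.oar_masks) >= 4
        for name, m in phantom.oar_masks.items():
            assert not np.any(m & phantom.ptv_mask), name


class TestFluence2D:
    def test_unblurred_single_segment_is_weighted_mask(self, machine):
        seg = sim.sample_segment(1, machine, (0.0, 0.0), 30.0)
        from leafseq.core import Beam
        beam = Beam(5.0, [seg], np.zeros(3))
        f = sim.fluence_2d(beam, machine, resolution_mm=2.0, sigma_mm=0.0)
        mask = aperture_mask(seg, machine, f.shape)
        assert np.array_equal(f, seg.mu_weight * mask)

    def test_linearity_in_segments(self, machine):
        from leafseq.core import Beam
        seg = sim.sample_segment(1, machine, (0.0, 0.0), 30.0)
        seg2 = Segment(seg.open_intervals.copy(), 2.5 * seg.mu_weight)
        one = sim.fluence_2d(Beam(5.0, [seg], np.zeros(3)), machine, 2.0)
        both = sim.fluence_2d(Beam(5.0, [seg, seg2], np.zeros(3)), machine, 2.0)
        assert np.allclose(both, one * 3.5, atol=1e-9)

    def test_gaussian_blur_preserves_integral(self, machine):
        from leafseq.core import Beam
        seg = sim.sample_segment(1, machine, (0.0, 0.0), 25.0)
        beam = Beam(5.0, [seg], np.zeros(3))
        sharp = sim.fluence_2d(beam, machine, 2.0, sigma_mm=0.0)
        blurred = sim.fluence_2d(beam, machine, 2.0, sigma_mm=3.0)
        assert blurred.sum() == pytest.approx(sharp.sum(), rel=1e-6)


class TestForwardDose:
    def test_no_attenuation_constant_along_ray(self, machine, phantom):
        # a 90-degree beam with the isocenter at the rotation centre maps
        # onto the grid axes exactly, so with mu = 0 the dose must be
        # constant along each ray
        from types import SimpleNamespace

        from leafseq.core import Beam
        seg = sim.sample_segment(2, machine, (0.0, 0.0), 25.0)
        beam = Beam(90.0, [seg], np.zeros(3))
        _, per = sim.forward_dose_3d(SimpleNamespace(beams=[beam]), phantom,
                                     machine, mu_attenuation=0.0,
                                     per_beam=True)
        d = per["B00"].values
        spread = d.max(axis=0) - d.min(axis=0)
        assert spread.max() <= 1e-9 * d.max()

    def test_linearity_in_mu(self, machine, phantom, plan):
        d1 = sim.forward_dose_3d(plan, phantom, machine)
        doubled = copy.deepcopy(plan)
        for b in doubled.beams:
            for s in b.segments:
                s.mu_weight *= 2.0
        d2 = sim.forward_dose_3d(doubled, phantom, machine)
        assert np.array_equal(d2.values, 2.0 * d1.values)

    def test_per_beam_doses_sum_to_plan(self, machine, phantom, plan):
        total, per = sim.forward_dose_3d(plan, phantom, machine,
                                         per_beam=True)
        assert len(per) == 11
        s = sum(d.values for d in per.values())
        assert np.allclose(s, total.values, atol=1e-9)

    def test_isocenter_outside_grid_rejected(self, machine, phantom, plan):
        bad = copy.deepcopy(plan)
        for b in bad.beams:
            b.isocenter = np.array([1e4, 0.0, 0.0])
        with pytest.raises(SimulationError, match="isocenter"):
            sim.forward_dose_3d(bad, phantom, machine)

    def test_rotational_equivariance(self, machine):
        """With a cylindrically symmetric phantom and aperture, rotating
        the gantry by 90 degrees rotates the dose field by the same angle
        (up to interpolation error)."""
        from leafseq.core import Beam, Plan, rotate_volume_z
        half = 31 * 6.0 / 2.0
        grid = Grid3((32, 32, 32), (6.0,) * 3, (-half,) * 3)
        coords = [grid.axis_coords(a) for a in range(3)]
        x, y, z = np.meshgrid(*coords, indexing="ij")
        body = (x ** 2 + y ** 2) <= 80.0 ** 2
        ptv = (x ** 2 + y ** 2 + z ** 2) <= 20.0 ** 2
        from leafseq.core import Phantom
        ph = Phantom(grid, body, ptv & body)
        seg = sim.sample_segment(3, machine, (0.0, 0.0), 20.0)

        from types import SimpleNamespace

        def one_beam_dose(angle):
            beam = Beam(angle, [Segment(seg.open_intervals.copy(),
                                        seg.mu_weight)], np.zeros(3))
            holder = SimpleNamespace(beams=[beam])
            _, per = sim.forward_dose_3d(holder, ph, machine, per_beam=True)
            return per["B00"].values

        d0 = one_beam_dose(5.0)
        d90 = one_beam_dose(95.0)
        rotated = rotate_volume_z(d0, 90.0, grid.center_index, grid.spacing)
        err = np.abs(d90 - rotated).max() / d0.max()
        assert err < 0.02
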