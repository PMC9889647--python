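"""Synthetic cohorts of step-and-shoot IMRT plans with idealized dose.

This module generates the study conditions the rest of the package is
exercised on: a 10-patient cohort, five fractionated plans each, 11 fixed
gantry angles per plan, 1-6 MLC apertures per beam with monitor-unit
weights, an ellipsoidal phantom with PTV and organ-at-risk masks, and an
idealized per-beam dose obtained by attenuated back-projection of the
MU-weighted aperture fluence.

The dose engine is deliberately simple — parallel rays, a Gaussian
penumbra, exponential attenuation inside the body, no scatter or
heterogeneity — but it is used consistently for both ground-truth and
predicted-plan dose so that downstream comparisons are internally valid.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (BEV_ROTATION_SIGN, GANTRY_ANGLES, Beam, Dose3D, Grid3,
                   MachineModel, Phantom, Plan, Segment, SimulationError,
                   aperture_mask, rotate_volume_z)

# Simulator defaults (all configurable through the sampler signatures):
DEFAULT_MU_RANGE = (20.0, 200.0)     # log-uniform MU per segment
DEFAULT_SIGMA_MM = 3.0               # Gaussian penumbra sigma
DEFAULT_ATTENUATION = 0.005          # /mm inside the body
DEFAULT_GRID = Grid3(shape=(96, 96, 96), spacing=(3.0, 3.0, 3.0),
                     origin=(-142.5, -142.5, -142.5))
DEFAULT_SEGMENT_RANGE = (1, 6)
MIN_OPENING_MM = 5.0                 # smallest leaf opening the sampler emits


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Phantom sampling
# ---------------------------------------------------------------------------

def _ellipsoid(grid: Grid3, center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    coords = [grid.axis_coords(a) for a in range(3)]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    return (((x - center[0]) / semi[0]) ** 2
            + ((y - center[1]) / semi[1]) ** 2
            + ((z - center[2]) / semi[2]) ** 2) <= 1.0


def sample_phantom(rng_seed, grid_spec: Grid3 = DEFAULT_GRID) -> Phantom:
    """Sample an abdominal-like phantom: ellipsoidal body, a PTV near the
    grid centre, and four organ-at-risk masks arranged to exercise DVH
    comparisons (an annular duodenum-like structure abutting the PTV, two
    lateral kidney-like ellipsoids, a posterior cord-like cylinder and an
    anterior stomach-like blob).

    Deterministic: identical masks for identical seeds.
    """
    rng = _as_rng(rng_seed)
    grid = grid_spec
    half = (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing) / 2.0
    c0 = grid.center_mm

    body_semi = half * np.array([0.88, 0.80, 0.96]) * rng.uniform(0.95, 1.05, 3)
    body = _ellipsoid(grid, c0, body_semi)

    ptv_center = c0 + rng.uniform(-6.0, 6.0, 3)
    ptv_semi = rng.uniform(12.0, 22.0, 3)
    ptv = _ellipsoid(grid, ptv_center, ptv_semi) & body

    coords = [grid.axis_coords(a) for a in range(3)]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    rxy = np.sqrt((x - ptv_center[0]) ** 2 + (y - ptv_center[1]) ** 2)
    shell_lo = ptv_semi[:2].max() + 2.0
    duodenum = ((rxy >= shell_lo) & (rxy <= shell_lo + 14.0)
                & (x >= ptv_center[0])
                & (np.abs(z - ptv_center[2]) <= 20.0))

    kidney_semi = np.array([16.0, 12.0, 24.0])
    kid_l = _ellipsoid(grid, c0 + np.array([-0.45 * half[0], 0.25 * half[1], 0.0])
                       + rng.uniform(-4, 4, 3), kidney_semi)
    kid_r = _ellipsoid(grid, c0 + np.array([0.45 * half[0], 0.25 * half[1], 0.0])
                       + rng.uniform(-4, 4, 3), kidney_semi)

    cord_c = c0 + np.array([0.0, 0.55 * half[1], 0.0])
    cord = (np.sqrt((x - cord_c[0]) ** 2 + (y - cord_c[1]) ** 2) <= 6.0)

    stomach = _ellipsoid(grid, c0 + np.array([-0.30 * half[0], -0.35 * half[1],
                                              0.10 * half[2]])
                         + rng.uniform(-5, 5, 3), np.array([24.0, 18.0, 28.0]))

    oars = {}
    for name, m in [("Duodenum", duodenum), ("Kidney_L", kid_l),
                    ("Kidney_R", kid_r), ("Cord", cord), ("Stomach", stomach)]:
        oars[name] = m & body & ~ptv
    return Phantom(grid=grid, body_mask=body, ptv_mask=ptv, oar_masks=oars)


# ---------------------------------------------------------------------------
# Segment / plan sampling
# ---------------------------------------------------------------------------

def sample_segment(rng_seed, machine: MachineModel, target_center,
                   target_radius: float,
                   mu_range: tuple[float, float] = DEFAULT_MU_RANGE,
                   min_opening: float = MIN_OPENING_MM,
                   edge_jitter: float = 2.5) -> Segment:
    """Sample a connected aperture roughly conformal to a perturbed ellipse
    about ``target_center`` (linac X, linac Y, mm at isocenter).

    Open intervals vary by at most two leaf widths between adjacent rows,
    the open rows form one contiguous run, and every position lies inside
    the field extents.  MU is drawn log-uniform over ``mu_range``.
    """
    rng = _as_rng(rng_seed)
    cx, cy = float(target_center[0]), float(target_center[1])
    r = float(target_radius)
    if (abs(cx) + r > machine.x_half) or (abs(cy) + r > machine.y_half):
        raise SimulationError(
            f"target (centre=({cx:.1f}, {cy:.1f}) mm, radius={r:.1f} mm) "
            f"does not fit inside the field extents "
            f"{machine.field_x_extent:.0f} x {machine.field_y_extent:.0f} mm")

    n = machine.n_leaf_rows
    w = machine.leaf_width
    row_centers = machine.bev_row_centers(n)  # leaf-row strip centres
    cy = float(np.clip(cy, -machine.y_half + min_opening / 2,
                       machine.y_half - min_opening / 2))
    intervals = np.tile([cy, cy], (n, 1)).astype(float)
    mu = float(np.exp(rng.uniform(np.log(mu_range[0]), np.log(mu_range[1]))))

    center_row = int(np.argmin(np.abs(row_centers - cx)))
    if r == 0.0:
        intervals[center_row] = [cy - min_opening / 2, cy + min_opening / 2]
        return Segment(open_intervals=intervals, mu_weight=mu)

    a = r * rng.uniform(0.85, 1.25)            # semi-axis along linac X
    b = r * rng.uniform(0.85, 1.25)            # semi-axis along linac Y
    a = min(a, machine.x_half - abs(cx))
    b = min(b, machine.y_half - abs(cy) - 1e-6)

    def ideal(row: int) -> tuple[float, float] | None:
        t = (row_centers[row] - cx) / a
        if abs(t) >= 1.0:
            return None
        half_chord = max(b * np.sqrt(1.0 - t * t), min_opening / 2)
        lo = cy - half_chord + rng.normal(0.0, edge_jitter)
        up = cy + half_chord + rng.normal(0.0, edge_jitter)
        return lo, up

    # Walk outward from the centre row, clamping edge travel to 2 leaf
    # widths per row so the aperture stays connected and smooth.
    intervals[center_row] = [cy - max(b, min_opening / 2),
                             cy + max(b, min_opening / 2)]
    for direction in (-1, +1):
        prev = intervals[center_row].copy()
        row = center_row + direction
        while 0 <= row < n:
            got = ideal(row)
            if got is None:
                break
            lo = float(np.clip(got[0], prev[0] - 2 * w, prev[0] + 2 * w))
            up = float(np.clip(got[1], prev[1] - 2 * w, prev[1] + 2 * w))
            lo = float(np.clip(lo, -machine.y_half, machine.y_half))
            up = float(np.clip(up, -machine.y_half, machine.y_half))
            if up - lo < 1.0:
                break
            intervals[row] = [lo, up]
            prev = np.array([lo, up])
            row += direction

    seg = Segment(open_intervals=intervals, mu_weight=mu)
    seg.validate(machine)
    return seg


def ptv_bev_footprint(phantom: Phantom, gantry_angle: float,
                      isocenter: np.ndarray) -> tuple[np.ndarray, float]:
    """Centre (linac X, Y mm) and radius of the PTV projected into the BEV
    of a beam at ``gantry_angle``."""
    idx = np.argwhere(phantom.ptv_mask)
    if idx.size == 0:
        raise SimulationError("phantom has an empty PTV mask")
    pos = phantom.grid.index_to_mm(idx) - np.asarray(isocenter)
    theta = np.deg2rad(BEV_ROTATION_SIGN * gantry_angle)
    c, s = np.cos(theta), np.sin(theta)
    x_rot = c * pos[:, 0] - s * pos[:, 1]
    bev_x = pos[:, 2]            # linac X follows patient z in the beam frame
    bev_y = x_rot                # linac Y follows rotated patient x
    center = np.array([bev_x.mean(), bev_y.mean()])
    half_x = (bev_x.max() - bev_x.min()) / 2.0
    half_y = (bev_y.max() - bev_y.min()) / 2.0
    radius = 0.5 * (half_x + half_y) + 4.0
    return center, float(radius)


def sample_plan(rng_seed, machine: MachineModel, phantom: Phantom,
                n_segments_range: tuple[int, int] = DEFAULT_SEGMENT_RANGE,
                patient_id: str = "P00", fraction_index: int = 1,
                prescription: float = 3500.0,
                mu_range: tuple[float, float] = DEFAULT_MU_RANGE) -> Plan:
    """Sample a step-and-shoot plan: 11 beams at the fixed gantry angles,
    a uniform number of segments per beam, apertures conformal to the PTV
    projection at each angle, isocenter at the PTV centroid."""
    rng = _as_rng(rng_seed)
    iso = phantom.ptv_centroid_mm
    lo, hi = n_segments_range
    beams = []
    for angle in GANTRY_ANGLES:
        center, radius = ptv_bev_footprint(phantom, angle, iso)
        n_seg = int(rng.integers(lo, hi + 1))
        segments = [sample_segment(rng, machine, center, radius,
                                   mu_range=mu_range)
                    for _ in range(n_seg)]
        beams.append(Beam(gantry_angle=angle, segments=segments,
                          isocenter=iso))
    return Plan(patient_id=patient_id, fraction_index=fraction_index,
                beams=beams, prescription=prescription)


@dataclass
class Cohort:
    """A simulated patient cohort: one phantom per patient, one plan per
    patient-fraction."""

    machine: MachineModel
    phantoms: dict[str, Phantom] = field(default_factory=dict)
    plans: list[Plan] = field(default_factory=list)

    def plans_for(self, patient_id: str) -> list[Plan]:
        return [p for p in self.plans if p.patient_id == patient_id]

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.phantoms)

    @property
    def n_beams(self) -> int:
        return sum(len(p.beams) for p in self.plans)


def sample_cohort(rng_seed, machine: MachineModel | None = None,
                  n_patients: int = 10, n_fractions: int = 5,
                  grid_spec: Grid3 = DEFAULT_GRID,
                  n_segments_range: tuple[int, int] = DEFAULT_SEGMENT_RANGE,
                  mu_range: tuple[float, float] = DEFAULT_MU_RANGE) -> Cohort:
    """Sample the full study cohort: ``n_patients`` phantoms, each with
    ``n_fractions`` daily plans (same phantom, independently re-sampled
    apertures, emulating daily adaptive replans)."""
    rng = _as_rng(rng_seed)
    machine = machine or MachineModel()
    cohort = Cohort(machine=machine)
    for i in range(n_patients):
        pid = f"P{i:02d}"
        phantom = sample_phantom(rng, grid_spec)
        cohort.phantoms[pid] = phantom
        for fx in range(1, n_fractions + 1):
            cohort.plans.append(
                sample_plan(rng, machine, phantom,
                            n_segments_range=n_segments_range,
                            patient_id=pid, fraction_index=fx,
                            mu_range=mu_range))
    return cohort


# ---------------------------------------------------------------------------
# Idealized forward dose engine
# ---------------------------------------------------------------------------

def fluence_2d(beam: Beam, machine: MachineModel,
               resolution_mm: float = 2.0,
               sigma_mm: float = DEFAULT_SIGMA_MM) -> np.ndarray:
    """MU-weighted sum of the beam's binary aperture masks on the
    full-field BEV raster, blurred with an isotropic Gaussian penumbra.

    Rows follow linac X, columns linac Y; pixel size ``resolution_mm``.
    """
    shape = (round(machine.field_x_extent / resolution_mm),
             round(machine.field_y_extent / resolution_mm))
    f = np.zeros(shape, dtype=float)
    for seg in beam.segments:
        f += seg.mu_weight * aperture_mask(seg, machine, shape)
    if sigma_mm > 0:
        f = ndimage.gaussian_filter(f, sigma_mm / resolution_mm,
                                    mode="grid-constant", cval=0.0)
    return f


def beam_key(index: int) -> str:
    return f"B{index:02d}"


def forward_dose_3d(plan: Plan, phantom: Phantom, machine: MachineModel,
                    mu_attenuation: float = DEFAULT_ATTENUATION,
                    sigma_mm: float = DEFAULT_SIGMA_MM,
                    fluence_resolution_mm: float = 2.0,
                    per_beam: bool = False):
    """Idealized plan dose: per beam, the BEV fluence is back-projected as
    parallel rays along the beam axis with exponential attenuation over the
    water-equivalent depth inside the body, then rotated by the gantry
    angle about the isocenter.  Exactly linear in the MU weights and fully
    deterministic.

    Returns the plan ``Dose3D``; with ``per_beam=True`` returns
    ``(plan_dose, {beam_key: Dose3D})``.
    """
    grid = phantom.grid
    total = np.zeros(grid.shape, dtype=float)
    beams: dict[str, Dose3D] = {}
    for bi, beam in enumerate(plan.beams):
        if not grid.contains_mm(beam.isocenter):
            raise SimulationError(
                f"isocenter {beam.isocenter} lies outside the phantom grid")
        iso_idx = grid.mm_to_index(beam.isocenter)

        body_rot = rotate_volume_z(phantom.body_mask.astype(float),
                                   BEV_ROTATION_SIGN * beam.gantry_angle,
                                   iso_idx, grid.spacing)
        dy = grid.spacing[1]
        depth = (np.cumsum(body_rot, axis=1) - 0.5 * body_rot) * dy

        fl = fluence_2d(beam, machine, fluence_resolution_mm, sigma_mm)
        # sample the fluence at each (x, z) column of the beam-frame grid
        x_rel = grid.axis_coords(0) - beam.isocenter[0]   # linac Y coords
        z_rel = grid.axis_coords(2) - beam.isocenter[2]   # linac X coords
        row = (z_rel + machine.x_half) / fluence_resolution_mm - 0.5
        col = (x_rel + machine.y_half) / fluence_resolution_mm - 0.5
        rr, cc = np.meshgrid(row, col, indexing="xy")  # (nx, nz)
        f_vox = ndimage.map_coordinates(fl, [rr, cc], order=1,
                                        mode="grid-constant", cval=0.0)

        dose_bf = f_vox[:, None, :] * np.exp(-mu_attenuation * depth)
        dose_pat = rotate_volume_z(dose_bf, -BEV_ROTATION_SIGN
                                   * beam.gantry_angle, iso_idx, grid.spacing)
        total += dose_pat
        if per_beam:
            beams[beam_key(bi)] = Dose3D(dose_pat, grid, beam_ref=beam_key(bi))

    plan_dose = Dose3D(total, grid, beam_ref="PLAN")
    if per_beam:
        return plan_dose, beams
    return plan_dose
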