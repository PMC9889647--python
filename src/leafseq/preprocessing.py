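"""From 3D per-beam dose to normalized BEV inputs and aperture targets.

The model input is made from the per-beam 3D dose: shift the isocenter to
the grid's rotation centre, rotate to the beam's eye view, sum along the
beam axis, resample onto the fixed 128 x 128 full-field raster and rescale
to [0, 1].  The model target is the MU-weighted aperture stack: each
segment rasterized as a binary mask on the same raster, multiplied by its
normalized MU, stacked into six channels with zero padding.

Both products live on the same machine raster (rows = linac X, columns =
linac Y, centred on the isocenter), which is what lets the network learn
the spatial correspondence between dose and aperture shape.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (BEV_ROTATION_SIGN, Beam, Dose3D, Grid3, MachineModel,
                   Plan, PreprocessingError, aperture_mask, rotate_volume_z)

N_CHANNELS = 6  # fixed number of output channels; shorter beams zero-padded


@dataclass
class DoseMap2D:
    """Normalized BEV dose image on the full-field raster.

    ``scale`` is the maximum dose (cGy-weighted projection units) removed
    by the normalization; 0 marks an all-zero map.
    """

    pixels: np.ndarray
    scale: float
    beam_ref: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)

    def denormalized(self) -> np.ndarray:
        return self.pixels * self.scale


@dataclass
class ApertureStack:
    """[H, W, 6] MU-weighted aperture channels; the model target.

    Channel ``c`` equals ``(mu_c / mu_scale) * mask_c`` for real segments
    and is exactly zero beyond ``n_real_segments``.
    """

    channels: np.ndarray
    mu_scale: float
    n_real_segments: int
    beam_ref: str | None = None

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)

    def channel_sum(self) -> np.ndarray:
        return self.channels.sum(axis=-1)


@dataclass
class BevMap:
    """An intermediate projected dose image with its physical geometry
    (mm relative to the isocenter) still attached."""

    values: np.ndarray
    rows_mm: np.ndarray  # linac X coordinate of each row
    cols_mm: np.ndarray  # linac Y coordinate of each column


# ---------------------------------------------------------------------------
# 3D dose manipulations
# ---------------------------------------------------------------------------

def extract_beam_dose(rtdose_set: Mapping[str, Dose3D], beam_ref: str) -> Dose3D:
    """Pull one beam's dose out of a per-beam dose collection."""
    try:
        return rtdose_set[beam_ref]
    except KeyError:
        raise PreprocessingError(
            f"no RTDose for beam {beam_ref!r}; available: "
            f"{sorted(rtdose_set)}") from None


def resample_to_planning_grid(dose: Dose3D, target_grid: Grid3) -> Dose3D:
    """Trilinear resample onto the planning grid; outside-source voxels 0."""
    src, dst = dose.grid, target_grid
    for ax in range(3):
        s_lo, s_hi = src.origin[ax], src.axis_coords(ax)[-1]
        d_lo, d_hi = dst.origin[ax], dst.axis_coords(ax)[-1]
        if s_hi < d_lo or d_hi < s_lo:
            raise PreprocessingError(
                f"source and target grids are disjoint along axis {ax}")
    if src == dst:
        return Dose3D(dose.values.copy(), dst, dose.beam_ref)
    coords = np.meshgrid(*[dst.axis_coords(a) for a in range(3)], indexing="ij")
    idx = [(coords[a] - src.origin[a]) / src.spacing[a] for a in range(3)]
    vals = ndimage.map_coordinates(dose.values, idx, order=1,
                                   mode="grid-constant", cval=0.0)
    return Dose3D(vals, dst, dose.beam_ref)


def shift_to_isocenter(dose: Dose3D, isocenter) -> Dose3D:
    """Translate the volume so the isocenter sits at the grid's rotation
    centre (trilinear for sub-voxel shifts, zero fill)."""
    grid = dose.grid
    if not grid.contains_mm(isocenter):
        raise PreprocessingError(f"isocenter {isocenter} outside the grid")
    shift_vox = grid.center_index - grid.mm_to_index(isocenter)
    if np.allclose(shift_vox, 0.0):
        return dose.copy_with(dose.values.copy())
    vals = ndimage.shift(dose.values, shift_vox, order=1,
                         mode="grid-constant", cval=0.0, prefilter=False)
    return dose.copy_with(vals)


def rotate_to_bev(dose: Dose3D, gantry_angle: float) -> Dose3D:
    """Rotate an isocenter-centred dose so the beam axis aligns with the
    grid's +y axis (content rotation by -gantry about patient z)."""
    vals = rotate_volume_z(dose.values, BEV_ROTATION_SIGN * gantry_angle,
                           dose.grid.center_index, dose.grid.spacing)
    return dose.copy_with(vals)


def project_bev(dose: Dose3D) -> BevMap:
    """Sum the BEV-aligned dose along the beam axis.

    Returns the 2D map in BEV orientation (rows = linac X = patient z,
    columns = linac Y = patient x) with mm coordinates relative to the
    grid centre (= the isocenter after :func:`shift_to_isocenter`).
    """
    grid = dose.grid
    proj = dose.values.sum(axis=1)          # (nx, nz), indexed [x, z]
    center = grid.center_mm
    rows_mm = grid.axis_coords(2) - center[2]
    cols_mm = grid.axis_coords(0) - center[0]
    return BevMap(values=proj.T, rows_mm=rows_mm, cols_mm=cols_mm)


def normalize_resample(map_2d, machine: MachineModel | None = None,
                       shape: tuple[int, int] = (128, 128),
                       beam_ref: str | None = None) -> DoseMap2D:
    """Resample a projected map onto the full-field raster and rescale to
    [0, 1], keeping the removed maximum as ``scale``.

    Accepts a :class:`BevMap` (physical geometry respected) or a plain
    array (assumed to already span the field raster).
    """
    machine = machine or MachineModel()
    if isinstance(map_2d, BevMap):
        if np.any(map_2d.values < 0):
            raise PreprocessingError("negative dose values in BEV map")
        r_idx = ((machine.bev_row_centers(shape[0]) - map_2d.rows_mm[0])
                 / (map_2d.rows_mm[1] - map_2d.rows_mm[0]))
        c_idx = ((machine.bev_col_centers(shape[1]) - map_2d.cols_mm[0])
                 / (map_2d.cols_mm[1] - map_2d.cols_mm[0]))
        rr, cc = np.meshgrid(r_idx, c_idx, indexing="ij")
        pix = ndimage.map_coordinates(map_2d.values, [rr, cc], order=1,
                                      mode="grid-constant", cval=0.0)
    else:
        arr = np.asarray(map_2d, dtype=float)
        if np.any(arr < 0):
            raise PreprocessingError("negative dose values in map")
        if arr.shape == tuple(shape):
            pix = arr.copy()
        else:
            r_idx = (np.arange(shape[0]) + 0.5) * arr.shape[0] / shape[0] - 0.5
            c_idx = (np.arange(shape[1]) + 0.5) * arr.shape[1] / shape[1] - 0.5
            rr, cc = np.meshgrid(r_idx, c_idx, indexing="ij")
            pix = ndimage.map_coordinates(arr, [rr, cc], order=1,
                                          mode="nearest")
    peak = float(pix.max())
    if peak <= 0.0:
        return DoseMap2D(np.zeros(shape), scale=0.0, beam_ref=beam_ref)
    return DoseMap2D(np.clip(pix, 0.0, None) / peak, scale=peak,
                     beam_ref=beam_ref)


def bev_dose_input(beam_dose: Dose3D, beam: Beam, machine: MachineModel,
                   shape: tuple[int, int] = (128, 128)) -> DoseMap2D:
    """The full input chain for one beam: shift to isocenter, rotate to
    BEV, project along the beam axis, resample and normalize."""
    d = shift_to_isocenter(beam_dose, beam.isocenter)
    d = rotate_to_bev(d, beam.gantry_angle)
    return normalize_resample(project_bev(d), machine, shape,
                              beam_ref=beam_dose.beam_ref)


# ---------------------------------------------------------------------------
# Aperture targets
# ---------------------------------------------------------------------------

def plan_mu_scale(plan: Plan) -> float:
    """Plan-level MU normalization constant: the largest segment MU."""
    return max(s.mu_weight for b in plan.beams for s in b.segments)


def segments_from_controlpoints(beam: Beam, machine: MachineModel,
                                mu_scale: float | None = None,
                                shape: tuple[int, int] = (128, 128),
                                overflow: str = "error",
                                beam_ref: str | None = None) -> ApertureStack:
    """Rasterize a beam's segments into the MU-weighted aperture stack.

    Each channel is the segment's binary mask (pixel centres inside the
    leaf openings) times its MU normalized by ``mu_scale``; channels are
    ordered by delivery order and zero-padded to six.  Beams with more
    than six segments follow the ``overflow`` policy: ``"error"``
    (default) or ``"merge"`` (repeatedly merge the two smallest-MU
    segments: union of masks, summed MU).
    """
    for seg in beam.segments:
        seg.validate(machine)
    if mu_scale is None:
        mu_scale = max(s.mu_weight for s in beam.segments)
    entries = [(aperture_mask(s, machine, shape), s.mu_weight)
               for s in beam.segments]
    if len(entries) > N_CHANNELS:
        if overflow == "error":
            raise PreprocessingError(
                f"beam has {len(entries)} segments but the model emits "
                f"{N_CHANNELS} channels (overflow policy 'error')")
        if overflow != "merge":
            raise ValueError(f"unknown overflow policy {overflow!r}")
        while len(entries) > N_CHANNELS:
            entries.sort(key=lambda e: e[1])
            (m1, w1), (m2, w2) = entries[0], entries[1]
            entries = [(m1 | m2, w1 + w2)] + entries[2:]
    channels = np.zeros((*shape, N_CHANNELS), dtype=float)
    for c, (mask, mu) in enumerate(entries):
        channels[:, :, c] = mask * (mu / mu_scale)
    return ApertureStack(channels=channels, mu_scale=float(mu_scale),
                         n_real_segments=len(entries), beam_ref=beam_ref)


# ---------------------------------------------------------------------------
# Training-pair archives
# ---------------------------------------------------------------------------

@dataclass
class TrainingSet:
    """Paired (input dose map, target aperture stack) tensors plus a
    metadata row per beam sample."""

    inputs: np.ndarray    # [N, H, W, 1] float32, in [0, 1]
    targets: np.ndarray   # [N, H, W, 6] float32
    meta: pd.DataFrame    # patient, fraction, beam, angle, scale, mu_scale

    def __len__(self) -> int:
        return self.inputs.shape[0]

    def subset(self, indices) -> "TrainingSet":
        idx = np.asarray(indices)
        return TrainingSet(self.inputs[idx], self.targets[idx],
                           self.meta.iloc[idx].reset_index(drop=True))

    def save_h5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("inputs", data=self.inputs, compression="gzip")
            f.create_dataset("targets", data=self.targets, compression="gzip")
            g = f.create_group("meta")
            for col in self.meta.columns:
                vals = self.meta[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                g.create_dataset(col, data=vals)

    @classmethod
    def load_h5(cls, path) -> "TrainingSet":
        import h5py
        with h5py.File(path, "r") as f:
            inputs = f["inputs"][...]
            targets = f["targets"][...]
            cols = {}
            for col in f["meta"]:
                v = f["meta"][col][...]
                if v.dtype.kind == "S":
                    v = v.astype(str)
                cols[col] = v
        return cls(inputs, targets, pd.DataFrame(cols))


def build_training_pairs(cohort, shape: tuple[int, int] = (128, 128),
                         engine_kwargs: dict | None = None) -> TrainingSet:
    """Run the simulator's dose engine over a cohort and assemble the
    (BEV dose map, aperture stack) pair for every beam."""
    from . import simulation

    engine_kwargs = engine_kwargs or {}
    machine = cohort.machine
    inputs, targets, rows = [], [], []
    for plan in cohort.plans:
        phantom = cohort.phantoms[plan.patient_id]
        _, per_beam = simulation.forward_dose_3d(plan, phantom, machine,
                                                 per_beam=True,
                                                 **engine_kwargs)
        mu_scale = plan_mu_scale(plan)
        for bi, beam in enumerate(plan.beams):
            key = simulation.beam_key(bi)
            dm = bev_dose_input(per_beam[key], beam, machine, shape)
            st = segments_from_controlpoints(beam, machine, mu_scale, shape,
                                             beam_ref=key)
            inputs.append(dm.pixels[..., None].astype(np.float32))
            targets.append(st.channels.astype(np.float32))
            rows.append({"patient": plan.patient_id,
                         "fraction": plan.fraction_index,
                         "beam": bi, "angle": beam.gantry_angle,
                         "scale": dm.scale, "mu_scale": mu_scale,
                         "n_segments": st.n_real_segments})
    return TrainingSet(np.stack(inputs), np.stack(targets),
                       pd.DataFrame(rows))
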