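"""Shared domain types and geometry conventions.

Coordinate conventions, used everywhere and defined only here:

* Patient grid: array index order ``(i, j, k)`` maps to patient axes
  ``(x, y, z)`` with ``z`` the superior-inferior axis (the gantry rotation
  axis).  Voxel centre position is ``origin + index * spacing`` (mm).
* Gantry: IEC scale, degrees.  At gantry 0 the beam travels along ``+y``;
  the beam direction at gantry ``g`` is ``Rz(g) @ (0, 1, 0)``.  Rotating the
  volume *content* by ``-g`` about ``z`` (about the isocenter) therefore
  brings any beam to the ``+y`` axis — the "beam frame".
* Beam's-eye-view (BEV) images: rows follow the linac X axis (the leaf-row
  / diaphragm axis, 572 mm full extent, mapped to patient ``z`` in the beam
  frame); columns follow the linac Y axis (the leaf-travel axis, 220 mm,
  mapped to patient ``x`` in the beam frame).  Pixel centres span the full
  field extents, centred on the isocenter.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: The fixed gantry-angle set (degrees) shared by every plan in a cohort.
GANTRY_ANGLES: tuple[float, ...] = (5.0, 25.0, 60.0, 90.0, 155.0, 175.0,
                                    195.0, 260.0, 290.0, 310.0, 345.0)

#: Sign convention for "rotate to BEV": volume content is rotated by
#: ``BEV_ROTATION_SIGN * gantry_angle`` about the patient z axis.
BEV_ROTATION_SIGN = -1.0


class LeafSeqError(Exception):
    """Base class for all package errors."""


class SimulationError(LeafSeqError):
    pass


class PreprocessingError(LeafSeqError):
    pass


class SequencingError(LeafSeqError):
    pass


class EmptySegmentError(SequencingError):
    """A predicted channel contains no deliverable aperture."""


class DicomIOError(LeafSeqError):
    pass


class EvaluationError(LeafSeqError):
    pass


# ---------------------------------------------------------------------------
# Machine model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MachineModel:
    """Linac beam-shaping geometry.

    Defaults describe an MR-linac head with 7.15 mm leaves: 80 leaf pairs
    cover 572 mm along the linac X axis, leaves travel along the linac Y
    axis over a 220 mm extent, and the diaphragms (jaws) move along X.
    """

    leaf_width: float = 7.15           # mm at isocenter, along linac X
    field_x_extent: float = 572.0      # mm (diaphragm / leaf-row axis)
    field_y_extent: float = 220.0      # mm (leaf-travel axis)
    leaf_travel_axis: str = "Y"
    diaphragm_axis: str = "X"

    def __post_init__(self) -> None:
        n = self.field_x_extent / self.leaf_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"field_x_extent ({self.field_x_extent} mm) must be an exact "
                f"multiple of leaf_width ({self.leaf_width} mm)")
        if self.leaf_travel_axis == self.diaphragm_axis:
            raise ValueError("leaf travel and diaphragm axes must differ")

    @property
    def n_leaf_rows(self) -> int:
        return round(self.field_x_extent / self.leaf_width)

    @property
    def x_half(self) -> float:
        return self.field_x_extent / 2.0

    @property
    def y_half(self) -> float:
        return self.field_y_extent / 2.0

    # -- BEV raster geometry -------------------------------------------------

    def bev_row_centers(self, n_rows: int) -> np.ndarray:
        """Pixel-centre positions (mm, linac X) for an n-row BEV raster."""
        dx = self.field_x_extent / n_rows
        return (np.arange(n_rows) + 0.5) * dx - self.x_half

    def bev_col_centers(self, n_cols: int) -> np.ndarray:
        """Pixel-centre positions (mm, linac Y) for an n-col BEV raster."""
        dy = self.field_y_extent / n_cols
        return (np.arange(n_cols) + 0.5) * dy - self.y_half

    def leaf_index_of_rows(self, n_rows: int) -> np.ndarray:
        """Leaf-row index owning each image row of an n-row BEV raster."""
        xc = self.bev_row_centers(n_rows)
        idx = np.floor((xc + self.x_half) / self.leaf_width).astype(int)
        return np.clip(idx, 0, self.n_leaf_rows - 1)

    def leaf_boundaries(self) -> np.ndarray:
        """The n_leaf_rows + 1 leaf-row boundary positions along linac X."""
        return np.arange(self.n_leaf_rows + 1) * self.leaf_width - self.x_half


# ---------------------------------------------------------------------------
# Plan hierarchy
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    """One static MLC aperture with its monitor-unit weight.

    ``open_intervals`` has shape ``(n_leaf_rows, 2)``: per leaf row the
    (lower, upper) leaf-tip positions along the leaf-travel (linac Y) axis,
    in mm at isocenter.  ``lower == upper`` means the row is closed.
    """

    open_intervals: np.ndarray
    mu_weight: float

    def __post_init__(self) -> None:
        self.open_intervals = np.asarray(self.open_intervals, dtype=float)

    def validate(self, machine: MachineModel) -> None:
        iv = self.open_intervals
        if iv.shape != (machine.n_leaf_rows, 2):
            raise ValueError(
                f"open_intervals shape {iv.shape} != ({machine.n_leaf_rows}, 2)")
        if np.any(iv[:, 0] > iv[:, 1] + 1e-9):
            raise ValueError("lower leaf position exceeds upper")
        if np.any(iv < -machine.y_half - 1e-6) or np.any(iv > machine.y_half + 1e-6):
            raise ValueError("leaf positions outside the field-Y extent")
        if not np.any(iv[:, 1] - iv[:, 0] > 1e-9):
            raise ValueError("segment has no open leaf row (open plans only)")
        if not self.mu_weight > 0:
            raise ValueError("mu_weight must be positive")

    @property
    def open_rows(self) -> np.ndarray:
        return np.flatnonzero(self.open_intervals[:, 1]
                              - self.open_intervals[:, 0] > 1e-9)


@dataclass
class Beam:
    gantry_angle: float
    segments: list[Segment]
    isocenter: np.ndarray  # (3,) mm in the patient grid frame

    def __post_init__(self) -> None:
        self.isocenter = np.asarray(self.isocenter, dtype=float)
        if not 1 <= len(self.segments) <= 12:
            raise ValueError("a beam carries between 1 and 12 segments")

    @property
    def total_mu(self) -> float:
        return float(sum(s.mu_weight for s in self.segments))


@dataclass
class Plan:
    patient_id: str
    fraction_index: int
    beams: list[Beam]
    prescription: float = 3500.0  # cGy

    def __post_init__(self) -> None:
        angles = tuple(b.gantry_angle for b in self.beams)
        if angles != GANTRY_ANGLES:
            raise ValueError(
                f"plan beam angles {angles} must equal the fixed set "
                f"{GANTRY_ANGLES}")


# ---------------------------------------------------------------------------
# Grids, volumes, phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid3:
    """A regular 3D voxel grid: shape (nx, ny, nz), spacing and origin in mm.

    ``origin`` is the position of the centre of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be positive")
        if any(n <= 0 for n in self.shape):
            raise ValueError("grid shape must be positive")

    @property
    def center_index(self) -> np.ndarray:
        """The grid's rotation centre, in (fractional) voxel indices."""
        return (np.asarray(self.shape, dtype=float) - 1.0) / 2.0

    @property
    def center_mm(self) -> np.ndarray:
        return self.index_to_mm(self.center_index)

    def index_to_mm(self, idx) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx) * np.asarray(self.spacing)

    def mm_to_index(self, pos) -> np.ndarray:
        return (np.asarray(pos) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def contains_mm(self, pos) -> bool:
        idx = self.mm_to_index(pos)
        return bool(np.all(idx >= 0) and np.all(idx <= np.asarray(self.shape) - 1))

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]


@dataclass
class Dose3D:
    """A dose volume (cGy) on a regular grid."""

    values: np.ndarray
    grid: Grid3
    beam_ref: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError(
                f"dose shape {self.values.shape} != grid shape {self.grid.shape}")

    def copy_with(self, values: np.ndarray) -> "Dose3D":
        return Dose3D(values, self.grid, self.beam_ref)


@dataclass
class Phantom:
    """A voxelised patient stand-in: body, PTV and named OAR masks."""

    grid: Grid3
    body_mask: np.ndarray
    ptv_mask: np.ndarray
    oar_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, m in self.all_masks().items():
            if m.shape != tuple(self.grid.shape):
                raise ValueError(f"mask {name!r} shape mismatch")
        if np.any(self.ptv_mask & ~self.body_mask):
            raise ValueError("PTV must lie inside the body")

    def all_masks(self) -> dict[str, np.ndarray]:
        out = {"BODY": self.body_mask, "PTV": self.ptv_mask}
        out.update(self.oar_masks)
        return out

    def roi_masks(self) -> dict[str, np.ndarray]:
        """PTV plus OARs — the ROIs that enter DVH comparisons."""
        out = {"PTV": self.ptv_mask}
        out.update(self.oar_masks)
        return out

    @property
    def ptv_centroid_mm(self) -> np.ndarray:
        idx = np.argwhere(self.ptv_mask)
        if idx.size == 0:
            raise SimulationError("phantom has an empty PTV mask")
        return self.grid.index_to_mm(idx.mean(axis=0))


# ---------------------------------------------------------------------------
# Aperture rasterization (shared by the simulator, preprocessing and
# sequencing so that the round trip mask -> leaves -> mask is exact)
# ---------------------------------------------------------------------------

def aperture_mask(segment: Segment, machine: MachineModel,
                  shape: tuple[int, int] = (128, 128)) -> np.ndarray:
    """Rasterize a segment as a binary mask on the full-field BEV raster.

    A pixel is open iff its centre lies in the owning leaf row's open
    interval: ``lower <= y_centre < upper``.  Rows follow linac X, columns
    linac Y (see module docstring).
    """
    n_rows, n_cols = shape
    leaf_of_row = machine.leaf_index_of_rows(n_rows)
    yc = machine.bev_col_centers(n_cols)
    lower = segment.open_intervals[leaf_of_row, 0][:, None]
    upper = segment.open_intervals[leaf_of_row, 1][:, None]
    return (yc[None, :] >= lower) & (yc[None, :] < upper)


def rotate_volume_z(values: np.ndarray, angle_deg: float,
                    center_index: np.ndarray,
                    spacing: Sequence[float], order: int = 1) -> np.ndarray:
    """Rotate volume content by ``angle_deg`` (counter-clockwise in the x-y
    plane, right-handed about +z) about ``center_index``, zero fill.

    Handles anisotropic in-plane spacing by rotating in mm space.
    """
    from scipy import ndimage

    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    # content rotation by theta: output(p) = input(R(-theta) (p - c) + c)
    r = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])
    sp = np.diag(spacing)
    m = np.linalg.inv(sp) @ r @ sp
    center = np.asarray(center_index, dtype=float)
    offset = center - m @ center
    return ndimage.affine_transform(values, m, offset=offset, order=order,
                                    mode="grid-constant", cval=0.0, prefilter=False)
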