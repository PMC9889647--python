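"""Predicted aperture channels -> deliverable MLC control points.

Per channel: a 2% intensity threshold removes low-level noise, the MU
weight is read off the channel maximum (all surviving pixels are forced
to it), the mask is collapsed onto the 80 leaf rows, and each row's open
interval is the [first, last] nonzero extent along the leaf-travel axis
(interior holes are bridged — a single leaf pair cannot form two
openings).  Diaphragms close down to the bounding box of the open rows.
Empty channels are dropped; a beam losing all segments is an error, since
a replan must not silently lose a beam.

On binary ground-truth stacks this conversion is lossless: re-rasterizing
the emitted control points reproduces the masks bitwise and the MUs
exactly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (Beam, EmptySegmentError, MachineModel, Plan, Segment,
                   SequencingError)
from .preprocessing import ApertureStack

POSITION_QUANTUM_MM = 0.1  # emitted leaf/jaw positions are rounded to this


@dataclass
class SegmentControlPoint:
    """Machine state for one segment: 80 leaf pairs, X jaws, MU."""

    leaf_lower: np.ndarray   # (n_leaf_rows,) mm along linac Y
    leaf_upper: np.ndarray
    jaw_x: tuple[float, float]
    mu: float


@dataclass
class ControlPointSequence:
    """All control points of one beam plus its delivery bookkeeping."""

    gantry_angle: float
    segments: list[SegmentControlPoint]

    @property
    def total_mu(self) -> float:
        return float(sum(s.mu for s in self.segments))

    def cumulative_meterset(self) -> np.ndarray:
        """Cumulative fractional meterset after each segment (ends at 1)."""
        mus = np.array([s.mu for s in self.segments])
        return np.cumsum(mus) / mus.sum()


def threshold_channel(channel: np.ndarray,
                      threshold_fraction: float = 0.02,
                      reference_max: float | None = None) -> np.ndarray:
    """Zero out values below ``threshold_fraction`` of the reference
    intensity (the channel's own maximum by default).

    When sequencing a full prediction the reference is the *stack*
    maximum: a zero-padded channel that carries only low-level noise then
    empties completely and is dropped, instead of having its specks kept
    relative to their own tiny peak.
    """
    channel = np.asarray(channel, dtype=float)
    if np.any(channel < 0):
        raise SequencingError("channel contains negative intensities")
    peak = channel.max() if reference_max is None else reference_max
    out = channel.copy()
    out[out < threshold_fraction * peak] = 0.0
    return out


def assign_mu(channel: np.ndarray,
              mu_scale: float = 1.0) -> tuple[float, np.ndarray]:
    """MU from the channel maximum; every open pixel forced to it.

    Returns ``(mu_weight, binarized_channel)`` with the MU de-normalized
    by ``mu_scale``.  Raises :class:`EmptySegmentError` on an all-zero
    channel.
    """
    channel = np.asarray(channel, dtype=float)
    peak = float(channel.max(initial=0.0))
    if peak <= 0.0:
        raise EmptySegmentError("channel is empty after thresholding")
    forced = np.where(channel > 0, peak, 0.0)
    return peak * mu_scale, forced


def segment_to_leaves(binarized_channel: np.ndarray,
                      machine: MachineModel) -> SegmentControlPoint:
    """Leaf and jaw positions for one binarized channel.

    The channel's rows are grouped onto the 80 leaf rows; per leaf row the
    open interval spans from the leading edge of the first open pixel to
    the trailing edge of the last (pixel centres define openness, pixel
    edges define the leaf positions — this makes rasterize/extract a
    projection pair).  Closed rows park both leaves at the negative field
    edge.  Positions are quantised to 0.1 mm.
    """
    ch = np.asarray(binarized_channel, dtype=float)
    n_rows, n_cols = ch.shape
    leaf_of_row = machine.leaf_index_of_rows(n_rows)
    dy = machine.field_y_extent / n_cols
    yc = machine.bev_col_centers(n_cols)

    n = machine.n_leaf_rows
    park = -machine.y_half
    lower = np.full(n, park)
    upper = np.full(n, park)
    open_rows = []
    for leaf in range(n):
        rows = np.flatnonzero(leaf_of_row == leaf)
        if rows.size == 0:
            continue
        cols = np.flatnonzero(ch[rows].max(axis=0) > 0)
        if cols.size == 0:
            continue
        lo = yc[cols[0]] - dy / 2.0       # bridge interior holes
        up = yc[cols[-1]] + dy / 2.0
        lower[leaf] = round(lo / POSITION_QUANTUM_MM) * POSITION_QUANTUM_MM
        upper[leaf] = round(up / POSITION_QUANTUM_MM) * POSITION_QUANTUM_MM
        open_rows.append(leaf)
    if not open_rows:
        raise EmptySegmentError("channel vanished when collapsed onto the "
                                "leaf rows")
    bounds = machine.leaf_boundaries()
    jaw = (round(bounds[open_rows[0]] / POSITION_QUANTUM_MM)
           * POSITION_QUANTUM_MM,
           round(bounds[open_rows[-1] + 1] / POSITION_QUANTUM_MM)
           * POSITION_QUANTUM_MM)
    return SegmentControlPoint(leaf_lower=lower, leaf_upper=upper,
                               jaw_x=jaw, mu=np.nan)


def sequence_stack(stack: ApertureStack, machine: MachineModel,
                   threshold_fraction: float = 0.02) -> list[SegmentControlPoint]:
    """Threshold, weight and convert every channel of a predicted stack;
    empty channels are dropped."""
    out = []
    stack_max = float(stack.channels.max(initial=0.0))
    for c in range(stack.channels.shape[-1]):
        ch = threshold_channel(stack.channels[:, :, c], threshold_fraction,
                               reference_max=stack_max)
        try:
            mu, forced = assign_mu(ch, stack.mu_scale)
            cp = segment_to_leaves(forced, machine)
        except EmptySegmentError:
            continue
        cp.mu = mu
        out.append(cp)
    if not out:
        raise SequencingError(
            "no channel survived sequencing; a replanned beam cannot be "
            "empty")
    return out


def control_points_to_segment(cp: SegmentControlPoint,
                              machine: MachineModel) -> Segment:
    """A control point as a plan segment the dose engine can rasterize."""
    iv = np.stack([cp.leaf_lower, cp.leaf_upper], axis=1)
    return Segment(open_intervals=iv, mu_weight=cp.mu)


def sequence_plan(stacks: dict[int, ApertureStack], template_plan: Plan,
                  machine: MachineModel,
                  threshold_fraction: float = 0.02) -> Plan:
    """Build a deliverable replan: the template's beam angles and
    isocenters with each beam's segments replaced by the sequenced
    predicted stacks (keyed by beam index)."""
    if sorted(stacks) != list(range(len(template_plan.beams))):
        raise SequencingError(
            f"stacks for beams {sorted(stacks)} do not match the template's "
            f"{len(template_plan.beams)} beams")
    beams = []
    for bi, tbeam in enumerate(template_plan.beams):
        cps = sequence_stack(stacks[bi], machine, threshold_fraction)
        segments = [control_points_to_segment(cp, machine) for cp in cps]
        beams.append(Beam(gantry_angle=tbeam.gantry_angle, segments=segments,
                          isocenter=tbeam.isocenter.copy()))
    return Plan(patient_id=template_plan.patient_id,
                fraction_index=template_plan.fraction_index,
                beams=beams, prescription=template_plan.prescription)
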