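"""DICOM RTPlan / RTDose readers and writers.

Plans are written as step-and-shoot beams: one DICOM beam per gantry
angle with an ASYMX jaw pair and an MLCY leaf bank (80 pairs, leaves
travelling along the linac Y axis), two control points per segment
(beam-on, beam-off) carrying the cumulative meterset weight, and the
beam meterset in the fraction group.  Doses are written as GY-valued
RTDose grids (internal unit is cGy) with the usual integer scaling.

Array axis convention: internal volumes are indexed (x, y, z); the DICOM
pixel array is stored (frame=z, row=y, col=x).
"""
from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .core import (Beam, DicomIOError, Dose3D, Grid3, MachineModel, Plan,
                   Segment)

RTPLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"
RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
_QUANT = 0.1  # mm, positional quantum for leaf/jaw DS values


def _file_meta(sop_class: str, sop_instance: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def _base_dataset(sop_class: str, modality: str, patient_id: str) -> Dataset:
    ds = Dataset()
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = generate_uid()
    ds.Modality = modality
    ds.PatientID = patient_id
    ds.PatientName = patient_id
    now = datetime.datetime.now()
    ds.InstanceCreationDate = now.strftime("%Y%m%d")
    ds.InstanceCreationTime = now.strftime("%H%M%S")
    ds.Manufacturer = "leafseq"
    ds.file_meta = _file_meta(sop_class, ds.SOPInstanceUID)
    return ds


def _q(v: float) -> float:
    return round(round(v / _QUANT) * _QUANT, 4)


# ---------------------------------------------------------------------------
# RTPlan
# ---------------------------------------------------------------------------

def write_rtplan(plan: Plan, machine: MachineModel, path,
                 template: Dataset | None = None) -> None:
    """Serialize a plan; with ``template`` the existing dataset is
    overwritten beam-by-beam (MLC, jaws, metersets), preserving unrelated
    attributes."""
    if template is not None:
        ds = template
        if len(ds.BeamSequence) != len(plan.beams):
            raise DicomIOError(
                f"template has {len(ds.BeamSequence)} beams, plan has "
                f"{len(plan.beams)}")
        for tb, pb in zip(ds.BeamSequence, plan.beams):
            t_angle = float(tb.ControlPointSequence[0].GantryAngle)
            if abs(t_angle - pb.gantry_angle) > 1e-6:
                raise DicomIOError(
                    f"template gantry {t_angle} != plan {pb.gantry_angle}")
    else:
        ds = _base_dataset(RTPLAN_SOP_CLASS, "RTPLAN", plan.patient_id)
        ds.RTPlanLabel = f"{plan.patient_id}-fx{plan.fraction_index}"
        ds.RTPlanGeometry = "TREATMENT_DEVICE"

    ds.PatientID = plan.patient_id
    ds.RTPlanLabel = f"{plan.patient_id}-fx{plan.fraction_index}"
    ds.RTPlanName = f"fraction {plan.fraction_index}"
    ds.PrescriptionDescription = f"{plan.prescription:.1f} cGy"

    boundaries = [f"{b:.2f}" for b in machine.leaf_boundaries()]
    beam_seq = []
    ref_beam_seq = []
    for bi, beam in enumerate(plan.beams):
        b = Dataset()
        b.BeamNumber = bi + 1
        b.BeamName = f"B{bi:02d}"
        b.BeamType = "STATIC"
        b.RadiationType = "PHOTON"
        b.TreatmentDeliveryType = "TREATMENT"
        b.NumberOfWedges = 0
        b.NumberOfCompensators = 0
        b.NumberOfBoli = 0
        b.NumberOfBlocks = 0

        bld_seq = []
        jaws = Dataset()
        jaws.RTBeamLimitingDeviceType = "ASYMX"
        jaws.NumberOfLeafJawPairs = 1
        mlc = Dataset()
        mlc.RTBeamLimitingDeviceType = "MLCY"
        mlc.NumberOfLeafJawPairs = machine.n_leaf_rows
        mlc.LeafPositionBoundaries = boundaries
        bld_seq.extend([jaws, mlc])
        b.BeamLimitingDeviceSequence = bld_seq

        total_mu = beam.total_mu
        cps = []
        cum = 0.0
        for si, seg in enumerate(beam.segments):
            on = Dataset()
            on.ControlPointIndex = len(cps)
            on.CumulativeMetersetWeight = round(cum, 6)
            if si == 0:
                on.GantryAngle = beam.gantry_angle
                on.GantryRotationDirection = "NONE"
                on.IsocenterPosition = [f"{v:.3f}" for v in beam.isocenter]
                on.NominalBeamEnergy = 7.0
            pos_seq = []
            jp = Dataset()
            jp.RTBeamLimitingDeviceType = "ASYMX"
            open_rows = seg.open_rows
            bounds = machine.leaf_boundaries()
            jp.LeafJawPositions = [f"{_q(bounds[open_rows[0]]):.2f}",
                                   f"{_q(bounds[open_rows[-1] + 1]):.2f}"]
            mp = Dataset()
            mp.RTBeamLimitingDeviceType = "MLCY"
            mp.LeafJawPositions = (
                [f"{_q(v):.2f}" for v in seg.open_intervals[:, 0]]
                + [f"{_q(v):.2f}" for v in seg.open_intervals[:, 1]])
            pos_seq.extend([jp, mp])
            on.BeamLimitingDevicePositionSequence = pos_seq
            cps.append(on)

            cum += seg.mu_weight / total_mu
            off = Dataset()
            off.ControlPointIndex = len(cps)
            off.CumulativeMetersetWeight = round(min(cum, 1.0), 6)
            cps.append(off)
        cps[-1].CumulativeMetersetWeight = 1.0
        b.ControlPointSequence = cps
        b.NumberOfControlPoints = len(cps)
        b.FinalCumulativeMetersetWeight = 1.0
        beam_seq.append(b)

        rb = Dataset()
        rb.ReferencedBeamNumber = bi + 1
        rb.BeamMeterset = round(total_mu, 6)
        ref_beam_seq.append(rb)

    ds.BeamSequence = beam_seq
    fg = Dataset()
    fg.FractionGroupNumber = plan.fraction_index
    fg.NumberOfFractionsPlanned = 1
    fg.NumberOfBeams = len(plan.beams)
    fg.ReferencedBeamSequence = ref_beam_seq
    ds.FractionGroupSequence = [fg]

    ds.save_as(str(path), enforce_file_format=True)


def read_rtplan(path, machine: MachineModel | None = None) -> Plan:
    """Read a plan written by :func:`write_rtplan` (or a compatible
    step-and-shoot RTPlan with an MLCY bank)."""
    machine = machine or MachineModel()
    ds = _read_checked(path, "RTPLAN")
    label = str(getattr(ds, "RTPlanLabel", "P00-fx1"))
    patient_id = str(getattr(ds, "PatientID", label.split("-fx")[0]))
    try:
        fraction = int(label.rsplit("-fx", 1)[1])
    except (IndexError, ValueError):
        fraction = int(ds.FractionGroupSequence[0].FractionGroupNumber)

    metersets = {int(rb.ReferencedBeamNumber): float(rb.BeamMeterset)
                 for rb in ds.FractionGroupSequence[0].ReferencedBeamSequence}
    beams = []
    for b in ds.BeamSequence:
        cps = list(b.ControlPointSequence)
        first = cps[0]
        gantry = float(first.GantryAngle)
        iso = np.array([float(v) for v in first.IsocenterPosition])
        total_mu = metersets[int(b.BeamNumber)]
        segments = []
        for on, off in zip(cps[0::2], cps[1::2]):
            mlc = None
            for p in on.BeamLimitingDevicePositionSequence:
                if p.RTBeamLimitingDeviceType.startswith("MLC"):
                    mlc = np.array([float(v) for v in p.LeafJawPositions])
            if mlc is None:
                raise DicomIOError(
                    f"beam {b.BeamNumber}: control point without MLC "
                    "positions")
            n = mlc.size // 2
            iv = np.stack([mlc[:n], mlc[n:]], axis=1)
            w = (float(off.CumulativeMetersetWeight)
                 - float(on.CumulativeMetersetWeight))
            segments.append(Segment(open_intervals=iv,
                                    mu_weight=w * total_mu))
        beams.append(Beam(gantry_angle=gantry, segments=segments,
                          isocenter=iso))
    return Plan(patient_id=patient_id, fraction_index=fraction, beams=beams)


# ---------------------------------------------------------------------------
# RTDose
# ---------------------------------------------------------------------------

def write_rtdose(dose: Dose3D, path, patient_id: str = "P00",
                 dose_summation: str = "PLAN") -> None:
    """RTDose with 32-bit integer pixels and DoseGridScaling; values are
    stored in Gy (internal cGy / 100)."""
    ds = _base_dataset(RTDOSE_SOP_CLASS, "RTDOSE", patient_id)
    grid = dose.grid
    gy = dose.values / 100.0
    peak = float(gy.max())
    scaling = peak / (2 ** 31 - 1) if peak > 0 else 1.0
    ints = np.round(gy / scaling).astype(np.uint32) if peak > 0 else \
        np.zeros(gy.shape, dtype=np.uint32)

    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = dose_summation
    ds.DoseGridScaling = scaling
    if dose.beam_ref:
        ds.InstanceNumber = 1
        ds.SeriesDescription = dose.beam_ref

    nx, ny, nz = grid.shape
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.PixelSpacing = [f"{grid.spacing[1]:.6f}", f"{grid.spacing[0]:.6f}"]
    ds.GridFrameOffsetVector = [round(k * grid.spacing[2], 6)
                                for k in range(nz)]
    ds.ImagePositionPatient = [f"{v:.4f}" for v in grid.origin]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.PixelData = np.ascontiguousarray(ints.transpose(2, 1, 0)).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def read_rtdose(path) -> Dose3D:
    ds = _read_checked(path, "RTDOSE")
    nz = int(ds.NumberOfFrames)
    ny, nx = int(ds.Rows), int(ds.Columns)
    raw = np.frombuffer(ds.PixelData, dtype=np.uint32).reshape(nz, ny, nx)
    gy = raw.astype(float) * float(ds.DoseGridScaling)
    values = gy.transpose(2, 1, 0) * 100.0  # back to cGy
    offsets = [float(v) for v in ds.GridFrameOffsetVector]
    dz = offsets[1] - offsets[0] if nz > 1 else 1.0
    spacing = (float(ds.PixelSpacing[1]), float(ds.PixelSpacing[0]), dz)
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    grid = Grid3(shape=(nx, ny, nz), spacing=spacing, origin=origin)
    beam_ref = str(getattr(ds, "SeriesDescription", "")) or None
    return Dose3D(values=values, grid=grid, beam_ref=beam_ref)


def _read_checked(path, modality: str) -> Dataset:
    path = Path(path)
    if not path.exists():
        raise DicomIOError(f"no such file: {path}")
    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:  # InvalidDicomError and friends
        raise DicomIOError(f"{path} is not readable DICOM: {exc}") from exc
    if str(getattr(ds, "Modality", "")) != modality:
        raise DicomIOError(
            f"{path}: expected modality {modality}, found "
            f"{getattr(ds, 'Modality', 'none')}")
    return ds


# ---------------------------------------------------------------------------
# Phantom masks (compressed binary volumes + JSON sidecar)
# ---------------------------------------------------------------------------

def write_phantom(phantom, directory) -> None:
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    masks = phantom.all_masks()
    np.savez_compressed(directory / "masks.npz",
                        **{k: v.astype(np.uint8) for k, v in masks.items()})
    sidecar = {"grid": {"shape": list(phantom.grid.shape),
                        "spacing": list(phantom.grid.spacing),
                        "origin": list(phantom.grid.origin)},
               "rois": sorted(masks)}
    (directory / "masks.json").write_text(json.dumps(sidecar, indent=2))


def read_phantom(directory):
    import json

    from .core import Phantom

    directory = Path(directory)
    sidecar = json.loads((directory / "masks.json").read_text())
    data = np.load(directory / "masks.npz")
    grid = Grid3(shape=tuple(sidecar["grid"]["shape"]),
                 spacing=tuple(sidecar["grid"]["spacing"]),
                 origin=tuple(sidecar["grid"]["origin"]))
    masks = {k: data[k].astype(bool) for k in sidecar["rois"]}
    oars = {k: v for k, v in masks.items() if k not in ("BODY", "PTV")}
    return Phantom(grid=grid, body_mask=masks["BODY"],
                   ptv_mask=masks["PTV"], oar_masks=oars)
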