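"""DICOM discovery, parsing, subject/session/scan grouping, volume assembly,
and NIfTI-1 export.

The on-disk unit is the classic single-frame DICOM file.  A directory scan
yields one :class:`DicomEntity` per parseable file; entities are grouped by
Patient ID into subjects, by Study Instance UID into sessions, and by Series
Instance UID into scans.  A scan's slices are stacked into a 3D volume (or a
4D volume when slice positions repeat across timepoints) and can be written
out as NIfTI-1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pydicom
from pydicom.errors import InvalidDicomError

from .errors import NoDicomDataError, SpatialInconsistencyError

log = logging.getLogger(__name__)

__all__ = [
    "DicomEntity",
    "ScanSeries",
    "SessionGroup",
    "SubjectGroup",
    "VolumeStack",
    "scan_directory",
    "group_entities",
    "split_scans",
    "assemble_volume",
    "export_nifti",
]

# Tags consulted for grouping and geometry.
TAG_PATIENT_ID = (0x0010, 0x0020)
TAG_STUDY_UID = (0x0020, 0x000D)
TAG_SERIES_UID = (0x0020, 0x000E)
TAG_SERIES_DESCRIPTION = (0x0008, 0x103E)
TAG_B_VALUE = (0x0018, 0x9087)
TAG_GRADIENT_DIRECTION = (0x0018, 0x9089)


@dataclass
class DicomEntity:
    """One parsed DICOM file: header plus a handle on the pixel payload.

    The full :class:`pydicom.Dataset` is retained so de-identification can
    rewrite the file without losing attributes this module does not model.
    """

    filepath: Path
    dataset: pydicom.Dataset

    # -- header accessors -------------------------------------------------

    @property
    def patient_id(self) -> str:
        return str(self.dataset.get("PatientID", "") or "")

    @property
    def study_uid(self) -> str:
        return str(self.dataset.get("StudyInstanceUID", "") or "")

    @property
    def series_uid(self) -> str:
        return str(self.dataset.get("SeriesInstanceUID", "") or "")

    @property
    def instance_number(self) -> int:
        value = self.dataset.get("InstanceNumber", 0)
        return int(value) if value not in (None, "") else 0

    @property
    def series_description(self) -> str:
        return str(self.dataset.get("SeriesDescription", "") or "")

    @property
    def pixel_shape(self) -> tuple[int, int]:
        return int(self.dataset.Rows), int(self.dataset.Columns)

    @property
    def pixel_spacing(self) -> tuple[float, float]:
        dr, dc = self.dataset.PixelSpacing
        return float(dr), float(dc)

    @property
    def slice_position(self) -> np.ndarray:
        return np.asarray([float(v) for v in self.dataset.ImagePositionPatient])

    @property
    def orientation(self) -> np.ndarray:
        """Row and column direction cosines, shape (2, 3)."""
        iop = [float(v) for v in self.dataset.ImageOrientationPatient]
        return np.asarray(iop).reshape(2, 3)

    @property
    def slice_normal(self) -> np.ndarray:
        row, col = self.orientation
        return np.cross(row, col)

    @property
    def pixel_array(self) -> np.ndarray:
        return self.dataset.pixel_array

    def get_tag(self, tag: tuple[int, int]):
        """Value of a (group, element) tag, or None if absent."""
        element = self.dataset.get(tag)
        return None if element is None else element.value

    def has_tag(self, tag: tuple[int, int]) -> bool:
        return tag in self.dataset

    @property
    def tags(self) -> dict[tuple[int, int], object]:
        """Top-level header as a (group, element) -> value mapping
        (pixel data excluded)."""
        out = {}
        for element in self.dataset:
            tag = (element.tag.group, element.tag.element)
            if tag == (0x7FE0, 0x0010):
                continue
            out[tag] = element.value
        return out

    def save(self, path: Path | str) -> Path:
        path = Path(path)
        self.dataset.save_as(path, enforce_file_format=True)
        return path

    @classmethod
    def from_file(cls, path: Path | str) -> "DicomEntity":
        path = Path(path)
        dataset = pydicom.dcmread(path)
        return cls(filepath=path, dataset=dataset)


MODALITY_HINTS = ("structural", "timeseries", "diffusion", "unknown")


@dataclass
class ScanSeries:
    """Files of one Series Instance UID, i.e. one scan."""

    series_uid: str
    entities: list[DicomEntity]
    declared_type: str = ""

    def __post_init__(self):
        self.entities = sorted(
            self.entities, key=lambda e: (e.instance_number, str(e.filepath))
        )
        if not self.declared_type and self.entities:
            self.declared_type = self.entities[0].series_description

    @property
    def modality_hint(self) -> str:
        if any(e.has_tag(TAG_GRADIENT_DIRECTION) or e.has_tag(TAG_B_VALUE)
               for e in self.entities):
            return "diffusion"
        try:
            n_slices, n_timepoints = _slice_time_layout(self.entities)
        except SpatialInconsistencyError:
            return "unknown"
        return "timeseries" if n_timepoints > 1 else "structural"


@dataclass
class SessionGroup:
    study_uid: str
    patient_id: str
    scans: list[ScanSeries]

    @property
    def entities(self) -> list[DicomEntity]:
        return [e for scan in self.scans for e in scan.entities]


@dataclass
class SubjectGroup:
    patient_id: str
    sessions: list[SessionGroup]


@dataclass
class VolumeStack:
    """Assembled 3D or 4D intensity volume with voxel geometry."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")

    @property
    def n_timepoints(self) -> int:
        return 1 if self.data.ndim == 3 else int(self.data.shape[3])

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))


# ---------------------------------------------------------------------------
# Discovery and grouping
# ---------------------------------------------------------------------------

def scan_directory(
    root: Path | str, recursive: bool = True
) -> tuple[list[DicomEntity], int]:
    """Find and parse every DICOM file under ``root``.

    Non-DICOM files are tolerated: they are skipped and counted, mirroring a
    directory scan over mixed scanner exports.

    Returns (entities, n_skipped).  Raises :class:`NoDicomDataError` when no
    valid DICOM file is found, and FileNotFoundError when ``root`` is absent.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"not a readable directory: {root}")
    paths = sorted(p for p in (root.rglob("*") if recursive else root.iterdir())
                   if p.is_file())
    entities: list[DicomEntity] = []
    skipped = 0
    for path in paths:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dataset = pydicom.dcmread(path)
        except (InvalidDicomError, OSError, ValueError):
            skipped += 1
            continue
        entities.append(DicomEntity(filepath=path, dataset=dataset))
    if not entities:
        raise NoDicomDataError(f"no valid DICOM data found under {root}")
    return entities, skipped


def group_entities(entities: Iterable[DicomEntity]) -> list[SubjectGroup]:
    """Partition entities by Patient ID, then by Study Instance UID, then by
    Series Instance UID.

    Entities lacking a Patient ID or Study Instance UID are excluded with a
    logged warning.  Output ordering is lexicographic in the identifiers so
    grouping is invariant under permutation of the input.
    """
    by_subject: dict[str, dict[str, list[DicomEntity]]] = {}
    for entity in entities:
        if not entity.patient_id or not entity.study_uid:
            log.warning("excluding %s: missing PatientID or StudyInstanceUID",
                        entity.filepath)
            continue
        by_subject.setdefault(entity.patient_id, {}).setdefault(
            entity.study_uid, []).append(entity)

    subjects = []
    for patient_id in sorted(by_subject):
        sessions = []
        for study_uid in sorted(by_subject[patient_id]):
            members = by_subject[patient_id][study_uid]
            sessions.append(SessionGroup(
                study_uid=study_uid, patient_id=patient_id,
                scans=split_scans(members)))
        subjects.append(SubjectGroup(patient_id=patient_id, sessions=sessions))
    return subjects


def split_scans(entities: Sequence[DicomEntity]) -> list[ScanSeries]:
    """Split one session's files into scans on Series Instance UID."""
    by_series: dict[str, list[DicomEntity]] = {}
    for entity in entities:
        by_series.setdefault(entity.series_uid, []).append(entity)
    return [ScanSeries(series_uid=uid, entities=members)
            for uid, members in sorted(by_series.items())]


# ---------------------------------------------------------------------------
# Volume assembly
# ---------------------------------------------------------------------------

def _slice_time_layout(
    entities: Sequence[DicomEntity],
) -> tuple[int, int]:
    """(n_slices, n_timepoints) implied by repeating slice positions."""
    normal = entities[0].slice_normal
    projections = [round(float(np.dot(e.slice_position, normal)), 4)
                   for e in entities]
    unique = sorted(set(projections))
    n_slices = len(unique)
    if len(entities) % n_slices != 0:
        raise SpatialInconsistencyError(
            f"{len(entities)} files do not tile {n_slices} slice positions")
    n_timepoints = len(entities) // n_slices
    counts = {p: projections.count(p) for p in unique}
    if any(c != n_timepoints for c in counts.values()):
        raise SpatialInconsistencyError("uneven slice-position multiplicity")
    return n_slices, n_timepoints


def assemble_volume(scan: ScanSeries) -> VolumeStack:
    """Stack a scan's slices into a 3D volume, or 4D when slice positions
    repeat across timepoints.

    Slices are ordered by the projection of Image Position (Patient) onto the
    slice normal (cross product of the row/column direction cosines),
    ascending; within one slice position, Instance Number orders timepoints.
    """
    entities = scan.entities
    if not entities:
        raise SpatialInconsistencyError("empty scan")

    shape0, spacing0 = entities[0].pixel_shape, entities[0].pixel_spacing
    for entity in entities[1:]:
        if entity.pixel_shape != shape0 or entity.pixel_spacing != spacing0:
            raise SpatialInconsistencyError(
                f"{entity.filepath}: shape/spacing differs within series")

    normal = entities[0].slice_normal
    keyed = sorted(
        entities,
        key=lambda e: (round(float(np.dot(e.slice_position, normal)), 4),
                       e.instance_number, str(e.filepath)),
    )
    n_slices, n_timepoints = _slice_time_layout(entities)
    if n_timepoints == 1:
        projections = [round(float(np.dot(e.slice_position, normal)), 4)
                       for e in entities]
        if len(set(projections)) != len(projections):
            raise SpatialInconsistencyError(
                "duplicate slice positions within a single timepoint")

    rows, cols = shape0
    data = np.empty((rows, cols, n_slices, n_timepoints),
                    dtype=keyed[0].pixel_array.dtype)
    for slice_index in range(n_slices):
        group = keyed[slice_index * n_timepoints:(slice_index + 1) * n_timepoints]
        for time_index, entity in enumerate(group):
            data[:, :, slice_index, time_index] = entity.pixel_array
    if n_timepoints == 1:
        data = data[:, :, :, 0]

    dr, dc = spacing0
    if n_slices > 1:
        positions = sorted(float(np.dot(e.slice_position, normal))
                           for e in entities)
        slice_step = (positions[-1] - positions[0]) / (n_slices - 1)
    else:
        slice_step = float(entities[0].dataset.get("SliceThickness", 1.0) or 1.0)

    first = keyed[0]
    row_cos, col_cos = first.orientation
    affine = np.eye(4)
    affine[:3, 0] = col_cos * dr       # axis 0 walks down rows
    affine[:3, 1] = row_cos * dc       # axis 1 walks across columns
    affine[:3, 2] = normal * slice_step
    affine[:3, 3] = first.slice_position
    return VolumeStack(data=data, voxel_size=(dr, dc, abs(slice_step)),
                       affine=affine)


def export_nifti(volume: VolumeStack, out: Path | str) -> Path:
    """Write a volume as NIfTI-1; voxel data round-trips bit-identically for
    integer pixel types."""
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    image = nib.Nifti1Image(volume.data, volume.affine)
    image.header.set_data_dtype(volume.data.dtype)
    nib.save(image, out)
    return out
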