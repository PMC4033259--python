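"""Seeded generator of synthetic DICOM fixtures with ground truth.

Everything the toolkit consumes can be fabricated here: identifier-rich
DICOM headers (every attribute of the default protected profile),
multi-subject / multi-session directory trees, structural phantoms built
from nested ellipsoids with distinct tissue intensities on a noisy
background, 4D time-series phantoms with scheduled intensity spikes and
spatial shifts, and diffusion series with b-values and gradient directions
encoded in the standard DICOM attributes.

The generator is deterministic: a fixed seed reproduces the emitted tree
byte for byte (UIDs, dates and noise all derive from the seed, never from
the clock).  Alongside the files it returns a :class:`GroundTruth` carrying
the source arrays, region masks, subject/session assignment map, artifact
schedule and the log of injected identifying fields, which downstream tests
use as the oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import yaml
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.sequence import Sequence
from pydicom.uid import ExplicitVRLittleEndian

from .anonymize import PROTECTED_FIELDS

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "UidFactory",
    "generate",
    "make_structural_phantom",
    "make_timeseries_phantom",
    "make_diffusion_phantom",
    "SIX_DIRECTIONS",
]

MR_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.4"
UID_ROOT = "1.2.826.0.1.3680043.10.511"
IMPLEMENTATION_UID = UID_ROOT + ".0.1"

#: classic six-direction diffusion-encoding scheme (unit vectors)
_R = 1.0 / np.sqrt(2.0)
SIX_DIRECTIONS = (
    (_R, _R, 0.0), (_R, -_R, 0.0), (_R, 0.0, _R),
    (_R, 0.0, -_R), (0.0, _R, _R), (0.0, _R, -_R),
)

#: synthetic values for each protected field (tag -> (VR, value))
_PHI_VALUES: dict[tuple[int, int], tuple[str, object]] = {
    (0x0008, 0x0050): ("SH", "ACC123456"),
    (0x0008, 0x0080): ("LO", "General Hospital"),
    (0x0008, 0x0090): ("PN", "Smith^John"),
    (0x0008, 0x0096): ("SQ", None),
    (0x0008, 0x1048): ("PN", "Jones^Mary"),
    (0x0008, 0x1049): ("SQ", None),
    (0x0008, 0x1050): ("PN", "Who^Doctor"),
    (0x0008, 0x1052): ("SQ", None),
    (0x0008, 0x1060): ("PN", "Reader^Rita"),
    (0x0008, 0x1062): ("SQ", None),
    (0x0010, 0x0030): ("DA", "19700101"),
    (0x0010, 0x0050): ("SQ", None),
    (0x0010, 0x0101): ("SQ", None),
    (0x0010, 0x1000): ("LO", "ALT-ID-1"),
    (0x0010, 0x1001): ("PN", "Doe^Jane"),
    (0x0010, 0x1002): ("SQ", None),
    (0x0010, 0x1005): ("PN", "Maiden^Name"),
    (0x0010, 0x1010): ("AS", "040Y"),
    (0x0010, 0x1040): ("LO", "123 Main St Springfield"),
    (0x0010, 0x1060): ("PN", "Mother^Maiden"),
}


def _phi_sequence_item() -> Dataset:
    item = Dataset()
    item.CodeValue = "0000"
    item.CodingSchemeDesignator = "L"
    item.CodeMeaning = "synthetic identifying entry"
    return item


class UidFactory:
    """Deterministic DICOM UID source: a fixed root, the seed, a counter."""

    def __init__(self, seed: int):
        self.seed = int(seed)
        self.counter = 0

    def __call__(self) -> str:
        self.counter += 1
        return f"{UID_ROOT}.{self.seed}.{self.counter}"


@dataclass
class PhantomSpec:
    """Parameters of a synthetic acquisition tree.

    Defaults describe a small but segmentable structural phantom: a 64x64x48
    1 mm grid holding nested tissue ellipsoids (CSF 300, gray 600, white 900)
    inside a scalp shell, over a background of mean 50 and noise SD 10.
    """

    kind: str = "structural"                     # structural|timeseries|diffusion
    shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tissue_means: tuple[float, float, float] = (300.0, 600.0, 900.0)  # csf, gray, white
    scalp_mean: float = 450.0
    background_mean: float = 50.0
    noise_sd: float = 10.0
    brain_axes: tuple[float, float, float] = (20.0, 20.0, 16.0)
    head_margin: float = 2.0
    n_timepoints: int = 1
    signal_mean: float = 1000.0
    drift_amplitude: float = 0.0
    spikes: tuple[tuple[int, float], ...] = ()       # (timepoint, factor)
    shifts: tuple[tuple[int, tuple[int, int, int]], ...] = ()  # (timepoint, dvox)
    bvals: tuple[float, ...] = ()
    bvecs: tuple[tuple[float, float, float], ...] = ()
    n_subjects: int = 1
    sessions_per_subject: int = 1
    phi_fields: tuple[tuple[int, int], ...] = tuple(PROTECTED_FIELDS)
    series_description: str = ""
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("structural", "timeseries", "diffusion"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.kind == "timeseries" and self.n_timepoints < 2:
            raise ValueError("timeseries phantom needs n_timepoints >= 2")
        for t, _ in tuple(self.spikes) + tuple(self.shifts):
            if not 0 <= t < max(self.n_timepoints, 1):
                raise ValueError(f"artifact time {t} outside the series")
        if self.kind == "diffusion":
            if len(self.bvals) != len(self.bvecs) or not self.bvals:
                raise ValueError("diffusion phantom needs matching bvals/bvecs")
        unknown = set(self.phi_fields) - set(PROTECTED_FIELDS)
        if unknown:
            raise ValueError(f"unknown phi_fields: {sorted(unknown)}")
        if not self.series_description:
            self.series_description = {
                "structural": "MPRAGE", "timeseries": "BOLD_resting",
                "diffusion": "DWI_6dir"}[self.kind]

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PhantomSpec":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown spec keys: {sorted(unknown)}")
        for key in ("shape", "voxel_size", "tissue_means", "brain_axes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "spikes" in raw:
            raw["spikes"] = tuple((int(t), float(f)) for t, f in raw["spikes"])
        if "shifts" in raw:
            raw["shifts"] = tuple((int(t), tuple(int(d) for d in delta))
                                  for t, delta in raw["shifts"])
        if "bvals" in raw:
            raw["bvals"] = tuple(float(b) for b in raw["bvals"])
        if "bvecs" in raw:
            raw["bvecs"] = tuple(tuple(float(x) for x in v) for v in raw["bvecs"])
        if "phi_fields" in raw:
            raw["phi_fields"] = tuple(
                (int(g, 16), int(e, 16)) if isinstance(g, str) else (g, e)
                for g, e in (item.split(",") if isinstance(item, str) else item
                             for item in raw["phi_fields"]))
        return cls(**raw)


@dataclass
class GroundTruth:
    """Oracle data describing what the generator actually emitted."""

    assignment: dict[str, dict[str, list[str]]]  # patient -> study -> series
    source_arrays: dict[str, np.ndarray]         # series uid -> voxel array
    masks: dict[str, dict[str, np.ndarray]]      # series uid -> region masks
    artifact_log: dict[str, dict] = dataclass_field(default_factory=dict)
    phi_log: dict[str, list[str]] = dataclass_field(default_factory=dict)
    true_values: dict[str, dict] = dataclass_field(default_factory=dict)
    seed: int = 0

    @property
    def n_sessions(self) -> int:
        return sum(len(v) for v in self.assignment.values())


# ---------------------------------------------------------------------------
# Phantom arrays
# ---------------------------------------------------------------------------

def _ellipsoid(shape, center, axes) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    distance = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    return distance <= 1.0


def make_structural_phantom(spec: PhantomSpec, rng: np.random.Generator
                            ) -> tuple[np.ndarray, dict[str, np.ndarray], dict]:
    """Nested-ellipsoid structural phantom.

    Returns (uint16 volume, ground-truth masks, true intensity summary).
    The head ellipsoid exceeds the brain by ``head_margin`` voxels on every
    semi-axis; tissue shells are concentric at 0.5 and 0.75 of the brain
    semi-axes (white innermost, then gray, then CSF).
    """
    shape = spec.shape
    center = tuple((n - 1) / 2.0 for n in shape)
    brain = _ellipsoid(shape, center, spec.brain_axes)
    head = _ellipsoid(shape, center,
                      tuple(a + spec.head_margin for a in spec.brain_axes))
    mid = _ellipsoid(shape, center, tuple(0.75 * a for a in spec.brain_axes))
    inner = _ellipsoid(shape, center, tuple(0.5 * a for a in spec.brain_axes))
    white = inner
    gray = mid & ~inner
    csf = brain & ~mid

    csf_mean, gray_mean, white_mean = spec.tissue_means
    clean = np.full(shape, spec.background_mean, dtype=float)
    clean[head] = spec.scalp_mean
    clean[csf] = csf_mean
    clean[gray] = gray_mean
    clean[white] = white_mean

    noisy = clean + rng.normal(0.0, spec.noise_sd, size=shape)
    volume = np.clip(np.rint(noisy), 0, 65535).astype(np.uint16)

    masks = {"head": head, "brain": brain, "white": white, "gray": gray,
             "csf": csf, "exterior": ~head}
    truth = {
        "brain_mean": float(clean[brain].mean()),
        "noise_sd": float(spec.noise_sd),
        "snr": float(clean[brain].mean() / spec.noise_sd)
        if spec.noise_sd > 0 else float("inf"),
    }
    return volume, masks, truth


def make_timeseries_phantom(spec: PhantomSpec, rng: np.random.Generator
                            ) -> tuple[np.ndarray, dict[str, np.ndarray], dict]:
    """4D phantom: a signal ellipsoid over dark background, with optional
    linear drift, multiplicative spikes, and integer-voxel shifts applied
    from their scheduled timepoint onward."""
    shape = spec.shape
    center = tuple((n - 1) / 2.0 for n in shape)
    signal_mask = _ellipsoid(shape, center, spec.brain_axes)
    base = np.zeros(shape, dtype=float)
    base[signal_mask] = spec.signal_mean

    T = spec.n_timepoints
    drift = (np.linspace(-0.5, 0.5, T) * spec.drift_amplitude
             if spec.drift_amplitude else np.zeros(T))
    spike_factor = np.ones(T)
    for t, factor in spec.spikes:
        spike_factor[t] *= factor

    frames = np.empty(shape + (T,), dtype=float)
    for t in range(T):
        shift = np.zeros(3, dtype=int)
        for when, delta in spec.shifts:
            if t >= when:
                shift += np.asarray(delta, dtype=int)
        frame = np.roll(base, tuple(shift), axis=(0, 1, 2))
        frame = frame * spike_factor[t]
        frame[frame > 0] += drift[t]
        frames[..., t] = frame
    frames += rng.normal(0.0, spec.noise_sd, size=frames.shape)
    volume = np.clip(np.rint(frames), 0, 65535).astype(np.uint16)

    truth = {
        "signal_mean": spec.signal_mean,
        "noise_sd": spec.noise_sd,
        "tsnr": (spec.signal_mean / spec.noise_sd
                 if spec.noise_sd > 0 else float("inf")),
        "spikes": list(spec.spikes),
        "shifts": [[t, list(d)] for t, d in spec.shifts],
    }
    return volume, {"signal": signal_mask}, truth


def make_diffusion_phantom(spec: PhantomSpec, rng: np.random.Generator
                           ) -> tuple[np.ndarray, dict[str, np.ndarray], dict]:
    """One volume per gradient-table row: a sphere whose intensity is
    attenuated for diffusion-weighted rows (mono-exponential decay,
    D = 1e-3 mm^2/s)."""
    shape = spec.shape
    center = tuple((n - 1) / 2.0 for n in shape)
    sphere = _ellipsoid(shape, center, spec.brain_axes)
    n_volumes = len(spec.bvals)
    frames = np.empty(shape + (n_volumes,), dtype=float)
    for index, bval in enumerate(spec.bvals):
        frame = np.zeros(shape, dtype=float)
        b = float(bval) if bval is not None else 0.0
        frame[sphere] = spec.signal_mean * np.exp(-b * 1e-3)
        frames[..., index] = frame
    frames += rng.normal(0.0, spec.noise_sd, size=frames.shape)
    volume = np.clip(np.rint(frames), 0, 65535).astype(np.uint16)
    truth = {"bvals": list(spec.bvals),
             "bvecs": [list(v) if v is not None else None
                       for v in spec.bvecs]}
    return volume, {"signal": sphere}, truth


# ---------------------------------------------------------------------------
# DICOM emission
# ---------------------------------------------------------------------------

def _base_dataset(uid: UidFactory) -> Dataset:
    dataset = Dataset()
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = MR_IMAGE_STORAGE
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    meta.ImplementationClassUID = IMPLEMENTATION_UID
    dataset.file_meta = meta
    dataset.SOPClassUID = MR_IMAGE_STORAGE
    dataset.Modality = "MR"
    dataset.StudyDate = "20140101"
    dataset.StudyTime = "120000"
    return dataset


def _inject_phi(dataset: Dataset, phi_fields) -> list[str]:
    injected = []
    for tag in phi_fields:
        vr, value = _PHI_VALUES[tag]
        if vr == "SQ":
            dataset.add_new(tag, vr, Sequence([_phi_sequence_item()]))
        else:
            dataset.add_new(tag, vr, value)
        injected.append(f"{tag[0]:04X},{tag[1]:04X}")
    return injected


def write_series(out_dir: Path, array: np.ndarray, *, patient_id: str,
                 study_uid: str, series_uid: str, series_description: str,
                 voxel_size: tuple[float, float, float], uid: UidFactory,
                 phi_fields=(), bvals=None, bvecs=None,
                 phi_log: dict | None = None,
                 phi_log_root: Path | None = None) -> list[Path]:
    """Write a 3D or 4D array as classic single-frame DICOM slices.

    Instance numbering is volume-major: all slices of timepoint 0, then
    timepoint 1, and so on.  For diffusion series, each volume's slices
    carry the b-value (0018,9087) and gradient direction (0018,9089)
    attributes, except where ``bvals[t]`` is None (used to fabricate
    incomplete tables).
    """
    out_dir.mkdir(parents=True, exist_ok=True)
    if array.ndim == 3:
        array = array[..., None]
    rows, cols, n_slices, n_volumes = array.shape
    dr, dc, dz = voxel_size
    paths = []
    for t in range(n_volumes):
        for k in range(n_slices):
            dataset = _base_dataset(uid)
            dataset.SOPInstanceUID = uid()
            dataset.file_meta.MediaStorageSOPInstanceUID = dataset.SOPInstanceUID
            dataset.PatientID = patient_id
            dataset.PatientName = patient_id
            dataset.StudyInstanceUID = study_uid
            dataset.SeriesInstanceUID = series_uid
            dataset.SeriesDescription = series_description
            dataset.InstanceNumber = t * n_slices + k + 1
            dataset.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
            dataset.ImagePositionPatient = [0.0, 0.0, float(k) * dz]
            dataset.PixelSpacing = [dr, dc]
            dataset.SliceThickness = dz
            dataset.Rows = rows
            dataset.Columns = cols
            dataset.SamplesPerPixel = 1
            dataset.PhotometricInterpretation = "MONOCHROME2"
            dataset.BitsAllocated = 16
            dataset.BitsStored = 16
            dataset.HighBit = 15
            dataset.PixelRepresentation = 0
            dataset.PixelData = np.ascontiguousarray(
                array[:, :, k, t], dtype=np.uint16).tobytes()
            if bvals is not None and bvals[t] is not None:
                dataset.add_new((0x0018, 0x9087), "FD", float(bvals[t]))
            if bvecs is not None and bvecs[t] is not None:
                dataset.add_new((0x0018, 0x9089), "FD",
                                [float(x) for x in bvecs[t]])
            injected = _inject_phi(dataset, phi_fields)
            path = out_dir / f"{series_description}_{t * n_slices + k + 1:04d}.dcm"
            dataset.save_as(path, enforce_file_format=True)
            if phi_log is not None:
                key = (str(path.relative_to(phi_log_root))
                       if phi_log_root else str(path))
                phi_log[key] = injected
            paths.append(path)
    return paths


def generate(spec: PhantomSpec, out: Path | str) -> tuple[list[Path], GroundTruth]:
    """Emit the DICOM tree described by ``spec`` under ``out``.

    Layout: ``out/<patient_id>/<session_dir>/<slice files>``, one scan per
    session.  Alongside the tree a ``ground_truth.json`` sidecar records the
    assignment map, artifact schedule, injected identifying fields, and the
    seed; voxel-level truth (arrays, masks) lives on the returned object.
    """
    out = Path(out)
    rng = np.random.default_rng(spec.seed)
    uid = UidFactory(spec.seed)
    maker = {"structural": make_structural_phantom,
             "timeseries": make_timeseries_phantom,
             "diffusion": make_diffusion_phantom}[spec.kind]

    truth = GroundTruth(assignment={}, source_arrays={}, masks={},
                        seed=spec.seed)
    paths: list[Path] = []
    for subject_index in range(spec.n_subjects):
        patient_id = f"PAT{subject_index + 1:03d}"
        truth.assignment[patient_id] = {}
        for session_index in range(spec.sessions_per_subject):
            study_uid = uid()
            series_uid = uid()
            truth.assignment[patient_id][study_uid] = [series_uid]
            array, masks, values = maker(spec, rng)
            truth.source_arrays[series_uid] = array
            truth.masks[series_uid] = masks
            truth.true_values[series_uid] = values
            if spec.kind in ("timeseries",):
                truth.artifact_log[series_uid] = {
                    "spikes": list(spec.spikes),
                    "shifts": [[t, list(d)] for t, d in spec.shifts]}
            session_dir = out / patient_id / f"ses{session_index + 1:02d}"
            bvals = list(spec.bvals) if spec.kind == "diffusion" else None
            bvecs = list(spec.bvecs) if spec.kind == "diffusion" else None
            paths.extend(write_series(
                session_dir, array, patient_id=patient_id,
                study_uid=study_uid, series_uid=series_uid,
                series_description=spec.series_description,
                voxel_size=spec.voxel_size, uid=uid,
                phi_fields=spec.phi_fields, bvals=bvals, bvecs=bvecs,
                phi_log=truth.phi_log, phi_log_root=out))

    sidecar = {
        "seed": spec.seed,
        "kind": spec.kind,
        "assignment": truth.assignment,
        "artifact_log": truth.artifact_log,
        "phi_log": truth.phi_log,
        "true_values": truth.true_values,
    }
    with open(out / "ground_truth.json", "w") as handle:
        json.dump(sidecar, handle, indent=2, sort_keys=True)
    return paths, truth
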