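"""Local archive emulating the server-side workflow: ingest with
anonymization and label checks, a project/subject/session/scan hierarchy on
disk, QA dispatch, sharing policy, and report generation.

Layout::

    <root>/
      index.json                  # records, projects, users
      reports/                    # rejection + QA reports
      <project>/<subject>/<session>/<scan>/
          dicom/   *.dcm          # archived (anonymized) slices
          nifti/   scan.nii.gz
          qa/      *.json, report.md

Ingest is atomic: every check (annotation, anonymization sweep, label
validation) runs before any byte is written, and file placement goes
through a staging directory, so a rejected upload leaves the archive
exactly as it was.  Rejections are written as report files in ``reports/``,
standing in for the notification e-mail a hosted service would send.

Permissions follow the project-level model: the first user to create a
project owns it, and only the owner can change its sharing policy or remove
it.
"""

from __future__ import annotations

import json
import shutil
import traceback
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import qa_diffusion, qa_struct, qa_timeseries
from .anonymize import (AnonymizationProfile, ShareAnnotation, default_profile,
                        read_annotation, verify_anonymization)
from .dicom_io import (DicomEntity, assemble_volume, export_nifti,
                       scan_directory, split_scans)
from .errors import (AnnotationError, NotApplicableError, PermissionDeniedError,
                     SpatialInconsistencyError)
from .identifiers import DEFAULT_RULE, IdentifierRule

__all__ = ["Archive", "ArchiveRecord", "IngestResult"]

STRUCTURAL_TYPE = "MPRAGE"   # declared scan type that gates structural QA


@dataclass
class ArchiveRecord:
    project: str
    subject_label: str
    session_label: str
    scan_id: str
    owner: str
    shared: bool = True
    qa_status: str = "pending"          # pending | done | failed
    declared_type: str = ""
    paths: dict = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.project, self.subject_label, self.session_label,
                self.scan_id)


@dataclass
class IngestResult:
    accepted: bool
    records: list[ArchiveRecord] = field(default_factory=list)
    reasons: list[str] = field(default_factory=list)
    report_path: Path | None = None


class Archive:
    """Filesystem-backed archive with a JSON index."""

    def __init__(self, root: Path | str, rule: IdentifierRule = DEFAULT_RULE,
                 open_registration: bool = True):
        self.root = Path(root)
        self.rule = rule
        self.open_registration = open_registration
        self.root.mkdir(parents=True, exist_ok=True)
        (self.root / "reports").mkdir(exist_ok=True)
        self._index_path = self.root / "index.json"
        if self._index_path.exists():
            raw = json.loads(self._index_path.read_text())
            self.records = [ArchiveRecord(**r) for r in raw["records"]]
            self.projects = raw["projects"]      # name -> {owner, shared}
            self.users = set(raw["users"])
        else:
            self.records: list[ArchiveRecord] = []
            self.projects: dict[str, dict] = {}
            self.users: set[str] = set()
            self._save()

    # -- persistence ------------------------------------------------------

    def _save(self) -> None:
        payload = {"records": [asdict(r) for r in self.records],
                   "projects": self.projects,
                   "users": sorted(self.users)}
        self._index_path.write_text(json.dumps(payload, indent=2))

    def add_user(self, name: str) -> None:
        self.users.add(name)
        self._save()

    def find(self, project=None, subject=None, session=None, scan=None
             ) -> list[ArchiveRecord]:
        out = []
        for record in self.records:
            if project is not None and record.project != project:
                continue
            if subject is not None and record.subject_label != subject:
                continue
            if session is not None and record.session_label != session:
                continue
            if scan is not None and record.scan_id != scan:
                continue
            out.append(record)
        return out

    # -- validation -------------------------------------------------------

    def validate_labels(self, note: ShareAnnotation) -> list[str]:
        """Issues that would block an ingest; an empty list means acceptable."""
        issues = []
        if not note.project:
            issues.append("no project given")
        for name, value in (("project", note.project),
                            ("subject", note.subject_label),
                            ("session", note.session_label),
                            ("user", note.user)):
            if value:
                explanation = self.rule.explain(value)
                if explanation is not None:
                    issues.append(f"invalid {name} identifier {value!r}: "
                                  f"{explanation}")
        if note.project in self.projects:
            owner = self.projects[note.project]["owner"]
            if owner != note.user:
                issues.append(f"project {note.project!r} is owned by "
                              f"another user ({owner})")
        if self.find(project=note.project, subject=note.subject_label,
                     session=note.session_label):
            issues.append(f"session already exists: {note.project}/"
                          f"{note.subject_label}/{note.session_label}")
        return issues

    # -- ingest -----------------------------------------------------------

    def _write_rejection(self, reasons: list[str], note=None) -> Path:
        number = 1 + len(list((self.root / "reports").glob("rejection_*.json")))
        path = self.root / "reports" / f"rejection_{number:04d}.json"
        payload = {"rejected": True, "reasons": reasons}
        if note is not None:
            payload["annotation"] = asdict(note)
        path.write_text(json.dumps(payload, indent=2))
        return path

    def ingest(self, entities: list[DicomEntity],
               profile: AnonymizationProfile | None = None) -> IngestResult:
        """Receive one session's worth of anonymized, annotated files.

        Runs the anonymization sweep and the label checks before writing
        anything; any violation rejects the entire session and produces a
        rejection report.  On success each scan (Series Instance UID) gets a
        record with QA pending, archived DICOM, and a NIfTI export.
        """
        profile = profile or default_profile()

        # annotation must be present, parseable, and consistent
        notes = set()
        for entity in entities:
            try:
                notes.add(read_annotation(entity))
            except AnnotationError as error:
                report = self._write_rejection(
                    [f"invalid annotation: {error}"])
                return IngestResult(False, reasons=["invalid annotation"],
                                    report_path=report)
        if len(notes) != 1:
            report = self._write_rejection(
                ["inconsistent annotations across files"])
            return IngestResult(False, reasons=["inconsistent annotation"],
                                report_path=report)
        note = notes.pop()

        if note.user not in self.users and not (
                self.open_registration and self.rule.is_valid(note.user)):
            report = self._write_rejection(
                [f"unknown user {note.user!r}"], note)
            return IngestResult(False, reasons=["unknown user"],
                                report_path=report)

        audit = verify_anonymization(entities, profile)
        if not audit.clean:
            reasons = [
                f"protected field present: {name} "
                f"({tag[0]:04X},{tag[1]:04X}) in {Path(filepath).name}"
                for filepath, tag, name in audit.violations]
            report = self._write_rejection(reasons, note)
            return IngestResult(False, reasons=reasons, report_path=report)

        issues = self.validate_labels(note)
        if issues:
            report = self._write_rejection(issues, note)
            return IngestResult(False, reasons=issues, report_path=report)

        # all checks passed: stage, then move into place
        staging = self.root / ".staging"
        if staging.exists():
            shutil.rmtree(staging)
        session_staging = staging / note.session_label
        records = []
        try:
            for index, scan in enumerate(split_scans(entities)):
                scan_id = f"scan{index + 1:02d}"
                scan_dir = session_staging / scan_id
                dicom_dir = scan_dir / "dicom"
                dicom_dir.mkdir(parents=True)
                for entity in scan.entities:
                    entity.save(dicom_dir / Path(entity.filepath).name)
                nifti_path = None
                try:
                    volume = assemble_volume(scan)
                    nifti_path = export_nifti(volume,
                                              scan_dir / "nifti" / "scan.nii.gz")
                except SpatialInconsistencyError:
                    pass    # archived anyway; diffusion QA will flag it
                (scan_dir / "qa").mkdir(exist_ok=True)
                records.append(ArchiveRecord(
                    project=note.project, subject_label=note.subject_label,
                    session_label=note.session_label, scan_id=scan_id,
                    owner=note.user, declared_type=scan.declared_type,
                    shared=self.projects.get(note.project,
                                             {"shared": True})["shared"]
                    if note.project in self.projects else True,
                    paths={"dicom": str(dicom_dir),
                           "nifti": str(nifti_path) if nifti_path else None,
                           "qa": str(scan_dir / "qa")}))
            final_session = (self.root / note.project / note.subject_label /
                             note.session_label)
            final_session.parent.mkdir(parents=True, exist_ok=True)
            shutil.move(str(session_staging), str(final_session))
        finally:
            if staging.exists():
                shutil.rmtree(staging)

        # rewrite staged paths to their final location
        for record in records:
            for key, value in record.paths.items():
                if value is not None:
                    record.paths[key] = value.replace(
                        str(session_staging), str(final_session))

        self.users.add(note.user)
        if note.project not in self.projects:
            self.projects[note.project] = {"owner": note.user, "shared": True}
        self.records.extend(records)
        self._save()
        return IngestResult(True, records=records)

    # -- QA dispatch ------------------------------------------------------

    def dispatch_qa(self, record: ArchiveRecord) -> dict:
        """Run every applicable QA procedure for one archived scan.

        Structural QA runs only when the declared scan type is MPRAGE
        (case-insensitive).  Time-series and diffusion QA are attempted for
        every scan and report ``not_applicable`` when the prerequisites are
        unmet (a single timepoint; no gradient encoding).  Results are
        written as JSON under the scan's qa/ directory.
        """
        qa_dir = Path(record.paths["qa"])
        results: dict[str, dict] = {}
        try:
            entities, _ = scan_directory(Path(record.paths["dicom"]))
            scan = split_scans(entities)[0]
            volume = None
            assembly_error = None
            try:
                volume = assemble_volume(scan)
            except SpatialInconsistencyError as error:
                assembly_error = str(error)

            if record.declared_type.upper() == STRUCTURAL_TYPE:
                if volume is not None and volume.data.ndim == 3:
                    results["structural"] = qa_struct.run_structural_qa(
                        volume).as_dict()
                else:
                    results["structural"] = {
                        "status": "not_applicable",
                        "reason": assembly_error or "not a 3D volume"}

            if volume is not None:
                try:
                    results["timeseries"] = qa_timeseries.run_timeseries_qa(
                        volume).as_dict()
                except NotApplicableError as error:
                    results["timeseries"] = {"status": "not_applicable",
                                             "reason": str(error)}
            else:
                results["timeseries"] = {"status": "not_applicable",
                                         "reason": assembly_error}

            table = qa_diffusion.extract_gradients(scan)
            if table is None:
                results["diffusion"] = {
                    "status": "not_applicable",
                    "reason": "no diffusion gradient information"}
            else:
                diffusion = qa_diffusion.run_checks(volume, table)
                results["diffusion"] = diffusion.as_dict()
                qa_diffusion.write_xml_report(diffusion,
                                              qa_dir / "diffusion.xml")

            for name, payload in results.items():
                (qa_dir / f"{name}.json").write_text(
                    json.dumps(payload, indent=2))
            record.qa_status = "done"
        except Exception:
            record.qa_status = "failed"
            (qa_dir / "error.log").write_text(traceback.format_exc())
        self._save()
        return results

    # -- sharing ----------------------------------------------------------

    def _require_owner(self, project: str, acting_user: str) -> None:
        if project not in self.projects:
            raise KeyError(f"unknown project {project!r}")
        if self.projects[project]["owner"] != acting_user:
            raise PermissionDeniedError(
                f"{acting_user!r} does not own project {project!r}")

    def set_sharing(self, project: str, shared: bool,
                    acting_user: str) -> list[ArchiveRecord]:
        """Flip the sharing flag for every record of a project (project-level
        permission model)."""
        self._require_owner(project, acting_user)
        self.projects[project]["shared"] = bool(shared)
        changed = []
        for record in self.records:
            if record.project == project:
                record.shared = bool(shared)
                changed.append(record)
        self._save()
        return changed

    def remove_project(self, project: str, acting_user: str) -> int:
        """Remove a project and all its data from the archive completely."""
        self._require_owner(project, acting_user)
        removed = [r for r in self.records if r.project == project]
        self.records = [r for r in self.records if r.project != project]
        del self.projects[project]
        project_dir = self.root / project
        if project_dir.exists():
            shutil.rmtree(project_dir)
        self._save()
        return len(removed)

    # -- reporting --------------------------------------------------------

    def _metric_of(self, record: ArchiveRecord) -> tuple[str, float] | None:
        qa_dir = Path(record.paths["qa"])
        structural = qa_dir / "structural.json"
        if structural.exists():
            payload = json.loads(structural.read_text())
            if payload.get("snr") is not None:
                return "snr", float(payload["snr"])
        timeseries = qa_dir / "timeseries.json"
        if timeseries.exists():
            payload = json.loads(timeseries.read_text())
            if "mean_sfnr" in payload and payload["mean_sfnr"] is not None:
                return "sfnr", float(payload["mean_sfnr"])
        return None

    def build_report(self, record: ArchiveRecord,
                     reference: list[float] | None = None,
                     bins: int = 10) -> Path:
        """Write a QA report (Markdown + JSON) for an archived scan.

        The scan's SNR (structural) or SFNR (time series) is shown against a
        histogram of a reference distribution — by default the same metric
        over the archive's own holdings; a caller may supply reference
        values from an external population instead.
        """
        if record.qa_status != "done":
            raise ValueError("QA has not completed for this record")
        qa_dir = Path(record.paths["qa"])
        metric = self._metric_of(record)
        lines = [f"# QA report — {'/'.join(record.key)}", ""]
        payload: dict = {"record": asdict(record)}

        for name in ("structural", "timeseries", "diffusion"):
            result_path = qa_dir / f"{name}.json"
            if result_path.exists():
                payload[name] = json.loads(result_path.read_text())
                lines.append(f"## {name}")
                lines.append("```json")
                lines.append(json.dumps(payload[name], indent=2))
                lines.append("```")
                lines.append("")

        if metric is not None:
            metric_name, value = metric
            if reference is None:
                reference = [m[1] for r in self.records
                             if r.qa_status == "done"
                             and (m := self._metric_of(r)) is not None
                             and m[0] == metric_name]
            if reference:
                counts, edges = np.histogram(np.asarray(reference, dtype=float),
                                             bins=bins)
                payload["histogram"] = {
                    "metric": metric_name, "value": value,
                    "counts": [int(c) for c in counts],
                    "bin_edges": [float(e) for e in edges],
                    "n_reference": int(len(reference)),
                }
                lines.append(f"## {metric_name.upper()} vs reference "
                             f"(n={len(reference)})")
                peak = max(counts.max(), 1)
                for count, lo, hi in zip(counts, edges[:-1], edges[1:]):
                    bar = "#" * int(round(20 * count / peak))
                    marker = "  <-- this scan" if lo <= value < hi or (
                        hi == edges[-1] and value == hi) else ""
                    lines.append(f"    {lo:10.2f}–{hi:10.2f} | "
                                 f"{bar:<20} {count}{marker}")
                lines.append("")
            else:
                lines.append("_No reference distribution available; "
                             "histogram omitted._")
                payload["histogram"] = None

        report_md = qa_dir / "report.md"
        report_md.write_text("\n".join(lines))
        (qa_dir / "report.json").write_text(json.dumps(payload, indent=2))
        return report_md
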