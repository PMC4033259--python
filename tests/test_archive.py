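"""Archive workflow: label validation, atomic ingest, QA dispatch gating,
sharing policy, reports."""

import json
from pathlib import Path

import pytest

from scanshare.anonymize import (PROTECTED_FIELDS, ShareAnnotation, annotate,
                                 apply_profile)
from scanshare.archive import Archive
from scanshare.dicom_io import scan_directory
from scanshare.errors import PermissionDeniedError
from scanshare.synthgen import SIX_DIRECTIONS, PhantomSpec, generate

NOTE = ShareAnnotation(user="alice", project="P1", subject_label="S01",
                       session_label="E01")


def prepared_session(tree_root, note=NOTE):
    """Anonymized + annotated entities of the first session in a tree."""
    entities, _ = scan_directory(tree_root)
    session = {}
    for entity in entities:
        session.setdefault((entity.patient_id, entity.study_uid),
                           []).append(entity)
    first = session[sorted(session)[0]]
    return [annotate(apply_profile(e), note) for e in first]


def tree_snapshot(root):
    return {str(p.relative_to(root)): p.read_bytes()
            for p in sorted(Path(root).rglob("*")) if p.is_file()}


@pytest.fixture()
def small_tree(tmp_path):
    spec = PhantomSpec(kind="structural", shape=(16, 16, 8),
                       brain_axes=(5, 5, 3), seed=50)
    generate(spec, tmp_path / "tree")
    return tmp_path / "tree"


class TestValidateLabels:
    def test_fresh_archive_valid_labels_ok(self, tmp_path):
        archive = Archive(tmp_path / "arch")
        assert archive.validate_labels(NOTE) == []

    def test_empty_project_reported(self, tmp_path):
        archive = Archive(tmp_path / "arch")
        note = ShareAnnotation(user="alice", project="",
                               subject_label="S01", session_label="E01")
        issues = archive.validate_labels(note)
        assert any("no project given" in issue for issue in issues)

    def test_invalid_characters_reported(self, tmp_path):
        archive = Archive(tmp_path / "arch")
        note = ShareAnnotation(user="alice", project="P 1",
                               subject_label="S01", session_label="E01")
        issues = archive.validate_labels(note)
        assert any("invalid" in issue for issue in issues)

    def test_session_collision_reported(self, tmp_path, small_tree):
        archive = Archive(tmp_path / "arch")
        assert archive.ingest(prepared_session(small_tree)).accepted
        issues = archive.validate_labels(NOTE)
        assert any("already exists" in issue for issue in issues)

    def test_foreign_project_reported(self, tmp_path, small_tree):
        archive = Archive(tmp_path / "arch")
        assert archive.ingest(prepared_session(small_tree)).accepted
        note = ShareAnnotation(user="mallory", project="P1",
                               subject_label="S09", session_label="E01")
        issues = archive.validate_labels(note)
        assert any("owned by another user" in issue for issue in issues)


class TestIngest:
    def test_clean_session_archived_with_pending_qa(self, tmp_path,
                                                    small_tree):
        archive = Archive(tmp_path / "arch")
        result = archive.ingest(prepared_session(small_tree))
        assert result.accepted
        assert len(result.records) == 1
        record = result.records[0]
        assert record.qa_status == "pending"
        assert record.key == ("P1", "S01", "E01", "scan01")
        scan_dir = tmp_path / "arch" / "P1" / "S01" / "E01" / "scan01"
        assert (scan_dir / "nifti" / "scan.nii.gz").exists()
        assert list((scan_dir / "dicom").glob("*.dcm"))

    def test_retained_protected_field_rejects_whole_session(self, tmp_path,
                                                            small_tree):
        archive = Archive(tmp_path / "arch")
        before = tree_snapshot(archive.root)
        entities = prepared_session(small_tree)
        entities[2].dataset.add_new((0x0010, 0x1010), "AS", "040Y")
        result = archive.ingest(entities)
        assert not result.accepted
        # atomic: archive byte-identical except the rejection report
        after = tree_snapshot(archive.root)
        new_files = set(after) - set(before)
        assert all(name.startswith("reports/") for name in new_files)
        assert {k: v for k, v in after.items() if k not in new_files} == before
        # report names the offending file and tag
        report = json.loads(result.report_path.read_text())
        assert report["rejected"]
        assert any("Patient's Age" in reason and
                   Path(entities[2].filepath).name in reason
                   for reason in report["reasons"])

    def test_missing_annotation_rejected(self, tmp_path, small_tree):
        archive = Archive(tmp_path / "arch")
        entities, _ = scan_directory(small_tree)
        cleaned = [apply_profile(e) for e in entities]
        result = archive.ingest(cleaned)
        assert not result.accepted
        assert result.reasons == ["invalid annotation"]

    def test_unknown_user_rejected_when_registration_closed(self, tmp_path,
                                                            small_tree):
        archive = Archive(tmp_path / "arch", open_registration=False)
        result = archive.ingest(prepared_session(small_tree))
        assert not result.accepted
        assert result.reasons == ["unknown user"]

    def test_no_archived_file_retains_protected_tags(self, tmp_path,
                                                     small_tree):
        archive = Archive(tmp_path / "arch")
        archive.ingest(prepared_session(small_tree))
        archived, _ = scan_directory(archive.root / "P1")
        for entity in archived:
            assert not any(entity.has_tag(tag) for tag in PROTECTED_FIELDS)


class TestQaDispatch:
    def _ingest(self, tmp_path, spec, note=NOTE):
        generate(spec, tmp_path / "data")
        archive = Archive(tmp_path / "arch")
        result = archive.ingest(prepared_session(tmp_path / "data", note))
        assert result.accepted
        return archive, result.records[0]

    def test_mprage_runs_structural_only(self, tmp_path):
        spec = PhantomSpec(kind="structural", shape=(24, 24, 18),
                           brain_axes=(8, 8, 6), seed=60)
        archive, record = self._ingest(tmp_path, spec)
        results = archive.dispatch_qa(record)
        assert record.qa_status == "done"
        assert "snr" in results["structural"]
        assert results["timeseries"]["status"] == "not_applicable"
        assert results["diffusion"]["status"] == "not_applicable"
        qa_dir = Path(record.paths["qa"])
        assert (qa_dir / "structural.json").exists()

    def test_bold_runs_timeseries_not_structural(self, tmp_path):
        spec = PhantomSpec(kind="timeseries", shape=(16, 16, 8),
                           brain_axes=(5, 5, 3), n_timepoints=8, seed=61)
        archive, record = self._ingest(tmp_path, spec)
        results = archive.dispatch_qa(record)
        assert "structural" not in results
        assert "mean_snr" in results["timeseries"]
        assert results["diffusion"]["status"] == "not_applicable"

    def test_dwi_runs_diffusion(self, tmp_path):
        spec = PhantomSpec(kind="diffusion", shape=(12, 12, 4),
                           brain_axes=(4, 4, 1.5),
                           bvals=(0.0,) + (1000.0,) * 6,
                           bvecs=((0.0, 0.0, 0.0),) + SIX_DIRECTIONS, seed=62)
        archive, record = self._ingest(tmp_path, spec)
        results = archive.dispatch_qa(record)
        assert results["diffusion"]["overall"] == "pass"
        assert (Path(record.paths["qa"]) / "diffusion.xml").exists()

    def test_mprage_named_in_lowercase_still_gated_in(self, tmp_path):
        spec = PhantomSpec(kind="structural", shape=(24, 24, 18),
                           brain_axes=(8, 8, 6),
                           series_description="mprage", seed=63)
        archive, record = self._ingest(tmp_path, spec)
        results = archive.dispatch_qa(record)
        assert "structural" in results


class TestSharing:
    def _populated(self, tmp_path, small_tree):
        archive = Archive(tmp_path / "arch")
        archive.ingest(prepared_session(small_tree))
        return archive

    def test_owner_flips_whole_project(self, tmp_path, small_tree):
        archive = self._populated(tmp_path, small_tree)
        changed = archive.set_sharing("P1", shared=False, acting_user="alice")
        assert changed and all(not r.shared for r in archive.records)
        reloaded = Archive(archive.root)
        assert all(not r.shared for r in reloaded.records)

    def test_non_owner_denied_and_state_unchanged(self, tmp_path, small_tree):
        archive = self._populated(tmp_path, small_tree)
        with pytest.raises(PermissionDeniedError):
            archive.set_sharing("P1", shared=False, acting_user="mallory")
        assert all(r.shared for r in archive.records)

    def test_owner_removes_project_completely(self, tmp_path, small_tree):
        archive = self._populated(tmp_path, small_tree)
        removed = archive.remove_project("P1", acting_user="alice")
        assert removed == 1
        assert archive.find(project="P1") == []
        assert not (archive.root / "P1").exists()


class TestReport:
    def test_histogram_counts_sum_to_reference_size(self, tmp_path):
        spec = PhantomSpec(kind="structural", shape=(24, 24, 18),
                           brain_axes=(8, 8, 6), n_subjects=3, seed=70)
        generate(spec, tmp_path / "data")
        archive = Archive(tmp_path / "arch")
        entities, _ = scan_directory(tmp_path / "data")
        sessions = {}
        for entity in entities:
            sessions.setdefault(entity.patient_id, []).append(entity)
        for index, patient in enumerate(sorted(sessions)):
            note = ShareAnnotation(user="alice", project="P1",
                                   subject_label=f"S{index:02d}",
                                   session_label="E01")
            prepared = [annotate(apply_profile(e), note)
                        for e in sessions[patient]]
            result = archive.ingest(prepared)
            for record in result.records:
                archive.dispatch_qa(record)
        record = archive.records[0]
        report = archive.build_report(record)
        payload = json.loads(
            (Path(record.paths["qa"]) / "report.json").read_text())
        histogram = payload["histogram"]
        assert histogram["metric"] == "snr"
        assert sum(histogram["counts"]) == histogram["n_reference"] == 3
        assert report.read_text().count("<-- this scan") == 1

    def test_external_reference_file(self, tmp_path, small_tree):
        archive = Archive(tmp_path / "arch")
        result = archive.ingest(prepared_session(small_tree))
        record = result.records[0]
        archive.dispatch_qa(record)
        reference = [20.0 + 0.5 * i for i in range(100)]
        archive.build_report(record, reference=reference)
        payload = json.loads(
            (Path(record.paths["qa"]) / "report.json").read_text())
        assert sum(payload["histogram"]["counts"]) == 100

    def test_empty_reference_notes_omission(self, tmp_path, small_tree):
        archive = Archive(tmp_path / "arch")
        result = archive.ingest(prepared_session(small_tree))
        record = result.records[0]
        archive.dispatch_qa(record)
        report = archive.build_report(record, reference=[])
        assert "histogram omitted" in report.read_text()
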