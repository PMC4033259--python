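"""Diffusion QA: gradient extraction and the sanity-check rule set."""

import math
import random

import numpy as np

from scanshare.dicom_io import assemble_volume, group_entities, scan_directory
from scanshare.qa_diffusion import (B_VALUE_RANGE, GradientTable,
                                    MIN_DIRECTIONS, UNIT_NORM_TOL,
                                    extract_gradients, read_fsl_gradients,
                                    run_checks, write_fsl_gradients,
                                    write_xml_report)
from scanshare.synthgen import SIX_DIRECTIONS, PhantomSpec, generate
from tests.conftest import as_stack

WELL_FORMED = GradientTable(
    bvals=[0.0] + [1000.0] * 6,
    bvecs=[(0.0, 0.0, 0.0)] + list(SIX_DIRECTIONS),
    n_volumes=7)


def _volume(n):
    return as_stack(np.ones((4, 4, 2, n)))


def statuses(result):
    return {c.name: c.status for c in result.checks}


# ---------------------------------------------------------------------------
# Independent oracle: re-evaluate the rule set by direct enumeration
# ---------------------------------------------------------------------------

def brute_force_statuses(n_volumes, table):
    """Brute-force reimplementation of the published rule set, kept separate
    from the library code path."""
    out = {}
    rows = [(b, v) for b, v in zip(table.bvals, table.bvecs)
            if b is not None and v is not None]
    out["spatial"] = "pass" if n_volumes == table.n_volumes else "fail"
    out["gradient_table_complete"] = ("pass" if len(rows) == table.n_volumes
                                      else "fail")
    bad_norm = False
    for b, v in rows:
        if b > 1e-6:
            norm = math.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
            if norm == 0 or abs(norm - 1.0) > UNIT_NORM_TOL:
                bad_norm = True
    out["gradient_norm"] = "fail" if bad_norm else "pass"

    unit = []
    for b, v in rows:
        norm = math.sqrt(sum(x * x for x in v))
        if b > 1e-6 and norm > 0:
            unit.append(tuple(x / norm for x in v))
    unique = []
    for v in unit:
        if not any(abs(abs(sum(a * b for a, b in zip(v, u))) - 1) < 1e-6
                   for u in unique):
            unique.append(v)
    out["duplicate_directions"] = ("warn" if len(unit) > len(unique)
                                   else "pass")
    out["direction_count"] = ("warn" if len(unique) < MIN_DIRECTIONS
                              else "pass")
    lo, hi = B_VALUE_RANGE
    out["b_values"] = ("warn" if any(b > 1e-6 and not lo <= b <= hi
                                     for b, _ in rows) else "pass")
    out["b0_present"] = ("pass" if any(b <= 1e-6 for b, _ in rows)
                         else "warn")
    return out


class TestExtract:
    def test_dwi_series_table_length(self, dwi_tree):
        out, _, truth = dwi_tree
        entities, _ = scan_directory(out)
        scan = group_entities(entities)[0].sessions[0].scans[0]
        table = extract_gradients(scan)
        assert table is not None and table.complete
        assert table.n_volumes == 7
        series_truth = truth.true_values[scan.series_uid]
        assert table.bvals == series_truth["bvals"]
        assert [list(v) for v in table.bvecs] == series_truth["bvecs"]
        assert scan.modality_hint == "diffusion"

    def test_structural_scan_not_applicable(self, dicom_tree):
        out, _, _ = dicom_tree
        entities, _ = scan_directory(out)
        scan = group_entities(entities)[0].sessions[0].scans[0]
        assert extract_gradients(scan) is None

    def test_partial_tagging_yields_incomplete_table(self, tmp_path):
        spec = PhantomSpec(kind="diffusion", shape=(8, 8, 2),
                           brain_axes=(3, 3, 0.8),
                           bvals=(0.0, 1000.0, 1000.0, None, None, None, None),
                           bvecs=((0, 0, 0), SIX_DIRECTIONS[0],
                                  SIX_DIRECTIONS[1], None, None, None, None),
                           seed=41)
        generate(spec, tmp_path)
        entities, _ = scan_directory(tmp_path)
        scan = group_entities(entities)[0].sessions[0].scans[0]
        table = extract_gradients(scan)
        assert table is not None and not table.complete
        result = run_checks(assemble_volume(scan), table)
        check = result.by_name("gradient_table_complete")
        assert check.status == "fail"
        assert "incomplete" in check.detail
        assert result.overall == "fail"


class TestRules:
    def test_well_formed_table_passes_everything(self):
        result = run_checks(_volume(7), WELL_FORMED)
        assert result.overall == "pass"
        assert set(statuses(result).values()) == {"pass"}

    def test_non_unit_direction_fails(self):
        table = GradientTable(bvals=[0.0, 1000.0],
                              bvecs=[(0, 0, 0), (2.0, 0.0, 0.0)],
                              n_volumes=2)
        result = run_checks(_volume(2), table)
        assert result.by_name("gradient_norm").status == "fail"
        assert result.overall == "fail"

    def test_zero_vector_with_nonzero_b_fails(self):
        table = GradientTable(bvals=[0.0, 1000.0],
                              bvecs=[(0, 0, 0), (0.0, 0.0, 0.0)],
                              n_volumes=2)
        assert run_checks(_volume(2), table).by_name(
            "gradient_norm").status == "fail"

    def test_low_b_value_warns(self):
        table = GradientTable(
            bvals=[0.0, 50.0] + [1000.0] * 5,
            bvecs=[(0.0, 0.0, 0.0)] + list(SIX_DIRECTIONS), n_volumes=7)
        result = run_checks(_volume(7), table)
        check = result.by_name("b_values")
        assert check.status == "warn" and "suspicious" in check.detail
        assert result.overall == "pass"    # warnings do not fail

    def test_few_directions_warns(self):
        table = GradientTable(
            bvals=[0.0] + [1000.0] * 3,
            bvecs=[(0.0, 0.0, 0.0)] + list(SIX_DIRECTIONS[:3]), n_volumes=4)
        check = run_checks(_volume(4), table).by_name("direction_count")
        assert check.status == "warn"
        assert "non-standard number" in check.detail

    def test_antipodal_counts_as_duplicate(self):
        directions = list(SIX_DIRECTIONS) + [tuple(-x for x in
                                                   SIX_DIRECTIONS[0])]
        table = GradientTable(bvals=[0.0] + [1000.0] * 7,
                              bvecs=[(0.0, 0.0, 0.0)] + directions,
                              n_volumes=8)
        assert run_checks(_volume(8), table).by_name(
            "duplicate_directions").status == "warn"

    def test_missing_b0_warns(self):
        table = GradientTable(bvals=[1000.0] * 6,
                              bvecs=list(SIX_DIRECTIONS), n_volumes=6)
        assert run_checks(_volume(6), table).by_name(
            "b0_present").status == "warn"

    def test_volume_count_mismatch_fails_spatial(self):
        assert run_checks(_volume(5), WELL_FORMED).by_name(
            "spatial").status == "fail"

    def test_assembly_failure_fails_spatial(self):
        result = run_checks(None, WELL_FORMED)
        assert result.by_name("spatial").status == "fail"
        assert result.overall == "fail"

    def test_idempotent_and_row_order_invariant(self):
        one = run_checks(_volume(7), WELL_FORMED)
        two = run_checks(_volume(7), WELL_FORMED)
        assert statuses(one) == statuses(two)
        order = list(range(7))
        random.Random(3).shuffle(order)
        permuted = GradientTable(
            bvals=[WELL_FORMED.bvals[i] for i in order],
            bvecs=[WELL_FORMED.bvecs[i] for i in order], n_volumes=7)
        assert statuses(run_checks(_volume(7), permuted)) == statuses(one)

    def test_randomized_corruptions_match_brute_force(self):
        """Exhaustive randomized corruption sweep against the independent
        oracle; also asserts overall == pass iff no check failed."""
        rng = random.Random(12345)
        for trial in range(300):
            n = rng.randint(1, 12)
            bvals, bvecs = [], []
            for _ in range(n):
                kind = rng.random()
                if kind < 0.25:
                    bvals.append(0.0)
                    bvecs.append((0.0, 0.0, 0.0))
                else:
                    bvals.append(rng.choice([50.0, 700.0, 1000.0, 3000.0,
                                             20000.0]))
                    direction = rng.choice(
                        list(SIX_DIRECTIONS) +
                        [(2.0, 0.0, 0.0), (0.0, 0.0, 0.0),
                         (1.0, 0.0, 0.0), (-1.0, 0.0, 0.0),
                         (0.6, 0.8, 0.0)])
                    bvecs.append(direction)
            table = GradientTable(bvals=bvals, bvecs=bvecs, n_volumes=n)
            n_volumes = n if rng.random() < 0.8 else n + 1
            result = run_checks(_volume(n_volumes), table)
            expected = brute_force_statuses(n_volumes, table)
            assert statuses(result) == expected, f"trial {trial}"
            assert (result.overall == "pass") == (
                "fail" not in expected.values())


class TestInterchange:
    def test_fsl_roundtrip(self, tmp_path):
        write_fsl_gradients(WELL_FORMED, tmp_path / "b.bval",
                            tmp_path / "b.bvec")
        back = read_fsl_gradients(tmp_path / "b.bval", tmp_path / "b.bvec")
        assert back.bvals == WELL_FORMED.bvals
        assert np.allclose(back.bvecs, WELL_FORMED.bvecs, atol=1e-6)

    def test_xml_report_structure(self, tmp_path):
        from xml.etree import ElementTree
        result = run_checks(_volume(7), WELL_FORMED)
        path = write_xml_report(result, tmp_path / "report.xml")
        tree = ElementTree.parse(path)
        root = tree.getroot()
        assert root.get("overall") == "pass"
        assert len(root.findall("check")) == len(result.checks)
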