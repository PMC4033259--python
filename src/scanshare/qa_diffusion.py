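"""Diffusion QA: gradient-table extraction and pass/fail/warn sanity checks.

The checks cover the categories a diffusion acquisition report needs before
any modeling is attempted: spatial consistency of the volumes, completeness
of the gradient table, unit norm of every diffusion-encoding direction,
presence of a b=0 reference, duplicate directions (antipodal pairs count as
duplicates, by tensor symmetry), an adequate number of unique directions,
and b-values in a plausible range.  Hard geometry/encoding errors fail;
merely unusual conditions warn.  The overall verdict is pass exactly when
no check fails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree

import numpy as np

from .dicom_io import (TAG_B_VALUE, TAG_GRADIENT_DIRECTION, ScanSeries,
                       VolumeStack, _slice_time_layout)

__all__ = [
    "GradientTable",
    "CheckResult",
    "DiffusionQaResult",
    "extract_gradients",
    "run_checks",
    "write_fsl_gradients",
    "read_fsl_gradients",
    "write_xml_report",
]

# Default thresholds; all configurable through run_checks keyword arguments.
UNIT_NORM_TOL = 0.01
B_VALUE_RANGE = (100.0, 10000.0)     # s/mm^2 for nonzero weightings
MIN_DIRECTIONS = 6
B_ZERO_THRESHOLD = 1e-6              # b at or below this counts as b=0


@dataclass
class GradientTable:
    """Per-volume diffusion encoding.  ``None`` entries mark volumes whose
    DICOM headers lacked the b-value / direction attributes."""

    bvals: list[float | None]
    bvecs: list[tuple[float, float, float] | None]
    n_volumes: int

    def __post_init__(self):
        if not (len(self.bvals) == len(self.bvecs) == self.n_volumes):
            raise ValueError("bvals/bvecs length must equal n_volumes")

    @property
    def complete(self) -> bool:
        return all(b is not None for b in self.bvals) and \
            all(v is not None for v in self.bvecs)

    @property
    def any_present(self) -> bool:
        return any(b is not None for b in self.bvals) or \
            any(v is not None for v in self.bvecs)


@dataclass(frozen=True)
class CheckResult:
    name: str
    status: str            # pass | fail | warn
    detail: str = ""


@dataclass
class DiffusionQaResult:
    checks: list[CheckResult] = field(default_factory=list)

    @property
    def overall(self) -> str:
        return "fail" if any(c.status == "fail" for c in self.checks) else "pass"

    def by_name(self, name: str) -> CheckResult:
        for check in self.checks:
            if check.name == name:
                return check
        raise KeyError(name)

    def as_dict(self) -> dict:
        return {"overall": self.overall,
                "checks": [{"name": c.name, "status": c.status,
                            "detail": c.detail} for c in self.checks]}


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def extract_gradients(scan: ScanSeries) -> GradientTable | None:
    """Read the b-value (0018,9087) and gradient direction (0018,9089) tags
    volume by volume.

    Returns None when no file in the series carries either tag — the series
    is not diffusion-weighted and diffusion QA is not applicable.  A series
    where only some volumes are tagged yields an incomplete table, which
    :func:`run_checks` fails.
    """
    entities = scan.entities
    try:
        n_slices, n_volumes = _slice_time_layout(entities)
    except Exception:
        n_slices, n_volumes = 1, len(entities)
    # one representative file per volume (instance numbering is volume-major
    # within a slice position; any slice of the volume carries the encoding)
    bvals: list[float | None] = []
    bvecs: list[tuple[float, float, float] | None] = []
    by_volume: dict[int, list] = {}
    for index, entity in enumerate(sorted(
            entities, key=lambda e: (e.instance_number, str(e.filepath)))):
        by_volume.setdefault(index // max(1, n_slices), []).append(entity)
    for volume_index in range(n_volumes):
        members = by_volume.get(volume_index, [])
        bval = bvec = None
        for entity in members:
            raw_b = entity.get_tag(TAG_B_VALUE)
            raw_v = entity.get_tag(TAG_GRADIENT_DIRECTION)
            if raw_b is not None:
                bval = float(raw_b)
            if raw_v is not None:
                bvec = tuple(float(x) for x in raw_v)
        bvals.append(bval)
        bvecs.append(bvec)
    table = GradientTable(bvals=bvals, bvecs=bvecs, n_volumes=n_volumes)
    if not table.any_present:
        return None
    return table


# ---------------------------------------------------------------------------
# Checks
# ---------------------------------------------------------------------------

def _unique_directions(table: GradientTable) -> list[np.ndarray]:
    """Unique nonzero-b directions, folding antipodal pairs together."""
    unique: list[np.ndarray] = []
    for bval, bvec in zip(table.bvals, table.bvecs):
        if bval is None or bvec is None or bval <= B_ZERO_THRESHOLD:
            continue
        vector = np.asarray(bvec, dtype=float)
        norm = np.linalg.norm(vector)
        if norm == 0:
            continue
        vector = vector / norm
        if not any(abs(abs(float(np.dot(vector, u))) - 1.0) < 1e-6
                   for u in unique):
            unique.append(vector)
    return unique


def run_checks(volume: VolumeStack | None, table: GradientTable,
               unit_norm_tol: float = UNIT_NORM_TOL,
               b_value_range: tuple[float, float] = B_VALUE_RANGE,
               min_directions: int = MIN_DIRECTIONS) -> DiffusionQaResult:
    """Evaluate the diffusion sanity rule set.

    ``volume`` may be None when volume assembly itself failed, which is
    recorded as a spatial failure.  All findings are statuses, never
    exceptions; the rule set is order-invariant and idempotent.
    """
    checks: list[CheckResult] = []

    # spatial consistency
    if volume is None:
        checks.append(CheckResult("spatial", "fail",
                                  "volumes disagree on shape or spacing"))
    elif volume.n_timepoints != table.n_volumes:
        checks.append(CheckResult(
            "spatial", "fail",
            f"{volume.n_timepoints} volumes vs {table.n_volumes} table rows"))
    else:
        checks.append(CheckResult("spatial", "pass",
                                  f"{table.n_volumes} consistent volumes"))

    # table completeness
    if not table.complete:
        missing = sum(1 for b, v in zip(table.bvals, table.bvecs)
                      if b is None or v is None)
        checks.append(CheckResult("gradient_table_complete", "fail",
                                  f"incomplete gradient table: {missing} of "
                                  f"{table.n_volumes} volumes untagged"))
    else:
        checks.append(CheckResult("gradient_table_complete", "pass", ""))

    rows = [(b, v) for b, v in zip(table.bvals, table.bvecs)
            if b is not None and v is not None]

    # gradient norms: nonzero-b directions must be unit vectors
    bad_norms = []
    for index, (bval, bvec) in enumerate(rows):
        if bval > B_ZERO_THRESHOLD:
            norm = math.sqrt(sum(x * x for x in bvec))
            if norm == 0 or abs(norm - 1.0) > unit_norm_tol:
                bad_norms.append((index, norm))
    if bad_norms:
        detail = "; ".join(
            f"volume {i}: |g|={n:.4f}" for i, n in bad_norms)
        checks.append(CheckResult("gradient_norm", "fail", detail))
    else:
        checks.append(CheckResult("gradient_norm", "pass", ""))

    # duplicate directions (antipodal folded)
    nonzero = [(b, v) for b, v in rows
               if b > B_ZERO_THRESHOLD and any(x != 0 for x in v)]
    unique = _unique_directions(table)
    n_duplicates = len(nonzero) - len(unique)
    if n_duplicates > 0:
        checks.append(CheckResult("duplicate_directions", "warn",
                                  f"{n_duplicates} repeated (or antipodal) "
                                  "direction(s)"))
    else:
        checks.append(CheckResult("duplicate_directions", "pass", ""))

    # number of unique non-collinear directions
    if len(unique) < min_directions:
        checks.append(CheckResult(
            "direction_count", "warn",
            f"non-standard number of gradient directions: {len(unique)} "
            f"unique (< {min_directions})"))
    else:
        checks.append(CheckResult("direction_count", "pass",
                                  f"{len(unique)} unique directions"))

    # b-value plausibility
    low, high = b_value_range
    suspicious = sorted({b for b, _ in rows
                         if b > B_ZERO_THRESHOLD and not (low <= b <= high)})
    if suspicious:
        checks.append(CheckResult(
            "b_values", "warn",
            "suspicious b-values: " + ", ".join(f"{b:g}" for b in suspicious)))
    else:
        checks.append(CheckResult("b_values", "pass", ""))

    # b=0 reference
    if not any(b <= B_ZERO_THRESHOLD for b, _ in rows):
        checks.append(CheckResult("b0_present", "warn", "no b=0 volume"))
    else:
        checks.append(CheckResult("b0_present", "pass", ""))

    return DiffusionQaResult(checks=checks)


# ---------------------------------------------------------------------------
# Interchange
# ---------------------------------------------------------------------------

def write_fsl_gradients(table: GradientTable, bval_path: Path | str,
                        bvec_path: Path | str) -> None:
    """Write the table in FSL text format (one bval row; three bvec rows)."""
    if not table.complete:
        raise ValueError("cannot export an incomplete gradient table")
    with open(bval_path, "w") as handle:
        handle.write(" ".join(f"{b:g}" for b in table.bvals) + "\n")
    with open(bvec_path, "w") as handle:
        for axis in range(3):
            handle.write(" ".join(f"{v[axis]:g}" for v in table.bvecs) + "\n")


def read_fsl_gradients(bval_path: Path | str,
                       bvec_path: Path | str) -> GradientTable:
    bvals = [float(x) for x in Path(bval_path).read_text().split()]
    rows = [[float(x) for x in line.split()]
            for line in Path(bvec_path).read_text().splitlines() if line.strip()]
    if len(rows) != 3 or any(len(r) != len(bvals) for r in rows):
        raise ValueError("malformed bvec file")
    bvecs = [tuple(rows[axis][i] for axis in range(3))
             for i in range(len(bvals))]
    return GradientTable(bvals=bvals, bvecs=bvecs, n_volumes=len(bvals))


def write_xml_report(result: DiffusionQaResult, path: Path | str) -> Path:
    """Flat XML report of the check outcomes."""
    root = ElementTree.Element("diffusion_qa", overall=result.overall)
    for check in result.checks:
        element = ElementTree.SubElement(root, "check", name=check.name,
                                         status=check.status)
        element.text = check.detail
    tree = ElementTree.ElementTree(root)
    ElementTree.indent(tree)
    path = Path(path)
    tree.write(path, encoding="unicode", xml_declaration=True)
    return path
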