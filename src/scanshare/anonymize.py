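"""De-identification against a fixed protected-field profile, plus sharing
annotation in Study Comments.

The default profile removes twenty header attributes that carry direct
identifiers (names and identification numbers of the patient's physicians,
birth date and birth names, address, age, insurance and language codes,
accession and institution).  Removal — deleting the attribute — is preferred
over blanking so that downstream audits can assert outright absence.  An
optional blank action is available for toolchains that require the
attributes to exist.

The sharing route (user, project, subject label, session label) is carried
in Study Comments (0032,4000), which is replaced or created as needed, in a
fixed ``incf:`` key=value wire format that needs no escaping because the
identifier character rule excludes the delimiters.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dicom_io import DicomEntity
from .errors import AnnotationError, LabelValidationError
from .identifiers import DEFAULT_RULE, IdentifierRule

__all__ = [
    "PROTECTED_FIELDS",
    "AnonymizationProfile",
    "ShareAnnotation",
    "AnonymizationAudit",
    "default_profile",
    "load_profile",
    "apply_profile",
    "annotate",
    "parse_annotation",
    "verify_anonymization",
]

ANNOTATION_TAG = (0x0032, 0x4000)  # Study Comments

#: Default protected attributes: (group, element) -> attribute name.
PROTECTED_FIELDS: dict[tuple[int, int], str] = {
    (0x0008, 0x0050): "Accession Number",
    (0x0008, 0x0080): "Institution Name",
    (0x0008, 0x0090): "Referring Physician's Name",
    (0x0008, 0x0096): "Referring Physician Identification Sequence",
    (0x0008, 0x1048): "Physician(s) of Record",
    (0x0008, 0x1049): "Physician(s) of Record Identification Sequence",
    (0x0008, 0x1050): "Performing Physician's Name",
    (0x0008, 0x1052): "Performing Physician Identification Sequence",
    (0x0008, 0x1060): "Name of Physician(s) Reading Study",
    (0x0008, 0x1062): "Physician(s) Reading Study Identification Sequence",
    (0x0010, 0x0030): "Patient's Birth Date",
    (0x0010, 0x0050): "Patient's Insurance Plan Code Sequence",
    (0x0010, 0x0101): "Patient's Primary Language Code Sequence",
    (0x0010, 0x1000): "Other Patient IDs",
    (0x0010, 0x1001): "Other Patient Names",
    (0x0010, 0x1002): "Other Patient IDs Sequence",
    (0x0010, 0x1005): "Patient's Birth Name",
    (0x0010, 0x1010): "Patient's Age",
    (0x0010, 0x1040): "Patient's Address",
    (0x0010, 0x1060): "Patient's Mother's Birth Name",
}


@dataclass(frozen=True)
class AnonymizationProfile:
    """Ordered set of protected (group, element) tags with a removal action.

    ``action`` is ``"remove"`` (delete the attribute, the default) or
    ``"blank"`` (replace its value with an empty string).
    """

    protected: tuple[tuple[int, int], ...]
    action: str = "remove"
    annotation_tag: tuple[int, int] = ANNOTATION_TAG

    def __post_init__(self):
        if self.action not in ("remove", "blank"):
            raise ValueError(f"unknown action {self.action!r}")
        if self.annotation_tag in self.protected:
            raise ValueError("annotation tag must not be protected")

    def field_name(self, tag: tuple[int, int]) -> str:
        return PROTECTED_FIELDS.get(tag, f"({tag[0]:04X},{tag[1]:04X})")


def default_profile() -> AnonymizationProfile:
    return AnonymizationProfile(protected=tuple(PROTECTED_FIELDS))


def load_profile(path: Path | str) -> AnonymizationProfile:
    """Load a profile from YAML/JSON: a mapping with a ``protected`` list of
    hex tag pairs (e.g. ``["0010,0030", ...]``) and an optional ``action``."""
    with open(path) as handle:
        raw = yaml.safe_load(handle)
    protected = []
    for item in raw["protected"]:
        if isinstance(item, str):
            group, element = item.split(",")
            protected.append((int(group, 16), int(element, 16)))
        else:
            group, element = item
            protected.append((int(group), int(element)))
    return AnonymizationProfile(protected=tuple(protected),
                                action=raw.get("action", "remove"))


@dataclass(frozen=True)
class ShareAnnotation:
    """Routing metadata carried in Study Comments."""

    user: str
    project: str
    subject_label: str
    session_label: str

    def validate(self, rule: IdentifierRule = DEFAULT_RULE) -> None:
        for name, value in (("user", self.user), ("project", self.project),
                            ("subject", self.subject_label),
                            ("session", self.session_label)):
            issue = rule.explain(value)
            if issue is not None:
                raise LabelValidationError(f"{name} {value!r}: {issue}")

    def serialize(self) -> str:
        return (f"incf:user={self.user};project={self.project};"
                f"subject={self.subject_label};session={self.session_label}")


def parse_annotation(text: str) -> ShareAnnotation:
    """Inverse of :meth:`ShareAnnotation.serialize`."""
    if not text or not text.startswith("incf:"):
        raise AnnotationError(f"not a sharing annotation: {text!r}")
    fields = {}
    for part in text[len("incf:"):].split(";"):
        if "=" not in part:
            raise AnnotationError(f"malformed annotation field: {part!r}")
        key, value = part.split("=", 1)
        fields[key] = value
    try:
        return ShareAnnotation(user=fields["user"], project=fields["project"],
                               subject_label=fields["subject"],
                               session_label=fields["session"])
    except KeyError as missing:
        raise AnnotationError(f"annotation missing field {missing}") from None


@dataclass
class AnonymizationAudit:
    """Outcome of a protected-field sweep over a set of files."""

    violations: list[tuple[Path, tuple[int, int], str]] = None

    def __post_init__(self):
        if self.violations is None:
            self.violations = []

    @property
    def clean(self) -> bool:
        return not self.violations


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def apply_profile(entity: DicomEntity,
                  profile: AnonymizationProfile | None = None) -> DicomEntity:
    """Return a copy of ``entity`` with every protected attribute removed
    (or blanked).  Non-protected attributes and pixel data are untouched;
    applying twice is a no-op the second time."""
    profile = profile or default_profile()
    dataset = copy.deepcopy(entity.dataset)
    for tag in profile.protected:
        if tag in dataset:
            if profile.action == "remove":
                del dataset[tag]
            else:
                dataset[tag].value = ""
    return DicomEntity(filepath=entity.filepath, dataset=dataset)


def annotate(entity: DicomEntity, note: ShareAnnotation,
             rule: IdentifierRule = DEFAULT_RULE) -> DicomEntity:
    """Write the sharing annotation into Study Comments, replacing any prior
    content.  Identifiers are validated before anything is written."""
    note.validate(rule)
    dataset = copy.deepcopy(entity.dataset)
    dataset.StudyComments = note.serialize()
    return DicomEntity(filepath=entity.filepath, dataset=dataset)


def read_annotation(entity: DicomEntity) -> ShareAnnotation:
    value = entity.get_tag(ANNOTATION_TAG)
    if value is None:
        raise AnnotationError(f"{entity.filepath}: no Study Comments")
    return parse_annotation(str(value))


def verify_anonymization(
    entities: list[DicomEntity],
    profile: AnonymizationProfile | None = None,
) -> AnonymizationAudit:
    """Sweep every entity for protected tags.  A protected tag present with
    any value — including an empty one — is a violation."""
    profile = profile or default_profile()
    audit = AnonymizationAudit()
    for entity in entities:
        for tag in profile.protected:
            if entity.has_tag(tag):
                audit.violations.append(
                    (entity.filepath, tag, profile.field_name(tag)))
    return audit
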