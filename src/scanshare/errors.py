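"""Exception hierarchy shared across the toolkit."""


class ScanShareError(Exception):
    """Base class for all toolkit errors."""


class NoDicomDataError(ScanShareError):
    """A directory scan found no parseable DICOM files."""


class SpatialInconsistencyError(ScanShareError):
    """Slices of a scan disagree on shape, spacing, or position."""


class EmptyImageError(ScanShareError):
    """An operation received an all-zero volume."""


class LabelValidationError(ScanShareError):
    """A sharing identifier violates the archive character rule."""


class AnnotationError(ScanShareError):
    """Study Comments is missing or cannot be parsed as an annotation."""


class PermissionDeniedError(ScanShareError):
    """The acting user does not own the project."""


class NotApplicableError(ScanShareError):
    """A QA procedure's prerequisites are not met (e.g. a single-timepoint
    series handed to time-series QA).  Dispatch converts this into a
    ``not_applicable`` status rather than a failure."""
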