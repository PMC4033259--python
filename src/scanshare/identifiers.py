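"""Character rule for project / subject / session identifiers.

The archive rejects labels that would be ambiguous on disk or in URLs.
Only ASCII letters, digits, underscore and hyphen are accepted, with a
length cap, which admits the usual site conventions (``BUSS_2030``,
``sess-01``) while excluding whitespace, path separators, and anything
that needs escaping.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["IdentifierRule", "DEFAULT_RULE"]


@dataclass(frozen=True)
class IdentifierRule:
    pattern: str = r"[A-Za-z0-9_-]+"
    max_length: int = 64
    _compiled: re.Pattern = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        object.__setattr__(self, "_compiled", re.compile(self.pattern))

    def is_valid(self, label: str) -> bool:
        if not label or len(label) > self.max_length:
            return False
        return self._compiled.fullmatch(label) is not None

    def explain(self, label: str) -> str | None:
        """Return a human-readable issue for ``label``, or None if valid."""
        if not label:
            return "empty identifier"
        if len(label) > self.max_length:
            return f"identifier longer than {self.max_length} characters"
        if self._compiled.fullmatch(label) is None:
            bad = sorted({c for c in label if not re.fullmatch(r"[A-Za-z0-9_-]", c)})
            return "invalid characters: " + "".join(bad)
        return None


DEFAULT_RULE = IdentifierRule()
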