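"""Exception hierarchy shared across the package.

Every error raised by a reader or pipeline stage is an :class:`AdgatError`
subclass so callers (and the CLI) can catch the family in one clause.
"""


class AdgatError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(AdgatError):
    """A file is structurally malformed (e.g. a mandatory column is missing)."""


class IntegrityError(AdgatError):
    """A uniqueness or cross-record consistency constraint is violated."""


class ValidationError(AdgatError):
    """A field value violates a type invariant (non-negativity, closed sets...)."""


class UnmatchedItemError(AdgatError):
    """No database record survived the matching pipeline for an item.

    Carries the full audit trail so the caller can see which rule removed
    each candidate.
    """

    def __init__(self, item_name: str, audit):
        self.item_name = item_name
        self.audit = list(audit)
        lines = [f"no surviving match for item '{item_name}'"]
        for entry in self.audit:
            lines.append(f"  {entry.food_id}: {entry.disposition} ({entry.rule})")
        super().__init__("\n".join(lines))


class SyntheticSpecError(AdgatError):
    """A synthetic-database spec cannot be honoured (capacity/fraction clash)."""
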