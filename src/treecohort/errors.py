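"""Exception types shared across the package."""


class TreecohortError(Exception):
    """Base class for all package-specific errors."""


class CohortParseError(TreecohortError):
    """Raised when a cohort document is not well-formed JSON."""


class CohortValidationError(TreecohortError):
    """Raised when a cohort document violates the format's invariants.

    Carries the full list of :class:`~treecohort.treecore.Violation`
    records so callers can report every problem at once.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(f"{v.path}: {v.message}" for v in self.violations[:5])
        more = "" if len(self.violations) <= 5 else f" (+{len(self.violations) - 5} more)"
        super().__init__(f"{len(self.violations)} violation(s): {lines}{more}")


class CapabilityError(TreecohortError):
    """An operation was requested that the given data cannot support
    (e.g. per-cluster analysis without clusters, sizes missing)."""


class DegenerateInputError(TreecohortError):
    """Input is structurally valid but numerically degenerate
    (e.g. all subclone sizes zero)."""


class FormatError(TreecohortError):
    """A tabular input file does not follow the expected column layout."""


class StructureError(TreecohortError):
    """A converter input does not describe a single rooted tree."""
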