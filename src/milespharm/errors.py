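"""Exception hierarchy shared across the package."""


class MilesError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MilesError):
    """Malformed record in a data file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class IntegrityError(MilesError):
    """Structural invariant violated (duplicate ids, empty bag, missing conformer)."""


class LabelError(MilesError):
    """Unrecognized or inconsistent activity label."""


class SchemaError(MilesError):
    """Unknown or corrupted serialization schema."""


class DimensionError(MilesError):
    """Mismatched fingerprint universes or array shapes."""


class ClassError(MilesError):
    """An operation requiring both activity classes received only one."""


class SpecError(MilesError):
    """Infeasible synthetic-data specification."""


class SolverError(MilesError):
    """The LP solver failed to report an optimal solution."""
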