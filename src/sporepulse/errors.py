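"""Exception types shared across the package."""


class SporepulseError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SporepulseError, ValueError):
    """Invalid simulation or analysis configuration."""


class InsufficientDataError(SporepulseError, ValueError):
    """A series or tree is too short/small for the requested operation."""


class DomainError(SporepulseError, ValueError):
    """Input values outside the mathematical domain (e.g. non-positive length)."""


class AlignmentError(SporepulseError, ValueError):
    """Series that must share a frame grid do not."""


class ConsistencyError(SporepulseError, ValueError):
    """Cross-referenced records disagree (unknown cell ids, out-of-range frames)."""


class ParseError(SporepulseError, ValueError):
    """A trace table on disk violates the format contract."""


class FitError(SporepulseError, RuntimeError):
    """A nonlinear fit failed to converge or is non-identifiable."""


class SolverError(SporepulseError, RuntimeError):
    """Numerical integration failed (blow-up, resolution too coarse)."""
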