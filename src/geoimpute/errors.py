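"""Exception hierarchy.

A deliberate distinction runs through the package: *no-match* (a demographic
category with zero population in the searched unit) is a value-level signal
(``None`` / ``UNIMPUTABLE`` status), never an exception, because the
strategies must count such records rather than crash on them.  Exceptions are
reserved for contract violations: unknown labels, broken geometry, malformed
inputs.
"""


class GeoimputeError(Exception):
    """Base class for all package errors."""


class CategoryResolutionError(GeoimputeError, KeyError):
    """A sex or race label (or an age) cannot be resolved in the schema.

    Carries the offending label so callers can build race-mapping tables
    for registry data whose race vocabulary differs from the census one.
    """

    def __init__(self, kind: str, label: object):
        self.kind = kind
        self.label = label
        super().__init__(f"unknown {kind} label: {label!r}")


class LookupIdError(GeoimputeError, KeyError):
    """An unknown block / group / tract / county identifier."""


class GeometryError(GeoimputeError, ValueError):
    """Invalid or degenerate geometry (zero area, self-intersection...)."""


class SamplingError(GeoimputeError, RuntimeError):
    """Rejection sampling exceeded its attempt cap."""


class ValidationError(GeoimputeError, ValueError):
    """A structural invariant of an input object does not hold."""


class ConfigError(GeoimputeError, ValueError):
    """Invalid scenario or pipeline configuration."""


class ScoringError(GeoimputeError, ValueError):
    """Evaluation asked for a quantity the inputs cannot support
    (missing true location, multiple imputation of a deterministic
    strategy, ...)."""
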