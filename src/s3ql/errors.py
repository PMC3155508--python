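"""Exception hierarchy.

Every error raised by the public API derives from :class:`S3QLError` so
callers (and the CLI) can map failures to exit codes in one place.
"""


class S3QLError(Exception):
    """Base class for all errors raised by this package."""


class CoreModelError(S3QLError):
    """A core-model description file is malformed or inconsistent."""


class ParseError(S3QLError):
    """A query, entity reference or serialized store could not be parsed."""


class ValidationError(S3QLError):
    """A structurally well-formed input violates the active core model."""


class DependencyError(ValidationError):
    """A required parent reference is missing; names the relationship."""

    def __init__(self, message: str, relationship: str | None = None):
        super().__init__(message)
        self.relationship = relationship


class TypeMismatchError(ValidationError):
    """An entity reference has the wrong entity type for its role."""


class DomainViolationError(ValidationError):
    """A statement does not fit the domain/range of its rule."""


class ImmutableAttributeError(ValidationError):
    """Attempt to set a system-assigned attribute (id, created, creator)."""


class NotFoundError(S3QLError):
    """A referenced entity instance does not exist (or is deprecated)."""


class ConflictError(S3QLError):
    """Duplicate registration of an identifier."""


class PermissionFormatError(S3QLError):
    """A permission state string is not three symbols over YSNysn-."""


class PermissionDenied(S3QLError):
    """An operation is blocked by the effective permission state."""

    def __init__(self, message: str, position: str | None = None):
        super().__init__(message)
        self.position = position


class ResolutionError(S3QLError):
    """A deployment identifier could not be dereferenced to a URL."""


class CycleError(ResolutionError):
    """Deployment qualification chain contains a cycle."""


class AuthenticationError(S3QLError):
    """User validation failed (token mismatch or tampering)."""


class TokenExpiredError(AuthenticationError):
    """The surrogate token's time-to-live has elapsed."""


class UnsupportedOperationError(S3QLError):
    """The operation is outside the supported fragment (e.g. SPARQL of a write)."""


class UnsupportedFragmentError(UnsupportedOperationError):
    """A SPARQL pattern falls outside the single-rule-predicate fragment."""
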