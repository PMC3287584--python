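"""Exception hierarchy.

Every error raised by the library derives from :class:`ProtrackError` so a
caller (notably the CLI) can map error classes onto exit statuses:
usage/validation problems, permission denials, data/format errors and
missing records are distinct branches.
"""


class ProtrackError(Exception):
    """Base class for all library errors."""


class NotFoundError(ProtrackError):
    """A referenced record (experiment, project, user, well ...) does not exist."""


class DuplicateError(ProtrackError):
    """A uniqueness constraint (project name, login, edge, well) was violated."""


class ValidationError(ProtrackError):
    """Input violates a model invariant (type/conditions mismatch, bad well ...)."""


class CycleError(ValidationError):
    """A provenance link would make the experiment graph cyclic."""


class PermissionDenied(ProtrackError):
    """The acting user may not perform the requested operation."""


class AuthenticationError(PermissionDenied):
    """Login failed; deliberately opaque about login-vs-password."""


class FormatError(ProtrackError):
    """An instrument file does not conform to its declared dialect."""


class UnsupportedFeatureError(FormatError):
    """A file uses a feature outside the supported dialect (names the feature)."""
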