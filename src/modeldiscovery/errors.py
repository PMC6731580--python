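"""Exception hierarchy.

Every error raised on a user-facing path derives from
:class:`ModelDiscoveryError` so the CLI can map failures to exit codes.
"""


class ModelDiscoveryError(Exception):
    """Base class for all package errors."""


class InvalidEntityError(ModelDiscoveryError):
    """A model entity is structurally invalid (empty file or component)."""


class MalformedUriError(ModelDiscoveryError):
    """An entity URI does not follow the ``file#component.variable`` scheme."""


class UnresolvedLabelError(ModelDiscoveryError):
    """A term URI has no label in the cache and remote lookup is unavailable."""

    def __init__(self, uri: str):
        super().__init__(f"no label available for term URI: {uri}")
        self.uri = uri


class AnnotationInvariantError(ModelDiscoveryError):
    """A composite annotation violates the type invariants."""


class ParseError(ModelDiscoveryError):
    """A document failed to parse; message carries file and position."""


class UnsupportedDialectError(ModelDiscoveryError):
    """An XML document is not in a supported CellML namespace."""


class NotFoundError(ModelDiscoveryError):
    """A requested entity, accession or resource does not exist."""


class RemoteServiceError(ModelDiscoveryError):
    """A remote endpoint call failed (network, HTTP or protocol error)."""


class InvalidInputError(ModelDiscoveryError):
    """Operation input violates a precondition (empty sequence, dup accession...)."""
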