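"""Exception hierarchy shared across the pipeline."""


class DegnetError(Exception):
    """Base class for all package errors."""


class ConfigError(DegnetError):
    """A simulation or run configuration violates its invariants."""


class FormatError(DegnetError):
    """A file does not conform to its declared on-disk schema."""


class SchemaError(DegnetError):
    """An in-memory table violates the invariants of its type."""


class ContrastError(DegnetError):
    """A requested condition is absent from the design."""


class NetworkError(DegnetError):
    """The gene-pathway network is empty or a graph-domain precondition fails."""


class PathCapExceeded(DegnetError):
    """Geodesic enumeration exceeded the configured cap."""


class NonIdentifiableError(DegnetError):
    """A dose-response fit has no finite maximum-likelihood solution."""
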