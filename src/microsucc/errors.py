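"""Exception types shared across the package."""


class MicrosuccError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MicrosuccError, ValueError):
    """Metadata or table violates the experimental schema (e.g. a sample
    present in the count table but missing from the metadata)."""


class ParseError(MicrosuccError, ValueError):
    """A file could not be parsed into a valid table or sequence set."""


class SimulationError(MicrosuccError, ValueError):
    """A synthetic-experiment specification is internally inconsistent."""
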