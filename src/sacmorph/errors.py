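"""Exception hierarchy shared across the package."""


class SacmorphError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SacmorphError, ValueError):
    """A generator or analysis parameter violates its contract."""


class GenerationError(SacmorphError, RuntimeError):
    """A synthetic-data generator could not satisfy its constraints."""


class DegenerateGeometryError(SacmorphError, ValueError):
    """Input geometry is too degenerate for the requested metric."""


class DegenerateProfileError(SacmorphError, ValueError):
    """An intensity profile carries no signal to normalize."""
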