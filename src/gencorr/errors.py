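"""Exception hierarchy shared across the package."""


class GencorrError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GencorrError):
    """A caller-supplied configuration (column map, option set) is invalid."""


class DataError(GencorrError):
    """Input data violate a structural invariant (duplicates, dimensions, emptiness)."""


class ParameterError(GencorrError):
    """Model parameters fall outside their admissible region."""


class FitError(GencorrError):
    """An optimisation failed to converge or produced no usable solution."""
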