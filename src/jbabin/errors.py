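"""Exception hierarchy shared across the package."""


class JbabinError(Exception):
    """Base class for all package-specific errors."""


class SpectraFormatError(JbabinError, ValueError):
    """Input file violates the expected layout (non-numeric or duplicate ppm header, ...)."""


class SpectraDataError(JbabinError, ValueError):
    """Data content is unusable (missing intensities, too few variables/samples, ...)."""


class ParameterError(JbabinError, ValueError):
    """An algorithm parameter is outside its admissible range."""


class DegenerateTestError(JbabinError, ValueError):
    """A statistical test cannot be computed (e.g. all paired differences are zero)."""
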