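"""Exception hierarchy shared across the package."""


class PcnslImmuneError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PcnslImmuneError):
    """A file does not conform to the expected tabular format."""


class ValidationError(PcnslImmuneError):
    """Parsed data violate a domain invariant (negative FPKM, bad event flag...)."""


class ConfigError(PcnslImmuneError):
    """A panel or simulation configuration is malformed."""


class AlignmentError(PcnslImmuneError):
    """Expression and clinical tables share no samples."""


class ConvergenceError(PcnslImmuneError):
    """An iterative fit failed to converge within its iteration budget."""
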