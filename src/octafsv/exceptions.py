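"""Exception hierarchy shared across the package."""


class OctaFsvError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(OctaFsvError, ValueError):
    """An input violates a documented precondition or contract."""


class DegenerateInputError(OctaFsvError, ValueError):
    """Input is formally valid but the requested statistic is undefined on it
    (e.g. zero total variance for an ICC, zero subject mean for a CV)."""
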