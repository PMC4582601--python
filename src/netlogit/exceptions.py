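"""Exception and warning types shared across the package."""


class NetlogitError(Exception):
    """Base class for all package-specific errors."""


class DataFormatError(NetlogitError, ValueError):
    """Malformed or inconsistent input data (exit code 2 in the CLI)."""


class NumericalError(NetlogitError, RuntimeError):
    """Optimization or numerical failure (exit code 3 in the CLI)."""


class SeparationWarning(UserWarning):
    """The logistic likelihood is (quasi-)separable; weights were capped."""
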