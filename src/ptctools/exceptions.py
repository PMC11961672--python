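"""Exception hierarchy shared across the package.

Data problems (malformed tables, impossible preconditions) raise
:class:`DataError`; optimizer failures raise :class:`ConvergenceError`.
The CLI maps DataError to exit code 1 and usage problems to exit code 2.
"""


class PtcToolsError(Exception):
    """Base class for all package-specific errors."""


class DataError(PtcToolsError, ValueError):
    """Invalid, inconsistent or degenerate input data."""


class ConvergenceError(PtcToolsError, RuntimeError):
    """A model fit failed to converge after all restarts."""
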