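"""Exception hierarchy shared across the pipeline.

The CLI maps these onto process exit codes: configuration problems exit 2,
degenerate data exits 3, fit non-convergence exits 4.
"""


class AnisopipeError(Exception):
    """Base class for all package errors."""


class ConfigError(AnisopipeError, ValueError):
    """Invalid configuration or contract violation in user input."""


class DegenerateDataError(AnisopipeError, ValueError):
    """Input data that cannot be processed (all-background frame, empty mask, ...)."""


class FitConvergenceError(AnisopipeError, RuntimeError):
    """A curve fit failed to converge after restarts."""
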