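"""Exception types shared across the package."""


class TadshiftError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(TadshiftError, ValueError):
    """A parameter violates its documented contract (e.g. bin_size <= 0)."""


class FormatError(TadshiftError, ValueError):
    """An on-disk file violates its dialect; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None, path=None):
        self.line_number = line_number
        self.path = path
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line_number is not None:
            loc += f":{line_number}"
        super().__init__(f"{loc}: {message}" if loc else message)


class ConvergenceError(TadshiftError, RuntimeError):
    """Iterative procedure failed to converge; carries the iteration count."""

    def __init__(self, message: str, iterations: int):
        self.iterations = iterations
        super().__init__(f"{message} (after {iterations} iterations)")


class InsufficientReplicationError(TadshiftError, ValueError):
    """A condition has fewer replicates than the test requires."""


class DependencyError(TadshiftError, RuntimeError):
    """A pipeline stage is missing an upstream intermediate; names the stage."""
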