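"""Exception hierarchy used across the toolkit."""


class RvflError(Exception):
    """Base class for all rvflkit errors."""


class ValidationError(RvflError, ValueError):
    """Invalid argument or malformed input data."""


class SolverError(RvflError, RuntimeError):
    """Closed-form solve failed (e.g. singular normal equations)."""


class TrainingError(RvflError, RuntimeError):
    """Iterative head training diverged or could not proceed."""


class ResourceError(RvflError, RuntimeError):
    """Requested model size exceeds the configured safety cap."""
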