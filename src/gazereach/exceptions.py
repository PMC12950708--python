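"""Exception hierarchy shared across the pipeline."""


class GazeReachError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GazeReachError):
    """Invalid or inconsistent configuration / parameters."""


class GenerationError(GazeReachError):
    """Constraint-satisfying design generation failed within the attempt budget."""


class ParseError(GazeReachError):
    """Malformed on-disk artifact (CSV/JSON) — message names the offending row."""


class ConvergenceError(GazeReachError):
    """Iterative estimator failed to converge; message carries diagnostics."""


class MissingArtifactError(GazeReachError):
    """A pipeline stage required an upstream artifact that was not found."""
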