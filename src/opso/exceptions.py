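"""Exception hierarchy shared across the package."""


class OPSOError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(OPSOError, ValueError):
    """Invalid parameter, bound, or run configuration."""


class DimensionError(OPSOError, ValueError):
    """Vector/matrix length mismatch."""


class ScheduleError(OPSOError, ValueError):
    """Iteration index outside the annealing schedule [0, t_max]."""


class EvaluationError(OPSOError, RuntimeError):
    """Objective or fitness evaluation failed (non-finite value, degenerate folds)."""


class FormatError(OPSOError, ValueError):
    """Malformed input file (dataset, metric table, or benchmark data file)."""
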