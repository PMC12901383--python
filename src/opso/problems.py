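"""Box-bounded minimization problems.

A :class:`BoundedProblem` is the single objective contract used by both
optimizers: a dimension, per-dimension finite bounds, and a point-wise
objective returning a finite scalar.  Built-in benchmarks additionally
provide a vectorized ``batch_objective`` evaluating a whole swarm at once;
the evaluation count is the same either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .exceptions import ConfigurationError, DimensionError, EvaluationError

__all__ = ["BoundedProblem"]


@dataclass
class BoundedProblem:
    """A box-bounded real objective to be minimized.

    Parameters
    ----------
    dimension : int
        Number of decision variables ``D``.
    lower, upper : array-like of shape (D,)
        Per-dimension bounds with ``lower[d] < upper[d]``.
    objective : callable
        Maps a length-``D`` vector to a finite scalar.
    name : str
        Label used in logs and result files.
    batch_objective : callable, optional
        Vectorized form mapping an ``(n, D)`` array to ``(n,)`` values.
        Must agree with ``objective`` point-wise.
    """

    dimension: int
    lower: np.ndarray
    upper: np.ndarray
    objective: Callable[[np.ndarray], float]
    name: str = ""
    batch_objective: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ConfigurationError(f"dimension must be >= 1, got {self.dimension}")
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if np.isscalar(self.lower) or self.lower.ndim == 0:
            self.lower = np.full(self.dimension, float(self.lower))
        if np.isscalar(self.upper) or self.upper.ndim == 0:
            self.upper = np.full(self.dimension, float(self.upper))
        if self.lower.shape != (self.dimension,) or self.upper.shape != (self.dimension,):
            raise ConfigurationError(
                f"bounds must have shape ({self.dimension},); "
                f"got {self.lower.shape} and {self.upper.shape}"
            )
        if not (np.isfinite(self.lower).all() and np.isfinite(self.upper).all()):
            raise ConfigurationError("bounds must be finite")
        if not np.all(self.lower < self.upper):
            bad = int(np.argmin(self.upper - self.lower))
            raise ConfigurationError(
                f"lower < upper violated at dimension {bad}: "
                f"[{self.lower[bad]}, {self.upper[bad]}]"
            )

    @property
    def width(self) -> np.ndarray:
        """Per-dimension box width ``upper - lower``."""
        return self.upper - self.lower

    def check_point(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.dimension,):
            raise DimensionError(
                f"point has shape {x.shape}, expected ({self.dimension},)"
            )
        return x

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Evaluate an ``(n, D)`` batch of points, validating finiteness.

        Raises
        ------
        EvaluationError
            If any objective value is non-finite, naming the offending point.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if points.shape[1] != self.dimension:
            raise DimensionError(
                f"points have dimension {points.shape[1]}, expected {self.dimension}"
            )
        if self.batch_objective is not None:
            values = np.asarray(self.batch_objective(points), dtype=float)
        else:
            values = np.array([float(self.objective(p)) for p in points])
        if not np.isfinite(values).all():
            bad = int(np.flatnonzero(~np.isfinite(values))[0])
            raise EvaluationError(
                f"objective '{self.name}' returned non-finite value "
                f"{values[bad]!r} at point {points[bad]!r}"
            )
        return values
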