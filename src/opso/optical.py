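"""The optical update operator.

This module simulates, purely mathematically, how a coherent optical device
would process particle-state information: the particle's current position,
personal best and global best are normalized to the unit box, concatenated,
and phase-encoded into a complex vector (amplitude = magnitude, phase =
2π-scaled value plus annealed Gaussian noise).  A fixed complex matrix
``W_opt`` — the first D rows of a Haar-random 3D×3D unitary, playing the role
of diffraction/interference in a linear optical medium — mixes the encoded
channels, a saturating nonlinearity models the response of a nonlinear
crystal, and the annealed real part of the output becomes the optical
displacement Δ_opt.  A decaying mixing ratio M_β blends Δ_opt (exploration)
with the classical cognitive/social delta (exploitation).

Because the rows of ``W_opt`` are orthonormal the mixing is non-expansive and
the saturation never amplifies, so ‖Δ_opt‖ is bounded by the annealing gain
times the box width — the operator perturbs, it cannot blow up the swarm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .exceptions import ConfigurationError, DimensionError, ScheduleError
from .problems import BoundedProblem

__all__ = [
    "OpticalConfig",
    "OpticalOperator",
    "normalize_state",
    "build_input_vector",
    "optical_noise",
    "encode_optical",
    "sample_unitary_rows",
    "optical_mix",
    "saturate",
    "optical_delta",
    "mixing_ratio",
    "combine_delta",
]


@dataclass
class OpticalConfig:
    """Knobs of the optical operator chain.

    Parameters
    ----------
    alpha : float
        Saturation strength α ≥ 0 in ``z / (1 + α|z|²)``.
    noise_hi, noise_lo : float
        Phase-noise standard deviation, linearly annealed σ₀ → σ₁ over the
        run (exploration early, convergence late). Requires σ₁ ≤ σ₀.
    delta_gain : float
        Gain A₀ of the annealing factor ``A(t) = A₀·(1 − t/t_max)`` applied
        to the real part of the saturated output.
    unitary_refresh : int or None
        If an integer, resample ``W_opt`` every that many iterations;
        ``None`` keeps one matrix per run (a fixed "device").
    saturation : {"divide", "literal"}
        ``"divide"`` is the saturating form ``z/(1+α|z|²)`` (a soft-limiting
        regularizer); ``"literal"`` is the amplifying form ``z·(1+α|z|²)``,
        kept as an explicit switch.
    delta_units : {"normalized", "box"}
        Units of the extracted Δ_opt.  ``"normalized"`` keeps the annealed
        real part as-is (a displacement on the unit-normalized state scale,
        independent of the box size); ``"box"`` additionally rescales by the
        per-dimension box width, which makes the kick proportional to the
        search range and is far more aggressive on wide boxes.
    """

    alpha: float = 1.0
    noise_hi: float = 0.1
    noise_lo: float = 0.01
    delta_gain: float = 0.5
    unitary_refresh: Optional[int] = None
    saturation: str = "divide"
    delta_units: str = "normalized"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ConfigurationError("alpha must be >= 0")
        if self.noise_hi < 0 or self.noise_lo < 0:
            raise ConfigurationError("noise levels must be >= 0")
        if self.noise_lo > self.noise_hi:
            raise ConfigurationError("noise_lo must be <= noise_hi")
        if self.delta_gain < 0:
            raise ConfigurationError("delta_gain must be >= 0")
        if self.saturation not in ("divide", "literal"):
            raise ConfigurationError(
                f"saturation must be 'divide' or 'literal', got {self.saturation!r}"
            )
        if self.unitary_refresh is not None and self.unitary_refresh < 1:
            raise ConfigurationError("unitary_refresh must be a positive integer or None")
        if self.delta_units not in ("normalized", "box"):
            raise ConfigurationError(
                f"delta_units must be 'normalized' or 'box', got {self.delta_units!r}"
            )


@dataclass
class OpticalOperator:
    """The fixed complex mixing matrix: D orthonormal rows of a Haar unitary."""

    W_opt: np.ndarray
    source_seed: int
    D: int

    def __post_init__(self) -> None:
        if self.W_opt.shape != (self.D, 3 * self.D):
            raise DimensionError(
                f"W_opt has shape {self.W_opt.shape}, expected ({self.D}, {3 * self.D})"
            )


def normalize_state(x: np.ndarray, problem: BoundedProblem) -> np.ndarray:
    """Min–max map of a point into [0, 1] by the problem box, clipping outside values."""
    x = np.asarray(x, dtype=float)
    width = problem.width
    if np.any(width <= 0):
        raise ConfigurationError("degenerate bounds: zero-width box")
    return np.clip((x - problem.lower) / width, 0.0, 1.0)


def build_input_vector(
    x: np.ndarray, pbest: np.ndarray, gbest: np.ndarray, problem: BoundedProblem
) -> np.ndarray:
    """Concatenate the normalized state vectors into the length-3D optical input."""
    x, pbest, gbest = (np.asarray(v, dtype=float) for v in (x, pbest, gbest))
    d = problem.dimension
    for v in (x, pbest, gbest):
        if v.shape != (d,):
            raise DimensionError(f"state vector has shape {v.shape}, expected ({d},)")
    return np.concatenate(
        [normalize_state(x, problem), normalize_state(pbest, problem), normalize_state(gbest, problem)]
    )


def noise_sigma(t: int, t_max: int, cfg: OpticalConfig) -> float:
    """Annealed phase-noise level σ(t) = σ₀ + (σ₁ − σ₀)·t/t_max."""
    _check_schedule(t, t_max)
    return cfg.noise_hi + (cfg.noise_lo - cfg.noise_hi) * (t / t_max)


def optical_noise(
    t: int, t_max: int, cfg: OpticalConfig, rng: np.random.Generator, size: int | tuple = None
) -> np.ndarray:
    """I.i.d. Gaussian phase-noise draws at the annealed level σ(t).

    ``size`` defaults to a single length-3 draw only when unspecified by the
    caller; the swarm loop passes ``(n_particles, 3D)``.
    """
    sigma = noise_sigma(t, t_max, cfg)
    if size is None:
        size = 3
    return rng.normal(0.0, sigma, size=size)


def encode_optical(in_r: np.ndarray, rn: np.ndarray) -> np.ndarray:
    """Phase-encode a real vector: ``|in_r| · exp(i·2π·(in_r + rn))``."""
    in_r = np.asarray(in_r, dtype=float)
    rn = np.asarray(rn, dtype=float)
    if in_r.shape != rn.shape:
        raise DimensionError(f"shape mismatch: {in_r.shape} vs {rn.shape}")
    return np.abs(in_r) * np.exp(1j * 2.0 * np.pi * (in_r + rn))


def sample_unitary_rows(D: int, seed: int) -> OpticalOperator:
    """Draw ``W_opt``: the first D rows of a Haar-random 3D×3D unitary.

    Haar sampling uses QR orthonormalization of a complex standard-Gaussian
    matrix with the standard phase correction (multiplying each column of Q
    by the unit phase of the corresponding diagonal entry of R).
    """
    if D < 1:
        raise ConfigurationError("D must be >= 1")
    rng = np.random.default_rng(seed)
    m = 3 * D
    G = (rng.standard_normal((m, m)) + 1j * rng.standard_normal((m, m))) / np.sqrt(2.0)
    Q, R = np.linalg.qr(G)
    diag = np.diagonal(R)
    Q = Q * (diag / np.abs(diag))
    return OpticalOperator(W_opt=Q[:D, :].copy(), source_seed=int(seed), D=int(D))


def optical_mix(op: OpticalOperator, opt_in: np.ndarray) -> np.ndarray:
    """Linear optical mixing ``z = W_opt · Opt_in`` (non-expansive)."""
    opt_in = np.asarray(opt_in)
    if opt_in.shape[-1] != 3 * op.D:
        raise DimensionError(
            f"optical input has length {opt_in.shape[-1]}, expected {3 * op.D}"
        )
    return opt_in @ op.W_opt.T


def saturate(z: np.ndarray, alpha: float, mode: str = "divide") -> np.ndarray:
    """Nonlinear saturation of the mixed signal.

    The default ``"divide"`` form ``z / (1 + α|z|²)`` never amplifies
    (|out| ≤ |z| for α ≥ 0) and soft-limits large components while passing
    small ones through linearly.  The ``"literal"`` form ``z·(1 + α|z|²)``
    amplifies instead and is kept only as an explicit configuration switch.
    """
    if alpha < 0:
        raise ConfigurationError("alpha must be >= 0")
    z = np.asarray(z)
    mag2 = np.abs(z) ** 2
    if mode == "divide":
        return z / (1.0 + alpha * mag2)
    if mode == "literal":
        return z * (1.0 + alpha * mag2)
    raise ConfigurationError(f"unknown saturation mode {mode!r}")


def annealing_factor(t: int, t_max: int, delta_gain: float) -> float:
    """Gain A(t) = A₀·(1 − t/t_max) applied to the real part of the output."""
    _check_schedule(t, t_max)
    return delta_gain * (1.0 - t / t_max)


def optical_delta(
    z_nl: np.ndarray,
    t: int,
    t_max: int,
    cfg: OpticalConfig,
    problem: BoundedProblem,
) -> np.ndarray:
    """Extract Δ_opt: the annealed real part of the saturated output.

    With ``cfg.delta_units == "normalized"`` (default) the delta is
    ``A(t)·Re(z_nl)`` exactly; with ``"box"`` it is further multiplied by
    the per-dimension box width, scaling the kick to the search range.
    """
    a = annealing_factor(t, t_max, cfg.delta_gain)
    d = a * np.real(z_nl)
    if cfg.delta_units == "box":
        d = d * problem.width
    return d


def mixing_ratio(t: int, t_max: int, mbeta0: float = 0.9) -> float:
    """Decaying optical mixing ratio ``M_β(t) = M_β0 · (1 − t/t_max)``."""
    _check_schedule(t, t_max)
    return mbeta0 * (1.0 - t / t_max)


def combine_delta(delta_opt: np.ndarray, delta_c: np.ndarray, m_beta: float) -> np.ndarray:
    """Convex blend ``Δ_Co = M_β·Δ_opt + (1 − M_β)·Δ_C``."""
    delta_opt = np.asarray(delta_opt, dtype=float)
    delta_c = np.asarray(delta_c, dtype=float)
    if delta_opt.shape != delta_c.shape:
        raise DimensionError(f"shape mismatch: {delta_opt.shape} vs {delta_c.shape}")
    if not 0.0 <= m_beta <= 1.0:
        raise ConfigurationError(f"m_beta must be in [0, 1], got {m_beta}")
    return m_beta * delta_opt + (1.0 - m_beta) * delta_c


def _check_schedule(t: int, t_max: int) -> None:
    if t_max < 1:
        raise ScheduleError("t_max must be >= 1")
    if not 0 <= t <= t_max:
        raise ScheduleError(f"iteration t={t} outside schedule [0, {t_max}]")
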