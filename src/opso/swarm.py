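"""Classical PSO baseline and the OPSO outer loop.

The baseline follows the canonical velocity rule

    v ← w·v + c1·r1∘(pbest − x) + c2·r2∘(gbest − x),    x ← x + v

with a linearly decreasing inertia weight.  OPSO replaces the raw
cognitive/social delta by an adaptive blend of that classical delta with an
optical delta (see :mod:`opso.optical`), damped by a constriction factor:

    Δ_C  = C1·r1∘(pbest − x) + C2·r2∘(gbest − x)
    Δ_Co = M_β(t)·Δ_opt + (1 − M_β(t))·Δ_C
    v    = χ(φ)·(w(t)·v + Δ_Co),        x ← x + v

with boundary absorption (clamp to the violated bound, zero that velocity
component) and occasional reseeding (probability p per particle per
iteration, never applied to the particle holding the global best).

Randomness protocol (this fixes bit-level reproducibility): one PCG64
generator per run; per iteration the draws are, in order, r1 then r2 as
(N, D) blocks, then — only when the optical path is enabled (mbeta0 > 0) —
the (N, 3D) phase-noise block, then — only when reseed_p > 0 — one uniform
per particle followed by an (N, D) block of replacement positions.  With
``mbeta0 = 0`` the optical path consumes no randomness, so an OPSO run is
draw-for-draw identical to a constricted classical PSO.
"""

from __future__ import annotations

import cmath
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .exceptions import ConfigurationError, DimensionError, ScheduleError
from .optical import (
    OpticalConfig,
    combine_delta,
    encode_optical,
    mixing_ratio,
    noise_sigma,
    optical_delta,
    optical_mix,
    sample_unitary_rows,
    saturate,
)
from .problems import BoundedProblem

__all__ = [
    "Particle",
    "SwarmState",
    "PSOParams",
    "OPSOParams",
    "OptimizationResult",
    "initialize_swarm",
    "classical_delta",
    "constriction_factor",
    "inertia_weight",
    "velocity_update",
    "position_update",
    "apply_boundary_absorption",
    "maybe_reseed",
    "run_pso",
    "run_opso",
]


@dataclass
class Particle:
    """One swarm member: position, velocity, and personal-best memory."""

    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float


@dataclass
class SwarmState:
    """Vectorized swarm state; row i of each array belongs to particle i."""

    positions: np.ndarray          # (N, D)
    velocities: np.ndarray         # (N, D)
    pbest_positions: np.ndarray    # (N, D)
    pbest_fitness: np.ndarray      # (N,)
    gbest_position: np.ndarray     # (D,)
    gbest_fitness: float
    iteration: int
    t_max: int
    rng: np.random.Generator
    history: list = field(default_factory=list)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def particle(self, i: int) -> Particle:
        return Particle(
            position=self.positions[i].copy(),
            velocity=self.velocities[i].copy(),
            pbest_position=self.pbest_positions[i].copy(),
            pbest_fitness=float(self.pbest_fitness[i]),
        )


@dataclass
class PSOParams:
    """Baseline PSO settings: c1 = c2 = 2.0, inertia 0.9 → 0.4 linearly."""

    population: int = 100
    t_max: int = 1000
    c1: float = 2.0
    c2: float = 2.0
    w_hi: float = 0.9
    w_lo: float = 0.4

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ConfigurationError("population must be >= 2")
        if self.t_max < 0:
            raise ConfigurationError("t_max must be >= 0")


@dataclass
class OPSOParams:
    """OPSO settings.

    ``C1 = C2 = 2.05`` matches the constriction literature; ``phi_stability``
    is the separate stability parameter of the constriction factor, fixed at
    2.05.  ``chi_mode`` selects how χ(φ) treats a negative discriminant:
    ``"complex"`` evaluates the square root in the complex domain and takes
    the modulus (giving χ(2.05) = 1 exactly), ``"real"`` is the classical
    real-arithmetic Clerc formula requiring φ ≥ 4.
    """

    population: int = 100
    t_max: int = 1000
    C1: float = 2.05
    C2: float = 2.05
    phi_stability: float = 2.05
    w_hi: float = 0.7
    w_lo: float = 0.3
    mbeta0: float = 0.9
    reseed_p: float = 0.03
    chi_mode: str = "complex"
    optical: OpticalConfig = field(default_factory=OpticalConfig)

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ConfigurationError("population must be >= 2")
        if self.t_max < 0:
            raise ConfigurationError("t_max must be >= 0")
        if not 0.0 <= self.reseed_p <= 1.0:
            raise ConfigurationError("reseed_p must be in [0, 1]")
        if not 0.0 <= self.w_lo <= self.w_hi:
            raise ConfigurationError("need 0 <= w_lo <= w_hi")
        if not 0.0 <= self.mbeta0 <= 1.0:
            raise ConfigurationError("mbeta0 must be in [0, 1]")
        if self.C1 < 0 or self.C2 < 0:
            raise ConfigurationError("C1, C2 must be >= 0")
        if self.chi_mode not in ("complex", "real"):
            raise ConfigurationError("chi_mode must be 'complex' or 'real'")


@dataclass
class OptimizationResult:
    """Outcome of one seeded run."""

    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray            # gbest fitness after each iteration, length t_max
    evaluations: int
    seed: int


def initialize_swarm(problem: BoundedProblem, n: int, seed: int, t_max: int = 1,
                     init_positions: Optional[np.ndarray] = None) -> SwarmState:
    """Uniform positions in the box, zero velocities, pbest = initial position.

    ``init_positions`` optionally overrides the first rows of the initial
    swarm (used by the feature-selection wrapper to guarantee the all-ones
    mask is always considered).
    """
    if n < 2:
        raise ConfigurationError("swarm size must be >= 2")
    rng = np.random.default_rng(seed)
    positions = rng.uniform(problem.lower, problem.upper, size=(n, problem.dimension))
    if init_positions is not None:
        init_positions = np.atleast_2d(np.asarray(init_positions, dtype=float))
        if init_positions.shape[1] != problem.dimension:
            raise DimensionError("init_positions dimension mismatch")
        k = min(len(init_positions), n)
        positions[:k] = np.clip(init_positions[:k], problem.lower, problem.upper)
    velocities = np.zeros_like(positions)
    fitness = problem.evaluate(positions)
    best = int(np.argmin(fitness))
    return SwarmState(
        positions=positions,
        velocities=velocities,
        pbest_positions=positions.copy(),
        pbest_fitness=fitness.copy(),
        gbest_position=positions[best].copy(),
        gbest_fitness=float(fitness[best]),
        iteration=0,
        t_max=t_max,
        rng=rng,
        history=[],
    )


def classical_delta(x: np.ndarray, pb: np.ndarray, pg: np.ndarray,
                    C1: float, C2: float, rng: np.random.Generator) -> np.ndarray:
    """Cognitive/social delta ``C1·r1∘(pb−x) + C2·r2∘(pg−x)``.

    r1 and r2 are fresh element-wise uniform(0,1) vectors.  Also accepts
    (N, D) blocks, in which case r1 is drawn as one (N, D) block before r2.
    """
    x, pb = np.asarray(x, float), np.asarray(pb, float)
    pg = np.asarray(pg, float)
    if x.shape != pb.shape or x.shape[-1] != pg.shape[-1]:
        raise DimensionError(f"shape mismatch: {x.shape}, {pb.shape}, {pg.shape}")
    if C1 < 0 or C2 < 0:
        raise ConfigurationError("C1, C2 must be >= 0")
    r1 = rng.random(x.shape)
    r2 = rng.random(x.shape)
    return C1 * r1 * (pb - x) + C2 * r2 * (pg - x)


def constriction_factor(phi: float, mode: str = "complex") -> float:
    """Constriction factor χ = 2 / |2 − φ − √(φ² − 4φ)|.

    For φ < 4 the discriminant is negative; in ``"complex"`` mode the square
    root is evaluated in the complex domain and the modulus of the whole
    denominator taken (χ(2.05) = 1 exactly, since |2−2.05−i·√3.9975| = 2).
    ``"real"`` mode is the classical Clerc formula and requires φ ≥ 4.
    """
    disc = phi * phi - 4.0 * phi
    if mode == "real":
        if disc < 0:
            raise ConfigurationError(
                f"real-arithmetic constriction requires phi >= 4, got {phi}"
            )
        denom = abs(2.0 - phi - np.sqrt(disc))
    elif mode == "complex":
        denom = abs(2.0 - phi - cmath.sqrt(complex(disc)))
    else:
        raise ConfigurationError(f"unknown chi mode {mode!r}")
    if denom == 0.0:
        raise ConfigurationError(f"degenerate stability parameter phi={phi}")
    return 2.0 / denom


def inertia_weight(t: int, t_max: int, w_hi: float, w_lo: float) -> float:
    """Linear inertia schedule ``w(t) = w_hi + (w_lo − w_hi)·t/t_max``."""
    if t_max < 1:
        raise ScheduleError("t_max must be >= 1")
    if not 0 <= t <= t_max:
        raise ScheduleError(f"iteration t={t} outside schedule [0, {t_max}]")
    return w_hi + (w_lo - w_hi) * (t / t_max)


def velocity_update(v: np.ndarray, delta_co: np.ndarray, w: float, chi: float) -> np.ndarray:
    """New velocity ``χ·(w·v + Δ_Co)``; no clamping here."""
    v = np.asarray(v, float)
    delta_co = np.asarray(delta_co, float)
    if v.shape != delta_co.shape:
        raise DimensionError(f"shape mismatch: {v.shape} vs {delta_co.shape}")
    if not (np.isfinite(v).all() and np.isfinite(delta_co).all()):
        raise ConfigurationError("non-finite velocity input")
    return chi * (w * v + delta_co)


def position_update(x: np.ndarray, v_new: np.ndarray) -> np.ndarray:
    """Element-wise ``x + v_new``."""
    x = np.asarray(x, float)
    v_new = np.asarray(v_new, float)
    if x.shape != v_new.shape:
        raise DimensionError(f"shape mismatch: {x.shape} vs {v_new.shape}")
    return x + v_new


def apply_boundary_absorption(x: np.ndarray, v: np.ndarray,
                              problem: BoundedProblem) -> tuple[np.ndarray, np.ndarray]:
    """Absorbing walls: clamp out-of-bounds coordinates, zero their velocity."""
    x = np.asarray(x, float)
    v = np.asarray(v, float)
    if x.shape != v.shape or x.shape[-1] != problem.dimension:
        raise DimensionError("position/velocity shape mismatch with problem dimension")
    out = (x < problem.lower) | (x > problem.upper)
    x_new = np.clip(x, problem.lower, problem.upper)
    v_new = np.where(out, 0.0, v)
    return x_new, v_new


def maybe_reseed(particle: Particle, problem: BoundedProblem, p: float,
                 rng: np.random.Generator) -> Particle:
    """With probability p: redraw position uniform-in-bounds, zero velocity.

    Personal-best memory is retained either way (elitism is preserved at the
    swarm level by never reseeding the gbest holder — enforced in the run
    loops, not here).
    """
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError("reseed probability must be in [0, 1]")
    if p > 0.0 and rng.random() < p:
        return Particle(
            position=rng.uniform(problem.lower, problem.upper, problem.dimension),
            velocity=np.zeros(problem.dimension),
            pbest_position=particle.pbest_position.copy(),
            pbest_fitness=particle.pbest_fitness,
        )
    return particle


def _update_bests(state: SwarmState, fitness: np.ndarray) -> None:
    improved = fitness < state.pbest_fitness
    state.pbest_positions[improved] = state.positions[improved]
    state.pbest_fitness[improved] = fitness[improved]
    best = int(np.argmin(state.pbest_fitness))
    if state.pbest_fitness[best] < state.gbest_fitness:
        state.gbest_fitness = float(state.pbest_fitness[best])
        state.gbest_position = state.pbest_positions[best].copy()


def _reseed_sweep(state: SwarmState, problem: BoundedProblem, p: float) -> None:
    """Vectorized reseeding sweep; skips the particle holding the global best."""
    if p <= 0.0:
        return
    n = state.n_particles
    u = state.rng.random(n)
    replacement = state.rng.uniform(problem.lower, problem.upper,
                                    size=(n, problem.dimension))
    mask = u < p
    gbest_holder = int(np.argmin(state.pbest_fitness))
    mask[gbest_holder] = False
    state.positions[mask] = replacement[mask]
    state.velocities[mask] = 0.0


def _finalize(state: SwarmState, problem: BoundedProblem, params, seed: int) -> OptimizationResult:
    return OptimizationResult(
        best_position=state.gbest_position.copy(),
        best_fitness=float(state.gbest_fitness),
        history=np.asarray(state.history, dtype=float),
        evaluations=params.population * (params.t_max + 1),
        seed=int(seed),
    )


def run_pso(problem: BoundedProblem, params: PSOParams, seed: int,
            init_positions: Optional[np.ndarray] = None) -> OptimizationResult:
    """Baseline PSO with linearly decreasing inertia and absorbing walls."""
    state = initialize_swarm(problem, params.population, seed,
                             t_max=max(params.t_max, 1), init_positions=init_positions)
    for t in range(params.t_max):
        w = inertia_weight(t, params.t_max, params.w_hi, params.w_lo)
        delta = classical_delta(state.positions, state.pbest_positions,
                                state.gbest_position, params.c1, params.c2, state.rng)
        state.velocities = w * state.velocities + delta
        state.positions = position_update(state.positions, state.velocities)
        state.positions, state.velocities = apply_boundary_absorption(
            state.positions, state.velocities, problem)
        fitness = problem.evaluate(state.positions)
        _update_bests(state, fitness)
        state.iteration = t + 1
        state.history.append(state.gbest_fitness)
    return _finalize(state, problem, params, seed)


def run_opso(problem: BoundedProblem, params: OPSOParams, seed: int,
             init_positions: Optional[np.ndarray] = None) -> OptimizationResult:
    """OPSO: hybrid optical/classical velocity update with constriction.

    When ``mbeta0 == 0`` the optical path is disabled entirely (no mixing
    matrix is sampled and no phase noise is drawn), which makes the run
    draw-for-draw identical to a constricted classical PSO.
    """
    state = initialize_swarm(problem, params.population, seed,
                             t_max=max(params.t_max, 1), init_positions=init_positions)
    chi = constriction_factor(params.phi_stability, params.chi_mode)
    cfg = params.optical
    optical_on = params.mbeta0 > 0.0
    op = None
    if optical_on:
        op_seed = int(state.rng.integers(2**31))
        op = sample_unitary_rows(problem.dimension, op_seed)

    width = problem.width
    for t in range(params.t_max):
        delta_c = classical_delta(state.positions, state.pbest_positions,
                                  state.gbest_position, params.C1, params.C2, state.rng)
        if optical_on:
            if cfg.unitary_refresh is not None and t > 0 and t % cfg.unitary_refresh == 0:
                op_seed = int(state.rng.integers(2**31))
                op = sample_unitary_rows(problem.dimension, op_seed)
            norm = (state.positions - problem.lower) / width
            norm_pb = (state.pbest_positions - problem.lower) / width
            norm_g = (state.gbest_position - problem.lower) / width
            in_r = np.concatenate(
                [np.clip(norm, 0, 1), np.clip(norm_pb, 0, 1),
                 np.broadcast_to(np.clip(norm_g, 0, 1),
                                 norm.shape).copy()], axis=1)
            sigma = noise_sigma(t, params.t_max, cfg)
            rn = state.rng.normal(0.0, sigma, size=in_r.shape)
            opt_in = encode_optical(in_r, rn)
            z = optical_mix(op, opt_in)
            z_nl = saturate(z, cfg.alpha, cfg.saturation)
            d_opt = optical_delta(z_nl, t, params.t_max, cfg, problem)
            m_beta = mixing_ratio(t, params.t_max, params.mbeta0)
            delta_co = combine_delta(d_opt, delta_c, m_beta)
        else:
            delta_co = delta_c
        w = inertia_weight(t, params.t_max, params.w_hi, params.w_lo)
        state.velocities = velocity_update(state.velocities, delta_co, w, chi)
        state.positions = position_update(state.positions, state.velocities)
        state.positions, state.velocities = apply_boundary_absorption(
            state.positions, state.velocities, problem)
        _reseed_sweep(state, problem, params.reseed_p)
        fitness = problem.evaluate(state.positions)
        _update_bests(state, fitness)
        state.iteration = t + 1
        state.history.append(state.gbest_fitness)
    return _finalize(state, problem, params, seed)
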