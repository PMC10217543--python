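"""Continuous grasshopper optimization (GOA).

The swarm model: each grasshopper is a point in a box-bounded search
space, pulled by a signed pairwise *social force* — repulsive at short
range, attractive at medium range, vanishing at long range — and
anchored to the best position found so far (the *target*).  A comfort
coefficient ``c`` decays linearly over iterations, shrinking the
comfort zone so the swarm moves from exploration to exploitation.

The position update for grasshopper ``i`` in dimension ``d`` is::

    x_i^d <- c * sum_{j != i}  c * (ub_d - lb_d)/2 * S(m(d_ij)) * (x_j^d - x_i^d)/d_ij  +  T^d

where ``S(r) = f*exp(-r/l) - exp(-r)`` is the social-force function,
``d_ij`` the Euclidean distance between grasshoppers ``i`` and ``j``,
``m`` an affine per-iteration rescaling of the pairwise distances onto
[1, 4] (``S`` saturates toward zero past r ~ 10, so raw distances in
large boxes would exert no force), and ``T`` the target position.
New positions are clamped to the box.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger("goafs")

__all__ = [
    "GoaConfig",
    "SwarmState",
    "social_force",
    "comfort_coefficient",
    "map_distance",
    "update_positions",
    "optimize",
]

#: Comfort distance printed for the default parameters f=0.5, l=1.5:
#: the unique positive root of S, equal to 3*ln(2) ~= 2.0794.
COMFORT_DISTANCE_DEFAULT = 3.0 * np.log(2.0)


@dataclass(frozen=True)
class GoaConfig:
    """Parameters of the grasshopper optimizer.

    Attributes
    ----------
    population_size : int
        Number of grasshoppers N (>= 1; N == 1 degenerates to
        target-copy since the pairwise sum is empty).
    max_iterations : int
        Number of position updates L.
    attraction_intensity : float
        Intensity f of the attractive exponential in S (default 0.5).
    attractive_length_scale : float
        Length scale l of the attractive exponential (default 1.5).
    c_max, c_min : float
        Endpoints of the linearly decaying comfort coefficient.
    lower_bounds, upper_bounds : array-like of float
        Per-dimension box bounds; equal length defines the problem
        dimension D.
    distance_map_range : (float, float)
        Interval onto which pairwise distances are rescaled each
        iteration before evaluating S (default (1, 4)).
    epsilon_distance : float
        Below this separation two grasshoppers are treated as
        coincident and the unit vector between them is replaced by a
        seeded random direction.
    seed : int
        Seed for the single random stream (initialization and
        coincidence tie-breaks, consumed in that order).
    """

    population_size: int = 25
    max_iterations: int = 80
    attraction_intensity: float = 0.5
    attractive_length_scale: float = 1.5
    c_max: float = 1.0
    c_min: float = 1e-5
    lower_bounds: Sequence[float] = (0.0,)
    upper_bounds: Sequence[float] = (1.0,)
    distance_map_range: tuple[float, float] = (1.0, 4.0)
    epsilon_distance: float = 1e-12
    seed: int = 0

    def __post_init__(self) -> None:
        lb = np.asarray(self.lower_bounds, dtype=float)
        ub = np.asarray(self.upper_bounds, dtype=float)
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not (self.attraction_intensity > 0):
            raise ValueError("attraction_intensity f must be > 0")
        if not (self.attractive_length_scale > 0):
            raise ValueError("attractive_length_scale l must be > 0")
        if not (self.c_max > self.c_min > 0):
            raise ValueError("require c_max > c_min > 0")
        if lb.shape != ub.shape or lb.ndim != 1:
            raise ValueError("bounds must be 1-D vectors of equal length")
        if not np.all(lb < ub):
            raise ValueError("every lower bound must be < its upper bound")
        lo, hi = self.distance_map_range
        if not lo < hi:
            raise ValueError("distance_map_range must be an increasing pair")
        object.__setattr__(self, "lower_bounds", tuple(lb))
        object.__setattr__(self, "upper_bounds", tuple(ub))

    @property
    def dimension(self) -> int:
        return len(self.lower_bounds)

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.asarray(self.lower_bounds, dtype=float),
            np.asarray(self.upper_bounds, dtype=float),
        )


@dataclass
class SwarmState:
    """The GOA iterate: positions, fitnesses, and best-so-far target."""

    positions: np.ndarray          # (N, D)
    fitness_values: np.ndarray     # (N,)
    target_position: np.ndarray    # (D,)
    target_fitness: float
    iteration_index: int = 0

    def copy(self) -> "SwarmState":
        return SwarmState(
            self.positions.copy(),
            self.fitness_values.copy(),
            self.target_position.copy(),
            float(self.target_fitness),
            self.iteration_index,
        )


def social_force(
    r: float | np.ndarray,
    f: float = 0.5,
    l: float = 1.5,
) -> float | np.ndarray:
    """Signed social force S(r) = f*exp(-r/l) - exp(-r) at distance r.

    Negative inside the repulsion zone (0, 3*ln 2 for the defaults),
    zero at the comfort distance, positive in the attraction zone, and
    decaying toward zero at large r.  Vectorized over ``r``.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ValueError("distance r must be non-negative")
    if not (f > 0 and l > 0):
        raise ValueError("require f > 0 and l > 0")
    out = f * np.exp(-r_arr / l) - np.exp(-r_arr)
    return float(out) if np.isscalar(r) or r_arr.ndim == 0 else out


def comfort_coefficient(current_iteration: int, cfg: GoaConfig) -> float:
    """Linearly decaying comfort coefficient.

    c = c_max - t * (c_max - c_min) / L for t in [0, L]; c(0) = c_max
    and c(L) = c_min exactly.
    """
    L = cfg.max_iterations
    if not 0 <= current_iteration <= L:
        raise ValueError(
            f"iteration {current_iteration} outside schedule range [0, {L}]"
        )
    # convex combination keeps both endpoints exact in floating point
    frac = current_iteration / L
    return (1.0 - frac) * cfg.c_max + frac * cfg.c_min


def map_distance(
    d_ij: float | np.ndarray,
    d_min: float,
    d_max: float,
    mapped_range: tuple[float, float] = (1.0, 4.0),
) -> float | np.ndarray:
    """Affinely rescale pairwise distances onto ``mapped_range``.

    ``d_min``/``d_max`` are the swarm's smallest and largest pairwise
    distances this iteration, mapped to the range endpoints.  If all
    distances coincide (d_max == d_min) every distance maps to the
    midpoint of the range.
    """
    lo, hi = mapped_range
    d = np.asarray(d_ij, dtype=float)
    span = d_max - d_min
    if span <= 0:
        out = np.full_like(d, 0.5 * (lo + hi))
    else:
        out = lo + (d - d_min) * (hi - lo) / span
    return float(out) if np.isscalar(d_ij) or d.ndim == 0 else out


def _social_sum(
    positions: np.ndarray,
    c: float,
    cfg: GoaConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inner c-scaled pairwise social term of the update, per grasshopper."""
    n, dim = positions.shape
    lb, ub = cfg.bounds_arrays()
    half_width = (ub - lb) / 2.0

    diff = positions[None, :, :] - positions[:, None, :]   # x_j - x_i
    dist = np.sqrt((diff ** 2).sum(axis=2))                # (N, N)

    # coincident pairs: substitute a seeded random unit direction
    coincident = (dist < cfg.epsilon_distance) & ~np.eye(n, dtype=bool)
    unit = np.zeros_like(diff)
    safe = dist > 0
    unit[safe] = diff[safe] / dist[safe][:, None]
    if coincident.any():
        idx = np.argwhere(coincident)
        for i, j in idx:
            if i < j:  # antisymmetric substitution per unordered pair
                v = rng.standard_normal(dim)
                v /= np.linalg.norm(v)
                unit[i, j] = v
                unit[j, i] = -v

    off = ~np.eye(n, dtype=bool)
    if off.any():
        d_off = dist[off]
        mapped = np.zeros_like(dist)
        mapped[off] = map_distance(
            d_off, float(d_off.min()), float(d_off.max()), cfg.distance_map_range
        )
    else:
        mapped = dist
    force = social_force(
        mapped, cfg.attraction_intensity, cfg.attractive_length_scale
    )
    force = np.where(off, force, 0.0)

    # sum_j c * (ub-lb)/2 * S(m(d_ij)) * unit_ij, per dimension
    return c * np.einsum("ij,d,ijd->id", force, half_width, unit)


def update_positions(
    state: SwarmState,
    c: float,
    cfg: GoaConfig,
    objective: Callable[[np.ndarray], float],
    rng: np.random.Generator,
) -> SwarmState:
    """One swarm step: social sum + target anchor, clamp, re-evaluate.

    The target (best-so-far) is updated after re-evaluation, so the
    target fitness never increases.
    """
    lb, ub = cfg.bounds_arrays()
    social = _social_sum(state.positions, c, cfg, rng)
    new_positions = c * social + state.target_position[None, :]
    np.clip(new_positions, lb, ub, out=new_positions)

    new_fitness = _evaluate_all(objective, new_positions)

    best_i = int(np.argmin(new_fitness))
    if new_fitness[best_i] < state.target_fitness:
        target = new_positions[best_i].copy()
        target_fitness = float(new_fitness[best_i])
    else:
        target = state.target_position.copy()
        target_fitness = float(state.target_fitness)

    return SwarmState(
        positions=new_positions,
        fitness_values=new_fitness,
        target_position=target,
        target_fitness=target_fitness,
        iteration_index=state.iteration_index + 1,
    )


def _evaluate_all(
    objective: Callable[[np.ndarray], float], positions: np.ndarray
) -> np.ndarray:
    values = np.empty(len(positions))
    for i, x in enumerate(positions):
        v = float(objective(x))
        if not np.isfinite(v):
            raise FloatingPointError(
                f"objective returned non-finite value {v!r} at position {x.tolist()}"
            )
        values[i] = v
    return values


def optimize(
    objective: Callable[[np.ndarray], float],
    cfg: GoaConfig,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Run the grasshopper optimizer.

    Initializes the swarm uniformly in the box with ``cfg.seed``, then
    performs ``cfg.max_iterations`` updates under the decaying comfort
    coefficient.

    Returns
    -------
    best_position : ndarray of shape (D,)
    best_fitness : float
    trace : ndarray of shape (L + 1,)
        Best-so-far fitness after initialization and after each
        iteration; non-increasing by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    lb, ub = cfg.bounds_arrays()
    n, L = cfg.population_size, cfg.max_iterations

    positions = rng.uniform(lb, ub, size=(n, len(lb)))
    fitness = _evaluate_all(objective, positions)
    best_i = int(np.argmin(fitness))
    state = SwarmState(
        positions=positions,
        fitness_values=fitness,
        target_position=positions[best_i].copy(),
        target_fitness=float(fitness[best_i]),
    )

    trace = np.empty(L + 1)
    trace[0] = state.target_fitness
    for t in range(1, L + 1):
        c = comfort_coefficient(t, cfg)
        state = update_positions(state, c, cfg, objective, rng)
        trace[t] = state.target_fitness
    logger.debug(
        "GOA finished: best fitness %.6g after %d iterations", state.target_fitness, L
    )
    return state.target_position.copy(), state.target_fitness, trace
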