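"""Explicit finite-difference scheme for the time-fractional tumor model.

The model is a one-dimensional reaction-diffusion equation

    D_t^alpha u = u_xx - k(x, t) u,      0 < alpha <= 1,

on [0, L] x [0, T], where D_t^alpha is the Caputo derivative of order
alpha and k is the net killing rate of tumor cells.  The Caputo
derivative is discretized by the L1-type sum with memory weights

    b_j = (j+1)^(1-alpha) - j^(1-alpha),

the Laplacian by centered differences at the current level, and the
reaction term explicitly.  With rho = dt^alpha * Gamma(2-alpha) and the
diffusion number s = rho / dx^2 the update for an interior node reads

    u_i^{n+1} = s (u_{i+1}^n + u_{i-1}^n) + (1 - 2s) u_i^n
                - rho k(x_i, t_n) u_i^n
                - sum_{j=1}^{n} b_j (u_i^{n+1-j} - u_i^{n-j}).

An algebraically identical regrouped form folds the telescoping memory
sum into per-level coefficients; both are provided and the solver uses
the regrouped one.  At alpha = 1 all b_j vanish and the scheme reduces
to classical FTCS with an explicit reaction term.

Fuzzy problems are solved by evaluating every fuzzy coefficient at each
(r, beta) sample of the double parametric form and running the crisp
solver per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gamma

from .fuzzy_param import FuzzyCoefficientField, band_is_valid

__all__ = [
    "GridSpec",
    "CaputoWeights",
    "SchemeCoefficients",
    "ModelSpec",
    "FuzzyModelSpec",
    "CrispSolutionGrid",
    "FuzzySolutionBundle",
    "caputo_weights",
    "scheme_coefficients",
    "explicit_step",
    "explicit_step_regrouped",
    "solve_crisp",
    "solve_fuzzy",
]

#: relative tolerance for "this point coincides with a grid node"
NODE_TOL = 1e-9


@dataclass(frozen=True)
class GridSpec:
    """Space/time discretization plus the fractional order.

    Parameters
    ----------
    L, T : float
        Domain length and final time (space/time units of the model).
    dx, dt : float
        Space and time steps; L/dx and T/dt must be whole numbers.
    alpha : float
        Caputo fractional order, in (0, 1].
    """

    L: float
    T: float
    dx: float
    dt: float
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if self.dx <= 0 or self.dt <= 0:
            raise ValueError("dx and dt must be positive")
        for total, step, name in ((self.L, self.dx, "L/dx"), (self.T, self.dt, "T/dt")):
            ratio = total / step
            if abs(ratio - round(ratio)) > 1e-6 * max(1.0, ratio):
                raise ValueError(f"{name} = {ratio} is not a whole number of steps")
        if self.n_space < 2:
            raise ValueError("need at least 2 space intervals")
        if self.n_time < 1:
            raise ValueError("need at least 1 time step")

    @property
    def n_space(self) -> int:
        """Number of space intervals M (M+1 nodes)."""
        return round(self.L / self.dx)

    @property
    def n_time(self) -> int:
        """Number of time steps N (N+1 levels)."""
        return round(self.T / self.dt)

    @property
    def x_nodes(self) -> np.ndarray:
        return np.arange(self.n_space + 1) * self.dx

    @property
    def t_levels(self) -> np.ndarray:
        return np.arange(self.n_time + 1) * self.dt

    def node_index(self, x: float) -> int:
        i = round(x / self.dx)
        if not 0 <= i <= self.n_space or abs(i * self.dx - x) > NODE_TOL * max(1.0, abs(x)):
            raise ValueError(f"x = {x} does not coincide with a grid node (dx = {self.dx})")
        return i

    def time_index(self, t: float) -> int:
        n = round(t / self.dt)
        if not 0 <= n <= self.n_time or abs(n * self.dt - t) > NODE_TOL * max(1.0, abs(t)):
            raise ValueError(f"t = {t} does not coincide with a time level (dt = {self.dt})")
        return n


@dataclass(frozen=True)
class CaputoWeights:
    """Memory weights b_j = (j+1)^(1-alpha) - j^(1-alpha), j = 1..n_max.

    The weights are positive, bounded by one and strictly decreasing for
    alpha < 1; with the convention b_0 = 1 they telescope:
    sum_{j=0}^{n-1} (b_j - b_{j+1}) = 1 - b_n.  At alpha = 1 every
    weight is zero and the scheme is memoryless.
    """

    weights: np.ndarray
    alpha: float

    def b(self, j: int) -> float:
        """b_j for j >= 0 (b_0 = 1 by convention)."""
        if j == 0:
            return 1.0
        return float(self.weights[j - 1])

    @property
    def n_max(self) -> int:
        return len(self.weights)


def caputo_weights(alpha: float, n_max: int) -> CaputoWeights:
    """Compute the Caputo L1 memory weights b_1..b_{n_max}."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    j = np.arange(1, n_max + 1, dtype=float)
    w = (j + 1.0) ** (1.0 - alpha) - j ** (1.0 - alpha)
    return CaputoWeights(weights=w, alpha=alpha)


@dataclass(frozen=True)
class SchemeCoefficients:
    """Diffusion number s and reaction multiplier rho = dt^alpha * Gamma(2-alpha)."""

    s: float
    rho: float


def scheme_coefficients(grid: GridSpec) -> SchemeCoefficients:
    """s = dt^alpha * Gamma(2-alpha) / dx^2 for the given grid."""
    rho = grid.dt ** grid.alpha * gamma(2.0 - grid.alpha)
    return SchemeCoefficients(s=rho / grid.dx ** 2, rho=rho)


@dataclass(frozen=True)
class ModelSpec:
    """A crisp model instance: initial condition, killing rate, boundaries.

    ``ic`` maps an array of node positions to initial values;
    ``killing_rate`` is k(x, t) (vectorized over x); ``bc_left`` and
    ``bc_right`` give the Dirichlet boundary values as functions of t.
    """

    ic: Callable[[np.ndarray], np.ndarray]
    killing_rate: Callable[[np.ndarray, float], np.ndarray]
    bc_left: Callable[[float], float]
    bc_right: Callable[[float], float]
    boundary_mode: str = "fixed-value"


@dataclass(frozen=True)
class FuzzyModelSpec:
    """A fuzzy model: coefficient fields plus (r, beta)-aware boundaries.

    ``ic`` and ``killing_rate`` are fuzzy scales times crisp kernels;
    boundary callables take (t, r, beta).  Evaluating everything at one
    (r, beta) sample yields a crisp ModelSpec.
    """

    ic: FuzzyCoefficientField
    killing_rate: FuzzyCoefficientField
    bc_left: Callable[[float, float, float], float]
    bc_right: Callable[[float, float, float], float]
    boundary_mode: str = "fixed-value"

    def crisp_at(self, r: float, beta: float) -> ModelSpec:
        ic_fn = self.ic.at(r, beta)
        k_fn = self.killing_rate.at(r, beta)
        return ModelSpec(
            ic=lambda x: ic_fn(x, 0.0),
            killing_rate=k_fn,
            bc_left=lambda t: self.bc_left(t, r, beta),
            bc_right=lambda t: self.bc_right(t, r, beta),
            boundary_mode=self.boundary_mode,
        )


@dataclass
class CrispSolutionGrid:
    """Solution values u[n][i] on the full space-time grid."""

    values: np.ndarray  # shape (N+1, M+1)
    grid: GridSpec
    boundary_mode: str = "fixed-value"

    def value_at(self, x: float, t: float) -> float:
        """Solution at a point that must coincide with a grid node."""
        return float(self.values[self.grid.time_index(t), self.grid.node_index(x)])

    def to_tidy_frame(self, r: float | None = None, beta: float | None = None) -> pd.DataFrame:
        g = self.grid
        n_idx, i_idx = np.meshgrid(
            np.arange(g.n_time + 1), np.arange(g.n_space + 1), indexing="ij"
        )
        frame = pd.DataFrame(
            {
                "n": n_idx.ravel(),
                "t": n_idx.ravel() * g.dt,
                "i": i_idx.ravel(),
                "x": i_idx.ravel() * g.dx,
                "u": self.values.ravel(),
            }
        )
        if r is not None:
            frame.insert(0, "r", r)
        if beta is not None:
            frame.insert(1, "beta", beta)
        return frame


def _eval_kernel(k_fn, x: np.ndarray, t: float) -> np.ndarray:
    out = np.asarray(k_fn(x, t), dtype=float)
    if out.shape == ():
        out = np.full(x.shape, float(out))
    return out


def explicit_step(
    values: np.ndarray,
    n: int,
    coeff: SchemeCoefficients,
    weights: CaputoWeights,
    k_fn: Callable[[np.ndarray, float], np.ndarray],
    *,
    x: np.ndarray,
    dt: float,
) -> np.ndarray:
    """One explicit update, direct memory-sum form; returns the interior row.

    ``values`` holds rows 0..n of the history.  The memory sum
    sum_{j=1}^{n} b_j (u^{n+1-j} - u^{n-j}) is evaluated term by term;
    at n = 0 it is empty.
    """
    if n > weights.n_max:
        raise ValueError(f"step n={n} exceeds available weights (n_max={weights.n_max})")
    s, rho = coeff.s, coeff.rho
    un = values[n]
    t_n = n * dt
    k_vals = _eval_kernel(k_fn, x[1:-1], t_n)
    new = (
        s * (un[2:] + un[:-2])
        + (1.0 - 2.0 * s) * un[1:-1]
        - rho * k_vals * un[1:-1]
    )
    for j in range(1, n + 1):
        new -= weights.b(j) * (values[n + 1 - j, 1:-1] - values[n - j, 1:-1])
    return new


def explicit_step_regrouped(
    values: np.ndarray,
    n: int,
    coeff: SchemeCoefficients,
    weights: CaputoWeights,
    k_fn: Callable[[np.ndarray, float], np.ndarray],
    *,
    x: np.ndarray,
    dt: float,
) -> np.ndarray:
    """One explicit update in the regrouped (telescoped) form.

    The memory sum is folded into a -b_1 contribution at the current
    level, (b_j - b_{j+1}) couplings to earlier levels and a +b_n pull
    toward the initial condition.  Algebraically identical to
    :func:`explicit_step`; agreement is floating-point roundoff only.
    """
    if n > weights.n_max:
        raise ValueError(f"step n={n} exceeds available weights (n_max={weights.n_max})")
    s, rho = coeff.s, coeff.rho
    un = values[n]
    t_n = n * dt
    k_vals = _eval_kernel(k_fn, x[1:-1], t_n)
    diag = 1.0 - 2.0 * s - rho * k_vals
    if n == 0:
        return s * (un[2:] + un[:-2]) + diag * un[1:-1]
    new = s * (un[2:] + un[:-2]) + (diag - weights.b(1)) * un[1:-1]
    for j in range(1, n):
        new -= (weights.b(j + 1) - weights.b(j)) * values[n - j, 1:-1]
    new += weights.b(n) * values[0, 1:-1]
    return new


def solve_crisp(
    model: ModelSpec,
    grid: GridSpec,
    *,
    stepper: str = "regrouped",
    warn_unstable: bool = True,
) -> CrispSolutionGrid:
    """March the explicit scheme over the full grid.

    A stability advisory (conservative stability bound) is emitted as a warning
    when violated; the solver proceeds regardless so that instability
    experiments are runnable.  Non-finite values abort with an
    OverflowError naming the offending time level.
    """
    M, N = grid.n_space, grid.n_time
    x = grid.x_nodes
    coeff = scheme_coefficients(grid)
    weights = caputo_weights(grid.alpha, N)

    if warn_unstable:
        from .stability import stability_bound_conservative, killing_rate_max

        k_max = killing_rate_max(model.killing_rate, grid)
        bound = stability_bound_conservative(coeff, weights, k_max)
        if coeff.s > bound:
            warnings.warn(
                f"diffusion number s = {coeff.s:.5g} exceeds the stability "
                f"bound {bound:.5g}; the solution may grow",
                RuntimeWarning,
                stacklevel=2,
            )

    step_fn = {"regrouped": explicit_step_regrouped, "direct": explicit_step}[stepper]

    u = np.empty((N + 1, M + 1))
    u[0] = np.asarray(model.ic(x), dtype=float)
    for n in range(N):
        t_next = (n + 1) * grid.dt
        u[n + 1, 1:M] = step_fn(u, n, coeff, weights, model.killing_rate, x=x, dt=grid.dt)
        u[n + 1, 0] = model.bc_left(t_next)
        u[n + 1, M] = model.bc_right(t_next)
        if not np.all(np.isfinite(u[n + 1])):
            raise OverflowError(
                f"non-finite solution values at time level n = {n + 1} "
                f"(t = {t_next:.6g}); the scheme is unstable for this grid"
            )
    return CrispSolutionGrid(values=u, grid=grid, boundary_mode=model.boundary_mode)


@dataclass
class FuzzySolutionBundle:
    """Crisp solution grids indexed by (r, beta) samples."""

    solutions: Dict[Tuple[float, float], CrispSolutionGrid]
    r_grid: np.ndarray
    beta_grid: np.ndarray

    def at(self, r: float, beta: float) -> CrispSolutionGrid:
        return self.solutions[(r, beta)]

    def band_valid_at(self, x: float, t: float) -> bool:
        """Do the beta=0/beta=1 branches form a valid fuzzy band at (x, t)?"""
        lows = [self.at(r, 0.0).value_at(x, t) for r in self.r_grid]
        ups = [self.at(r, 1.0).value_at(x, t) for r in self.r_grid]
        return band_is_valid(lows, ups, atol=1e-12)

    def to_tidy_frame(self) -> pd.DataFrame:
        frames = [
            sol.to_tidy_frame(r=r, beta=beta)
            for (r, beta), sol in sorted(self.solutions.items())
        ]
        return pd.concat(frames, ignore_index=True)


def solve_fuzzy(
    model: FuzzyModelSpec,
    grid: GridSpec,
    r_grid: Sequence[float],
    beta_grid: Sequence[float],
    *,
    warn_unstable: bool = True,
) -> FuzzySolutionBundle:
    """Solve the crisp PDE at every (r, beta) sample of the fuzzy model."""
    r_arr = np.asarray(list(r_grid), dtype=float)
    b_arr = np.asarray(list(beta_grid), dtype=float)
    if r_arr.size == 0 or b_arr.size == 0:
        raise ValueError("r_grid and beta_grid must be non-empty")
    solutions: Dict[Tuple[float, float], CrispSolutionGrid] = {}
    for r in r_arr:
        for beta in b_arr:
            crisp = model.crisp_at(float(r), float(beta))
            solutions[(float(r), float(beta))] = solve_crisp(
                crisp, grid, warn_unstable=warn_unstable
            )
            warn_unstable = False  # one advisory per bundle is enough
    return FuzzySolutionBundle(solutions=solutions, r_grid=r_arr, beta_grid=b_arr)
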