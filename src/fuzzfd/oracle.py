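"""Reference solutions used to validate the finite-difference solver.

Three independent yardsticks:

* the truncated power-series solution of the worked example with
  killing rate k(t) = t^2 and initial condition phi(r, beta) * e^{kx},

      u(x, t) = phi(r, beta) * e^{kx} * (1 + k^2 t^alpha / Gamma(1+alpha)
                                           + k^4 t^{2alpha} / Gamma(1+2alpha)),

  a truncated series, not the full closed-form solution — adequate at
  the short horizons it is used for;
* the classical heat-equation closed form e^{-pi^2 t} sin(pi x) for the
  alpha = 1, k = 0 limit on [0, 1] with zero boundaries; and
* a deliberately naive direct-history stepper that re-evaluates the
  full Caputo memory sum from scratch at every level, kept free of the
  production solver's regrouped algebra so the two can disagree if
  either is wrong.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gamma

from .caputo_scheme import (
    CrispSolutionGrid,
    FuzzySolutionBundle,
    GridSpec,
    ModelSpec,
    caputo_weights,
    scheme_coefficients,
)
from .fuzzy_param import TriangularFuzzyNumber, double_param_value

__all__ = [
    "SeriesSolutionSpec",
    "ErrorTable",
    "exact_crisp",
    "exact_fuzzy",
    "abs_error_table",
    "classical_heat_exact",
    "direct_history_oracle",
]

#: largest grid (levels x nodes) the naive oracle will accept
DIRECT_ORACLE_MAX = 200


@dataclass(frozen=True)
class SeriesSolutionSpec:
    """Parameters of the worked-example series: exponent k in e^{kx} and alpha."""

    k_exp: float
    alpha: float


def exact_crisp(x: float, t: float, spec: SeriesSolutionSpec) -> float:
    """Crisp series factor C(x, t) = e^{kx} (1 + k^2 t^a/G(1+a) + k^4 t^{2a}/G(1+2a))."""
    k, a = spec.k_exp, spec.alpha
    series = (
        1.0
        + k ** 2 * t ** a / gamma(1.0 + a)
        + k ** 4 * t ** (2.0 * a) / gamma(1.0 + 2.0 * a)
    )
    return float(np.exp(k * x) * series)


def exact_fuzzy(
    x: float,
    t: float,
    spec: SeriesSolutionSpec,
    phi_source: TriangularFuzzyNumber,
    r: float,
    beta: float,
) -> float:
    """phi(r, beta) times the crisp series factor.

    The fuzzy scale multiplies the entire series, so the solution
    vanishes identically at r = 1 for the zero-core scale of the worked
    example.
    """
    return double_param_value(phi_source, r, beta) * exact_crisp(x, t, spec)


class ErrorTable(pd.DataFrame):
    """Tidy table of (r, beta, x, t, numerical, exact, abs_error) rows."""

    @property
    def _constructor(self):
        return ErrorTable


def abs_error_table(
    bundle: FuzzySolutionBundle,
    spec: SeriesSolutionSpec,
    phi_source: TriangularFuzzyNumber,
    eval_points: Iterable[Tuple[float, float]],
) -> ErrorTable:
    """Numerical vs series solution at grid-node evaluation points.

    One row per (r, beta, x, t); points must coincide with grid nodes
    (no interpolation is performed).
    """
    rows = []
    points = list(eval_points)
    for (r, beta), sol in sorted(bundle.solutions.items()):
        for x, t in points:
            num = sol.value_at(x, t)
            exa = exact_fuzzy(x, t, spec, phi_source, r, beta)
            rows.append(
                {
                    "r": r,
                    "beta": beta,
                    "x": x,
                    "t": t,
                    "numerical": num,
                    "exact": exa,
                    "abs_error": abs(num - exa),
                }
            )
    return ErrorTable(rows)


def classical_heat_exact(x: float, t: float) -> float:
    """e^{-pi^2 t} sin(pi x): heat equation on [0,1], IC sin(pi x), zero BCs."""
    return float(np.exp(-np.pi ** 2 * t) * np.sin(np.pi * x))


def direct_history_oracle(model: ModelSpec, grid: GridSpec) -> CrispSolutionGrid:
    """Naive reference stepper re-evaluating the full memory sum each level.

    Scalar loops over nodes and history, no telescoping, no caching —
    intended for small grids only (refuses beyond
    ``DIRECT_ORACLE_MAX`` levels or nodes).
    """
    M, N = grid.n_space, grid.n_time
    if M + 1 > DIRECT_ORACLE_MAX or N + 1 > DIRECT_ORACLE_MAX:
        raise ValueError(
            f"grid {N + 1} x {M + 1} too large for the direct-history oracle "
            f"(limit {DIRECT_ORACLE_MAX} per axis); use solve_crisp instead"
        )
    coeff = scheme_coefficients(grid)
    w = caputo_weights(grid.alpha, N)
    s, rho = coeff.s, coeff.rho
    x = grid.x_nodes
    u = np.empty((N + 1, M + 1))
    u[0] = np.asarray(model.ic(x), dtype=float)
    for n in range(N):
        t_n = n * grid.dt
        for i in range(1, M):
            mem = 0.0
            for j in range(1, n + 1):
                mem += w.b(j) * (u[n + 1 - j, i] - u[n - j, i])
            k_val = float(np.asarray(model.killing_rate(np.array([x[i]]), t_n))[0])
            u[n + 1, i] = (
                s * (u[n, i + 1] + u[n, i - 1])
                + (1.0 - 2.0 * s) * u[n, i]
                - rho * k_val * u[n, i]
                - mem
            )
        u[n + 1, 0] = model.bc_left((n + 1) * grid.dt)
        u[n + 1, M] = model.bc_right((n + 1) * grid.dt)
    return CrispSolutionGrid(values=u, grid=grid, boundary_mode=model.boundary_mode)
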