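"""Triangular fuzzy numbers and the double parametric (r, beta) form.

A triangular fuzzy number is determined by its support endpoints and its
core (the unique point with membership one).  Its r-level cut is the
interval of values with membership >= r; for a triangular shape the cut
endpoints are linear in r.  The double parametric substitution

    u(r, beta) = beta * (upper(r) - lower(r)) + lower(r)

collapses the lower/upper interval pair into a single scalar family over
(r, beta) in [0,1]^2: beta = 0 recovers the lower branch, beta = 1 the
upper.  Model coefficients (initial condition, killing rate) enter the
PDE as a fuzzy scale multiplying a crisp space/time kernel, so the fuzzy
problem reduces to a family of crisp problems indexed by (r, beta).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TriangularFuzzyNumber",
    "RCutInterval",
    "DoubleParametricScalar",
    "FuzzyCoefficientField",
    "r_cut",
    "double_param_value",
    "fuzzify_field",
    "band_is_valid",
]


def _check_unit_interval(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class TriangularFuzzyNumber:
    """A triangular fuzzy number ``(left, core, right)``.

    Membership rises linearly from 0 at ``left`` to 1 at ``core`` and
    falls back to 0 at ``right``.  ``left == core == right`` gives a
    crisp (degenerate) number.
    """

    left: float
    core: float
    right: float

    def __post_init__(self) -> None:
        if not (self.left <= self.core <= self.right):
            raise ValueError(
                f"requires left <= core <= right, got "
                f"({self.left}, {self.core}, {self.right})"
            )

    @property
    def is_crisp(self) -> bool:
        return self.left == self.core == self.right

    def to_json(self) -> dict:
        return {"left": self.left, "core": self.core, "right": self.right}

    @classmethod
    def from_json(cls, obj: dict) -> "TriangularFuzzyNumber":
        return cls(float(obj["left"]), float(obj["core"]), float(obj["right"]))


@dataclass(frozen=True)
class RCutInterval:
    """The r-level cut ``[lower, upper]`` of a fuzzy number."""

    lower: float
    upper: float
    r: float

    def __post_init__(self) -> None:
        _check_unit_interval(self.r, "r")
        if self.lower > self.upper:
            raise ValueError(f"cut endpoints crossed: {self.lower} > {self.upper}")

    @property
    def width(self) -> float:
        return self.upper - self.lower


def r_cut(fuzzy: TriangularFuzzyNumber, r: float) -> RCutInterval:
    """r-level cut of a triangular fuzzy number.

    Linear cuts: ``lower = left + r*(core - left)`` and
    ``upper = right - r*(right - core)``.  At r=0 this is the support,
    at r=1 the degenerate interval at the core.
    """
    _check_unit_interval(r, "r")
    # convex-combination form keeps lower <= upper exact in floating point
    lower = (1.0 - r) * fuzzy.left + r * fuzzy.core
    upper = (1.0 - r) * fuzzy.right + r * fuzzy.core
    return RCutInterval(lower=float(lower), upper=float(upper), r=float(r))


def double_param_value(fuzzy: TriangularFuzzyNumber, r: float, beta: float) -> float:
    """Scalar representative ``beta*(upper(r) - lower(r)) + lower(r)``.

    ``beta=0`` gives the lower branch of the r-cut, ``beta=1`` the upper;
    intermediate beta interpolates linearly.  Continuous in both
    arguments; identically the core value at r=1.
    """
    _check_unit_interval(beta, "beta")
    cut = r_cut(fuzzy, r)
    if beta == 0.0:  # endpoints reproduce the cut exactly, no roundoff
        return cut.lower
    if beta == 1.0:
        return cut.upper
    return beta * cut.width + cut.lower


@dataclass(frozen=True)
class DoubleParametricScalar:
    """A fuzzy scale evaluated at one (r, beta) sample."""

    source: TriangularFuzzyNumber
    r: float
    beta: float
    value: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "value", double_param_value(self.source, self.r, self.beta)
        )


@dataclass(frozen=True)
class FuzzyCoefficientField:
    """Fuzzy scale times a crisp kernel: ``field(x, t) = scale * kernel(x, t)``.

    This is the only fuzzy arithmetic the model needs — each coefficient
    is a fuzzy convex number multiplying a crisp function of space/time.
    """

    scale: TriangularFuzzyNumber
    kernel: Callable[[float, float], float]

    def at(self, r: float, beta: float) -> Callable[[float, float], float]:
        """Crisp kernel obtained by evaluating the scale at (r, beta)."""
        return fuzzify_field(self.scale, self.kernel, r, beta)


def fuzzify_field(
    scale: TriangularFuzzyNumber,
    kernel: Callable[[float, float], float],
    r: float,
    beta: float,
) -> Callable[[float, float], float]:
    """Return the crisp function ``(x, t) -> phi(r, beta) * kernel(x, t)``."""
    phi = double_param_value(scale, r, beta)

    def crisp(x, t):
        return phi * kernel(x, t)

    return crisp


def band_is_valid(
    lower_values: Sequence[float],
    upper_values: Sequence[float],
    *,
    atol: float = 0.0,
) -> bool:
    """Check that lower/upper branches over an r grid form a fuzzy band.

    The sequences are indexed by increasing r.  Validity requires
    ``lower <= upper`` pointwise and nesting: lower nondecreasing and
    upper nonincreasing as r grows (intervals shrink toward the core).
    """
    lo = np.asarray(lower_values, dtype=float)
    up = np.asarray(upper_values, dtype=float)
    if lo.shape != up.shape:
        raise ValueError(f"shape mismatch: {lo.shape} vs {up.shape}")
    if np.any(lo > up + atol):
        return False
    if lo.size >= 2:
        if np.any(np.diff(lo) < -atol) or np.any(np.diff(up) > atol):
            return False
    return True
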