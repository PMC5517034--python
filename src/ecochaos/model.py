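"""Core eco-evolutionary predator-prey model.

A two-species system in which the prey's per-capita growth rate is a
density-dependent fitness landscape over an evolving quantitative trait.
Prey density ``x`` and predator density ``y`` follow Holling type II
interactions, while the population-mean trait ``cbar`` climbs the local
fitness gradient at a speed set by the additive genetic variance ``V``
(gradient dynamics).  The fitness landscape combines a saturating,
trait-dependent birth rate with a quartic mortality term, so changing prey
density can tilt the landscape between single-peaked (stabilizing
selection) and multi-peaked (disruptive selection) shapes.

This module defines the parameter and state containers, the fitness
function, the ODE right-hand side, its analytic Jacobian, and the
instantaneous geometry (stationary points) of the fitness landscape.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from fractions import Fraction
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "EcoState",
    "StationaryPoint",
    "LandscapeShape",
    "FIG2_PARAMS",
    "fitness",
    "rhs",
    "jacobian",
    "landscape_extrema",
    "cbar_dagger",
]

# Repeating decimals in the canonical parameter table ("1.3bar", "0.3bar",
# "0.06bar") are read as exact rationals.
_B2 = float(Fraction(4, 3))
V_LIMIT_CYCLE = float(Fraction(1, 15))
V_CHAOTIC = float(Fraction(1, 3))

_PARAM_SYMBOLS = ("a1", "b1", "a2", "b2", "d1", "d2", "k1", "k2", "k4", "ya", "V")


@dataclass(frozen=True)
class ModelParams:
    """The eleven rate/shape constants of the model.

    Attributes
    ----------
    a1 : float
        Prey birth saturation amplitude (1/time).
    b1 : float
        Prey birth half-saturation shape (1/trait).
    a2 : float
        Predation rate (1/(density*time)).
    b2 : float
        Predation half-saturation shape (1/density).
    d1 : float
        Prey base death rate (1/time).
    d2 : float
        Predator death rate (1/time).
    k1 : float
        Density-dependent directional selection strength (1/(density*trait)).
    k2 : float
        Quadratic fitness-landscape coefficient (1/trait^2).
    k4 : float
        Quartic fitness-landscape coefficient (1/trait^4).
    ya : float
        Predator conversion asymmetry (dimensionless).
    V : float
        Additive genetic variance of the prey trait (trait^2); sets the
        timescale of mean-trait evolution.
    """

    a1: float = 2.5
    b1: float = 6.0
    a2: float = 0.05
    b2: float = _B2
    d1: float = 0.16
    d2: float = 0.004
    k1: float = 6.0
    k2: float = 9.0
    k4: float = 9.0
    ya: float = 8.0
    V: float = V_CHAOTIC

    def __post_init__(self) -> None:
        for name in _PARAM_SYMBOLS:
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"parameter {name!r} must be finite and > 0, got {value!r}")

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in _PARAM_SYMBOLS}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        unknown = set(d) - set(_PARAM_SYMBOLS)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ModelParams":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))

    def with_V(self, V: float) -> "ModelParams":
        return replace(self, V=V)


#: Canonical parameter set (chaotic variant, V = 1/3).
FIG2_PARAMS = ModelParams()


class EcoState(NamedTuple):
    """One point (x, y, cbar) in phase space.

    ``x`` prey density, ``y`` predator density, ``cbar`` population-mean
    trait value; each nonnegative (zero is the invariant boundary).
    """

    x: float
    y: float
    cbar: float

    def validate(self) -> "EcoState":
        arr = np.asarray(self, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite state {self!r}")
        if np.any(arr < 0):
            raise ValueError(f"negative component in state {self!r}")
        return self


def cbar_dagger(params: ModelParams) -> float:
    """Prey viability threshold of the mean trait.

    With a frozen trait and no predator, the prey grows exponentially when
    ``cbar`` exceeds ``d1 / (a1 - b1*d1)`` and collapses below it.
    """
    denom = params.a1 - params.b1 * params.d1
    if denom <= 0:
        raise ValueError("requires a1 > b1*d1 for a finite viability threshold")
    return params.d1 / denom


def fitness(state: EcoState, c, params: ModelParams):
    """Fitness r(x, y, cbar, c) of an individual with trait value ``c``.

    Three terms: a saturating trait-dependent birth rate whose direction is
    tilted by prey density, a quartic trait-dependent mortality, and a
    trait-independent predation loss.  ``c`` may be a scalar or array; the
    result is a rate (1/time) and may be negative.
    """
    x, y, cbar = state
    c = np.asarray(c, dtype=float)
    if not (np.all(np.isfinite(c)) and all(np.isfinite(v) for v in state)):
        raise ValueError("non-finite input to fitness")
    birth = params.a1 * cbar / (1.0 + params.b1 * cbar) * (1.0 - params.k1 * x * (c - cbar))
    death = params.d1 * (1.0 - params.k2 * (c**2 - cbar**2) + params.k4 * (c**4 - cbar**4))
    predation = params.a2 * x * y / (1.0 + params.b2 * x)
    out = birth - death - predation
    return float(out) if out.ndim == 0 else out


def rhs(state: EcoState, params: ModelParams) -> np.ndarray:
    """Velocity (dx/dt, dy/dt, dcbar/dt) of the three-variable system."""
    x, y, cbar = state
    p = params
    hx = 1.0 / (1.0 + p.b2 * x)
    hc = 1.0 / (1.0 + p.b1 * cbar)
    xdot = x * (p.a1 * cbar * hc - p.a2 * y * hx - p.d1)
    ydot = y * (p.ya * p.a2 * x * hx - p.d2)
    cdot = cbar * p.V * (2.0 * p.k2 * p.d1 - 4.0 * p.k4 * p.d1 * cbar**2 - p.a1 * p.k1 * x * hc)
    return np.array([xdot, ydot, cdot])


def jacobian(state: EcoState, params: ModelParams) -> np.ndarray:
    """Analytic 3x3 Jacobian of :func:`rhs` at ``state``."""
    x, y, cbar = state
    p = params
    hx = 1.0 / (1.0 + p.b2 * x)
    hc = 1.0 / (1.0 + p.b1 * cbar)
    growth_x = p.a1 * cbar * hc - p.a2 * y * hx - p.d1
    sel = 2.0 * p.k2 * p.d1 - 4.0 * p.k4 * p.d1 * cbar**2 - p.a1 * p.k1 * x * hc
    J = np.empty((3, 3))
    J[0, 0] = growth_x + x * p.a2 * p.b2 * y * hx * hx
    J[0, 1] = -p.a2 * x * hx
    J[0, 2] = x * p.a1 * hc * hc
    J[1, 0] = y * p.ya * p.a2 * hx * hx
    J[1, 1] = p.ya * p.a2 * x * hx - p.d2
    J[1, 2] = 0.0
    J[2, 0] = -cbar * p.V * p.a1 * p.k1 * hc
    J[2, 1] = 0.0
    J[2, 2] = p.V * sel + cbar * p.V * (-8.0 * p.k4 * p.d1 * cbar + p.a1 * p.k1 * x * p.b1 * hc * hc)
    return J


# ---------------------------------------------------------------------------
# Instantaneous fitness-landscape geometry
# ---------------------------------------------------------------------------

class StationaryPoint(NamedTuple):
    c: float
    kind: str  # "min" | "max" | "fold"


@dataclass(frozen=True)
class LandscapeShape:
    """Stationary points of the fitness landscape in the individual trait.

    The landscape is evaluated at fixed prey density ``x`` and mean trait
    ``cbar``; its shape is independent of predator density because the
    predation term does not involve the individual trait.
    """

    x: float
    cbar: float
    stationary_points: tuple[StationaryPoint, ...]
    boundary_is_max: bool
    n_local_maxima: int


def _dr_dc_coeffs(x: float, cbar: float, p: ModelParams) -> np.ndarray:
    # dr/dc = -4 d1 k4 c^3 + 2 d1 k2 c - a1 cbar k1 x / (1 + b1 cbar)
    tilt = p.a1 * cbar * p.k1 * x / (1.0 + p.b1 * cbar)
    return np.array([-4.0 * p.d1 * p.k4, 0.0, 2.0 * p.d1 * p.k2, -tilt])


def landscape_extrema(
    x: float,
    cbar: float,
    params: ModelParams,
    c_max: float = 2.0,
    fold_tol: float = 1e-6,
) -> LandscapeShape:
    """Locate and classify the landscape's stationary points on c >= 0.

    Interior stationary points are the real positive roots of the cubic
    dr/dc = 0, classified by the sign of the second derivative; a pair of
    roots closer than ``fold_tol`` is merged and flagged ``"fold"``.  The
    origin is reported as a boundary maximum whenever the landscape slopes
    downward there (x > 0 and cbar > 0).
    """
    if x < 0 or cbar < 0 or c_max <= 0:
        raise ValueError("x, cbar must be >= 0 and c_max > 0")
    p = params
    coeffs = _dr_dc_coeffs(x, cbar, p)
    roots = np.roots(coeffs)
    real = [float(r.real) for r in roots if abs(r.imag) < 1e-9 and 0.0 < r.real <= c_max]
    # polish with a Newton step on the cubic
    dcoeffs = np.polyder(coeffs)
    polished = []
    for c in sorted(real):
        for _ in range(3):
            f, df = np.polyval(coeffs, c), np.polyval(dcoeffs, c)
            if df == 0.0:
                break
            c -= f / df
        polished.append(c)

    points: list[StationaryPoint] = []
    i = 0
    while i < len(polished):
        c = polished[i]
        if i + 1 < len(polished) and abs(polished[i + 1] - c) < fold_tol:
            points.append(StationaryPoint(0.5 * (c + polished[i + 1]), "fold"))
            i += 2
            continue
        curv = 2.0 * p.d1 * p.k2 - 12.0 * p.d1 * p.k4 * c * c
        points.append(StationaryPoint(c, "max" if curv < 0 else "min"))
        i += 1

    slope0 = float(np.polyval(coeffs, 0.0))  # dr/dc at c = 0
    boundary_is_max = slope0 < 0.0
    n_max = sum(1 for s in points if s.kind == "max") + int(boundary_is_max)
    return LandscapeShape(
        x=float(x),
        cbar=float(cbar),
        stationary_points=tuple(points),
        boundary_is_max=boundary_is_max,
        n_local_maxima=n_max,
    )
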