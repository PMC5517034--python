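"""Fast-equilibration phase diagram and hysteresis analysis.

Treating the mean trait as instantaneously equilibrated at fixed prey
density (``cbar -> c_eq``), the trait equilibria are the roots of a cubic
whose shape is controlled by the prey density x — the analogue of a
Landau free-energy with x as the control parameter and the trait as the
order parameter.  The positive equilibrium branch folds at a critical
prey density (forward jump of the hysteresis loop) and crosses the origin
at a lower one (backward jump); both fold points have closed forms.

Naming: the forward fold (the literature's x*, c*) is ``x_fwd, c_fwd``;
the backward jump (x**, c**) is ``x_bwd, c_bwd``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .model import ModelParams, cbar_dagger
from .simulate import Trajectory

__all__ = [
    "Equilibrium",
    "CriticalPoints",
    "PhaseDiagram",
    "JumpEvent",
    "cbar_equilibria",
    "critical_points",
    "phase_diagram",
    "hysteresis_from_trajectory",
]


class Equilibrium(NamedTuple):
    """One trait equilibrium at fixed prey density.

    ``c_eq`` is the real part of the root; ``is_complex`` marks complex
    pairs (reported by real part, never mixed silently with real
    equilibria); ``stable`` is None for complex roots.
    """

    c_eq: float
    stable: bool | None
    is_complex: bool


def _g_coeffs(p: ModelParams) -> np.ndarray:
    # g(c) = (2 k2 d1 - 4 k4 d1 c^2)(1 + b1 c), descending powers
    return np.array(
        [
            -4.0 * p.k4 * p.d1 * p.b1,
            -4.0 * p.k4 * p.d1,
            2.0 * p.k2 * p.d1 * p.b1,
            2.0 * p.k2 * p.d1,
        ]
    )


def _dcdot_dcbar(c: float, x: float, p: ModelParams) -> float:
    """d(cbar_dot)/d(cbar) of the one-dimensional trait dynamics at fixed x."""
    denom = 1.0 + p.b1 * c
    if abs(denom) < 1e-12:  # pole of the birth saturation (only off-domain roots)
        return np.nan
    hc = 1.0 / denom
    sel = 2.0 * p.k2 * p.d1 - 4.0 * p.k4 * p.d1 * c * c - p.a1 * p.k1 * x * hc
    return p.V * sel + c * p.V * (-8.0 * p.k4 * p.d1 * c + p.a1 * p.k1 * x * p.b1 * hc * hc)


def cbar_equilibria(x: float, params: ModelParams, imag_tol: float = 1e-9) -> list[Equilibrium]:
    """All trait equilibria of the fast-equilibration dynamics at fixed x.

    Returns c = 0 (always an equilibrium: the trait equation factors)
    plus the three roots of the cubic g(c) = a1 k1 x.  Stability is the
    sign of the derivative of the one-dimensional trait dynamics.
    """
    if x < 0:
        raise ValueError("x must be >= 0")
    p = params
    coeffs = _g_coeffs(p).copy()
    coeffs[3] -= p.a1 * p.k1 * x
    out = [Equilibrium(0.0, _dcdot_dcbar(0.0, x, p) < 0.0, False)]
    for r in np.roots(coeffs):
        if abs(r.imag) < imag_tol:
            c = float(r.real)
            slope = _dcdot_dcbar(c, x, p)
            out.append(Equilibrium(c, bool(slope < 0.0) if np.isfinite(slope) else None, False))
        else:
            out.append(Equilibrium(float(r.real), None, True))
    out.sort(key=lambda e: e.c_eq)
    return out


@dataclass(frozen=True)
class CriticalPoints:
    """Closed-form critical points of the hysteresis loop.

    ``x_fwd, c_fwd``: fold of the positive equilibrium branch — as prey
    density rises through ``x_fwd`` the stable trait equilibrium vanishes
    and the trait jumps from ``c_fwd`` to the origin.  ``x_bwd, c_bwd``:
    as prey density falls through ``x_bwd`` the origin destabilizes and
    the trait jumps back up to ``c_bwd``.  ``ceq_max`` is the limiting
    stable equilibrium as x -> 0 (the maximum the mean trait attains
    anywhere on the attractor); ``cbar_dagger`` is the prey viability
    threshold of the mean trait.
    """

    x_fwd: float
    c_fwd: float
    x_bwd: float
    c_bwd: float
    ceq_max: float
    cbar_dagger: float

    @property
    def hysteresis_window(self) -> tuple[float, float]:
        return (self.x_bwd, self.x_fwd)


def critical_points(params: ModelParams, cross_validate: bool = True) -> CriticalPoints:
    """Closed-form fold/jump points, cross-checked by a numeric branch scan.

    Raises ValueError for parameter sets without a positive fold (monotone
    branch function: no hysteresis window).
    """
    p = params
    # stationarity of g: 6 k4 b1 c^2 + 4 k4 c - k2 b1 = 0
    a, b, c0 = 6.0 * p.k4 * p.b1, 4.0 * p.k4, -p.k2 * p.b1
    disc = b * b - 4.0 * a * c0
    if disc <= 0:
        raise ValueError("no hysteresis window: branch function has no positive fold")
    c_fwd = (-b + np.sqrt(disc)) / (2.0 * a)
    if c_fwd <= 0:
        raise ValueError("no hysteresis window: fold not at positive trait value")
    g_cfwd = float(np.polyval(_g_coeffs(p), c_fwd))
    x_fwd = g_cfwd / (p.a1 * p.k1)
    x_bwd = 2.0 * p.k2 * p.d1 / (p.a1 * p.k1)  # g(0) / (a1 k1)
    # branch value the backward jump lands on: 4 k4 b1 c^2 + 4 k4 c - 2 k2 b1 = 0
    a2_, b2_, c2_ = 4.0 * p.k4 * p.b1, 4.0 * p.k4, -2.0 * p.k2 * p.b1
    c_bwd = (-b2_ + np.sqrt(b2_ * b2_ - 4.0 * a2_ * c2_)) / (2.0 * a2_)
    cp = CriticalPoints(
        x_fwd=float(x_fwd),
        c_fwd=float(c_fwd),
        x_bwd=float(x_bwd),
        c_bwd=float(c_bwd),
        ceq_max=float(np.sqrt(p.k2 / (2.0 * p.k4))),
        cbar_dagger=cbar_dagger(p),
    )
    if cross_validate:
        _validate_against_scan(cp, p)
    return cp


def _positive_stable_branch(x: float, p: ModelParams) -> float | None:
    cands = [
        e.c_eq for e in cbar_equilibria(x, p) if not e.is_complex and e.stable and e.c_eq > 1e-12
    ]
    return max(cands) if cands else None


def _validate_against_scan(cp: CriticalPoints, p: ModelParams, tol: float = 1e-6) -> None:
    """Bisect the disappearance of the positive stable branch; compare folds."""
    lo, hi = cp.x_bwd, 4.0 * cp.x_fwd
    if _positive_stable_branch(lo, p) is None or _positive_stable_branch(hi, p) is not None:
        raise AssertionError("branch scan bracket failed; closed forms inconsistent")
    while hi - lo > 0.25 * tol:
        mid = 0.5 * (lo + hi)
        if _positive_stable_branch(mid, p) is None:
            hi = mid
        else:
            lo = mid
    x_fold = 0.5 * (lo + hi)
    if abs(x_fold - cp.x_fwd) > tol * max(1.0, abs(cp.x_fwd)):
        raise AssertionError(
            f"closed-form x_fwd={cp.x_fwd!r} disagrees with branch scan {x_fold!r}"
        )
    b0 = _positive_stable_branch(cp.x_bwd + 1e-9, p)
    if b0 is None or abs(b0 - cp.c_bwd) > 1e-4:
        raise AssertionError("closed-form c_bwd disagrees with branch scan")


@dataclass(frozen=True)
class PhaseDiagram:
    """Equilibrium branches c_eq(x) with the embedded critical points.

    ``branches`` has shape (len(x_grid), 4): per x, the real parts of the
    four equilibria (origin plus cubic roots) sorted descending;
    ``is_complex`` and ``is_stable`` are matching masks (``is_stable`` is
    False for complex entries).  The forward/backward overlays reproduce
    the path of the trait equilibrium as prey density is swept up or down
    through the hysteresis window.
    """

    x_grid: np.ndarray
    branches: np.ndarray
    is_complex: np.ndarray
    is_stable: np.ndarray
    critical_points: CriticalPoints

    def forward_overlay(self) -> np.ndarray:
        """Trait equilibrium swept by increasing x (jumps at x_fwd)."""
        cp = self.critical_points
        out = np.zeros_like(self.x_grid)
        for i, x in enumerate(self.x_grid):
            if x < cp.x_fwd:
                mask = self.is_stable[i] & (self.branches[i] > 1e-12)
                out[i] = self.branches[i][mask].max() if mask.any() else 0.0
        return out

    def backward_overlay(self) -> np.ndarray:
        """Trait equilibrium swept by decreasing x (jumps at x_bwd)."""
        cp = self.critical_points
        out = np.zeros_like(self.x_grid)
        for i, x in enumerate(self.x_grid):
            if x < cp.x_bwd:
                mask = self.is_stable[i] & (self.branches[i] > 1e-12)
                out[i] = self.branches[i][mask].max() if mask.any() else 0.0
        return out


def phase_diagram(params: ModelParams, x_grid: Sequence[float]) -> PhaseDiagram:
    """Equilibrium branches over an ascending grid of prey densities."""
    x_grid = np.asarray(x_grid, dtype=float)
    if np.any(np.diff(x_grid) < 0) or np.any(x_grid < 0):
        raise ValueError("x_grid must be ascending and nonnegative")
    n = len(x_grid)
    branches = np.empty((n, 4))
    is_complex = np.zeros((n, 4), dtype=bool)
    is_stable = np.zeros((n, 4), dtype=bool)
    for i, x in enumerate(x_grid):
        eqs = cbar_equilibria(float(x), params)
        eqs.sort(key=lambda e: -e.c_eq)
        branches[i] = [e.c_eq for e in eqs]
        is_complex[i] = [e.is_complex for e in eqs]
        is_stable[i] = [bool(e.stable) for e in eqs]
    return PhaseDiagram(x_grid, branches, is_complex, is_stable, critical_points(params))


# ---------------------------------------------------------------------------
# Hysteresis events in simulated trajectories
# ---------------------------------------------------------------------------

class JumpEvent(NamedTuple):
    direction: str  # "forward" (collapse toward 0) | "backward" (recovery)
    t: float
    x_at_event: float
    cbar_before: float
    cbar_after: float


def hysteresis_from_trajectory(
    traj: Trajectory,
    critical: CriticalPoints | None = None,
    min_dwell: float = 50.0,
    lookaround: float = 10.0,
) -> list[JumpEvent]:
    """Detect the trait's forward collapses and backward recoveries.

    Events are crossings of the mean trait through the midpoint between
    the fold trait ``c_fwd`` and the re-entry trait ``c_bwd`` — the
    middle of either jump.  A downward crossing counts as a *forward*
    (collapse) event when the trait had stayed above ``c_fwd`` for at
    least ``min_dwell`` time units beforehand (a genuine metastable
    dwell, not one swing of the rapid cycling, whose excursions above
    ``c_fwd`` last only ~10-20 time units).  An upward crossing counts as
    a *backward* (recovery) event when the trait then stays above
    ``c_fwd`` for at least ``min_dwell``.  The prey density is recorded
    at the crossing; ``cbar_before``/``cbar_after`` are taken
    ``lookaround`` time units on either side.  Because the genetic
    variance is finite the recorded densities lag the analytic critical
    points: collapses overshoot ``x_fwd`` somewhat, recoveries overshoot
    ``x_bwd`` strongly downward.  Trajectories without transitions
    return an empty list with a warning.
    """
    if critical is None:
        critical = critical_points(traj.params)
    c_mid = 0.5 * (critical.c_fwd + critical.c_bwd)
    c_ref = critical.c_fwd
    c = traj.cbar
    t = traj.times
    x = traj.x
    dt = traj.dt
    w_dwell = max(1, int(round(min_dwell / dt)))
    w_look = max(1, int(round(lookaround / dt)))
    n = len(c)

    above_mid = c > c_mid
    crossings = np.flatnonzero(np.diff(above_mid.astype(np.int8)))
    below_ref = c < c_ref
    events: list[JumpEvent] = []
    for i in crossings:
        downward = above_mid[i]
        if downward:
            lo = max(0, i - w_dwell)
            sustained = i - w_dwell >= 0 and not below_ref[lo:i].any()
        else:
            hi = min(n, i + 1 + w_dwell)
            sustained = i + w_dwell < n and not below_ref[i + 1 : hi].any()
        if not sustained:
            continue
        events.append(
            JumpEvent(
                direction="forward" if downward else "backward",
                t=float(t[i]),
                x_at_event=float(x[i]),
                cbar_before=float(c[max(0, i - w_look)]),
                cbar_after=float(c[min(n - 1, i + w_look)]),
            )
        )
    if not events:
        warnings.warn("no hysteresis transitions detected in trajectory")
    return events
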