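"""Shared integration and steady-state machinery for the pathway models.

All three models are small, mildly stiff ODE systems in uM/min units.  They
share one convergence convention: a state is steady when the largest relative
rate of change max_i |dy_i/dt| / max(|y_i|, floor) falls below `ss_tol`
(per minute).  Steady states are found by chunked integration with LSODA;
an independent algebraic route (root of the RHS on reduced coordinates) is
provided per model for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "Trajectory",
    "SteadyState",
    "IntegrationError",
    "integrate",
    "integrate_to_steady",
    "solve_positive_root",
]

#: Default relative solver tolerance.
RTOL = 1e-8
#: Default absolute solver tolerance (uM).
ATOL = 1e-10
#: Steady-state criterion: max relative rate of change, per minute.
SS_TOL = 1e-9
#: Floor (uM) for the relative-rate denominator, protecting near-zero species.
SS_FLOOR = 1e-6


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails or the state leaves its domain."""


@dataclass(frozen=True)
class Trajectory:
    """Dense time course: `t` (min,) and `y` (n_species, n_times) in uM."""

    t: np.ndarray
    y: np.ndarray
    names: tuple[str, ...]

    @property
    def final(self) -> np.ndarray:
        return self.y[:, -1]

    def species(self, name: str) -> np.ndarray:
        return self.y[self.names.index(name)]


@dataclass(frozen=True)
class SteadyState:
    """Endpoint of a relaxation run plus its convergence diagnostics."""

    state: np.ndarray
    names: tuple[str, ...]
    converged: bool
    residual: float  # max relative rate of change, per min
    time: float  # total integration time, min

    def species(self, name: str) -> float:
        return float(self.state[self.names.index(name)])


def solve_positive_root(
    residual: Callable,
    starts: list[np.ndarray],
    scale_factors: tuple[float, ...] = (1.0, 0.3, 3.0, 0.1, 10.0),
    ftol: float = 1e-12,
) -> np.ndarray:
    """Root of `residual` over strictly positive unknowns.

    Solves in log-coordinates (enforcing positivity and evening out scale
    differences) with a deterministic multi-start: each start vector is also
    tried rescaled by `scale_factors`.  Returns the first root whose maximum
    absolute residual, relative to the solution scale, is below `ftol**0.5`.
    """
    from scipy.optimize import root as _root

    best = None
    for start in starts:
        start = np.asarray(start, dtype=float)
        for factor in scale_factors:
            x0 = np.log(np.maximum(start * factor, 1e-12))
            # clamp the log coordinates so intermediate iterates cannot
            # overflow or collapse to exact zero
            expz = lambda z: np.exp(np.clip(z, -27.6, 27.6))
            sol = _root(lambda z: residual(expz(z)), x0, method="hybr")
            x = expz(sol.x)
            err = float(np.max(np.abs(residual(x))))
            if best is None or err < best[0]:
                best = (err, x)
            if sol.success and err < 1e-9:
                return x
    if best is None or best[0] > 1e-6:
        raise RuntimeError(
            f"steady-state root solve failed (best residual {None if best is None else best[0]:.3e})"
        )
    return best[1]


def rel_rate(rhs: Callable, y: np.ndarray, floor: float = SS_FLOOR) -> float:
    """Largest relative rate of change of any species, per minute."""
    dy = np.asarray(rhs(0.0, y), dtype=float)
    return float(np.max(np.abs(dy) / np.maximum(np.abs(y), floor)))


def integrate(
    rhs: Callable,
    y0: np.ndarray,
    horizon: float,
    names: tuple[str, ...],
    rtol: float = RTOL,
    atol: float = ATOL,
    n_points: int = 201,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate `rhs` over [0, horizon] and return a dense trajectory.

    Small negative excursions (below -1e-6 of the state scale) abort with
    `IntegrationError`; excursions within tolerance are clipped to zero.
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be > 0, got {horizon}")
    y0 = np.asarray(y0, dtype=float)
    sol = solve_ivp(
        rhs,
        (0.0, float(horizon)),
        y0,
        method=method,
        t_eval=np.linspace(0.0, float(horizon), n_points),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    scale = max(float(np.max(np.abs(y0))), 1.0)
    if np.min(sol.y) < -1e-6 * scale:
        raise IntegrationError(
            f"negative state excursion beyond tolerance (min {np.min(sol.y):.3e})"
        )
    return Trajectory(t=sol.t, y=np.clip(sol.y, 0.0, None), names=names)


def integrate_to_steady(
    rhs: Callable,
    y0: np.ndarray,
    names: tuple[str, ...],
    chunk: float = 2000.0,
    max_time: float = 2e6,
    ss_tol: float = SS_TOL,
    rtol: float = RTOL,
    atol: float = ATOL,
    frozen: tuple[int, ...] = (),
) -> SteadyState:
    """Relax to steady state by repeated integration chunks.

    `frozen` lists state indices excluded from the convergence criterion
    (e.g. a cumulative sink that grows without bound).
    """
    y = np.asarray(y0, dtype=float)
    mask = np.ones(len(y), dtype=bool)
    mask[list(frozen)] = False

    def residual(state: np.ndarray) -> float:
        dy = np.asarray(rhs(0.0, state), dtype=float)
        rel = np.abs(dy) / np.maximum(np.abs(state), SS_FLOOR)
        return float(np.max(rel[mask])) if mask.any() else 0.0

    elapsed = 0.0
    res = residual(y)
    while res > ss_tol and elapsed < max_time:
        sol = solve_ivp(rhs, (0.0, chunk), y, method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(f"ODE solver failed en route to steady state: {sol.message}")
        y = np.clip(sol.y[:, -1], 0.0, None)
        elapsed += chunk
        res = residual(y)
        chunk = min(chunk * 2.0, max_time - elapsed) if elapsed < max_time else chunk
    return SteadyState(state=y, names=names, converged=res <= ss_tol, residual=res, time=elapsed)
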