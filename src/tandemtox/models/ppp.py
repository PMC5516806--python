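"""Oxidative pentose-phosphate pathway: G6P supply to NADPH/NADP+ ratio.

Two NADP+-linked dehydrogenases — glucose-6-phosphate dehydrogenase (G6PD)
and 6-phosphogluconate dehydrogenase (6PGD) — oxidise G6P to ribulose-5-
phosphate, each reducing one NADP+ with bi-substrate Michaelis-Menten
kinetics v = Vmax * (A/(Km_A+A)) * (NADP/(Km_NADP+NADP)).  A first-order
NADPH demand (biosynthesis plus glutathione reduction, lumped) regenerates
NADP+.  G6P is a clamped supply relaxing toward ``g6p_initial`` at rate
``k_g6p_refresh``, so the steady state depends on the supplied G6P level:
less G6P means less oxidative flux and a lower NADPH/NADP+ ratio.  A
depleting (no-refresh) variant is available via ``clamped=False``.

Ribulose-5-phosphate is a terminal sink here (non-oxidative branch omitted):
it is reported as cumulative production and excluded from the steady-state
criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from tandemtox.models.base import (
    SteadyState,
    Trajectory,
    integrate,
    integrate_to_steady,
    solve_positive_root,
)

__all__ = [
    "PppParams",
    "PppState",
    "simulate_ppp",
    "steady_state",
    "steady_state_root",
    "nadph_ratio",
    "nadph_ratio_curve",
    "rescale_concentrations",
]

SPECIES = ("g6p", "pg6", "ru5p", "nadp", "nadph")
#: index of the cumulative ru5p sink, excluded from steadiness checks
_SINK = 2


@dataclass(frozen=True)
class PppParams:
    """Reference kinetic parameters (uM, min); a designed minimal oxidative
    branch, not a published parameterization."""

    vmax_g6pd: float = 10.0      # uM/min
    km_g6pd_g6p: float = 50.0    # uM
    km_g6pd_nadp: float = 10.0   # uM
    vmax_6pgd: float = 10.0      # uM/min
    km_6pgd_6pg: float = 20.0    # uM
    km_6pgd_nadp: float = 10.0   # uM
    k_nadph_drain: float = 0.2   # /min, lumped NADPH demand
    k_g6p_refresh: float = 1.0   # /min, relaxation to the supplied G6P level
    nadp_total: float = 50.0     # uM conserved pyridine pool
    g6p_initial: float = 100.0   # uM reference G6P supply level

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if name == "g6p_initial":
                if not np.isfinite(value) or value < 0:
                    raise ValueError(f"g6p_initial must be >= 0, got {value}")
            elif not np.isfinite(value) or value <= 0:
                raise ValueError(f"parameter {name} must be finite and > 0, got {value}")


@dataclass(frozen=True)
class PppState:
    g6p: float
    pg6: float
    ru5p: float
    nadp: float
    nadph: float

    def as_array(self) -> np.ndarray:
        return np.array([self.g6p, self.pg6, self.ru5p, self.nadp, self.nadph])


def _rhs(t: float, y: np.ndarray, p: PppParams, g6p_target: float, clamped: bool) -> np.ndarray:
    g6p, pg6, _ru5p, nadp, nadph = y
    v1 = p.vmax_g6pd * (g6p / (p.km_g6pd_g6p + g6p)) * (nadp / (p.km_g6pd_nadp + nadp))
    v2 = p.vmax_6pgd * (pg6 / (p.km_6pgd_6pg + pg6)) * (nadp / (p.km_6pgd_nadp + nadp))
    refresh = p.k_g6p_refresh * (g6p_target - g6p) if clamped else 0.0
    drain = p.k_nadph_drain * nadph
    return np.array([refresh - v1, v1 - v2, v2, drain - v1 - v2, v1 + v2 - drain])


def _initial_state(p: PppParams, g6p_initial: float) -> np.ndarray:
    # start fully oxidised; the pyridine pool redistributes dynamically
    return np.array([g6p_initial, 0.0, 0.0, p.nadp_total, 0.0])


def simulate_ppp(
    params: PppParams,
    g6p_initial: float | None = None,
    horizon: float = 500.0,
    clamped: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the oxidative branch from a fully oxidised pyridine pool."""
    g6p0 = params.g6p_initial if g6p_initial is None else float(g6p_initial)
    if g6p0 < 0:
        raise ValueError("g6p_initial must be >= 0")
    return integrate(
        lambda t, y: _rhs(t, y, params, g6p0, clamped),
        _initial_state(params, g6p0),
        horizon,
        SPECIES,
        rtol=rtol,
        atol=atol,
    )


def steady_state(
    params: PppParams, g6p_initial: float | None = None, clamped: bool = True
) -> SteadyState:
    """Relax the dynamical core to steady state (ru5p sink excluded)."""
    g6p0 = params.g6p_initial if g6p_initial is None else float(g6p_initial)
    return integrate_to_steady(
        lambda t, y: _rhs(t, y, params, g6p0, clamped),
        _initial_state(params, g6p0),
        SPECIES,
        chunk=500.0,
        frozen=(_SINK,),
    )


def steady_state_root(params: PppParams, g6p_initial: float | None = None) -> np.ndarray:
    """Algebraic steady state of the clamped-supply core (g6p, 6pg, nadph);
    nadp eliminated via the conserved pool.  Independent of integration."""
    p = params
    g6p0 = p.g6p_initial if g6p_initial is None else float(g6p_initial)
    if g6p0 == 0.0:  # no substrate: fluxes vanish, NADPH drains away
        return np.array([0.0, 0.0, 0.0, p.nadp_total, 0.0])

    # nadph parameterized as total*b/(1+b) to stay inside the pyridine pool
    def residual(u: np.ndarray) -> np.ndarray:
        g6p, pg6, b = u
        nadph = p.nadp_total * b / (1.0 + b)
        y = np.array([g6p, pg6, 0.0, p.nadp_total - nadph, nadph])
        f = _rhs(0.0, y, p, g6p0, True)
        return np.array([f[0], f[1], f[4]])

    starts = [
        np.array([g6p0, 0.5 * p.km_6pgd_6pg, 1.0]),
        np.array([0.5 * g6p0, 5.0 * p.km_6pgd_6pg, 0.1]),
    ]
    g6p, pg6, b = solve_positive_root(residual, starts)
    nadph = p.nadp_total * b / (1.0 + b)
    return np.array([g6p, pg6, 0.0, p.nadp_total - nadph, nadph])


def nadph_ratio(state: np.ndarray, floor: float = 1e-12) -> float:
    """NADPH/NADP+ ratio of a state vector (ordered as SPECIES)."""
    return float(state[4] / max(state[3], floor))


def nadph_ratio_curve(
    params: PppParams, g6p_grid, clamped: bool = True
) -> list[dict[str, float | bool]]:
    """Steady-state NADPH/NADP+ ratio for each supplied G6P level.

    Returns one record per grid point with the ratio and a convergence flag.
    """
    records = []
    for g6p0 in g6p_grid:
        if g6p0 < 0:
            raise ValueError("g6p grid values must be >= 0")
        ss = steady_state(params, g6p_initial=float(g6p0), clamped=clamped)
        records.append(
            {
                "g6p_initial": float(g6p0),
                "nadph_ratio": nadph_ratio(ss.state),
                "nadph": ss.species("nadph"),
                "converged": ss.converged,
            }
        )
    return records


_CONC_FIELDS = (
    "vmax_g6pd", "km_g6pd_g6p", "km_g6pd_nadp",
    "vmax_6pgd", "km_6pgd_6pg", "km_6pgd_nadp",
    "nadp_total", "g6p_initial",
)


def rescale_concentrations(params: PppParams, factor: float) -> PppParams:
    """Express the model in concentration units scaled by `factor`."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    return replace(params, **{f: getattr(params, f) * factor for f in _CONC_FIELDS})
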