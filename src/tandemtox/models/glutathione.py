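"""Glutathione redox cycle under H2O2 load, with an optional vitamin-E node.

Glutathione peroxidase (GPx) detoxifies H2O2 at the cost of two reduced
glutathione (2 GSH + H2O2 -> GSSG + 2 H2O); glutathione reductase (GR)
regenerates GSH using NADPH (GSSG + NADPH -> 2 GSH + NADP+).  NADPH is
resupplied at flux ``k_nadph_supply`` scaled by the oxidised fraction of the
pyridine pool — this supply is the handle through which an upstream
pentose-phosphate deficit (the drug condition) is imposed.  Optional
first-order GSSG efflux and zero-order GSH synthesis open the glutathione
moiety; both default to zero, closing the pool (GSH + 2 GSSG conserved).

The vitamin-E node quenches H2O2 directly at second-order rate
``k_vite_quench * vite_pool * h2o2``; the tocopherol pool is treated as
non-depleting (regenerated by other cellular reductants) by default, with a
depleting variant behind a flag.  Quenching relieves GPx demand for GSH, so
antioxidant loading restores GSH under a reduced NADPH supply.
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
    "GshParams",
    "GshState",
    "simulate_gsh",
    "steady_state",
    "steady_state_root",
    "gsh_vs_nadph",
    "gsh_vs_vitamin_e",
    "unstressed_gsh",
    "rescale_concentrations",
]

SPECIES = ("gsh", "gssg", "h2o2", "nadph", "nadp")
#: index of the depleting vitamin-E pool when enabled
_VITE = 5


@dataclass(frozen=True)
class GshParams:
    """Reference kinetics (uM, min); a compact designed redox cycle."""

    k_h2o2_prod: float = 2.0      # uM/min constant H2O2 production
    vmax_gpx: float = 50.0        # uM/min
    km_gpx_gsh: float = 1000.0    # uM
    km_gpx_h2o2: float = 1.0      # uM
    vmax_gr: float = 10.0         # uM/min
    km_gr_gssg: float = 500.0     # uM
    km_gr_nadph: float = 50.0     # uM
    k_nadph_supply: float = 10.0  # uM/min, the tandem interface parameter
    k_synth: float = 0.0          # uM/min de-novo GSH synthesis
    k_efflux: float = 0.0         # /min GSSG efflux/degradation
    k_vite_quench: float = 1.0    # /uM/min second-order vitamin-E quench
    vite_pool: float = 0.0        # uM vitamin E (0 disables the node)
    nadp_total: float = 50.0      # uM conserved pyridine pool
    gsh_total_init: float = 3000.0  # uM initial total glutathione (GSH + 2 GSSG)

    def __post_init__(self) -> None:
        positive = {"vmax_gpx", "km_gpx_gsh", "km_gpx_h2o2", "vmax_gr", "km_gr_gssg",
                    "km_gr_nadph", "nadp_total", "gsh_total_init"}
        for name, value in self.__dict__.items():
            if not np.isfinite(value) or value < 0 or (name in positive and value <= 0):
                raise ValueError(f"parameter {name} out of domain: {value}")


@dataclass(frozen=True)
class GshState:
    gsh: float
    gssg: float
    h2o2: float
    nadph: float
    nadp: float

    def as_array(self) -> np.ndarray:
        return np.array([self.gsh, self.gssg, self.h2o2, self.nadph, self.nadp])


def default_initial(params: GshParams) -> GshState:
    """Fully reduced glutathione pool, fully reduced pyridine pool, no H2O2."""
    return GshState(
        gsh=params.gsh_total_init, gssg=0.0, h2o2=0.0,
        nadph=params.nadp_total, nadp=0.0,
    )


def _rhs(t: float, y: np.ndarray, p: GshParams, depleting_vite: bool) -> np.ndarray:
    gsh, gssg, h2o2, nadph, nadp = y[:5]
    vite = y[_VITE] if depleting_vite else p.vite_pool
    v_gpx = p.vmax_gpx * (gsh / (p.km_gpx_gsh + gsh)) * (h2o2 / (p.km_gpx_h2o2 + h2o2))
    v_gr = p.vmax_gr * (gssg / (p.km_gr_gssg + gssg)) * (nadph / (p.km_gr_nadph + nadph))
    v_quench = p.k_vite_quench * vite * h2o2
    v_supply = p.k_nadph_supply * (nadp / p.nadp_total)
    dydt = [
        p.k_synth + 2.0 * v_gr - 2.0 * v_gpx,        # gsh
        v_gpx - v_gr - p.k_efflux * gssg,            # gssg
        p.k_h2o2_prod - v_gpx - v_quench,            # h2o2
        v_supply - v_gr,                             # nadph
        v_gr - v_supply,                             # nadp
    ]
    if depleting_vite:
        dydt.append(-v_quench)
    return np.array(dydt)


def simulate_gsh(
    params: GshParams,
    initial: GshState | None = None,
    horizon: float = 1000.0,
    depleting_vite: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the redox cycle; vitamin E is a parameter unless depleting."""
    if initial is None:
        initial = default_initial(params)
    y0 = initial.as_array()
    names = SPECIES
    if depleting_vite:
        y0 = np.append(y0, params.vite_pool)
        names = SPECIES + ("vite",)
    return integrate(
        lambda t, y: _rhs(t, y, params, depleting_vite),
        y0,
        horizon,
        names,
        rtol=rtol,
        atol=atol,
    )


def steady_state(params: GshParams, initial: GshState | None = None) -> SteadyState:
    """Relax to steady state (non-depleting vitamin-E node)."""
    if initial is None:
        initial = default_initial(params)
    return integrate_to_steady(
        lambda t, y: _rhs(t, y, params, False), initial.as_array(), SPECIES, chunk=2000.0
    )


def steady_state_root(params: GshParams) -> np.ndarray:
    """Algebraic steady state via root-solving, independent of integration.

    With synthesis/efflux off, both moieties are conserved and the system
    reduces to (gssg, h2o2, nadph); otherwise the full 5-state root is used.
    """
    p = params
    closed = p.k_synth == 0.0 and p.k_efflux == 0.0
    half_pool = 0.5 * p.gsh_total_init

    if closed:
        # gssg bounded by the glutathione moiety, nadph by the pyridine pool
        def residual(u: np.ndarray) -> np.ndarray:
            c, h2o2, b = u
            gssg = half_pool * c / (1.0 + c)
            nadph = p.nadp_total * b / (1.0 + b)
            y = np.array([p.gsh_total_init - 2.0 * gssg, gssg, h2o2,
                          nadph, p.nadp_total - nadph])
            f = _rhs(0.0, y, p, False)
            return np.array([f[1], f[2], f[3]])

        starts = [np.array([0.2, 0.1 * p.km_gpx_h2o2, 1.0]),
                  np.array([2.0, p.km_gpx_h2o2, 0.2])]
        c, h2o2, b = solve_positive_root(residual, starts)
        gssg = half_pool * c / (1.0 + c)
        nadph = p.nadp_total * b / (1.0 + b)
        return np.array([p.gsh_total_init - 2.0 * gssg, gssg, h2o2,
                         nadph, p.nadp_total - nadph])

    def residual_open(u: np.ndarray) -> np.ndarray:
        gsh, gssg, h2o2, b = u
        nadph = p.nadp_total * b / (1.0 + b)
        y = np.array([gsh, gssg, h2o2, nadph, p.nadp_total - nadph])
        return _rhs(0.0, y, p, False)[:4]

    starts = [np.array([p.gsh_total_init, 0.1 * half_pool, 0.1 * p.km_gpx_h2o2, 1.0])]
    gsh, gssg, h2o2, b = solve_positive_root(residual_open, starts)
    nadph = p.nadp_total * b / (1.0 + b)
    return np.array([gsh, gssg, h2o2, nadph, p.nadp_total - nadph])


def gsh_vs_nadph(params: GshParams, nadph_supply_grid) -> list[dict[str, float | bool]]:
    """Steady-state GSH as a function of the NADPH supply flux (uM/min)."""
    records = []
    for supply in nadph_supply_grid:
        if supply < 0:
            raise ValueError("NADPH supply values must be >= 0")
        ss = steady_state(replace(params, k_nadph_supply=float(supply)))
        records.append(
            {
                "k_nadph_supply": float(supply),
                "gsh": ss.species("gsh"),
                "gssg": ss.species("gssg"),
                "converged": ss.converged,
            }
        )
    return records


def gsh_vs_vitamin_e(params: GshParams, vite_grid) -> list[dict[str, float | bool]]:
    """Steady-state GSH versus vitamin-E load, at the supplied (typically
    drug-reduced) NADPH supply held in `params`."""
    records = []
    for vite in vite_grid:
        if vite < 0:
            raise ValueError("vitamin-E pool values must be >= 0")
        ss = steady_state(replace(params, vite_pool=float(vite)))
        h2o2 = ss.species("h2o2")
        records.append(
            {
                "vite_pool": float(vite),
                "gsh": ss.species("gsh"),
                "h2o2": h2o2,
                "quench_flux": params.k_vite_quench * float(vite) * h2o2,
                "converged": ss.converged,
            }
        )
    return records


def unstressed_gsh(params: GshParams) -> float:
    """Steady-state GSH with no H2O2 load and full NADPH supply — the
    benchmark an antioxidant rescue is measured against."""
    ss = steady_state(replace(params, k_h2o2_prod=0.0, vite_pool=0.0))
    return ss.species("gsh")


_CONC_FIELDS = (
    "k_h2o2_prod", "vmax_gpx", "km_gpx_gsh", "km_gpx_h2o2",
    "vmax_gr", "km_gr_gssg", "km_gr_nadph", "k_nadph_supply",
    "k_synth", "vite_pool", "nadp_total", "gsh_total_init",
)


def rescale_concentrations(params: GshParams, factor: float) -> GshParams:
    """Express the model in concentration units scaled by `factor`; the
    second-order quench constant scales inversely."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    changes = {f: getattr(params, f) * factor for f in _CONC_FIELDS}
    changes["k_vite_quench"] = params.k_vite_quench / factor
    return replace(params, **changes)
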