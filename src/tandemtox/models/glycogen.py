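"""Glycogen-phosphorylase cascade with competitive drug inhibition of PHK.

Phosphorylase kinase (PHK) phosphorylates inactive glycogen phosphorylase
(GPb -> GPa, activating glycogenolysis) and, as part of the same kinase
activity, inactivates glycogen synthase (GSa -> GSb).  Protein phosphatase 1
reverses both.  A multi-targeted kinase inhibitor acts as a competitive
inhibitor of PHK with inhibition constant ``ki_drug`` (default 5.5 uM), so
increasing drug shifts the cascade toward less phosphorylase and more
synthase activity: glycogen accumulates and glucose-6-phosphate (G6P) falls.

Species (uM): gpa/gpb (active/inactive phosphorylase, conserved pool),
gsa/gsb (active/inactive synthase, conserved pool), gly (glucosyl units of
glycogen), g6p.  Rates in uM/min; time in minutes.

A first-order non-phosphorolytic glycogen turnover (``k_gly_loss``, lumping
lysosomal/debranching routes that do not return glucosyl units to the G6P
pool) gives the glycogen branch a genuine steady state at which synthesis
exceeds phosphorolysis, so steady-state G6P retains its dependence on drug
dose.
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
    "GlycogenParams",
    "GlycogenState",
    "CascadeEndpoint",
    "phk_rate",
    "simulate_glycogen",
    "endpoint_summary",
    "reference_steady_state",
    "steady_state",
    "steady_state_root",
    "rescale_concentrations",
]

SPECIES = ("gpa", "gpb", "gsa", "gsb", "gly", "g6p")


@dataclass(frozen=True)
class GlycogenParams:
    """Kinetic parameters; units uM and minutes.  Defaults are the packaged
    reference set (a designed minimal cascade, not a published fit)."""

    vmax_phk: float = 1.0       # uM/min, PHK on GPb
    km_phk: float = 5.0         # uM
    ki_drug: float = 5.5        # uM, competitive inhibition constant
    vmax_pp1: float = 2.0       # uM/min, PP1 on GPa and on GSb
    km_pp1: float = 5.0         # uM
    k_gs_inact: float = 1.0     # /min, GS inactivation per unit scaled PHK activity
    vmax_gp: float = 2.55       # /min per uM GPa, glycogenolysis
    km_gp_gly: float = 2000.0   # uM
    vmax_gs: float = 15.0       # /min per uM GSa, glycogen synthesis
    km_gs_g6p: float = 100.0    # uM
    k_g6p_in: float = 10.0      # uM/min, lumped hexokinase supply
    k_g6p_out: float = 0.1      # /min, drain to glycolysis
    k_gly_loss: float = 0.001   # /min, non-phosphorolytic glycogen turnover
    gp_total: float = 10.0      # uM conserved phosphorylase pool
    gs_total: float = 10.0      # uM conserved synthase pool
    gly_cap: float = 50000.0    # uM, synthesis capacity ceiling

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"parameter {name} must be finite and > 0, got {value}")


@dataclass(frozen=True)
class GlycogenState:
    gpa: float
    gpb: float
    gsa: float
    gsb: float
    gly: float
    g6p: float

    def as_array(self) -> np.ndarray:
        return np.array([self.gpa, self.gpb, self.gsa, self.gsb, self.gly, self.g6p])

    @staticmethod
    def from_array(y: np.ndarray) -> "GlycogenState":
        return GlycogenState(*map(float, y))


@dataclass(frozen=True)
class CascadeEndpoint:
    """Activities and contents at the end of a simulation."""

    phk_activity: float  # uM/min flux through PHK at the endpoint
    gp_activity: float   # fraction gpa / gp_total
    gs_activity: float   # fraction gsa / gs_total
    glycogen: float      # uM
    g6p: float           # uM


def phk_rate(substrate: float, inhibitor: float, params: GlycogenParams) -> float:
    """Competitively inhibited Michaelis-Menten PHK flux, uM/min.

    v = Vmax * S / (Km * (1 + I/Ki) + S): the inhibitor raises the apparent
    Km without touching Vmax, so saturating substrate overrides inhibition.
    """
    substrate = np.asarray(substrate, dtype=float)
    inhibitor = np.asarray(inhibitor, dtype=float)
    if np.any(substrate < 0) or np.any(inhibitor < 0):
        raise ValueError("substrate and inhibitor concentrations must be >= 0")
    km_app = params.km_phk * (1.0 + inhibitor / params.ki_drug)
    v = params.vmax_phk * substrate / (km_app + substrate)
    return float(v) if v.ndim == 0 else v


def _fluxes(y: np.ndarray, drug: float, p: GlycogenParams) -> tuple[float, ...]:
    gpa, gpb, gsa, gsb, gly, g6p = y
    km_app = p.km_phk * (1.0 + drug / p.ki_drug)
    v_phk = p.vmax_phk * gpb / (km_app + gpb)
    v_pp1_gp = p.vmax_pp1 * gpa / (p.km_pp1 + gpa)
    v_pp1_gs = p.vmax_pp1 * gsb / (p.km_pp1 + gsb)
    # GS is phosphorylated by the same kinase activity, scaled to [0, 1).
    v_gs_inact = p.k_gs_inact * (v_phk / p.vmax_phk) * gsa
    v_gp = p.vmax_gp * gpa * gly / (p.km_gp_gly + gly)
    v_gs = p.vmax_gs * gsa * (g6p / (p.km_gs_g6p + g6p)) * max(1.0 - gly / p.gly_cap, 0.0)
    return v_phk, v_pp1_gp, v_pp1_gs, v_gs_inact, v_gp, v_gs


def _rhs(t: float, y: np.ndarray, drug: float, p: GlycogenParams) -> np.ndarray:
    v_phk, v_pp1_gp, v_pp1_gs, v_gs_inact, v_gp, v_gs = _fluxes(y, drug, p)
    gly, g6p = y[4], y[5]
    return np.array(
        [
            v_phk - v_pp1_gp,                     # gpa
            v_pp1_gp - v_phk,                     # gpb
            v_pp1_gs - v_gs_inact,                # gsa
            v_gs_inact - v_pp1_gs,                # gsb
            v_gs - v_gp - p.k_gly_loss * gly,     # gly
            p.k_g6p_in + v_gp - v_gs - p.k_g6p_out * g6p,  # g6p
        ]
    )


def simulate_glycogen(
    params: GlycogenParams,
    initial: GlycogenState,
    drug_conc: float,
    horizon: float = 1000.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the cascade at a fixed drug concentration (uM)."""
    if drug_conc < 0:
        raise ValueError("drug_conc must be >= 0")
    y0 = initial.as_array()
    if np.any(y0 < 0):
        raise ValueError("initial state must be non-negative")
    return integrate(
        lambda t, y: _rhs(t, y, drug_conc, params),
        y0,
        horizon,
        SPECIES,
        rtol=rtol,
        atol=atol,
    )


def endpoint_summary(
    trajectory: Trajectory, params: GlycogenParams, drug_conc: float
) -> CascadeEndpoint:
    """Activities/contents at the final time point; PHK flux recomputed
    from the final state."""
    y = trajectory.final
    return CascadeEndpoint(
        phk_activity=phk_rate(y[1], drug_conc, params),
        gp_activity=float(y[0] / params.gp_total),
        gs_activity=float(y[2] / params.gs_total),
        glycogen=float(y[4]),
        g6p=float(y[5]),
    )


def steady_state(
    params: GlycogenParams, drug_conc: float, initial: GlycogenState | None = None
) -> SteadyState:
    """Relax to the steady state at `drug_conc` by chunked integration."""
    if initial is None:
        initial = _default_initial(params)
    return integrate_to_steady(
        lambda t, y: _rhs(t, y, drug_conc, params), initial.as_array(), SPECIES
    )


def reference_steady_state(params: GlycogenParams) -> GlycogenState:
    """Drug-free steady state, the documented reference initial condition."""
    ss = steady_state_root(params, drug_conc=0.0)
    return GlycogenState.from_array(ss)


def steady_state_root(
    params: GlycogenParams, drug_conc: float, guess: GlycogenState | None = None
) -> np.ndarray:
    """Algebraic steady state: root of the RHS on reduced coordinates.

    The conserved pools are eliminated (gpb = gp_total - gpa, likewise GS),
    leaving a 4-dimensional root problem solved with a quasi-Newton method.
    Independent of the time-integration route.
    """
    p = params
    if guess is None:
        guess = _default_initial(p)
    g = guess.as_array()

    # active fractions are parameterized as total*a/(1+a), a > 0, keeping
    # both conserved pools inside their bounds during iteration
    def odds(x: float, total: float) -> float:
        x = min(max(x, 1e-9 * total), (1.0 - 1e-9) * total)
        return x / (total - x)

    def residual(u: np.ndarray) -> np.ndarray:
        a_gp, a_gs, gly, g6p = u
        gpa = p.gp_total * a_gp / (1.0 + a_gp)
        gsa = p.gs_total * a_gs / (1.0 + a_gs)
        y = np.array([gpa, p.gp_total - gpa, gsa, p.gs_total - gsa, gly, g6p])
        f = _rhs(0.0, y, drug_conc, p)
        return np.array([f[0], f[2], f[4], f[5]])

    starts = [
        np.array([odds(g[0], p.gp_total), odds(g[2], p.gs_total), max(g[4], 1.0), max(g[5], 1.0)]),
        np.array([1.0, 1.0, 0.1 * p.gly_cap, p.k_g6p_in / p.k_g6p_out]),
    ]
    a_gp, a_gs, gly, g6p = solve_positive_root(residual, starts)
    gpa = p.gp_total * a_gp / (1.0 + a_gp)
    gsa = p.gs_total * a_gs / (1.0 + a_gs)
    return np.array([gpa, p.gp_total - gpa, gsa, p.gs_total - gsa, gly, g6p])


def _default_initial(p: GlycogenParams) -> GlycogenState:
    """Neutral starting point: half-active pools, modest stores."""
    return GlycogenState(
        gpa=0.5 * p.gp_total,
        gpb=0.5 * p.gp_total,
        gsa=0.5 * p.gs_total,
        gsb=0.5 * p.gs_total,
        gly=0.1 * p.gly_cap,
        g6p=p.k_g6p_in / p.k_g6p_out,
    )


_CONC_FIELDS = (
    "vmax_phk", "km_phk", "ki_drug", "vmax_pp1", "km_pp1",
    "km_gp_gly", "km_gs_g6p", "k_g6p_in", "gp_total", "gs_total", "gly_cap",
)


def rescale_concentrations(params: GlycogenParams, factor: float) -> GlycogenParams:
    """Express the model in concentration units scaled by `factor`.

    First-order rate constants (per-min) are unit-free and unchanged; drug
    concentrations passed to a rescaled model must be rescaled consistently.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    return replace(params, **{f: getattr(params, f) * factor for f in _CONC_FIELDS})
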