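"""Sequential (tandem) coupling of the three pathway models.

The three models are parameterized independently and may use different
baseline scales; what transfers between them is the *relative* change of the
interface species, not its absolute value.  For each drug dose the chain is:

1. glycogen cascade at the dose → fold-change of steady-state G6P
   (relative to the drug-free steady state);
2. pentose-phosphate model with its G6P supply multiplied by that
   fold-change → fold-change of the steady-state NADPH/NADP+ ratio;
3. glutathione model with its NADPH supply flux multiplied by that
   fold-change → steady-state GSH.

Because only ratios propagate, the composition at dose 0 is the identity and
the scan is invariant to rescaling any single model's concentration units.
There is no feedback across interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import pandas as pd

from tandemtox.models import glutathione as gsh_model
from tandemtox.models import glycogen as glycogen_model
from tandemtox.models import ppp as ppp_model

__all__ = [
    "FoldChange",
    "InterfaceSpec",
    "TandemChain",
    "DoseScan",
    "fold_changes",
    "model_fold_changes",
    "propagate",
    "run_tandem",
]


@dataclass(frozen=True)
class FoldChange:
    """Relative change of one quantity between baseline and perturbed runs."""

    quantity: str
    baseline: float
    perturbed: float

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError(
                f"fold-change of {self.quantity!r} needs a positive baseline, "
                f"got {self.baseline}"
            )

    @property
    def ratio(self) -> float:
        return self.perturbed / self.baseline


@dataclass(frozen=True)
class InterfaceSpec:
    """How an upstream model's output adjusts a downstream model's input.

    `species_map` maps upstream quantity names to downstream parameter
    names.  In fold-change mode (default) the downstream parameter is
    multiplied by the upstream ratio; in absolute mode it is overwritten
    with the upstream perturbed value (only meaningful when the two models
    share units, hence non-default).
    """

    upstream_model: str
    downstream_model: str
    species_map: tuple[tuple[str, str], ...]
    coupling_mode: Literal["fold-change", "absolute"] = "fold-change"

    def __post_init__(self) -> None:
        if not self.species_map:
            raise ValueError("species_map must be non-empty")
        if self.coupling_mode not in ("fold-change", "absolute"):
            raise ValueError(f"unknown coupling mode {self.coupling_mode!r}")


#: model-1 → model-2 coupling: steady-state G6P scales the PPP G6P supply.
G6P_INTERFACE = InterfaceSpec("glycogen", "ppp", (("g6p", "g6p_initial"),))
#: model-2 → model-3 coupling: NADPH/NADP+ ratio scales the NADPH supply flux.
NADPH_INTERFACE = InterfaceSpec("ppp", "gsh", (("nadph_ratio", "k_nadph_supply"),))


@dataclass(frozen=True)
class TandemChain:
    """The three parameter sets plus their two interfaces."""

    glycogen: glycogen_model.GlycogenParams = field(
        default_factory=glycogen_model.GlycogenParams
    )
    ppp: ppp_model.PppParams = field(default_factory=ppp_model.PppParams)
    gsh: gsh_model.GshParams = field(default_factory=gsh_model.GshParams)
    interfaces: tuple[InterfaceSpec, ...] = (G6P_INTERFACE, NADPH_INTERFACE)

    def __post_init__(self) -> None:
        order = ("glycogen", "ppp", "gsh")
        for spec in self.interfaces:
            i = order.index(spec.upstream_model)
            if order[i + 1] != spec.downstream_model:
                raise ValueError(
                    f"interface {spec.upstream_model}->{spec.downstream_model} "
                    "must connect adjacent models"
                )


@dataclass(frozen=True)
class DoseScan:
    """Per-dose endpoints and interface fold-changes of a tandem scan."""

    records: tuple[dict, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.records))


def fold_changes(
    baseline_values: dict[str, float], perturbed_values: dict[str, float], quantities
) -> list[FoldChange]:
    """Fold-changes of `quantities` between two named-value mappings."""
    out = []
    for q in quantities:
        if q not in baseline_values or q not in perturbed_values:
            raise KeyError(f"quantity {q!r} missing from model outputs")
        out.append(FoldChange(q, float(baseline_values[q]), float(perturbed_values[q])))
    return out


def model_fold_changes(
    model: str, params, perturbation: dict, quantities
) -> list[FoldChange]:
    """Run a named model at baseline and under `perturbation`; return ratios.

    `perturbation` entries are either a drug dose (``{"drug_conc": x}`` for
    the glycogen cascade) or parameter overrides applied with
    ``dataclasses.replace`` (e.g. ``{"g6p_initial": 50.0}`` for the PPP
    model, ``{"k_nadph_supply": 5.0}`` for the glutathione model).
    """
    if model == "glycogen":
        dose = float(perturbation.get("drug_conc", 0.0))
        overrides = {k: v for k, v in perturbation.items() if k != "drug_conc"}
        base = glycogen_outputs(params, 0.0)
        pert = glycogen_outputs(replace(params, **overrides) if overrides else params, dose)
    elif model == "ppp":
        base = ppp_outputs(params)
        pert = ppp_outputs(replace(params, **perturbation))
    elif model == "gsh":
        base = gsh_outputs(params)
        pert = gsh_outputs(replace(params, **perturbation))
    else:
        raise ValueError(f"unknown model {model!r}")
    return fold_changes(base, pert, quantities)


def propagate(fc: Sequence[FoldChange], spec: InterfaceSpec, downstream_params):
    """Adjust a downstream parameter set according to an interface spec."""
    by_name = {f.quantity: f for f in fc}
    changes = {}
    for upstream_q, downstream_p in spec.species_map:
        if upstream_q not in by_name:
            raise KeyError(f"no fold-change supplied for interface quantity {upstream_q!r}")
        f = by_name[upstream_q]
        if spec.coupling_mode == "fold-change":
            changes[downstream_p] = getattr(downstream_params, downstream_p) * f.ratio
        else:
            changes[downstream_p] = f.perturbed
    return replace(downstream_params, **changes)


def glycogen_outputs(params: glycogen_model.GlycogenParams, drug_conc: float,
                     initial=None) -> dict[str, float]:
    """Steady-state quantities of the cascade exposed to the coupler."""
    ss = glycogen_model.steady_state(params, drug_conc, initial=initial)
    y = ss.state
    return {
        "phk_activity": glycogen_model.phk_rate(y[1], drug_conc, params),
        "gp_activity": float(y[0] / params.gp_total),
        "gs_activity": float(y[2] / params.gs_total),
        "glycogen": float(y[4]),
        "g6p": float(y[5]),
        "converged": float(ss.converged),
    }


def ppp_outputs(params: ppp_model.PppParams) -> dict[str, float]:
    ss = ppp_model.steady_state(params)
    return {
        "nadph": ss.species("nadph"),
        "nadph_ratio": ppp_model.nadph_ratio(ss.state),
        "converged": float(ss.converged),
    }


def gsh_outputs(params: gsh_model.GshParams) -> dict[str, float]:
    ss = gsh_model.steady_state(params)
    return {
        "gsh": ss.species("gsh"),
        "gssg": ss.species("gssg"),
        "h2o2": ss.species("h2o2"),
        "converged": float(ss.converged),
    }


def run_tandem(chain: TandemChain, drug_grid: Sequence[float]) -> DoseScan:
    """Scan drug dose through the full chain.

    The grid must include dose 0 (the shared baseline).  A stage failure at
    one dose is recorded (`status` column) and the scan continues.
    """
    drug_grid = [float(d) for d in drug_grid]
    if 0.0 not in drug_grid:
        raise ValueError("drug grid must include dose 0 (the baseline)")
    if any(d < 0 for d in drug_grid):
        raise ValueError("drug doses must be >= 0")

    ref_state = glycogen_model.reference_steady_state(chain.glycogen)
    base_glycogen = glycogen_outputs(chain.glycogen, 0.0, initial=ref_state)
    base_ppp = ppp_outputs(chain.ppp)
    g6p_spec, nadph_spec = chain.interfaces

    records = []
    for dose in drug_grid:
        rec: dict = {"drug_conc": dose, "status": "ok"}
        try:
            gly_out = glycogen_outputs(chain.glycogen, dose, initial=ref_state)
            fc1 = fold_changes(base_glycogen, gly_out, [q for q, _ in g6p_spec.species_map])
            ppp_params = propagate(fc1, g6p_spec, chain.ppp)
            ppp_out = ppp_outputs(ppp_params)
            fc2 = fold_changes(base_ppp, ppp_out, [q for q, _ in nadph_spec.species_map])
            gsh_params = propagate(fc2, nadph_spec, chain.gsh)
            gsh_out = gsh_outputs(gsh_params)
        except Exception as exc:  # per-dose failure, scan continues
            rec["status"] = f"failed: {exc}"
            records.append(rec)
            continue
        rec.update(
            phk_activity=gly_out["phk_activity"],
            gp_activity=gly_out["gp_activity"],
            gs_activity=gly_out["gs_activity"],
            glycogen=gly_out["glycogen"],
            g6p=gly_out["g6p"],
            g6p_fold=fc1[0].ratio,
            nadph_ratio=ppp_out["nadph_ratio"],
            nadph_ratio_fold=fc2[0].ratio,
            gsh=gsh_out["gsh"],
            gssg=gsh_out["gssg"],
            h2o2=gsh_out["h2o2"],
        )
        records.append(rec)
    return DoseScan(records=tuple(records))
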