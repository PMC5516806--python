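"""Seedable generators for every input the pipeline consumes.

The kinome generator emulates the structure of a two-drug selectivity panel:
both drugs bind a small set of shared primary targets tightly, one drug
("drug A") additionally binds a planted set of off-target kinases at
affinities comparable to its exposure, and the remaining kinome is weak
background (or censored).  Default ranges are chosen so the planted
off-targets — and only they — satisfy the documented shortlist thresholds
(occupancy >= 0.5 for drug A, <= 0.1 for drug B) for every seed, so the
differential shortlisting stage can always recover the planted truth.

Every generator is a pure function of its scenario (including the seed):
reruns are byte-identical.  No global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, is_dataclass, replace
from typing import Any

import numpy as np
import pandas as pd

from tandemtox.ic50 import InhibitionAssay, four_param_logistic
from tandemtox.occupancy import DrugExposure

__all__ = [
    "KinomeScenario",
    "AssayScenario",
    "generate_kinome_table",
    "generate_assay_curve",
    "jitter_params",
]


@dataclass(frozen=True)
class KinomeScenario:
    """Layout of a synthetic two-drug kinome affinity panel (Kd in uM)."""

    n_kinases: int = 50
    n_shared_primary: int = 3
    n_offtarget_a: int = 4
    kd_primary_range: tuple[float, float] = (0.001, 0.05)
    kd_offtarget_range: tuple[float, float] = (0.1, 0.9)
    kd_background_range: tuple[float, float] = (10.0, 10_000.0)
    cpuss_a: float = 1.0
    cpuss_b: float = 1.0
    censored_background_frac: float = 0.3
    drug_a: str = "drugA"
    drug_b: str = "drugB"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shared_primary + self.n_offtarget_a > self.n_kinases:
            raise ValueError("planted kinases exceed panel size")
        for lo, hi in (self.kd_primary_range, self.kd_offtarget_range,
                       self.kd_background_range):
            if not (0 < lo <= hi):
                raise ValueError("Kd ranges must be positive and ordered")
        if not 0 <= self.censored_background_frac <= 1:
            raise ValueError("censored_background_frac must be in [0, 1]")


@dataclass(frozen=True)
class AssayScenario:
    """Ground truth and design of a synthetic inhibition dilution series."""

    true_ic50: float = 5.5
    true_hill: float = 1.0
    top: float = 100.0
    bottom: float = 5.0
    conc_min: float = 0.01
    conc_max: float = 100.0
    n_concs: int = 8
    noise_cv: float = 0.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conc_max / self.conc_min < 100.0:
            raise ValueError("concentration grid must span at least 2 log units")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.true_ic50 <= 0 or self.true_hill <= 0:
            raise ValueError("true_ic50 and true_hill must be > 0")

    @property
    def conc_grid(self) -> np.ndarray:
        """Zero-inhibitor anchor plus a log-spaced dilution series."""
        return np.concatenate(
            [[0.0], np.geomspace(self.conc_min, self.conc_max, self.n_concs)]
        )


def _uniform(rng: np.random.Generator, bounds: tuple[float, float], n: int) -> np.ndarray:
    return rng.uniform(bounds[0], bounds[1], size=n)


def generate_kinome_table(
    scenario: KinomeScenario,
) -> tuple[pd.DataFrame, dict[str, DrugExposure], dict[str, Any]]:
    """Synthesize an affinity table, exposures, and a planted-truth manifest.

    Returns
    -------
    table:
        Long-format frame (kinase_id, drug_id, kd, unit) with kd in uM and
        NaN marking censored "no measurable binding" entries.
    exposures:
        ``{drug_id: DrugExposure}`` for both drugs.
    manifest:
        Planted assignments: shared-primary ids, drug-A off-target ids and
        the scenario used.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    width = len(str(sc.n_kinases - 1))
    kinases = np.array([f"KIN{idx:0{width}d}" for idx in range(sc.n_kinases)])
    roles = np.array(["background"] * sc.n_kinases, dtype=object)
    planted = rng.choice(sc.n_kinases, sc.n_shared_primary + sc.n_offtarget_a, replace=False)
    roles[planted[: sc.n_shared_primary]] = "primary"
    roles[planted[sc.n_shared_primary:]] = "offtarget_a"

    rows = []
    for idx, (kinase, role) in enumerate(zip(kinases, roles)):
        if role == "primary":
            kd_a = _uniform(rng, sc.kd_primary_range, 1)[0]
            kd_b = _uniform(rng, sc.kd_primary_range, 1)[0]
        elif role == "offtarget_a":
            kd_a = _uniform(rng, sc.kd_offtarget_range, 1)[0]
            kd_b = np.nan  # censored: no measurable binding for drug B
        else:
            kd_a = _uniform(rng, sc.kd_background_range, 1)[0]
            kd_b = (
                np.nan
                if rng.random() < sc.censored_background_frac
                else _uniform(rng, sc.kd_background_range, 1)[0]
            )
        rows.append((kinase, sc.drug_a, kd_a, "uM"))
        rows.append((kinase, sc.drug_b, kd_b, "uM"))

    table = pd.DataFrame(rows, columns=["kinase_id", "drug_id", "kd", "unit"])
    exposures = {
        sc.drug_a: DrugExposure(sc.drug_a, sc.cpuss_a),
        sc.drug_b: DrugExposure(sc.drug_b, sc.cpuss_b),
    }
    manifest = {
        "shared_primary": sorted(kinases[roles == "primary"].tolist()),
        "offtargets_a": sorted(kinases[roles == "offtarget_a"].tolist()),
        "scenario": {f.name: getattr(sc, f.name) for f in fields(sc)},
    }
    return table, exposures, manifest


def generate_assay_curve(scenario: AssayScenario) -> tuple[InhibitionAssay, dict[str, Any]]:
    """Synthesize a 4PL dilution series with multiplicative Gaussian noise."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    concs = sc.conc_grid
    clean = four_param_logistic(concs, sc.top, sc.bottom, sc.true_ic50, sc.true_hill)
    shape = (sc.replicates, concs.size) if sc.replicates > 1 else concs.size
    noise = rng.normal(1.0, sc.noise_cv, size=shape) if sc.noise_cv > 0 else np.ones(shape)
    responses = np.maximum(clean * noise, 1e-9)
    manifest = {f.name: getattr(sc, f.name) for f in fields(sc)}
    return InhibitionAssay(inhibitor_concs=concs, responses=responses), manifest


def jitter_params(reference_params, cv: float, seed: int):
    """Multiply each positive parameter by a log-normal factor of the given
    coefficient of variation; cv=0 is the identity.  Used for robustness
    sweeps of the pathway models' qualitative (monotonicity) claims."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if not is_dataclass(reference_params):
        raise TypeError("reference_params must be a parameter dataclass")
    if cv == 0:
        return reference_params
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))
    changes = {}
    for f in fields(reference_params):
        value = getattr(reference_params, f.name)
        if isinstance(value, (int, float)) and not isinstance(value, bool) and value > 0:
            changes[f.name] = float(value) * float(rng.lognormal(0.0, sigma))
    return replace(reference_params, **changes)
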