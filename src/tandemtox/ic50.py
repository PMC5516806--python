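"""Four-parameter-logistic IC50 fitting of in-vitro inhibition assays.

An inhibition assay measures remaining substrate signal (e.g. residual ATP in
a luminescent kinase assay) across an inhibitor dilution series.  The curve is
fitted with the four-parameter logistic (4PL, Hill) model

    response(c) = bottom + (top - bottom) / (1 + (c / IC50)^hill)

by unweighted (uniform-weight) nonlinear least squares.  The contract is the
minimised sum of squared residuals, not a particular optimiser: fitting uses a
bounded trust-region least-squares solver with multi-start over a log-spaced
grid of IC50 initial guesses, which is robust to poor starting values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = ["InhibitionAssay", "InhibitionFit", "fit_ic50", "four_param_logistic"]

#: Responses whose relative spread falls below this are non-identifiable.
_FLAT_TOL = 1e-9


@dataclass(frozen=True)
class InhibitionAssay:
    """Inhibitor concentration grid (uM) and measured responses (a.u.).

    `responses` may be 1-D (one value per concentration) or 2-D with a
    leading replicate axis; replicates are used as independent observations.
    A zero-inhibitor point anchors the uninhibited response.
    """

    inhibitor_concs: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        concs = np.asarray(self.inhibitor_concs, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "inhibitor_concs", concs)
        object.__setattr__(self, "responses", resp)
        if concs.ndim != 1:
            raise ValueError("inhibitor_concs must be 1-D")
        if np.any(concs < 0) or not np.all(np.isfinite(concs)):
            raise ValueError("inhibitor concentrations must be finite and >= 0")
        if len(np.unique(concs)) < 4:
            raise ValueError("need at least 4 distinct inhibitor concentrations")
        if 0.0 not in concs:
            raise ValueError("assay must include a zero-inhibitor point")
        if resp.shape[-1] != concs.shape[0]:
            raise ValueError("responses last axis must match inhibitor_concs")
        if np.any(resp <= 0) or not np.all(np.isfinite(resp)):
            raise ValueError("responses must be finite and > 0")

    def flattened(self) -> tuple[np.ndarray, np.ndarray]:
        """(concs, responses) with replicates unrolled to observations."""
        resp = np.atleast_2d(self.responses)
        concs = np.tile(self.inhibitor_concs, resp.shape[0])
        return concs, resp.ravel()


@dataclass(frozen=True)
class InhibitionFit:
    """Fitted 4PL parameters; `converged` is the optimiser success flag."""

    ic50: float
    hill: float
    top: float
    bottom: float
    rss: float
    converged: bool
    extrapolated: bool = field(default=False)

    def predict(self, concs: np.ndarray) -> np.ndarray:
        return four_param_logistic(
            np.asarray(concs, float), self.top, self.bottom, self.ic50, self.hill
        )


def four_param_logistic(
    concs: np.ndarray, top: float, bottom: float, ic50: float, hill: float
) -> np.ndarray:
    """4PL response; exactly `top` at zero inhibitor (hill > 0)."""
    concs = np.asarray(concs, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(concs > 0, (concs / ic50) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


def fit_ic50(
    assay: InhibitionAssay,
    fix_hill: float | None = None,
    n_starts: int = 8,
) -> InhibitionFit:
    """Least-squares 4PL fit with uniform weights.

    Parameters
    ----------
    assay:
        The dilution-series measurements.
    fix_hill:
        If given, the Hill slope is clamped to this value (e.g. 1.0 for pure
        one-site competition) and only three parameters are fitted.
    n_starts:
        Number of log-spaced IC50 starting values across the positive
        concentration range; the best (lowest-RSS) solution is kept.

    Raises
    ------
    ValueError
        If the responses are flat (curve carries no concentration
        information, so IC50 is non-identifiable).
    """
    concs, resp = assay.flattened()
    spread = resp.max() - resp.min()
    if spread <= _FLAT_TOL * max(1.0, abs(resp.mean())):
        raise ValueError("responses are flat: IC50 is non-identifiable")

    positive = np.unique(concs[concs > 0])
    lo, hi = positive.min(), positive.max()
    top0 = float(resp[concs == 0].mean())
    bot0 = float(resp[concs == concs.max()].mean())

    def residuals(theta: np.ndarray) -> np.ndarray:
        top, bottom, log_ic50, hill = _unpack(theta)
        return four_param_logistic(concs, top, bottom, np.exp(log_ic50), hill) - resp

    def _unpack(theta):
        if fix_hill is None:
            return theta[0], theta[1], theta[2], theta[3]
        return theta[0], theta[1], theta[2], fix_hill

    best = None
    for log_ic50_start in np.log(np.geomspace(lo, hi, n_starts)):
        x0 = [top0, bot0, log_ic50_start]
        lb = [0.0, 0.0, np.log(lo) - np.log(1e4)]
        ub = [np.inf, np.inf, np.log(hi) + np.log(1e4)]
        if fix_hill is None:
            x0.append(1.0)
            lb.append(0.05)
            ub.append(10.0)
        sol = least_squares(residuals, x0=x0, bounds=(lb, ub), method="trf")
        if best is None or sol.cost < best.cost:
            best = sol

    top, bottom, log_ic50, hill = _unpack(best.x)
    ic50 = float(np.exp(log_ic50))
    return InhibitionFit(
        ic50=ic50,
        hill=float(hill),
        top=float(top),
        bottom=float(bottom),
        rss=float(2.0 * best.cost),
        converged=bool(best.success),
        extrapolated=not (lo <= ic50 <= hi),
    )
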