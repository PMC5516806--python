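"""Glycogen-phosphorylase cascade: rate law, conservation, steady states."""

import numpy as np
import pytest

from tandemtox.models.glycogen import (
    GlycogenParams,
    GlycogenState,
    endpoint_summary,
    phk_rate,
    rescale_concentrations,
    simulate_glycogen,
    steady_state,
    steady_state_root,
)


def test_phk_rate_reduces_to_michaelis_menten(glycogen_params):
    p = glycogen_params
    for s in [0.1, 1.0, 5.0, 50.0]:
        assert phk_rate(s, 0.0, p) == pytest.approx(p.vmax_phk * s / (p.km_phk + s))


def test_phk_rate_competitive_limit(glycogen_params):
    p = glycogen_params
    assert phk_rate(5.0, 1e6 * p.ki_drug, p) < 1e-3 * p.vmax_phk


def test_phk_rate_half_inhibition_at_ki_low_substrate(glycogen_params):
    """At S << Km, I = Ki halves the rate (apparent Km doubles)."""
    p = glycogen_params
    s = 0.01 * p.km_phk
    ratio = phk_rate(s, p.ki_drug, p) / phk_rate(s, 0.0, p)
    assert 0.498 <= ratio <= 0.503


def test_phk_rate_rejects_negative_inputs(glycogen_params):
    with pytest.raises(ValueError):
        phk_rate(-1.0, 0.0, glycogen_params)
    with pytest.raises(ValueError):
        phk_rate(1.0, -0.1, glycogen_params)


def test_enzyme_pools_conserved(glycogen_params, glycogen_reference_state):
    p = glycogen_params
    traj = simulate_glycogen(p, glycogen_reference_state, drug_conc=25.0, horizon=2000.0)
    gp_pool = traj.species("gpa") + traj.species("gpb")
    gs_pool = traj.species("gsa") + traj.species("gsb")
    assert np.max(np.abs(gp_pool - p.gp_total)) / p.gp_total <= 1e-6
    assert np.max(np.abs(gs_pool - p.gs_total)) / p.gs_total <= 1e-6


def test_zero_drug_reference_state_is_fixed_point(glycogen_params, glycogen_reference_state):
    """Starting at the root-solved drug-free steady state, the trajectory stays put."""
    traj = simulate_glycogen(glycogen_params, glycogen_reference_state, drug_conc=0.0)
    y0 = glycogen_reference_state.as_array()
    assert np.max(np.abs(traj.final - y0) / np.maximum(np.abs(y0), 1e-6)) < 1e-3


def test_high_drug_shifts_cascade(glycogen_params, glycogen_reference_state):
    p = glycogen_params
    free = endpoint_summary(
        simulate_glycogen(p, glycogen_reference_state, 0.0, horizon=5000.0), p, 0.0
    )
    dosed = endpoint_summary(
        simulate_glycogen(p, glycogen_reference_state, 100.0 * p.ki_drug, horizon=5000.0),
        p, 100.0 * p.ki_drug,
    )
    assert dosed.gp_activity < free.gp_activity
    assert dosed.gs_activity > free.gs_activity
    assert dosed.glycogen > free.glycogen
    assert dosed.g6p < free.g6p


def test_endpoint_steadiness_under_horizon_doubling(glycogen_params):
    """From a relaxed state, doubling the horizon leaves the endpoint put."""
    p = glycogen_params
    relaxed = GlycogenState.from_array(steady_state(p, 10.0).state)
    e1 = endpoint_summary(simulate_glycogen(p, relaxed, 10.0, horizon=1000.0), p, 10.0)
    e2 = endpoint_summary(simulate_glycogen(p, relaxed, 10.0, horizon=2000.0), p, 10.0)
    for field in ("phk_activity", "gp_activity", "gs_activity", "glycogen", "g6p"):
        assert getattr(e1, field) == pytest.approx(getattr(e2, field), rel=1e-3)


def test_endpoint_invariant_to_tolerance_tightening(glycogen_params, glycogen_reference_state):
    p = glycogen_params
    loose = simulate_glycogen(p, glycogen_reference_state, 30.0, rtol=1e-6, atol=1e-8)
    tight = simulate_glycogen(p, glycogen_reference_state, 30.0, rtol=1e-9, atol=1e-11)
    assert np.max(np.abs(loose.final - tight.final) / np.maximum(tight.final, 1e-6)) < 1e-3


def test_integrated_steady_state_matches_root(glycogen_params):
    for drug in (0.0, 5.5, 55.0):
        integrated = steady_state(glycogen_params, drug).state
        algebraic = steady_state_root(glycogen_params, drug)
        assert np.max(np.abs(integrated - algebraic) / np.maximum(algebraic, 1e-6)) < 1e-3


def test_dose_grid_endpoints_monotone(glycogen_params):
    p = glycogen_params
    doses = [0.0] + list(np.geomspace(0.01, 100.0, 7))
    ss = [steady_state(p, d).state for d in doses]
    phk = [phk_rate(y[1], d, p) for y, d in zip(ss, doses)]
    gpa = [y[0] for y in ss]
    gsa = [y[2] for y in ss]
    gly = [y[4] for y in ss]
    g6p = [y[5] for y in ss]
    assert all(np.diff(phk) <= 1e-9)
    assert all(np.diff(gpa) <= 1e-9)
    assert all(np.diff(gsa) >= -1e-9)
    assert all(np.diff(gly) >= -1e-9)
    assert all(np.diff(g6p) <= 1e-9)


def test_rescaled_units_give_rescaled_steady_state(glycogen_params):
    """Scaling all concentration units by 10 scales the steady state by 10."""
    p10 = rescale_concentrations(glycogen_params, 10.0)
    base = steady_state_root(glycogen_params, 5.5)
    scaled = steady_state_root(p10, 55.0)  # drug dose expressed in the new units
    np.testing.assert_allclose(scaled, 10.0 * base, rtol=1e-6)


def test_parameter_validation():
    with pytest.raises(ValueError):
        GlycogenParams(ki_drug=-1.0)
    with pytest.raises(ValueError):
        GlycogenParams(vmax_phk=0.0)
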