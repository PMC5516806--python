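"""Fold-change propagation and the three-model tandem chain."""

from dataclasses import replace

import numpy as np
import pytest

from tandemtox.models import glutathione as gsh_model
from tandemtox.models import glycogen as glycogen_model
from tandemtox.models import ppp as ppp_model
from tandemtox.tandem import (
    G6P_INTERFACE,
    NADPH_INTERFACE,
    FoldChange,
    InterfaceSpec,
    TandemChain,
    model_fold_changes,
    propagate,
    run_tandem,
)

GRID = [0.0, 0.1, 1.0, 10.0, 100.0]


def test_fold_change_invariants():
    fc = FoldChange("x", baseline=4.0, perturbed=1.0)
    assert fc.ratio * fc.baseline == fc.perturbed
    with pytest.raises(ValueError):
        FoldChange("x", baseline=0.0, perturbed=1.0)


def test_interface_spec_validation():
    with pytest.raises(ValueError):
        InterfaceSpec("a", "b", ())
    with pytest.raises(ValueError):
        InterfaceSpec("a", "b", (("x", "y"),), coupling_mode="averaged")
    with pytest.raises(ValueError):  # non-adjacent coupling
        TandemChain(interfaces=(InterfaceSpec("glycogen", "gsh", (("g6p", "k_synth"),)),))


def test_null_perturbation_gives_unit_ratios(glycogen_params):
    fcs = model_fold_changes("glycogen", glycogen_params, {"drug_conc": 0.0},
                             ["g6p", "glycogen", "gp_activity"])
    assert all(f.ratio == pytest.approx(1.0, abs=1e-9) for f in fcs)


def test_high_dose_lowers_g6p_ratio(glycogen_params):
    (fc,) = model_fold_changes(
        "glycogen", glycogen_params,
        {"drug_conc": 100.0 * glycogen_params.ki_drug}, ["g6p"],
    )
    assert fc.ratio < 1.0


def test_fold_changes_invariant_to_unit_rescaling(glycogen_params):
    """Only the degree of change transfers: ratios ignore the model's units."""
    scaled = glycogen_model.rescale_concentrations(glycogen_params, 10.0)
    (fc,) = model_fold_changes("glycogen", glycogen_params, {"drug_conc": 55.0}, ["g6p"])
    (fc10,) = model_fold_changes("glycogen", scaled, {"drug_conc": 550.0}, ["g6p"])
    assert fc10.ratio == pytest.approx(fc.ratio, rel=1e-6)


def test_propagate_identity_and_halving(ppp_params):
    unit = [FoldChange("g6p", 2.0, 2.0)]
    assert propagate(unit, G6P_INTERFACE, ppp_params) == ppp_params
    halved = propagate([FoldChange("g6p", 2.0, 1.0)], G6P_INTERFACE, ppp_params)
    assert halved.g6p_initial == pytest.approx(0.5 * ppp_params.g6p_initial)


def test_propagate_absolute_mode(gsh_params):
    spec = replace(NADPH_INTERFACE, coupling_mode="absolute")
    out = propagate([FoldChange("nadph_ratio", 2.0, 3.5)], spec, gsh_params)
    assert out.k_nadph_supply == 3.5


def test_propagate_missing_mapping(ppp_params):
    with pytest.raises(KeyError):
        propagate([FoldChange("glycogen", 1.0, 2.0)], G6P_INTERFACE, ppp_params)


@pytest.fixture(scope="module")
def reference_scan():
    return run_tandem(TandemChain(), GRID).to_frame()


def test_dose_zero_reproduces_standalone_baselines(reference_scan, ppp_params, gsh_params):
    row = reference_scan.iloc[0]
    assert row.g6p_fold == pytest.approx(1.0, abs=1e-9)
    assert row.nadph_ratio_fold == pytest.approx(1.0, abs=1e-9)
    standalone_ppp = ppp_model.steady_state(ppp_params)
    assert row.nadph_ratio == pytest.approx(
        ppp_model.nadph_ratio(standalone_ppp.state), rel=1e-3
    )
    standalone_gsh = gsh_model.steady_state(gsh_params)
    assert row.gsh == pytest.approx(standalone_gsh.species("gsh"), rel=1e-3)


def test_scan_is_monotone(reference_scan):
    df = reference_scan
    assert (df.status == "ok").all()
    assert np.all(np.diff(df.glycogen) >= -1e-9)
    assert np.all(np.diff(df.g6p) <= 1e-9)
    assert np.all(np.diff(df.nadph_ratio) <= 1e-9)
    assert np.all(np.diff(df.gsh) <= 1e-6)


def test_scan_requires_zero_dose():
    with pytest.raises(ValueError):
        run_tandem(TandemChain(), [1.0, 10.0])


def test_scan_deterministic(reference_scan):
    again = run_tandem(TandemChain(), GRID).to_frame()
    assert again.equals(reference_scan)


def test_vitamin_e_rescues_high_dose_gsh(gsh_params):
    """Saturating antioxidant restores the high-dose GSH endpoint to the
    dose-0 baseline through the whole chain."""
    chain = TandemChain(gsh=replace(gsh_params, vite_pool=1e5))
    df = run_tandem(chain, [0.0, 100.0]).to_frame()
    assert df.gsh.iloc[1] >= 0.95 * df.gsh.iloc[0]
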