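"""Occupancy algebra, drug profiles and differential shortlisting."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tandemtox.occupancy import (
    DrugExposure,
    OccupancyProfile,
    compute_occupancy,
    differential_candidates,
    profile_drug,
    read_affinity_table,
    read_exposure_table,
)
from tandemtox.synthetic import KinomeScenario, generate_kinome_table

positive = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)


@pytest.mark.parametrize(
    "kd, cpuss, expected",
    [
        (5.5, 5.5, 0.5),      # C = Kd: half occupancy
        (1.0, 0.0, 0.0),      # no free drug
        (123.4, 0.0, 0.0),
        (1.0, 9.0, 0.9),
    ],
)
def test_occupancy_examples(kd, cpuss, expected):
    assert compute_occupancy(kd, cpuss) == pytest.approx(expected, abs=1e-15)


@pytest.mark.parametrize("kd, cpuss", [(0.0, 1.0), (-1.0, 1.0), (1.0, -0.5), (np.inf, 1.0)])
def test_occupancy_domain_errors(kd, cpuss):
    with pytest.raises(ValueError):
        compute_occupancy(kd, cpuss)


@given(kd=positive, cpuss=positive, factor=st.floats(min_value=1.01, max_value=100))
def test_occupancy_monotone_and_bounded(kd, cpuss, factor):
    occ = compute_occupancy(kd, cpuss)
    assert 0.0 < occ < 1.0
    assert compute_occupancy(kd, cpuss * factor) > occ  # increasing in exposure
    assert compute_occupancy(kd * factor, cpuss) < occ  # decreasing in Kd


def toy_table():
    return pd.DataFrame(
        {
            "kinase_id": ["K1", "K2", "K3"],
            "drug_id": ["d", "d", "d"],
            "kd": [1.0, 9.0, np.nan],
            "unit": ["uM"] * 3,
        }
    )


def test_profile_toy_table():
    profile = profile_drug(toy_table(), DrugExposure("d", 1.0))
    assert profile.occupancies == {"K1": 0.5, "K2": 0.1, "K3": 0.0}


def test_profile_zero_exposure_is_all_zero():
    profile = profile_drug(toy_table(), DrugExposure("d", 0.0))
    assert set(profile.occupancies.values()) == {0.0}


def test_profile_missing_drug_raises():
    with pytest.raises(KeyError):
        profile_drug(toy_table(), DrugExposure("other", 1.0))


def test_profile_rejects_duplicate_pairs():
    table = pd.concat([toy_table(), toy_table().iloc[[0]]])
    with pytest.raises(ValueError, match="duplicate"):
        profile_drug(table, DrugExposure("d", 1.0))


def test_profile_matches_elementwise_formula():
    """Profile of a 50-kinase synthetic panel equals per-entry C/(Kd+C)."""
    table, exposures, _ = generate_kinome_table(KinomeScenario(seed=42))
    exposure = exposures["drugA"]
    profile = profile_drug(table, exposure)
    rows = table[table.drug_id == "drugA"]
    for kinase, kd in zip(rows.kinase_id, rows.kd):
        expected = 0.0 if pd.isna(kd) else exposure.cpuss / (kd + exposure.cpuss)
        assert profile.occupancies[kinase] == pytest.approx(expected, rel=1e-12)


def _brute_force(pa, pb, lo, hi):
    universe = set(pa.occupancies) | set(pb.occupancies)
    hits = [
        (k, pa.occupancies.get(k, 0.0), pb.occupancies.get(k, 0.0))
        for k in universe
        if pa.occupancies.get(k, 0.0) >= lo and pb.occupancies.get(k, 0.0) <= hi
    ]
    hits.sort(key=lambda t: (-(t[1] - t[2]), t[0]))
    return [k for k, *_ in hits]


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_candidates_equal_brute_force(seed):
    rng = np.random.default_rng(seed)
    kinases = [f"K{i}" for i in range(rng.integers(1, 30))]
    pa = OccupancyProfile("a", {k: float(rng.random()) for k in kinases})
    pb = OccupancyProfile("b", {k: float(rng.random()) for k in rng.permutation(kinases)})
    hits = differential_candidates(pa, pb, 0.5, 0.3)
    assert [h.kinase_id for h in hits] == _brute_force(pa, pb, 0.5, 0.3)
    for h in hits:
        assert h.delta == h.occupancy_a - h.occupancy_b


def test_candidates_identical_profiles_empty():
    p = OccupancyProfile("a", {"K1": 0.4, "K2": 0.9})
    assert differential_candidates(p, p, min_occ_a=0.5, max_occ_b=0.1) == []


def test_candidates_trivial_thresholds_return_all_sorted():
    pa = OccupancyProfile("a", {"K1": 0.2, "K2": 0.9, "K3": 0.5})
    pb = OccupancyProfile("b", {"K1": 0.1, "K2": 0.1})
    hits = differential_candidates(pa, pb, min_occ_a=0.0, max_occ_b=1.0)
    assert [h.kinase_id for h in hits] == ["K2", "K3", "K1"]


def test_candidates_threshold_validation():
    p = OccupancyProfile("a", {"K1": 0.5})
    with pytest.raises(ValueError):
        differential_candidates(p, p, min_occ_a=-0.1, max_occ_b=0.5)
    with pytest.raises(ValueError):
        differential_candidates(p, p, min_occ_a=0.5, max_occ_b=1.5)


def test_read_affinity_table_converts_nm_and_censors():
    text = "kinase_id,drug_id,kd,unit\nK1,d,500,nM\nK2,d,2.0,uM\nK3,d,NA,uM\n"
    table = read_affinity_table(io.StringIO(text))
    kd = dict(zip(table.kinase_id, table.kd))
    assert kd["K1"] == pytest.approx(0.5)
    assert kd["K2"] == pytest.approx(2.0)
    assert np.isnan(kd["K3"])


def test_read_exposure_table_roundtrip():
    text = "drug_id\tcpuss_uM\nd1\t0.25\nd2\t1.5\n"
    exposures = read_exposure_table(io.StringIO(text))
    assert exposures["d1"].cpuss == 0.25
    assert exposures["d2"].cpuss == 1.5
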