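"""Unit and property tests for the four ecosystem-service models."""

import numpy as np
import pandas as pd
import pytest

from esdrought import (
    RusleFactors,
    WaterRetentionInputs,
    allocate_food_supply,
    compute_carbon_sequestration,
    compute_soil_conservation,
    compute_water_retention,
)
from esdrought.exceptions import AllocationError, DomainError

from conftest import make_field


def wr_scalar(velocity, ti, ks, yield_):
    """Loop-free scalar reference for water retention."""
    return (
        min(1.0, 249.0 / velocity)
        * min(1.0, 0.9 * ti / 3.0)
        * min(1.0, ks / 300.0)
        * yield_
    )


def sc_scalar(r, k, l, s, p, c):
    return r * k * l * s * (1.0 - p * c)


@pytest.mark.parametrize(
    "velocity,ti,ks,yield_,expected",
    [
        (200.0, 4.0, 350.0, 800.0, 800.0),  # all attenuation terms saturate
        (498.0, 5.0 / 3.0, 150.0, 400.0, 50.0),  # 0.5 * 0.5 * 0.5 * 400
        (100.0, 10.0, 500.0, 0.0, 0.0),  # zero yield
    ],
)
def test_water_retention_hand_values(velocity, ti, ks, yield_, expected):
    out = compute_water_retention(
        WaterRetentionInputs(
            make_field([[velocity]]), make_field([[ti]]),
            make_field([[ks]]), make_field([[yield_]]),
        )
    )
    assert out.values[0, 0] == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize(
    "r,k,l,s,p,c,expected",
    [
        (100.0, 0.5, 1.2, 2.0, 0.5, 0.4, 96.0),  # 120 * (1 - 0.2)
        (100.0, 0.5, 1.2, 2.0, 0.0, 0.4, 120.0),  # no practice factor
        (0.0, 0.5, 1.2, 2.0, 0.5, 0.4, 0.0),  # zero erosivity
    ],
)
def test_soil_conservation_hand_values(r, k, l, s, p, c, expected):
    out = compute_soil_conservation(
        RusleFactors(*[make_field([[v]]) for v in (r, k, l, s, c, p)])
    )
    assert out.values[0, 0] == pytest.approx(expected, abs=1e-9)


def test_soil_conservation_textbook_variant():
    factors = RusleFactors(*[make_field([[v]]) for v in (100.0, 0.5, 1.2, 2.0, 0.4, 0.5)])
    printed = compute_soil_conservation(factors, "printed").values[0, 0]
    textbook = compute_soil_conservation(factors, "textbook").values[0, 0]
    assert printed == pytest.approx(120.0 * 0.8)
    assert textbook == pytest.approx(120.0 * 0.6 * 0.5)


def test_carbon_sequestration_hand_values():
    out = compute_carbon_sequestration(make_field([[600.0, 0.0]]))
    assert out.values[0, 0] == pytest.approx(978.0, abs=1e-9)
    assert out.values[0, 1] == 0.0
    # per-area value whose coefficient implies NPP ~ 613.79 for CS ~ 1000.48
    cs = compute_carbon_sequestration(make_field([[613.79]]))
    assert cs.values[0, 0] == pytest.approx(1000.48, abs=0.005)
    # per-cell total scales with area
    big = compute_carbon_sequestration(make_field([[600.0]], cell_km=2.0), per_cell=True)
    assert big.values[0, 0] == pytest.approx(978.0 * 4.0)


def test_water_retention_monotone_and_bounded():
    rng = np.random.default_rng(3)
    vel = rng.uniform(100, 500, (10, 10))
    ti = rng.uniform(0.5, 6, (10, 10))
    ks = rng.uniform(50, 500, (10, 10))
    yld = rng.uniform(0, 1500, (10, 10))
    base = compute_water_retention(
        WaterRetentionInputs(make_field(vel), make_field(ti), make_field(ks), make_field(yld))
    ).values
    assert np.all(base <= yld + 1e-12)  # retention never exceeds yield
    more_yield = compute_water_retention(
        WaterRetentionInputs(make_field(vel), make_field(ti), make_field(ks), make_field(yld * 1.3))
    ).values
    assert np.all(more_yield >= base - 1e-12)
    faster = compute_water_retention(
        WaterRetentionInputs(make_field(vel * 1.5), make_field(ti), make_field(ks), make_field(yld))
    ).values
    assert np.all(faster <= base + 1e-12)


def test_gridded_models_match_scalar_oracle():
    rng = np.random.default_rng(11)
    vel = rng.uniform(100, 500, (10, 10))
    ti = rng.uniform(0.5, 6, (10, 10))
    ks = rng.uniform(50, 500, (10, 10))
    yld = rng.uniform(0, 1500, (10, 10))
    wr = compute_water_retention(
        WaterRetentionInputs(make_field(vel), make_field(ti), make_field(ks), make_field(yld))
    ).values
    r = rng.uniform(0, 5000, (10, 10))
    k = rng.uniform(0, 1, (10, 10))
    l = rng.uniform(0.5, 4, (10, 10))
    s = rng.uniform(0.5, 8, (10, 10))
    c = rng.uniform(0, 1, (10, 10))
    p = rng.uniform(0, 1, (10, 10))
    sc = compute_soil_conservation(
        RusleFactors(*[make_field(v) for v in (r, k, l, s, c, p)])
    ).values
    for i in range(10):
        for j in range(10):
            assert wr[i, j] == pytest.approx(wr_scalar(vel[i, j], ti[i, j], ks[i, j], yld[i, j]), abs=1e-12)
            assert sc[i, j] == pytest.approx(
                sc_scalar(r[i, j], k[i, j], l[i, j], s[i, j], p[i, j], c[i, j]), rel=1e-12
            )


def test_sc_linear_in_each_factor_and_cs_proportional():
    base = RusleFactors(*[make_field([[100.0, 40.0]]) if i == 0 else make_field([[0.4, 0.6]])
                          for i in range(6)])
    q1 = compute_soil_conservation(base).values
    doubled = RusleFactors(make_field([[200.0, 80.0]]), base.k, base.l, base.s, base.c, base.p)
    assert np.allclose(compute_soil_conservation(doubled).values, 2 * q1)
    npp = make_field(np.random.default_rng(0).uniform(0, 900, (4, 4)))
    cs1 = compute_carbon_sequestration(npp).values
    cs3 = compute_carbon_sequestration(make_field(3.0 * npp.values)).values
    assert np.allclose(cs3, 3.0 * cs1)


def _zone_table(zone_id, year, p_sum):
    return pd.DataFrame({"zone_id": [zone_id], "year": [year], "p_sum_t": [p_sum]})


def test_food_supply_proportional_allocation():
    ndvi = make_field([[0.2, 0.3, 0.5]])
    land_use = np.ones((1, 3), dtype=int)  # cropland
    zones = np.ones((1, 3), dtype=int)
    out = allocate_food_supply(ndvi, land_use, zones, _zone_table(1, 2000, 100.0),
                               year=2000, as_density=False)
    assert np.allclose(out.values, [[20.0, 30.0, 50.0]], atol=1e-9)


def test_food_supply_degenerate_cases():
    land_use = np.array([[1, 2]])  # one cropland, one forest
    zones = np.ones((1, 2), dtype=int)
    ndvi = make_field([[0.4, 0.9]])
    out = allocate_food_supply(ndvi, land_use, zones, _zone_table(1, 2000, 77.0),
                               year=2000, as_density=False)
    assert out.values[0, 0] == pytest.approx(77.0)  # single cropland cell gets all
    assert out.values[0, 1] == 0.0  # forest gets nothing
    zero = allocate_food_supply(ndvi, land_use, zones, _zone_table(1, 2000, 0.0), year=2000)
    assert np.allclose(zero.values, 0.0)


def test_food_supply_mass_conservation_random_layouts():
    rng = np.random.default_rng(42)
    for _ in range(20):
        R, C = rng.integers(4, 12, 2)
        ndvi = make_field(rng.uniform(0.05, 0.9, (R, C)))
        land_use = rng.choice([1, 2, 4], size=(R, C), p=[0.6, 0.2, 0.2])
        zones = rng.integers(1, 4, size=(R, C))
        table = pd.DataFrame(
            [{"zone_id": z, "year": 2000, "p_sum_t": float(rng.uniform(10, 500))}
             for z in np.unique(zones)
             if ((zones == z) & (land_use == 1)).any()]
        )
        out = allocate_food_supply(ndvi, land_use, zones, table, year=2000, as_density=False)
        for _, row in table.iterrows():
            got = out.values[zones == row.zone_id].sum()
            assert got == pytest.approx(row.p_sum_t, rel=1e-9)


def test_food_supply_negative_ndvi_excluded_with_warning():
    ndvi = make_field([[-0.2, 0.5, 0.5]])
    land_use = np.ones((1, 3), dtype=int)
    zones = np.ones((1, 3), dtype=int)
    with pytest.warns(UserWarning, match="negative"):
        out = allocate_food_supply(ndvi, land_use, zones, _zone_table(1, 2000, 100.0),
                                   year=2000, as_density=False)
    assert out.values[0, 0] == 0.0
    assert out.values[0, 1] == pytest.approx(50.0)
    assert np.nansum(out.values) == pytest.approx(100.0, rel=1e-9)


def test_domain_and_allocation_errors():
    with pytest.raises(DomainError):
        compute_water_retention(
            WaterRetentionInputs(make_field([[0.0]]), make_field([[1.0]]),
                                 make_field([[1.0]]), make_field([[1.0]]))
        )
    with pytest.raises(DomainError):
        compute_soil_conservation(
            RusleFactors(*[make_field([[1.0]]) for _ in range(4)],
                         make_field([[1.4]]), make_field([[0.5]]))
        )
    with pytest.raises(DomainError):
        compute_carbon_sequestration(make_field([[-5.0]]))
    with pytest.raises(AllocationError, match="zone 1"):
        allocate_food_supply(
            make_field([[0.5]]), np.array([[2]]), np.array([[1]]),
            _zone_table(1, 2000, 10.0), year=2000,
        )
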