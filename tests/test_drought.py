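"""Drought classification, frequency and ES-stratification tests."""

import dataclasses

import numpy as np
import pytest

from esdrought import (
    BoundaryHump,
    DroughtClassTable,
    SyntheticConfig,
    binned_spei_surface,
    classify_drought,
    compute_es_stack,
    drought_frequency,
    generate_landscape,
    stratify_es_by_drought,
    summarize_drought,
)
from esdrought.drought import DROUGHT_CLASSES
from esdrought.exceptions import ConfigurationError, DataError
from esdrought.grid import ES_NAMES, LAND_USE_CODES


@pytest.mark.parametrize(
    "spei,expected",
    [
        (0.0, "none"),
        (-0.4999, "none"),
        (-0.5, "slight"),  # boundary closed on the severe side
        (-1.0, "medium"),
        (-1.2, "medium"),
        (-1.5, "serious"),
        (-2.0, "extreme"),
        (-2.3, "extreme"),
    ],
)
def test_class_boundaries(spei, expected):
    table = DroughtClassTable()
    code = table.classify_values(np.array([spei]))[0]
    assert DROUGHT_CLASSES[code] == expected


def test_classification_partitions_every_cell_year(small_landscape):
    labels = classify_drought(
        small_landscape.variables["SPEI"].astype(float), small_landscape.mask
    )
    m = small_landscape.mask
    assert np.all(labels[:, m] >= 0)
    summary = summarize_drought(
        small_landscape.variables["SPEI"].astype(float), small_landscape.mask
    )
    assert np.all(summary.class_counts[:, m].sum(axis=0) == small_landscape.n_years)
    f = summary.spei_f.values[m]
    assert np.all((f >= 0) & (f <= 1))


def test_monotone_severity():
    table = DroughtClassTable()
    x = np.random.default_rng(0).uniform(-3, 1, 500)
    assert np.all(table.classify_values(x - 0.3) >= table.classify_values(x))


def test_drought_frequency_hand_counts():
    mask = np.ones((1, 1), dtype=bool)
    none = np.zeros((23, 1, 1))
    assert drought_frequency(classify_drought(none, mask), mask).values[0, 0] == 0.0
    mixed = np.zeros((23, 1, 1))
    mixed[:5] = -0.9  # 5 slight-drought years
    got = drought_frequency(classify_drought(mixed, mask), mask).values[0, 0]
    assert got == pytest.approx(5 / 23)
    alld = np.full((23, 1, 1), -2.5)
    assert drought_frequency(classify_drought(alld, mask), mask).values[0, 0] == 1.0


def test_spei_f_depends_only_on_drought_membership():
    # relabeling which drought class a year falls in leaves SPEI_F unchanged
    mask = np.ones((1, 1), dtype=bool)
    a = np.zeros((10, 1, 1)); a[:4] = -0.7   # slight
    b = np.zeros((10, 1, 1)); b[:4] = -2.2   # extreme
    fa = drought_frequency(classify_drought(a, mask), mask).values[0, 0]
    fb = drought_frequency(classify_drought(b, mask), mask).values[0, 0]
    assert fa == fb == pytest.approx(0.4)


def test_invalid_inputs_raise():
    mask = np.ones((1, 1), dtype=bool)
    with pytest.raises(DataError):
        classify_drought(np.full((3, 1, 1), np.nan), mask)
    with pytest.raises(ConfigurationError):
        DroughtClassTable(cutoffs=(-0.5, -0.4, -1.5, -2.0))


def test_planted_drought_suppression_recovered():
    # flat envelopes + 30% WR suppression in drought cell-years: the
    # drought-stratum WR mean should be ~0.7x the non-drought mean
    flat = {
        (es, lu): BoundaryHump(apex=0.0, height=h, curvature=0.0)
        for es, h in zip(ES_NAMES, (900.0, 450.0, 1150.0, 130.0))
        for lu in LAND_USE_CODES
    }
    from esdrought import BundleCentroid

    one_bundle = [BundleCentroid({e: 0.8 for e in ES_NAMES}, spei_f=0.3, fraction=1.0)]
    cfg = SyntheticConfig(
        n_rows=60, n_cols=60, n_years=12, seed=21, drought_years=(4, 9),
        boundary_spec=flat, level_cv=0.0, trend_spec={}, cluster_spec=one_bundle,
        drought_suppression={"WR": 0.3, "SC": 0.0, "CS": 0.0, "FS": 0.0},
    )
    ds = generate_landscape(cfg)
    es = compute_es_stack(ds)
    labels = classify_drought(ds.variables["SPEI"].astype(float), ds.mask)
    table = stratify_es_by_drought(es, labels, ds.land_use, mode="cell-year")
    row = table[(table.land_use == "all") & (table.es == "WR")].iloc[0]
    assert row.drought_mean / row.nondrought_mean == pytest.approx(0.7, abs=0.03)
    assert row.p_welch < 1e-3
    cs = table[(table.land_use == "all") & (table.es == "CS")].iloc[0]
    assert cs.drought_mean / cs.nondrought_mean == pytest.approx(1.0, abs=0.05)


def test_class_zone_mode_and_empty_stratum(small_landscape, small_es):
    labels = classify_drought(
        small_landscape.variables["SPEI"].astype(float), small_landscape.mask
    )
    table = stratify_es_by_drought(small_es, labels, small_landscape.land_use,
                                   mode="class-zone")
    allwr = table[(table.land_use == "all") & (table.es == "WR")]
    assert set(allwr.drought_class) == set(DROUGHT_CLASSES)
    none_row = allwr[allwr.drought_class == "none"].iloc[0]
    assert none_row.delta_vs_none == pytest.approx(0.0, abs=1e-9)
    # any stratum with <2 observations must be flagged, not crash
    empty = table[table.n < 2]
    assert empty.undefined.all()


def test_binned_surface_constant_and_planted_minimum(small_landscape):
    mask = np.ones((1, 2), dtype=bool)
    tem = np.tile(np.array([[15.0, 24.0]]), (4, 1, 1)).reshape(4, 1, 2)
    pre = np.tile(np.array([[1000.0, 500.0]]), (4, 1, 1)).reshape(4, 1, 2)
    spei = np.full((4, 1, 2), 0.3)
    out = binned_spei_surface(tem, pre, spei, mask,
                              np.arange(14, 26), np.arange(400, 1200, 100))
    filled = out[out.n > 0]
    assert np.allclose(filled.mean_spei, 0.3)
    # planted hot-dry signature on the generated landscape
    ds = small_landscape
    surf = binned_spei_surface(
        ds.variables["TEM"].astype(float), ds.variables["PRE"].astype(float),
        ds.variables["SPEI"].astype(float), ds.mask,
        np.arange(10, 28), np.arange(300, 1700, 100),
    )
    best = surf.loc[surf.mean_spei.idxmin()]
    assert 23 <= best.tem_low and best.tem_high <= 25
    assert 400 <= best.pre_low and best.pre_high <= 600
    with pytest.raises(ConfigurationError):
        binned_spei_surface(tem, pre, spei, mask, np.array([3, 2, 1]), np.arange(0, 300, 100))
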