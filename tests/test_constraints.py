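"""Constraint-line extraction, fitting and threshold tests."""

import numpy as np
import pytest

from esdrought import (
    BoundaryHump,
    SyntheticConfig,
    compute_es_stack,
    constraint_analysis_by_landuse,
    extract_boundary_points,
    find_threshold,
    fit_constraint_line,
    generate_boundary_scatter,
    generate_landscape,
)
from esdrought.constraints import ConstraintFit, find_threshold_raw
from esdrought.exceptions import InsufficientDataError


def test_constant_response_gives_constant_boundary():
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 1, 5000)
    pts = extract_boundary_points(x, np.full_like(x, 7.0), n_bins=20, min_count=10)
    assert np.allclose(pts.boundary_y, 7.0)


def test_percentile_uses_linear_interpolation():
    # each of 10 bins holds the sequence 1..1000: its 99.9th percentile is
    # 999.001 under order-statistic interpolation
    centers = np.arange(10, dtype=float)
    x = np.repeat(centers, 1000) + 0.001  # strictly inside each unit bin
    y = np.tile(np.arange(1, 1001, dtype=float), 10)
    pts = extract_boundary_points(x, y, n_bins=10, q=99.9, min_count=10)
    assert np.allclose(pts.boundary_y, 999.001, atol=1e-9)
    # brute-force sort-based percentile agrees exactly
    seq = np.arange(1, 1001, dtype=float)
    k = 0.999 * (len(seq) - 1)
    brute = seq[int(k)] + (k - int(k)) * (seq[int(k) + 1] - seq[int(k)])
    assert brute == pytest.approx(999.001, abs=1e-12)


def test_boundary_dominance():
    hump = BoundaryHump(apex=-0.3, height=50.0, curvature=2.0)
    x, y = generate_boundary_scatter(hump, n=50_000, seed=3)
    pts = extract_boundary_points(x, y, n_bins=100, min_count=10)
    edges = pts.bin_edges
    idx = np.clip(np.digitize(x, edges[1:-1]), 0, len(edges) - 2)
    below = 0
    total = 0
    kept = {round(float(m), 9) for m in pts.boundary_x}
    for b in range(len(edges) - 1):
        mid = round(float(0.5 * (edges[b] + edges[b + 1])), 9)
        if mid not in kept:
            continue
        sel = idx == b
        top = pts.boundary_y[list(kept).index(mid)] if False else None
        # look up boundary by midpoint
        top = pts.boundary_y[np.argmin(np.abs(pts.boundary_x - mid))]
        below += int(np.sum(y[sel] <= top + 1e-12))
        total += int(sel.sum())
    assert below / total >= 0.995


def _points_on_curve(fn, lo=-2.0, hi=2.0, n=60):
    from esdrought.constraints import BoundaryPointSet

    x = np.linspace(lo, hi, n)
    return BoundaryPointSet(
        bin_edges=np.linspace(lo, hi, n + 1),
        boundary_x=x, boundary_y=fn(x), bin_counts=np.full(n, 100),
    )


def test_exact_parabola_recovers_apex_and_r2():
    pts = _points_on_curve(lambda x: -((x - 0.81) ** 2) + 2.0)
    fit = fit_constraint_line(pts)
    assert fit.family == "hump_quadratic"
    assert fit.r2 == pytest.approx(1.0, abs=1e-10)
    assert fit.threshold_x == pytest.approx(0.81, abs=1e-6)
    # coefficients match y = -x^2 + 1.62x + (2 - 0.81^2)
    assert np.allclose(fit.coefficients, [-1.0, 1.62, 2.0 - 0.81**2], atol=1e-8)


def test_exact_cubic_with_interior_max():
    pts = _points_on_curve(lambda x: x**3 - 3 * x)  # local max at x = -1
    fit = fit_constraint_line(pts, families=("convex_wave_cubic",))
    assert fit.r2 == pytest.approx(1.0, abs=1e-10)
    assert fit.threshold_x == pytest.approx(-1.0, abs=1e-6)
    assert fit.flag == ""


def test_monotone_cubic_flags_boundary_max():
    coef = np.array([1.0, 0.0, 1.0, 0.0])  # y = x^3 + x, strictly increasing
    x, y, flag = find_threshold_raw("convex_wave_cubic", coef, (-1.0, 2.0))
    assert flag == "boundary_max"
    assert x == 2.0
    fit = ConstraintFit("convex_wave_cubic", coef, 1.0, x, y, flag)
    assert find_threshold(fit, (-1.0, 2.0))[0] == 2.0


def test_scale_equivariance_of_boundary_and_threshold():
    hump = BoundaryHump(apex=0.4, height=10.0, curvature=1.0)
    x, y = generate_boundary_scatter(hump, n=20_000, seed=8)
    p1 = extract_boundary_points(x, y, min_count=10)
    p2 = extract_boundary_points(x, 5.0 * y + 2.0, min_count=10)
    assert np.allclose(p2.boundary_y, 5.0 * p1.boundary_y + 2.0, atol=1e-9)
    f1 = fit_constraint_line(p1, families=("hump_quadratic",))
    f2 = fit_constraint_line(p2, families=("hump_quadratic",))
    assert f2.threshold_x == pytest.approx(f1.threshold_x, abs=1e-8)
    assert f2.threshold_y == pytest.approx(5.0 * f1.threshold_y + 2.0, rel=1e-8)


def test_noisy_parabola_prefers_quadratic_family():
    hump = BoundaryHump(apex=0.5, height=100.0, curvature=10.0)
    wins = 0
    for seed in range(100):
        x, y = generate_boundary_scatter(hump, n=10_000, noise_sd=2.0, seed=seed)
        pts = extract_boundary_points(x, y, min_count=10)
        if fit_constraint_line(pts).family == "hump_quadratic":
            wins += 1
    assert wins >= 95


def test_insufficient_bins_raises():
    with pytest.raises(InsufficientDataError):
        extract_boundary_points(np.ones(100), np.ones(100), n_bins=100, min_count=10)


def test_landuse_analysis_recovers_planted_apices():
    cfg = SyntheticConfig(
        n_rows=70, n_cols=70, n_years=23, seed=13, trend_spec={},
        level_cv=0.0, drought_suppression={},
        land_use_fracs={"cropland": 0.4, "forest": 0.6, "shrub": 0.0,
                        "grassland": 0.0, "other": 0.0},
    )
    ds = generate_landscape(cfg)
    es = compute_es_stack(ds)
    # ~66k cell-years per stratum: requiring 50 points per bin drops the
    # sparse tail bins whose upper percentile is biased low
    fits = constraint_analysis_by_landuse(ds, es, min_count=50)
    forest_sc = fits[(fits.es == "SC") & (fits.land_use == "forest")].iloc[0]
    assert not forest_sc.skipped
    assert forest_sc.threshold_x == pytest.approx(0.96, abs=0.1)
    forest_wr = fits[(fits.es == "WR") & (fits.land_use == "forest")].iloc[0]
    crop_wr = fits[(fits.es == "WR") & (fits.land_use == "cropland")].iloc[0]
    assert forest_wr.threshold_x == pytest.approx(0.81, abs=0.1)
    assert crop_wr.threshold_x == pytest.approx(0.20, abs=0.1)
    assert forest_wr.threshold_x > crop_wr.threshold_x  # planted ordering
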