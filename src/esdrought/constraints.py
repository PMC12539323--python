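"""Constraint-line (upper boundary) extraction and threshold analysis.

A constraint line is the upper envelope of a response-vs-driver scatter:
the maximum attainable response at each driver value.  It is estimated by
quantile segmentation — the driver range is split into equal-width bins
(100 by default) and the 99.9th percentile of the response within each
sufficiently populated bin becomes a boundary point.  Candidate curve
families are least-squares fitted to the boundary points and the winning
family's maximum defines the response threshold: the driver value beyond
which the attainable response declines.

Candidate families:

* ``hump_quadratic`` — ``y = a x² + b x + c`` (hump when a < 0);
* ``hump_gaussian`` — ``y = A exp(-(x-mu)²/(2 sigma²)) + c``;
* ``convex_wave_cubic`` — ``y = a x³ + b x² + c x + d``.

Because the polynomial families are nested, raw R² cannot prefer the
simpler curve; the winner is chosen by BIC (with a parsimony tie-break
when residuals vanish) while the plain R² on the boundary points is
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .es_models import EsStack
from .exceptions import FitError, InsufficientDataError
from .grid import ES_NAMES, LAND_USE_NAMES, LandscapeDataset

DEFAULT_FAMILIES: tuple[str, ...] = (
    "hump_quadratic",
    "hump_gaussian",
    "convex_wave_cubic",
)

_N_PARAMS = {"hump_quadratic": 3, "hump_gaussian": 4, "convex_wave_cubic": 4}


@dataclass
class BoundaryPointSet:
    """Per-bin boundary points of a response-vs-driver scatter."""

    bin_edges: np.ndarray
    boundary_x: np.ndarray  # bin midpoints of qualifying bins
    boundary_y: np.ndarray  # within-bin response percentile
    bin_counts: np.ndarray
    q: float = 99.9


@dataclass
class ConstraintFit:
    """A fitted boundary curve and its derivative-derived threshold."""

    family: str
    coefficients: np.ndarray
    r2: float
    threshold_x: float
    threshold_y: float
    flag: str = ""  # "" | "boundary_max"
    candidates: dict[str, float] = field(default_factory=dict)  # family -> r2


def extract_boundary_points(
    x: np.ndarray,
    y: np.ndarray,
    n_bins: int = 100,
    q: float = 99.9,
    min_count: int = 10,
) -> BoundaryPointSet:
    """Equal-width binning of x with a per-bin upper percentile of y.

    Percentiles use linear interpolation between order statistics.  Bins
    with fewer than ``min_count`` points are omitted; fewer than 10
    qualifying bins raises :class:`InsufficientDataError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size == 0:
        raise InsufficientDataError("no finite (x, y) pairs")
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    # right-inclusive final bin so max(x) is counted
    idx = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    mids, tops, counts = [], [], []
    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        if n < min_count:
            continue
        mids.append(0.5 * (edges[b] + edges[b + 1]))
        tops.append(np.percentile(y[sel], q))
        counts.append(n)
    if len(mids) < 10:
        raise InsufficientDataError(
            f"only {len(mids)} bins with >= {min_count} points; "
            "boundary not extractable"
        )
    return BoundaryPointSet(
        bin_edges=edges,
        boundary_x=np.asarray(mids),
        boundary_y=np.asarray(tops),
        bin_counts=np.asarray(counts),
        q=q,
    )


def _eval_family(family: str, coef: np.ndarray, x: np.ndarray) -> np.ndarray:
    if family == "hump_quadratic":
        return np.polyval(coef, x)
    if family == "convex_wave_cubic":
        return np.polyval(coef, x)
    if family == "hump_gaussian":
        a, mu, sigma, c = coef
        return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + c
    raise ValueError(f"unknown family {family!r}")


def _fit_family(family: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    if family == "hump_quadratic":
        return np.polyfit(x, y, 2)
    if family == "convex_wave_cubic":
        return np.polyfit(x, y, 3)
    if family == "hump_gaussian":
        span = y.max() - y.min()
        p0 = [span if span > 0 else 1.0, x[np.argmax(y)], (x.max() - x.min()) / 4.0, y.min()]
        coef, _ = curve_fit(
            lambda xx, a, mu, s, c: a * np.exp(-0.5 * ((xx - mu) / s) ** 2) + c,
            x, y, p0=p0, maxfev=20000,
        )
        return coef
    raise ValueError(f"unknown family {family!r}")


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_constraint_line(
    points: BoundaryPointSet,
    families: tuple[str, ...] = DEFAULT_FAMILIES,
) -> ConstraintFit:
    """Fit each candidate family to the boundary points; keep the best.

    Families with fewer than ``n_params + 2`` points are skipped.  Model
    choice is by BIC with a positive-evidence margin: a family with more
    parameters must beat a simpler one by more than 2 BIC points per extra
    parameter (near-zero residual sums tie-break to the fewest
    parameters).  The reported ``r2`` is the plain coefficient of
    determination on the boundary points.
    """
    x, y = points.boundary_x, points.boundary_y
    n = len(x)
    results: dict[str, tuple[np.ndarray, float, float]] = {}
    for fam in families:
        p = _N_PARAMS[fam]
        if n < p + 2:
            continue
        try:
            coef = _fit_family(fam, x, y)
        except Exception:
            continue
        if not np.all(np.isfinite(coef)):
            continue
        yhat = _eval_family(fam, coef, x)
        rss = float(np.sum((y - yhat) ** 2))
        scale = float(np.sum(y**2)) or 1.0
        if rss / scale < 1e-16:  # numerically exact fit: parsimony tie-break
            bic = -1e18 + p
        else:
            bic = n * np.log(rss / n) + p * np.log(n)
        results[fam] = (coef, _r2(y, yhat), bic)
    if not results:
        raise FitError(f"no candidate family could be fitted: tried {list(families)}")
    best = min(results, key=lambda f: results[f][2] + 2.0 * _N_PARAMS[f])
    coef, r2, _ = results[best]
    thr_x, thr_y, flag = find_threshold_raw(best, coef, (x.min(), x.max()))
    return ConstraintFit(
        family=best,
        coefficients=np.asarray(coef, dtype=float),
        r2=r2,
        threshold_x=thr_x,
        threshold_y=thr_y,
        flag=flag,
        candidates={f: results[f][1] for f in results},
    )


def find_threshold_raw(
    family: str, coef: np.ndarray, x_range: tuple[float, float]
) -> tuple[float, float, str]:
    """Arg-max of a fitted family on ``x_range`` via its derivative.

    The critical point solves ``dy/dx = 0`` in closed form (vertex of the
    quadratic, roots of the cubic's derivative, mean of the gaussian); when
    no interior maximum exists the curve attains its maximum at a range
    endpoint and the result is flagged ``boundary_max``.
    """
    lo, hi = float(x_range[0]), float(x_range[1])
    candidates: list[float] = []
    if family == "hump_quadratic":
        a, b, _ = coef
        if a < 0:
            candidates.append(-b / (2 * a))
    elif family == "convex_wave_cubic":
        a, b, c, _ = coef
        roots = np.roots([3 * a, 2 * b, c])
        for r in roots:
            if abs(r.imag) < 1e-10 and 6 * a * r.real + 2 * b < 0:
                candidates.append(float(r.real))
    elif family == "hump_gaussian":
        a, mu, _, _ = coef
        if a > 0:
            candidates.append(float(mu))
    else:
        raise ValueError(f"unknown family {family!r}")
    interior = [c for c in candidates if lo < c < hi]
    if interior:
        xs = max(interior, key=lambda c: float(_eval_family(family, coef, np.array([c]))[0]))
        return float(xs), float(_eval_family(family, coef, np.array([xs]))[0]), ""
    y_lo = float(_eval_family(family, coef, np.array([lo]))[0])
    y_hi = float(_eval_family(family, coef, np.array([hi]))[0])
    if y_hi >= y_lo:
        return hi, y_hi, "boundary_max"
    return lo, y_lo, "boundary_max"


def find_threshold(
    fit: ConstraintFit, x_range: tuple[float, float]
) -> tuple[float, float]:
    """Threshold of an existing fit on a (possibly different) x-range."""
    x, y, _ = find_threshold_raw(fit.family, fit.coefficients, x_range)
    return x, y


def constraint_analysis_by_landuse(
    dataset: LandscapeDataset,
    es: EsStack,
    n_bins: int = 100,
    q: float = 99.9,
    min_count: int = 10,
    families: tuple[str, ...] = DEFAULT_FAMILIES,
) -> pd.DataFrame:
    """One constraint fit per (service, land-use class) of ES against SPEI.

    Pools all cell-years of a land-use stratum.  Strata without enough
    populated bins are reported with ``skipped=True``.
    """
    spei = dataset.variables["SPEI"]
    rows = []
    for lu in np.unique(dataset.land_use[dataset.mask]):
        sel = dataset.mask & (dataset.land_use == lu)
        x = spei[:, sel].ravel()
        for name in ES_NAMES:
            y = es.get(name)[:, sel].ravel()
            entry = {
                "es": name,
                "land_use": LAND_USE_NAMES.get(int(lu), str(int(lu))),
                "skipped": False,
            }
            try:
                pts = extract_boundary_points(x, y, n_bins=n_bins, q=q, min_count=min_count)
                fit = fit_constraint_line(pts, families=families)
            except (InsufficientDataError, FitError) as exc:
                entry.update(
                    {
                        "skipped": True, "reason": str(exc), "family": None,
                        "coefficients": None, "r2": np.nan,
                        "threshold_x": np.nan, "threshold_y": np.nan, "flag": "",
                    }
                )
            else:
                entry.update(
                    {
                        "reason": "",
                        "family": fit.family,
                        "coefficients": fit.coefficients.tolist(),
                        "r2": fit.r2,
                        "threshold_x": fit.threshold_x,
                        "threshold_y": fit.threshold_y,
                        "flag": fit.flag,
                    }
                )
            rows.append(entry)
    return pd.DataFrame(rows)
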