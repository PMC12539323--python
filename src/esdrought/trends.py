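"""Per-cell monotone trend analysis: Theil–Sen slope and Mann–Kendall test.

The Theil–Sen estimator is the median of all pairwise slopes
``(x_j - x_i) / (j - i)`` over ``j > i``.  The Mann–Kendall S statistic is
``S = sum_{i<j} sign(x_j - x_i)`` with the tie-corrected variance

    Var(S) = [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18

(the sum runs over tie-group sizes t), a continuity-corrected normal score
``z = (S -/+ 1)/sqrt(Var(S))`` (0 when S = 0), and a two-sided p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError
from .grid import GridField


@dataclass
class TrendResult:
    """Trend statistics for one series."""

    slope: float
    s_stat: int
    z: float
    p: float
    sig_class: str  # sig_increase | sig_decrease | nonsig


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    i, j = np.triu_indices(n, k=1)
    return i, j


def sen_slope(series: np.ndarray, times: np.ndarray | None = None) -> float:
    """Theil–Sen median slope of a series (units per time step).

    Missing values (NaN) are dropped pairwise while their time indices keep
    their calendar spacing, so the slope stays in units per calendar step.
    """
    x = np.asarray(series, dtype=float)
    t = np.arange(len(x), dtype=float) if times is None else np.asarray(times, dtype=float)
    ok = np.isfinite(x)
    x, t = x[ok], t[ok]
    if len(x) < 3:
        raise InsufficientDataError("sen_slope needs at least 3 finite values")
    i, j = _pair_indices(len(x))
    return float(np.median((x[j] - x[i]) / (t[j] - t[i])))


def _mk_var(values: np.ndarray) -> float:
    n = len(values)
    var = n * (n - 1) * (2 * n + 5)
    _, counts = np.unique(values, return_counts=True)
    ties = counts[counts > 1]
    if ties.size:
        var -= np.sum(ties * (ties - 1) * (2 * ties + 5))
    return var / 18.0


def mann_kendall(series: np.ndarray, alpha: float = 0.05) -> TrendResult:
    """Mann–Kendall monotone-trend test with tie correction.

    An all-tied series yields ``z = 0, p = 1`` (no trend), not an error.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 4:
        raise InsufficientDataError("mann_kendall needs at least 4 finite values")
    i, j = _pair_indices(len(x))
    s = int(np.sum(np.sign(x[j] - x[i])))
    var = _mk_var(x)
    if var <= 0 or s == 0:
        z = 0.0
    else:
        z = (s - 1) / np.sqrt(var) if s > 0 else (s + 1) / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    slope = sen_slope(x) if len(x) >= 3 else np.nan
    if p < alpha and s > 0:
        sig = "sig_increase"
    elif p < alpha and s < 0:
        sig = "sig_decrease"
    else:
        sig = "nonsig"
    return TrendResult(slope=slope, s_stat=s, z=float(z), p=p, sig_class=sig)


def trend_raster(
    series: np.ndarray,
    mask: np.ndarray,
    alpha: float = 0.05,
    cell_km: float = 1.0,
) -> dict[str, GridField]:
    """Per-cell Sen slope, MK p-value and significance map for a stack.

    ``series`` has shape ``(n_years, rows, cols)``.  Returns GridFields
    ``slope``, ``p`` and ``sig`` (coded +1 significant increase, -1
    significant decrease, 0 otherwise).  Vectorized over cells; tie
    corrections fall back to a per-cell pass only where ties occur.
    """
    T = series.shape[0]
    vals = series[:, mask].astype(float)  # (T, M)
    i, j = _pair_indices(T)
    diffs = vals[j] - vals[i]  # (n_pairs, M)
    dt = (j - i).astype(float)[:, None]
    slopes = np.median(diffs / dt, axis=0)
    s = np.sum(np.sign(diffs), axis=0)
    var = np.full(vals.shape[1], T * (T - 1) * (2 * T + 5) / 18.0)
    tied = np.any(diffs == 0, axis=0)
    for idx in np.nonzero(tied)[0]:
        var[idx] = _mk_var(vals[:, idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(s > 0, (s - 1) / np.sqrt(var), (s + 1) / np.sqrt(var))
    z = np.where((s == 0) | (var <= 0), 0.0, z)
    p = 2.0 * stats.norm.sf(np.abs(z))
    sig = np.where(p < alpha, np.sign(s), 0.0)

    def to_grid(flat: np.ndarray) -> GridField:
        out = np.full(mask.shape, np.nan)
        out[mask] = flat
        return GridField(out, mask, cell_km)

    return {"slope": to_grid(slopes), "p": to_grid(p), "sig": to_grid(sig)}


def zone_mean_slopes(
    trend_fields: dict[str, dict[str, GridField]], zones: np.ndarray, mask: np.ndarray
) -> pd.DataFrame:
    """Zone-mean Sen slope per variable (columns zone_id, variable, mean_slope)."""
    rows = []
    for var, fields in trend_fields.items():
        slope = fields["slope"].values
        for zid in np.unique(zones[mask]):
            sel = mask & (zones == zid)
            rows.append(
                {
                    "zone_id": int(zid),
                    "variable": var,
                    "mean_slope": float(np.nanmean(slope[sel])),
                }
            )
    return pd.DataFrame(rows)
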