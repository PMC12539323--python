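"""Trade-off / synergy correlations among services and ES~SPEI regressions.

A negative Pearson correlation between two services over the observation
units of a stratum is read as a trade-off, a positive one as a synergy.
Strata are typically drought-degree classes (most severe level a cell
experienced) or SOM bundles.  p-values come from the exact t-transform of
r with n-2 degrees of freedom; stars follow the usual convention
(* p<0.05, ** p<0.01, *** p<0.001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .es_models import EsStack
from .grid import ES_NAMES, LAND_USE_NAMES, GridField


def stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations within one stratum."""

    stratum: str
    names: list[str]
    r: np.ndarray
    p: np.ndarray
    n: int
    flags: np.ndarray  # True where r is undefined (zero variance)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.names):
            for j, b in enumerate(self.names):
                if j <= i:
                    continue
                r = self.r[i, j]
                rows.append(
                    {
                        "stratum": self.stratum,
                        "feature_a": a,
                        "feature_b": b,
                        "r": r,
                        "p": self.p[i, j],
                        "n": self.n,
                        "stars": stars(self.p[i, j]),
                        "relation": (
                            "undefined" if self.flags[i, j]
                            else "trade-off" if r < 0
                            else "synergy" if r > 0
                            else "none"
                        ),
                    }
                )
        return pd.DataFrame(rows)


def _pearson_matrix(cols: np.ndarray, names: list[str], stratum: str) -> CorrelationMatrix:
    k = cols.shape[1]
    n = cols.shape[0]
    r = np.eye(k)
    p = np.zeros((k, k))
    flags = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = cols[:, i], cols[:, j]
            if np.std(xi) == 0 or np.std(xj) == 0 or n < 3:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                flags[i, j] = flags[j, i] = True
                continue
            res = stats.pearsonr(xi, xj)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return CorrelationMatrix(stratum=stratum, names=names, r=r, p=p, n=n, flags=flags)


def tradeoff_matrix(
    es: EsStack,
    strata: np.ndarray,
    stratum_names: dict[int, str] | None = None,
    spei_f: GridField | None = None,
    per_year: bool = False,
) -> dict[str, CorrelationMatrix]:
    """Pearson correlation matrices among services, one per stratum.

    ``strata`` assigns each cell an integer stratum label on the grid
    (values < 0 or cells outside the mask are skipped).  Observations are
    period-mean services per cell by default; ``per_year=True`` pools
    cell-years instead.  ``spei_f`` adds drought frequency as a feature
    (period-mean mode only).  Strata with n < 3 are skipped.
    """
    mask = es.mask
    names = list(ES_NAMES)
    out: dict[str, CorrelationMatrix] = {}
    for s in np.unique(strata[mask]):
        if s < 0:
            continue
        sel = mask & (strata == s)
        if per_year:
            cols = np.column_stack([es.get(nm)[:, sel].ravel() for nm in ES_NAMES])
            these = list(names)
        else:
            cols = np.column_stack([es.get(nm)[:, sel].mean(axis=0) for nm in ES_NAMES])
            these = list(names)
            if spei_f is not None:
                cols = np.column_stack([cols, spei_f.values[sel]])
                these = these + ["SPEI_F"]
        if cols.shape[0] < 3:
            continue
        label = stratum_names.get(int(s), str(int(s))) if stratum_names else str(int(s))
        out[label] = _pearson_matrix(cols, these, label)
    return out


def es_spei_regression(
    es: EsStack, spei: np.ndarray, land_use: np.ndarray
) -> pd.DataFrame:
    """OLS slope of annual class-mean ES on class-mean SPEI per land use.

    One observation per year: the mean service and mean SPEI over the
    stratum's cells.  Degenerate x-variance is flagged undefined.
    """
    mask = es.mask
    rows = []
    for lu in np.unique(land_use[mask]):
        sel = mask & (land_use == lu)
        x = spei[:, sel].mean(axis=1)
        for name in ES_NAMES:
            y = es.get(name)[:, sel].mean(axis=1)
            undefined = len(x) < 3 or np.std(x) == 0 or np.std(y) == 0
            if undefined:
                slope = r = p = np.nan
            else:
                res = stats.linregress(x, y)
                slope, r, p = res.slope, res.rvalue, res.pvalue
            rows.append(
                {
                    "land_use": LAND_USE_NAMES.get(int(lu), str(int(lu))),
                    "es": name,
                    "slope": slope,
                    "r": r,
                    "p": p,
                    "stars": stars(p) if not undefined else "",
                    "n_years": len(x),
                    "undefined": undefined,
                }
            )
    return pd.DataFrame(rows)
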