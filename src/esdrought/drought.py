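"""SPEI drought classification, frequency and ES stratification.

SPEI is a unitless standardized drought index; more negative means more
severe drought.  Annual SPEI is classified into five ordered levels with
half-open intervals (closed on the severe side):

=========  ==================
none       SPEI > -0.5
slight     -1.0 < SPEI <= -0.5
medium     -1.5 < SPEI <= -1.0
serious    -2.0 < SPEI <= -1.5
extreme    SPEI <= -2.0
=========  ==================

The table is configurable; severity strictly increases as the interval
upper bound decreases.  Drought frequency (SPEI_F) is the fraction of
years a cell spends in any drought class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .es_models import EsStack
from .exceptions import ConfigurationError, DataError, DimensionError
from .grid import ES_NAMES, LAND_USE_NAMES, GridField

DROUGHT_CLASSES: tuple[str, ...] = ("none", "slight", "medium", "serious", "extreme")


@dataclass
class DroughtClassTable:
    """Ordered drought levels defined by their upper cutoffs.

    ``cutoffs[k]`` is the (inclusive) upper bound of class ``classes[k+1]``:
    with the default cutoffs (-0.5, -1.0, -1.5, -2.0), SPEI values in
    (-1.0, -0.5] are *slight*, values <= -2.0 are *extreme*, and anything
    above -0.5 is *none*.
    """

    classes: tuple[str, ...] = DROUGHT_CLASSES
    cutoffs: tuple[float, ...] = (-0.5, -1.0, -1.5, -2.0)

    def __post_init__(self) -> None:
        if len(self.cutoffs) != len(self.classes) - 1:
            raise ConfigurationError("cutoffs must have one entry per drought class")
        if not all(a > b for a, b in zip(self.cutoffs, self.cutoffs[1:])):
            raise ConfigurationError("cutoffs must be strictly decreasing")

    def classify_values(self, spei: np.ndarray) -> np.ndarray:
        """Integer class codes (0 = none, rising with severity)."""
        spei = np.asarray(spei, dtype=float)
        # code = number of cutoffs at or above the value
        codes = np.zeros(spei.shape, dtype=np.int8)
        for cut in self.cutoffs:
            codes += (spei <= cut).astype(np.int8)
        return codes


@dataclass
class DroughtSummary:
    """Per-cell drought class counts and frequency over the period."""

    class_counts: np.ndarray  # (n_classes, n_rows, n_cols)
    spei_f: GridField
    table: DroughtClassTable = field(default_factory=DroughtClassTable)


def classify_drought(
    spei: np.ndarray, mask: np.ndarray, table: DroughtClassTable | None = None
) -> np.ndarray:
    """Classify a ``(n_years, rows, cols)`` SPEI stack into level codes.

    Returns int codes with -1 on invalid cells.  Raises
    :class:`DataError` on non-finite SPEI over valid cells.
    """
    table = table or DroughtClassTable()
    spei = np.asarray(spei, dtype=float)
    if spei.ndim != 3:
        raise DimensionError("SPEI stack must be 3-D (years, rows, cols)")
    if not np.isfinite(spei[:, mask]).all():
        raise DataError("non-finite SPEI on a valid cell")
    labels = table.classify_values(spei).astype(np.int8)
    labels[:, ~mask] = -1
    return labels


def drought_frequency(labels: np.ndarray, mask: np.ndarray, cell_km: float = 1.0) -> GridField:
    """SPEI_F: fraction of years with any drought class, in [0, 1]."""
    n_years = labels.shape[0]
    freq = (labels > 0).sum(axis=0) / float(n_years)
    out = np.where(mask, freq, np.nan)
    return GridField(out, mask, cell_km)


def summarize_drought(
    spei: np.ndarray, mask: np.ndarray, table: DroughtClassTable | None = None,
    cell_km: float = 1.0,
) -> DroughtSummary:
    """Classify, count classes per cell and compute SPEI_F in one call."""
    table = table or DroughtClassTable()
    labels = classify_drought(spei, mask, table)
    counts = np.stack([(labels == k).sum(axis=0) for k in range(len(table.classes))])
    return DroughtSummary(counts, drought_frequency(labels, mask, cell_km), table)


def cell_drought_degree(labels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Most severe class a cell experienced over the period (-1 invalid)."""
    deg = labels.max(axis=0).astype(np.int8)
    deg[~mask] = -1
    return deg


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or len(b) < 2:
        return np.nan
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def stratify_es_by_drought(
    es: EsStack,
    labels: np.ndarray,
    land_use: np.ndarray,
    mode: str = "cell-year",
) -> pd.DataFrame:
    """Compare service levels between drought strata.

    mode ``"cell-year"``
        Per land-use class (and pooled), mean ± SD of each service over
        drought vs non-drought cell-years, with a Welch two-sample p-value.
        A cell-year is "drought" when its class is any drought level.
    mode ``"class-zone"``
        Per drought class, the distribution of each service (mean, SD,
        median, IQR) and the change Δ = mean(ES | class) − mean(ES | none).

    Strata with fewer than two observations are flagged ``undefined``.
    """
    if mode not in ("cell-year", "class-zone"):
        raise ConfigurationError(f"unknown stratification mode {mode!r}")
    m = es.mask
    lu_classes = [int(c) for c in np.unique(land_use[m])]
    rows: list[dict] = []
    if mode == "cell-year":
        drought = labels > 0
        for lu in [None, *lu_classes]:
            cell_sel = m if lu is None else (m & (land_use == lu))
            for name in ES_NAMES:
                vals = es.get(name)[:, cell_sel]
                dr = drought[:, cell_sel]
                a, b = vals[dr], vals[~dr]
                undefined = len(a) < 2 or len(b) < 2
                rows.append(
                    {
                        "land_use": "all" if lu is None else LAND_USE_NAMES.get(lu, str(lu)),
                        "es": name,
                        "n_drought": int(len(a)),
                        "n_nondrought": int(len(b)),
                        "drought_mean": float(np.mean(a)) if len(a) else np.nan,
                        "drought_sd": float(np.std(a, ddof=1)) if len(a) > 1 else np.nan,
                        "nondrought_mean": float(np.mean(b)) if len(b) else np.nan,
                        "nondrought_sd": float(np.std(b, ddof=1)) if len(b) > 1 else np.nan,
                        "p_welch": np.nan if undefined else _welch(a, b),
                        "undefined": undefined,
                    }
                )
        return pd.DataFrame(rows)
    # class-zone mode
    for lu in [None, *lu_classes]:
        cell_sel = m if lu is None else (m & (land_use == lu))
        baselines: dict[str, float] = {}
        for name in ES_NAMES:
            vals_none = es.get(name)[:, cell_sel][labels[:, cell_sel] == 0]
            baselines[name] = float(np.mean(vals_none)) if len(vals_none) else np.nan
        for k, cls in enumerate(DROUGHT_CLASSES):
            lab_sel = labels[:, cell_sel] == k
            for name in ES_NAMES:
                vals = es.get(name)[:, cell_sel][lab_sel]
                undefined = len(vals) < 2
                q25, med, q75 = (
                    np.percentile(vals, [25, 50, 75]) if len(vals) else (np.nan,) * 3
                )
                rows.append(
                    {
                        "land_use": "all" if lu is None else LAND_USE_NAMES.get(lu, str(lu)),
                        "drought_class": cls,
                        "es": name,
                        "n": int(len(vals)),
                        "mean": float(np.mean(vals)) if len(vals) else np.nan,
                        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                        "median": float(med),
                        "iqr_low": float(q25),
                        "iqr_high": float(q75),
                        "delta_vs_none": (
                            float(np.mean(vals)) - baselines[name] if len(vals) else np.nan
                        ),
                        "undefined": undefined,
                    }
                )
    return pd.DataFrame(rows)


def binned_spei_surface(
    tem: np.ndarray,
    pre: np.ndarray,
    spei: np.ndarray,
    mask: np.ndarray,
    tem_edges: np.ndarray,
    pre_edges: np.ndarray,
) -> pd.DataFrame:
    """Mean SPEI on a temperature × precipitation grid of bins.

    Pools all valid cell-years; empty bins are NaN.  Returns a tidy frame
    with bin edges, counts and the bin-mean SPEI.
    """
    tem_edges = np.asarray(tem_edges, dtype=float)
    pre_edges = np.asarray(pre_edges, dtype=float)
    for name, e in (("temperature", tem_edges), ("precipitation", pre_edges)):
        if len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ConfigurationError(f"{name} bin edges must be strictly increasing")
    t = tem[:, mask].ravel()
    p = pre[:, mask].ravel()
    s = spei[:, mask].ravel()
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        stat, _, _, _ = stats.binned_statistic_2d(
            t, p, s, statistic="mean", bins=[tem_edges, pre_edges]
        )
        count, _, _, _ = stats.binned_statistic_2d(
            t, p, s, statistic="count", bins=[tem_edges, pre_edges]
        )
    rows = []
    for i in range(len(tem_edges) - 1):
        for j in range(len(pre_edges) - 1):
            rows.append(
                {
                    "tem_low": tem_edges[i],
                    "tem_high": tem_edges[i + 1],
                    "pre_low": pre_edges[j],
                    "pre_high": pre_edges[j + 1],
                    "n": int(count[i, j]),
                    "mean_spei": float(stat[i, j]) if count[i, j] > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)
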