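"""Ecosystem-service bundles via a self-organizing map (SOM).

Cells are described by their period-mean services plus drought frequency,
z-score standardized, and assigned to the best-matching unit of a small
SOM (2×2 by default, one unit per bundle).  Training is deterministic
batch SOM: each epoch assigns every row to its best-matching unit and
moves each codebook vector toward the neighborhood-weighted mean of the
data, with the neighborhood radius and the blending rate decaying
linearly over epochs.  With a fixed seed (codebook initialized from
random data rows) the result is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .es_models import EsStack
from .exceptions import ConfigurationError, InsufficientDataError
from .grid import ES_NAMES, GridField


@dataclass
class FeatureMatrix:
    """Standardized per-cell feature rows with the inverse transform retained."""

    values: np.ndarray  # (n_rows, n_features), z-scored
    names: list[str]
    means: np.ndarray
    sds: np.ndarray
    cell_index: np.ndarray  # flat indices into the grid (per row)
    grid_shape: tuple[int, int]
    standardized: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)

    def unstandardize(self) -> np.ndarray:
        return self.values * self.sds + self.means


@dataclass
class BundleAssignment:
    """Per-cell bundle labels with the trained codebook."""

    labels: np.ndarray  # (n_rows,), 1..k
    codebook: np.ndarray  # (k_units, n_features) in standardized space
    quantization_error: float
    grid_shape: tuple[int, int]
    cell_index: np.ndarray
    realized_k: int

    def label_grid(self, cell_km: float = 1.0) -> GridField:
        """Bundle labels on the grid (0 = invalid)."""
        flat = np.zeros(int(np.prod(self.grid_shape)), dtype=np.int32)
        flat[self.cell_index] = self.labels
        mask = np.zeros_like(flat, dtype=bool)
        mask[self.cell_index] = True
        return GridField(
            flat.reshape(self.grid_shape).astype(float),
            mask.reshape(self.grid_shape),
            cell_km,
        )


def standardize(values: np.ndarray, names: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column z-scores (sample SD, ddof=1); zero-variance columns are an error."""
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1) if len(values) > 1 else values.std(axis=0)
    bad = np.nonzero(sds == 0)[0]
    if bad.size:
        raise ConfigurationError(
            f"zero-variance feature column(s): {[names[i] for i in bad]}"
        )
    return (values - means) / sds, means, sds


def build_feature_matrix(
    es: EsStack,
    spei_f: GridField,
    period_stat: str = "mean",
) -> FeatureMatrix:
    """Assemble (WR, SC, CS, FS, SPEI_F) rows for every valid cell.

    ``period_stat="mean"`` gives one row per cell (period-mean services);
    ``"per-year"`` stacks one row per cell-year (SPEI_F repeated).
    """
    if period_stat not in ("mean", "per-year"):
        raise ConfigurationError(f"unknown period_stat {period_stat!r}")
    mask = es.mask
    cell_index = np.nonzero(mask.ravel())[0]
    names = list(ES_NAMES) + ["SPEI_F"]
    if period_stat == "mean":
        cols = [es.get(n)[:, mask].mean(axis=0) for n in ES_NAMES]
        cols.append(spei_f.values[mask])
        raw = np.column_stack(cols)
        idx = cell_index
    else:
        cols = [es.get(n)[:, mask].ravel() for n in ES_NAMES]
        cols.append(np.tile(spei_f.values[mask], es.n_years))
        raw = np.column_stack(cols)
        idx = np.tile(cell_index, es.n_years)
    z, means, sds = standardize(raw, names)
    return FeatureMatrix(
        values=z, names=names, means=means, sds=sds,
        cell_index=idx, grid_shape=mask.shape,
    )


class SelfOrganizingMap:
    """Minimal batch SOM on a rectangular unit grid with Gaussian neighborhood."""

    def __init__(
        self,
        grid_shape: tuple[int, int] = (2, 2),
        epochs: int = 50,
        radius: tuple[float, float] = (1.0, 0.05),
        rate: tuple[float, float] = (0.5, 0.01),
        seed: int = 0,
    ):
        self.grid_shape = grid_shape
        self.epochs = epochs
        self.radius = radius
        self.rate = rate
        self.seed = seed
        ii, jj = np.meshgrid(
            np.arange(grid_shape[0]), np.arange(grid_shape[1]), indexing="ij"
        )
        self._unit_pos = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)
        self.codebook: np.ndarray | None = None

    @property
    def n_units(self) -> int:
        return int(np.prod(self.grid_shape))

    def fit(self, data: np.ndarray) -> "SelfOrganizingMap":
        rng = np.random.default_rng(self.seed)
        init_rows = rng.choice(len(data), size=self.n_units, replace=False)
        codebook = data[init_rows].astype(float).copy()
        unit_d2 = (
            (self._unit_pos[:, None, :] - self._unit_pos[None, :, :]) ** 2
        ).sum(axis=-1)
        for epoch in range(self.epochs):
            frac = epoch / max(self.epochs - 1, 1)
            sigma = self.radius[0] + frac * (self.radius[1] - self.radius[0])
            alpha = self.rate[0] + frac * (self.rate[1] - self.rate[0])
            bmu = self._bmu(data, codebook)
            h = np.exp(-unit_d2 / (2.0 * sigma**2))  # (units, units)
            w = h[:, bmu]  # (units, n_rows)
            denom = w.sum(axis=1)
            target = np.where(
                denom[:, None] > 0, (w @ data) / np.maximum(denom, 1e-300)[:, None],
                codebook,
            )
            codebook = (1 - alpha) * codebook + alpha * target
        self.codebook = codebook
        return self

    @staticmethod
    def _bmu(data: np.ndarray, codebook: np.ndarray) -> np.ndarray:
        d2 = ((data[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=-1)
        return np.argmin(d2, axis=1)

    def predict(self, data: np.ndarray) -> np.ndarray:
        return self._bmu(data, self.codebook)

    def quantization_error(self, data: np.ndarray) -> float:
        d2 = ((data[:, None, :] - self.codebook[None, :, :]) ** 2).sum(axis=-1)
        return float(np.sqrt(d2.min(axis=1)).mean())


def som_cluster(
    features: FeatureMatrix,
    k: int = 4,
    grid_shape: tuple[int, int] | None = None,
    epochs: int = 50,
    seed: int = 0,
) -> BundleAssignment:
    """Cluster feature rows into ES bundles with a SOM.

    ``grid_shape`` defaults to the most square factorization of ``k``.
    Empty units raise a warning and the realized bundle count is reported;
    labels are renumbered 1..realized_k over non-empty units.
    """
    data = features.values
    if len(data) < 10 * k:
        raise InsufficientDataError(f"need at least {10 * k} rows for k={k}")
    if grid_shape is None:
        rows = int(np.floor(np.sqrt(k)))
        while k % rows:
            rows -= 1
        grid_shape = (rows, k // rows)
    if int(np.prod(grid_shape)) != k:
        raise ConfigurationError(f"grid_shape {grid_shape} does not give k={k} units")
    som = SelfOrganizingMap(grid_shape=grid_shape, epochs=epochs, seed=seed).fit(data)
    units = som.predict(data)
    occupied = np.unique(units)
    if len(occupied) < k:
        warnings.warn(
            f"only {len(occupied)} of {k} SOM units are occupied", stacklevel=2
        )
    relabel = {u: i + 1 for i, u in enumerate(occupied)}
    labels = np.array([relabel[u] for u in units], dtype=np.int32)
    return BundleAssignment(
        labels=labels,
        codebook=som.codebook[occupied],
        quantization_error=som.quantization_error(data),
        grid_shape=features.grid_shape,
        cell_index=features.cell_index,
        realized_k=len(occupied),
    )


def summarize_bundles(
    assignment: BundleAssignment, features: FeatureMatrix
) -> pd.DataFrame:
    """Median/IQR/mean/SD of each feature per bundle, in original units."""
    raw = features.unstandardize()
    rows = []
    for b in range(1, assignment.realized_k + 1):
        sel = assignment.labels == b
        for f, name in enumerate(features.names):
            vals = raw[sel, f]
            q25, med, q75 = np.percentile(vals, [25, 50, 75])
            rows.append(
                {
                    "bundle": b,
                    "feature": name,
                    "n": int(sel.sum()),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "median": float(med),
                    "iqr_low": float(q25),
                    "iqr_high": float(q75),
                }
            )
    return pd.DataFrame(rows)
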