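"""Fixture I/O: single-band TIFF rasters plus a JSON manifest.

A landscape fixture directory holds one float32 TIFF per variable-year
(``<VAR>_<YEAR>.tif``), integer rasters for the static land-use / zone /
ground-truth-label maps, the zonal grain-yield table as CSV, and a
``manifest.json`` carrying the grid metadata (shape, cell size, years)
and a SHA-256 checksum per file.  Reading verifies checksums,
completeness and co-registration, and reproduces the dataset bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .exceptions import AlignmentError, ChecksumError
from .grid import VARIABLES, LandscapeDataset

MANIFEST_NAME = "manifest.json"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_raster(path: Path, values: np.ndarray, meta: dict) -> None:
    tifffile.imwrite(path, values, description=json.dumps(meta, sort_keys=True))


def read_raster(path: Path) -> tuple[np.ndarray, dict]:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    return arr, meta


def write_fixture(dataset: LandscapeDataset, directory: str | Path) -> dict:
    """Write a landscape to ``directory``; returns the manifest dict."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    years = [int(y) for y in dataset.years]
    base_meta = {"cell_km": dataset.cell_km}
    for var in VARIABLES:
        arr = dataset.variables[var]
        for t, year in enumerate(years):
            name = f"{var}_{year}.tif"
            write_raster(
                directory / name,
                arr[t],
                {**base_meta, "variable": var, "year": year, "nodata": "nan"},
            )
            files[name] = _sha256(directory / name)
    int_layers = {
        "land_use.tif": dataset.land_use,
        "zones.tif": dataset.zones,
        "mask.tif": dataset.mask.astype(np.int32),
    }
    if dataset.true_bundle is not None:
        int_layers["true_bundle.tif"] = dataset.true_bundle
    if dataset.true_stratum is not None:
        int_layers["true_stratum.tif"] = dataset.true_stratum
    for name, arr in int_layers.items():
        write_raster(
            directory / name,
            np.asarray(arr, dtype=np.int32),
            {**base_meta, "variable": name.removesuffix(".tif")},
        )
        files[name] = _sha256(directory / name)
    table_path = directory / "zone_grain_yield.csv"
    dataset.zone_grain_yield.to_csv(table_path, index=False)
    files["zone_grain_yield.csv"] = _sha256(table_path)
    manifest = {
        "shape": list(dataset.shape),
        "cell_km": dataset.cell_km,
        "years": years,
        "variables": list(VARIABLES),
        "has_true_labels": dataset.true_bundle is not None,
        "files": files,
    }
    (directory / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def read_landscape(directory: str | Path) -> LandscapeDataset:
    """Read a fixture directory back into a :class:`LandscapeDataset`.

    Raises :class:`ChecksumError` naming any corrupted file, a
    ``FileNotFoundError`` listing missing variable-years, and
    :class:`AlignmentError` for rasters off the common grid.
    """
    directory = Path(directory)
    manifest = json.loads((directory / MANIFEST_NAME).read_text())
    missing = [n for n in manifest["files"] if not (directory / n).exists()]
    if missing:
        raise FileNotFoundError(f"fixture incomplete, missing: {sorted(missing)}")
    for name, digest in manifest["files"].items():
        if _sha256(directory / name) != digest:
            raise ChecksumError(f"checksum mismatch for {name}")
    shape = tuple(manifest["shape"])
    years = manifest["years"]
    variables: dict[str, np.ndarray] = {}
    for var in manifest["variables"]:
        layers = []
        for year in years:
            arr, _ = read_raster(directory / f"{var}_{year}.tif")
            if arr.shape != shape:
                raise AlignmentError(
                    f"{var}_{year}.tif has shape {arr.shape}, expected {shape}"
                )
            layers.append(arr)
        variables[var] = np.stack(layers)
    land_use, _ = read_raster(directory / "land_use.tif")
    zones, _ = read_raster(directory / "zones.tif")
    mask, _ = read_raster(directory / "mask.tif")
    for name, arr in (("land_use", land_use), ("zones", zones), ("mask", mask)):
        if arr.shape != shape:
            raise AlignmentError(f"{name}.tif has shape {arr.shape}, expected {shape}")
    true_bundle = true_stratum = None
    if manifest.get("has_true_labels"):
        true_bundle, _ = read_raster(directory / "true_bundle.tif")
        true_stratum, _ = read_raster(directory / "true_stratum.tif")
    table = pd.read_csv(directory / "zone_grain_yield.csv", float_precision="round_trip")
    return LandscapeDataset(
        variables=variables,
        land_use=land_use.astype(np.int32),
        zones=zones.astype(np.int32),
        zone_grain_yield=table,
        mask=mask.astype(bool),
        cell_km=float(manifest["cell_km"]),
        years=np.asarray(years, dtype=int),
        true_bundle=true_bundle,
        true_stratum=true_stratum,
    )
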