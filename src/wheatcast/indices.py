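"""Vegetation indices from red/NIR surface reflectance.

Three indices are supported:

* ``NDVI = (NIR - RED) / (NIR + RED)``, clipped to [-1, 1];
* ``NIRv = (NDVI - 0.08) * NIR``, the near-infrared reflectance of
  vegetation, a structural proxy for photosynthesis/SIF;
* ``kNDVI = tanh(NDVI**2)``, the kernelized NDVI with improved sensitivity
  at high greenness.

Reflectance is expected in [0, 1]; slightly out-of-range inputs (common in
real surface-reflectance products) are accepted and logged at DEBUG level.
Cloud screening is represented purely as input validity masks — apply them
with :func:`wheatcast.raster.mask_where` before index computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .raster import RasterCube, RasterGrid

__all__ = ["BandPair", "VI_NAMES", "compute_ndvi", "compute_nirv", "compute_kndvi", "vi_cube"]

logger = logging.getLogger(__name__)

VI_NAMES = ("NDVI", "NIRv", "kNDVI")

NIRV_OFFSET = 0.08  # fixed constant of the NIRv formula


@dataclass
class BandPair:
    """Red and near-infrared reflectance grids sharing one GridSpec."""

    red: RasterGrid
    nir: RasterGrid

    def __post_init__(self) -> None:
        if self.red.spec != self.nir.spec:
            raise ValueError("red and nir bands must share a GridSpec")
        for name, band in (("red", self.red), ("nir", self.nir)):
            vals = band.values[band.valid]
            if vals.size and (vals.min() < 0 or vals.max() > 1):
                logger.debug("%s reflectance outside [0, 1]: range [%g, %g]", name, vals.min(), vals.max())


def compute_ndvi(bands: BandPair) -> RasterGrid:
    """Normalized difference vegetation index, invalid where NIR+RED == 0."""
    red, nir = bands.red, bands.nir
    denom = nir.values + red.values
    ok = red.valid & nir.valid & (denom != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = (nir.values - red.values) / denom
    ndvi = np.clip(ndvi, -1.0, 1.0)
    return RasterGrid(red.spec, np.where(ok, ndvi, 0.0), ok)


def compute_nirv(ndvi: RasterGrid, nir: RasterGrid) -> RasterGrid:
    """NIRv = (NDVI - 0.08) * NIR."""
    if ndvi.spec != nir.spec:
        raise ValueError("ndvi and nir must share a GridSpec")
    ok = ndvi.valid & nir.valid
    nirv = (ndvi.values - NIRV_OFFSET) * nir.values
    return RasterGrid(ndvi.spec, np.where(ok, nirv, 0.0), ok)


def compute_kndvi(ndvi: RasterGrid) -> RasterGrid:
    """kNDVI = tanh(NDVI^2); output in [0, tanh(1)], validity inherited."""
    kndvi = np.tanh(ndvi.values**2)
    return RasterGrid(ndvi.spec, np.where(ndvi.valid, kndvi, 0.0), ndvi.valid.copy())


def vi_cube(red_cube: RasterCube, nir_cube: RasterCube, vi_name: str) -> RasterCube:
    """Apply the chosen index per timestamp of paired red/NIR cubes.

    NIRv and kNDVI are derived from the NDVI of the same timestamp.
    """
    if vi_name not in VI_NAMES:
        raise ValueError(f"unknown vi_name {vi_name!r}; expected one of {VI_NAMES}")
    if red_cube.timestamps != nir_cube.timestamps:
        raise ValueError("red and nir cubes must share timestamps")
    layers = []
    for red, nir in zip(red_cube.layers, nir_cube.layers):
        ndvi = compute_ndvi(BandPair(red, nir))
        if vi_name == "NDVI":
            layers.append(ndvi)
        elif vi_name == "NIRv":
            layers.append(compute_nirv(ndvi, nir))
        else:
            layers.append(compute_kndvi(ndvi))
    return RasterCube(red_cube.spec, list(red_cube.timestamps), layers)
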