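"""Nuclei-distribution heatmaps from segmented H&E nuclei centroids.

Nuclei are segmented from the H&E image by an external tool; this module
consumes the resulting centroids (CSV) or label mask (TIFF), counts nuclei
per unit area on a regular tile grid, optionally smooths the count map, and
min-max normalises it to [0, 1] where 1 marks densely packed nuclei.  Tiles
at or above 0.5 are classified as high nuclei distribution (HND), below 0.5
as low (LND).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "NucleiSet",
    "DensityMap",
    "density_map",
    "classify_density",
    "CLASS_LND",
    "CLASS_HND",
    "DENSITY_CUT",
    "load_centroids_csv",
    "centroids_from_label_image",
]

CLASS_LND = 1
CLASS_HND = 2

#: Class boundary; the boundary value itself is HND (upper class closed),
#: mirroring the coherence rule.
DENSITY_CUT = 0.5


@dataclass
class NucleiSet:
    """Nuclei centroids in physical µm coordinates within a source extent."""

    centroids: np.ndarray  # (n, 2) of (x_um, y_um)
    source_extent_um: tuple[float, float]  # (width, height), origin at (0, 0)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        w, h = self.source_extent_um
        if w <= 0 or h <= 0:
            raise ValueError("extent must be positive")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroid coordinates must be finite")
        x, y = self.centroids[:, 0], self.centroids[:, 1]
        if len(x) and (x.min() < 0 or y.min() < 0 or x.max() > w or y.max() > h):
            raise ValueError("centroids outside the source extent")

    def __len__(self) -> int:
        return len(self.centroids)


@dataclass
class DensityMap:
    """Min-max-normalised nuclei-per-tile map in [0, 1] (y-down rows)."""

    values: np.ndarray
    tile_um: float
    raw_counts: np.ndarray
    origin_um: tuple[float, float] = (0.0, 0.0)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.raw_counts = np.asarray(self.raw_counts, dtype=float)
        if self.values.shape != self.raw_counts.shape:
            raise ValueError("values/raw_counts shape mismatch")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("density values must lie in [0, 1]")


def density_map(nuclei: NucleiSet, tile_um: float = 100.0, smooth: bool = True) -> DensityMap:
    """Count nuclei per tile and min-max normalise to [0, 1].

    Tiles are half-open ``[x, x+tile) x [y, y+tile)`` on a regular grid
    covering the source extent.  With ``smooth=True`` the count map is
    Gaussian-filtered (sigma = 1 tile) before normalisation.  If all tiles
    hold the same (smoothed) count the map is set to 0.5 everywhere so that
    classification stays well defined.
    """
    if tile_um <= 0:
        raise ValueError("tile_um must be positive")
    if len(nuclei) == 0:
        raise ValueError("empty NucleiSet")
    w, h = nuclei.source_extent_um
    nx = max(1, int(np.ceil(w / tile_um)))
    ny = max(1, int(np.ceil(h / tile_um)))
    ix = np.floor(nuclei.centroids[:, 0] / tile_um).astype(int)
    iy = np.floor(nuclei.centroids[:, 1] / tile_um).astype(int)
    # points exactly on the far extent edge fall into the last tile
    ix = np.clip(ix, 0, nx - 1)
    iy = np.clip(iy, 0, ny - 1)
    counts = np.zeros((ny, nx))
    np.add.at(counts, (iy, ix), 1.0)
    v = ndi.gaussian_filter(counts, sigma=1.0, mode="reflect") if smooth else counts.copy()
    lo, hi = v.min(), v.max()
    if hi > lo:
        v = (v - lo) / (hi - lo)
    else:
        v = np.full_like(v, 0.5)
    return DensityMap(v, tile_um, counts, (0.0, 0.0), {"smooth": smooth})


def classify_density(dm: DensityMap) -> np.ndarray:
    """Classify tiles: values in [0, 0.5) -> LND, [0.5, 1] -> HND."""
    out = np.full(dm.values.shape, CLASS_LND, dtype=np.uint8)
    out[dm.values >= DENSITY_CUT] = CLASS_HND
    return out


def load_centroids_csv(path: str | Path, extent_um: tuple[float, float]) -> NucleiSet:
    """Read a centroid table with an ``x_um,y_um`` header."""
    import pandas as pd

    df = pd.read_csv(path)
    if not {"x_um", "y_um"} <= set(df.columns):
        raise ValueError("centroid CSV must have columns x_um, y_um")
    return NucleiSet(df[["x_um", "y_um"]].values, extent_um)


def centroids_from_label_image(labels: np.ndarray, um_per_px: float) -> NucleiSet:
    """Reduce a nuclei label mask to per-label centers of mass (µm)."""
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if len(ids) == 0:
        raise ValueError("label image contains no nuclei")
    cy_cx = ndi.center_of_mass(labels > 0, labels, ids)
    pts = np.array([(cx * um_per_px, cy * um_per_px) for cy, cx in cy_cx])
    h, w = labels.shape
    return NucleiSet(pts, (w * um_per_px, h * um_per_px))
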