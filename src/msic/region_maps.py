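"""Co-registration of heatmaps and annotations onto the MSI pixel grid.

The microscopy heatmaps (collagen coherence, nuclei density) live on fine
image grids; MSI pixels are 50 µm footprints.  Everything is brought onto a
shared physical frame (µm, 0-based, y-down, half-open pixel footprints
``[x, x + spacing)``) by an explicit affine transform — identity when all
modalities were generated on one frame.  Continuous maps are aggregated per
MSI footprint by the mean, class maps by majority vote; pathologist
annotations (QuPath-dialect GeoJSON polygons) label an MSI pixel when its
center lies inside the polygon.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape

from .msi_core import MSIDataset

__all__ = [
    "AffineTransform",
    "resample_to_msi",
    "import_annotations",
    "percent_area",
    "build_region_labels",
    "write_region_labels",
]

logger = logging.getLogger(__name__)

#: Label values treated as "not evaluated" by percent_area.
BACKGROUND_TOKENS = frozenset({"background", "none", ""})


@dataclass
class AffineTransform:
    """2x3 affine matrix mapping modality coordinates (µm) to MSI µm."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 3)
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise ValueError("affine transform is not invertible")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse(self) -> "AffineTransform":
        A = self.matrix[:, :2]
        b = self.matrix[:, 2]
        Ai = np.linalg.inv(A)
        return AffineTransform(np.hstack([Ai, (-Ai @ b)[:, None]]))

    @classmethod
    def from_landmarks(cls, src: np.ndarray, dst: np.ndarray) -> "AffineTransform":
        """Least-squares affine from >= 3 point pairs; logs the residual."""
        src = np.asarray(src, dtype=float).reshape(-1, 2)
        dst = np.asarray(dst, dtype=float).reshape(-1, 2)
        if len(src) < 3 or len(src) != len(dst):
            raise ValueError("need >= 3 matching landmark pairs")
        A = np.hstack([src, np.ones((len(src), 1))])
        coef, res, *_ = np.linalg.lstsq(A, dst, rcond=None)
        t = cls(coef.T)
        rms = float(np.sqrt(np.mean((t.apply(src) - dst) ** 2)))
        logger.info("landmark affine fitted, RMS residual %.3f um", rms)
        return t


def _pixel_row_grid(ds: MSIDataset) -> np.ndarray:
    """Dense (ix, iy) -> dataset row index grid; -1 marks absent pixels."""
    mx, my = ds.coords[:, 0].max(), ds.coords[:, 1].max()
    grid = np.full((mx + 1, my + 1), -1, dtype=int)
    grid[ds.coords[:, 0], ds.coords[:, 1]] = np.arange(ds.n_pixels)
    return grid


def resample_to_msi(
    map_values: np.ndarray,
    um_per_px: float,
    ds: MSIDataset,
    T: AffineTransform | None = None,
    rule: str = "mean",
    origin_um: tuple[float, float] = (0.0, 0.0),
    valid: np.ndarray | None = None,
) -> np.ndarray:
    """Pull a raster map back onto the MSI pixel grid.

    Every map pixel center is pushed through ``T`` into the MSI physical
    frame and binned into the half-open MSI footprint it falls in.

    Parameters
    ----------
    map_values
        2-D raster (continuous field or small-integer class map with 0 =
        background).
    um_per_px
        Pixel (or tile) size of the raster in µm.
    rule
        ``'mean'`` for continuous maps (returns float per MSI pixel, NaN
        where no valid sample lands) or ``'majority'`` for class maps
        (returns int per MSI pixel, 0 where no foreground sample lands;
        background class 0 is excluded from the vote).
    valid
        Optional boolean mask of map pixels to include (e.g. the SHG
        foreground for a coherence map).
    """
    if rule not in ("mean", "majority"):
        raise ValueError(f"unknown rule {rule!r}")
    if T is None:
        T = AffineTransform.identity()
    vals = np.asarray(map_values)
    ny, nx = vals.shape
    ox, oy = ds.origin_um
    row_grid = _pixel_row_grid(ds)
    n = ds.n_pixels

    if rule == "mean":
        sums = np.zeros(n)
        counts = np.zeros(n)
    else:
        classes = np.unique(vals[vals > 0]).astype(int)
        votes = np.zeros((n, len(classes)))

    # chunk rows so very large microscopy mosaics do not blow memory
    chunk = max(1, int(4e6 / max(nx, 1)))
    for r0 in range(0, ny, chunk):
        r1 = min(ny, r0 + chunk)
        rows, cols = np.mgrid[r0:r1, 0:nx]
        x = origin_um[0] + (cols.ravel() + 0.5) * um_per_px
        y = origin_um[1] + (rows.ravel() + 0.5) * um_per_px
        v = vals[r0:r1].ravel()
        keep = np.isfinite(v.astype(float))
        if valid is not None:
            keep &= valid[r0:r1].ravel()
        if rule == "majority":
            keep &= v > 0
        if not keep.any():
            continue
        p = T.apply(np.column_stack([x[keep], y[keep]]))
        ix = np.floor((p[:, 0] - ox) / ds.spacing_um).astype(int)
        iy = np.floor((p[:, 1] - oy) / ds.spacing_um).astype(int)
        v = v[keep]
        inb = (
            (ix >= 0)
            & (iy >= 0)
            & (ix < row_grid.shape[0])
            & (iy < row_grid.shape[1])
        )
        ix, iy, v = ix[inb], iy[inb], v[inb]
        row = row_grid[ix, iy]
        hit = row >= 0
        row, v = row[hit], v[hit]
        if rule == "mean":
            np.add.at(sums, row, v.astype(float))
            np.add.at(counts, row, 1.0)
        else:
            ci = np.searchsorted(classes, v.astype(int))
            np.add.at(votes, (row, ci), 1.0)

    if rule == "mean":
        out = np.full(n, np.nan)
        ok = counts > 0
        out[ok] = sums[ok] / counts[ok]
        return out
    out = np.zeros(n, dtype=int)
    if len(classes):
        hit = votes.sum(axis=1) > 0
        out[hit] = classes[np.argmax(votes[hit], axis=1)]
    return out


def import_annotations(
    path,
    ds: MSIDataset,
    T: AffineTransform | None = None,
    default: str = "none",
) -> np.ndarray:
    """Label MSI pixels from a GeoJSON FeatureCollection of polygons.

    A pixel takes a polygon's class iff its center lies inside the polygon
    (boundary counts as inside).  Overlapping polygons: the last-listed
    feature wins and the overlap is logged.  Class names follow the QuPath
    dialect (``properties.classification.name``) with ``properties.name``
    as fallback.
    """
    with open(path) as fh:
        gj = json.load(fh)
    features = gj.get("features", [])
    centers = ds.pixel_centers_um()
    if T is not None:
        centers = T.inverse().apply(centers)
    pts = shapely.points(centers[:, 0], centers[:, 1])
    labels = np.full(ds.n_pixels, default, dtype=object)
    for i, feat in enumerate(features):
        geom = shapely_shape(feat["geometry"])
        fid = feat.get("id", i)
        if not geom.is_valid:
            raise ValueError(f"invalid (self-intersecting?) polygon in feature {fid!r}")
        props = feat.get("properties", {}) or {}
        name = (props.get("classification") or {}).get("name") or props.get(
            "name", "region"
        )
        inside = shapely.covers(geom, pts)
        overlap = int(np.sum(inside & (labels != default)))
        if overlap:
            logger.info(
                "feature %r overwrites %d already-labelled pixels (last wins)",
                fid,
                overlap,
            )
        labels[inside] = name
    return labels


def build_region_labels(ds: MSIDataset, **attributes: np.ndarray) -> pd.DataFrame:
    """Assemble the per-MSI-pixel attribute table.

    Keyword arguments are per-pixel label arrays (strings, or small ints
    which are kept as-is), e.g. ``group=..., coherence_class=...,
    density_class=..., annotation=...``.  Rows align with ``ds.coords``.
    """
    data = {"ix": ds.coords[:, 0], "iy": ds.coords[:, 1]}
    for name, arr in attributes.items():
        arr = np.asarray(arr)
        if len(arr) != ds.n_pixels:
            raise ValueError(f"attribute {name!r} length mismatch")
        data[name] = arr
    return pd.DataFrame(data)


def _evaluated_mask(col: pd.Series) -> np.ndarray:
    if col.dtype.kind in "iuf":
        return col.values > 0
    return ~col.astype(str).str.lower().isin(BACKGROUND_TOKENS).values


def percent_area(
    labels: pd.DataFrame,
    attribute: str,
    within: tuple[str, object] | None = None,
) -> pd.Series:
    """Percent of evaluated (non-background) pixels per class of an attribute.

    ``within=(other_attribute, value)`` restricts the evaluation to pixels
    of that class first (e.g. within the tumour annotation).  The returned
    percentages sum to 100.
    """
    if attribute not in labels.columns:
        raise KeyError(f"unknown attribute {attribute!r}")
    df = labels
    if within is not None:
        attr, val = within
        df = df[df[attr] == val]
    df = df[_evaluated_mask(df[attribute])]
    if len(df) == 0:
        raise ValueError("zero evaluated pixels for this attribute/filter")
    counts = df[attribute].value_counts().sort_index()
    return 100.0 * counts / counts.sum()


def write_region_labels(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, sep="\t", index=False)
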