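"""Data model and I/O for MALDI mass spectrometry imaging (MSI) datacubes.

An MSI acquisition is a raster of mass spectra over a tissue section: each
pixel of a regular grid (typically 50 µm pitch) holds one peptide mass
spectrum in the 800-3200 m/z range.  This module provides the in-memory
containers (:class:`Spectrum`, :class:`MSIDataset`, :class:`PeakTable`,
:class:`FeatureMatrix`), readers/writers for imzML and a plain NPZ fixture
dialect, total-ion-count (TIC) normalisation, dataset-wide peak finding on
the mean spectrum, and construction of the pixels x peaks feature matrix in
"maximal interval" mode (feature value = maximum intensity inside a fixed
m/z interval).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks, medfilt

__all__ = [
    "Spectrum",
    "MSIDataset",
    "PeakTable",
    "FeatureMatrix",
    "read_msi",
    "write_msi",
    "write_imzml",
    "tic_normalize",
    "mean_spectrum",
    "detect_peaks",
    "build_feature_matrix",
]

# Scale factor turning a median absolute deviation into a Gaussian-equivalent
# standard deviation.
MAD_TO_SD = 1.4826


@dataclass
class Spectrum:
    """A single mass spectrum: strictly increasing m/z, non-negative counts."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays")
        if len(self.mz) != len(self.intensity):
            raise ValueError(
                f"inconsistent array lengths: {len(self.mz)} m/z values vs "
                f"{len(self.intensity)} intensities"
            )
        if len(self.mz) and np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def tic(self) -> float:
        """Total ion count (sum of intensities)."""
        return float(self.intensity.sum())


@dataclass
class MSIDataset:
    """A pixel grid of spectra with physical coordinates.

    Parameters
    ----------
    coords
        ``(n_pixels, 2)`` integer array of ``(ix, iy)`` grid coordinates
        (0-based, y-down).
    spacing_um
        Raster pitch in µm (50 µm for the reference acquisition).
    spectra
        One :class:`Spectrum` per pixel, aligned with ``coords``.
    origin_um
        Physical offset of grid pixel ``(0, 0)`` in µm.
    metadata
        Free-form key/value metadata (instrument mode, mass range, flags).
    """

    coords: np.ndarray
    spacing_um: float
    spectra: list[Spectrum]
    origin_um: tuple[float, float] = (0.0, 0.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")
        if len(self.spectra) != len(self.coords):
            raise ValueError("every pixel must have a spectrum")
        uniq = {tuple(c) for c in self.coords}
        if len(uniq) != len(self.coords):
            raise ValueError("pixel coordinates must be unique")

    @property
    def n_pixels(self) -> int:
        return len(self.spectra)

    def tics(self) -> np.ndarray:
        return np.array([s.tic for s in self.spectra])

    def pixel_centers_um(self) -> np.ndarray:
        """Physical centers of the pixel footprints, shape (n, 2)."""
        return np.asarray(self.origin_um) + (self.coords + 0.5) * self.spacing_um

    def mass_range(self) -> tuple[float, float]:
        lo = min(s.mz[0] for s in self.spectra if len(s))
        hi = max(s.mz[-1] for s in self.spectra if len(s))
        return lo, hi


@dataclass
class PeakTable:
    """Aligned m/z intervals detected on the dataset mean spectrum.

    Intervals are stored as explicit ``[lo, hi]`` bounds because midpoint
    truncation of crowded peaks makes them asymmetric around their centers.
    """

    centers: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.lo = np.asarray(self.lo, dtype=float)
        self.hi = np.asarray(self.hi, dtype=float)
        if not (len(self.centers) == len(self.lo) == len(self.hi)):
            raise ValueError("centers/lo/hi length mismatch")
        if len(self.centers) > 1 and np.any(np.diff(self.centers) <= 0):
            raise ValueError("peak centers must be strictly increasing")
        if np.any(self.lo > self.centers) or np.any(self.hi < self.centers):
            raise ValueError("each interval must contain its center")
        if len(self.centers) > 1 and np.any(self.hi[:-1] > self.lo[1:]):
            raise ValueError("peak intervals must be pairwise disjoint")

    def __len__(self) -> int:
        return len(self.centers)

    @property
    def half_widths(self) -> np.ndarray:
        return (self.hi - self.lo) / 2.0

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"center_mz": self.centers, "lo_mz": self.lo, "hi_mz": self.hi}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PeakTable":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(df["center_mz"].values, df["lo_mz"].values, df["hi_mz"].values)


@dataclass
class FeatureMatrix:
    """Pixels x peaks matrix of maximal-interval feature intensities."""

    values: np.ndarray
    pixel_index: np.ndarray  # (n_pixels, 2) grid coords, row order
    peak_index: np.ndarray  # (n_peaks,) peak centers, column order
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.pixel_index = np.asarray(self.pixel_index, dtype=int)
        self.peak_index = np.asarray(self.peak_index, dtype=float)
        if self.values.shape != (len(self.pixel_index), len(self.peak_index)):
            raise ValueError("feature matrix shape inconsistent with indices")
        if np.any(self.values < 0):
            raise ValueError("feature intensities must be non-negative")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_msi(ds: MSIDataset, path: str | Path) -> None:
    """Write a dataset to the NPZ fixture dialect (bit-exact round trip).

    Ragged (processed-mode) spectra are stored as concatenated ``mz`` /
    ``intensity`` arrays plus per-pixel ``offsets``.
    """
    path = Path(path)
    mz = np.concatenate([s.mz for s in ds.spectra]) if ds.spectra else np.empty(0)
    inten = (
        np.concatenate([s.intensity for s in ds.spectra]) if ds.spectra else np.empty(0)
    )
    offsets = np.cumsum([0] + [len(s) for s in ds.spectra])
    np.savez(
        path,
        mz=mz,
        intensity=inten,
        offsets=offsets,
        coords=ds.coords,
        spacing_um=np.float64(ds.spacing_um),
        origin_um=np.asarray(ds.origin_um, dtype=float),
        metadata=np.bytes_(json.dumps(ds.metadata, sort_keys=True).encode()),
    )


def _read_fixture(path: Path) -> MSIDataset:
    with np.load(path) as z:
        required = {"mz", "intensity", "coords", "spacing_um"}
        missing = required - set(z.files)
        if missing:
            raise ValueError(f"fixture missing required field(s): {sorted(missing)}")
        mz, inten = z["mz"], z["intensity"]
        offsets = z["offsets"] if "offsets" in z.files else None
        coords = z["coords"]
        spacing = float(z["spacing_um"])
        origin = tuple(z["origin_um"]) if "origin_um" in z.files else (0.0, 0.0)
        meta = (
            json.loads(bytes(z["metadata"]).decode()) if "metadata" in z.files else {}
        )
    if offsets is None:
        # shared-axis layout: mz 1-D, intensity (n_pixels, n_mz)
        spectra = [Spectrum(mz, row) for row in np.atleast_2d(inten)]
    else:
        spectra = [
            Spectrum(mz[a:b], inten[a:b]) for a, b in zip(offsets[:-1], offsets[1:])
        ]
    return MSIDataset(coords, spacing, spectra, origin, meta)


def _read_imzml(path: Path, spacing_um: float | None) -> MSIDataset:
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    if spacing_um is None:
        spacing_um = parser.imzmldict.get("pixel size x")
        if spacing_um is None:
            raise ValueError(
                "imzML file carries no 'pixel size x' metadata; "
                "pass spacing_um explicitly"
            )
    coords = np.array([(c[0] - 1, c[1] - 1) for c in parser.coordinates], dtype=int)
    spectra = []
    for i in range(len(parser.coordinates)):
        mz, inten = parser.getspectrum(i)
        spectra.append(Spectrum(np.asarray(mz), np.asarray(inten)))
    meta = {"source": str(path), "format": "imzml"}
    return MSIDataset(coords, float(spacing_um), spectra, (0.0, 0.0), meta)


def read_msi(
    path: str | Path,
    format: str | None = None,
    spacing_um: float | None = None,
) -> MSIDataset:
    """Read an MSI datacube from imzML or from the NPZ fixture dialect.

    ``format`` is inferred from the file suffix when not given.  Continuous
    and processed mode imzML are both accepted; grid coordinates are taken
    from the file's (1-based) pixel indices and shifted to 0-based.
    """
    path = Path(path)
    if format is None:
        format = "imzml" if path.suffix.lower() == ".imzml" else "fixture"
    if format == "imzml":
        return _read_imzml(path, spacing_um)
    if format == "fixture":
        return _read_fixture(path)
    raise ValueError(f"unknown format {format!r}")


def write_imzml(ds: MSIDataset, path: str | Path) -> None:
    """Export to imzML 1.1 (processed mode, 1-based pixel indices)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    with ImzMLWriter(str(path), mode="processed", mz_dtype=np.float64,
                     intensity_dtype=np.float64) as w:
        for (ix, iy), s in zip(ds.coords, ds.spectra):
            w.addSpectrum(s.mz, s.intensity, (int(ix) + 1, int(iy) + 1, 1))


# ---------------------------------------------------------------------------
# Normalisation / peak finding / feature matrix
# ---------------------------------------------------------------------------


def tic_normalize(ds: MSIDataset) -> MSIDataset:
    """Scale each spectrum so its TIC equals the dataset mean TIC.

    The mean is taken over pixels with non-zero TIC; zero-TIC pixels are
    left untouched but recorded in ``metadata['excluded_pixels']`` so that
    downstream statistics can drop them.  Relative intensities within a
    spectrum are unchanged, and the operation is idempotent.
    """
    tics = ds.tics()
    included = tics > 0
    if not included.any():
        raise ValueError("all spectra have zero TIC; cannot normalize")
    target = tics[included].mean()
    spectra = []
    for s, t, ok in zip(ds.spectra, tics, included):
        if ok:
            spectra.append(Spectrum(s.mz.copy(), s.intensity * (target / t)))
        else:
            spectra.append(Spectrum(s.mz.copy(), s.intensity.copy()))
    meta = dict(ds.metadata)
    meta["tic_normalized"] = True
    meta["excluded_pixels"] = [int(i) for i in np.flatnonzero(~included)]
    return MSIDataset(ds.coords.copy(), ds.spacing_um, spectra, ds.origin_um, meta)


def mean_spectrum(
    ds: MSIDataset,
    grid_da: float = 0.1,
    mz_range: tuple[float, float] | None = None,
) -> Spectrum:
    """Dataset mean spectrum on a common m/z grid.

    Each bin holds the across-pixel mean of the per-pixel maximum intensity
    inside the bin; pixels with no data point in a bin contribute zero.
    """
    if grid_da <= 0:
        raise ValueError("grid_da must be positive")
    if ds.n_pixels == 0:
        raise ValueError("empty dataset")
    if mz_range is None:
        mz_range = ds.mass_range()
    lo, hi = mz_range
    n_bins = max(1, int(np.ceil((hi - lo) / grid_da - 1e-9)))
    sums = np.zeros(n_bins)
    buf = np.empty(n_bins)
    for s in ds.spectra:
        idx = np.floor((s.mz - lo) / grid_da).astype(int)
        ok = (idx >= 0) & (idx < n_bins)
        buf[:] = 0.0
        np.maximum.at(buf, idx[ok], s.intensity[ok])
        sums += buf
    centers = lo + (np.arange(n_bins) + 0.5) * grid_da
    return Spectrum(centers, sums / ds.n_pixels)


def detect_peaks(
    mean: Spectrum,
    snr_min: float = 3.0,
    half_width_da: float = 0.4,
    noise_mode: str = "medium",
) -> PeakTable:
    """Detect peaks on the mean spectrum and define aligned m/z intervals.

    Noise is estimated as ``1.4826 x MAD`` of the (filtered) mean spectrum;
    local maxima with intensity >= ``snr_min x noise`` become peaks.
    ``noise_mode='medium'`` applies a 3-bin median filter before maxima
    detection, ``'none'`` applies no filtering.  Each peak gets a
    ``+-half_width_da`` interval; overlapping intervals are truncated at the
    midpoint between adjacent centers so the table is pairwise disjoint.
    """
    if len(mean) == 0:
        raise ValueError("empty spectrum")
    if noise_mode not in ("none", "medium"):
        raise ValueError(f"unknown noise_mode {noise_mode!r}")
    y = mean.intensity
    if noise_mode == "medium" and len(y) >= 3:
        y = medfilt(y, kernel_size=3)
    noise = MAD_TO_SD * np.median(np.abs(y - np.median(y)))
    height = snr_min * noise if noise > 0 else np.finfo(float).tiny
    idx, _ = find_peaks(y, height=height)
    centers = mean.mz[idx]
    lo = centers - half_width_da
    hi = centers + half_width_da
    if len(centers) > 1:
        mid = (centers[:-1] + centers[1:]) / 2.0
        hi[:-1] = np.minimum(hi[:-1], mid)
        lo[1:] = np.maximum(lo[1:], mid)
    return PeakTable(
        centers,
        lo,
        hi,
        provenance={
            "snr_min": snr_min,
            "half_width_da": half_width_da,
            "noise_mode": noise_mode,
            "noise": float(noise),
        },
    )


def build_feature_matrix(ds: MSIDataset, peaks: PeakTable) -> FeatureMatrix:
    """Maximal-interval feature matrix: entry (p, k) is the maximum intensity
    of pixel p's spectrum inside closed interval k, or 0 if no data point
    falls inside."""
    if len(peaks) == 0:
        raise ValueError("empty PeakTable")
    values = np.zeros((ds.n_pixels, len(peaks)))
    for p, s in enumerate(ds.spectra):
        i0 = np.searchsorted(s.mz, peaks.lo, side="left")
        i1 = np.searchsorted(s.mz, peaks.hi, side="right")
        # pad so reduceat may index one past the end of the data
        padded = np.append(s.intensity, 0.0)
        segs = np.column_stack([i0, np.maximum(i1, i0 + 1)]).ravel()
        row = np.maximum.reduceat(padded, np.minimum(segs, len(s.intensity)))[::2]
        row[i1 <= i0] = 0.0  # interval holds no data point
        values[p] = row
    return FeatureMatrix(
        values,
        ds.coords.copy(),
        peaks.centers.copy(),
        normalized=bool(ds.metadata.get("tic_normalized", False)),
    )
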