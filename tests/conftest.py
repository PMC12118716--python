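"""Shared fixtures: small synthetic datasets reused across the suite."""

import numpy as np
import pytest

from msic import (
    build_feature_matrix,
    default_phantom_spec,
    detect_peaks,
    mean_spectrum,
    tic_normalize,
)
from msic.msi_core import MSIDataset, Spectrum
from msic import synthetic as syn


def make_random_processed_dataset(seed: int, n_pixels: int = 6, n_points: int = 40):
    """A tiny ragged (processed-mode) dataset with positive TICs."""
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_pixels)))
    coords = np.array([(i % side, i // side) for i in range(n_pixels)])
    spectra = []
    for _ in range(n_pixels):
        k = int(rng.integers(n_points // 2, n_points))
        mz = np.sort(rng.uniform(800, 3200, k))
        mz = np.unique(mz)
        spectra.append(Spectrum(mz, rng.uniform(0.1, 50, len(mz))))
    return MSIDataset(coords, 50.0, spectra)


@pytest.fixture(scope="session")
def phantom_spec():
    """Default crossed phantom at 2 µm/px rendering scale."""
    return default_phantom_spec(seed=1, image_um_per_px=2.0)


@pytest.fixture(scope="session")
def phantom_msi(phantom_spec):
    """(raw dataset, manifest) of the default phantom's MSI modality."""
    return syn.make_msi(phantom_spec)


@pytest.fixture(scope="session")
def phantom_features(phantom_msi):
    """TIC-normalised dataset, detected peaks and feature matrix."""
    ds_raw, manifest = phantom_msi
    ds = tic_normalize(ds_raw)
    mean = mean_spectrum(ds, 0.1, (800.0, 3200.0))
    peaks = detect_peaks(mean)
    fm = build_feature_matrix(ds, peaks)
    return ds, peaks, fm, manifest
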