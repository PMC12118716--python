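"""Co-registered multimodal phantoms for end-to-end testing.

Real acquisitions of this kind (patient tissue sections imaged by 2PLSM,
MALDI-MSI and H&E in series) are not redistributable, so every pipeline
stage is exercised on synthetic phantoms that share one physical frame:

* an SHG-like fibre image rendered from line segments whose orientations
  follow a wrapped normal with region-specific dispersion (dispersion -> 0
  gives aligned/"organised" texture, large dispersion gives "chaotic");
* an inhomogeneous Poisson nuclei point pattern with region-wise intensity;
* an MSI datacube (processed-mode spectra, 800-3200 m/z, 50 µm raster) with
  Gaussian peptide peaks whose amplitudes carry planted between-class
  effects expressed in units of the within-class SD, log-normal pixel TIC
  variation and additive spectral noise;
* a peptide identification table with >= 2 near-peak peptides per "real"
  protein and decoy peptides more than 0.15 Da from every peak;
* region polygons in QuPath-style GeoJSON.

Everything is driven by a single :class:`PhantomSpec` and a single RNG
seed; identical spec + seed reproduces identical fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Polygon, box, mapping
from scipy import ndimage as ndi
from skimage.draw import line as draw_line

from .fibre_coherence import IntensityImage
from .msi_core import MSIDataset, Spectrum, write_msi
from .nuclei_density import NucleiSet
from .discriminative import PeptideRecord, write_peptide_table

__all__ = [
    "RegionSpec",
    "PhantomSpec",
    "default_phantom_spec",
    "make_shg",
    "make_nuclei",
    "make_msi",
    "make_peptide_table",
    "region_ids_at",
    "regions_geojson",
    "write_phantom",
]

#: Fibre orientation dispersion (rad) at or above which a region is rendered
#: with fully uniform orientations.
UNIFORM_DISPERSION = np.pi

_PROTEIN_NAMES = [
    ("P1001", "plectin"),
    ("P1002", "vinculin"),
    ("P1003", "vimentin"),
    ("P1004", "myosin-9"),
    ("P1005", "talin-1"),
    ("P1006", "alpha-enolase"),
    ("P1007", "collagen alpha-2(I) chain"),
    ("P1008", "prelamin-A/C"),
]
_AA = np.array(list("ACDEFGHILMNPQSTVWY"))


@dataclass
class RegionSpec:
    """One labelled tissue region with its generative parameters."""

    name: str
    polygon: Polygon
    group: str = "LSCC"
    fibre_dispersion: float = 0.1  # rad; >= UNIFORM_DISPERSION -> uniform
    fibre_angle: float = 0.0  # mean orientation (rad)
    nuclei_per_mm2: float = 500.0
    coherence_truth: str = "organised"
    density_truth: str = "LND"


@dataclass
class PhantomSpec:
    """Study-condition parameters shared by all modalities of one phantom."""

    regions: list[RegionSpec]
    extent_um: tuple[float, float] = (2000.0, 2000.0)
    msi_spacing_um: float = 50.0
    image_um_per_px: float = 0.38
    mz_range: tuple[float, float] = (800.0, 3200.0)
    n_peaks: int = 50
    n_planted: int = 10
    effect_size_sd: float = 1.5  # planted shift in within-class SD units
    plant_on: str = "group"  # attribute carrying the effect
    plant_positive: str = "RSCC"  # class whose mean is shifted
    sigma_mz: float = 0.2  # Da, Gaussian peak width
    amp_cv: float = 0.25  # within-class amplitude CV
    tic_cv: float = 0.2  # log-normal TIC factor SD
    noise_sd: float = 1.0  # additive spectral noise scale
    n_noise_points: int = 250  # dataset-level chemical-noise positions
    noise_jitter_da: float = 0.02  # per-pixel m/z jitter of noise positions
    seed: int = 0

    def __post_init__(self) -> None:
        if self.msi_spacing_um <= 0 or self.image_um_per_px <= 0:
            raise ValueError("spacing and resolution must be positive")
        ext = box(0, 0, *self.extent_um)
        for r in self.regions:
            if not r.polygon.within(ext.buffer(1e-6)):
                raise ValueError(f"region {r.name!r} extends outside the extent")
        if not (0 <= self.n_planted <= self.n_peaks):
            raise ValueError("n_planted must be within [0, n_peaks]")
        if not np.isfinite(self.effect_size_sd):
            raise ValueError("effect size must be finite")


def default_phantom_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """The default crossed phantom: 40 x 40 MSI pixels over 2 x 2 mm.

    The x halves carry the two patient groups (LSCC left, RSCC right); the
    y quarters cross the collagen classes (chaotic / organised) with the
    nuclei classes (LND at 250 nuclei/mm², HND at 2500 nuclei/mm²), giving
    the 2 x 2 x 2 layout every comparison pair needs.
    """
    w, h = overrides.pop("extent_um", (2000.0, 2000.0))
    regions = []
    coh = [("chaotic", UNIFORM_DISPERSION), ("organised", 0.06)]
    den = [("LND", 250.0), ("HND", 2500.0)]
    for gx, group in enumerate(["LSCC", "RSCC"]):
        for qy in range(4):
            cname, disp = coh[qy // 2]
            dname, rate = den[qy % 2]
            poly = box(gx * w / 2, qy * h / 4, (gx + 1) * w / 2, (qy + 1) * h / 4)
            regions.append(
                RegionSpec(
                    name=f"{group}_{cname}_{dname}",
                    polygon=poly,
                    group=group,
                    fibre_dispersion=disp,
                    fibre_angle=0.35,
                    nuclei_per_mm2=rate,
                    coherence_truth=cname,
                    density_truth=dname,
                )
            )
    return PhantomSpec(regions=regions, extent_um=(w, h), seed=seed, **overrides)


# ---------------------------------------------------------------------------
# shared-frame helpers
# ---------------------------------------------------------------------------


def region_ids_at(spec: PhantomSpec, points: np.ndarray) -> np.ndarray:
    """Region index (first covering region, -1 if none) per (x, y) µm point."""
    pts = shapely.points(points[:, 0], points[:, 1])
    out = np.full(len(pts), -1, dtype=int)
    for i, r in enumerate(spec.regions):
        hit = (out < 0) & shapely.covers(r.polygon, pts)
        out[hit] = i
    return out


def _image_region_ids(spec: PhantomSpec, um_per_px: float) -> np.ndarray:
    w, h = spec.extent_um
    nx = int(round(w / um_per_px))
    ny = int(round(h / um_per_px))
    out = np.empty((ny, nx), dtype=int)
    chunk = max(1, int(2e6 / max(nx, 1)))
    for r0 in range(0, ny, chunk):
        r1 = min(ny, r0 + chunk)
        rows, cols = np.mgrid[r0:r1, 0:nx]
        pts = np.column_stack(
            [(cols.ravel() + 0.5) * um_per_px, (rows.ravel() + 0.5) * um_per_px]
        )
        out[r0:r1] = region_ids_at(spec, pts).reshape(r1 - r0, nx)
    return out


# ---------------------------------------------------------------------------
# SHG fibre image
# ---------------------------------------------------------------------------


def make_shg(
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
    um_per_px: float | None = None,
    fibre_length_um: float = 80.0,
    fibre_spacing_um: float = 3.0,
    fibre_intensity: float = 200.0,
    background_sd: float = 2.0,
) -> tuple[IntensityImage, dict[str, str]]:
    """Render the SHG fibre phantom.

    Per region, fibres are line segments of fixed length whose orientations
    are drawn from a wrapped normal around the region's mean angle with the
    region's dispersion (dispersion >= pi gives uniform orientations).
    Fibres are clipped to their region, blurred to ~2 px width, and low
    additive background noise is added so Otsu finds a clean foreground.

    Returns the image and the intended coherence class per region name.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    upp = spec.image_um_per_px if um_per_px is None else um_per_px
    rid = _image_region_ids(spec, upp)
    ny, nx = rid.shape
    img = np.zeros((ny, nx))
    L = fibre_length_um / upp
    for i, r in enumerate(spec.regions):
        mask = rid == i
        if not mask.any():
            continue
        n_fibres = max(1, int(r.polygon.area / (fibre_length_um * fibre_spacing_um)))
        minx, miny, maxx, maxy = r.polygon.bounds
        cx = rng.uniform(minx, maxx, n_fibres) / upp
        cy = rng.uniform(miny, maxy, n_fibres) / upp
        if r.fibre_dispersion >= UNIFORM_DISPERSION:
            theta = rng.uniform(0.0, np.pi, n_fibres)
        else:
            theta = np.mod(r.fibre_angle + rng.normal(0, r.fibre_dispersion, n_fibres), np.pi)
        canvas = np.zeros_like(img)
        dx, dy = 0.5 * L * np.cos(theta), 0.5 * L * np.sin(theta)
        x0 = np.clip(cx - dx, 0, nx - 1).astype(int)
        x1 = np.clip(cx + dx, 0, nx - 1).astype(int)
        y0 = np.clip(cy - dy, 0, ny - 1).astype(int)
        y1 = np.clip(cy + dy, 0, ny - 1).astype(int)
        for k in range(n_fibres):
            rr, cc = draw_line(y0[k], x0[k], y1[k], x1[k])
            canvas[rr, cc] += 1.0
        img += canvas * mask
    img = ndi.gaussian_filter(img, 1.0) * fibre_intensity
    img += np.abs(rng.normal(0.0, background_sd, img.shape))
    truth = {r.name: r.coherence_truth for r in spec.regions}
    return IntensityImage(img, upp), truth


# ---------------------------------------------------------------------------
# nuclei point pattern
# ---------------------------------------------------------------------------


def make_nuclei(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> tuple[NucleiSet, dict[str, str]]:
    """Inhomogeneous Poisson nuclei with region-wise intensity.

    Ground-truth density class per region is taken from the region's
    intensity relative to the midpoint of the phantom's min/max intensity.
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    if any(r.nuclei_per_mm2 < 0 for r in spec.regions):
        raise ValueError("nuclei intensities must be non-negative")
    pts = []
    for r in spec.regions:
        area_mm2 = r.polygon.area / 1e6
        n = rng.poisson(r.nuclei_per_mm2 * area_mm2)
        got = 0
        minx, miny, maxx, maxy = r.polygon.bounds
        while got < n:
            m = max(32, 2 * (n - got))
            cand = np.column_stack(
                [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
            )
            ok = shapely.covers(r.polygon, shapely.points(cand[:, 0], cand[:, 1]))
            take = cand[ok][: n - got]
            pts.append(take)
            got += len(take)
    centroids = np.vstack(pts) if pts else np.empty((0, 2))
    rates = [r.nuclei_per_mm2 for r in spec.regions]
    mid = (min(rates) + max(rates)) / 2.0
    truth = {
        r.name: ("HND" if r.nuclei_per_mm2 >= mid else "LND") for r in spec.regions
    }
    return NucleiSet(centroids, spec.extent_um), truth


# ---------------------------------------------------------------------------
# MSI datacube
# ---------------------------------------------------------------------------


def _pixel_attribute(spec: PhantomSpec, region_idx: np.ndarray, attr: str) -> np.ndarray:
    fields = {
        "group": lambda r: r.group,
        "coherence": lambda r: r.coherence_truth,
        "density": lambda r: r.density_truth,
    }
    get = fields[attr]
    vals = np.array([get(r) for r in spec.regions] + ["none"], dtype=object)
    return vals[region_idx]


def make_msi(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> tuple[MSIDataset, dict]:
    """Generate the MSI datacube plus a planted-marker manifest.

    Each pixel spectrum is a processed-mode point list: 13 grid points per
    peptide peak (Gaussian profile, sigma ``sigma_mz``) plus a dataset-wide
    comb of chemical-noise positions (shared across pixels up to a small
    per-pixel m/z jitter, emulating matrix-cluster noise) carrying
    half-normal intensities.  Everything is multiplied by a log-normal
    per-pixel TIC factor.  Planted peaks shift the amplitude mean of the
    positive class by ``effect_size_sd`` within-class SDs.
    """
    rng = np.random.default_rng(spec.seed + 2) if rng is None else rng
    w, h = spec.extent_um
    nx = int(round(w / spec.msi_spacing_um))
    ny = int(round(h / spec.msi_spacing_um))
    coords = np.array([(ix, iy) for iy in range(ny) for ix in range(nx)], dtype=int)
    centers = (coords + 0.5) * spec.msi_spacing_um
    region_idx = region_ids_at(spec, centers)
    attr = _pixel_attribute(spec, region_idx, spec.plant_on)
    positive = attr == spec.plant_positive

    lo, hi = spec.mz_range
    # peak centers with a minimum 5 Da separation
    peak_centers: list[float] = []
    while len(peak_centers) < spec.n_peaks:
        c = rng.uniform(lo + 50, hi - 50)
        if all(abs(c - p) > 5.0 for p in peak_centers):
            peak_centers.append(c)
    peak_centers = np.sort(np.array(peak_centers))
    planted = np.zeros(spec.n_peaks, dtype=bool)
    planted[rng.choice(spec.n_peaks, spec.n_planted, replace=False)] = True
    direction = np.zeros(spec.n_peaks, dtype=int)
    direction[planted] = rng.choice([-1, 1], int(planted.sum()))

    mu = rng.uniform(10.0, 60.0, spec.n_peaks)
    sd = spec.amp_cv * mu
    mean = np.tile(mu, (len(coords), 1))
    mean[positive] += direction * spec.effect_size_sd * sd
    amp = np.clip(rng.normal(mean, sd), 0.0, None)

    # sample each Gaussian profile at sigma/2 out to +-3 sigma (13 points),
    # finer than any sensible analysis bin width
    offsets = np.arange(-6, 7) * (spec.sigma_mz / 2.0)
    profile = np.exp(-0.5 * (offsets / spec.sigma_mz) ** 2)
    peak_mz = (peak_centers[:, None] + offsets[None, :]).ravel()

    spectra = []
    n_noise = spec.n_noise_points
    noise_comb = rng.uniform(lo, hi, n_noise)
    for p in range(len(coords)):
        tic_factor = float(np.exp(rng.normal(0.0, spec.tic_cv)))
        mz_noise = noise_comb + rng.normal(0.0, spec.noise_jitter_da, n_noise)
        i_noise = np.abs(rng.normal(0.0, spec.noise_sd, n_noise))
        mz_all = np.concatenate([peak_mz, mz_noise])
        i_all = np.concatenate([(amp[p][:, None] * profile).ravel(), i_noise])
        order = np.argsort(mz_all, kind="stable")
        mz_all, i_all = mz_all[order], i_all[order]
        # merge (vanishingly rare) duplicate m/z positions
        uniq, inv = np.unique(mz_all, return_inverse=True)
        if len(uniq) < len(mz_all):
            merged = np.zeros(len(uniq))
            np.add.at(merged, inv, i_all)
            mz_all, i_all = uniq, merged
        spectra.append(Spectrum(mz_all, i_all * tic_factor))

    ds = MSIDataset(
        coords,
        spec.msi_spacing_um,
        spectra,
        (0.0, 0.0),
        {"mass_range": list(spec.mz_range), "mode": "processed", "synthetic": True},
    )
    manifest = {
        "peak_centers": peak_centers.tolist(),
        "planted": planted.tolist(),
        "direction": direction.tolist(),
        "effect_size_sd": spec.effect_size_sd,
        "plant_on": spec.plant_on,
        "plant_positive": spec.plant_positive,
        "region_index": region_idx.tolist(),
        "region_names": [r.name for r in spec.regions],
        "group": _pixel_attribute(spec, region_idx, "group").tolist(),
        "coherence_truth": _pixel_attribute(spec, region_idx, "coherence").tolist(),
        "density_truth": _pixel_attribute(spec, region_idx, "density").tolist(),
    }
    return ds, manifest


# ---------------------------------------------------------------------------
# peptide table
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator) -> str:
    n = int(rng.integers(8, 16))
    body = "".join(rng.choice(_AA, n))
    return body + str(rng.choice(["K", "R"]))


def make_peptide_table(
    spec: PhantomSpec,
    manifest: dict,
    rng: np.random.Generator | None = None,
    n_proteins: int = 6,
    n_decoy_proteins: int = 4,
    peptides_per_protein: int = 2,
) -> tuple[list[PeptideRecord], dict]:
    """Build the LC-MS/MS-style peptide table matched to the phantom peaks.

    "Real" proteins each get ``peptides_per_protein`` peptides within
    0.05 Da of distinct planted-first peak centers, so the >= 2 peptide /
    >= 2 peak identification rule can fire; decoy proteins only get
    peptides more than 0.15 Da away from every peak.  Scores are uniform
    in [20, 80].
    """
    rng = np.random.default_rng(spec.seed + 3) if rng is None else rng
    centers = np.array(manifest["peak_centers"])
    planted = np.array(manifest["planted"], dtype=bool)
    order = np.concatenate([np.flatnonzero(planted), np.flatnonzero(~planted)])
    need = n_proteins * peptides_per_protein
    if need > len(centers):
        raise ValueError("not enough peaks for the requested protein count")
    records: list[PeptideRecord] = []
    names = (_PROTEIN_NAMES * ((n_proteins // len(_PROTEIN_NAMES)) + 1))[:n_proteins]
    for i, (acc, name) in enumerate(names):
        for j in range(peptides_per_protein):
            c = centers[order[i * peptides_per_protein + j]]
            records.append(
                PeptideRecord(
                    _random_sequence(rng),
                    float(c + rng.uniform(-0.05, 0.05)),
                    acc,
                    name,
                    float(rng.uniform(20, 80)),
                )
            )
    lo, hi = spec.mz_range
    for i in range(n_decoy_proteins):
        acc = f"DEC{i + 1:03d}"
        for _ in range(peptides_per_protein):
            while True:
                m = rng.uniform(lo + 50, hi - 50)
                if np.min(np.abs(centers - m)) > 0.2:
                    break
            records.append(
                PeptideRecord(
                    _random_sequence(rng), float(m), acc, f"decoy-{i + 1}",
                    float(rng.uniform(20, 80)),
                )
            )
    truth = {
        "identifiable": [acc for acc, _ in names],
        "decoys": [f"DEC{i + 1:03d}" for i in range(n_decoy_proteins)],
    }
    return records, truth


# ---------------------------------------------------------------------------
# GeoJSON + bundle writer
# ---------------------------------------------------------------------------


def regions_geojson(spec: PhantomSpec, annotation_class: str = "tumour") -> dict:
    """Region polygons as a QuPath-dialect FeatureCollection."""
    features = []
    for r in spec.regions:
        features.append(
            {
                "type": "Feature",
                "id": r.name,
                "geometry": mapping(r.polygon),
                "properties": {
                    "classification": {"name": annotation_class},
                    "name": r.name,
                    "group": r.group,
                    "coherence_truth": r.coherence_truth,
                    "density_truth": r.density_truth,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_phantom(spec: PhantomSpec, outdir: str | Path) -> dict:
    """Generate every modality of the phantom and write the fixture bundle.

    Writes ``shg.tif``, ``nuclei.csv``, ``msi.npz``, ``regions.geojson``,
    ``peptides.tsv`` and ``manifest.json`` (ground truth) into ``outdir``;
    returns the manifest.
    """
    import pandas as pd
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    img, coh_truth = make_shg(spec)
    nuclei, den_truth = make_nuclei(spec)
    ds, manifest = make_msi(spec)
    peptides, pep_truth = make_peptide_table(spec, manifest)

    tifffile.imwrite(str(outdir / "shg.tif"), img.values.astype(np.float32))
    pd.DataFrame(nuclei.centroids, columns=["x_um", "y_um"]).to_csv(
        outdir / "nuclei.csv", index=False
    )
    write_msi(ds, outdir / "msi.npz")
    (outdir / "regions.geojson").write_text(json.dumps(regions_geojson(spec)))
    write_peptide_table(peptides, outdir / "peptides.tsv")
    manifest = dict(
        manifest,
        coherence_truth_by_region=coh_truth,
        density_truth_by_region=den_truth,
        peptide_truth=pep_truth,
        image_um_per_px=spec.image_um_per_px,
        extent_um=list(spec.extent_um),
        seed=spec.seed,
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
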