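"""End-to-end orchestration of the correlative workflow.

One run executes: SHG coherence heatmap -> nuclei density heatmap ->
co-registration of both (plus annotations) onto the MSI grid -> TIC
normalisation, peak finding and feature-matrix construction -> per-m/z ROC
for every comparison pair (group vs group over the whole tumour, HND vs
LND, and group-vs-group within the HND / chaotic / organised strata) ->
protein assignment -> PCA -> bisecting k-means segmentation with per-class
composition tables -> two-way ANOVA of percent areas across simulated
samples.  Every output table carries the configuration hash in a leading
``#`` comment line, so reruns are verifiably reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import discriminative as da
from . import fibre_coherence as fc
from . import msi_core as mc
from . import nuclei_density as nd
from . import region_maps as rm
from . import segmentation as sg
from . import synthetic as syn

__all__ = ["RunConfig", "run_pipeline", "COMPARISON_PAIRS", "simulate_percent_area_table"]

logger = logging.getLogger(__name__)

#: The comparison pairs of the reference analysis:
#: (name, attribute, class_a, class_b, stratum or None).
COMPARISON_PAIRS = [
    ("LSCC_vs_RSCC", "group", "LSCC", "RSCC", None),
    ("HND_vs_LND", "density_class", "HND", "LND", None),
    ("HND_LSCC_vs_HND_RSCC", "group", "LSCC", "RSCC", ("density_class", "HND")),
    ("chaotic_LSCC_vs_chaotic_RSCC", "group", "LSCC", "RSCC", ("coherence_class", "chaotic")),
    ("organised_LSCC_vs_organised_RSCC", "group", "LSCC", "RSCC", ("coherence_class", "organised")),
]

_COH_NAMES = {fc.CLASS_BACKGROUND: "background", fc.CLASS_CHAOTIC: "chaotic",
              fc.CLASS_ORGANISED: "organised"}
_DEN_NAMES = {0: "background", nd.CLASS_LND: "LND", nd.CLASS_HND: "HND"}


@dataclass
class RunConfig:
    """All parameters of one pipeline run, with the documented defaults.

    The named constants mirror the reference workflow: 0.5 heatmap class
    cut, AUC 0.6 / 0.4 with p < 0.01 for marker selection, 0.15 Da protein
    mass tolerance, 50 µm MSI raster (carried by the dataset/phantom).
    """

    out_dir: str | Path = "msic_run"
    seed: int = 0
    phantom: syn.PhantomSpec | None = None  # None -> default crossed phantom
    # coherence
    sigma_g: float = 2.0
    sigma_w: float = 8.0
    # density
    tile_um: float = 100.0
    smooth: bool = True
    # peak finding
    grid_da: float = 0.1
    snr_min: float = 3.0
    half_width_da: float = 0.4
    noise_mode: str = "medium"
    # selection
    auc_hi: float = da.AUC_HI_DEFAULT
    auc_lo: float = da.AUC_LO_DEFAULT
    p_max: float = da.P_MAX_DEFAULT
    mass_tol_da: float = da.MASS_TOL_DEFAULT
    # segmentation
    K: int = 5
    metric: str = "correlation"
    # percent-area ANOVA across simulated samples per group
    n_samples_per_group: int = 7

    def __post_init__(self) -> None:
        if not (0.5 < self.auc_hi <= 1.0):
            raise ValueError("auc_hi must exceed 0.5 (and auc_lo)")
        if not (0.0 <= self.auc_lo < 0.5):
            raise ValueError("auc_lo must be below 0.5")
        if not (0.0 < self.p_max <= 1.0):
            raise ValueError("p_max must lie in (0, 1]")
        if not (self.sigma_w >= self.sigma_g > 0):
            raise ValueError("require sigma_w >= sigma_g > 0")
        if self.tile_um <= 0 or self.grid_da <= 0 or self.half_width_da <= 0:
            raise ValueError("tile_um, grid_da and half_width_da must be positive")
        if self.K < 1:
            raise ValueError("K must be >= 1")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["out_dir"] = None  # the output location does not change the result
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, cfg_hash: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def simulate_percent_area_table(
    cfg: RunConfig, attribute: str = "coherence"
) -> pd.DataFrame:
    """Per-sample percent areas for the two-way ANOVA stage.

    Each "sample" is an independent small single-group phantom (1 x 1 mm at
    2 µm/px) whose chaotic-stripe height is jittered across samples, run
    through the full heatmap -> classification -> percent-area path.
    Returns rows of (sample, group, region_class, percent).
    """
    rows = []
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 77]))
    for gi, group in enumerate(["LSCC", "RSCC"]):
        for s in range(cfg.n_samples_per_group):
            frac = float(np.clip(rng.normal(0.60, 0.05), 0.35, 0.85))
            w = h = 1000.0
            from shapely.geometry import box

            regions = [
                syn.RegionSpec(
                    "chaotic_part", box(0, 0, w, h * frac), group,
                    fibre_dispersion=syn.UNIFORM_DISPERSION,
                    nuclei_per_mm2=2500.0, coherence_truth="chaotic",
                    density_truth="HND",
                ),
                syn.RegionSpec(
                    "organised_part", box(0, h * frac, w, h), group,
                    fibre_dispersion=0.06, fibre_angle=0.35,
                    nuclei_per_mm2=250.0, coherence_truth="organised",
                    density_truth="LND",
                ),
            ]
            spec = syn.PhantomSpec(
                regions=regions, extent_um=(w, h), image_um_per_px=2.0,
                seed=int(rng.integers(2**31)),
            )
            sample = f"{group}_{s}"
            if attribute == "coherence":
                img, _ = syn.make_shg(spec)
                cm = fc.coherence_map(img, cfg.sigma_g, cfg.sigma_w)
                classes = fc.classify_coherence(cm)
                n_fg = int((classes > 0).sum())
                for cid, cname in ((fc.CLASS_CHAOTIC, "chaotic"),
                                   (fc.CLASS_ORGANISED, "organised")):
                    rows.append(
                        dict(sample=sample, group=group, region_class=cname,
                             percent=100.0 * float((classes == cid).sum()) / n_fg)
                    )
            else:
                nuclei, _ = syn.make_nuclei(spec)
                dm = nd.density_map(nuclei, cfg.tile_um, cfg.smooth)
                classes = nd.classify_density(dm)
                n = classes.size
                for cid, cname in ((nd.CLASS_HND, "HND"), (nd.CLASS_LND, "LND")):
                    rows.append(
                        dict(sample=sample, group=group, region_class=cname,
                             percent=100.0 * float((classes == cid).sum()) / n)
                    )
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow; returns the result bundle and writes the
    report tables.  Any stage failure aborts with the stage name."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("msic")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    result: dict = {"config_hash": cfg_hash}

    def stage(name):
        logger.info("stage %s", name)

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, et, ev, tb):
                if et is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {ev}") from ev

        return _Ctx()

    spec = cfg.phantom or syn.default_phantom_spec(seed=cfg.seed, image_um_per_px=2.0)

    with stage("synthesis"):
        img, _ = syn.make_shg(spec)
        nuclei, _ = syn.make_nuclei(spec)
        ds_raw, manifest = syn.make_msi(spec)
        peptides, _ = syn.make_peptide_table(spec, manifest)
        (out / "regions.geojson").write_text(json.dumps(syn.regions_geojson(spec)))

    with stage("coherence"):
        cm = fc.coherence_map(img, cfg.sigma_g, cfg.sigma_w)
        coh_classes_img = fc.classify_coherence(cm)

    with stage("density"):
        dm = nd.density_map(nuclei, cfg.tile_um, cfg.smooth)
        den_classes_tiles = nd.classify_density(dm)

    with stage("coregistration"):
        coh_msi = rm.resample_to_msi(
            coh_classes_img, cm.um_per_px, ds_raw, rule="majority"
        )
        den_msi = rm.resample_to_msi(
            den_classes_tiles, dm.tile_um, ds_raw, rule="majority"
        )
        annotation = rm.import_annotations(out / "regions.geojson", ds_raw)
        labels = rm.build_region_labels(
            ds_raw,
            group=np.array(manifest["group"], dtype=object),
            coherence_class=np.array([_COH_NAMES[c] for c in coh_msi], dtype=object),
            density_class=np.array([_DEN_NAMES[c] for c in den_msi], dtype=object),
            annotation=annotation,
        )
        rm.write_region_labels(labels, out / "region_labels.tsv")

    with stage("msi_features"):
        ds = mc.tic_normalize(ds_raw)
        mean = mc.mean_spectrum(ds, cfg.grid_da, spec.mz_range)
        peaks = mc.detect_peaks(mean, cfg.snr_min, cfg.half_width_da, cfg.noise_mode)
        fm = mc.build_feature_matrix(ds, peaks)
        peaks.to_tsv(out / "peaks.tsv")
    result.update(n_peaks=len(peaks), n_pixels=ds.n_pixels)

    with stage("roc"):
        roc_results = {}
        for name, attribute, a, b, stratum in COMPARISON_PAIRS:
            sub = labels
            fmx = fm
            if stratum is not None:
                keep = (labels[stratum[0]] == stratum[1]).values
                sub = labels[keep].reset_index(drop=True)
                fmx = mc.FeatureMatrix(
                    fm.values[keep], fm.pixel_index[keep], fm.peak_index, fm.normalized
                )
            rocs = da.roc_per_peak(fmx, sub, a, b, attribute=attribute)
            da.select_candidates(rocs, cfg.auc_hi, cfg.auc_lo, cfg.p_max)
            roc_results[name] = rocs
            _write_table(da.roc_table(rocs), out / f"roc_{name}.tsv", cfg_hash)
    result["roc"] = roc_results

    main_rocs = roc_results["LSCC_vs_RSCC"]
    sel_idx = [r.peak_id for r in main_rocs if r.selected]
    result["n_selected_main"] = len(sel_idx)

    with stage("protein_assignment"):
        sel_peaks = mc.PeakTable(
            peaks.centers[sel_idx], peaks.lo[sel_idx], peaks.hi[sel_idx]
        ) if sel_idx else peaks
        matches, proteins = da.assign_proteins(sel_peaks, peptides, cfg.mass_tol_da)
        _write_table(matches, out / "peptide_matches.tsv", cfg_hash)
        _write_table(proteins, out / "proteins.tsv", cfg_hash)
    result["proteins"] = proteins

    with stage("pca"):
        if len(sel_idx) >= 2:
            pca = da.pca_on_candidates(fm.values[:, sel_idx])
            _write_table(
                pd.DataFrame({"component": np.arange(1, len(pca.explained_variance_ratio) + 1),
                              "explained_variance_ratio": pca.explained_variance_ratio}),
                out / "pca_evr.tsv", cfg_hash,
            )
            result["pca"] = pca

    with stage("segmentation"):
        feats = fm.values[:, sel_idx] if len(sel_idx) >= 2 else fm.values
        seg = sg.bisecting_kmeans(feats, cfg.K, cfg.seed, cfg.metric)
        seg_df = pd.DataFrame(
            {"ix": ds.coords[:, 0], "iy": ds.coords[:, 1], "segment": seg.labels}
        )
        _write_table(seg_df, out / "segments.tsv", cfg_hash)
        (out / "split_tree.json").write_text(seg.tree_json())
        for attr in ("group", "coherence_class", "density_class"):
            comp = sg.segment_composition(seg, labels, attr)
            _write_table(comp, out / f"composition_{attr}.tsv", cfg_hash, index=True)
    result["segmentation"] = seg

    with stage("percent_areas"):
        pa_rows = []
        for attr in ("coherence_class", "density_class"):
            for group in ("LSCC", "RSCC"):
                pct = rm.percent_area(labels, attr, within=("group", group))
                for cls, val in pct.items():
                    pa_rows.append(
                        dict(attribute=attr, group=group, region_class=cls, percent=val)
                    )
        pa = pd.DataFrame(pa_rows)
        _write_table(pa, out / "percent_areas.tsv", cfg_hash)
    result["percent_areas"] = pa

    with stage("anova"):
        anovas = {}
        for attr in ("coherence", "density"):
            tbl = simulate_percent_area_table(cfg, attr)
            an = da.compare_area_groups(tbl)
            _write_table(tbl, out / f"sample_percent_{attr}.tsv", cfg_hash)
            _write_table(an, out / f"anova_{attr}.tsv", cfg_hash, index=True)
            anovas[attr] = an
    result["anova"] = anovas

    manifest_out = {
        "config_hash": cfg_hash,
        "seed": cfg.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(cfg).items() if k != "phantom"
        },
        "comparison_pairs": [p[0] for p in COMPARISON_PAIRS],
        "n_peaks": len(peaks),
        "n_selected_main": len(sel_idx),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest_out, indent=2, default=str))
    root.removeHandler(handler)
    handler.close()
    result["labels"] = labels
    result["feature_matrix"] = fm
    result["peaks"] = peaks
    return result
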