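# Methods

This note documents the models, parameter choices and known limitations of
the package, in the spirit of a methods supplement.

## Coordinate frame

All modalities share one physical frame: micrometres, origin at the top-left
corner, y pointing down.  Pixels and MSI raster cells are half-open
footprints `[x, x + size) × [y, y + size)`; a cell's representative point is
its center.  Co-registration between modalities is an explicit 2×3 affine
transform (identity when data were generated or acquired on a shared frame);
a least-squares landmark fit (≥ 3 point pairs) is provided and logs its RMS
residual.  Deformable registration is out of scope.

## MSI processing

**Containers.** Spectra are (m/z, intensity) point lists with strictly
increasing m/z — both continuous-mode (shared axis) and processed-mode
(per-pixel axis) data fit this model.  imzML 1.1 is read via pyimzML; a
plain NPZ fixture dialect (concatenated `mz`/`intensity` arrays with
per-pixel `offsets`, `coords`, `spacing_um`) round-trips bit-exactly.

**TIC normalisation** scales each spectrum so its total ion count equals
the dataset mean TIC of non-empty pixels.  The target being the *mean* (not
1) keeps intensities on their native scale; the operation is idempotent and
zero-TIC pixels are flagged and excluded from statistics rather than
imputed.

**Peak finding** operates on a dataset mean spectrum: a common grid
(default 0.1 Da) where each bin holds the across-pixel mean of the
per-pixel maximum intensity in the bin.  Noise is estimated as
1.4826 × MAD of the (optionally 3-bin-median-filtered, "medium" noise
reduction) mean spectrum; local maxima at ≥ `snr_min` (default 3) times the
noise become peaks with ±`half_width_da` (default 0.4 Da) intervals,
truncated at the midpoint between adjacent centers so intervals are always
pairwise disjoint.  This MAD rule assumes a sparse baseline (median ≈ 0);
on spectra with a dense continuous baseline a baseline subtraction would be
required first, which the package deliberately does not perform.

**Feature matrix.** "Maximal interval" means entry (pixel, peak) is the
maximum intensity of that pixel's spectrum inside the peak interval (0 when
no data point falls inside).  This is robust to small mass-calibration
jitter between pixels, at the cost of a positive bias relative to
area-integration.

## Collagen coherence

Foreground is `intensity > Otsu threshold` (global, 256-bin histogram).
Coherence is the structure-tensor anisotropy (λ₁−λ₂)/(λ₁+λ₂) with
Gaussian-derivative gradients at σ_g = 2 px and tensor smoothing at
σ_w = 8 px (both configurable; the defaults suit ~0.4–2 µm/px acquisitions
where 8 px spans a few fibre widths).  All convolutions use reflective
padding.  Where the tensor trace falls below ε = 10⁻³ × mean gradient
energy the orientation is undefined and coherence is set to 0.  Coherence
is invariant to positive intensity rescaling and (discretely) equivariant
under 90° rotation.  The class boundary is 0.5 with the boundary value
assigned to *organised* — the published class intervals share the endpoint,
so the upper class was closed by convention, and the same convention is
mirrored by the nuclei classes.

## Nuclei density

Centroids (from CSV or a label mask reduced to per-label centers of mass)
are counted on a tile grid (default 100 µm — coarse enough for stable
counts, fine enough to map onto a 50 µm MSI raster), optionally smoothed
with a Gaussian of σ = 1 tile, then min-max normalised to [0, 1].  An
all-equal count map normalises to 0.5 everywhere so classification stays
defined.  Min-max normalisation makes the HND/LND split *relative to the
section*, not an absolute cellularity scale — a deliberate property shared
with the heatmap convention it reproduces.

## Region statistics

Continuous maps are pulled onto MSI pixels by the mean of map-pixel centers
landing in the footprint; class maps by majority vote with background
excluded (an all-background footprint stays background).  GeoJSON
annotations (QuPath dialect, `properties.classification.name`) label a
pixel iff its center is covered by the polygon (boundary inclusive);
overlapping polygons are resolved last-listed-wins and logged.  Percent
areas are taken over non-background pixels and always sum to 100.

## Discriminative analysis

Per-peak AUC is computed from midranks, which is exactly the all-pairs
estimate P(X_b > X_a) + ½P(X_b = X_a); p-values use the normal
approximation of the Mann–Whitney U test with tie and continuity
correction.  Selection uses the raw p < 0.01 together with AUC ≥ 0.6 or
≤ 0.4; Benjamini–Hochberg q-values are reported for information only, so
that the selection rule matches the reference workflow while the multiple-
testing burden remains visible.  Whether a permutation test would have been
preferable is moot at the pixel counts involved (hundreds per class); the
normal approximation is accurate there.

PCA mean-centers columns without unit-variance scaling (vendor-style
default; scaling would equalise noise features with markers) and uses the
covariance eigendecomposition, with each component's sign fixed by making
its largest-magnitude loading positive.

Protein assignment: a peak matches peptides with |Δm| < 0.15 Da (strict; a
10⁻⁹ Da guard keeps decimal inputs sitting exactly on the boundary out
despite float rounding).  Per peak the smallest-Δm candidate wins, ties
broken by the higher −10lgP score, then lexicographically.  A protein is
*identified* only when ≥ 2 distinct peaks match ≥ 2 distinct peptide
sequences, so one ambiguous peak can never identify a protein.

The two-way ANOVA on percent areas is fixed-effects with interaction,
Type II sums of squares (equal to the textbook decomposition when the
design is balanced, tolerant of mild imbalance otherwise).

## Segmentation

Bisecting k-means: split the leaf with the largest within-cluster SSE by
2-means (greedy k-means++, 10 restarts, keep the lowest-SSE split) until K
(default 5, matching the typical segment count of such analyses) leaves
exist.  The `correlation` metric (default) standardises each pixel's
feature row to zero mean and unit SD before Euclidean 2-means, clustering
spectral *shape* rather than overall intensity.  Determinism: per-split
seeds derive from the user seed, rows are brought into canonical
lexicographic order before each split, and the child containing the
canonically smallest row keeps its parent's id — so results are identical
across reruns and invariant to pixel storage order.  The split-selection
rule and restart count stand in for an unpublished vendor algorithm and are
configurable.

## Synthetic phantoms

The generator emulates the study conditions: 50 µm MSI raster, m/z
800–3200, 50 peptide peaks of which 10 carry planted between-group effects
of 1.5 within-class SD (scale-free after TIC normalisation), log-normal
per-pixel TIC variation (CV 0.2), and a dataset-wide comb of 250
chemical-noise positions (shared across pixels up to 0.02 Da jitter,
emulating matrix-cluster noise) with half-normal intensities.  Peak
profiles are Gaussian (σ = 0.2 Da) sampled at σ/2 — finer than any sensible
analysis bin.  The default phantom is 40 × 40 MSI pixels over 2 × 2 mm in a
crossed layout (2 groups × 2 collagen classes × 2 nuclei classes), rendered
at 2 µm/px so a full end-to-end run takes seconds; `image_um_per_px`
accepts the native ~0.38 µm/px of real acquisitions.

SHG phantoms render 80 µm line-segment fibres (one per 80 × 3 µm² of
region area, blurred to ~2 px width) whose orientations follow a wrapped
normal with region-specific dispersion; dispersion ≥ π switches to uniform
orientations.  These lengths/densities were chosen so that aligned regions
measure > 0.9 mean coherence while uniform-orientation regions stay well
below the 0.5 class cut at the default σ_w.  Nuclei are an inhomogeneous
Poisson process with region-wise intensity (defaults 250 vs 2500 /mm²,
i.e. a 10:1 contrast).  The peptide table gives each "real" protein two
peptides within 0.05 Da of distinct peaks and keeps decoys > 0.15 Da from
every peak.

What the phantoms do **not** emulate: isotope envelopes, mass-calibration
drift, baseline humps, H&E colour, fibre waviness and branching, nuclei
shape, or spatial autocorrelation of peptide intensities beyond the region
structure.  Passing recovery tests therefore demonstrates correctness of
the algorithms under the stated generative model, not instrument-level
realism.

## Numerical conventions and edge cases

* Bin counts use `ceil((hi−lo)/Δ − 1e−9)` to survive float division.
* Otsu on a constant image raises "degenerate histogram"; an all-zero MSI
  dataset raises on normalisation.
* A 2-means split of identical points falls back to a half/half split so
  the requested K is always reached.
* The per-sample ANOVA stage simulates each "patient" as an independent
  1 × 1 mm single-group phantom whose chaotic-stripe fraction is drawn from
  N(0.60, 0.05) — chaotic-dominant in both groups with no group effect,
  which is the structure the area comparison is meant to detect (or
  correctly not detect).  Default 7 samples per group.

## Known limitations

* No baseline subtraction, recalibration or deisotoping of MSI spectra;
  vendor raw formats are not parsed (imzML or the NPZ fixture only).
* Nuclei segmentation itself is external; the package consumes centroids.
* Registration is affine; serial-section warping is not modelled.
* The MAD noise rule presumes sparse baselines (see above).
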