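"""Supervised discrimination of m/z features between pixel classes.

For every aligned m/z feature a receiver-operating-characteristic (ROC)
analysis compares its intensity distribution between two pixel classes.
The area under the curve equals the normalised Mann-Whitney U statistic,

    AUC = P(X_b > X_a) + 0.5 * P(X_b = X_a),

with class B treated as positive, so AUC near 1 (or 0) marks a peptide
enriched in B (or A) and 0.5 marks no spatial difference.  Peaks with
AUC >= 0.6 or <= 0.4 and a rank-test p below 0.01 are candidate markers;
they feed principal component analysis, spatial segmentation, and protein
assignment by mass matching against an LC-MS/MS peptide table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .msi_core import FeatureMatrix, PeakTable

__all__ = [
    "ROCResult",
    "PeptideRecord",
    "PCAResult",
    "roc_per_peak",
    "roc_table",
    "select_candidates",
    "assign_proteins",
    "pca_on_candidates",
    "compare_area_groups",
    "read_peptide_table",
    "write_peptide_table",
]

AUC_HI_DEFAULT = 0.6
AUC_LO_DEFAULT = 0.4
P_MAX_DEFAULT = 0.01
MASS_TOL_DEFAULT = 0.15  # Da


@dataclass
class ROCResult:
    """Per-feature ROC outcome (class B positive)."""

    peak_id: int
    peak_mz: float
    auc: float
    p_value: float
    q_value: float
    n_a: int
    n_b: int
    selected: bool = False

    @property
    def direction(self) -> str:
        """'up' if enriched in class B (AUC > 0.5), else 'down'."""
        return "up" if self.auc > 0.5 else ("down" if self.auc < 0.5 else "flat")


@dataclass
class PeptideRecord:
    """One LC-MS/MS-identified tryptic peptide."""

    sequence: str
    mz_theoretical: float
    protein_accession: str
    protein_name: str = ""
    score: float = 0.0  # -10lgP identification confidence

    def __post_init__(self) -> None:
        if self.mz_theoretical <= 0:
            raise ValueError("mz_theoretical must be positive")
        if self.score < 0:
            raise ValueError("score must be non-negative")


@dataclass
class PCAResult:
    loadings: np.ndarray  # peaks x components
    scores: np.ndarray  # pixels x components
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        evr = np.asarray(self.explained_variance_ratio, dtype=float)
        if np.any(evr < -1e-12) or np.any(evr > 1 + 1e-12):
            raise ValueError("explained variance ratios must lie in [0, 1]")
        if np.any(np.diff(evr) > 1e-12):
            raise ValueError("explained variance ratios must be non-increasing")
        if evr.sum() > 1 + 1e-9:
            raise ValueError("explained variance ratios must sum to <= 1")


def _class_values(labels, attribute: str | None):
    if isinstance(labels, pd.DataFrame):
        if attribute is None:
            raise ValueError("attribute name required with a label table")
        return labels[attribute].values
    return np.asarray(labels)


def roc_per_peak(
    fm: FeatureMatrix,
    labels,
    class_a: str,
    class_b: str,
    attribute: str | None = None,
) -> list[ROCResult]:
    """Rank-based ROC of every feature between two pixel classes.

    ``labels`` is either a per-pixel class array aligned with the feature
    matrix rows or a region-label table (then ``attribute`` names the
    column).  The AUC is computed from midranks (exact all-pairs value,
    ties counted half); the two-sided p-value uses the normal approximation
    of the Mann-Whitney U test with tie correction and continuity
    correction.  Benjamini-Hochberg q-values are attached for information
    only — selection uses the raw p.
    """
    cls = _class_values(labels, attribute)
    if len(cls) != fm.n_pixels:
        raise ValueError("labels length does not match feature matrix rows")
    ma = cls == class_a
    mb = cls == class_b
    n_a, n_b = int(ma.sum()), int(mb.sum())
    if n_a < 2 or n_b < 2:
        raise ValueError(
            f"need >= 2 pixels per class (got {n_a} {class_a!r}, {n_b} {class_b!r})"
        )
    X = fm.values[ma | mb]
    isb = mb[ma | mb]
    N = n_a + n_b

    ranks = stats.rankdata(X, axis=0)  # midranks, per feature column
    r_b = ranks[isb].sum(axis=0)
    U = r_b - n_b * (n_b + 1) / 2.0
    auc = U / (n_a * n_b)

    # tie-corrected normal approximation
    mu = n_a * n_b / 2.0
    Xs = np.sort(X, axis=0)
    tie_term = np.zeros(X.shape[1])
    for k in range(X.shape[1]):
        _, counts = np.unique(Xs[:, k], return_counts=True)
        tie_term[k] = float(np.sum(counts**3 - counts))
    var = n_a * n_b / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    p = np.ones(X.shape[1])
    ok = var > 0
    z = (np.abs(U[ok] - mu) - 0.5) / np.sqrt(var[ok])  # continuity correction
    p[ok] = 2.0 * stats.norm.sf(np.maximum(z, 0.0))
    np.clip(p, 0.0, 1.0, out=p)
    q = multipletests(p, method="fdr_bh")[1]

    return [
        ROCResult(k, float(fm.peak_index[k]), float(auc[k]), float(p[k]),
                  float(q[k]), n_a, n_b)
        for k in range(X.shape[1])
    ]


def select_candidates(
    rocs: list[ROCResult],
    auc_hi: float = AUC_HI_DEFAULT,
    auc_lo: float = AUC_LO_DEFAULT,
    p_max: float = P_MAX_DEFAULT,
) -> list[ROCResult]:
    """Flag and return candidate markers: (AUC >= auc_hi or <= auc_lo) and
    p < p_max.  Defaults are the standard 0.6 / 0.4 / 0.01 cuts."""
    if not (0.0 <= auc_lo < auc_hi <= 1.0):
        raise ValueError("require 0 <= auc_lo < auc_hi <= 1")
    selected = []
    for r in rocs:
        r.selected = bool(
            (r.auc >= auc_hi or r.auc <= auc_lo) and r.p_value < p_max
        )
        if r.selected:
            selected.append(r)
    return selected


def roc_table(rocs: list[ROCResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak_id": [r.peak_id for r in rocs],
            "peak_mz": [r.peak_mz for r in rocs],
            "auc": [r.auc for r in rocs],
            "p": [r.p_value for r in rocs],
            "q": [r.q_value for r in rocs],
            "selected": [r.selected for r in rocs],
            "direction": [r.direction for r in rocs],
        }
    )


def assign_proteins(
    peaks: PeakTable,
    peptides: list[PeptideRecord],
    tol_da: float = MASS_TOL_DEFAULT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Match MSI peaks to LC-MS/MS peptides by monoisotopic mass.

    A peak matches candidate peptides with |center - mz_theoretical| < tol
    (strict).  Per peak, the candidate with the smallest mass difference is
    kept; exact ties are broken by the highest identification score, then
    lexicographically for determinism.  A protein counts as *identified*
    only when at least two distinct peaks match at least two distinct
    peptide sequences of that protein, so one ambiguous peak can never
    identify a protein on its own.

    Returns
    -------
    matches, proteins
        ``matches`` has one row per matched peak; ``proteins`` summarises
        per accession with an ``identified`` flag.
    """
    if tol_da <= 0:
        raise ValueError("tol_da must be positive")
    if not peptides:
        raise ValueError("empty peptide table")
    peps = sorted(
        peptides, key=lambda r: (r.mz_theoretical, r.protein_accession, r.sequence)
    )
    rows = []
    for k, center in enumerate(peaks.centers):
        best = None
        for rec in peps:
            d = abs(center - rec.mz_theoretical)
            # strict < tol; the 1e-9 guard keeps decimal inputs that sit
            # exactly on the boundary out despite float rounding
            if d < tol_da - 1e-9:
                key = (d, -rec.score, rec.protein_accession, rec.sequence)
                if best is None or key < best[0]:
                    best = (key, rec, d)
        if best is not None:
            _, rec, d = best
            rows.append(
                {
                    "peak_id": k,
                    "peak_mz": float(center),
                    "sequence": rec.sequence,
                    "mz_theoretical": rec.mz_theoretical,
                    "delta_mz": float(d),
                    "accession": rec.protein_accession,
                    "protein_name": rec.protein_name,
                    "score": rec.score,
                }
            )
    matches = pd.DataFrame(
        rows,
        columns=[
            "peak_id",
            "peak_mz",
            "sequence",
            "mz_theoretical",
            "delta_mz",
            "accession",
            "protein_name",
            "score",
        ],
    )
    if len(matches):
        g = matches.groupby("accession")
        proteins = pd.DataFrame(
            {
                "accession": g.size().index,
                "protein_name": g["protein_name"].first().values,
                "n_peaks": g["peak_id"].nunique().values,
                "n_peptides": g["sequence"].nunique().values,
            }
        )
        proteins["identified"] = (proteins["n_peaks"] >= 2) & (
            proteins["n_peptides"] >= 2
        )
        proteins = proteins.sort_values("accession").reset_index(drop=True)
    else:
        proteins = pd.DataFrame(
            columns=["accession", "protein_name", "n_peaks", "n_peptides", "identified"]
        )
    return matches, proteins


def pca_on_candidates(
    X: np.ndarray | FeatureMatrix, n_components: int | None = None
) -> PCAResult:
    """PCA of the candidate feature matrix via covariance eigendecomposition.

    Columns (features) are mean-centered but not variance-scaled.  The sign
    of each component is fixed by making its largest-magnitude loading
    positive, so the output is deterministic.  Explained-variance ratios
    are eigenvalues over the total variance (trace of the covariance).
    """
    X = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    n, d = X.shape
    if d < 2 or n < 3:
        raise ValueError("need >= 2 selected peaks and >= 3 pixels")
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / (n - 1)
    total = np.trace(C)
    if total <= 0:
        raise ValueError("rank-0 matrix: no variance to decompose")
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, V = np.clip(w[order], 0.0, None), V[:, order]
    if n_components is not None:
        w, V = w[:n_components], V[:, :n_components]
    for j in range(V.shape[1]):
        if V[np.argmax(np.abs(V[:, j])), j] < 0:
            V[:, j] = -V[:, j]
    return PCAResult(V, Xc @ V, w / total)


def compare_area_groups(
    table: pd.DataFrame,
    factor_a: str = "group",
    factor_b: str = "region_class",
    response: str = "percent",
) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA with interaction on per-sample percent
    areas (Type II sums of squares, tolerant of mild imbalance).

    ``table`` has one row per sample x class with columns for the two
    factors and the response.  Returns the ANOVA table (sum_sq, df, F, p)
    indexed by term.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for col in (factor_a, factor_b, response):
        if col not in table.columns:
            raise KeyError(f"missing column {col!r}")
    cells = table.groupby([factor_a, factor_b]).size()
    la = table[factor_a].nunique()
    lb = table[factor_b].nunique()
    if len(cells) < la * lb or (cells < 2).any():
        raise ValueError("every factor cell needs >= 2 samples")
    df = table.rename(columns={factor_a: "_A", factor_b: "_B", response: "_y"})
    model = smf.ols("_y ~ C(_A) * C(_B)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    anova = anova.rename(
        index={
            "C(_A)": factor_a,
            "C(_B)": factor_b,
            "C(_A):C(_B)": f"{factor_a}:{factor_b}",
            "Residual": "residual",
        }
    )
    return anova.rename(columns={"PR(>F)": "p"})


def read_peptide_table(path: str | Path) -> list[PeptideRecord]:
    """Read a peptide TSV: sequence, mz, accession, protein_name, score."""
    df = pd.read_csv(path, sep="\t")
    return [
        PeptideRecord(
            r["sequence"],
            float(r["mz"]),
            r["accession"],
            str(r.get("protein_name", "")),
            float(r.get("score", 0.0)),
        )
        for _, r in df.iterrows()
    ]


def write_peptide_table(peptides: list[PeptideRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sequence": [p.sequence for p in peptides],
            "mz": [p.mz_theoretical for p in peptides],
            "accession": [p.protein_accession for p in peptides],
            "protein_name": [p.protein_name for p in peptides],
            "score": [p.score for p in peptides],
        }
    ).to_csv(path, sep="\t", index=False)
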