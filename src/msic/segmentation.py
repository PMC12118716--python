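"""Bisecting k-means segmentation of MSI pixels on candidate features.

Divisive clustering: start with one cluster holding every pixel and
repeatedly 2-means-split the leaf with the largest within-cluster sum of
squared errors (SSE) until K segments exist.  Each split runs 2-means with
greedy k-means++ initialisation and 10 restarts, keeping the lowest-SSE
partition, and is fully determined by the user seed.  Rows are brought
into canonical (lexicographic) order before each split so the result does
not depend on pixel storage order.  The 'correlation' metric standardises
each pixel's feature row (zero mean, unit SD) before Euclidean 2-means,
the usual trick for shape-based spectral clustering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .msi_core import FeatureMatrix

__all__ = ["SegmentationResult", "bisecting_kmeans", "segment_composition"]


@dataclass
class SegmentationResult:
    """Per-pixel segment ids (1..K) plus the binary split tree."""

    labels: np.ndarray
    split_tree: list[dict]
    K: int
    seed: int
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        ids = np.unique(self.labels)
        if len(ids) != self.K or ids.min() < 1:
            raise ValueError("labels must cover segments 1..K")

    def tree_json(self) -> str:
        return json.dumps(self.split_tree, indent=2)


def _sse(X: np.ndarray, idx: np.ndarray) -> float:
    sub = X[idx]
    return float(((sub - sub.mean(axis=0)) ** 2).sum())


def _row_standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    out = np.zeros_like(X, dtype=float)
    np.divide(X - mu, sd, out=out, where=sd > 0)
    return out


def bisecting_kmeans(
    fm: FeatureMatrix | np.ndarray,
    K: int = 5,
    seed: int = 0,
    metric: str = "euclidean",
    n_restarts: int = 10,
) -> SegmentationResult:
    """Segment pixels into K clusters by bisecting k-means.

    Deterministic given ``seed``; invariant to pixel storage order.
    Segment ids are assigned in split order: the child containing the
    canonically-smallest row keeps its parent's id, the other child takes
    the next free id.
    """
    X = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, dtype=float)
    n = X.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K = {K} exceeds the number of pixels ({n})")
    if X.shape[1] == 0:
        raise ValueError("empty feature set")
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unknown metric {metric!r}")
    Xw = _row_standardize(X) if metric == "correlation" else X

    labels = np.ones(n, dtype=int)
    leaves: dict[int, np.ndarray] = {1: np.arange(n)}
    tree: list[dict] = []
    child_seeds = np.random.SeedSequence(seed).generate_state(max(K - 1, 1)) % (2**31)

    for split in range(K - 1):
        # split the leaf with the largest SSE (ties -> smallest id); leaves
        # of one pixel cannot be split
        candidates = {k: _sse(Xw, idx) for k, idx in leaves.items() if len(idx) >= 2}
        if not candidates:
            raise ValueError("no splittable cluster left before reaching K")
        leaf = min(candidates, key=lambda k: (-candidates[k], k))
        idx = leaves[leaf]
        sub = Xw[idx]
        order = np.lexsort(sub.T[::-1])  # canonical row order
        km = KMeans(
            n_clusters=2,
            init="k-means++",
            n_init=n_restarts,
            random_state=int(child_seeds[split]),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # duplicate-point ConvergenceWarning
            lab = km.fit_predict(sub[order])
        if len(np.unique(lab)) < 2:  # all points identical: split by halves
            lab = np.zeros(len(order), dtype=int)
            lab[len(order) // 2 :] = 1
        keep = lab[0]  # cluster of the canonically-smallest row keeps parent id
        new_id = max(leaves) + 1
        assignment = np.where(lab == keep, leaf, new_id)
        rows = idx[order]
        labels[rows] = assignment
        leaves[leaf] = rows[assignment == leaf]
        leaves[new_id] = rows[assignment == new_id]
        tree.append(
            {
                "parent": int(leaf),
                "children": [int(leaf), int(new_id)],
                "n": int(len(idx)),
                "sse_before": candidates[leaf],
                "sse_after": _sse(Xw, leaves[leaf]) + _sse(Xw, leaves[new_id]),
            }
        )

    return SegmentationResult(labels, tree, K, seed, metric)


def segment_composition(
    seg: SegmentationResult,
    labels: pd.DataFrame | np.ndarray,
    attribute: str | None = None,
) -> pd.DataFrame:
    """Per region class, the percentage of its pixels in each segment.

    Rows are region classes (background/none classes are skipped), columns
    segment ids; every row sums to 100.  Classes with zero pixels are
    omitted with a warning.
    """
    if isinstance(labels, pd.DataFrame):
        if attribute is None:
            raise ValueError("attribute name required with a label table")
        cls = labels[attribute].values
    else:
        cls = np.asarray(labels)
    if len(cls) != len(seg.labels):
        raise ValueError("labels and segmentation cover different pixel sets")
    seg_ids = np.unique(seg.labels)
    rows = {}
    for c in pd.unique(cls):
        name = str(c)
        if name.lower() in ("background", "none", "0", ""):
            continue
        mask = cls == c
        if not mask.any():
            warnings.warn(f"region class {c!r} has zero pixels; row omitted")
            continue
        counts = np.array([(seg.labels[mask] == s).sum() for s in seg_ids], float)
        rows[name] = 100.0 * counts / counts.sum()
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[int(s) for s in seg_ids]
    )
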