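"""Tag-density matrices around peak centers and centered-correlation k-means.

Accessibility profiles are binned fragment-midpoint densities in a window
around each peak center, normalized to fragments-per-10-million. Peaks are
grouped with Lloyd-style k-means under the centered-Pearson-correlation
metric (distance = 1 - r on mean-centered rows), the similarity metric used
by classic expression-clustering tools, so that profile *shape* rather than
amplitude drives the grouping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import IntervalSet
from .nucspacing import FragmentSet

__all__ = [
    "TagDensityMatrix",
    "ClusterAssignment",
    "tag_density",
    "kmeans_centered_correlation",
    "cluster_condition_profiles",
]

NORM_FACTOR = 1e7  # fragments-per-10-million normalization


@dataclass
class TagDensityMatrix:
    """Peaks x relative-position bins of normalized fragment-midpoint counts."""

    values: np.ndarray            # (n_peaks, n_bins), >= 0
    peaks: IntervalSet
    window: int
    binsize: int
    condition: str = ""

    def __post_init__(self) -> None:
        if self.values.shape[1] != (2 * self.window) // self.binsize:
            raise ValueError("column count must equal 2*window/binsize")
        if (self.values < 0).any():
            raise ValueError("densities must be non-negative")

    @property
    def bin_offsets(self) -> np.ndarray:
        """Left edge of each bin relative to the peak center."""
        return -self.window + np.arange(self.values.shape[1]) * self.binsize


@dataclass
class ClusterAssignment:
    """Per-peak cluster ids (1..k) with centroids and fit metadata."""

    labels: np.ndarray            # int, 1..k
    centroids: np.ndarray         # (k, n_features), unit-norm centered profiles
    k: int
    seed: int
    n_iter: int
    objective: float              # sum of within-cluster (1 - r) distances
    objective_history: list[float] | None = None

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)

    def to_tsv(self, peaks: IntervalSet, path) -> None:
        df = peaks.to_dataframe()[["chrom", "start", "end"]].copy()
        df["cluster"] = self.labels
        df.to_csv(path, sep="\t", index=False)


def tag_density(
    peaks: IntervalSet,
    fragments: FragmentSet,
    window: int = 500,
    binsize: int = 10,
    lib_size: int | None = None,
    condition: str = "",
) -> TagDensityMatrix:
    """Count fragment midpoints in bins around each peak center.

    Bin ``b`` of a peak covers ``[center - window + b*binsize, center -
    window + (b+1)*binsize)``. Counts are scaled by 1e7 / library size
    (library size defaults to the total fragment count).
    """
    if lib_size is None:
        lib_size = len(fragments)
    n_bins = (2 * window) // binsize
    out = np.zeros((len(peaks), n_bins), dtype=np.float64)
    by_chrom = {
        str(c): np.sort(fragments.dyads[fragments.chroms == c])
        for c in np.unique(fragments.chroms)
    }
    for i, iv in enumerate(peaks):
        dy = by_chrom.get(iv.chrom)
        if dy is None:
            continue
        center = iv.midpoint
        lo = np.searchsorted(dy, center - window, "left")
        hi = np.searchsorted(dy, center + window, "left")
        if hi > lo:
            bins = (dy[lo:hi] - (center - window)) // binsize
            np.add.at(out[i], bins, 1.0)
    scale = NORM_FACTOR / lib_size if lib_size > 0 else 0.0
    return TagDensityMatrix(out * scale, peaks, window, binsize, condition)


def _center_normalize(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-center rows and scale to unit norm; flag zero-variance rows."""
    c = m - m.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(c, axis=1)
    degenerate = norms <= 1e-12
    safe = np.where(degenerate, 1.0, norms)
    return c / safe[:, None], degenerate


def kmeans_centered_correlation(
    m: np.ndarray | TagDensityMatrix,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
) -> ClusterAssignment:
    """Lloyd k-means under distance = 1 - Pearson r of mean-centered rows.

    Rows are centered and unit-normalized, making the distance a cosine
    distance; centroids are the (re-normalized) means of member rows, the
    spherical-k-means update under which the objective is non-increasing.
    Initialization is seeded k-means++ so a fixed seed gives bit-identical
    assignments. Zero-variance rows are at distance 1 from every centroid
    and are assigned to the largest cluster, with a warning.
    """
    x = m.values if isinstance(m, TagDensityMatrix) else np.asarray(m, dtype=np.float64)
    n = x.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows ({n})")

    xc, degenerate = _center_normalize(x)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance rows assigned to the largest cluster",
            stacklevel=2,
        )
    live = np.flatnonzero(~degenerate)
    rng = np.random.default_rng(seed)

    if len(live) == 0:
        labels = np.ones(n, dtype=np.int64)
        return ClusterAssignment(labels, np.zeros((k, x.shape[1])), k, seed, 0, float(n), [])

    xl = xc[live]
    # k-means++ seeding in correlation-distance space
    n_live = len(xl)
    k_eff = min(k, n_live)
    centroids = np.empty((k_eff, x.shape[1]))
    first = rng.integers(0, n_live)
    centroids[0] = xl[first]
    d2 = np.maximum(1.0 - xl @ centroids[0], 0.0) ** 2
    for j in range(1, k_eff):
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n_live, 1.0 / n_live)
        pick = rng.choice(n_live, p=probs)
        centroids[j] = xl[pick]
        d2 = np.minimum(d2, np.maximum(1.0 - xl @ centroids[j], 0.0) ** 2)

    labels_live = np.zeros(n_live, dtype=np.int64)
    history: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        sims = xl @ centroids.T                       # Pearson r to each centroid
        new_labels = np.argmax(sims, axis=1)
        for j in range(k_eff):                        # re-seed empty clusters
            if not np.any(new_labels == j):
                worst = np.argmin(sims[np.arange(n_live), new_labels])
                new_labels[worst] = j
        history.append(float(np.sum(1.0 - sims[np.arange(n_live), new_labels])))
        if n_iter > 1 and np.array_equal(new_labels, labels_live):
            labels_live = new_labels
            break
        labels_live = new_labels
        for j in range(k_eff):
            mean = xl[labels_live == j].mean(axis=0)
            norm = np.linalg.norm(mean)
            if norm > 1e-12:
                centroids[j] = mean / norm

    sims = xl @ centroids.T
    objective = float(np.sum(1.0 - sims[np.arange(n_live), labels_live]))

    labels = np.empty(n, dtype=np.int64)
    labels[live] = labels_live + 1
    if degenerate.any():
        sizes = np.bincount(labels_live, minlength=k_eff)
        labels[degenerate] = int(np.argmax(sizes)) + 1
        objective += float(degenerate.sum())          # distance 1 to every centroid
    return ClusterAssignment(labels, centroids, k_eff, seed, n_iter, objective, history)


def cluster_condition_profiles(
    assign: ClusterAssignment,
    matrices: dict[str, TagDensityMatrix | np.ndarray],
) -> pd.DataFrame:
    """Per-cluster arithmetic-mean density profile for each condition.

    Returns a long DataFrame (bin_offset, cluster, condition,
    mean_density).
    """
    rows = []
    for cond, m in matrices.items():
        vals = m.values if isinstance(m, TagDensityMatrix) else np.asarray(m)
        offsets = (
            m.bin_offsets
            if isinstance(m, TagDensityMatrix)
            else np.arange(vals.shape[1])
        )
        for c in range(1, assign.k + 1):
            idx = assign.members(c)
            if len(idx) == 0:
                continue
            prof = vals[idx].mean(axis=0)
            for off, v in zip(offsets, prof):
                rows.append({"bin_offset": int(off), "cluster": c,
                             "condition": cond, "mean_density": v})
    return pd.DataFrame(rows)
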