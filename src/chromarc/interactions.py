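"""Pairwise interaction enrichment with a feature-randomization null.

Interactions (paired anchors, e.g. from RNA Pol II-mediated chromatin
loops) are filtered to intra-chromosomal pairs spanning 5 kb - 1 Mb with
matching UMI barcodes; each endpoint is assigned to every feature category
within 3 kb; and the observed count of category pairs joined by an
interaction is compared with its expectation under uniform shuffling of
category labels across all potential interaction endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import IntervalSet, read_bedpe, write_bedpe

__all__ = [
    "InteractionSet",
    "FeatureCatalog",
    "EnrichmentMatrix",
    "filter_interactions",
    "assign_endpoints",
    "pairwise_enrichment",
]

MIN_SPAN = 5_000
MAX_SPAN = 1_000_000
ASSIGN_RADIUS = 3_000
PSEUDOCOUNT = 0.5


class InteractionSet:
    """Paired anchors with UMI barcodes, backed by a BEDPE-style DataFrame.

    Required columns: chrom1, start1, end1, chrom2, start2, end2, umi1,
    umi2. Anchors are kept coordinate-ordered (anchor 1 <= anchor 2).
    """

    REQUIRED = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "umi1", "umi2"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"interaction table missing columns: {missing}")
        df = df.reset_index(drop=True).copy()
        # enforce anchor ordering
        key1 = list(zip(df["chrom1"], (df["start1"] + df["end1"]) // 2))
        key2 = list(zip(df["chrom2"], (df["start2"] + df["end2"]) // 2))
        flip = np.array([k1 > k2 for k1, k2 in zip(key1, key2)])
        if flip.any():
            c1 = df.loc[flip, ["chrom1", "start1", "end1", "umi1"]].to_numpy()
            df.loc[flip, ["chrom1", "start1", "end1", "umi1"]] = (
                df.loc[flip, ["chrom2", "start2", "end2", "umi2"]].to_numpy()
            )
            df.loc[flip, ["chrom2", "start2", "end2", "umi2"]] = c1
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def mids1(self) -> np.ndarray:
        return ((self.df["start1"] + self.df["end1"]) // 2).to_numpy(dtype=np.int64)

    @property
    def mids2(self) -> np.ndarray:
        return ((self.df["start2"] + self.df["end2"]) // 2).to_numpy(dtype=np.int64)

    @property
    def spans(self) -> np.ndarray:
        """Anchor-midpoint distance; NaN for inter-chromosomal pairs."""
        same = (self.df["chrom1"] == self.df["chrom2"]).to_numpy()
        s = np.abs(self.mids2 - self.mids1).astype(np.float64)
        s[~same] = np.nan
        return s

    @classmethod
    def from_bedpe(cls, path) -> "InteractionSet":
        df = read_bedpe(path)
        if "umi1" not in df.columns:
            df["umi1"] = df["umi2"] = ""
        return cls(df)

    def to_bedpe(self, path) -> None:
        df = self.df.copy()
        df["name"] = df["umi1"].astype(str) + "|" + df["umi2"].astype(str)
        write_bedpe(df, path)


class FeatureCatalog(dict):
    """Mapping category label -> IntervalSet; a region may carry several labels."""

    def __init__(self, sets: dict[str, IntervalSet]):
        super().__init__(sets)

    def mid_index(self) -> dict[str, dict[str, np.ndarray]]:
        """category -> chrom -> sorted feature midpoints."""
        out: dict[str, dict[str, np.ndarray]] = {}
        for label, iset in self.items():
            per: dict[str, list[int]] = {}
            for iv in iset:
                per.setdefault(iv.chrom, []).append(iv.midpoint)
            out[label] = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in per.items()}
        return out


@dataclass
class EnrichmentMatrix:
    """Observed and permutation-expected counts per category pair."""

    table: pd.DataFrame          # catA, catB, observed, expected_mean, expected_sd,
                                 # log2_ratio, z, p_emp  (catA <= catB)
    n_permutations: int
    seed: int

    def matrix(self, value: str = "log2_ratio") -> pd.DataFrame:
        cats = sorted(set(self.table["catA"]) | set(self.table["catB"]))
        m = pd.DataFrame(np.nan, index=cats, columns=cats)
        for _, r in self.table.iterrows():
            m.loc[r["catA"], r["catB"]] = r[value]
            m.loc[r["catB"], r["catA"]] = r[value]
        return m

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def filter_interactions(
    raw: InteractionSet,
    min_span: int = MIN_SPAN,
    max_span: int = MAX_SPAN,
    require_umi_match: bool = True,
) -> InteractionSet:
    """Keep intra-chromosomal pairs with min_span <= span <= max_span
    (inclusive bounds) and, if required, identical UMIs on both ends."""
    spans = raw.spans
    keep = np.isfinite(spans) & (spans >= min_span) & (spans <= max_span)
    if require_umi_match:
        keep &= (raw.df["umi1"] == raw.df["umi2"]).to_numpy()
    return InteractionSet(raw.df.loc[keep])


def assign_endpoints(
    ints: InteractionSet, cat: FeatureCatalog, radius: int = ASSIGN_RADIUS
) -> list[frozenset[str]]:
    """Label each endpoint with every category within ``radius`` bp.

    Distance is feature-midpoint to anchor-midpoint; <= radius assigns.
    Returns a flat list of 2n label sets ordered (end1 of pair 0, end2 of
    pair 0, end1 of pair 1, ...); unlabeled endpoints get an empty set and
    remain potential endpoints for the permutation null.
    """
    index = cat.mid_index()
    chroms = np.concatenate(
        [ints.df["chrom1"].to_numpy(dtype=object), ints.df["chrom2"].to_numpy(dtype=object)]
    )
    mids = np.concatenate([ints.mids1, ints.mids2])
    n = len(ints)
    labels: list[set[str]] = [set() for _ in range(2 * n)]
    for label, per_chrom in index.items():
        for slot in range(2 * n):
            arr = per_chrom.get(str(chroms[slot]))
            if arr is None or len(arr) == 0:
                continue
            m = int(mids[slot])
            j = int(np.searchsorted(arr, m))
            near = min(
                abs(int(arr[k]) - m) for k in (j - 1, j) if 0 <= k < len(arr)
            )
            if near <= radius:
                labels[slot].add(label)
    # interleave back to (end1_i, end2_i) order
    out = []
    for i in range(n):
        out.append(frozenset(labels[i]))
        out.append(frozenset(labels[n + i]))
    return out


def _pair_counts(L1: np.ndarray, L2: np.ndarray) -> np.ndarray:
    """Symmetric K x K counts of label pairs joined by an interaction.

    Off-diagonal (A, B): interactions with one end labeled A and the other
    B (counted once). Diagonal (A, A): interactions with both ends labeled
    A.
    """
    c = L1.T.astype(np.float64) @ L2.astype(np.float64)
    out = c + c.T
    np.fill_diagonal(out, np.diag(c))
    return out


def pairwise_enrichment(
    assigned: list[frozenset[str]],
    n_perm: int = 1000,
    seed: int = 0,
    categories: list[str] | None = None,
) -> EnrichmentMatrix:
    """Observed vs label-shuffle-expected counts for every category pair.

    ``assigned`` holds 2n endpoint label sets (pairs are consecutive).
    The null shuffles the label sets uniformly across all 2n potential
    endpoints, holding the interaction graph and the label multiset fixed.
    The log2 ratio uses pseudocount 0.5 on observed and expected; a
    permutation z-score and a two-sided empirical p (with the +1
    correction) are reported per pair.
    """
    if n_perm < 10:
        raise ValueError("n_perm < 10: permutation null too coarse")
    if len(assigned) % 2:
        raise ValueError("assigned endpoint list must have even length")
    n = len(assigned) // 2
    if categories is None:
        categories = sorted(set().union(*assigned)) if assigned else []
    if not categories or n == 0:
        raise ValueError("no assigned categories among endpoints")
    K = len(categories)
    cat_idx = {c: k for k, c in enumerate(categories)}
    L = np.zeros((2 * n, K), dtype=np.int8)
    for slot, labs in enumerate(assigned):
        for lab in labs:
            if lab in cat_idx:
                L[slot, cat_idx[lab]] = 1

    even, odd = np.arange(0, 2 * n, 2), np.arange(1, 2 * n, 2)
    obs = _pair_counts(L[even], L[odd])

    rng = np.random.default_rng(seed)
    perm_counts = np.empty((n_perm, K, K))
    for t in range(n_perm):
        p = rng.permutation(2 * n)
        Lp = L[p]
        perm_counts[t] = _pair_counts(Lp[even], Lp[odd])
    exp_mean = perm_counts.mean(axis=0)
    exp_sd = perm_counts.std(axis=0, ddof=1)

    rows = []
    for a in range(K):
        for b in range(a, K):
            o, e, s = obs[a, b], exp_mean[a, b], exp_sd[a, b]
            log2_ratio = np.log2((o + PSEUDOCOUNT) / (e + PSEUDOCOUNT))
            z = (o - e) / s if s > 0 else np.nan
            pc = perm_counts[:, a, b]
            upper = (1 + np.sum(pc >= o)) / (n_perm + 1)
            lower = (1 + np.sum(pc <= o)) / (n_perm + 1)
            p_emp = min(1.0, 2 * min(upper, lower))
            rows.append(
                {
                    "catA": categories[a], "catB": categories[b],
                    "observed": int(o), "expected_mean": e, "expected_sd": s,
                    "log2_ratio": log2_ratio, "z": z, "p_emp": p_emp,
                }
            )
    return EnrichmentMatrix(table=pd.DataFrame(rows), n_permutations=n_perm, seed=seed)
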