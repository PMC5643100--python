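"""Enhancer taxonomy and observed/expected genomic-element enrichment.

Enhancers are H3K4me regions more than 1 kb from both the nearest
annotated TSS and the nearest H3K4me3 (promoter-mark) region, split into
poised (no H3K27ac overlap) and active (H3K27ac overlap). Active enhancers
are further split into typical and super-enhancers with a rank-curve
tangent cutoff on acetylation tag density: on the unit-rescaled ascending
rank curve, every region past the first point where the discrete slope
exceeds 1 is a super-enhancer.

Element enrichment assigns each queried site one primary genomic-element
label (promoter > TTS > 5'UTR > 3'UTR > exon > intron > intergenic) and
compares observed category counts with the expectation from background
composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import IntervalSet, TssAnnotation, overlap_sets

__all__ = [
    "EnhancerClassification",
    "ElementAnnotation",
    "classify_enhancers",
    "call_super_enhancers",
    "element_enrichment",
]

TSS_EXCLUSION = 1000   # bp; enhancers must be farther than this from TSS / K4me3
PSEUDOCOUNT = 0.5
PRIORITY = ["promoter", "TTS", "5UTR", "3UTR", "exon", "intron"]
INTERGENIC = "intergenic"


@dataclass
class EnhancerClassification:
    """Per-region enhancer class with supporting distances and scores.

    ``table`` has one row per input K4me region: chrom, start, end,
    tss_dist, k4me3_dist, is_enhancer, enhancer_class (one of
    poised_enhancer / active_enhancer / super_enhancer, or "" for
    non-enhancers), score (K27ac tag density for active regions).
    """

    table: pd.DataFrame

    def regions(self, enhancer_class: str) -> IntervalSet:
        from .core import GenomicInterval

        sub = self.table[self.table["enhancer_class"] == enhancer_class]
        return IntervalSet(
            GenomicInterval(r.chrom, int(r.start), int(r.end),
                            score=None if pd.isna(r.score) else float(r.score))
            for r in sub.itertuples()
        ).sorted()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _nearest_point_gap(region, positions: dict[str, np.ndarray]) -> float:
    arr = positions.get(region.chrom)
    if arr is None or len(arr) == 0:
        return np.inf
    d = np.maximum.reduce([region.start - arr, arr - (region.end - 1), np.zeros_like(arr)])
    return float(d.min())


def _nearest_region_gap(region, by_chrom: dict[str, tuple[np.ndarray, np.ndarray]]) -> float:
    arrs = by_chrom.get(region.chrom)
    if arrs is None:
        return np.inf
    starts, ends = arrs
    d = np.maximum.reduce([starts - region.end, region.start - ends, np.zeros_like(starts)])
    return float(d.min())


def classify_enhancers(
    k4me: IntervalSet,
    k4me3: IntervalSet,
    k27ac: IntervalSet,
    tss: TssAnnotation,
    exclusion: int = TSS_EXCLUSION,
) -> EnhancerClassification:
    """Classify stitched K4me regions into poised/active/super enhancers.

    A region is an enhancer when its gap to the nearest TSS *and* to the
    nearest K4me3 region both exceed ``exclusion`` bp (a region 500 bp from
    a TSS is excluded). Enhancers with no K27ac overlap (>= 1 bp) are
    poised; the rest are active and carry the summed score of overlapping
    K27ac regions, from which super-enhancers are carved out by
    :func:`call_super_enhancers`. An empty K4me set yields an empty
    classification.
    """
    tss_pos = {c: p for c, (p, _, _) in tss.by_chrom_sorted().items()}
    k4me3_by_chrom = {
        c: (np.array([iv.start for iv in ivs], dtype=np.int64),
            np.array([iv.end for iv in ivs], dtype=np.int64))
        for c, ivs in k4me3.sorted().by_chrom().items()
    }
    k27_by_chrom = {
        c: sorted(ivs, key=lambda iv: iv.start) for c, ivs in k27ac.sorted().by_chrom().items()
    }

    rows = []
    for iv in k4me:
        td = _nearest_point_gap(iv, tss_pos)
        kd = _nearest_region_gap(iv, k4me3_by_chrom)
        is_enh = td > exclusion and kd > exclusion
        score = np.nan
        klass = ""
        if is_enh:
            overlapping = [
                o for o in k27_by_chrom.get(iv.chrom, [])
                if o.start < iv.end and o.end > iv.start
            ]
            if overlapping:
                klass = "active_enhancer"
                score = float(sum(o.score if o.score is not None else 0.0 for o in overlapping))
            else:
                klass = "poised_enhancer"
        rows.append(
            {
                "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                "tss_dist": td, "k4me3_dist": kd,
                "is_enhancer": is_enh, "enhancer_class": klass, "score": score,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "tss_dist", "k4me3_dist",
                 "is_enhancer", "enhancer_class", "score"],
    )

    active = table.index[table["enhancer_class"] == "active_enhancer"]
    if len(active) >= 3:
        super_mask = call_super_enhancers(table.loc[active, "score"].to_numpy())
        table.loc[active[super_mask], "enhancer_class"] = "super_enhancer"
    return EnhancerClassification(table=table)


def call_super_enhancers(scores: np.ndarray) -> np.ndarray:
    """Tangent cutoff on the ascending rank curve of acetylation scores.

    Ranks and scores are rescaled to [0, 1]; scanning ascending, the first
    consecutive-point slope exceeding 1 sets the cutoff, and every region
    ranked above it is flagged super. An exactly linear curve (slope = 1
    everywhere) yields no super-enhancers; all-equal scores yield none,
    with a warning. Returns a boolean mask aligned with the input order.
    """
    scores = np.asarray(scores, dtype=np.float64)
    n = len(scores)
    if n < 3:
        raise ValueError("need at least 3 scored regions to call super-enhancers")
    if np.any(scores < 0):
        raise ValueError("scores must be non-negative")
    mask = np.zeros(n, dtype=bool)
    if np.ptp(scores) == 0:
        warnings.warn("all scores equal: no super-enhancers called", stacklevel=2)
        return mask
    order = np.argsort(scores, kind="stable")
    y = (scores[order] - scores.min()) / np.ptp(scores)
    # x spacing is 1/(n-1) after rescaling rank to [0, 1]
    slopes = np.diff(y) * (n - 1)
    above = np.flatnonzero(slopes > 1.0 + 1e-9)   # tolerance: exactly-linear curves stay empty
    if len(above) == 0:
        return mask
    cutoff = above[0]                 # slope between ranked points cutoff, cutoff+1
    mask[order[cutoff + 1:]] = True
    return mask


@dataclass
class ElementAnnotation:
    """Genomic-element partition: category -> IntervalSet, with a fixed
    priority order for sites spanning several elements."""

    elements: dict[str, IntervalSet]
    priority: list[str] = field(default_factory=lambda: list(PRIORITY))

    def __post_init__(self) -> None:
        unknown = set(self.elements) - set(self.priority)
        if unknown:
            raise ValueError(f"categories without a priority rank: {sorted(unknown)}")

    @property
    def categories(self) -> list[str]:
        return [c for c in self.priority if c in self.elements] + [INTERGENIC]

    def primary_labels(self, sites: IntervalSet) -> np.ndarray:
        """One label per site: highest-priority category sharing >= 1 bp,
        else intergenic. Every queried site receives exactly one label."""
        labels = np.array([INTERGENIC] * len(sites), dtype=object)
        if len(sites) == 0:
            return labels
        unresolved = np.ones(len(sites), dtype=bool)
        for cat in self.priority:
            if cat not in self.elements or not unresolved.any():
                continue
            hits = overlap_sets(sites, self.elements[cat]).hits
            take = hits & unresolved
            labels[take] = cat
            unresolved &= ~hits
        return labels


def element_enrichment(
    sites: IntervalSet,
    ann: ElementAnnotation,
    background: IntervalSet,
) -> pd.DataFrame:
    """Observed vs background-expected site counts per genomic element.

    ``expected`` for a category is |sites| times the fraction of the
    background set whose primary label is that category; the log2 ratio
    uses pseudocount 0.5 on both terms. Observed counts over all primary
    labels sum to |sites| (each site carries exactly one primary label).
    """
    if len(sites) == 0 or len(background) == 0:
        raise ValueError("sites and background must be non-empty")
    site_labels = ann.primary_labels(sites)
    bg_labels = ann.primary_labels(background)
    cats = ann.categories
    rows = []
    for cat in cats:
        obs = int(np.sum(site_labels == cat))
        frac = float(np.mean(bg_labels == cat))
        exp = len(sites) * frac
        rows.append(
            {
                "category": cat,
                "observed": obs,
                "expected": exp,
                "log2_ratio": np.log2((obs + PSEUDOCOUNT) / (exp + PSEUDOCOUNT)),
            }
        )
    return pd.DataFrame(rows)
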