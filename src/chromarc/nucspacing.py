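"""Nucleosome spacing around TF motifs from paired-end fragment dyads.

Mononucleosome-sized fragments (180-247 bp by default) are selected from a
paired-end fragment set; the midpoint of each fragment is taken as a
surrogate for the nucleosome dyad. Dyads are accumulated at single-bp
resolution around motif centers, and the spacing between the flanking
nucleosomes is the distance between the density maxima upstream and
downstream of the motif. Comparing spacing across genotypes quantifies how
a remodeler shifts the nucleosomes that bracket a factor-bound site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .core import IntervalSet

__all__ = [
    "FragmentSet",
    "DyadProfile",
    "SpacingEstimate",
    "select_mononucleosome",
    "dyad_profile",
    "estimate_spacing",
    "spacing_delta",
]

MONONUC_LO = 180  # bp, inclusive
MONONUC_HI = 247  # bp, inclusive


@dataclass
class FragmentSet:
    """Paired-end fragments as parallel arrays (0-based half-open spans).

    ``dyad`` is floor((start+end)/2), the standard midpoint surrogate for
    the nucleosome dyad of a mononucleosome-sized fragment.
    """

    chroms: np.ndarray        # object/str array
    starts: np.ndarray        # int64
    ends: np.ndarray          # int64
    sample: str = ""

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("fragment arrays must have equal length")
        if np.any(self.ends <= self.starts):
            raise ValueError("fragments must have end > start")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def dyads(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    def subset(self, mask: np.ndarray) -> "FragmentSet":
        return FragmentSet(self.chroms[mask], self.starts[mask], self.ends[mask], self.sample)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for c, s, e in zip(self.chroms, self.starts, self.ends):
                fh.write(f"{c}\t{s}\t{e}\n")

    @classmethod
    def from_bed(cls, path, sample: str = "") -> "FragmentSet":
        chroms, starts, ends = [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                chroms.append(f[0])
                starts.append(int(f[1]))
                ends.append(int(f[2]))
        return cls(np.array(chroms, dtype=object), np.array(starts), np.array(ends), sample)


@dataclass
class DyadProfile:
    """Mean dyad density per motif at single-bp offsets around motif centers."""

    offsets: np.ndarray       # -window..window inclusive
    density: np.ndarray       # mean dyad count per motif per bp
    n_motifs: int
    n_fragments_used: int
    bandwidth: float = 0.0
    condition: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "density": self.density})


@dataclass
class SpacingEstimate:
    """Offsets of the flanking nucleosome density maxima and their distance."""

    upstream: int             # bp, negative
    downstream: int           # bp, positive
    condition: str = ""

    def __post_init__(self) -> None:
        if not (self.upstream < 0 < self.downstream):
            raise ValueError("upstream peak must be negative, downstream positive")

    @property
    def spacing(self) -> int:
        return self.downstream - self.upstream


def select_mononucleosome(
    fragments: FragmentSet, lo: int = MONONUC_LO, hi: int = MONONUC_HI
) -> FragmentSet:
    """Keep fragments with lo <= length <= hi (both bounds inclusive)."""
    lengths = fragments.lengths
    return fragments.subset((lengths >= lo) & (lengths <= hi))


def dyad_profile(
    fragments: FragmentSet,
    motifs: IntervalSet,
    window: int = 500,
    bandwidth: float = 0.0,
    condition: str = "",
) -> DyadProfile:
    """Accumulate fragment dyads at single-bp offsets around motif midpoints.

    ``density[offset]`` is the total dyad count at that offset divided by the
    number of motifs. Motif strand is ignored; offsets are genomic
    (motif-center-relative). ``bandwidth > 0`` applies Gaussian smoothing
    with that sd in bp; 0 returns the raw histogram.
    """
    if len(motifs) == 0:
        raise ValueError("motif set is empty")
    offsets = np.arange(-window, window + 1)
    counts = np.zeros(2 * window + 1, dtype=np.float64)
    used = 0
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in np.unique(fragments.chroms):
        by_chrom[str(chrom)] = np.sort(fragments.dyads[fragments.chroms == chrom])
    for m in motifs:
        dy = by_chrom.get(m.chrom)
        if dy is None:
            continue
        center = m.midpoint
        lo = np.searchsorted(dy, center - window, side="left")
        hi = np.searchsorted(dy, center + window, side="right")
        if hi > lo:
            local = dy[lo:hi] - center + window
            np.add.at(counts, local, 1.0)
            used += hi - lo
    density = counts / len(motifs)
    if bandwidth > 0:
        density = gaussian_filter1d(density, sigma=bandwidth, mode="nearest")
    return DyadProfile(
        offsets=offsets,
        density=density,
        n_motifs=len(motifs),
        n_fragments_used=used,
        bandwidth=bandwidth,
        condition=condition,
    )


def _argmax_toward_zero(offsets: np.ndarray, density: np.ndarray) -> int:
    """Offset of the maximum density; ties resolve to the smallest |offset|."""
    best = density.max()
    cand = offsets[density >= best]
    return int(cand[np.argmin(np.abs(cand))])


def estimate_spacing(
    profile: DyadProfile, exclusion: int = 50, condition: str | None = None
) -> SpacingEstimate:
    """Find flanking density maxima outside a +/-``exclusion`` bp footprint zone.

    The upstream peak is the argmax over offsets <= -exclusion, the
    downstream peak over offsets >= +exclusion; spacing is their distance.
    Raises ``ValueError`` naming the side if one side carries no signal.
    """
    up_mask = profile.offsets <= -exclusion
    down_mask = profile.offsets >= exclusion
    for side, mask in (("upstream", up_mask), ("downstream", down_mask)):
        if not np.any(profile.density[mask] > 0):
            raise ValueError(f"no dyad density on the {side} side beyond the exclusion zone")
    up = _argmax_toward_zero(profile.offsets[up_mask], profile.density[up_mask])
    down = _argmax_toward_zero(profile.offsets[down_mask], profile.density[down_mask])
    return SpacingEstimate(
        upstream=up,
        downstream=down,
        condition=condition if condition is not None else profile.condition,
    )


def spacing_delta(
    estimates: dict[str, SpacingEstimate], reference: str
) -> pd.DataFrame:
    """Spacing change of each condition relative to ``reference``.

    Returns a DataFrame (condition, up_offset, down_offset, spacing,
    delta_vs_reference); the reference row has delta 0.
    """
    if reference not in estimates:
        raise KeyError(f"reference condition {reference!r} not among estimates")
    ref = estimates[reference].spacing
    rows = [
        {
            "condition": cond,
            "up_offset": est.upstream,
            "down_offset": est.downstream,
            "spacing": est.spacing,
            "delta_vs_reference": est.spacing - ref,
        }
        for cond, est in estimates.items()
    ]
    return pd.DataFrame(rows)
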