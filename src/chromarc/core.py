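"""Interval algebra, TSS annotation, and BED/BEDPE/bedGraph readers and writers.

All coordinates are 0-based half-open (BED convention). Every other module
builds on the containers defined here: :class:`GenomicInterval`,
:class:`IntervalSet`, and :class:`TssAnnotation`.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "TssAnnotation",
    "OverlapReport",
    "merge_intervals",
    "overlap_sets",
    "nearest_tss",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "write_bedgraph",
]

DISTAL_THRESHOLD = 3000  # bp; sites farther than this from the nearest TSS are distal


class IntervalValidationError(ValueError):
    """Raised when an interval record violates the coordinate invariants."""


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware genomic interval with optional score and name.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``end > start`` is
    enforced so empty intervals cannot be constructed.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise IntervalValidationError("interval has empty chromosome name")
        if self.start < 0:
            raise IntervalValidationError(
                f"interval {self.chrom}:{self.start}-{self.end} has negative start"
            )
        if self.end <= self.start:
            raise IntervalValidationError(
                f"interval {self.chrom}:{self.start}-{self.end} has end <= start"
            )
        if self.strand not in ("+", "-", "."):
            raise IntervalValidationError(f"invalid strand {self.strand!r}")
        if self.score is not None and math.isnan(self.score):
            raise IntervalValidationError(
                f"interval {self.chrom}:{self.start}-{self.end} has NaN score"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    The set keeps track of whether it is sorted by ``(chrom, start, end)``;
    operations that need sorted input call :meth:`sorted` which is a no-op
    on already-sorted sets.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), *, is_sorted: bool = False):
        self.intervals: list[GenomicInterval] = list(intervals)
        self.is_sorted = is_sorted and self._check_sorted()

    def _check_sorted(self) -> bool:
        key = [(iv.chrom, iv.start, iv.end) for iv in self.intervals]
        return all(key[i] <= key[i + 1] for i in range(len(key) - 1))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, sorted={self.is_sorted})"

    def sorted(self) -> "IntervalSet":
        """Return a set sorted by (chrom, start, end); self if already sorted."""
        if self.is_sorted:
            return self
        ivs = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        out = IntervalSet(ivs)
        out.is_sorted = True
        return out

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name for iv in self.intervals],
                "score": [iv.score for iv in self.intervals],
                "strand": [iv.strand for iv in self.intervals],
            }
        )

    def with_scores(self, scores: Sequence[float]) -> "IntervalSet":
        if len(scores) != len(self):
            raise ValueError("score vector length mismatch")
        out = IntervalSet(replace(iv, score=float(s)) for iv, s in zip(self.intervals, scores))
        out.is_sorted = self.is_sorted
        return out


@dataclass
class TssAnnotation:
    """Single-bp TSS positions carrying gene id and strand.

    Every record must be 1 bp wide (``end == start + 1``) and carry a
    non-empty gene id in ``name``.
    """

    tss: IntervalSet = field(default_factory=IntervalSet)

    def __post_init__(self) -> None:
        for iv in self.tss:
            if iv.end != iv.start + 1:
                raise IntervalValidationError(
                    f"TSS record {iv.chrom}:{iv.start}-{iv.end} is not a single bp"
                )
            if not iv.name:
                raise IntervalValidationError(
                    f"TSS record {iv.chrom}:{iv.start} lacks a gene id"
                )

    def __len__(self) -> int:
        return len(self.tss)

    def by_chrom_sorted(self) -> dict[str, tuple[np.ndarray, list[str], list[str]]]:
        """Per chromosome: (positions, gene ids, strands), sorted by (pos, gene id)."""
        out: dict[str, tuple[np.ndarray, list[str], list[str]]] = {}
        for chrom, ivs in self.tss.by_chrom().items():
            ivs = sorted(ivs, key=lambda iv: (iv.start, iv.name))
            out[chrom] = (
                np.array([iv.start for iv in ivs], dtype=np.int64),
                [iv.name for iv in ivs],
                [iv.strand for iv in ivs],
            )
        return out


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------


def merge_intervals(iset: IntervalSet, gap: int = 0) -> IntervalSet:
    """Union intervals, joining neighbours separated by at most ``gap`` bp.

    With ``gap=0`` this is a plain union that also joins book-ended
    intervals ([100,200) + [200,300) -> [100,300)). With ``gap=1000`` it
    reproduces the 1 kb stitching used to build histone ChIP regions.
    Idempotent and invariant to input order.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    s = iset.sorted()
    merged: list[GenomicInterval] = []
    cur: GenomicInterval | None = None
    for iv in s:
        if cur is not None and iv.chrom == cur.chrom and iv.start - cur.end <= gap:
            if iv.end > cur.end:
                cur = replace(cur, end=iv.end, score=None, name=None, strand=".")
        else:
            if cur is not None:
                merged.append(cur)
            cur = GenomicInterval(iv.chrom, iv.start, iv.end)
    if cur is not None:
        merged.append(cur)
    out = IntervalSet(merged)
    out.is_sorted = True
    return out


@dataclass
class OverlapReport:
    """Per-interval hit flags of a query set against a subject set."""

    hits: np.ndarray          # bool, len == |a|
    n_hits: int
    proportion: float
    band: str                 # "high" (>=0.5), "low" (<=0.1), "intermediate"

    LOW = 0.1
    HIGH = 0.5


def _chrom_arrays(iset: IntervalSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per chromosome: (starts sorted, running max of ends) for stab queries."""
    out = {}
    for chrom, ivs in iset.sorted().by_chrom().items():
        starts = np.array([iv.start for iv in ivs], dtype=np.int64)
        ends = np.maximum.accumulate(np.array([iv.end for iv in ivs], dtype=np.int64))
        out[chrom] = (starts, ends)
    return out


def overlap_sets(a: IntervalSet, b: IntervalSet) -> OverlapReport:
    """Flag each interval of ``a`` that shares >= 1 bp with any interval of ``b``.

    The set-level proportion hits/|a| is classified into the bands used for
    overlap heat-tables: >= 0.5 "high", <= 0.1 "low", else "intermediate".

    Raises ``ValueError`` for empty ``a`` (the proportion is undefined and
    must not be conflated with 0).
    """
    if len(a) == 0:
        raise ValueError("overlap proportion undefined for empty query set")
    barr = _chrom_arrays(b)
    hits = np.zeros(len(a), dtype=bool)
    for i, iv in enumerate(a):
        if iv.chrom not in barr:
            continue
        starts, maxends = barr[iv.chrom]
        # candidate subjects start before the query ends
        j = np.searchsorted(starts, iv.end, side="left")
        hits[i] = j > 0 and maxends[j - 1] > iv.start
    n_hits = int(hits.sum())
    prop = n_hits / len(a)
    if prop >= OverlapReport.HIGH:
        band = "high"
    elif prop <= OverlapReport.LOW:
        band = "low"
    else:
        band = "intermediate"
    return OverlapReport(hits=hits, n_hits=n_hits, proportion=prop, band=band)


def nearest_tss(sites: IntervalSet, ann: TssAnnotation) -> pd.DataFrame:
    """Assign each site to its nearest TSS by midpoint distance.

    Returns a DataFrame with one row per site: ``gene_id``, ``distance``
    (signed in the gene's transcriptional orientation: positive downstream
    of the TSS), ``distal`` (|distance| > 3 kb) and ``unannotated`` (site on
    a chromosome absent from the annotation; such sites are kept, not
    dropped). Ties in absolute distance break toward the lexicographically
    smaller gene id.
    """
    by_chrom = ann.by_chrom_sorted()
    rows = []
    for iv in sites:
        mid = iv.midpoint
        if iv.chrom not in by_chrom:
            rows.append((None, np.nan, False, True))
            continue
        pos, genes, strands = by_chrom[iv.chrom]
        j = int(np.searchsorted(pos, mid, side="left"))
        best_d = None
        for cand in (j - 1, j):
            if 0 <= cand < len(pos):
                d = abs(int(pos[cand]) - mid)
                if best_d is None or d < best_d:
                    best_d = d
        assert best_d is not None
        # all TSSs at exactly best_d: positions mid - best_d and mid + best_d
        best_gene = None
        best_idx = -1
        for p in (mid - best_d, mid + best_d):
            k = bisect_left(pos, p)
            while k < len(pos) and pos[k] == p:
                if best_gene is None or genes[k] < best_gene:
                    best_gene, best_idx = genes[k], k
                k += 1
        genomic = mid - int(pos[best_idx])
        signed = genomic if strands[best_idx] != "-" else -genomic
        rows.append((best_gene, signed, abs(signed) > DISTAL_THRESHOLD, False))
    return pd.DataFrame(rows, columns=["gene_id", "distance", "distal", "unannotated"])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_COMMENT_PREFIXES = ("#", "track", "browser")


def _data_lines(path) -> Iterator[list[str]]:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(_COMMENT_PREFIXES):
                continue
            yield line.split("\t")


def read_bed(path) -> IntervalSet:
    """Read BED3/BED6 (tab-separated, '#'/'track'/'browser' lines skipped)."""
    ivs = []
    for f in _data_lines(path):
        name = f[3] if len(f) > 3 and f[3] != "." else None
        score = float(f[4]) if len(f) > 4 and f[4] != "." else None
        strand = f[5] if len(f) > 5 else "."
        ivs.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand, score, name))
    return IntervalSet(ivs)


def write_bed(iset: IntervalSet, path, *, score_digits: int = 6) -> None:
    with open(path, "w") as fh:
        for iv in iset:
            score = "." if iv.score is None else f"{iv.score:.{score_digits}g}"
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_bedpe(path) -> pd.DataFrame:
    """Read BEDPE into a DataFrame.

    Columns: chrom1,start1,end1,chrom2,start2,end2,name,score,strand1,strand2
    plus, when present, an 11th ``umi`` column. A name of the form
    "UMI1|UMI2" is also recognised and split into ``umi1``/``umi2``.
    """
    recs = []
    for f in _data_lines(path):
        rec = {
            "chrom1": f[0], "start1": int(f[1]), "end1": int(f[2]),
            "chrom2": f[3], "start2": int(f[4]), "end2": int(f[5]),
            "name": f[6] if len(f) > 6 else ".",
            "score": float(f[7]) if len(f) > 7 and f[7] != "." else np.nan,
            "strand1": f[8] if len(f) > 8 else ".",
            "strand2": f[9] if len(f) > 9 else ".",
        }
        if len(f) > 10:
            rec["umi1"] = rec["umi2"] = f[10]
        elif "|" in rec["name"]:
            rec["umi1"], rec["umi2"] = rec["name"].split("|", 1)
        recs.append(rec)
    return pd.DataFrame(recs)


def write_bedpe(df: pd.DataFrame, path) -> None:
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            base = "\t".join(str(r[c]) for c in cols)
            name = r.get("name", ".")
            if "umi1" in df.columns and (name == "." or pd.isna(name)):
                name = f"{r['umi1']}|{r['umi2']}"
            score = r.get("score", ".")
            score = "." if (isinstance(score, float) and math.isnan(score)) else score
            fh.write(f"{base}\t{name}\t{score}\t{r.get('strand1', '.')}\t{r.get('strand2', '.')}\n")


def write_bedgraph(chrom_values: dict[str, np.ndarray], path, *, span: int = 1) -> None:
    """Write per-bp (or per-``span``-bp) density tracks as bedGraph, merging runs."""
    with open(path, "w") as fh:
        for chrom in sorted(chrom_values):
            vals = np.asarray(chrom_values[chrom])
            if len(vals) == 0:
                continue
            change = np.flatnonzero(np.diff(vals) != 0) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vals)]))
            for s, e in zip(starts, ends):
                v = vals[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s * span}\t{e * span}\t{v:g}\n")


def intervals_from_arrays(chrom, starts, ends, **kw) -> IntervalSet:
    """Convenience constructor from parallel arrays (single chromosome)."""
    return IntervalSet(
        GenomicInterval(chrom, int(s), int(e), **kw) for s, e in zip(starts, ends)
    )
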