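"""Synthetic-data generators for every pipeline input.

Each generator is a pure function of ``(config, seed)`` and emits ground
truth alongside the data, so every downstream estimator (differential
caller, clusterer, spacing estimator, interaction enrichment) can be scored
without external downloads. Child RNG streams are spawned per dataset kind
from the master seed, so adding a generator does not perturb the others.

What is emulated: two-condition, two-replicate negative-binomial peak count
tables with planted gain/loss classes; paired-end fragment-length mixtures
with a mononucleosome mode whose dyads sit at planted offsets around motif
centers; histone-mark region sets consistent with a promoter/poised/active
enhancer taxonomy, with heavy-tailed acetylation scores that produce a
super-enhancer elbow; and feature-anchored interactions with UMIs and
planted pairwise enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .core import GenomicInterval, IntervalSet, TssAnnotation, intervals_from_arrays
from .nucspacing import FragmentSet

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_peak_counts",
    "simulate_fragments",
    "simulate_gene_annotation",
    "simulate_marks_and_features",
    "simulate_interactions",
    "grid_feature_anchors",
]

# RNG stream indices (SeedSequence spawn order is part of the contract)
_STREAMS = {"peaks": 0, "fragments": 1, "marks": 2, "interactions": 3, "genes": 4, "expression": 5}


@dataclass
class SimConfig:
    """All tunable knobs of the generators, with study-scale defaults.

    ``cluster_spec`` lists (label, fraction of peaks, log2 effect in the
    perturbed condition); the default fractions mirror an experiment where
    12.5% of accessible sites lose and 5.2% gain accessibility at |log2FC|
    = 1.5. ``nuc_spacing`` gives the planted flanking-dyad offset (bp from
    the motif center) per condition; the defaults encode an intact
    remodeler placing nucleosomes at +/-120 bp and a deficient one at
    +/-101 bp, i.e. a 38 bp loss of inter-nucleosome spacing.
    """

    seed: int = 0
    n_chrom: int = 4
    chrom_len: int = 10_000_000
    n_peaks: int = 10_000
    peak_width: int = 500
    cluster_spec: list[tuple[str, float, float]] = field(
        default_factory=lambda: [
            ("loss", 0.125, -1.5),
            ("gain", 0.052, 1.5),
            ("stable", 0.823, 0.0),
        ]
    )
    dispersion: float = 0.05
    base_log_mean: float = 4.605170185988092  # ln(100): ~100 fragments per peak

    base_log_sd: float = 0.5
    lib_factor_range: tuple[float, float] = (0.7, 1.3)
    conditions: tuple[str, str] = ("WT", "KO")
    n_replicates: int = 2

    # fragment generator
    frag_len_mix: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(60.0, 20.0, 0.5), (200.0, 10.0, 0.5)]
    )
    n_fragments: int = 100_000
    nuc_spacing: dict[str, float] = field(default_factory=lambda: {"WT": 120.0, "KO": 101.0})
    nuc_sd: float = 20.0
    mono_background: float = 0.2

    # marks / features
    n_genes: int = 600
    frac_enhancer: float = 0.4
    frac_active: float = 0.6
    se_tail_alpha: float = 1.2
    motif_frac: float = 0.3

    # interactions
    n_interactions: int = 2000
    umi_alphabet_size: int = 4096
    decoy_fraction: float = 0.1
    interaction_enrichment: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("coregulated_down", "rna_down_tss"): 5.0}
    )
    anchor_spacing: int = 5_000
    min_span: int = 5_000
    max_span: int = 1_000_000

    def __post_init__(self) -> None:
        total = sum(f for _, f, _ in self.cluster_spec)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cluster_spec fractions sum to {total}, expected 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if any(v <= 0 for v in self.nuc_spacing.values()):
            raise ValueError("dyad offsets must be positive")
        for n in (self.n_chrom, self.chrom_len, self.n_peaks, self.n_fragments, self.n_interactions):
            if n < 0:
                raise ValueError("counts must be non-negative")
        w = sum(w for _, _, w in self.frag_len_mix)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("fragment-length mixture weights must sum to 1")

    def rng(self, stream: str) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(ss[_STREAMS[stream]])

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    # -- flat YAML round-trip -------------------------------------------------
    def to_yaml(self, path) -> None:
        def _plain(x):
            if isinstance(x, dict):
                return {k: _plain(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [_plain(v) for v in x]
            if isinstance(x, np.generic):
                return x.item()
            return x

        d = asdict(self)
        d["interaction_enrichment"] = {
            f"{a}|{b}": v for (a, b), v in self.interaction_enrichment.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(d), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "interaction_enrichment" in d:
            d["interaction_enrichment"] = {
                tuple(k.split("|", 1)): float(v)
                for k, v in d["interaction_enrichment"].items()
            }
        for key in ("cluster_spec", "frag_len_mix"):
            if key in d:
                d[key] = [tuple(x) for x in d[key]]
        for key in ("lib_factor_range", "conditions"):
            if key in d:
                d[key] = tuple(d[key])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted truth emitted alongside each dataset."""

    peak_labels: np.ndarray | None = None          # cluster label per peak
    true_log2_effect: np.ndarray | None = None
    is_differential: np.ndarray | None = None
    dyad_offsets: dict[str, float] | None = None   # per condition
    enhancer_class: np.ndarray | None = None       # per K4me region
    enriched_pairs: dict[tuple[str, str], float] | None = None
    is_decoy: np.ndarray | None = None
    anchor_labels: list[str] | None = None


# ---------------------------------------------------------------------------
# peak counts
# ---------------------------------------------------------------------------


def simulate_peak_counts(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Two-condition, two-replicate NB peak count table with planted effects.

    Returns ``(peaks, CountMatrix, GroundTruth)``. Peaks occupy distinct
    1 kb slots so they never overlap; per-sample library factors are drawn
    uniform from ``lib_factor_range``; replicate counts are
    NB(mean = base x 2^effect x factor, dispersion = cfg.dispersion).
    """
    from .peaks import CountMatrix  # deferred: peaks imports FragmentSet only

    rng = rng if rng is not None else cfg.rng("peaks")
    chroms = cfg.chrom_names()
    slots_per_chrom = cfg.chrom_len // 1000
    total_slots = slots_per_chrom * cfg.n_chrom
    if cfg.n_peaks > total_slots:
        raise ValueError("too many peaks for the configured genome size")
    slot_ids = np.sort(rng.choice(total_slots, size=cfg.n_peaks, replace=False))
    chrom_idx = slot_ids // slots_per_chrom
    starts = (slot_ids % slots_per_chrom) * 1000 + (1000 - cfg.peak_width) // 2
    peaks = IntervalSet(
        GenomicInterval(chroms[c], int(s), int(s + cfg.peak_width))
        for c, s in zip(chrom_idx, starts)
    )
    peaks.is_sorted = True

    # planted classes: deterministic counts from fractions, shuffled placement
    labels = np.empty(cfg.n_peaks, dtype=object)
    effects = np.zeros(cfg.n_peaks)
    counts_per = [int(round(f * cfg.n_peaks)) for _, f, _ in cfg.cluster_spec]
    counts_per[-1] = cfg.n_peaks - sum(counts_per[:-1])
    pos = 0
    order = rng.permutation(cfg.n_peaks)
    for (label, _, eff), n in zip(cfg.cluster_spec, counts_per):
        idx = order[pos:pos + n]
        labels[idx] = label
        effects[idx] = eff
        pos += n

    base = np.exp(rng.normal(cfg.base_log_mean, cfg.base_log_sd, size=cfg.n_peaks))
    lo, hi = cfg.lib_factor_range
    sample_names, cols, lib = [], {}, {}
    meta = {}
    r = 1.0 / cfg.dispersion
    for cond in cfg.conditions:
        eff_factor = 2.0 ** effects if cond == cfg.conditions[1] else np.ones(cfg.n_peaks)
        for rep in range(1, cfg.n_replicates + 1):
            name = f"{cond}_rep{rep}"
            factor = rng.uniform(lo, hi)
            mean = base * eff_factor * factor
            cols[name] = rng.negative_binomial(r, r / (r + mean))
            lib[name] = float(cols[name].sum())
            meta[name] = {"condition": cond, "replicate": str(rep)}
            sample_names.append(name)

    cm = CountMatrix(
        peaks=peaks,
        counts=pd.DataFrame(cols),
        samples=pd.DataFrame.from_dict(meta, orient="index"),
        lib_sizes=pd.Series(lib),
    )
    truth = GroundTruth(
        peak_labels=labels,
        true_log2_effect=effects,
        is_differential=effects != 0,
    )
    return peaks, cm, truth


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

_MONO_RANGE = (150.0, 250.0)  # a mixture component with mean here is nucleosomal


def simulate_fragments(
    cfg: SimConfig,
    motifs: IntervalSet,
    condition: str,
    rng: np.random.Generator | None = None,
    n_fragments: int | None = None,
) -> FragmentSet:
    """Fragment-length mixture with planted flanking dyads around motifs.

    Mononucleosome-component fragments place their dyad Normal(+/-offset,
    ``nuc_sd``) around a random motif center (sign equiprobable), except
    for a ``mono_background`` fraction placed uniformly; sub-nucleosomal
    components are uniform over the chromosomes carrying motifs.
    """
    if len(motifs) == 0:
        raise ValueError("motif set is empty")
    if condition not in cfg.nuc_spacing:
        raise KeyError(f"no planted dyad offset for condition {condition!r}")
    rng = rng if rng is not None else cfg.rng("fragments")
    n = cfg.n_fragments if n_fragments is None else n_fragments
    if n == 0:
        return FragmentSet(np.array([], dtype=object), np.array([], dtype=np.int64),
                           np.array([], dtype=np.int64), condition)

    offset = cfg.nuc_spacing[condition]
    means = np.array([m for m, _, _ in cfg.frag_len_mix])
    sds = np.array([s for _, s, _ in cfg.frag_len_mix])
    weights = np.array([w for _, _, w in cfg.frag_len_mix])
    comp = rng.choice(len(means), size=n, p=weights)
    lengths = np.maximum(np.rint(rng.normal(means[comp], sds[comp])).astype(np.int64), 20)

    centers = np.array([m.midpoint for m in motifs], dtype=np.int64)
    motif_chroms = np.array([m.chrom for m in motifs], dtype=object)
    chrom_pool = np.unique(motif_chroms)

    is_mono = (means[comp] >= _MONO_RANGE[0]) & (means[comp] <= _MONO_RANGE[1])
    dyads = np.empty(n, dtype=np.int64)
    chroms = np.empty(n, dtype=object)

    # nucleosomal: planted flanking dyads with a uniform background admixture
    mono_idx = np.flatnonzero(is_mono)
    if len(mono_idx):
        pick = rng.integers(0, len(centers), size=len(mono_idx))
        sign = rng.choice([-1.0, 1.0], size=len(mono_idx))
        planted = centers[pick] + np.rint(
            rng.normal(sign * offset, cfg.nuc_sd)
        ).astype(np.int64)
        bg = rng.random(len(mono_idx)) < cfg.mono_background
        planted[bg] = rng.integers(0, cfg.chrom_len, size=int(bg.sum()))
        dyads[mono_idx] = planted
        chroms[mono_idx] = motif_chroms[pick]
        chroms[mono_idx[bg]] = rng.choice(chrom_pool, size=int(bg.sum()))

    sub_idx = np.flatnonzero(~is_mono)
    if len(sub_idx):
        dyads[sub_idx] = rng.integers(0, cfg.chrom_len, size=len(sub_idx))
        chroms[sub_idx] = rng.choice(chrom_pool, size=len(sub_idx))

    starts = np.maximum(dyads - lengths // 2, 0)
    return FragmentSet(chroms, starts, starts + lengths, condition)


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------


def simulate_gene_annotation(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Random gene models and the genomic-element partition they imply.

    Returns ``(TssAnnotation, element_sets)`` where ``element_sets`` maps
    category -> IntervalSet for promoter (TSS +/- 1 kb), TTS (transcript
    end +/- 1 kb), 5'/3' UTRs, exons, and introns. Genes are laid out on
    disjoint slots so transcripts never overlap.
    """
    rng = rng if rng is not None else cfg.rng("genes")
    chroms = cfg.chrom_names()
    slot = 50_000  # gene footprint ceiling, keeps transcripts disjoint
    per_chrom = cfg.chrom_len // slot
    if cfg.n_genes > per_chrom * cfg.n_chrom:
        raise ValueError("too many genes for the configured genome size")
    slot_ids = np.sort(rng.choice(per_chrom * cfg.n_chrom, size=cfg.n_genes, replace=False))

    tss_ivs = []
    elements: dict[str, list[GenomicInterval]] = {
        k: [] for k in ("promoter", "TTS", "5UTR", "3UTR", "exon", "intron")
    }
    for gi, sid in enumerate(slot_ids):
        chrom = chroms[sid // per_chrom]
        base = (sid % per_chrom) * slot + 2000
        length = int(rng.integers(5_000, 40_000))
        strand = "+" if rng.random() < 0.5 else "-"
        g_start, g_end = base, base + length
        gene = f"gene{gi:05d}"
        tss_pos = g_start if strand == "+" else g_end - 1
        tts_pos = g_end - 1 if strand == "+" else g_start
        tss_ivs.append(GenomicInterval(chrom, tss_pos, tss_pos + 1, strand, name=gene))
        elements["promoter"].append(
            GenomicInterval(chrom, max(tss_pos - 1000, 0), tss_pos + 1000)
        )
        elements["TTS"].append(
            GenomicInterval(chrom, max(tts_pos - 1000, 0), tts_pos + 1000)
        )
        # three exons: first/last carry the UTRs
        n_ex = 3
        bounds = np.sort(rng.choice(np.arange(1, length - 1), size=2 * n_ex - 2, replace=False))
        edges = np.concatenate(([0], bounds, [length])) + g_start
        exons = [(int(edges[2 * i]), int(edges[2 * i + 1])) for i in range(n_ex)]
        introns = [(int(edges[2 * i + 1]), int(edges[2 * i + 2])) for i in range(n_ex - 1)]
        for s, e in exons:
            if e > s:
                elements["exon"].append(GenomicInterval(chrom, s, e))
        for s, e in introns:
            if e > s:
                elements["intron"].append(GenomicInterval(chrom, s, e))
        first, last = exons[0], exons[-1]
        utr5, utr3 = (first, last) if strand == "+" else (last, first)
        s, e = utr5
        elements["5UTR"].append(GenomicInterval(chrom, s, min(s + 200, e)))
        s, e = utr3
        elements["3UTR"].append(GenomicInterval(chrom, max(e - 300, s), e))

    element_sets = {k: IntervalSet(v).sorted() for k, v in elements.items()}
    return TssAnnotation(IntervalSet(tss_ivs).sorted()), element_sets


# ---------------------------------------------------------------------------
# histone marks / features
# ---------------------------------------------------------------------------


def simulate_marks_and_features(
    cfg: SimConfig,
    peaks: IntervalSet,
    tss: TssAnnotation,
    rng: np.random.Generator | None = None,
):
    """Histone-mark and factor-binding sets consistent with the enhancer taxonomy.

    A ``frac_enhancer`` fraction of TSS-distal peaks (> 2 kb away) receives
    a 2 kb H3K4me region; ``frac_active`` of those also receive an
    overlapping H3K27ac region whose score is drawn from a Pareto tail
    (shape ``se_tail_alpha``) so that a small top fraction forms a
    super-enhancer elbow. H3K4me3 regions are placed at gene TSSs; motif
    sites (8 bp) and SWI/SNF- and AP-1-binding regions are placed at subsets
    of peak centers. Returns ``(feature_sets, GroundTruth)``.
    """
    from .core import nearest_tss

    rng = rng if rng is not None else cfg.rng("marks")
    ann = nearest_tss(peaks, tss)
    dist_ok = (~ann["unannotated"]) & (ann["distance"].abs() > 2000)
    distal_idx = np.flatnonzero(dist_ok.to_numpy())

    n_enh = int(round(cfg.frac_enhancer * len(distal_idx)))
    enh_idx = rng.choice(distal_idx, size=n_enh, replace=False) if n_enh else np.array([], dtype=int)
    n_active = int(round(cfg.frac_active * n_enh))
    active_mask = np.zeros(n_enh, dtype=bool)
    if n_active:
        active_mask[rng.choice(n_enh, size=n_active, replace=False)] = True

    k4me, k27ac = [], []
    classes = np.empty(n_enh, dtype=object)
    peak_list = list(peaks)
    for j, (pi, act) in enumerate(zip(enh_idx, active_mask)):
        c = peak_list[pi].midpoint
        chrom = peak_list[pi].chrom
        k4me.append(GenomicInterval(chrom, max(c - 1000, 0), c + 1000))
        classes[j] = "active" if act else "poised"
        if act:
            score = 10.0 * (1.0 + rng.pareto(cfg.se_tail_alpha))
            k27ac.append(GenomicInterval(chrom, max(c - 800, 0), c + 800, score=float(score)))

    k4me3 = IntervalSet(
        GenomicInterval(iv.chrom, max(iv.start - 500, 0), iv.start + 500)
        for iv in tss.tss
        if rng.random() < 0.8
    ).sorted()

    n_motif = int(round(cfg.motif_frac * len(peaks)))
    motif_idx = np.sort(rng.choice(len(peaks), size=n_motif, replace=False)) if n_motif else []
    motifs = IntervalSet(
        GenomicInterval(peak_list[i].chrom, peak_list[i].midpoint - 4, peak_list[i].midpoint + 4)
        for i in motif_idx
    ).sorted()

    def _factor_set(frac: float) -> IntervalSet:
        n = int(round(frac * len(peaks)))
        idx = np.sort(rng.choice(len(peaks), size=n, replace=False)) if n else []
        return IntervalSet(
            GenomicInterval(peak_list[i].chrom, max(peak_list[i].midpoint - 200, 0),
                            peak_list[i].midpoint + 200)
            for i in idx
        ).sorted()

    features = {
        "k4me": IntervalSet(k4me).sorted(),
        "k4me3": k4me3,
        "k27ac": IntervalSet(k27ac).sorted(),
        "motifs": motifs,
        "swisnf": _factor_set(0.4),
        "fra1": _factor_set(0.35),
    }
    truth = GroundTruth(enhancer_class=classes)
    return features, truth


# ---------------------------------------------------------------------------
# interactions
# ---------------------------------------------------------------------------


def grid_feature_anchors(
    categories: dict[str, int],
    n_unlabeled: int,
    spacing: int = 5_000,
    block_len: int = 1_000_000,
    anchor_width: int = 500,
    chrom_prefix: str = "chr",
    rng: np.random.Generator | None = None,
) -> IntervalSet:
    """Labeled anchor features on a regular grid with valid pairwise spans.

    Anchors are spaced ``spacing`` bp apart within per-chromosome blocks of
    ``block_len`` bp, so any same-chromosome anchor pair has a span inside
    [spacing, block_len]. Category labels are assigned to grid points at
    random (label placement independent of geometry); unlabeled anchors get
    name ``None``.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    n_total = sum(categories.values()) + n_unlabeled
    per_block = block_len // spacing
    labels: list[str | None] = sum(
        ([lab] * n for lab, n in categories.items()), []
    ) + [None] * n_unlabeled
    rng.shuffle(labels)
    ivs = []
    for i, lab in enumerate(labels):
        chrom = f"{chrom_prefix}{i // per_block + 1}"
        center = (i % per_block) * spacing + spacing // 2
        ivs.append(
            GenomicInterval(chrom, max(center - anchor_width // 2, 0),
                            center + anchor_width // 2, name=lab)
        )
    return IntervalSet(ivs).sorted()


def _solve_forced_pairs(n_pairs: int, n_a: int, n_b: int, n_anchors: int, factor: float) -> int:
    """Number of forced A-B pairs so observed/shuffle-expected ~= factor.

    Forcing inflates the label frequencies among endpoint slots, which in
    turn inflates the shuffle expectation, so the achievable enrichment
    saturates near 1 / (4 q (1-q)) for label frequency q. The smallest m
    reaching the requested factor is found numerically; an unreachable
    factor raises, pointing at the label frequencies.
    """
    qa, qb = n_a / n_anchors, n_b / n_anchors

    def ratio(m: float) -> float:
        nb_ = n_pairs - m
        obs = m + 2 * nb_ * qa * qb
        sa = (m + 2 * nb_ * qa) / (2 * n_pairs)
        sb = (m + 2 * nb_ * qb) / (2 * n_pairs)
        return obs / (2 * n_pairs * sa * sb)

    if factor <= 1.0:
        return 0
    grid = np.linspace(0.0, n_pairs, 512)
    vals = np.array([ratio(m) for m in grid])
    above = np.flatnonzero(vals >= factor)
    if len(above) == 0:
        raise ValueError(
            f"requested enrichment {factor:.3g} exceeds the achievable maximum "
            f"{vals.max():.3g} at these label frequencies (qa={qa:.3g}, qb={qb:.3g}); "
            "use rarer labels or a smaller factor"
        )
    j = above[0]
    if j == 0:
        return 0
    return int(round(brentq(lambda m: ratio(m) - factor, grid[j - 1], grid[j])))


def _random_umis(rng: np.random.Generator, n: int, alphabet_size: int) -> np.ndarray:
    width = max(len(np.base_repr(max(alphabet_size - 1, 1), base=4)), 1)
    codes = rng.integers(0, alphabet_size, size=n)
    trans = str.maketrans("0123", "ACGT")
    return np.array(
        [np.base_repr(c, base=4).zfill(width).translate(trans) for c in codes], dtype=object
    )


def simulate_interactions(
    cfg: SimConfig,
    features: IntervalSet,
    rng: np.random.Generator | None = None,
):
    """Anchor pairs with UMIs, planted pairwise enrichment, and decoys.

    ``features`` is a labeled anchor set (``name`` = category or None),
    typically from :func:`grid_feature_anchors` so that all same-chromosome
    spans are valid. For each planted pair (A, B) with factor f, enough
    A-B endpoint pairs are forced so that the observed count is f times
    the label-shuffle expectation; the remaining pairs draw endpoints
    uniformly (rejecting pairs whose span falls outside
    [min_span, max_span]). A ``decoy_fraction`` of interactions instead
    violates the span window or carries mismatched UMIs. Returns
    ``(InteractionSet, GroundTruth)``.
    """
    from .interactions import InteractionSet

    rng = rng if rng is not None else cfg.rng("interactions")
    anchors = list(features)
    n_anchors = len(anchors)
    if n_anchors < 2:
        raise ValueError("need at least two anchor features")
    labels = [iv.name for iv in anchors]
    chrom_arr = np.array([iv.chrom for iv in anchors], dtype=object)
    mids = np.array([iv.midpoint for iv in anchors], dtype=np.int64)

    n_decoy = int(rng.binomial(cfg.n_interactions, cfg.decoy_fraction))
    n_valid = cfg.n_interactions - n_decoy

    def _span_ok(i: int, j: int) -> bool:
        return (
            i != j
            and chrom_arr[i] == chrom_arr[j]
            and cfg.min_span <= abs(int(mids[i]) - int(mids[j])) <= cfg.max_span
        )

    def _draw_pair(pool_i: np.ndarray, pool_j: np.ndarray) -> tuple[int, int]:
        for _ in range(10_000):
            i = int(pool_i[rng.integers(0, len(pool_i))])
            j = int(pool_j[rng.integers(0, len(pool_j))])
            if _span_ok(i, j):
                return i, j
        raise RuntimeError("could not draw a span-valid anchor pair; check anchor layout")

    label_idx: dict[str, np.ndarray] = {}
    for lab in set(l for l in labels if l is not None):
        label_idx[lab] = np.flatnonzero(np.array([l == lab for l in labels]))
    all_idx = np.arange(n_anchors)

    pairs: list[tuple[int, int]] = []
    remaining = n_valid
    for (a, b), f in cfg.interaction_enrichment.items():
        if a not in label_idx or b not in label_idx:
            raise KeyError(f"planted pair ({a}, {b}) not present among feature labels")
        m = _solve_forced_pairs(n_valid, len(label_idx[a]), len(label_idx[b]), n_anchors, f)
        m = min(m, remaining)
        for _ in range(m):
            pairs.append(_draw_pair(label_idx[a], label_idx[b]))
        remaining -= m
    for _ in range(remaining):
        pairs.append(_draw_pair(all_idx, all_idx))
    order = rng.permutation(len(pairs))
    pairs = [pairs[k] for k in order]

    umis = _random_umis(rng, cfg.n_interactions, cfg.umi_alphabet_size)
    recs = []
    is_decoy = np.zeros(cfg.n_interactions, dtype=bool)
    for k, (i, j) in enumerate(pairs):
        a, b = (i, j) if (chrom_arr[i], mids[i]) <= (chrom_arr[j], mids[j]) else (j, i)
        recs.append(
            (chrom_arr[a], anchors[a].start, anchors[a].end,
             chrom_arr[b], anchors[b].start, anchors[b].end, umis[k], umis[k])
        )
    # decoys: half span-violating (same UMI), half UMI-mismatched (valid span)
    for k in range(n_valid, cfg.n_interactions):
        is_decoy[k] = True
        i = int(rng.integers(0, n_anchors))
        if rng.random() < 0.5:
            # span below the window: second anchor offset < min_span
            off = int(rng.integers(600, cfg.min_span - 100))
            recs.append(
                (chrom_arr[i], anchors[i].start, anchors[i].end,
                 chrom_arr[i], anchors[i].start + off, anchors[i].end + off,
                 umis[k], umis[k])
            )
        else:
            j = i
            while not _span_ok(i, j):
                j = int(rng.integers(0, n_anchors))
            other = _random_umis(rng, 1, cfg.umi_alphabet_size)[0]
            while other == umis[k]:
                other = _random_umis(rng, 1, cfg.umi_alphabet_size)[0]
            a, b = (i, j) if (chrom_arr[i], mids[i]) <= (chrom_arr[j], mids[j]) else (j, i)
            recs.append(
                (chrom_arr[a], anchors[a].start, anchors[a].end,
                 chrom_arr[b], anchors[b].start, anchors[b].end, umis[k], other)
            )

    df = pd.DataFrame(
        recs,
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "umi1", "umi2"],
    )
    truth = GroundTruth(
        enriched_pairs=dict(cfg.interaction_enrichment),
        is_decoy=is_decoy,
        anchor_labels=[l if l is not None else "" for l in labels],
    )
    return InteractionSet(df), truth
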