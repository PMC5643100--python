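"""End-to-end orchestration: the co-regulated-site cascade, per-cluster
expression summaries, headline percentages, and the full demo pipeline.

The cascade reproduces the intersection chain used to define co-regulated
sites: accessibility-down sites are successively intersected with
remodeler-bound regions, acetylation-down regions, and AP-1-bound regions,
and the survivors are annotated to their nearest TSS and intersected with
the differentially downregulated gene set.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import clustering, enhancers, interactions, nucspacing, peaks as peaks_mod, simulate
from .core import IntervalSet, TssAnnotation, nearest_tss, overlap_sets, write_bed

__all__ = [
    "CascadeReport",
    "ExpressionTable",
    "coregulation_cascade",
    "percent_changed",
    "expression_fold_by_cluster",
    "run_pipeline",
]


@dataclass
class CascadeReport:
    """Surviving-site counts along the intersection chain, plus final genes."""

    stage_names: list[str]
    stage_counts: list[int]
    genes: set[str] = field(default_factory=set)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # the final stage is a gene count; it may not exceed the site count
        # that produced it, and site counts are non-increasing along the chain
        if any(b > a for a, b in zip(self.stage_counts, self.stage_counts[1:])):
            raise ValueError("cascade counts must be non-increasing")

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.stage_names, self.stage_counts))


@dataclass
class ExpressionTable:
    """Gene-level FPKM per sample with condition labels (consumed, not computed)."""

    fpkm: pd.DataFrame            # index: gene id; columns: sample names
    conditions: pd.Series         # index: sample names -> condition label

    def __post_init__(self) -> None:
        if (self.fpkm.values < 0).any():
            raise ValueError("FPKM values must be non-negative")
        missing = set(self.fpkm.columns) - set(self.conditions.index)
        if missing:
            raise ValueError(f"samples without condition labels: {sorted(missing)}")

    def condition_mean(self, condition: str) -> pd.Series:
        cols = [s for s in self.fpkm.columns if self.conditions[s] == condition]
        if not cols:
            raise ValueError(f"no samples for condition {condition!r}")
        return self.fpkm[cols].mean(axis=1)


def percent_changed(n_subset: int, n_total: int, decimals: int = 1) -> float:
    """Percentage of a total, rounded half-away-from-zero at ``decimals``.

    percent_changed(12623, 101140) -> 12.5; percent_changed(n, n) -> 100.0.
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if n_subset > n_total:
        raise ValueError("n_subset exceeds n_total")
    value = 100.0 * n_subset / n_total
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(value) * factor + 0.5), value) / factor


def coregulation_cascade(
    atac_down: IntervalSet,
    swisnf_bound: IntervalSet,
    k27ac_down: IntervalSet,
    fra1_bound: IntervalSet,
    de_down_genes: set[str],
    tss: TssAnnotation,
) -> CascadeReport:
    """Sequentially intersect accessibility-down sites with binding/mark sets.

    Stages: atac_down -> overlap(>=1 bp) remodeler-bound -> overlap
    acetylation-down -> overlap AP-1-bound -> nearest-TSS genes intersected
    with the downregulated gene set. The final stage reports a gene count.
    """

    def _surviving(current: IntervalSet, other: IntervalSet) -> IntervalSet:
        if len(current) == 0:
            return current
        hits = overlap_sets(current, other).hits
        return IntervalSet(iv for iv, h in zip(current, hits) if h)

    s0 = atac_down
    s1 = _surviving(s0, swisnf_bound)
    s2 = _surviving(s1, k27ac_down)
    s3 = _surviving(s2, fra1_bound)
    if len(s3):
        ann = nearest_tss(s3, tss)
        genes = set(ann.loc[~ann["unannotated"], "gene_id"]) & set(de_down_genes)
    else:
        genes = set()
    return CascadeReport(
        stage_names=[
            "atac_down",
            "swisnf_bound",
            "k27ac_down",
            "fra1_bound",
            "rna_down_genes",
        ],
        stage_counts=[len(s0), len(s1), len(s2), len(s3), len(genes)],
        genes=genes,
    )


def expression_fold_by_cluster(
    assign: clustering.ClusterAssignment,
    expr: ExpressionTable,
    peak_set: IntervalSet,
    tss: TssAnnotation,
    condition: str,
    reference: str,
    top_fraction: float = 0.25,
    baseline_cluster: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster log2 expression fold changes of nearest genes.

    Peaks are annotated to their nearest gene; within each cluster only
    genes in the top ``top_fraction`` by reference-condition FPKM are kept,
    and per-gene log2((FPKM_cond + 0.5) / (FPKM_ref + 0.5)) is computed.
    Each cluster is compared with ``baseline_cluster`` (default: the
    largest cluster) by a two-sided Wilcoxon rank-sum test, BH-corrected
    across clusters. Returns (per-gene table, per-cluster summary).
    """
    ann = nearest_tss(peak_set, tss)
    ref = expr.condition_mean(reference)
    cond = expr.condition_mean(condition)
    rows = []
    for cluster in range(1, assign.k + 1):
        idx = assign.members(cluster)
        genes = sorted(
            {
                g
                for g in ann.iloc[idx]["gene_id"]
                if g is not None and g in expr.fpkm.index
            }
        )
        if not genes:
            continue
        ref_vals = ref.loc[genes]
        n_keep = max(int(math.ceil(top_fraction * len(genes))), 1)
        top = ref_vals.sort_values(ascending=False).index[:n_keep]
        lfc = np.log2((cond.loc[top] + 0.5) / (ref.loc[top] + 0.5))
        for g, v in lfc.items():
            rows.append({"cluster": cluster, "gene_id": g, "log2fc": float(v)})
    gene_table = pd.DataFrame(rows, columns=["cluster", "gene_id", "log2fc"])

    if baseline_cluster is None:
        sizes = {c: len(assign.members(c)) for c in range(1, assign.k + 1)}
        baseline_cluster = max(sizes, key=lambda c: (sizes[c], -c))
    base = gene_table.loc[gene_table["cluster"] == baseline_cluster, "log2fc"]
    summaries = []
    for cluster, grp in gene_table.groupby("cluster"):
        if cluster == baseline_cluster or len(base) == 0 or len(grp) == 0:
            p = np.nan
        else:
            p = stats.ranksums(grp["log2fc"], base).pvalue
        summaries.append(
            {
                "cluster": cluster,
                "n_genes": len(grp),
                "median_log2fc": float(grp["log2fc"].median()),
                "p": p,
            }
        )
    summary = pd.DataFrame(summaries)
    tested = summary["p"].notna()
    summary["q"] = np.nan
    if tested.any():
        summary.loc[tested, "q"] = peaks_mod.bh_adjust(summary.loc[tested, "p"].to_numpy())
    return gene_table, summary


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def _simulate_expression(
    cfg: simulate.SimConfig,
    tss: TssAnnotation,
    down_sites: IntervalSet,
    up_sites: IntervalSet,
) -> tuple[ExpressionTable, set[str], set[str]]:
    """FPKM table where genes nearest to changed sites shift accordingly."""
    rng = cfg.rng("expression")
    genes = sorted({iv.name for iv in tss.tss})
    base = np.exp(rng.normal(np.log(20.0), 1.0, size=len(genes)))
    effect = pd.Series(0.0, index=genes)
    for sites, eff in ((down_sites, -1.5), (up_sites, 1.5)):
        if len(sites) == 0:
            continue
        ann = nearest_tss(sites, tss)
        hit = [g for g in ann.loc[~ann["unannotated"], "gene_id"] if g is not None]
        effect.loc[sorted(set(hit))] = eff
    cols = {}
    conds = {}
    for cond in cfg.conditions:
        mult = 2.0 ** effect.to_numpy() if cond == cfg.conditions[1] else 1.0
        for rep in (1, 2):
            name = f"{cond}_rna{rep}"
            noise = np.exp(rng.normal(0.0, 0.1, size=len(genes)))
            cols[name] = base * mult * noise
            conds[name] = cond
    table = ExpressionTable(
        fpkm=pd.DataFrame(cols, index=genes), conditions=pd.Series(conds)
    )
    de_down = set(effect.index[effect < 0])
    de_up = set(effect.index[effect > 0])
    return table, de_down, de_up


def run_pipeline(cfg: simulate.SimConfig, outdir, k: int = 7, n_perm: int = 200) -> dict:
    """Run every stage on synthetic data and write all outputs to ``outdir``.

    Stages execute in dependency order: simulate -> differential peaks ->
    tag-density clustering -> enhancer taxonomy and element enrichment ->
    nucleosome spacing -> interaction enrichment -> co-regulation cascade.
    A machine-readable ``summary.json`` (headline counts and percentages,
    parameters, master seed) is written last; reruns with the same config
    are bit-identical.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    # 1. genome annotation + peak counts + differential calls
    tss, element_sets = simulate.simulate_gene_annotation(cfg)
    peak_set, cm, truth = simulate.simulate_peak_counts(cfg)
    diff = peaks_mod.differential_peaks(cm, *cfg.conditions)
    diff.to_tsv(out / "differential_peaks.tsv")
    down = diff.called("down")
    up = diff.called("up")
    n_total = len(peak_set)
    pct_down = percent_changed(len(down), n_total)
    pct_up = percent_changed(len(up), n_total)

    # 2. clustering of tag-density change profiles
    cond_a, cond_b = cfg.conditions
    marks, _ = simulate.simulate_marks_and_features(cfg, peak_set, tss)
    frag_a = simulate.simulate_fragments(cfg, marks["motifs"], cond_a, cfg.rng("fragments"))
    frag_b = simulate.simulate_fragments(
        cfg, marks["motifs"], cond_b, np.random.default_rng((cfg.seed + 104729) % 2**31)
    )
    td_a = clustering.tag_density(peak_set, frag_a, condition=cond_a)
    td_b = clustering.tag_density(peak_set, frag_b, condition=cond_b)
    change = np.log2((td_b.values + 0.5) / (td_a.values + 0.5))
    stacked = np.hstack([td_a.values, change])
    assign = clustering.kmeans_centered_correlation(stacked, k=min(k, len(peak_set)), seed=cfg.seed)
    assign.to_tsv(peak_set, out / "cluster_assignments.tsv")
    profiles = clustering.cluster_condition_profiles(assign, {cond_a: td_a, cond_b: td_b})
    profiles.to_csv(out / "cluster_profiles.tsv", sep="\t", index=False)

    # 3. enhancer taxonomy + element enrichment
    classification = enhancers.classify_enhancers(
        marks["k4me"], marks["k4me3"], marks["k27ac"], tss
    )
    classification.to_tsv(out / "enhancer_classes.tsv")
    class_counts = classification.table["enhancer_class"].value_counts().to_dict()
    ann = enhancers.ElementAnnotation(element_sets)
    enrich_tables = {}
    for label, sites in (("decreased", down), ("increased", up)):
        if len(sites):
            tbl = enhancers.element_enrichment(sites, ann, peak_set)
            tbl.to_csv(out / f"element_enrichment_{label}.tsv", sep="\t", index=False)
            enrich_tables[label] = tbl

    # 4. nucleosome spacing around motifs
    estimates = {}
    for cond, frag in ((cond_a, frag_a), (cond_b, frag_b)):
        mono = nucspacing.select_mononucleosome(frag)
        prof = nucspacing.dyad_profile(mono, marks["motifs"], bandwidth=10.0, condition=cond)
        prof.to_frame().to_csv(out / f"dyad_profile_{cond}.tsv", sep="\t", index=False)
        estimates[cond] = nucspacing.estimate_spacing(prof)
    spacing = nucspacing.spacing_delta(estimates, reference=cond_a)
    spacing.to_csv(out / "nucleosome_spacing.tsv", sep="\t", index=False)

    # 5. interaction enrichment
    anchor_rng = cfg.rng("interactions")
    # rare planted categories: the achievable enrichment factor falls with
    # label frequency, so the planted pair's categories stay below ~4%
    feature_counts = {
        "coregulated_down": 15, "atac_down": 40, "atac_up": 40,
        "k27ac_down": 40, "k27ac_up": 40, "rna_down_tss": 15, "rna_up_tss": 40,
    }
    anchors = simulate.grid_feature_anchors(
        feature_counts, n_unlabeled=170, spacing=cfg.anchor_spacing, rng=anchor_rng
    )
    raw_ints, int_truth = simulate.simulate_interactions(cfg, anchors, anchor_rng)
    raw_ints.to_bedpe(out / "interactions_raw.bedpe")
    kept = interactions.filter_interactions(raw_ints)
    catalog = interactions.FeatureCatalog(
        {
            lab: IntervalSet([iv for iv in anchors if iv.name == lab]).sorted()
            for lab in feature_counts
        }
    )
    assigned = interactions.assign_endpoints(kept, catalog)
    em = interactions.pairwise_enrichment(assigned, n_perm=n_perm, seed=cfg.seed)
    em.to_tsv(out / "interaction_enrichment.tsv")

    # 6. co-regulation cascade
    expr, de_down, de_up = _simulate_expression(cfg, tss, down, up)
    cascade = coregulation_cascade(
        down, marks["swisnf"], marks["k27ac"], marks["fra1"], de_down, tss
    )
    gene_table, cluster_expr = expression_fold_by_cluster(
        assign, expr, peak_set, tss, condition=cond_b, reference=cond_a
    )
    cluster_expr.to_csv(out / "cluster_expression.tsv", sep="\t", index=False)

    write_bed(down, out / "sites_down.bed")
    write_bed(up, out / "sites_up.bed")

    summary = {
        "seed": cfg.seed,
        "n_peaks": n_total,
        "n_down": len(down),
        "n_up": len(up),
        "pct_down": pct_down,
        "pct_up": pct_up,
        "enhancer_classes": {k_: int(v) for k_, v in class_counts.items()},
        "spacing": {
            r["condition"]: {"spacing": int(r["spacing"]), "delta": int(r["delta_vs_reference"])}
            for _, r in spacing.iterrows()
        },
        "cascade": cascade.as_dict(),
        "n_interactions_kept": len(kept),
        "clusters": {str(c): int(np.sum(assign.labels == c)) for c in range(1, assign.k + 1)},
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
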