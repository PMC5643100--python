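# chromarc

Regulatory-chromatin analysis of remodeler-dependent accessibility, written
for epigenomics analysts who want a tested, reusable reimplementation of a
classic ATAC-seq / ChIP-seq / ChIA-PET analysis stack — with a synthetic-data
generator that emits ground truth, so every estimator can be validated
without touching raw sequencing data.

The motivating biology: BAF (SWI/SNF) chromatin-remodeling complexes keep
enhancer chromatin open. When the remodeler's targeting subunits are lost,
thousands of accessible sites collapse, the nucleosomes flanking AP-1
transcription-factor motifs slide inward, acetylation at active enhancers
drops, and looping interactions from those enhancers to promoters stop
paying off in transcription. `chromarc` implements each step of that
analysis chain.

## What it computes

| Stage | Method |
| --- | --- |
| Peak calling | sliding windows > 4-fold over 10 kb local background (ATAC); plus > 2-fold over input and Poisson BH-FDR < 0.001, 1 kb stitching (ChIP) |
| Differential accessibility | NB exact-style test with a moderated common dispersion; calls at \|log2 FC\| ≥ log2 1.5 and BH q < 0.05 |
| Profile clustering | k-means with centred-Pearson distance (1 − r) on tag-density matrices (peak centre ± 500 bp, 10 bp bins, fragments-per-10M) |
| Enhancer taxonomy | H3K4me regions > 1 kb from TSS and H3K4me3 → poised (H3K27ac−) / active (H3K27ac+); super-enhancers by the rank-curve tangent cutoff (first discrete slope > 1 on the unit-rescaled curve) |
| Element enrichment | observed/expected site counts over promoter/UTR/exon/intron/TTS/intergenic with background composition as the null |
| Nucleosome spacing | 180–247 bp fragments → midpoint dyads → mean dyad density per motif at 1 bp resolution → distance between flanking density maxima |
| Interaction enrichment | BEDPE anchors filtered to 5 kb–1 Mb spans with matching UMIs; endpoints labelled by features within 3 kb; observed vs label-shuffle expectation over all potential endpoints (permutation z and empirical p) |
| Co-regulation cascade | ATAC-down ∩ remodeler-bound ∩ H3K27ac-down ∩ AP-1-bound → nearest-TSS genes ∩ RNA-down |

For the differential test, per-peak counts are library-normalized and summed
per condition; under the null the split of the total between conditions
follows the normalized product of the two group-sum NB pmfs
(sum of n i.i.d. NB(μ, 1/φ) is NB(nμ, n/φ)), and the two-sided p-value sums
all splits no more likely than the observed one. The common dispersion φ is
the median of per-peak method-of-moments estimates after a χ²-median bias
correction of the pooled replicate variances.

## Worked example

```python
from chromarc.simulate import SimConfig
from chromarc.pipeline import run_pipeline

cfg = SimConfig(seed=1, n_peaks=1000, n_genes=300,
                n_fragments=20_000, n_interactions=2000)
summary = run_pipeline(cfg, "out/")
print(summary["pct_down"], summary["pct_up"])     # 11.6 5.1
print(summary["spacing"])
# {'WT': {'spacing': 240, 'delta': 0}, 'KO': {'spacing': 203, 'delta': -37}}
print(summary["cascade"])
# {'atac_down': 116, 'swisnf_bound': 41, 'k27ac_down': 13,
#  'fra1_bound': 6, 'rna_down_genes': 5}
```

At this demo scale the generator plants a 12.5% loss / 5.2% gain structure
(the caller recovers 11.6% / 5.1% at q < 0.05), flanking nucleosome dyads
at ±120 bp in the intact condition vs ±101 bp in the deficient one (the
estimator reports spacings 240 vs 203 bp, a 37 bp loss), and the cascade
counts shrink monotonically down to the co-regulated gene set.

The same pipeline is scriptable from the shell:

```bash
chromarc run-all --seed 1 --outdir out/          # everything + summary.json
chromarc simulate --seed 1 --outdir sim/         # synthetic inputs + truth
chromarc diff --counts sim/counts.tsv --cond-a WT --cond-b KO --out diff.tsv
chromarc nucspacing --fragments WT=wt.bed --fragments KO=ko.bed \
    --motifs motifs.bed --reference WT --out spacing.tsv
```

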