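"""Enhancer taxonomy, super-enhancer tangent cutoff, element enrichment."""

import numpy as np
import pytest

from chromarc.core import GenomicInterval, IntervalSet, TssAnnotation
from chromarc.enhancers import (
    ElementAnnotation,
    call_super_enhancers,
    classify_enhancers,
    element_enrichment,
)


def _tss(positions, chrom="chr1"):
    return TssAnnotation(
        IntervalSet(
            GenomicInterval(chrom, p, p + 1, "+", name=f"g{i:03d}")
            for i, p in enumerate(positions)
        ).sorted()
    )


def _iset(spans, chrom="chr1", scores=None):
    scores = scores if scores is not None else [None] * len(spans)
    return IntervalSet(
        GenomicInterval(chrom, s, e, score=sc) for (s, e), sc in zip(spans, scores)
    ).sorted()


def brute_force_super(scores):
    """Exhaustive first-slope>1 scan over the unit-rescaled ascending curve."""
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    order = np.argsort(scores, kind="stable")
    y = (scores[order] - scores.min()) / np.ptp(scores)
    mask = np.zeros(n, dtype=bool)
    for i in range(n - 1):
        slope = (y[i + 1] - y[i]) / (1.0 / (n - 1))
        if slope > 1.0 + 1e-9:
            mask[order[i + 1:]] = True
            break
    return mask


class TestClassifyEnhancers:
    def test_region_too_close_to_tss_is_excluded(self):
        tss = _tss([10_000])
        # region edge 500 bp from the TSS: not an enhancer
        k4me = _iset([(10_500 + 1, 12_000)])
        k4me_close = _iset([(8_000, 9_500)])  # gap 501 bp
        cls = classify_enhancers(k4me_close, _iset([]), _iset([]), tss)
        assert not cls.table["is_enhancer"].iloc[0]
        far = _iset([(12_000, 14_000)])  # gap 2001 bp
        cls2 = classify_enhancers(far, _iset([]), _iset([]), tss)
        assert cls2.table["is_enhancer"].iloc[0]

    def test_k4me3_proximity_also_excludes(self):
        tss = _tss([100_000])
        k4me = _iset([(10_000, 12_000)])
        k4me3_near = _iset([(12_500, 13_500)])  # gap 500
        cls = classify_enhancers(k4me, k4me3_near, _iset([]), tss)
        assert not cls.table["is_enhancer"].iloc[0]

    def test_poised_vs_active_by_k27ac_overlap(self):
        tss = _tss([100_000])
        k4me = _iset([(10_000, 12_000), (20_000, 22_000)])
        k27ac = _iset([(11_500, 12_500)], scores=[5.0])  # overlaps first only
        cls = classify_enhancers(k4me, _iset([]), k27ac, tss)
        assert cls.table["enhancer_class"].tolist() == ["active_enhancer", "poised_enhancer"]
        assert cls.table["score"].iloc[0] == 5.0

    def test_empty_k4me_yields_empty_classification(self):
        cls = classify_enhancers(_iset([]), _iset([]), _iset([]), _tss([100]))
        assert len(cls.table) == 0

    def test_matches_brute_force_rule_evaluation(self, rng):
        tss_pos = sorted(rng.choice(500_000, size=30, replace=False).tolist())
        tss = _tss(tss_pos)
        k4me = _iset(
            [(int(s), int(s + rng.integers(500, 3000))) for s in rng.integers(0, 490_000, 100)]
        )
        k4me3 = _iset(
            [(int(s), int(s + 1000)) for s in rng.integers(0, 490_000, 40)]
        )
        k27ac = _iset(
            [(int(s), int(s + rng.integers(300, 2000))) for s in rng.integers(0, 490_000, 60)],
            scores=rng.random(60).tolist(),
        )
        cls = classify_enhancers(k4me, k4me3, k27ac, tss)

        def gap_point(iv, p):
            return 0 if iv.start <= p < iv.end else (iv.start - p if p < iv.start else p - iv.end + 1)

        def gap_region(iv, o):
            if iv.start < o.end and o.start < iv.end:
                return 0
            return o.start - iv.end if o.start >= iv.end else iv.start - o.end

        for i, iv in enumerate(sorted(k4me, key=lambda v: (v.chrom, v.start, v.end))):
            td = min(gap_point(iv, p) for p in tss_pos)
            kd = min(gap_region(iv, o) for o in k4me3)
            expect_enh = td > 1000 and kd > 1000
            row = cls.table.iloc[i]
            assert row["is_enhancer"] == expect_enh
            if expect_enh:
                has_k27 = any(o.start < iv.end and iv.start < o.end for o in k27ac)
                if has_k27:
                    assert row["enhancer_class"] in ("active_enhancer", "super_enhancer")
                else:
                    assert row["enhancer_class"] == "poised_enhancer"

    def test_larger_exclusion_radius_shrinks_enhancer_set(self, rng):
        tss = _tss(sorted(rng.choice(300_000, size=20, replace=False).tolist()))
        k4me = _iset([(int(s), int(s + 1500)) for s in rng.integers(0, 295_000, 80)])
        small = classify_enhancers(k4me, _iset([]), _iset([]), tss, exclusion=1000)
        large = classify_enhancers(k4me, _iset([]), _iset([]), tss, exclusion=5000)
        assert large.table["is_enhancer"].sum() <= small.table["is_enhancer"].sum()
        assert not (large.table["is_enhancer"] & ~small.table["is_enhancer"]).any()


class TestSuperEnhancers:
    def test_linear_curve_yields_none(self):
        # slope is exactly 1 everywhere; the strict > 1 rule calls nothing
        mask = call_super_enhancers(np.arange(10, dtype=float))
        assert not mask.any()

    def test_single_outlier_is_the_only_super(self):
        mask = call_super_enhancers(np.array([1.0, 1.0, 1.0, 1.0, 100.0]))
        np.testing.assert_array_equal(mask, [False, False, False, False, True])

    def test_all_equal_scores_warn_and_yield_none(self):
        with pytest.warns(UserWarning, match="all scores equal"):
            mask = call_super_enhancers(np.full(5, 3.0))
        assert not mask.any()

    def test_geometric_curve_matches_exhaustive_cutoff_search(self):
        scores = 2.0 ** np.arange(12)
        np.testing.assert_array_equal(call_super_enhancers(scores), brute_force_super(scores))

    def test_matches_oracle_on_random_curves(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 200))
            scores = rng.pareto(1.5, size=n) + rng.random(n)
            np.testing.assert_array_equal(
                call_super_enhancers(scores), brute_force_super(scores)
            )

    def test_super_set_is_an_upper_set_of_the_ranking(self, rng):
        scores = rng.pareto(1.0, size=100)
        mask = call_super_enhancers(scores)
        if mask.any():
            assert scores[mask].min() >= scores[~mask].max()

    def test_too_few_regions_is_an_error(self):
        with pytest.raises(ValueError, match="at least 3"):
            call_super_enhancers(np.array([1.0, 2.0]))


def _partition_annotation():
    return ElementAnnotation(
        {
            "promoter": _iset([(0, 2000), (50_000, 52_000)]),
            "exon": _iset([(2000, 4000), (52_000, 54_000)]),
            "intron": _iset([(4000, 10_000), (54_000, 60_000)]),
        }
    )


class TestElementEnrichment:
    def test_sites_from_background_have_unit_ratios(self, rng):
        ann = _partition_annotation()
        bg_starts = rng.integers(0, 99_000, size=2_000)
        background = _iset([(int(s), int(s + 100)) for s in bg_starts])
        pick = rng.choice(len(background), size=400, replace=False)
        sites = IntervalSet([background[i] for i in pick]).sorted()
        table = element_enrichment(sites, ann, background)
        n = len(sites)
        for _, r in table.iterrows():
            p = r["expected"] / n
            sd = np.sqrt(n * p * (1 - p))
            assert abs(r["observed"] - r["expected"]) <= 3 * max(sd, 1.0)

    def test_concentrated_sites_enrich_their_category_only(self):
        ann = _partition_annotation()
        sites = _iset([(100, 200), (500, 600), (1500, 1600)])  # all promoter
        background = _iset([(100, 200), (3000, 3100), (5000, 5100), (98_000, 98_100)])
        table = element_enrichment(sites, ann, background).set_index("category")
        assert table.loc["promoter", "observed"] == 3
        assert table.loc["promoter", "log2_ratio"] > 1
        assert table.loc["exon", "observed"] == 0

    def test_observed_counts_partition_the_sites(self, rng):
        ann = _partition_annotation()
        sites = _iset([(int(s), int(s + 150)) for s in rng.integers(0, 99_000, 300)])
        background = _iset([(int(s), int(s + 150)) for s in rng.integers(0, 99_000, 500)])
        table = element_enrichment(sites, ann, background)
        assert table["observed"].sum() == len(sites)

    def test_priority_resolves_multi_element_sites(self):
        ann = _partition_annotation()
        # spans promoter+exon boundary: promoter wins
        labels = ann.primary_labels(_iset([(1900, 2100)]))
        assert labels[0] == "promoter"
        labels = ann.primary_labels(_iset([(3900, 4100)]))  # exon+intron
        assert labels[0] == "exon"
        labels = ann.primary_labels(_iset([(80_000, 80_100)]))
        assert labels[0] == "intergenic"

    def test_matches_brute_force_labeling(self, rng):
        ann = _partition_annotation()
        sites = _iset([(int(s), int(s + 120)) for s in rng.integers(0, 99_000, 200)])
        labels = ann.primary_labels(sites)
        for iv, lab in zip(sites, labels):
            expect = "intergenic"
            for cat in ("promoter", "TTS", "5UTR", "3UTR", "exon", "intron"):
                if cat in ann.elements and any(
                    o.start < iv.end and iv.start < o.end for o in ann.elements[cat]
                ):
                    expect = cat
                    break
            assert lab == expect
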