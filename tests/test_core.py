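"""Interval algebra, nearest-TSS assignment, and file round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromarc.core import (
    GenomicInterval,
    IntervalSet,
    IntervalValidationError,
    TssAnnotation,
    merge_intervals,
    nearest_tss,
    overlap_sets,
    read_bed,
    read_bedpe,
    write_bed,
    write_bedpe,
)

from conftest import brute_force_merge, brute_force_overlap_hits, random_interval_set


class TestGenomicInterval:
    def test_rejects_malformed_records(self):
        with pytest.raises(IntervalValidationError, match="end <= start"):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(IntervalValidationError, match="negative start"):
            GenomicInterval("chr1", -5, 100)
        with pytest.raises(IntervalValidationError, match="empty chromosome"):
            GenomicInterval("", 0, 100)
        with pytest.raises(IntervalValidationError, match="NaN"):
            GenomicInterval("chr1", 0, 100, score=float("nan"))

    def test_tss_annotation_requires_single_bp_and_gene_id(self):
        with pytest.raises(IntervalValidationError, match="single bp"):
            TssAnnotation(IntervalSet([GenomicInterval("chr1", 10, 12, name="g")]))
        with pytest.raises(IntervalValidationError, match="gene id"):
            TssAnnotation(IntervalSet([GenomicInterval("chr1", 10, 11)]))


class TestMergeIntervals:
    def test_empty_and_singleton(self):
        assert len(merge_intervals(IntervalSet(), gap=1000)) == 0
        single = IntervalSet([GenomicInterval("chr1", 100, 200)])
        merged = merge_intervals(single, gap=1000)
        assert [(iv.start, iv.end) for iv in merged] == [(100, 200)]

    def test_gap_stitching_joins_neighbours_within_gap(self):
        ivs = IntervalSet(
            [
                GenomicInterval("chr1", 0, 100),
                GenomicInterval("chr1", 1100, 1200),   # 1000 bp away: joined at gap=1000
                GenomicInterval("chr1", 2300, 2400),   # 1100 bp away: not joined
            ]
        )
        merged = merge_intervals(ivs, gap=1000)
        assert [(iv.start, iv.end) for iv in merged] == [(0, 1200), (2300, 2400)]

    @pytest.mark.parametrize("gap", [0, 1000])
    def test_matches_per_base_oracle_on_random_sets(self, rng, gap):
        for _ in range(30):
            iset = random_interval_set(rng, 200, chrom_len=100_000)
            got = merge_intervals(iset, gap=gap)
            expected = brute_force_merge(iset, gap=gap)
            assert [(iv.chrom, iv.start, iv.end) for iv in got] == [
                (iv.chrom, iv.start, iv.end) for iv in expected
            ]

    def test_idempotent_and_order_invariant(self, rng):
        iset = random_interval_set(rng, 100)
        once = merge_intervals(iset, gap=50)
        assert merge_intervals(once, gap=50) == once
        perm = IntervalSet([iset[i] for i in rng.permutation(len(iset))])
        assert merge_intervals(perm, gap=50) == once

    @given(
        st.lists(
            st.tuples(st.integers(0, 5000), st.integers(1, 300)), min_size=1, max_size=40
        ),
        st.integers(0, 200),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_merge_output_is_disjoint_and_covers_input(self, spans, gap):
        iset = IntervalSet(GenomicInterval("c", s, s + w) for s, w in spans)
        merged = merge_intervals(iset, gap=gap)
        for a, b in zip(merged, merged.intervals[1:]):
            assert b.start - a.end > gap
        for iv in iset:
            assert any(m.start <= iv.start and iv.end <= m.end for m in merged)


class TestOverlapSets:
    def test_self_overlap_is_total(self, rng):
        a = random_interval_set(rng, 20)
        rep = overlap_sets(a, a)
        assert rep.proportion == 1.0 and rep.band == "high"

    def test_disjoint_sets_have_zero_overlap(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 100)])
        b = IntervalSet([GenomicInterval("chr1", 500, 600)])
        rep = overlap_sets(a, b)
        assert rep.proportion == 0.0 and rep.band == "low"

    def test_empty_query_is_an_error_not_zero(self):
        with pytest.raises(ValueError, match="undefined"):
            overlap_sets(IntervalSet(), IntervalSet([GenomicInterval("chr1", 0, 10)]))

    def test_single_shared_bp_counts(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 101)])
        b = IntervalSet([GenomicInterval("chr1", 100, 200)])
        assert overlap_sets(a, b).n_hits == 1
        b2 = IntervalSet([GenomicInterval("chr1", 101, 200)])  # book-ended: no shared bp
        assert overlap_sets(a, b2).n_hits == 0

    def test_matches_quadratic_oracle_on_random_sets(self, rng):
        for _ in range(30):
            a = random_interval_set(rng, 500, chroms=("chrT", "chrU"))
            b = random_interval_set(rng, 500, chroms=("chrT", "chrU"))
            rep = overlap_sets(a, b)
            np.testing.assert_array_equal(rep.hits, brute_force_overlap_hits(a, b))

    def test_proportion_monotone_as_subject_grows(self, rng):
        a = random_interval_set(rng, 200)
        b = random_interval_set(rng, 100)
        extra = random_interval_set(rng, 100)
        grown = IntervalSet(list(b) + list(extra))
        assert overlap_sets(a, grown).proportion >= overlap_sets(a, b).proportion


def _tss(records):
    return TssAnnotation(
        IntervalSet(
            GenomicInterval(c, p, p + 1, strand, name=g) for c, p, strand, g in records
        )
    )


class TestNearestTss:
    def test_site_at_tss_has_zero_distance(self):
        ann = _tss([("chr1", 500, "+", "geneA")])
        sites = IntervalSet([GenomicInterval("chr1", 400, 600)])  # midpoint 500
        res = nearest_tss(sites, ann)
        assert res.loc[0, "gene_id"] == "geneA"
        assert res.loc[0, "distance"] == 0
        assert not res.loc[0, "distal"]

    def test_distal_boundary_is_strictly_beyond_3kb(self):
        ann = _tss([("chr1", 10_000, "+", "geneA")])
        at_3000 = IntervalSet([GenomicInterval("chr1", 12_999, 13_001)])
        beyond = IntervalSet([GenomicInterval("chr1", 13_000, 13_002)])
        assert not nearest_tss(at_3000, ann).loc[0, "distal"]
        assert nearest_tss(beyond, ann).loc[0, "distal"]

    def test_sign_follows_gene_orientation(self):
        ann = _tss([("chr1", 1000, "+", "gPlus"), ("chr2", 1000, "-", "gMinus")])
        sites = IntervalSet(
            [GenomicInterval("chr1", 1400, 1600), GenomicInterval("chr2", 1400, 1600)]
        )
        res = nearest_tss(sites, ann)
        assert res.loc[0, "distance"] == 500      # downstream of + gene
        assert res.loc[1, "distance"] == -500     # upstream of - gene

    def test_ties_break_to_smaller_gene_id(self):
        ann = _tss([("chr1", 400, "+", "geneB"), ("chr1", 600, "+", "geneA")])
        sites = IntervalSet([GenomicInterval("chr1", 499, 501)])  # midpoint 500
        assert nearest_tss(sites, ann).loc[0, "gene_id"] == "geneA"

    def test_unannotated_chromosome_is_flagged_not_dropped(self):
        ann = _tss([("chr1", 100, "+", "geneA")])
        sites = IntervalSet([GenomicInterval("chrM", 0, 10)])
        res = nearest_tss(sites, ann)
        assert len(res) == 1 and res.loc[0, "unannotated"]

    def test_matches_exhaustive_search_on_random_layout(self, rng):
        positions = rng.choice(100_000, size=50, replace=False)
        genes = [f"g{i:03d}" for i in range(50)]
        strands = ["+" if rng.random() < 0.5 else "-" for _ in range(50)]
        ann = _tss(
            [("chrT", int(p), s, g) for p, s, g in zip(positions, strands, genes)]
        )
        sites = random_interval_set(rng, 1000)
        res = nearest_tss(sites, ann)
        for i, iv in enumerate(sites):
            mid = iv.midpoint
            dists = np.abs(positions - mid)
            best = dists.min()
            cands = sorted(genes[j] for j in np.flatnonzero(dists == best))
            assert res.loc[i, "gene_id"] == cands[0]
            assert abs(res.loc[i, "distance"]) == best

    def test_invariant_to_adding_farther_tss(self, rng):
        ann = _tss([("chrT", 50_000, "+", "gNear")])
        sites = random_interval_set(rng, 50, chrom_len=20_000)  # all within 20 kb
        base = nearest_tss(sites, ann)
        ann2 = _tss([("chrT", 50_000, "+", "gNear"), ("chrT", 99_000, "+", "gFar")])
        again = nearest_tss(sites, ann2)
        assert (base["distance"] == again["distance"]).all()
        assert (base["gene_id"] == again["gene_id"]).all()


class TestRoundTrips:
    def test_bed_round_trip_is_exact(self, tmp_path, rng):
        iset = IntervalSet(
            GenomicInterval(
                "chr%d" % rng.integers(1, 4),
                int(s),
                int(s + rng.integers(1, 500)),
                strand=["+", "-", "."][rng.integers(0, 3)],
                score=float(np.round(rng.random(), 4)),
                name=f"iv{i}",
            )
            for i, s in enumerate(rng.integers(0, 10_000, size=50))
        )
        path = tmp_path / "x.bed"
        write_bed(iset, path)
        again = read_bed(path)
        assert again == IntervalSet(list(iset))

    def test_bed_reader_skips_comments_and_track_lines(self, tmp_path):
        path = tmp_path / "c.bed"
        path.write_text("# comment\ntrack name=x\nchr1\t0\t100\n")
        assert len(read_bed(path)) == 1

    def test_bedpe_round_trip_with_umi(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {
                "chrom1": ["chr1"], "start1": [0], "end1": [100],
                "chrom2": ["chr1"], "start2": [5000], "end2": [5100],
                "umi1": ["ACGT"], "umi2": ["ACGT"],
            }
        )
        path = tmp_path / "x.bedpe"
        write_bedpe(df, path)
        again = read_bedpe(path)
        assert again.loc[0, "umi1"] == "ACGT"
        assert (again.loc[0, ["start1", "end1", "start2", "end2"]].astype(int).tolist()
                == [0, 100, 5000, 5100])
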