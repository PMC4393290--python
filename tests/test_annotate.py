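"""Co-localization: interORF classes, placement, UTRs, repeats, distances."""

import numpy as np
import pytest

from dnaflex.annotate import (
    assign_repeats,
    classify_interorf,
    find_at_repeats,
    interorf_class_counts,
    locate_peaks,
    nearest_feature_distance,
    oclass_counts,
    placement_counts,
    polya_distance,
    utr_overlap,
)
from dnaflex.core import reverse_complement
from dnaflex.io import FeatureInterval, ScoredSite, UtrRecord
from dnaflex.peaks import FlexRegion

from conftest import random_sequence


def orf(chrom, start, end, strand, fid):
    return FeatureInterval(chrom, start, end, strand, "ORF", fid)


def peak(chrom, start, end, name="p"):
    return FlexRegion(chrom, start, end, max_value=14.0, mean_value=13.0,
                      n_windows=end - start - 99, status="peak", name=name)


class TestClassifyInterorf:
    def test_orientation_definitions(self):
        regions = classify_interorf([
            orf("c1", 0, 100, "+", "a"), orf("c1", 200, 300, "-", "b"),
            orf("c1", 400, 500, "+", "c"), orf("c1", 600, 700, "+", "d"),
        ])
        assert [r.oclass for r in regions] == ["convergent", "divergent", "unidirectional"]
        assert (regions[0].start, regions[0].end) == (100, 200)

    def test_overlapping_orfs_yield_no_region(self):
        regions = classify_interorf([
            orf("c1", 0, 150, "+", "a"), orf("c1", 100, 300, "-", "b"),
            orf("c1", 400, 500, "+", "c"),
        ])
        # only the b->c gap survives
        assert len(regions) == 1 and regions[0].left_id == "b"

    def test_terminal_gaps_excluded(self):
        regions = classify_interorf([orf("c1", 100, 200, "+", "a")])
        assert regions == []

    def test_synthetic_class_mix_recovered_exactly(self, sim):
        _, manifest = sim
        regions = classify_interorf(manifest.orfs)
        assert [(r.chrom, r.start, r.end, r.oclass) for r in regions] == [
            (g.chrom, g.start, g.end, g.oclass) for g in manifest.gaps
        ]
        truth = manifest.gap_class_counts()
        assert interorf_class_counts(regions) == truth


class TestLocatePeaks:
    FEATURES = [
        FeatureInterval("c1", 0, 300, ".", "telomere", "tel"),
        orf("c1", 1000, 2000, "+", "a"),
        orf("c1", 2500, 3500, "-", "b"),
        orf("c1", 4000, 5000, "-", "c"),
        FeatureInterval("c2", 0, 2000, "+", "rRNA", "rdn"),
        orf("c2", 3000, 4000, "+", "d"),
        orf("c2", 5000, 6000, "+", "e"),
    ]

    def test_inside_orf(self):
        anns = locate_peaks([peak("c1", 1200, 1500)], self.FEATURES)
        assert anns[0].placement == "inside_ORF"

    def test_midpoint_in_convergent_gap(self):
        anns = locate_peaks([peak("c1", 2100, 2400)], self.FEATURES)
        assert anns[0].placement == "interORF" and anns[0].oclass == "convergent"

    def test_unidirectional_gap(self):
        anns = locate_peaks([peak("c2", 4200, 4600)], self.FEATURES)
        assert anns[0].oclass == "unidirectional"

    def test_telomere_and_rrna_take_priority(self):
        anns = locate_peaks([peak("c1", 100, 400), peak("c2", 1800, 3200)], self.FEATURES)
        assert [a.placement for a in anns] == ["telomere", "rRNA"]

    def test_straddling_peak_with_minor_orf_overlap_is_interorf(self):
        # 40% inside ORF b, midpoint in the b->c gap
        anns = locate_peaks([peak("c1", 3380, 3680)], self.FEATURES)
        assert anns[0].placement == "interORF" and anns[0].oclass == "unidirectional"

    def test_unannotated_chromosome_unresolved(self, caplog):
        anns = locate_peaks([peak("c9", 0, 300)], self.FEATURES)
        assert anns[0].placement == "unresolved"

    def test_counts_sum_to_peak_total(self, pipeline_result):
        res = pipeline_result
        assert sum(placement_counts(res.annotations).values()) == len(res.peaks)
        n_interorf = placement_counts(res.annotations).get("interORF", 0)
        assert sum(oclass_counts(res.annotations).values()) == n_interorf


class TestUtrOverlap:
    ORFS = [orf("c1", 1000, 2000, "+", "a"), orf("c1", 2500, 3500, "-", "b")]
    UTRS = [UtrRecord("a", 50, 100), UtrRecord("b", 60, 200)]

    def test_abutting_peak_is_not_a_hit(self):
        # a's 3'UTR is [2000, 2100); a peak ending at 2000 does not overlap
        hits, summary = utr_overlap([peak("c1", 1900, 2000)], self.ORFS, self.UTRS)
        assert hits[0][1] == [] and summary.n_peaks_3utr == 0

    def test_one_bp_overlap_is_a_hit(self):
        hits, _ = utr_overlap([peak("c1", 1900, 2001)], self.ORFS, self.UTRS)
        assert hits[0][1] == ["a"]

    def test_peak_spanning_two_convergent_3utrs(self):
        # a: 3'UTR [2000,2100)+; b: 3'UTR [2300,2500)- -> one peak, two ORFs
        hits, summary = utr_overlap([peak("c1", 2050, 2350)], self.ORFS, self.UTRS)
        assert hits[0][1] == ["a", "b"]
        assert summary.n_peaks_3utr == 1 and summary.n_orfs_3utr == 2

    def test_missing_orf_falls_back_to_table_means(self):
        orfs = self.ORFS + [orf("c1", 5000, 6000, "+", "zz")]
        # mean utr3 of the table is 150 -> zz 3'UTR = [6000, 6150)
        hits, _ = utr_overlap([peak("c1", 6100, 6400)], orfs, self.UTRS)
        assert hits[0][1] == ["zz"]

    def test_planted_utr_peaks_recovered(self, sim, pipeline_result):
        _, manifest = sim
        by_name = {}
        for a in pipeline_result.annotations:
            by_name[(a.peak.chrom, a.peak.start, a.peak.end)] = a
        for tract in manifest.tracts:
            if tract.context != "interorf" or tract.primary_orf is None:
                continue
            hosts = [
                a for a in pipeline_result.annotations
                if a.peak.chrom == tract.chrom
                and a.peak.start <= tract.midpoint < a.peak.end
            ]
            assert hosts, f"planted tract at {tract.chrom}:{tract.start} not inside any peak"
            assert tract.primary_orf in hosts[0].utr3_orfs


class TestFindAtRepeats:
    def test_pure_ta_tract(self):
        seq = "G" * 30 + "TA" * 15 + "C" * 30
        reps = find_at_repeats(seq)
        assert len(reps) == 1
        r = reps[0]
        assert (r.start, r.end, r.fid) == (30, 60, "(TA)n")

    def test_short_tract_below_min_len(self):
        seq = "G" * 30 + "TA" * 6 + "C" * 30
        assert find_at_repeats(seq, min_len=20) == []

    def test_tta_family(self):
        seq = "G" * 30 + "TTA" * 10 + "C" * 30
        reps = find_at_repeats(seq)
        assert [r.fid for r in reps] == ["(TTA)n"]

    def test_at_rich_fallback(self):
        rng = np.random.default_rng(5)
        core = "".join(rng.choice(list("AT"), size=40))
        seq = "G" * 30 + core + "C" * 30
        reps = find_at_repeats(seq)
        assert reps and all(r.fid in {"(TA)n", "(TTA)n", "AT-rich"} for r in reps)

    def test_noisy_tract_detected_with_tight_boundaries(self, rng):
        for _ in range(20):
            bg = random_sequence(rng, 400, gc=0.4)
            tract = list("TA" * 25)  # 50 bp
            # ~10% substitutions at interior, well-spaced positions: a
            # substitution within a few bp of a terminus (or a dense cluster
            # of them) genuinely redefines the tract boundary, which is not
            # what this check is about
            for i in (4, 13, 22, 31, 40):
                tract[i] = rng.choice([b for b in "ACGT" if b != tract[i]])
            seq = bg[:200] + "G" + "".join(tract) + "C" + bg[200:]
            reps = [r for r in find_at_repeats(seq) if r.start < 260 and r.end > 200]
            assert reps, "planted noisy tract missed"
            best = max(reps, key=lambda r: len(r))
            assert abs(best.start - 201) <= 2 and abs(best.end - 251) <= 2

    def test_reverse_complement_mirrors_intervals(self, rng):
        seq = ("G" * 20 + "TA" * 20 + "C" * 20 + "TTA" * 12 + "G" * 20)
        n = len(seq)
        fwd = find_at_repeats(seq)
        rev = find_at_repeats(reverse_complement(seq))
        mirrored = sorted((n - r.end, n - r.start, r.fid) for r in rev)
        assert sorted((r.start, r.end, r.fid) for r in fwd) == mirrored

    def test_min_len_validation(self):
        with pytest.raises(ValueError):
            find_at_repeats("TATATA", min_len=2)


class TestPolyaDistance:
    def annotated_peak_with_repeat(self, chrom="c1", mid=1000):
        p = peak(chrom, mid - 150, mid + 150)
        from dnaflex.annotate import PeakAnnotation

        a = PeakAnnotation(p, "interORF", "convergent")
        a.repeats = [FeatureInterval(chrom, mid - 25, mid + 25, ".", "repeat", "(TA)n")]
        return a

    def test_site_at_midpoint_distance_zero(self):
        ann = self.annotated_peak_with_repeat()
        res = polya_distance([ScoredSite("c1", 1000, "+", 1000)], [ann])
        assert res.distances.tolist() == [0]

    def test_max_dist_boundary(self):
        ann = self.annotated_peak_with_repeat()
        sites = [ScoredSite("c1", 1501, "+", 1000), ScoredSite("c1", 1500, "+", 1000)]
        res = polya_distance(sites, [ann], max_dist=500)
        assert res.distances.tolist() == [500]

    def test_score_filter(self):
        ann = self.annotated_peak_with_repeat()
        sites = [ScoredSite("c1", 1000, "+", 944), ScoredSite("c1", 1010, "+", 945)]
        res = polya_distance(sites, [ann], score_min=945)
        assert res.n_scored == 1 and res.distances.tolist() == [10]

    def test_order_invariance(self, rng):
        ann = self.annotated_peak_with_repeat()
        sites = [ScoredSite("c1", int(1000 + d), "+", 1000) for d in rng.integers(-400, 400, 50)]
        res1 = polya_distance(sites, [ann])
        res2 = polya_distance(list(reversed(sites)), [ann])
        assert res1.distances.tolist() == res2.distances.tolist()
        assert res1.frac_within_25 == res2.frac_within_25

    def test_no_repeats_warns_and_returns_empty(self, caplog):
        from dnaflex.annotate import PeakAnnotation

        a = PeakAnnotation(peak("c1", 0, 300), "interORF")
        res = polya_distance([ScoredSite("c1", 100, "+", 1000)], [a])
        assert res.n_retained == 0

    def test_empirical_fractions_match_planted_offsets(self, sim, pipeline_result):
        _, manifest = sim
        res = polya_distance(
            [s.site for s in manifest.sites],
            pipeline_result.annotations,
            families=["(TA)n"],
        )
        planted = [
            abs(s.offset) for s in manifest.sites
            if s.tract_index >= 0 and s.site.score >= 945 and abs(s.offset) <= 500
        ]
        expected = np.mean([d <= 25 for d in planted])
        n = len(planted)
        tol = 3 * np.sqrt(expected * (1 - expected) / n) + 0.03  # + boundary slack
        assert abs(res.frac_within_25 - expected) <= tol


class TestNearestFeatureDistance:
    def test_overlapping_is_zero(self):
        d = nearest_feature_distance([peak("c1", 0, 300)],
                                     [FeatureInterval("c1", 200, 400, ".", "other", "x")])
        assert d.tolist() == [0]

    def test_gap_distance(self):
        d = nearest_feature_distance([peak("c1", 0, 100)],
                                     [FeatureInterval("c1", 200, 300, ".", "other", "x")])
        assert d.tolist() == [100]

    def test_no_shared_chromosome_empty(self, caplog):
        d = nearest_feature_distance([peak("c1", 0, 300)],
                                     [FeatureInterval("c2", 0, 100, ".", "other", "x")])
        assert d.size == 0

    def test_matches_brute_force(self, rng):
        peaks = [peak("c1", int(s), int(s) + 200) for s in rng.integers(0, 50_000, 25)]
        feats = [
            FeatureInterval("c1", int(s), int(s) + int(rng.integers(1, 300)), ".", "other", str(i))
            for i, s in enumerate(rng.integers(0, 50_000, 25))
        ]
        got = nearest_feature_distance(peaks, feats)
        for p, g in zip(peaks, got):
            expected = min(
                max(0, f.start - p.end) if f.start >= p.end else max(0, p.start - f.end)
                for f in feats
            )
            assert g == expected
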