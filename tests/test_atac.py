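"""Consensus peaks, annotation, TMM/CPM, promoter OCR stats and metaprofiles."""

import numpy as np
import pandas as pd
import pytest

from helpers import toy_annotation
from neutronet.atac import (annotate_peaks, expression_accessibility_correlation,
                            merge_consensus_peaks, normalize_peak_counts,
                            promoter_ocr_stats, signal_metaprofile, tmm_factors)
from neutronet.containers import PeakSet


def ps(intervals, counts=None, names=None):
    names = names or [f"p{i + 1}" for i in range(len(intervals))]
    peaks = pd.DataFrame(intervals, columns=["chrom", "start", "end"],
                         index=pd.Index(names, name="name"))
    cdf = None
    if counts is not None:
        cdf = pd.DataFrame(counts, index=peaks.index)
    return PeakSet(peaks=peaks, counts=cdf)


class TestMergeConsensusPeaks:
    def test_identical_replicates(self):
        a = ps([("chr1", 100, 200), ("chr1", 300, 400)])
        out = merge_consensus_peaks([a, a])
        assert [(r.start, r.end) for r in out.peaks.itertuples()] == [(100, 200), (300, 400)]

    def test_overlap_merged_counts_summed(self):
        a = ps([("chr1", 100, 200)], {"s1": [5.0]})
        b = ps([("chr1", 150, 250)], {"s1": [3.0]})
        out = merge_consensus_peaks([a, b])
        assert list(out.peaks[["start", "end"]].iloc[0]) == [100, 250]
        assert out.counts.iloc[0, 0] == 8.0

    def test_disjoint_not_merged_across_gap(self):
        a = ps([("chr1", 0, 50), ("chr1", 60, 100)])
        assert len(merge_consensus_peaks([a])) == 2

    def test_idempotent_and_coverage_monotone(self):
        a = ps([("chr1", 0, 120), ("chr1", 100, 200), ("chr2", 5, 10)])
        once = merge_consensus_peaks([a])
        twice = merge_consensus_peaks([once])
        pd.testing.assert_frame_equal(once.peaks.reset_index(drop=True),
                                      twice.peaks.reset_index(drop=True))
        assert once.widths.sum() <= a.widths.sum()
        assert once.widths.sum() >= a.widths.max()


class TestAnnotatePeaks:
    def annotation(self):
        exons = pd.DataFrame({"gene_id": ["g1", "g1"], "chrom": ["chr1", "chr1"],
                              "start": [50_000, 60_000], "end": [51_000, 62_000]})
        # g1: + strand, TSS 50_000, body 50_000-70_000
        ann = toy_annotation([50_000], body=20_000, exons=exons)
        return ann

    def label_of(self, mid, ann=None):
        ann = ann or self.annotation()
        peaks = ps([("chr1", mid - 10, mid + 10)])
        labels, _ = annotate_peaks(peaks, ann)
        return labels.iloc[0]

    def test_midpoint_at_tss_is_promoter(self):
        assert self.label_of(50_000) == "promoter"

    def test_promoter_boundary_3kb(self):
        assert self.label_of(50_000 + 2_999) == "promoter"
        assert self.label_of(50_000 + 3_001) != "promoter"

    def test_intron_and_exon(self):
        assert self.label_of(61_000) == "exon"
        assert self.label_of(55_000) == "intron"

    def test_tts_beats_exon(self):
        # TES at 69_999; a peak near it labels TTS by priority
        assert self.label_of(69_500) == "TTS"

    def test_unknown_chromosome_intergenic_with_warning(self):
        peaks = ps([("chrUn", 100, 200)])
        with pytest.warns(UserWarning):
            labels, summary = annotate_peaks(peaks, self.annotation())
        assert labels.iloc[0] == "intergenic"
        assert summary["fraction"].sum() == pytest.approx(1.0)


class TestTmmCpm:
    def test_identical_samples_unit_factors(self):
        p = ps([("chr1", 0, 1000), ("chr1", 2000, 2500)],
               {"a": [10.0, 40.0], "b": [10.0, 40.0]})
        out = normalize_peak_counts(p)
        f = tmm_factors(p.counts.div((p.peaks.end - p.peaks.start) / 1000, axis=0))
        np.testing.assert_allclose(f, [1.0, 1.0])
        pd.testing.assert_series_equal(out.counts["a"], out.counts["b"], check_names=False)
        assert out.counts["a"].sum() == pytest.approx(1e6)

    def test_proportional_sample_equalized(self):
        rng = np.random.default_rng(0)
        base = rng.gamma(2, 30, 40)
        intervals = [("chr1", i * 3000, i * 3000 + 1000 + 10 * i) for i in range(40)]
        p = ps(intervals, {"a": base, "b": 2 * base})
        out = normalize_peak_counts(p)
        np.testing.assert_allclose(out.counts["a"], out.counts["b"], rtol=1e-9)

    def test_rpk_definition(self):
        p = ps([("chr1", 0, 2000)], {"a": [10.0]})
        rpk = p.counts.div((p.peaks.end - p.peaks.start) / 1000, axis=0)
        assert rpk.iloc[0, 0] == 5.0

    def test_all_zero_sample_error(self):
        p = ps([("chr1", 0, 1000)], {"a": [3.0], "b": [0.0]})
        with pytest.raises(ValueError, match="b"):
            normalize_peak_counts(p)


class TestPromoterOcrStats:
    def test_hand_example(self):
        ann = toy_annotation([10_000])
        p = ps([("chr1", 6500, 7500), ("chr1", 12_000, 12_400)],
               {"a": [5.0, 3.0]})
        p.norm = "TMM_CPM"
        stats = promoter_ocr_stats(p, ann, flank=3000)
        assert stats.loc["g1", "intensity"] == pytest.approx(8.0)
        assert stats.loc["g1", "length"] == 900
        assert stats.loc["g1", "n_peaks"] == 2

    def test_no_peak_zeroes_retained(self):
        ann = toy_annotation([10_000, 500_000])
        p = ps([("chr1", 6500, 7500)], {"a": [5.0]})
        stats = promoter_ocr_stats(p, ann)
        assert stats.loc["g2", "intensity"] == 0
        assert stats.loc["g2", "n_peaks"] == 0

    def test_shared_peak_counts_for_both_genes(self):
        ann = toy_annotation([10_000, 14_000])
        p = ps([("chr1", 11_000, 12_000)], {"a": [7.0]})
        stats = promoter_ocr_stats(p, ann)
        assert stats.loc["g1", "intensity"] == 7.0
        assert stats.loc["g2", "intensity"] == 7.0

    def test_additive_under_partition(self):
        ann = toy_annotation([10_000])
        whole = ps([("chr1", 9000, 11_000)], {"a": [6.0]})
        parts = ps([("chr1", 9000, 10_000), ("chr1", 10_000, 11_000)],
                   {"a": [2.0, 4.0]})
        s1 = promoter_ocr_stats(whole, ann)
        s2 = promoter_ocr_stats(parts, ann)
        assert s1.loc["g1", "intensity"] == s2.loc["g1", "intensity"]
        assert s1.loc["g1", "length"] == s2.loc["g1", "length"]


class TestExpressionAccessibilityCorrelation:
    def test_identical_vectors_r_one(self):
        stats = pd.DataFrame({"intensity": [1.0, 4.0, 9.0, 20.0],
                              "length": [1, 2, 3, 4]},
                             index=["g1", "g2", "g3", "g4"])
        expr = pd.Series([1.0, 4.0, 9.0, 20.0], index=stats.index)
        out = expression_accessibility_correlation(stats, expr, {"all": stats.index})
        assert out.loc["all", "r_intensity"] == pytest.approx(1.0)

    def test_small_set_raises(self):
        stats = pd.DataFrame({"intensity": [1.0], "length": [1]}, index=["g1"])
        with pytest.raises(ValueError):
            expression_accessibility_correlation(stats, pd.Series([1.0], index=["g1"]),
                                                 {"tiny": ["g1"]})


class TestSignalMetaprofile:
    sizes = {"chr1": 100_000}

    def test_constant_signal_flat(self):
        track = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100_000],
                              "value": [0.8]})
        anchors = pd.DataFrame({"chrom": ["chr1"], "pos": [50_000], "strand": ["+"]})
        _, prof = signal_metaprofile(track, anchors, self.sizes, flank=2000, bins=40)
        np.testing.assert_allclose(prof, 0.8)

    def test_step_mirrored_on_minus_strand(self):
        track = pd.DataFrame({"chrom": ["chr1", "chr1"],
                              "start": [0, 50_000], "end": [50_000, 100_000],
                              "value": [0.0, 1.0]})
        plus = pd.DataFrame({"chrom": ["chr1"], "pos": [50_000], "strand": ["+"]})
        minus = plus.assign(strand="-")
        _, p_prof = signal_metaprofile(track, plus, self.sizes, flank=2000, bins=40)
        _, m_prof = signal_metaprofile(track, minus, self.sizes, flank=2000, bins=40)
        np.testing.assert_allclose(m_prof, p_prof[::-1])
        assert p_prof[0] == 0.0 and p_prof[-1] == 1.0

    def test_hand_binned_values(self):
        track = pd.DataFrame({"chrom": ["chr1"] * 2,
                              "start": [49_000, 50_000], "end": [50_000, 51_000],
                              "value": [0.2, 0.6]})
        anchors = pd.DataFrame({"chrom": ["chr1"], "pos": [50_000], "strand": ["+"]})
        mat, _ = signal_metaprofile(track, anchors, self.sizes, flank=1000, bins=4)
        np.testing.assert_allclose(mat[0], [0.2, 0.2, 0.6, 0.6])

    def test_symmetric_signal_symmetric_profile(self):
        rng = np.random.default_rng(5)
        vals = rng.random(10)
        sym = np.concatenate([vals, vals[::-1]])
        starts = 49_000 + 100 * np.arange(20)
        track = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 100,
                              "value": sym})
        anchors = pd.DataFrame({"chrom": ["chr1"], "pos": [50_000], "strand": ["+"]})
        _, prof = signal_metaprofile(track, anchors, self.sizes, flank=1000, bins=20)
        np.testing.assert_allclose(prof, prof[::-1])

    def test_out_of_bounds_anchor_missing_row(self):
        track = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100_000],
                              "value": [1.0]})
        anchors = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [200_000, 50_000],
                                "strand": ["+", "+"]})
        with pytest.warns(UserWarning):
            mat, prof = signal_metaprofile(track, anchors, self.sizes,
                                           flank=2000, bins=10)
        assert np.isnan(mat[0]).all() and not np.isnan(mat[1]).any()
        np.testing.assert_allclose(prof, mat[1])

    def test_empty_anchor_list_raises(self):
        track = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10],
                              "value": [1.0]})
        with pytest.raises(ValueError):
            signal_metaprofile(track, track.iloc[:0], self.sizes)
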