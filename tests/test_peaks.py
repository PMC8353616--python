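import numpy as np
import pytest

from scpas.annotation import GeneModel, Genome, GenomeInterval, Transcript
from scpas.dip import dip_pvalue, dip_statistic
from scpas.peaks import (
    Peak,
    _greedy_windows,
    aggregate_gene_peaks,
    assess_modality,
    call_raw_peaks,
    filter_internal_priming,
    filter_low_coverage,
    split_multimodal,
)
from tests.conftest import recovery_fraction


class TestDip:
    def test_unimodal_samples_accepted(self):
        rng = np.random.default_rng(0)
        for sample in (rng.normal(200, 40, 400), rng.uniform(0, 400, 400)):
            _, p = dip_pvalue(sample, n_boot=200, seed=1)
            assert p > 0.05

    def test_separated_bimodal_rejected(self):
        rng = np.random.default_rng(1)
        sample = np.concatenate([rng.normal(100, 20, 200), rng.normal(400, 20, 200)])
        _, p = dip_pvalue(sample, n_boot=200, seed=1)
        assert p < 0.05

    def test_degenerate_samples_have_zero_dip(self):
        assert dip_statistic(np.array([5.0, 5.0, 5.0, 5.0, 5.0])) == 0.0
        assert dip_statistic(np.array([1.0, 2.0])) == 0.0


class TestModality:
    def test_gaussian_profile_unimodal(self):
        rng = np.random.default_rng(2)
        profile = np.bincount(
            np.clip(rng.normal(200, 40, 500).astype(int), 0, 399), minlength=400
        )
        modality, ad = assess_modality(profile)
        assert modality == "unimodal"
        assert ad is not None

    def test_balanced_mixture_multimodal(self):
        rng = np.random.default_rng(3)
        samples = np.concatenate(
            [rng.normal(60, 20, 250), rng.normal(360, 20, 250)]
        ).astype(int)
        profile = np.bincount(np.clip(samples, 0, 399), minlength=400)
        modality, _ = assess_modality(profile)
        assert modality == "multimodal"

    def test_point_mass_unimodal(self):
        profile = np.zeros(400)
        profile[200] = 100
        assert assess_modality(profile)[0] == "unimodal"


def _single_exon_gene(gene_id="g", chrom="c1", start=0, end=5000, strand="+"):
    tx = Transcript(f"{gene_id}.t1", [GenomeInterval(chrom, start, end, strand)])
    return GeneModel(gene_id, [tx])


class TestRawCalling:
    def test_single_pileup_one_peak_exact_count(self):
        rng = np.random.default_rng(0)
        starts = np.sort(rng.integers(1000, 1350, size=100))
        gene = _single_exon_gene()
        peaks = call_raw_peaks({("c1", "+"): starts}, [gene])
        assert len(peaks) == 1
        assert peaks[0].read_count == 100
        assert peaks[0].category == "exonic"

    def test_empty_alignments_no_peaks(self):
        assert call_raw_peaks({}, [_single_exon_gene()]) == []

    def test_two_pileups_recovered_with_correct_summits(self):
        rng = np.random.default_rng(1)
        starts = np.sort(
            np.concatenate(
                [rng.integers(500, 850, 80), rng.integers(2500, 2850, 120)]
            )
        )
        peaks = call_raw_peaks({("c1", "+"): starts}, [_single_exon_gene(end=4000)])
        assert len(peaks) == 2
        ends = sorted(p.three_prime_end for p in peaks)
        # the pile downstream edge + ~50 nt of window slack
        assert abs(ends[0] - 900) <= 60
        assert abs(ends[1] - 2900) <= 60

    def test_min_count_threshold(self):
        starts = np.array([100, 105, 110])
        assert call_raw_peaks({("c1", "+"): starts}, [_single_exon_gene()], min_count=10) == []

    def test_junction_spanning_footprint(self):
        # 150-nt exons, 400-nt window -> peak footprint spans the junction
        tx = Transcript(
            "t",
            [GenomeInterval("c1", 0, 150, "+"), GenomeInterval("c1", 1000, 1300, "+")],
        )
        gene = GeneModel("g", [tx])
        starts = np.concatenate([np.arange(100, 150), np.arange(1000, 1150)])
        peaks = [p for p in call_raw_peaks({("c1", "+"): starts}, [gene], min_count=10)
                 if p.category == "exonic"]
        assert len(peaks) == 1
        assert len(peaks[0].blocks) == 2

    def test_intronic_pile_yields_intronic_category(self, default_sim):
        intronic = [p for p in default_sim["raw_peaks"] if p.category == "intronic"]
        exon_sets = {
            g.gene_id: [(e.start, e.end) for t in g.transcripts for e in t.exons]
            for g in default_sim["genes"]
        }
        assert intronic
        for p in intronic:
            assert not any(
                lo <= p.three_prime_end < hi for lo, hi in exon_sets[p.gene_id]
            )


class TestSplitMultimodal:
    def _bimodal_peak(self):
        profile = np.concatenate(
            [np.full(200, 5.0), np.full(20, 0.5), np.full(180, 5.0)]
        )
        peak = Peak(
            interval=GenomeInterval("c1", 1000, 1400, "+"),
            blocks=[GenomeInterval("c1", 1000, 1400, "+")],
            gene_id="g",
            transcript_id="t",
            read_count=int(profile.sum()),
            three_prime_end=1399,
            category="exonic",
            modality="multimodal",
            profile=profile,
        )
        return peak, profile

    def test_split_at_internal_minimum_conserves_counts(self):
        peak, profile = self._bimodal_peak()
        children = split_multimodal(peak, profile)
        assert len(children) == 2
        assert sum(c.read_count for c in children) == peak.read_count
        cut = children[0].interval.end - peak.interval.start
        assert 200 <= cut <= 220  # the low-coverage valley

    def test_unimodal_returned_unchanged(self):
        peak, _ = self._bimodal_peak()
        peak.modality = "unimodal"
        assert split_multimodal(peak) == [peak]


def _peak(start, end, count, gene="g", strand="+", chrom="c1"):
    return Peak(
        interval=GenomeInterval(chrom, start, end, strand),
        blocks=[GenomeInterval(chrom, start, end, strand)],
        gene_id=gene,
        transcript_id="t",
        read_count=count,
        three_prime_end=end - 1 if strand == "+" else start,
        category="exonic",
    )


class TestAggregation:
    def test_majority_overlap_keeps_max_expressed(self):
        a = _peak(0, 400, 100)
        b = _peak(160, 560, 80)  # 60% of the shorter peak overlaps
        kept = aggregate_gene_peaks([a, b])
        assert kept == [a]

    def test_minor_overlap_keeps_both(self):
        a = _peak(0, 400, 100)
        b = _peak(360, 760, 80)  # 10% overlap
        assert len(aggregate_gene_peaks([a, b])) == 2

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        peaks = [
            _peak(int(s), int(s) + 400, int(c))
            for s, c in zip(rng.integers(0, 3000, 30), rng.integers(1, 500, 30))
        ]
        once = aggregate_gene_peaks(peaks)
        assert aggregate_gene_peaks(once) == once

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_grouping(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        peaks = [
            _peak(int(s), int(s + rng.integers(100, 500)), int(c))
            for s, c in zip(rng.integers(0, 4000, n), rng.integers(1, 999, n))
        ]
        # oracle: transitive closure over the >= 50%-of-shorter overlap relation
        def linked(a, b):
            ov = a.interval.overlap(b.interval)
            return ov >= 0.5 * min(len(a.interval), len(b.interval))

        groups = []
        for p in peaks:
            hit = [g for g in groups if any(linked(p, q) for q in g)]
            merged = [p] + [q for g in hit for q in g]
            groups = [g for g in groups if g not in hit] + [merged]
        expected = sorted(
            (max(g, key=lambda p: p.read_count).interval for g in groups),
            key=lambda iv: iv.start,
        )
        got = sorted((p.interval for p in aggregate_gene_peaks(peaks)), key=lambda iv: iv.start)
        assert got == expected


class TestCoverageFilter:
    def test_one_percent_boundary_removed(self):
        peaks = [_peak(0, 400, 990), _peak(1000, 1400, 10)]
        kept = filter_low_coverage(peaks)
        assert [p.read_count for p in kept] == [990]

    def test_symmetric_counts_retained(self):
        peaks = [_peak(0, 400, 50), _peak(1000, 1400, 50)]
        assert len(filter_low_coverage(peaks)) == 2

    def test_single_peak_always_retained(self):
        assert len(filter_low_coverage([_peak(0, 400, 1)])) == 1


class TestInternalPrimingFilter:
    def _genome_with(self, downstream):
        seq = "C" * 1000 + downstream + "C" * 1000
        return Genome({"c1": seq})

    def _intronic_peak(self, end=1000):
        p = _peak(end - 400, end, 50)
        p.category = "intronic"
        return p

    def test_eight_adenines_removed_seven_retained(self):
        for n_a, expect_kept in [(8, 0), (7, 1)]:
            genome = self._genome_with("A" * n_a)
            kept = filter_internal_priming([self._intronic_peak()], genome)
            assert len(kept) == expect_kept

    def test_exonic_peaks_untouched(self):
        genome = self._genome_with("A" * 10)
        peak = _peak(600, 1000, 50)  # exonic
        assert filter_internal_priming([peak], genome) == [peak]

    def test_window_clipped_at_contig_edge(self):
        genome = Genome({"c1": "C" * 30})
        p = _peak(0, 25, 50)
        p.category = "intronic"
        assert filter_internal_priming([p], genome) == [p]


class TestPlantedRecovery:
    def test_planted_sites_recovered_on_both_strands(self, default_sim):
        truth = default_sim["truth"]
        for strand in "+-":
            subset = [t for t in truth.pas if t.strand == strand]
            assert recovery_fraction(default_sim["peaks"], subset) >= 0.9

    def test_peak_count_monotone_through_aggregation_and_filters(self, default_sim):
        n_split = len(
            [p for p in default_sim["raw_peaks"]]
        )
        assert len(default_sim["peaks"]) <= len(default_sim["prefilter_peaks"])
        assert len(default_sim["prefilter_peaks"]) <= n_split + len(default_sim["raw_peaks"])
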