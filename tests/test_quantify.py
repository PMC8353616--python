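import numpy as np
import pysam
import pytest

from scpas.annotation import GeneModel, GenomeInterval, Transcript, read_gtf
from scpas.peaks import Peak
from scpas.quantify import (
    PASTranscript,
    assign_peaks_to_transcripts,
    compute_rpm,
    count_umis,
    write_pas_gtf,
)


def _peak(start, end, gene="g", tx="t", strand="+", chrom="c1", blocks=None):
    return Peak(
        interval=GenomeInterval(chrom, start, end, strand),
        blocks=blocks or [GenomeInterval(chrom, start, end, strand)],
        gene_id=gene,
        transcript_id=tx,
        read_count=100,
        three_prime_end=end - 1 if strand == "+" else start,
        category="exonic",
    )


@pytest.fixture
def toy_gene():
    tx = Transcript(
        "g.t1",
        [GenomeInterval("c1", 0, 150, "+"), GenomeInterval("c1", 1000, 1400, "+")],
    )
    return GeneModel("g", [tx])


class TestAssignment:
    def test_peak_in_last_exon_single_exon_feature(self, toy_gene):
        feats = assign_peaks_to_transcripts([_peak(1000, 1300)], [toy_gene])
        assert len(feats) == 1
        f = feats[0]
        assert len(f.exons) == 1
        assert f.exons[-1].end - 1 == f.pas_site == 1299
        assert not f.unspliced

    def test_junction_spanning_peak_multi_exon_feature(self, toy_gene):
        # footprint covers both exons: clipped chain keeps the junction
        blocks = [GenomeInterval("c1", 100, 150, "+"), GenomeInterval("c1", 1000, 1350, "+")]
        peak = _peak(100, 1350, blocks=blocks)
        feats = assign_peaks_to_transcripts([peak], [toy_gene])
        assert len(feats[0].exons) == 2
        # feature never extends past the PAS
        assert max(e.end for e in feats[0].exons) - 1 == peak.three_prime_end

    def test_two_pas_one_gene_share_gene_id(self, toy_gene):
        feats = assign_peaks_to_transcripts(
            [_peak(1000, 1200), _peak(1200, 1400)], [toy_gene]
        )
        assert {f.gene_id for f in feats} == {"g"}
        assert len({f.feature_id for f in feats}) == 2

    def test_orphan_peak_flagged_unspliced(self, toy_gene):
        feats = assign_peaks_to_transcripts([_peak(5000, 5400)], [toy_gene])
        assert feats[0].unspliced

    def test_pas_gtf_round_trip(self, toy_gene, tmp_path):
        blocks = [GenomeInterval("c1", 100, 150, "+"), GenomeInterval("c1", 1000, 1350, "+")]
        feats = assign_peaks_to_transcripts(
            [_peak(100, 1350, blocks=blocks), _peak(1000, 1400)], [toy_gene]
        )
        path = str(tmp_path / "pas.gtf")
        write_pas_gtf(feats, path)
        genes = read_gtf(path)
        back = {
            t.transcript_id: sorted(t.exons, key=lambda e: e.start)
            for g in genes
            for t in g.transcripts
        }
        for f in feats:
            assert back[f.feature_id] == sorted(f.exons, key=lambda e: e.start)


def _write_bam(path, reads, chrom_len=10000):
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "c1", "LN": chrom_len}]}
    reads = sorted(reads, key=lambda r: r[0])
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for i, (pos, rev, tags, length, mapq) in enumerate(reads):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = f"r{i}"
            a.query_sequence = "A" * length
            a.flag = 16 if rev else 0
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = mapq
            a.cigarstring = f"{length}M"
            for tag, val in tags.items():
                a.set_tag(tag, val)
            bam.write(a)
    pysam.index(path)
    return path


def _feature(fid, start, end, strand="+"):
    return PASTranscript(
        feature_id=fid,
        gene_id=fid.split(":")[0],
        transcript_id=fid,
        exons=[GenomeInterval("c1", start, end, strand)],
        peak_region=GenomeInterval("c1", start, end, strand),
        pas_site=end - 1 if strand == "+" else start,
    )


class TestCountUmis:
    def test_umi_dedup_and_distinct_molecules(self, tmp_path):
        bam = _write_bam(
            str(tmp_path / "a.bam"),
            [
                (100, False, {"CB": "cell1", "UB": "u1"}, 90, 60),
                (120, False, {"CB": "cell1", "UB": "u1"}, 90, 60),
                (140, False, {"CB": "cell1", "UB": "u1"}, 90, 60),
                (160, False, {"CB": "cell1", "UB": "u2"}, 90, 60),
            ],
        )
        mat = count_umis(bam, [_feature("g:0", 0, 400)])
        assert mat.to_frame().loc["g:0", "cell1"] == 2

    def test_largest_overlap_wins(self, tmp_path):
        # read [350, 440): 50 nt in g:0 (ends 400), 90 in g:1 -> g:1? No:
        # overlap with g:0 = 400-350 = 50, with g:1 (starts 380) = 60
        bam = _write_bam(
            str(tmp_path / "b.bam"),
            [(350, False, {"CB": "c", "UB": "u"}, 90, 60)],
        )
        feats = [_feature("g:0", 0, 400), _feature("g:1", 380, 800)]
        df = count_umis(bam, feats).to_frame()
        assert df.loc["g:1", "c"] == 1
        assert df.loc["g:0", "c"] == 0

    def test_antisense_reads_not_counted(self, tmp_path):
        bam = _write_bam(
            str(tmp_path / "c.bam"),
            [(100, True, {"CB": "c", "UB": "u"}, 90, 60)],
        )
        mat = count_umis(bam, [_feature("g:0", 0, 400)])
        assert mat.total() == 0

    def test_missing_tags_reported_in_qc(self, tmp_path):
        bam = _write_bam(
            str(tmp_path / "d.bam"),
            [(100, False, {"CB": "c"}, 90, 60), (100, False, {"CB": "c", "UB": "u"}, 90, 60)],
        )
        mat = count_umis(bam, [_feature("g:0", 0, 400)])
        assert mat.qc["n_missing_tags"] == 1
        assert mat.total() == 1

    def test_matrix_equals_truth_with_duplicates(self, dup_sim):
        """Distinct-UMI counts reproduce the generator's truth exactly."""
        truth, feats = dup_sim["truth"], dup_sim["features"]
        df = dup_sim["matrix"].to_frame()
        checked = 0
        for f in feats:
            cands = [p for p in truth.pas
                     if p.gene_id == f.gene_id and abs(p.site - f.pas_site) <= 50]
            if len(cands) != 1:
                continue
            for cb, n in cands[0].cell_counts.items():
                got = df.loc[f.feature_id, cb] if cb in df.columns else 0
                assert got == n
                checked += 1
        assert checked > 500
        total_truth = sum(sum(p.cell_counts.values()) for p in truth.pas)
        assert dup_sim["matrix"].total() == total_truth

    def test_mtx_export_round_trip(self, dup_sim, tmp_path):
        from scipy.io import mmread

        out = str(tmp_path / "mtx")
        dup_sim["matrix"].write_mtx(out)
        counts = mmread(f"{out}/matrix.mtx").tocsr()
        assert counts.sum() == dup_sim["matrix"].total()


class TestRpm:
    def test_definition_and_determinism(self, tmp_path):
        reads = [(i * 10, False, {}, 90, 60) for i in range(40)]  # starts 0..390
        bam = _write_bam(str(tmp_path / "r.bam"), reads)
        regions = {
            "a": GenomeInterval("c1", 0, 500, "+"),
            "b": GenomeInterval("c1", 0, 500, "+"),
            "empty": GenomeInterval("c1", 5000, 6000, "+"),
        }
        rpm = compute_rpm(bam, regions)
        assert rpm["a"] == rpm["b"] == pytest.approx(1e6)
        assert rpm["empty"] == 0.0

    def test_low_mapq_reads_excluded(self, tmp_path):
        reads = [(100, False, {}, 90, 60), (100, False, {}, 90, 0)]
        bam = _write_bam(str(tmp_path / "q.bam"), reads)
        rpm = compute_rpm(bam, {"a": GenomeInterval("c1", 0, 500, "+")})
        # 1 of 2 mapped reads passes MAPQ >= 3
        assert rpm["a"] == pytest.approx(0.5e6)

    def test_no_mapped_reads_errors(self, tmp_path):
        bam = _write_bam(str(tmp_path / "e.bam"), [])
        with pytest.raises(ValueError):
            compute_rpm(bam, {"a": GenomeInterval("c1", 0, 500, "+")})
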