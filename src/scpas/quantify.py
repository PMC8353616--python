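"""PAS-based transcript annotation and per-cell UMI quantification.

Each surviving PAS becomes a feature: the exon chain of its best-matching
transcript truncated at the cleavage site.  Reads are then re-assigned to
these features (sense strand, largest overlap wins) and distinct UMIs are
counted per cell barcode per feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree
from scipy import sparse

from .annotation import GeneModel, GenomeInterval, Transcript
from .peaks import Peak


@dataclass
class PASTranscript:
    """A PAS-defined transcript isoform (exon chain clipped at the PAS)."""

    feature_id: str
    gene_id: str
    transcript_id: str
    exons: list[GenomeInterval]  # 5'->3' along the strand
    peak_region: GenomeInterval
    pas_site: int
    unspliced: bool = False

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand


@dataclass
class CellPASMatrix:
    features: list[str]
    barcodes: list[str]
    counts: sparse.csr_matrix  # features x barcodes
    qc: dict = field(default_factory=dict)

    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.toarray(), index=self.features, columns=self.barcodes
        )

    def write_mtx(self, directory: str) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        from scipy.io import mmwrite

        mmwrite(os.path.join(directory, "matrix.mtx"), self.counts)
        with open(os.path.join(directory, "features.tsv"), "w") as fh:
            fh.write("\n".join(self.features) + ("\n" if self.features else ""))
        with open(os.path.join(directory, "barcodes.tsv"), "w") as fh:
            fh.write("\n".join(self.barcodes) + ("\n" if self.barcodes else ""))

    def write_wide_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="feature")


def _clip_blocks_at(blocks: list[GenomeInterval], pas_site: int, strand: str) -> list[GenomeInterval]:
    """Peak footprint truncated at (and including) the PAS position."""
    out = []
    for b in sorted(blocks, key=lambda b: b.start):
        if strand == "+":
            lo, hi = b.start, min(b.end, pas_site + 1)
        else:
            lo, hi = max(b.start, pas_site), b.end
        if lo < hi:
            out.append(GenomeInterval(b.chrom, lo, hi, strand))
    return out


def _footprint_overlap(blocks: list[GenomeInterval], exons: list[GenomeInterval]) -> int:
    return sum(b.overlap(e) for b in blocks for e in exons)


def assign_peaks_to_transcripts(
    pas_calls: list[Peak], gene_models: list[GeneModel]
) -> list[PASTranscript]:
    """Assign each surviving PAS to the transcript that best contains its peak.

    The winning transcript maximises exonic overlap with the peak footprint
    (ties broken toward the longest transcript); the feature exon chain is
    the peak footprint — which may span exon junctions of that transcript —
    clipped at the PAS 3' end.  Peaks matching no transcript become
    contiguous features flagged ``unspliced``.
    """
    genes = {g.gene_id: g for g in gene_models}
    features: list[PASTranscript] = []
    per_gene_index: dict[str, int] = {}
    for peak in sorted(pas_calls, key=lambda p: (p.gene_id, p.three_prime_end)):
        gene = genes.get(peak.gene_id)
        idx = per_gene_index.get(peak.gene_id, 0)
        per_gene_index[peak.gene_id] = idx + 1
        feature_id = f"{peak.gene_id}:{idx}"
        best: tuple[int, int, Transcript] | None = None
        if gene is not None:
            for tx in gene.transcripts:
                ov = _footprint_overlap(peak.blocks, tx.exons)
                if ov > 0 and (best is None or (ov, tx.length) > (best[0], best[1])):
                    best = (ov, tx.length, tx)
        clipped = None
        if best is not None:
            clipped = _clip_blocks_at(peak.blocks, peak.three_prime_end, peak.strand)
        if clipped:
            features.append(
                PASTranscript(
                    feature_id=feature_id,
                    gene_id=peak.gene_id,
                    transcript_id=best[2].transcript_id,
                    exons=clipped,
                    peak_region=peak.interval,
                    pas_site=peak.three_prime_end,
                )
            )
        else:
            features.append(
                PASTranscript(
                    feature_id=feature_id,
                    gene_id=peak.gene_id,
                    transcript_id=peak.transcript_id,
                    exons=[peak.interval],
                    peak_region=peak.interval,
                    pas_site=peak.three_prime_end,
                    unspliced=True,
                )
            )
    return features


def write_pas_gtf(features: list[PASTranscript], path: str, source: str = "scpas") -> None:
    """Emit the PAS-based annotation as GTF (transcript_id = feature_id)."""
    with open(path, "w") as fh:
        fh.write("##format: gtf\n")
        by_gene: dict[str, list[PASTranscript]] = {}
        for f in features:
            by_gene.setdefault(f.gene_id, []).append(f)
        for gene_id, members in by_gene.items():
            lo = min(e.start for f in members for e in f.exons)
            hi = max(e.end for f in members for e in f.exons)
            chrom, strand = members[0].chrom, members[0].strand
            fh.write(
                f'{chrom}\t{source}\tgene\t{lo + 1}\t{hi}\t.\t{strand}\t.\tgene_id "{gene_id}";\n'
            )
            for f in members:
                span_lo = min(e.start for e in f.exons)
                span_hi = max(e.end for e in f.exons)
                attrs = f'gene_id "{gene_id}"; transcript_id "{f.feature_id}";'
                fh.write(
                    f"{chrom}\t{source}\ttranscript\t{span_lo + 1}\t{span_hi}\t.\t{strand}\t.\t{attrs}\n"
                )
                for e in sorted(f.exons, key=lambda e: e.start):
                    fh.write(
                        f"{chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{strand}\t.\t{attrs}\n"
                    )


def _feature_trees(features: list[PASTranscript]) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for fi, f in enumerate(features):
        key = (f.chrom, f.strand)
        tree = trees.setdefault(key, IntervalTree())
        for e in f.exons:
            tree.addi(e.start, e.end, fi)
    return trees


def count_umis(
    alignments: str | pysam.AlignmentFile,
    features: list[PASTranscript],
    cb_tag: str = "CB",
    umi_tag: str = "UB",
) -> CellPASMatrix:
    """Count distinct UMIs per (cell barcode, PAS feature).

    Reads are assigned sense-strand only; a read overlapping several
    features goes to the one with the largest overlap.  Exact overlap ties
    (nested isoforms sharing their exon prefix) go to the shortest feature:
    in 3' tag chemistry a read in the shared region piles against the
    nearest cleavage site.  Reads missing either tag are skipped and tallied
    in the QC report.
    """
    own = isinstance(alignments, str)
    bam = pysam.AlignmentFile(alignments) if own else alignments
    trees = _feature_trees(features)
    umis: dict[tuple[str, int], set[str]] = {}
    qc = {"n_reads": 0, "n_missing_tags": 0, "n_unassigned": 0, "n_assigned": 0}
    try:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            qc["n_reads"] += 1
            if not (read.has_tag(cb_tag) and read.has_tag(umi_tag)):
                qc["n_missing_tags"] += 1
                continue
            strand = "-" if read.is_reverse else "+"
            tree = trees.get((read.reference_name, strand))
            if tree is None:
                qc["n_unassigned"] += 1
                continue
            overlaps: dict[int, int] = {}
            for blk_start, blk_end in read.get_blocks():
                for hit in tree.overlap(blk_start, blk_end):
                    ov = min(blk_end, hit.end) - max(blk_start, hit.begin)
                    overlaps[hit.data] = overlaps.get(hit.data, 0) + ov
            if not overlaps:
                qc["n_unassigned"] += 1
                continue
            best = min(
                overlaps.items(),
                key=lambda kv: (
                    -kv[1],
                    sum(len(e) for e in features[kv[0]].exons),
                    features[kv[0]].feature_id,
                ),
            )[0]
            qc["n_assigned"] += 1
            cb = read.get_tag(cb_tag)
            ub = read.get_tag(umi_tag)
            umis.setdefault((cb, best), set()).add(ub)
    finally:
        if own:
            bam.close()
    barcodes = sorted({cb for cb, _ in umis})
    bc_index = {cb: i for i, cb in enumerate(barcodes)}
    rows, cols, vals = [], [], []
    for (cb, fi), u in umis.items():
        rows.append(fi)
        cols.append(bc_index[cb])
        vals.append(len(u))
    counts = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(features), len(barcodes)), dtype=np.int64
    )
    return CellPASMatrix([f.feature_id for f in features], barcodes, counts, qc)


def compute_rpm(
    alignments: str | pysam.AlignmentFile,
    regions: dict[str, GenomeInterval],
    min_mapq: int = 3,
) -> pd.Series:
    """Reads-per-million over stranded regions (multi-region overlap allowed).

    A read (primary, mapped, MAPQ >= ``min_mapq``) is counted once in every
    sense-strand region it overlaps; normalisation is by the total number of
    mapped primary reads in the file, times one million.
    """
    own = isinstance(alignments, str)
    bam = pysam.AlignmentFile(alignments) if own else alignments
    trees: dict[tuple[str, str], IntervalTree] = {}
    ids = list(regions)
    for i, rid in enumerate(ids):
        iv = regions[rid]
        trees.setdefault((iv.chrom, iv.strand), IntervalTree()).addi(iv.start, iv.end, i)
    counts = np.zeros(len(ids))
    total = 0
    try:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            total += 1
            if read.mapping_quality < min_mapq:
                continue
            strand = "-" if read.is_reverse else "+"
            tree = trees.get((read.reference_name, strand))
            if tree is None:
                continue
            hits = set()
            for blk_start, blk_end in read.get_blocks():
                for hit in tree.overlap(blk_start, blk_end):
                    hits.add(hit.data)
            for h in hits:
                counts[h] += 1
    finally:
        if own:
            bam.close()
    if total == 0:
        raise ValueError("alignment file contains no mapped reads")
    return pd.Series(counts / total * 1e6, index=ids)
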