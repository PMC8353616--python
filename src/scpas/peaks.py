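"""Transcript-level peak calling from 3' tag scRNA-seq alignments.

3' tag chemistry piles read 5' starts in a ~400-nt window upstream of each
cleavage site, so peaks are called on read-start coverage with a fixed
width and the peak's strand-oriented downstream edge is taken as the
candidate cleavage position.  Coverage is scanned per transcript in spliced
(exon) coordinate space — called windows may therefore span exon junctions —
and additionally per intron in contiguous genomic space, which is where
internal-priming artifacts accumulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pysam
from scipy import stats

from .annotation import GeneModel, Genome, GenomeInterval, Transcript
from .dip import dip_pvalue

DEFAULT_PEAK_SIZE = 400
DEFAULT_MIN_DIST = 10
DEFAULT_MIN_COUNT = 10


@dataclass
class Peak:
    """A called coverage peak anchored at a candidate cleavage site."""

    interval: GenomeInterval  # genomic span (first..last block)
    blocks: list[GenomeInterval]  # genomic footprint, may span junctions
    gene_id: str
    transcript_id: str
    read_count: int
    three_prime_end: int  # genomic position of the strand-oriented 3' edge
    category: str  # "exonic" | "intronic"
    modality: str = "unassessed"  # "unimodal" | "multimodal" | "unassessed"
    profile: np.ndarray | None = field(default=None, repr=False)
    normality_stat: float | None = None

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand


def _read_five_prime(read: pysam.AlignedSegment) -> int:
    return read.reference_end - 1 if read.is_reverse else read.reference_start


def _read_strand(read: pysam.AlignedSegment) -> str:
    return "-" if read.is_reverse else "+"


def collect_read_starts(
    alignments: str | pysam.AlignmentFile,
) -> dict[tuple[str, str], np.ndarray]:
    """Read 5'-start positions per (chrom, strand) from a sorted BAM/SAM."""
    own = isinstance(alignments, str)
    bam = pysam.AlignmentFile(alignments) if own else alignments
    try:
        if bam.header.get("HD", {}).get("SO") != "coordinate":
            raise ValueError("alignments must be coordinate-sorted (SO:coordinate)")
        starts: dict[tuple[str, str], list[int]] = {}
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            key = (read.reference_name, _read_strand(read))
            starts.setdefault(key, []).append(_read_five_prime(read))
    finally:
        if own:
            bam.close()
    return {k: np.sort(np.array(v, dtype=np.int64)) for k, v in starts.items()}


def _greedy_windows(
    coverage: np.ndarray, size: int, min_dist: int, min_count: int
) -> list[tuple[int, int, np.ndarray]]:
    """Greedy fixed-width window selection on a 1-D read-start coverage array.

    Repeatedly accepts the window with the highest remaining start count,
    removes the starts it consumed, and enforces that accepted summits are
    more than ``min_dist`` apart.  Returns (window_start, count, profile).
    """
    cov = coverage.astype(float).copy()
    n = len(cov)
    if n == 0:
        return []
    size = min(size, n)
    out: list[tuple[int, int, np.ndarray]] = []
    summits: list[int] = []
    kernel = np.ones(size)
    while True:
        win = np.convolve(cov, kernel, mode="valid")  # win[w] = sum cov[w:w+size]
        # among tied windows take the most 3' one: read starts pile upstream
        # of the cleavage site, so the downstream window edge is the site
        w = len(win) - 1 - int(np.argmax(win[::-1]))
        count = win[w]
        if count < min_count:
            break
        profile = cov[w : w + size].copy()
        summit = w + int(np.argmax(profile))
        if all(abs(summit - s) > min_dist for s in summits):
            out.append((w, int(round(count)), profile))
            summits.append(summit)
        cov[w : w + size] = 0.0
    return out


def _coverage_from_starts(starts: np.ndarray, lo: int, hi: int) -> np.ndarray:
    sel = starts[(starts >= lo) & (starts < hi)]
    return np.bincount(sel - lo, minlength=hi - lo).astype(float)


def call_raw_peaks(
    alignments: str | pysam.AlignmentFile | dict[tuple[str, str], np.ndarray],
    gene_models: list[GeneModel],
    size: int = DEFAULT_PEAK_SIZE,
    min_dist: int = DEFAULT_MIN_DIST,
    min_count: int = DEFAULT_MIN_COUNT,
) -> list[Peak]:
    """Call fixed-width peaks per transcript (spliced space) and per intron.

    Peaks are returned ordered by descending read count.  Exonic peaks carry
    a genomic footprint mapped back through the exon chain; intronic peaks
    (3' end outside all exons of the assigned transcript) are contiguous.
    """
    if isinstance(alignments, dict):
        starts_by_key = alignments
    else:
        starts_by_key = collect_read_starts(alignments)
    peaks: list[Peak] = []
    for gene in gene_models:
        for tx in gene.transcripts:
            key = (tx.chrom, tx.strand)
            starts = starts_by_key.get(key)
            if starts is None or len(starts) == 0:
                continue
            peaks.extend(
                _call_transcript(starts, gene.gene_id, tx, size, min_dist, min_count)
            )
            peaks.extend(
                _call_introns(starts, gene.gene_id, tx, size, min_dist, min_count)
            )
    peaks.sort(key=lambda p: -p.read_count)
    return peaks


def _call_transcript(
    starts: np.ndarray,
    gene_id: str,
    tx: Transcript,
    size: int,
    min_dist: int,
    min_count: int,
) -> list[Peak]:
    # spliced 5'->3' coverage of read starts falling in exons
    cov = np.zeros(tx.length)
    span = tx.span
    for pos in starts[(starts >= span.start) & (starts < span.end)]:
        sp = tx.to_spliced(int(pos))
        if sp is not None:
            cov[sp] += 1
    out = []
    for w, count, profile in _greedy_windows(cov, size, min_dist, min_count):
        w_end = min(w + size, tx.length)
        blocks = tx.spliced_blocks(w, w_end)
        three_prime = tx.to_genomic(w_end - 1)
        interval = GenomeInterval(
            tx.chrom, min(b.start for b in blocks), max(b.end for b in blocks), tx.strand
        )
        out.append(
            Peak(
                interval=interval,
                blocks=blocks,
                gene_id=gene_id,
                transcript_id=tx.transcript_id,
                read_count=count,
                three_prime_end=three_prime,
                category="exonic",
                profile=profile,
            )
        )
    return out


def _call_introns(
    starts: np.ndarray,
    gene_id: str,
    tx: Transcript,
    size: int,
    min_dist: int,
    min_count: int,
) -> list[Peak]:
    out = []
    for intron in tx.introns():
        cov = _coverage_from_starts(starts, intron.start, intron.end)
        if tx.strand == "-":
            cov = cov[::-1]  # scan 5'->3' along the strand
        for w, count, profile in _greedy_windows(cov, size, min_dist, min_count):
            w_end = min(w + size, len(cov))
            if tx.strand == "+":
                g0, g1 = intron.start + w, intron.start + w_end
                three_prime = g1 - 1
            else:
                g1, g0 = intron.end - w, intron.end - w_end
                three_prime = g0
            iv = GenomeInterval(intron.chrom, g0, g1, tx.strand)
            out.append(
                Peak(
                    interval=iv,
                    blocks=[iv],
                    gene_id=gene_id,
                    transcript_id=tx.transcript_id,
                    read_count=count,
                    three_prime_end=three_prime,
                    category="intronic",
                    profile=profile,
                )
            )
    return out


def assess_modality(
    coverage_profile: np.ndarray,
    alpha: float = 0.05,
    max_points: int = 120,
    n_boot: int = 100,
    seed: int = 0,
) -> tuple[str, float | None]:
    """Classify a peak coverage profile as unimodal or multimodal.

    The profile (per-position read-start counts) is converted into a
    position sample via weighted quantiles, dithered to break integer ties,
    and tested with the dip statistic; rejection at ``alpha`` means
    multimodal.  An Anderson-Darling normality statistic on the same sample
    is returned as metadata.
    """
    profile = np.asarray(coverage_profile, dtype=float)
    total = profile.sum()
    if total <= 0:
        return "unimodal", None
    nonzero = np.count_nonzero(profile)
    if nonzero == 1 or len(profile) < 30:
        return "unimodal", None
    # deterministic weighted-quantile sample of positions; never draw more
    # points than there are reads, or duplicates masquerade as modes
    n_points = int(min(max_points, total))
    cdf = np.cumsum(profile) / total
    q = (np.arange(n_points) + 0.5) / n_points
    samples = np.searchsorted(cdf, q).astype(float)
    rng = np.random.default_rng(seed)
    samples = samples + rng.uniform(-0.5, 0.5, size=len(samples))
    _, p = dip_pvalue(samples, n_boot=n_boot, seed=seed)
    try:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", FutureWarning)
            ad = float(stats.anderson(samples, dist="norm").statistic)
    except Exception:
        ad = None
    return ("multimodal" if p < alpha else "unimodal"), ad


def split_multimodal(peak: Peak, coverage_profile: np.ndarray | None = None) -> list[Peak]:
    """Split a multimodal peak at the deepest minimum between its two top modes."""
    if peak.modality != "multimodal":
        return [peak]
    profile = coverage_profile if coverage_profile is not None else peak.profile
    if profile is None:
        return [peak]
    profile = np.asarray(profile, dtype=float)
    smooth = np.convolve(profile, np.ones(11) / 11, mode="same")
    # two highest separated local maxima (plateau-aware)
    from scipy.signal import find_peaks

    maxima, _props = find_peaks(smooth, distance=25, plateau_size=1)
    if len(maxima) < 2:
        return [peak]
    top2 = maxima[np.argsort(smooth[maxima])[::-1][:2]]
    m1, m2 = int(top2[0]), int(top2[1])
    lo, hi = sorted((m1, m2))
    cut = lo + int(np.argmin(smooth[lo : hi + 1]))
    if cut <= 0 or cut >= len(profile) - 1:
        return [peak]
    left_count = int(round(profile[:cut].sum()))
    right_count = peak.read_count - left_count
    children = []
    for side, (p0, p1, count) in enumerate(
        [(0, cut, left_count), (cut, len(profile), right_count)]
    ):
        child = _clip_peak(peak, p0, p1)
        if child is None:
            continue
        child.read_count = count
        child.modality = "unimodal"
        child.profile = profile[p0:p1].copy()
        children.append(child)
    return children if len(children) == 2 else [peak]


def _clip_peak(peak: Peak, p0: int, p1: int) -> Peak | None:
    """Clip a peak to profile positions [p0, p1) (5'->3' along the strand)."""
    width = sum(len(b) for b in peak.blocks)
    p1 = min(p1, width)
    if p0 >= p1:
        return None
    blocks5to3 = peak.blocks if peak.strand == "+" else list(reversed(peak.blocks))
    new_blocks: list[GenomeInterval] = []
    offset = 0
    for b in blocks5to3:
        lo = max(p0, offset)
        hi = min(p1, offset + len(b))
        if lo < hi:
            if peak.strand == "+":
                new_blocks.append(
                    GenomeInterval(b.chrom, b.start + (lo - offset), b.start + (hi - offset), b.strand)
                )
            else:
                new_blocks.append(
                    GenomeInterval(b.chrom, b.end - (hi - offset), b.end - (lo - offset), b.strand)
                )
        offset += len(b)
    new_blocks.sort(key=lambda b: b.start)
    interval = GenomeInterval(
        peak.chrom,
        min(b.start for b in new_blocks),
        max(b.end for b in new_blocks),
        peak.strand,
    )
    three_prime = interval.end - 1 if peak.strand == "+" else interval.start
    return replace(
        peak,
        interval=interval,
        blocks=new_blocks,
        three_prime_end=three_prime,
        profile=None,
    )


def assess_and_split(peaks: list[Peak], alpha: float = 0.05, seed: int = 0) -> list[Peak]:
    """Run modality assessment on each peak and split the multimodal ones."""
    out: list[Peak] = []
    for peak in peaks:
        if peak.profile is not None:
            modality, ad = assess_modality(peak.profile, alpha=alpha, seed=seed)
            peak.modality = modality
            peak.normality_stat = ad
        else:
            peak.modality = "unimodal"
        out.extend(split_multimodal(peak) if peak.modality == "multimodal" else [peak])
    return out


def _overlap_fraction(a: Peak, b: Peak) -> float:
    ov = a.interval.overlap(b.interval)
    shorter = min(len(a.interval), len(b.interval))
    return ov / shorter if shorter else 0.0


def aggregate_gene_peaks(peaks: list[Peak], min_overlap: float = 0.5) -> list[Peak]:
    """Within each gene, collapse peaks overlapping >= 50% (of the shorter peak).

    Groups are formed transitively; each group keeps only its maximally
    expressed member.  The result is idempotent: retained peaks within a
    gene pairwise overlap below the threshold.
    """
    by_gene: dict[str, list[Peak]] = {}
    for p in peaks:
        by_gene.setdefault(p.gene_id, []).append(p)
    out: list[Peak] = []
    for members in by_gene.values():
        n = len(members)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if (
                    members[i].strand == members[j].strand
                    and _overlap_fraction(members[i], members[j]) >= min_overlap
                ):
                    parent[find(i)] = find(j)
        groups: dict[int, list[Peak]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(members[i])
        for group in groups.values():
            out.append(max(group, key=lambda p: p.read_count))
    out.sort(key=lambda p: -p.read_count)
    return out


def filter_low_coverage(peaks: list[Peak], max_fraction: float = 0.01) -> list[Peak]:
    """Drop peaks contributing <= 1% of the read count of their gene locus."""
    totals: dict[str, int] = {}
    for p in peaks:
        totals[p.gene_id] = totals.get(p.gene_id, 0) + p.read_count
    return [
        p
        for p in peaks
        if totals[p.gene_id] == 0 or p.read_count / totals[p.gene_id] > max_fraction
    ]


def filter_internal_priming(
    peaks: list[Peak],
    genome: Genome,
    min_a_run: int = 8,
    window_upstream: int = 10,
    window_downstream: int = 20,
) -> list[Peak]:
    """Remove intronic peaks with >= 8 consecutive adenines around the 3' end.

    The scan window is strand-oriented [3'end - 10, 3'end + 20], clipped at
    contig bounds; exonic peaks are untouched — oligo(dT) mispriming on
    genomic A-runs is an intron-specific artifact mode.
    """
    run = "A" * min_a_run
    out = []
    for p in peaks:
        if p.category != "intronic":
            out.append(p)
            continue
        tpe = p.three_prime_end
        if p.strand == "+":
            lo, hi = tpe - window_upstream, tpe + window_downstream + 1
        else:
            lo, hi = tpe - window_downstream, tpe + window_upstream + 1
        lo = max(0, lo)
        hi = min(genome.length(p.chrom), hi)
        seq = genome.fetch(p.chrom, lo, hi, p.strand)
        if run not in seq:
            out.append(p)
    return out


def write_peaks_bed(peaks: list[Peak], path: str) -> None:
    """BED6 + annotation columns (gene, transcript, count, category, modality)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(
                f"{p.chrom}\t{p.interval.start}\t{p.interval.end}\tpeak_{i}\t"
                f"{p.read_count}\t{p.strand}\t{p.gene_id}\t{p.transcript_id}\t"
                f"{p.three_prime_end}\t{p.category}\t{p.modality}\n"
            )
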