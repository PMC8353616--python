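"""Synthetic genomes, annotations and tagged alignments with known truth.

The generator emulates the geometry this pipeline assumes from 3' tag
(oligo(dT)-primed) single-cell chemistry: multi-exon genes; planted
cleavage sites carrying the canonical AATAAA signal ~25 nt upstream, CA at
the cut and a downstream U-rich (T on DNA) stretch; read 5' starts piled in
the ~400-nt window upstream of each site; cell-barcode/UMI tags with an
optional PCR-duplicate rate; and intronic adenine runs with an upstream
read pile as internal-priming artifacts.  Every emitted file is consistent
with the returned truth table, so each stage of the pipeline can be scored
against planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pysam

from .annotation import (
    GeneModel,
    Genome,
    GenomeInterval,
    PASRecord,
    PASSet,
    Transcript,
    reverse_complement,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the default synthetic benchmark."""

    n_chroms: int = 2
    n_genes: int = 50
    exon_len: int = 200  # first/middle exons
    intron_len: int = 600
    pas_per_gene: tuple[int, int] = (2, 3)  # inclusive range
    first_pas_offset: int = 450  # into the last exon
    pas_spacing: int = 600
    last_exon_margin: int = 150  # sequence past the distal PAS
    intergenic_len: int = 1500
    n_cells: int = 200
    umis_per_pas_per_cell: float = 0.5  # ~100 molecules per site at 200 cells
    umi_length: int = 10
    barcode_length: int = 12
    read_length: int = 90
    duplicate_rate: float = 0.0
    internal_priming_rate: float = 0.3  # fraction of genes with an intronic A-run
    artifact_run_length: int = 12
    artifact_reads: int = 150
    polya_signal_strength: float = 1.0
    background_homopolymer_rate: float = 0.5  # A/T runs per kb of intergenic sequence
    seed: int = 0


@dataclass
class PlantedPAS:
    gene_id: str
    chrom: str
    strand: str
    site: int  # genomic cleavage position (0-based)
    has_signal: bool
    cell_counts: dict[str, int] = field(default_factory=dict)  # barcode -> distinct UMIs

    def record(self) -> PASRecord:
        return PASRecord(self.chrom, self.site, self.strand, frozenset({"GENCODE"}))


@dataclass
class ArtifactSite:
    gene_id: str
    chrom: str
    strand: str
    position: int  # genomic position of the artifact "cleavage" point


@dataclass
class TruthTable:
    pas: list[PlantedPAS]
    artifacts: list[ArtifactSite]

    def pas_set(self) -> PASSet:
        return PASSet([p.record() for p in self.pas], tier="known")

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("kind\tgene_id\tchrom\tposition\tstrand\thas_signal\ttotal_umis\n")
            for p in self.pas:
                fh.write(
                    f"pas\t{p.gene_id}\t{p.chrom}\t{p.site}\t{p.strand}\t"
                    f"{int(p.has_signal)}\t{sum(p.cell_counts.values())}\n"
                )
            for a in self.artifacts:
                fh.write(f"artifact\t{a.gene_id}\t{a.chrom}\t{a.position}\t{a.strand}\t0\t0\n")


T_RICH = ("T", "T", "T", "T", "T", "T", "T", "A", "C", "G")  # 70% T


def _sense_to_genomic(gstart: int, gend: int, strand: str, s: int) -> int:
    return gstart + s if strand == "+" else gend - 1 - s


def _plant_sense(seq: np.ndarray, gstart: int, gend: int, strand: str,
                 sense_start: int, motif: str) -> None:
    """Write ``motif`` (sense alphabet) at sense offset range into the genomic array."""
    if strand == "+":
        g0 = gstart + sense_start
        seq[g0 : g0 + len(motif)] = list(motif)
    else:
        g1 = gend - sense_start  # exclusive sense start maps to genomic end
        g0 = g1 - len(motif)
        seq[g0:g1] = list(reverse_complement(motif))


def simulate_genome(config: SimulationConfig) -> tuple[Genome, list[GeneModel], TruthTable]:
    """Build a random genome with planted genes, PASs and intronic artifacts."""
    rng = np.random.default_rng(config.seed)
    cfg = config
    genes_per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        genes_per_chrom[i] += 1
    chrom_seqs: dict[str, str] = {}
    gene_models: list[GeneModel] = []
    planted: list[PlantedPAS] = []
    artifacts: list[ArtifactSite] = []
    gene_idx = 0
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        pieces: list[np.ndarray] = []
        cursor = 0
        layout: list[tuple[int, int, str, int, bool]] = []  # gstart, gene_len, strand, n_pas, artifact

        def _random_seq(n: int) -> np.ndarray:
            return rng.choice(list("ACGT"), size=n)

        def _intergenic_seq(n: int) -> np.ndarray:
            # real intergenic sequence is rich in low-complexity homopolymers;
            # emulate with Poisson-placed A/T runs so sampled negatives see them
            s = _random_seq(n)
            for _ in range(rng.poisson(n / 1000 * cfg.background_homopolymer_rate)):
                run_len = int(rng.integers(6, 16))
                if run_len >= n:
                    continue
                pos = int(rng.integers(0, n - run_len))
                s[pos : pos + run_len] = "A" if rng.uniform() < 0.5 else "T"
            return s

        pieces.append(_intergenic_seq(cfg.intergenic_len))
        cursor += cfg.intergenic_len
        for _ in range(genes_per_chrom[ci]):
            n_pas = int(rng.integers(cfg.pas_per_gene[0], cfg.pas_per_gene[1] + 1))
            last_exon_len = (
                cfg.first_pas_offset + (n_pas - 1) * cfg.pas_spacing + cfg.last_exon_margin
            )
            gene_len = 2 * cfg.exon_len + 2 * cfg.intron_len + last_exon_len
            strand = "+" if gene_idx % 2 == 0 else "-"
            has_artifact = rng.uniform() < cfg.internal_priming_rate
            layout.append((cursor, gene_len, strand, n_pas, has_artifact))
            pieces.append(_random_seq(gene_len))
            cursor += gene_len
            pieces.append(_intergenic_seq(cfg.intergenic_len))
            cursor += cfg.intergenic_len
            gene_idx += 1
        seq = np.concatenate(pieces)
        for gstart, gene_len, strand, n_pas, has_artifact in layout:
            gid = f"gene_{len(gene_models):04d}"
            gend = gstart + gene_len
            # sense-space exon layout: exon1, intron, exon2, intron, last exon
            e = cfg.exon_len
            i_len = cfg.intron_len
            sense_exons = [
                (0, e),
                (e + i_len, 2 * e + i_len),
                (2 * e + 2 * i_len, gene_len),
            ]
            exon_ivs = []
            for s0, s1 in sense_exons:
                g_a = _sense_to_genomic(gstart, gend, strand, s0)
                g_b = _sense_to_genomic(gstart, gend, strand, s1 - 1)
                lo, hi = min(g_a, g_b), max(g_a, g_b) + 1
                exon_ivs.append(GenomeInterval(chrom, lo, hi, strand))
            tx = Transcript(f"{gid}.t1", exon_ivs)
            gene_models.append(GeneModel(gid, [tx]))
            last_exon_sense_start = 2 * e + 2 * i_len
            for k in range(n_pas):
                sense_pos = last_exon_sense_start + cfg.first_pas_offset + k * cfg.pas_spacing
                has_signal = bool(rng.uniform() < cfg.polya_signal_strength)
                if has_signal:
                    sig_start = int(rng.integers(-30, -25))  # motif stays in [-30, -20]
                    _plant_sense(seq, gstart, gend, strand, sense_pos + sig_start, "AATAAA")
                    _plant_sense(seq, gstart, gend, strand, sense_pos - 1, "CA")
                    trich = "".join(rng.choice(T_RICH, size=20))
                    _plant_sense(seq, gstart, gend, strand, sense_pos + 5, trich)
                site = _sense_to_genomic(gstart, gend, strand, sense_pos)
                planted.append(PlantedPAS(gid, chrom, strand, site, has_signal))
            if has_artifact:
                # artifact point deep in the first intron, far enough that the
                # whole upstream read pile stays intronic
                sense_art = e + i_len - 150
                run = "A" * cfg.artifact_run_length
                _plant_sense(seq, gstart, gend, strand, sense_art, run)
                apos = _sense_to_genomic(gstart, gend, strand, sense_art)
                artifacts.append(ArtifactSite(gid, chrom, strand, apos))
        chrom_seqs[chrom] = "".join(seq)
    genome = Genome(chrom_seqs)
    return genome, gene_models, TruthTable(planted, artifacts)


def _make_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seen: set[str] = set()
    while len(seen) < n:
        seen.add("".join(rng.choice(list("ACGT"), size=length)))
    return sorted(seen)


def simulate_reads(
    genome: Genome,
    gene_models: list[GeneModel],
    truth: TruthTable,
    config: SimulationConfig,
    bam_path: str,
) -> TruthTable:
    """Emit a coordinate-sorted, indexed BAM of tagged reads.

    Read 5' starts are uniform in the strand-oriented window [site-400,
    site-50]; artifact reads pile upstream of the planted intronic A-runs.
    The returned truth table carries the per-cell distinct-UMI counts that
    were actually emitted, so UMI counting can be checked exactly.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1)
    barcodes = _make_barcodes(rng, cfg.n_cells, cfg.barcode_length)
    tx_by_gene = {g.gene_id: g.transcripts[0] for g in gene_models}
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": genome.length(c)} for c in genome.chroms()],
    }
    reads: list[tuple[str, int, bool, str, str, str]] = []  # chrom,pos,rev,seq,cb,ub
    new_pas: list[PlantedPAS] = []

    def _emit(chrom: str, strand: str, sense_site_to_genomic, sense_lo: int, sense_hi: int,
              cb: str, ub: str, clip_at: int | None = None) -> None:
        s0 = int(rng.integers(sense_lo, sense_hi + 1))
        # a cDNA read cannot extend past the cleavage point of its transcript
        # (the site position itself is the first untemplated tail base)
        length = cfg.read_length
        if clip_at is not None:
            length = min(length, clip_at - s0)
        g_a = sense_site_to_genomic(s0)
        g_b = sense_site_to_genomic(s0 + length - 1)
        pos = min(g_a, g_b)
        seq = genome.fetch(chrom, pos, pos + length, "+")
        reads.append((chrom, pos, strand == "-", seq, cb, ub))

    for p in truth.pas:
        tx = tx_by_gene[p.gene_id]
        sense_site = tx.to_spliced(p.site)
        assert sense_site is not None

        def site_map(s: int, tx=tx) -> int:
            return tx.to_genomic(s)

        counts: dict[str, int] = {}
        n_per_cell = rng.poisson(cfg.umis_per_pas_per_cell, size=cfg.n_cells)
        if n_per_cell.sum() == 0:
            n_per_cell[int(rng.integers(cfg.n_cells))] = 1
        for cell_i in np.nonzero(n_per_cell)[0]:
            cb = barcodes[cell_i]
            n_umi = int(n_per_cell[cell_i])
            umis: set[str] = set()
            while len(umis) < n_umi:
                umis.add("".join(rng.choice(list("ACGT"), size=cfg.umi_length)))
            counts[cb] = n_umi
            for ub in sorted(umis):
                _emit(p.chrom, p.strand, site_map, sense_site - 400, sense_site - 50,
                      cb, ub, clip_at=sense_site)
                while rng.uniform() < cfg.duplicate_rate:
                    _emit(p.chrom, p.strand, site_map, sense_site - 400, sense_site - 50,
                          cb, ub, clip_at=sense_site)
        new_pas.append(replace(p, cell_counts=counts))

    for a in truth.artifacts:
        # contiguous genomic pile upstream (sense) of the A-run
        def art_map(s: int, a=a) -> int:
            return a.position + s if a.strand == "+" else a.position - s

        for _ in range(cfg.artifact_reads):
            cb = barcodes[int(rng.integers(cfg.n_cells))]
            ub = "".join(rng.choice(list("ACGT"), size=cfg.umi_length))
            _emit(a.chrom, a.strand, art_map, -400, -50, cb, ub)

    reads.sort(key=lambda r: (r[0], r[1]))
    with pysam.AlignmentFile(bam_path, "wb", header=header) as bam:
        for i, (chrom, pos, rev, seq, cb, ub) in enumerate(reads):
            aln = pysam.AlignedSegment(bam.header)
            aln.query_name = f"read_{i}"
            aln.query_sequence = seq
            aln.flag = 16 if rev else 0
            aln.reference_id = bam.get_tid(chrom)
            aln.reference_start = pos
            aln.mapping_quality = 60
            aln.cigarstring = f"{len(seq)}M"
            aln.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            aln.set_tag("CB", cb)
            aln.set_tag("UB", ub)
            bam.write(aln)
    pysam.index(bam_path)
    return TruthTable(new_pas, truth.artifacts)


@dataclass
class TrainingBenchmark:
    genome: Genome
    gene_models: list[GeneModel]
    pas_train: PASSet
    pas_validation: PASSet
    shifted_positives: list
    fixed_positives: list
    negatives: list  # matched to the shifted positives
    negatives_fixed: list


def make_training_benchmark(
    n_pas: int = 556,  # 9:1 split leaves 500 training sites -> ~5,000 shifted windows
    n_per_pas: int = 10,
    seed: int = 0,
    polya_signal_strength: float = 1.0,
    split_ratio: float = 0.9,
) -> TrainingBenchmark:
    """Desk-scale labelled corpus: planted signal-bearing sites vs background.

    Builds a dedicated synthetic genome carrying ``n_pas`` signal-bearing
    sites, splits them 9:1 into training and validation, and constructs the
    class-balanced shifted and fixed positive sets plus matched intergenic
    negatives — the same construction the classifier applies to real
    annotation, applied to planted truth.
    """
    from .annotation import split_train_validation
    from .classifier import make_fixed_positives, make_shifted_positives, sample_negatives

    pas_per_gene = 2
    n_genes = max(2, (n_pas + pas_per_gene - 1) // pas_per_gene)
    cfg = SimulationConfig(
        n_chroms=4,
        n_genes=n_genes,
        pas_per_gene=(pas_per_gene, pas_per_gene),
        internal_priming_rate=0.0,
        polya_signal_strength=polya_signal_strength,
        seed=seed,
    )
    genome, genes, truth = simulate_genome(cfg)
    full = truth.pas_set()
    full.records = full.records[:n_pas]
    train, val = split_train_validation(full, split_ratio, seed=seed + 1)
    shifted = make_shifted_positives(train, genome, n_per_pas=n_per_pas, seed=seed + 2)
    fixed = make_fixed_positives(train, genome)
    negatives = sample_negatives(genome, full, genes, n=len(shifted), seed=seed + 3)
    negatives_fixed = negatives[: len(fixed)]
    return TrainingBenchmark(
        genome=genome,
        gene_models=genes,
        pas_train=train,
        pas_validation=val,
        shifted_positives=shifted,
        fixed_positives=fixed,
        negatives=negatives,
        negatives_fixed=negatives_fixed,
    )
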