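"""Genomic data model and standard-format I/O.

Coordinates are 0-based half-open internally; GTF I/O converts to and from
the 1-based inclusive convention.  Strand-oriented arithmetic ("upstream",
"3' end") always refers to the transcribed strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

STRANDS = ("+", "-")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Recognised PAS database labels.  DB1..DB3 are the three site databases;
#: GENCODE is the curated annotation.
PAS_SOURCES = ("DB1", "DB2", "DB3", "GENCODE")
_DB_SOURCES = frozenset(PAS_SOURCES[:3])


class FormatError(ValueError):
    """Raised when an input file does not conform to its declared format."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomeInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    @property
    def three_prime(self) -> int:
        """Position of the last transcribed base (strand-oriented 3' end)."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class Transcript:
    transcript_id: str
    exons: list[GenomeInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        strand = self.exons[0].strand
        ordered = sorted(self.exons, key=lambda e: e.start, reverse=(strand == "-"))
        for a, b in zip(ordered, ordered[1:]):
            gap_ok = b.start >= a.end if strand == "+" else a.start >= b.end
            if not gap_ok:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"{(a.start, a.end)} and {(b.start, b.end)}"
                )
        self.exons = ordered  # 5' -> 3' along the strand

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(
            self.chrom,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
            self.strand,
        )

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def three_prime(self) -> int:
        return self.exons[-1].three_prime

    def introns(self) -> list[GenomeInterval]:
        out = []
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if b.start > a.end:
                out.append(GenomeInterval(self.chrom, a.end, b.start, self.strand))
        return out

    def to_spliced(self, genomic_pos: int) -> int | None:
        """Map a genomic position into 5'->3' spliced coordinates (or None)."""
        offset = 0
        for exon in self.exons:
            if exon.start <= genomic_pos < exon.end:
                if self.strand == "+":
                    return offset + (genomic_pos - exon.start)
                return offset + (exon.end - 1 - genomic_pos)
            offset += len(exon)
        return None

    def to_genomic(self, spliced_pos: int) -> int:
        """Map a spliced 5'->3' coordinate back to a genomic position."""
        if not 0 <= spliced_pos < self.length:
            raise ValueError(f"spliced position {spliced_pos} outside transcript")
        offset = 0
        for exon in self.exons:
            if spliced_pos < offset + len(exon):
                within = spliced_pos - offset
                if self.strand == "+":
                    return exon.start + within
                return exon.end - 1 - within
            offset += len(exon)
        raise AssertionError("unreachable")

    def spliced_blocks(self, sp_start: int, sp_end: int) -> list[GenomeInterval]:
        """Genomic footprint of the spliced window [sp_start, sp_end)."""
        if not (0 <= sp_start < sp_end <= self.length):
            raise ValueError("spliced window outside transcript")
        blocks: list[GenomeInterval] = []
        offset = 0
        for exon in self.exons:
            lo = max(sp_start, offset)
            hi = min(sp_end, offset + len(exon))
            if lo < hi:
                if self.strand == "+":
                    g0 = exon.start + (lo - offset)
                    g1 = exon.start + (hi - offset)
                else:
                    g1 = exon.end - (lo - offset)
                    g0 = exon.end - (hi - offset)
                blocks.append(GenomeInterval(self.chrom, g0, g1, self.strand))
            offset += len(exon)
        return sorted(blocks, key=lambda b: b.start)


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[Transcript]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(
            self.chrom,
            min(t.span.start for t in self.transcripts),
            max(t.span.end for t in self.transcripts),
            self.strand,
        )

    @property
    def three_prime(self) -> int:
        """Annotated gene 3' end: the most 3' transcript end."""
        ends = [t.three_prime for t in self.transcripts]
        return max(ends) if self.strand == "+" else min(ends)

    def exons(self) -> list[GenomeInterval]:
        return [e for t in self.transcripts for e in t.exons]


class Genome:
    """In-memory genome with strand-aware subsequence extraction."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {c: s.upper() for c, s in sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def chroms(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Strand-oriented subsequence; minus strand is reverse-complemented.

        Coordinates are clipped to the contig bounds.
        """
        seq = self._seqs[chrom]
        sub = seq[max(0, start) : max(0, end)]
        return reverse_complement(sub) if strand == "-" else sub

    def fetch_interval(self, iv: GenomeInterval) -> str:
        return self.fetch(iv.chrom, iv.start, iv.end, iv.strand)


def read_fasta(path: str) -> Genome:
    """Load a FASTA file into a :class:`Genome` (sequences upper-cased)."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(">"):
            raise FormatError(f"{path}: line 1: expected FASTA header starting with '>'")
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(path, "fasta"):
        if record.id in seqs:
            raise FormatError(f"{path}: duplicate sequence name {record.id!r}")
        s = str(record.seq).upper()
        if not s:
            raise FormatError(f"{path}: empty sequence for {record.id!r}")
        bad = set(s) - set("ACGTN")
        if bad:
            raise FormatError(f"{path}: sequence {record.id!r} has invalid characters {sorted(bad)}")
        seqs[record.id] = s
    return Genome(seqs)


def write_fasta(genome: Genome, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chroms():
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _parse_attrs(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gtf(path: str) -> list[GeneModel]:
    """Read a GENCODE-style GTF into gene models (internal 0-based coords)."""
    exons: dict[tuple[str, str], list[GenomeInterval]] = {}
    tx_gene: dict[str, str] = {}
    tx_order: list[tuple[str, str]] = []
    tx_bounds: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 GTF columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature not in ("gene", "transcript", "exon"):
                continue
            a = _parse_attrs(attrs)
            iv = GenomeInterval(chrom, int(start) - 1, int(end), strand)
            if feature == "transcript":
                tx_bounds[a["transcript_id"]] = (iv.start, iv.end)
            if feature != "exon":
                continue
            gene_id, tx_id = a["gene_id"], a["transcript_id"]
            key = (gene_id, tx_id)
            if key not in exons:
                exons[key] = []
                tx_order.append(key)
            tx_gene[tx_id] = gene_id
            exons[key].append(iv)
    genes: dict[str, GeneModel] = {}
    for gene_id, tx_id in tx_order:
        ivs = exons[(gene_id, tx_id)]
        if tx_id in tx_bounds:
            lo, hi = tx_bounds[tx_id]
            for iv in ivs:
                if iv.start < lo or iv.end > hi:
                    raise FormatError(
                        f"{path}: exon [{iv.start},{iv.end}) outside transcript "
                        f"{tx_id} bounds [{lo},{hi})"
                    )
        tx = Transcript(tx_id, ivs)
        if gene_id in genes:
            genes[gene_id].transcripts.append(tx)
        else:
            genes[gene_id] = GeneModel(gene_id, [tx])
    return list(genes.values())


def write_gtf(genes: Iterable[GeneModel], path: str, source: str = "scpas") -> None:
    """Write gene models as GTF (1-based inclusive); round-trips with read_gtf."""
    with open(path, "w") as fh:
        fh.write("##format: gtf\n")
        for gene in genes:
            span = gene.span
            attrs = f'gene_id "{gene.gene_id}";'
            fh.write(
                f"{gene.chrom}\t{source}\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{gene.strand}\t.\t{attrs}\n"
            )
            for tx in gene.transcripts:
                tspan = tx.span
                tattrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}";'
                fh.write(
                    f"{gene.chrom}\t{source}\ttranscript\t{tspan.start + 1}\t{tspan.end}\t.\t"
                    f"{gene.strand}\t.\t{tattrs}\n"
                )
                for exon in sorted(tx.exons, key=lambda e: e.start):
                    fh.write(
                        f"{gene.chrom}\t{source}\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                        f"{gene.strand}\t.\t{tattrs}\n"
                    )


@dataclass(frozen=True)
class PASRecord:
    """An annotated cleavage/polyadenylation site."""

    chrom: str
    site: int  # 0-based cleavage position
    strand: str
    sources: frozenset = field(default_factory=frozenset)

    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.site, self.strand)


@dataclass
class PASSet:
    records: list[PASRecord]
    tier: str  # "known" or "stringent"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def site_index(self) -> dict[tuple[str, str], np.ndarray]:
        """Sorted site arrays keyed by (chrom, strand) for fast window queries."""
        idx: dict[tuple[str, str], list[int]] = {}
        for r in self.records:
            idx.setdefault((r.chrom, r.strand), []).append(r.site)
        return {k: np.array(sorted(v)) for k, v in idx.items()}


def build_known_pas_set(per_source_records: Iterable[PASRecord]) -> PASSet:
    """Combine per-database site records into the known PAS set.

    A site qualifies when it is reported by at least two of the three site
    databases, or appears in the curated gene annotation.  Duplicate sites
    are merged with the union of their source flags.
    """
    merged: dict[tuple[str, int, str], set] = {}
    for rec in per_source_records:
        for src in rec.sources:
            if src not in PAS_SOURCES:
                raise ValueError(f"unknown PAS source label {src!r}")
        merged.setdefault(rec.key(), set()).update(rec.sources)
    records = []
    for (chrom, site, strand), sources in sorted(merged.items()):
        n_db = len(sources & _DB_SOURCES)
        if n_db >= 2 or "GENCODE" in sources:
            records.append(PASRecord(chrom, site, strand, frozenset(sources)))
    return PASSet(records, tier="known")


def build_stringent_set(known: PASSet) -> PASSet:
    """Subset of the known set reported in all three databases or the annotation."""
    if known.tier != "known":
        raise ValueError("build_stringent_set expects a known-tier PASSet")
    records = [
        r
        for r in known.records
        if _DB_SOURCES <= r.sources or "GENCODE" in r.sources
    ]
    return PASSet(records, tier="stringent")


def split_train_validation(
    pas: PASSet, ratio: float, seed: int
) -> tuple[PASSet, PASSet]:
    """Randomly partition a PAS set into training and validation subsets.

    ``|train| = round(N * ratio)`` with round-half-up; the partition is a
    uniform random split, deterministic for a fixed seed.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie strictly between 0 and 1")
    n = len(pas)
    if n == 0:
        raise ValueError("cannot split an empty PAS set")
    n_train = int(np.floor(n * ratio + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    records = pas.records
    train = [records[i] for i in sorted(perm[:n_train])]
    valid = [records[i] for i in sorted(perm[n_train:])]
    return PASSet(train, tier=pas.tier), PASSet(valid, tier=pas.tier)


def overlaps_known(
    end_pos: int,
    chrom: str,
    strand: str,
    known_index: Mapping[tuple[str, str], np.ndarray],
    upstream: int = 50,
    downstream: int = 25,
) -> bool:
    """True if a known site lies within [-upstream, +downstream] of a peak 3' end.

    Offsets are strand-oriented: upstream is the 5' direction of the peak's
    strand.  Both window boundaries are inclusive.
    """
    sites = known_index.get((chrom, strand))
    if sites is None or len(sites) == 0:
        return False
    if strand == "+":
        lo, hi = end_pos - upstream, end_pos + downstream
    else:
        lo, hi = end_pos - downstream, end_pos + upstream
    i = np.searchsorted(sites, lo, side="left")
    return bool(i < len(sites) and sites[i] <= hi)


def read_pas_tsv(path: str) -> list[PASRecord]:
    """Read a BED6-like PAS table (chrom, site, site+1, name, score, strand, sources)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand", "sources"],
        dtype={"chrom": str},
    )
    records = []
    for row in df.itertuples(index=False):
        sources = frozenset(str(row.sources).split(",")) if pd.notna(row.sources) else frozenset()
        records.append(PASRecord(str(row.chrom), int(row.start), row.strand, sources))
    return records


def write_pas_tsv(pas: PASSet | Sequence[PASRecord], path: str) -> None:
    records = pas.records if isinstance(pas, PASSet) else list(pas)
    with open(path, "w") as fh:
        for i, r in enumerate(records):
            srcs = ",".join(sorted(r.sources))
            fh.write(f"{r.chrom}\t{r.site}\t{r.site + 1}\tpas_{i}\t0\t{r.strand}\t{srcs}\n")
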