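"""Alternative-polyadenylation statistics on the cell x PAS-feature matrix.

"Proximal" means the PAS farthest from the annotated gene 3' end (its use
shortens the 3'UTR); "distal" is the gene-end-most site.  Usage is the
log-ratio of the proximal feature's CPM to the pooled CPM of the gene's
remaining features, computed per cell; averaging usage over a cell's
expressed multi-PAS genes and Z-scoring across cells gives a per-cell
global 3'UTR-shortening preference.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel, Genome
from .quantify import CellPASMatrix, PASTranscript

# DNA-alphabet poly(A) signal hexamers: canonical AATAAA and variants
POLYA_MOTIFS = ("AATAAA", "ATTAAA", "AGTAAA", "ACTAAA", "AAGAAA", "AACAAA")


def order_pas_by_distance(
    features_of_gene: Sequence[PASTranscript], gene_models: Mapping[str, GeneModel] | list[GeneModel]
) -> list[PASTranscript]:
    """Sort a gene's PAS features by distance to the gene 3' end, descending.

    The first element is the proximal PAS (greatest strand-oriented distance
    from the annotated gene end, i.e. shortest 3'UTR).
    """
    if isinstance(gene_models, list):
        gene_models = {g.gene_id: g for g in gene_models}
    out = []
    for f in features_of_gene:
        gene = gene_models[f.gene_id]
        end = gene.three_prime
        dist = (end - f.pas_site) if gene.strand == "+" else (f.pas_site - end)
        out.append((dist, f))
    out.sort(key=lambda t: (-t[0], t[1].feature_id))
    return [f for _, f in out]


def proximal_usage(cpm_proximal: float, cpm_rest_total: float) -> float:
    """log2((CPM_proximal + 1) / (sum CPM_rest + 1))."""
    return float(np.log2((cpm_proximal + 1.0) / (cpm_rest_total + 1.0)))


def cpm_matrix(matrix: CellPASMatrix) -> pd.DataFrame:
    """Counts-per-million per cell over all PAS features (features x cells)."""
    df = matrix.to_frame().astype(float)
    totals = df.sum(axis=0)
    keep = totals > 0
    return df.loc[:, keep].div(totals[keep], axis=1) * 1e6


def _gene_of_feature(feature_id: str) -> str:
    return feature_id.rsplit(":", 1)[0]


def gene_usage_table(
    matrix: CellPASMatrix,
    feature_order: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Per (gene, cell) proximal PAS usage.

    ``feature_order`` maps gene_id to its feature ids sorted proximal-first
    (see :func:`order_pas_by_distance`).  Genes with fewer than two PAS
    features are excluded; cells with zero total counts are excluded.
    Returns a genes x cells frame of usage values (NaN where the gene has no
    counts in a cell is NOT used here: usage is defined at zero CPM too).
    """
    cpm = cpm_matrix(matrix)
    rows = {}
    for gene_id, order in feature_order.items():
        if len(order) < 2:
            continue
        present = [f for f in order if f in cpm.index]
        if len(present) < 2:
            continue
        prox = cpm.loc[present[0]]
        rest = cpm.loc[present[1:]].sum(axis=0)
        rows[gene_id] = np.log2((prox + 1.0) / (rest + 1.0))
    return pd.DataFrame(rows).T  # genes x cells


@dataclass
class CellPreference:
    barcode: str
    mean_usage: float
    z: float


def cell_preference(
    matrix: CellPASMatrix,
    feature_order: Mapping[str, Sequence[str]],
    min_expressed_genes: int = 1,
) -> list[CellPreference]:
    """Per-cell mean proximal usage over expressed multi-PAS genes, Z-scored.

    A gene counts as expressed in a cell when its PAS features have a
    nonzero summed count there.  Cells with fewer than
    ``min_expressed_genes`` scored genes are dropped with a warning.
    Z-scoring uses the sample standard deviation (ddof=1); an all-equal set
    of cells gets z = 0 for everyone.
    """
    usage = gene_usage_table(matrix, feature_order)
    counts = matrix.to_frame()
    means: dict[str, float] = {}
    dropped = 0
    for cell in usage.columns:
        expressed = []
        for gene_id in usage.index:
            feats = [f for f in feature_order[gene_id] if f in counts.index]
            if counts.loc[feats, cell].sum() > 0:
                expressed.append(gene_id)
        if len(expressed) < min_expressed_genes:
            dropped += 1
            continue
        means[cell] = float(usage.loc[expressed, cell].mean())
    if dropped:
        warnings.warn(f"{dropped} cells dropped (< {min_expressed_genes} expressed multi-PAS genes)")
    if not means:
        return []
    vals = np.array(list(means.values()))
    sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
    if sd == 0:
        z = np.zeros(len(vals))
    else:
        z = (vals - vals.mean()) / sd
    return [
        CellPreference(cell, float(m), float(zz))
        for (cell, m), zz in zip(means.items(), z)
    ]


def differential_usage(
    matrix: CellPASMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    logfc_min: float = 1.2,
    p_max: float = 0.05,
    min_pct: float = 0.3,
) -> pd.DataFrame:
    """Per-feature differential expression between two cell groups.

    Per feature: log2 fold change between group means of CPM (+1), a
    two-sided Wilcoxon rank-sum P value, and the fraction of expressing
    cells per group.  A feature is significant when |logFC| >= 1.2, P <=
    0.05 and the expressing fraction reaches ``min_pct`` in at least one
    group.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("each group needs at least 3 cells")
    cpm = cpm_matrix(matrix)
    a = cpm.loc[:, [c for c in group_a if c in cpm.columns]]
    b = cpm.loc[:, [c for c in group_b if c in cpm.columns]]
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise ValueError("group cells not found in the matrix")
    rows = []
    for feat in cpm.index:
        xa = a.loc[feat].to_numpy()
        xb = b.loc[feat].to_numpy()
        logfc = float(np.log2((xa.mean() + 1.0) / (xb.mean() + 1.0)))
        if np.all(xa == xa[0]) and np.all(xb == xb[0]) and xa[0] == xb[0]:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
        pct_a = float(np.mean(xa > 0))
        pct_b = float(np.mean(xb > 0))
        sig = abs(logfc) >= logfc_min and p <= p_max and max(pct_a, pct_b) >= min_pct
        rows.append((feat, logfc, p, pct_a, pct_b, sig))
    return pd.DataFrame(
        rows, columns=["feature", "log2fc", "pvalue", "pct_a", "pct_b", "significant"]
    ).set_index("feature")


def polya_signal_occurrence(
    sites: Sequence[tuple[str, int, str]],
    genome: Genome,
    upstream: int = 50,
    downstream: int = 25,
    motifs: Sequence[str] = POLYA_MOTIFS,
) -> tuple[float, dict[str, int]]:
    """Fraction of sites with a poly(A)-signal hexamer in [-50, +25].

    ``sites`` are (chrom, 3'-end position, strand) triples; the scan is on
    the sense strand.  A site counts once even with several motif hits;
    per-motif tallies count each motif at most once per site.
    """
    per_motif = {m: 0 for m in motifs}
    n_with = 0
    for chrom, pos, strand in sites:
        if strand == "+":
            lo, hi = pos - upstream, pos + downstream + 1
        else:
            lo, hi = pos - downstream, pos + upstream + 1
        lo = max(0, lo)
        hi = min(genome.length(chrom), hi)
        seq = genome.fetch(chrom, lo, hi, strand)
        found = False
        for m in motifs:
            if m in seq:
                per_motif[m] += 1
                found = True
        if found:
            n_with += 1
    frac = n_with / len(sites) if sites else 0.0
    return frac, per_motif


def positional_profiles(
    sites: Sequence[tuple[str, int, str]],
    genome: Genome,
    flank: int = 100,
    motifs: Sequence[str] = POLYA_MOTIFS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-position motif-start density and base composition around 3' ends.

    Positions run -flank..+flank relative to the site (sense orientation).
    Returns (motif_density, base_frequencies); base-frequency rows sum to 1
    (N excluded from the denominator).  Overlapping occurrences of the same
    motif are counted at every start.
    """
    positions = np.arange(-flank, flank + 1)
    density = {m: np.zeros(len(positions)) for m in motifs}
    base_counts = np.zeros((len(positions), 4))
    n_seq = 0
    base_col = {"A": 0, "C": 1, "G": 2, "T": 3}
    for chrom, pos, strand in sites:
        lo, hi = pos - flank, pos + flank + 1  # symmetric, so strand-independent
        if lo < 0 or hi > genome.length(chrom):
            continue
        seq = genome.fetch(chrom, lo, hi, strand)
        n_seq += 1
        for i, base in enumerate(seq):
            if base in base_col:
                base_counts[i, base_col[base]] += 1
        for m in motifs:
            for match in re.finditer(f"(?={m})", seq):
                start = match.start()
                if start < len(positions):
                    density[m][start] += 1
    if n_seq == 0:
        empty = pd.DataFrame(index=positions)
        return empty, empty
    dens = pd.DataFrame(
        {m: v / n_seq for m, v in density.items()}, index=positions
    )
    totals = base_counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    freqs = pd.DataFrame(
        base_counts / totals, index=positions, columns=["A", "C", "G", "T"]
    )
    return dens, freqs
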