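"""End-to-end pipeline: peak calling -> sequence-model filtering -> per-cell
quantification -> APA statistics, with manifest-stamped, reproducible runs."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .annotation import Genome, read_fasta, read_gtf
from .apa import cell_preference, gene_usage_table, order_pas_by_distance
from .classifier import SequenceClassifier, predict
from .peaks import (
    aggregate_gene_peaks,
    assess_and_split,
    call_raw_peaks,
    filter_internal_priming,
    filter_low_coverage,
    write_peaks_bed,
)
from .quantify import assign_peaks_to_transcripts, count_umis, write_pas_gtf

logger = logging.getLogger("scpas")


@dataclass
class PipelineConfig:
    genome_fasta: str
    gtf: str
    bam: str
    model: str  # trained classifier checkpoint (.npz)
    output_dir: str
    seed: int = 0
    peak_size: int = 400
    min_dist: int = 10
    min_count: int = 10
    probability_cutoff: float = 0.5
    cb_tag: str = "CB"
    umi_tag: str = "UB"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        extra = {k: v for k, v in data.items() if k not in cls.__dataclass_fields__}
        return cls(**known, extra=extra)


def _manifest(config: PipelineConfig, stage: str, outputs: list[str]) -> dict:
    cfg = asdict(config)
    cfg.pop("output_dir", None)  # hash covers the scientific parameters only
    digest = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
    return {
        "stage": stage,
        "version": __version__,
        "seed": config.seed,
        "parameter_hash": digest,
        "outputs": outputs,
    }


def _write_manifest(config: PipelineConfig, stage: str, outputs: list[str]) -> None:
    path = os.path.join(config.output_dir, f"{stage}.manifest.json")
    with open(path, "w") as fh:
        json.dump(_manifest(config, stage, outputs), fh, indent=2, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> str:
    """Execute callpeak -> predict/filter -> quantify -> apa; returns output dir."""
    for path_attr in ("genome_fasta", "gtf", "bam", "model"):
        path = getattr(config, path_attr)
        if not os.path.exists(path):
            raise FileNotFoundError(f"{path_attr}: no such file: {path}")
    os.makedirs(config.output_dir, exist_ok=True)
    genome = read_fasta(config.genome_fasta)
    genes = read_gtf(config.gtf)

    # stage 1: peak calling + filters
    stage = "callpeak"
    try:
        raw = call_raw_peaks(
            config.bam, genes, size=config.peak_size,
            min_dist=config.min_dist, min_count=config.min_count,
        )
        peaks = assess_and_split(raw, seed=config.seed)
        peaks = aggregate_gene_peaks(peaks)
        peaks = filter_low_coverage(peaks)
        peaks = filter_internal_priming(peaks, genome)
        bed = os.path.join(config.output_dir, "peaks.bed")
        write_peaks_bed(peaks, bed)
        _write_manifest(config, stage, [bed])
        logger.info("callpeak: %d peaks after filters", len(peaks))
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # stage 2: sequence-model filtering
    stage = "predict"
    try:
        model = SequenceClassifier.load(config.model)
        seqs, keepable = [], []
        for p in peaks:
            lo = p.three_prime_end - 100
            hi = lo + 200
            if lo < 0 or hi > genome.length(p.chrom):
                continue
            seqs.append(genome.fetch(p.chrom, lo, hi, p.strand))
            keepable.append(p)
        preds = predict(model, seqs)
        positive = [
            p for p, pr in zip(keepable, preds) if pr.probability > config.probability_cutoff
        ]
        tsv = os.path.join(config.output_dir, "predictions.tsv")
        with open(tsv, "w") as fh:
            fh.write("chrom\tend\tstrand\tgene_id\tprobability\tlabel\n")
            for p, pr in zip(keepable, preds):
                fh.write(
                    f"{p.chrom}\t{p.three_prime_end}\t{p.strand}\t{p.gene_id}\t"
                    f"{pr.probability:.6f}\t{pr.label}\n"
                )
        _write_manifest(config, stage, [tsv])
        logger.info("predict: %d/%d peaks kept", len(positive), len(keepable))
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # stage 3: quantification
    stage = "quantify"
    try:
        features = assign_peaks_to_transcripts(positive, genes)
        gtf_out = os.path.join(config.output_dir, "pas_transcripts.gtf")
        write_pas_gtf(features, gtf_out)
        matrix = count_umis(config.bam, features, config.cb_tag, config.umi_tag)
        mtx_dir = os.path.join(config.output_dir, "matrix")
        matrix.write_mtx(mtx_dir)
        _write_manifest(config, stage, [gtf_out, mtx_dir])
        logger.info("quantify: %d features x %d cells, %d UMIs",
                    len(matrix.features), len(matrix.barcodes), matrix.total())
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # stage 4: APA statistics
    stage = "apa"
    try:
        by_gene: dict[str, list] = {}
        for f in features:
            by_gene.setdefault(f.gene_id, []).append(f)
        feature_order = {
            gid: [f.feature_id for f in order_pas_by_distance(fs, genes)]
            for gid, fs in by_gene.items()
            if len(fs) >= 2
        }
        usage_path = os.path.join(config.output_dir, "proximal_usage.tsv")
        pref_path = os.path.join(config.output_dir, "cell_preference.tsv")
        if feature_order and matrix.barcodes:
            usage = gene_usage_table(matrix, feature_order)
            usage.to_csv(usage_path, sep="\t", index_label="gene_id")
            prefs = cell_preference(matrix, feature_order)
            with open(pref_path, "w") as fh:
                fh.write("barcode\tmean_usage\tz\n")
                for c in prefs:
                    fh.write(f"{c.barcode}\t{c.mean_usage:.6f}\t{c.z:.6f}\n")
        else:
            open(usage_path, "w").close()
            open(pref_path, "w").close()
        _write_manifest(config, stage, [usage_path, pref_path])
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    return config.output_dir
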