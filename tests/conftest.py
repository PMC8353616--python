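import numpy as np
import pytest

from scpas.classifier import train
from scpas.nn import ModelSpec
from scpas.peaks import (
    aggregate_gene_peaks,
    assess_and_split,
    call_raw_peaks,
    filter_internal_priming,
    filter_low_coverage,
)
from scpas.quantify import assign_peaks_to_transcripts, count_umis
from scpas.simulate import (
    SimulationConfig,
    make_training_benchmark,
    simulate_genome,
    simulate_reads,
)


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """Default synthetic study: 50 genes, 2-3 PASs each, 200 cells, ~100 UMIs/site."""
    cfg = SimulationConfig(seed=0)
    genome, genes, truth = simulate_genome(cfg)
    bam = str(tmp_path_factory.mktemp("sim") / "sim.bam")
    truth = simulate_reads(genome, genes, truth, cfg, bam)
    raw = call_raw_peaks(bam, genes)
    peaks = assess_and_split(raw, seed=0)
    peaks = aggregate_gene_peaks(peaks)
    peaks = filter_low_coverage(peaks)
    filtered = filter_internal_priming(peaks, genome)
    return {
        "config": cfg,
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "bam": bam,
        "raw_peaks": raw,
        "prefilter_peaks": peaks,
        "peaks": filtered,
    }


@pytest.fixture(scope="session")
def dup_sim(tmp_path_factory):
    """Smaller study with a 50% PCR duplicate rate, for UMI dedup checks."""
    cfg = SimulationConfig(n_genes=20, n_cells=100, duplicate_rate=0.5, seed=11)
    genome, genes, truth = simulate_genome(cfg)
    bam = str(tmp_path_factory.mktemp("dupsim") / "sim.bam")
    truth = simulate_reads(genome, genes, truth, cfg, bam)
    peaks = [p for p in call_raw_peaks(bam, genes) if p.category == "exonic"]
    features = assign_peaks_to_transcripts(peaks, genes)
    matrix = count_umis(bam, features)
    return {
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "bam": bam,
        "features": features,
        "matrix": matrix,
    }


@pytest.fixture(scope="session")
def bench():
    """Planted-signal training corpus: 500 training sites -> 5,000 shifted windows."""
    return make_training_benchmark(seed=7)


@pytest.fixture(scope="session")
def reduced_spec():
    return ModelSpec().scaled(0.25)


@pytest.fixture(scope="session")
def shifted_model(bench, reduced_spec):
    result = train(
        reduced_spec,
        bench.shifted_positives + bench.negatives,
        batch_size=256,
        max_epochs=10,
        patience=10,
        seed=7,
        lr=2e-3,
    )
    return result


@pytest.fixture(scope="session")
def fixed_model(bench, reduced_spec):
    result = train(
        reduced_spec,
        bench.fixed_positives + bench.negatives_fixed,
        batch_size=256,
        max_epochs=40,
        patience=10,
        seed=7,
        lr=2e-3,
    )
    return result


def recovery_fraction(peaks, truth_pas, tolerance=50):
    """Fraction of planted sites with a peak 3' end within ±tolerance nt."""
    ends = {}
    for p in peaks:
        ends.setdefault((p.chrom, p.strand), []).append(p.three_prime_end)
    ends = {k: np.sort(np.array(v)) for k, v in ends.items()}
    hit = 0
    for t in truth_pas:
        arr = ends.get((t.chrom, t.strand))
        if arr is not None and len(arr) and np.min(np.abs(arr - t.site)) <= tolerance:
            hit += 1
    return hit / len(truth_pas)
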