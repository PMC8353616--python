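# scpas

Cleavage-and-polyadenylation site (PAS) calling, filtering and
quantification for 3' tag single-cell RNA-seq.

## The problem

3' tag scRNA-seq chemistries (oligo(dT)-primed, e.g. 10x Chromium) pile
reads near transcript 3' ends, which makes them an untapped readout of
*where* each transcript is cleaved and polyadenylated. Exploiting that
signal requires solving three problems that standard gene-level pipelines
ignore: (1) finding candidate cleavage sites from read pileups at
transcript resolution, (2) separating genuine PASs from internal-priming
artifacts — oligo(dT) annealing to genomic A-rich stretches — and other
false peaks, and (3) quantifying the resulting PAS-defined transcript
isoforms per cell so that alternative polyadenylation (APA, e.g. 3'UTR
shortening) can be compared across cell types and conditions.

`scpas` is a stepwise pipeline for exactly this:

1. **Peak calling** — strand-specific read-start coverage is scanned per
   transcript in spliced coordinate space (and per intron for artifact
   candidates) with a fixed-width (400 nt) greedy caller; peaks are
   assessed for multimodality (dip statistic), aggregated within genes
   (≥ 50% overlap keeps only the maximally expressed peak), and filtered
   for low coverage (≤ 1% of the gene's reads) and intronic internal
   priming (≥ 8 consecutive A in [−10, +20] of the 3' end).
2. **Sequence-model filtering** — each candidate's 200-nt window is scored
   by a CNN+BiLSTM classifier,

       O = softmax ∘ dense_ReLU ∘ BiLSTM ∘ maxpool ∘ conv_ReLU ∘ conv_ReLU (X),

   trained on windows *shifted* around annotated sites with offsets drawn
   from round(N(0, 10)) so that prediction is position-insensitive.
   Probability > 0.5 keeps a site.
3. **Quantification** — surviving PASs become transcript features (exon
   chains clipped at the cleavage site); distinct UMIs are counted per
   cell barcode per feature (sense strand, largest overlap).
4. **APA statistics** — proximal PAS usage
   `log2((CPM_proximal + 1)/(Σ CPM_rest + 1))` per gene per cell, Z-scored
   per-cell global proximal preference, Wilcoxon differential usage between
   cell groups (|log2FC| ≥ 1.2, P ≤ 0.05, min.pct ≥ 0.3), and
   poly(A)-signal motif scans (AATAAA and variants in [−50, +25]).

Candidate sites are evaluated against read-coverage geometry via the
enrichment score `log2((RPM_up + 0.1)/(RPM_down + 0.1))`: a true cleavage
site has dense coverage in the 400 nt upstream and little downstream.

A fully synthetic data generator (genomes, annotations, tagged BAMs with
planted truth) makes every stage testable without downloads.

## Worked example

```bash
python examples/01_simulate_and_call_peaks.py
```

prints, for the default synthetic study (50 genes, 2–3 PASs each,
200 cells, ~100 molecules per site):

```
simulated 50 genes, 121 planted PASs, 12 intronic internal-priming loci
132 peaks after filtering (0 intronic survive)
recovery: 121/121 planted sites have a peak 3' end within +/-50 nt ...
```

i.e. every planted cleavage site is recovered at the resolution the
downstream −50/+25 nt overlap window assumes, and every planted
internal-priming locus is removed by the A-run filter.
`examples/02_train_classifier.py` trains a width-reduced classifier on
5,000 shifted positive windows + 5,000 intergenic negatives and reports a
held-out AUC of ~1.0 with a flat positional-tolerance profile;
`examples/03_quantify_per_cell.py` shows the UMI matrix reproducing the
generator's per-cell molecule counts exactly under a 50% duplicate rate;
`examples/04_apa_statistics.py` recovers a planted proximal-usage shift
between two cell groups.

The same stages are available as a CLI:

```bash
scpas simulate --out-prefix sim --n-genes 50 --n-cells 200
scpas callpeak --bam sim.bam --gtf sim.gtf --fasta sim.fa --out peaks.bed
scpas train --examples corpus.tsv --out model.npz --scale 0.25
scpas predict --model model.npz --peaks peaks.bed --fasta sim.fa --out calls.tsv
scpas quantify --bam sim.bam --pas-gtf pas.gtf --out-dir matrix/
scpas run --config pipeline.yaml
```

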