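"""Position-insensitive PAS sequence classifier.

A candidate cleavage site is judged from the 200-nt window around it.  The
training trick that makes the model position-insensitive is *shifting*:
instead of one window fixed on each training site, ~10 windows per site are
drawn with integer offsets from round(N(0, 10)), so the poly(A) signal
appears at varying positions and the model cannot anchor on a fixed
coordinate.  Negatives are intergenic windows that avoid all annotated
sites.  Prediction above probability 0.5 (strict) calls a window positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .annotation import GeneModel, Genome, GenomeInterval, PASRecord, PASSet
from .nn import Adam, ModelSpec, SequenceClassifier, cross_entropy

WINDOW = 200
MAX_ABS_OFFSET = 90  # keeps the cleavage site inside the window

# one-hot channel order: A, T, G, C
_BASE_INDEX = {"A": 0, "T": 1, "G": 2, "C": 3}


@dataclass
class SequenceExample:
    sequence: str
    label: int  # 1 = PAS, 0 = non-PAS
    origin_pas: PASRecord | None = None
    offset: int = 0
    region: "GenomeInterval | None" = None  # genomic provenance, if known

    def __post_init__(self) -> None:
        if len(self.sequence) != WINDOW:
            raise ValueError(f"sequence must be {WINDOW} nt, got {len(self.sequence)}")


@dataclass
class Prediction:
    probability: float

    @property
    def label(self) -> int:
        return 1 if self.probability > 0.5 else 0


@dataclass
class FilterMotif:
    filter_index: int
    ppm: np.ndarray  # (width, 4), rows sum to 1, column order A,C,G,T
    pwm: np.ndarray
    entropy: float  # total information content (bits)
    n_sites: int

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.ppm.argmax(axis=1))


def one_hot(sequence: str) -> np.ndarray:
    """One-hot encode a 200-nt sequence; channel order (A, T, G, C); N -> zeros."""
    if len(sequence) != WINDOW:
        raise ValueError(f"sequence must be {WINDOW} nt, got {len(sequence)}")
    mat = np.zeros((WINDOW, 4))
    for i, base in enumerate(sequence):
        if base == "N":
            continue
        try:
            mat[i, _BASE_INDEX[base]] = 1.0
        except KeyError:
            raise ValueError(f"invalid base {base!r} at position {i}")
    return mat


def decode_one_hot(mat: np.ndarray) -> str:
    out = []
    for row in mat:
        out.append("N" if row.sum() == 0 else "ATGC"[int(row.argmax())])
    return "".join(out)


def encode_batch(sequences: list[str]) -> np.ndarray:
    return np.stack([one_hot(s) for s in sequences]) if sequences else np.zeros((0, WINDOW, 4))


def _window_for_site(genome: Genome, pas: PASRecord, offset: int, width: int) -> str | None:
    """Strand-oriented window of ``width`` nt centred on site+offset (strand sense)."""
    g_off = offset if pas.strand == "+" else -offset
    centre = pas.site + g_off
    lo = centre - width // 2
    hi = lo + width
    if lo < 0 or hi > genome.length(pas.chrom):
        return None
    return genome.fetch(pas.chrom, lo, hi, pas.strand)


def make_shifted_positives(
    pas_set: PASSet,
    genome: Genome,
    n_per_pas: int = 10,
    mu: float = 0.0,
    sigma: float = 10.0,
    width: int = WINDOW,
    seed: int = 0,
) -> list[SequenceExample]:
    """Per site, draw ``n_per_pas`` distinct integer offsets from round(N(mu, sigma))
    and extract the shifted windows; exact duplicate sequences are removed
    globally afterwards."""
    if sigma <= 0:
        raise ValueError("sigma must be positive: distinct offsets are unreachable otherwise")
    rng = np.random.default_rng(seed)
    examples: list[SequenceExample] = []
    seen: set[str] = set()
    n_skipped = 0
    for pas in pas_set:
        offsets: set[int] = set()
        tries = 0
        while len(offsets) < n_per_pas and tries < 1000 * n_per_pas:
            off = int(round(rng.normal(mu, sigma)))
            tries += 1
            if abs(off) <= MAX_ABS_OFFSET:
                offsets.add(off)
        got_any = False
        for off in sorted(offsets):
            seq = _window_for_site(genome, pas, off, width)
            if seq is None:
                continue
            got_any = True
            if seq in seen:
                continue
            seen.add(seq)
            examples.append(SequenceExample(seq, 1, origin_pas=pas, offset=off))
        if not got_any:
            n_skipped += 1
    if n_skipped:
        warnings.warn(f"{n_skipped} sites too close to a contig edge were skipped")
    return examples


def make_fixed_positives(
    pas_set: PASSet, genome: Genome, width: int = WINDOW
) -> list[SequenceExample]:
    """One window per site, centred exactly on the cleavage position (fixed baseline)."""
    examples: list[SequenceExample] = []
    seen: set[str] = set()
    n_skipped = 0
    for pas in pas_set:
        seq = _window_for_site(genome, pas, 0, width)
        if seq is None:
            n_skipped += 1
            continue
        if seq in seen:
            continue
        seen.add(seq)
        examples.append(SequenceExample(seq, 1, origin_pas=pas, offset=0))
    if n_skipped:
        warnings.warn(f"{n_skipped} sites too close to a contig edge were skipped")
    return examples


def intergenic_regions(genome: Genome, gene_models: list[GeneModel]) -> dict[str, list[tuple[int, int]]]:
    """Complement of gene-body spans per chromosome."""
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chroms()}
    for g in gene_models:
        s = g.span
        spans.setdefault(s.chrom, []).append((s.start, s.end))
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in spans.items():
        merged: list[tuple[int, int]] = []
        for lo, hi in sorted(ivs):
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        gaps = []
        prev = 0
        for lo, hi in merged:
            if lo > prev:
                gaps.append((prev, lo))
            prev = max(prev, hi)
        if prev < genome.length(chrom):
            gaps.append((prev, genome.length(chrom)))
        out[chrom] = gaps
    return out


def sample_negatives(
    genome: Genome,
    known_pas: PASSet,
    gene_models: list[GeneModel],
    n: int,
    width: int = WINDOW,
    seed: int = 0,
) -> list[SequenceExample]:
    """Uniformly sample ``n`` distinct intergenic windows avoiding annotated sites."""
    regions = intergenic_regions(genome, gene_models)
    usable = [
        (chrom, lo, hi)
        for chrom, gaps in regions.items()
        for lo, hi in gaps
        if hi - lo >= width
    ]
    if not usable:
        raise ValueError("no intergenic region long enough for a negative window")
    sites_by_chrom: dict[str, list[int]] = {}
    for r in known_pas:
        sites_by_chrom.setdefault(r.chrom, []).append(r.site)
    site_arrays = {c: np.array(sorted(v)) for c, v in sites_by_chrom.items()}
    weights = np.array([hi - lo - width + 1 for _, lo, hi in usable], dtype=float)
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    examples: list[SequenceExample] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = 200 * n + 1000
    while len(examples) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(f"could not sample {n} distinct negative windows")
        ridx = rng.choice(len(usable), p=weights)
        chrom, lo, hi = usable[ridx]
        start = int(rng.integers(lo, hi - width + 1))
        sites = site_arrays.get(chrom)
        if sites is not None:
            i = np.searchsorted(sites, start, side="left")
            if i < len(sites) and sites[i] < start + width:
                continue
        strand = "+" if rng.uniform() < 0.5 else "-"
        seq = genome.fetch(chrom, start, start + width, strand)
        if seq in seen:
            continue
        seen.add(seq)
        examples.append(
            SequenceExample(seq, 0, region=GenomeInterval(chrom, start, start + width, strand))
        )
    return examples


def _clean(examples: list[SequenceExample], max_n_frac: float = 0.1) -> list[SequenceExample]:
    return [e for e in examples if e.sequence.count("N") <= max_n_frac * WINDOW]


@dataclass
class TrainResult:
    model: SequenceClassifier
    history: list[dict] = field(default_factory=list)
    best_epoch: int = 0


def train(
    spec: ModelSpec,
    train_examples: list[SequenceExample],
    batch_size: int = 5000,
    max_epochs: int = 100,
    patience: int = 10,
    seed: int = 0,
    lr: float = 1e-3,
    monitor_fraction: float = 0.05,
) -> TrainResult:
    """Train the classifier with early stopping.

    A ``monitor_fraction`` held-out slice of the training examples is used to
    monitor loss; training stops after ``patience`` epochs without
    improvement (or at ``max_epochs``) and the best-epoch parameters are
    restored.
    """
    examples = _clean(train_examples)
    labels = np.array([e.label for e in examples])
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    x = encode_batch([e.sequence for e in examples])
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(x))
    x, labels = x[perm], labels[perm]
    n_val = max(1, int(len(x) * monitor_fraction))
    x_val, y_val = x[:n_val], labels[:n_val]
    x_tr, y_tr = x[n_val:], labels[n_val:]
    model = SequenceClassifier(spec, seed=seed)
    opt = Adam(model.params, lr=lr)
    best_loss = np.inf
    best_params = model.copy_params()
    best_epoch = 0
    stale = 0
    history = []
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(len(x_tr))
        epoch_loss = 0.0
        n_batches = 0
        for i in range(0, len(order), batch_size):
            idx = order[i : i + batch_size]
            probs, cache = model.forward(x_tr[idx], train=True, rng=rng)
            epoch_loss += cross_entropy(probs, y_tr[idx])
            n_batches += 1
            grads = model.backward(probs, y_tr[idx], cache)
            opt.step(model.params, grads)
        val_probs = model.predict_proba(x_val)
        val_loss = cross_entropy(np.stack([1 - val_probs, val_probs], axis=1), y_val)
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / max(1, n_batches), "monitor_loss": val_loss}
        )
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_params = model.copy_params()
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    model.set_params(best_params)
    return TrainResult(model=model, history=history, best_epoch=best_epoch)


def predict(model: SequenceClassifier, sequences: list[str]) -> list[Prediction]:
    """Score 200-nt windows; probability > 0.5 (strict) is a positive call."""
    x = encode_batch(list(sequences))
    probs = model.predict_proba(x)
    return [Prediction(float(p)) for p in probs]


def evaluate_position_tolerance(
    model: SequenceClassifier,
    validation_pas: PASSet,
    genome: Genome,
    stride: int = 5,
    max_offset: int = 50,
    width: int = WINDOW,
) -> dict[int, float]:
    """True-positive rate of the model on windows shifted off the true site."""
    offsets = list(range(-max_offset, max_offset + 1, stride))
    out: dict[int, float] = {}
    for off in offsets:
        seqs = []
        for pas in validation_pas:
            seq = _window_for_site(genome, pas, off, width)
            if seq is not None:
                seqs.append(seq)
        if not seqs:
            out[off] = float("nan")
            continue
        probs = model.predict_proba(encode_batch(seqs))
        out[off] = float(np.mean(probs > 0.5))
    return out


def evaluate_internal_priming(
    model: SequenceClassifier,
    genome: Genome,
    known_pas: PASSet,
    gene_models: list[GeneModel],
    run_lengths: range = range(8, 16),
    n_per_length: int = 50,
    min_distance_to_pas: int = 1000,
    seed: int = 0,
    width: int = WINDOW,
) -> dict[int, float]:
    """True-negative rate on intergenic windows centred on adenine runs.

    Pseudo internal-priming sites are built by planting A-runs of each length
    at the centre of intergenic windows far from any annotated site; the
    returned value per run length is the fraction classified negative.
    """
    rng = np.random.default_rng(seed)
    regions = intergenic_regions(genome, gene_models)
    sites_by_chrom: dict[str, np.ndarray] = {}
    for r in known_pas:
        sites_by_chrom.setdefault(r.chrom, np.array([]))
    tmp: dict[str, list[int]] = {}
    for r in known_pas:
        tmp.setdefault(r.chrom, []).append(r.site)
    sites_by_chrom = {c: np.array(sorted(v)) for c, v in tmp.items()}
    usable = [
        (chrom, lo, hi)
        for chrom, gaps in regions.items()
        for lo, hi in gaps
        if hi - lo >= width
    ]
    out: dict[int, float] = {}
    for run_len in run_lengths:
        seqs = []
        attempts = 0
        while len(seqs) < n_per_length and attempts < 100 * n_per_length:
            attempts += 1
            chrom, lo, hi = usable[rng.integers(len(usable))]
            start = int(rng.integers(lo, hi - width + 1))
            sites = sites_by_chrom.get(chrom)
            if sites is not None and len(sites):
                d = np.min(np.abs(sites - (start + width // 2)))
                if d < min_distance_to_pas:
                    continue
            base = genome.fetch(chrom, start, start + width, "+")
            mid = width // 2 - run_len // 2
            seqs.append(base[:mid] + "A" * run_len + base[mid + run_len :])
        if not seqs:
            continue
        probs = model.predict_proba(encode_batch(seqs))
        out[run_len] = float(np.mean(probs <= 0.5))
    return out


def extract_filter_motifs(
    model: SequenceClassifier,
    positive_examples: list[SequenceExample],
    pseudocount: float = 1e-3,
    batch_size: int = 512,
) -> list[FilterMotif]:
    """Per first-layer filter, align the maximally activating k-mers of the
    positive training sequences into a PPM/PWM; motifs sorted by information
    content (descending).  Filters that never activate (> 0) are omitted."""
    width = model.spec.conv1_width
    n_filters = model.spec.conv1_filters
    seqs = [e.sequence for e in positive_examples if e.label == 1]
    counts = np.zeros((n_filters, width, 4))
    n_sites = np.zeros(n_filters, dtype=int)
    base_to_col = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i in range(0, len(seqs), batch_size):
        chunk = seqs[i : i + batch_size]
        acts = model.conv1_activations(encode_batch(chunk))  # (B, Lout, F)
        best_pos = acts.argmax(axis=1)  # (B, F)
        best_val = acts.max(axis=1)
        for bi, seq in enumerate(chunk):
            for f in range(n_filters):
                if best_val[bi, f] <= 0:
                    continue
                kmer = seq[best_pos[bi, f] : best_pos[bi, f] + width]
                if "N" in kmer:
                    continue
                for pos, base in enumerate(kmer):
                    counts[f, pos, base_to_col[base]] += 1
                n_sites[f] += 1
    motifs: list[FilterMotif] = []
    for f in range(n_filters):
        if n_sites[f] == 0:
            warnings.warn(f"filter {f} never activated on positive sequences; omitted")
            continue
        col_tot = counts[f].sum(axis=1, keepdims=True)
        col_tot[col_tot == 0] = 1.0
        ppm = counts[f] / col_tot
        pwm = np.log2((ppm + pseudocount) / 0.25)
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(ppm > 0, ppm * np.log2(ppm), 0.0)
        info = float(np.sum(2.0 + plogp.sum(axis=1)))
        motifs.append(FilterMotif(f, ppm, pwm, info, int(n_sites[f])))
    motifs.sort(key=lambda m: -m.entropy)
    return motifs


def write_meme(motifs: list[FilterMotif], path: str) -> None:
    """Export motifs in MEME minimal motif format (ACGT alphabet)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for m in motifs:
            fh.write(f"MOTIF filter_{m.filter_index}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.ppm.shape[0]} "
                f"nsites= {m.n_sites} E= 0\n"
            )
            for row in m.ppm:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def write_examples_tsv(examples: list[SequenceExample], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tlabel\toffset\n")
        for e in examples:
            fh.write(f"{e.sequence}\t{e.label}\t{e.offset}\n")


def read_examples_tsv(path: str) -> list[SequenceExample]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sequence"):
            raise ValueError(f"{path}: expected header 'sequence\\tlabel\\toffset'")
        for line in fh:
            seq, label, offset = line.rstrip("\n").split("\t")
            out.append(SequenceExample(seq, int(label), offset=int(offset)))
    return out
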