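"""Enrichment-score PAS evaluation, confusion metrics, and ROC/AUC.

A true cleavage site sits at the 3' boundary of its read peak: dense
coverage in the 400 nt upstream, little in the 400 nt downstream.  The
enrichment score log2((RPM_up + 0.1) / (RPM_down + 0.1)) quantifies this,
and thresholding it (default >= 2) defines "actual" positives against
which the sequence model's calls are scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .annotation import GenomeInterval, PASSet
from .peaks import Peak
from .quantify import compute_rpm

REGION_WIDTH = 400


@dataclass
class EnrichmentRecord:
    pas_id: str
    rpm_region: float  # over the reported peak region (expression filter)
    rpm_upstream: float
    rpm_downstream: float

    @property
    def score(self) -> float:
        return enrichment_score(self.rpm_upstream, self.rpm_downstream)


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else float("nan")


def enrichment_score(rpm_up: float, rpm_down: float) -> float:
    """log2((RPM_up + 0.1) / (RPM_down + 0.1)); antisymmetric in its arguments."""
    if rpm_up < 0 or rpm_down < 0:
        raise ValueError("RPM values must be nonnegative")
    return float(np.log2((rpm_up + 0.1) / (rpm_down + 0.1)))


def flanking_regions(
    end_pos: int, chrom: str, strand: str, contig_length: int, width: int = REGION_WIDTH
) -> tuple[GenomeInterval, GenomeInterval]:
    """Strand-oriented upstream/downstream windows around a 3' end, clipped."""
    if strand == "+":
        up = (end_pos - width + 1, end_pos + 1)
        down = (end_pos + 1, end_pos + width + 1)
    else:
        up = (end_pos, end_pos + width)
        down = (end_pos - width, end_pos)
    clip = lambda lo, hi: (max(0, lo), min(contig_length, hi))
    u, d = clip(*up), clip(*down)
    return (
        GenomeInterval(chrom, u[0], u[1], strand),
        GenomeInterval(chrom, d[0], d[1], strand),
    )


def enrichment_records(
    alignments,
    peaks: list[Peak],
    contig_lengths: Mapping[str, int],
) -> dict[str, EnrichmentRecord]:
    """Compute RPM over peak regions and their 400-nt flanks in one pass."""
    regions: dict[str, GenomeInterval] = {}
    for i, p in enumerate(peaks):
        pid = f"peak_{i}"
        up, down = flanking_regions(
            p.three_prime_end, p.chrom, p.strand, contig_lengths[p.chrom]
        )
        regions[f"{pid}:region"] = p.interval
        regions[f"{pid}:up"] = up
        regions[f"{pid}:down"] = down
    rpm = compute_rpm(alignments, regions)
    out = {}
    for i in range(len(peaks)):
        pid = f"peak_{i}"
        out[pid] = EnrichmentRecord(
            pid,
            float(rpm[f"{pid}:region"]),
            float(rpm[f"{pid}:up"]),
            float(rpm[f"{pid}:down"]),
        )
    return out


def confusion_from_scores(
    predictions: Mapping[str, float],
    records: Mapping[str, EnrichmentRecord],
    expr_min_rpm: float = 1.0,
    score_cutoff: float = 2.0,
) -> ConfusionSummary:
    """Confusion matrix of model calls against enrichment-defined truth.

    Peaks are first filtered to expression RPM >= ``expr_min_rpm``;
    predicted positive means probability > 0.5 (strict), actual positive
    means enrichment score >= ``score_cutoff``.
    """
    if set(predictions) != set(records):
        raise ValueError("predictions and enrichment records must share keys")
    tp = fp = tn = fn = 0
    n_kept = 0
    for pid, prob in predictions.items():
        rec = records[pid]
        if rec.rpm_region < expr_min_rpm:
            continue
        n_kept += 1
        pred_pos = prob > 0.5
        actual_pos = rec.score >= score_cutoff
        if pred_pos and actual_pos:
            tp += 1
        elif pred_pos:
            fp += 1
        elif actual_pos:
            fn += 1
        else:
            tn += 1
    if n_kept == 0:
        raise ValueError("no peaks remain after the expression (RPM) filter")
    return ConfusionSummary(tp, fp, tn, fn)


def confusion_sweep(
    predictions: Mapping[str, float],
    records: Mapping[str, EnrichmentRecord],
    cutoffs: Sequence[float] = (1.5, 1.75, 2.0, 2.25, 2.5),
    expr_min_rpm: float = 1.0,
) -> dict[float, ConfusionSummary]:
    return {
        c: confusion_from_scores(predictions, records, expr_min_rpm, c) for c in cutoffs
    }


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> tuple[np.ndarray, float]:
    """Threshold-sweep ROC (ties grouped) and trapezoidal AUC."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    # group tied scores: keep only the last index of each tie block
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def recapture_rate(
    identified_peaks: list[Peak],
    stringent_pas: PASSet,
    alignments,
    contig_lengths: Mapping[str, int],
    expr_min_rpm: float = 1.0,
    upstream: int = 50,
    downstream: int = 25,
) -> float:
    """Fraction of expressed annotated sites recovered by the identified peaks.

    A site counts as expressed when the RPM over the 400 nt upstream of its
    annotated position is >= ``expr_min_rpm``, and as recovered when it
    falls within the strand-oriented [-upstream, +downstream] window of any
    identified peak's 3' end.
    """
    regions = {}
    recs = list(stringent_pas)
    for i, r in enumerate(recs):
        if r.strand == "+":
            lo, hi = r.site - REGION_WIDTH + 1, r.site + 1
        else:
            lo, hi = r.site, r.site + REGION_WIDTH
        lo = max(0, lo)
        hi = min(contig_lengths[r.chrom], hi)
        regions[f"pas_{i}"] = GenomeInterval(r.chrom, lo, hi, r.strand)
    rpm = compute_rpm(alignments, regions)
    ends: dict[tuple[str, str], np.ndarray] = {}
    for p in identified_peaks:
        ends.setdefault((p.chrom, p.strand), []).append(p.three_prime_end)  # type: ignore[arg-type]
    ends = {k: np.sort(np.array(v)) for k, v in ends.items()}
    n_expressed = 0
    n_recovered = 0
    for i, r in enumerate(recs):
        if rpm[f"pas_{i}"] < expr_min_rpm:
            continue
        n_expressed += 1
        arr = ends.get((r.chrom, r.strand))
        if arr is None or len(arr) == 0:
            continue
        # site in [end-upstream, end+downstream] (sense)  <=>  end in the inverse window
        if r.strand == "+":
            lo, hi = r.site - downstream, r.site + upstream
        else:
            lo, hi = r.site - upstream, r.site + downstream
        j = np.searchsorted(arr, lo, side="left")
        if j < len(arr) and arr[j] <= hi:
            n_recovered += 1
    return n_recovered / n_expressed if n_expressed else 0.0
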