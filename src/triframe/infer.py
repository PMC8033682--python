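"""Inference: 6-frame, fragment-aware classification with outlier rejection.

A read is cropped into fragments of at most the model's nucleotide window;
each fragment and its reverse complement are encoded and classified, so all
six reading frames are covered. The read's call is the (fragment, strand)
pass whose softmax vector has the largest maximum probability — a read is
assigned a family as long as one of its windows looks like that family.

Rejection uses the max-softmax score: a holdout mixture of in-distribution
and outlier reads is swept over candidate thresholds and the threshold
maximizing the detection F1 is kept; at prediction time reads scoring below
it are rejected as carrying no trained domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import encode_batch, crop_read, reverse_complement
from .nn import ModelConfig, ModelParams, ShortReadError, forward
from .simulate import DnaRead, LabeledDataset, OUTLIER

REJECT = OUTLIER  # rejected reads are labeled like outliers in call tables


@dataclass
class PredictionResult:
    read_id: str
    softmax: np.ndarray | None
    predicted_label: int | None
    max_softmax: float
    accepted: bool
    strand: str = "+"
    fragment_index: int = 0
    status: str = "ok"  # "ok" | "too_short"


@dataclass
class CalibrationResult:
    threshold: float
    f1: float
    precision: float
    recall: float


def predict_read(
    params: ModelParams,
    config: ModelConfig,
    read: DnaRead | str,
    threshold: float = 0.0,
) -> PredictionResult:
    """Classify one read over all fragments x strands (6 reading frames).

    Reads shorter than the largest filter span are rejected with status
    ``"too_short"`` rather than scored.
    """
    if isinstance(read, str):
        read = DnaRead("read", read, OUTLIER)
    res = predict_batch(params, config, [read], threshold)
    return res[0]


def predict_batch(
    params: ModelParams,
    config: ModelConfig,
    reads: list[DnaRead],
    threshold: float = 0.0,
    batch_size: int = 256,
) -> list[PredictionResult]:
    """Vectorized :func:`predict_read` over many reads."""
    window_nt = 3 * config.window
    passes: list[str] = []
    owners: list[tuple[int, str, int]] = []  # (read index, strand, fragment)
    results: list[PredictionResult | None] = [None] * len(reads)
    for ri, read in enumerate(reads):
        if len(read.sequence) < config.min_read_nt:
            results[ri] = PredictionResult(
                read.read_id, None, None, 0.0, False, status="too_short"
            )
            continue
        for fi, frag in enumerate(crop_read(read.sequence, window_nt)):
            if len(frag) < config.min_read_nt:
                continue  # trailing sliver below the filter span
            for strand, seq in (("+", frag), ("-", reverse_complement(frag))):
                passes.append(seq)
                owners.append((ri, strand, fi))

    best: dict[int, tuple[float, np.ndarray, str, int]] = {}
    for s in range(0, len(passes), batch_size):
        chunk = passes[s : s + batch_size]
        tens, lens = encode_batch(chunk, config.window)
        probs = forward(params, config, tens, lens)
        for k, p in enumerate(probs):
            ri, strand, fi = owners[s + k]
            score = float(p.max())
            cur = best.get(ri)
            if cur is None or score > cur[0]:
                best[ri] = (score, p, strand, fi)

    for ri, read in enumerate(reads):
        if results[ri] is not None:
            continue
        if ri not in best:  # every fragment was below the filter span
            results[ri] = PredictionResult(
                read.read_id, None, None, 0.0, False, status="too_short"
            )
            continue
        score, p, strand, fi = best[ri]
        results[ri] = PredictionResult(
            read.read_id,
            p,
            int(p.argmax()),
            score,
            score >= threshold,
            strand,
            fi,
        )
    return results


def _detection_counts(accept_in, correct_in, accept_out):
    """Precision/recall of in-distribution detection at one threshold."""
    n_in = len(accept_in)
    accepted_total = int(np.sum(accept_in)) + int(np.sum(accept_out))
    tp_recall = int(np.sum(accept_in & correct_in))
    recall = tp_recall / n_in if n_in else 0.0
    precision = (
        int(np.sum(accept_in)) / accepted_total if accepted_total else 1.0
    )
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def calibrate_threshold(
    scores_in: list[tuple[float, bool]],
    scores_out: list[float],
) -> CalibrationResult:
    """F1-maximizing max-softmax threshold on a labeled holdout.

    Candidate thresholds are the midpoints between consecutive distinct
    observed scores plus the sentinels 0 and 1, so the result does not
    depend on tie ordering. Ties in F1 break toward the smallest threshold.
    When nothing is accepted, precision is defined as 1 (empty-accept
    convention), keeping the sweep total.
    """
    if not scores_in or not scores_out:
        raise ValueError("both score lists must be non-empty")
    s_in = np.array([s for s, _ in scores_in], dtype=np.float64)
    c_in = np.array([c for _, c in scores_in], dtype=bool)
    s_out = np.asarray(scores_out, dtype=np.float64)

    observed = np.unique(np.concatenate([s_in, s_out]))
    mids = (observed[:-1] + observed[1:]) / 2.0
    candidates = np.unique(np.concatenate([[0.0], mids, [1.0]]))

    best = None
    for t in candidates:
        precision, recall, f1 = _detection_counts(
            s_in >= t, c_in, s_out >= t
        )
        if best is None or f1 > best.f1 + 1e-15:
            best = CalibrationResult(float(t), f1, precision, recall)
    return best


def detect(
    params: ModelParams,
    config: ModelConfig,
    reads: list[DnaRead],
    threshold: float,
) -> list[PredictionResult]:
    """Classify reads and reject those scoring below the threshold."""
    return predict_batch(params, config, reads, threshold)


def collect_scores(
    params: ModelParams,
    config: ModelConfig,
    d_in: LabeledDataset,
    d_out: LabeledDataset,
) -> tuple[list[tuple[float, bool]], list[float]]:
    """Max-softmax scores of a holdout, ready for threshold calibration."""
    res_in = predict_batch(params, config, d_in.reads)
    res_out = predict_batch(params, config, d_out.reads)
    scores_in = [
        (r.max_softmax, r.predicted_label == read.true_label)
        for r, read in zip(res_in, d_in.reads)
        if r.status == "ok"
    ]
    scores_out = [r.max_softmax for r in res_out if r.status == "ok"]
    return scores_in, scores_out
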