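"""Evaluation: accuracy, detection metrics, frame-order and filter probes.

Detection metrics follow the open-set convention: recall is the fraction of
in-distribution reads that were accepted and correctly classified;
precision is the fraction of accepted reads that are in-distribution;
micro-F1 is their harmonic mean.

Two interpretability probes are provided. The frame-order experiment feeds
every permutation of the three frame channels of the test tensors to a
fixed trained model and reports accuracy per order — for a well-trained
model the spread (max - min) is small, i.e. the channel order the model was
trained with is not load-bearing. Fragment extraction ranks the multi-size
convolutional filters by how often each wins the max-over-time pool across
reads and emits, for the top filters, the peptide window under the winning
position in each reading frame; stacking those windows and taking the
per-column consensus recovers the conserved (planted) motif the filter
learned.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .encoding import encode_batch, translate_frame
from .infer import PredictionResult
from .nn import ModelConfig, ModelParams, forward
from .simulate import LabeledDataset, OUTLIER

FRAME_ORDERS = tuple(itertools.permutations((0, 1, 2)))


@dataclass
class MetricReport:
    n_reads: int
    accuracy: float
    recall: float
    precision: float
    micro_f1: float
    confusion: dict[tuple[int, int], int] = field(default_factory=dict)
    per_class: dict[int, dict[str, float]] = field(default_factory=dict)


@dataclass
class ActivatedFragment:
    filter_id: tuple[int, int]  # (size-group index, filter index)
    read_id: str
    channel: int
    peptide: str
    activation: float
    position: int  # start codon of the receptive field


def classification_accuracy(
    calls: dict[str, int], truth: dict[str, int]
) -> float:
    """Fraction of reads whose top-1 call matches the truth."""
    if set(calls) != set(truth):
        raise ValueError("call and truth id sets differ")
    if not calls:
        return 0.0
    return sum(calls[i] == truth[i] for i in calls) / len(calls)


def detection_metrics(
    calls: list[PredictionResult], truth: dict[str, int]
) -> MetricReport:
    """Open-set recall/precision/micro-F1 over calls with OUTLIER truth.

    A rejected or too-short read counts as labeled OUTLIER. Recall counts
    correctly classified in-distribution reads over all in-distribution
    reads; precision counts in-distribution reads among all accepted reads.
    """
    n_in = acc_total = acc_in = tp = 0
    confusion: Counter = Counter()
    class_tp: Counter = Counter()
    class_true: Counter = Counter()
    class_pred: Counter = Counter()
    correct = 0
    for r in calls:
        t = truth[r.read_id]
        pred = r.predicted_label if (r.accepted and r.status == "ok") else OUTLIER
        confusion[(t, pred)] += 1
        if pred == t:
            correct += 1
        if t != OUTLIER:
            n_in += 1
            class_true[t] += 1
        if pred != OUTLIER:
            acc_total += 1
            class_pred[pred] += 1
            if t != OUTLIER:
                acc_in += 1
                if pred == t:
                    tp += 1
                    class_tp[t] += 1
    recall = tp / n_in if n_in else 0.0
    precision = acc_in / acc_total if acc_total else 1.0
    micro_f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    per_class = {
        k: {
            "recall": class_tp[k] / class_true[k] if class_true[k] else 0.0,
            "precision": class_tp[k] / class_pred[k] if class_pred[k] else 1.0,
        }
        for k in class_true
    }
    return MetricReport(
        n_reads=len(calls),
        accuracy=correct / len(calls) if calls else 0.0,
        recall=recall,
        precision=precision,
        micro_f1=micro_f1,
        confusion=dict(confusion),
        per_class=per_class,
    )


def frame_order_experiment(
    params: ModelParams,
    config: ModelConfig,
    dataset: LabeledDataset,
    orders: tuple = FRAME_ORDERS,
    batch_size: int = 256,
) -> dict:
    """Test-time channel-permutation probe (model fixed).

    Returns accuracy per frame order and the spread max - min.
    """
    tens, lens = encode_batch(dataset.sequences(), config.window)
    labels = dataset.labels()
    accs: dict[tuple[int, int, int], float] = {}
    for order in orders:
        correct = 0
        permuted = tens[:, list(order)]
        for i in range(0, len(labels), batch_size):
            p = forward(
                params, config, permuted[i : i + batch_size],
                lens[i : i + batch_size],
            )
            correct += int(np.sum(p.argmax(axis=1) == labels[i : i + batch_size]))
        accs[order] = correct / len(labels)
    vals = list(accs.values())
    return {
        "accuracy_per_order": accs,
        "delta": max(vals) - min(vals),
    }


def _receptive_field(config: ModelConfig, multi_size: int) -> int:
    return sum(h - 1 for _, h in config.fixed_geometry) + multi_size


def extract_activated_fragments(
    params: ModelParams,
    config: ModelConfig,
    dataset: LabeledDataset,
    top_k_filters: int = 1,
    pool_winners_only: bool = True,
    batch_size: int = 256,
) -> list[ActivatedFragment]:
    """Peptide windows under the most frequently pool-winning filters.

    A filter "wins" a read when its pooled activation is the largest among
    all multi-size filters for that read (with ``pool_winners_only=False``
    every filter with positive activation contributes instead). For each of
    the ``top_k_filters`` most frequent winners, the receptive-field peptide
    window at the winning position is emitted per read and frame channel.
    """
    if top_k_filters <= 0:
        return []
    if config.variant != "three_frame":
        raise ValueError("fragment extraction expects the three_frame variant")
    seqs = dataset.sequences()
    tens, lens = encode_batch(seqs, config.window)

    # flat ids over all multi-size filters
    sizes = [h for h, _ in config.multi_geometry]
    counts = [f for _, f in config.multi_geometry]
    offsets = np.cumsum([0] + counts)

    win_counter: Counter = Counter()
    per_read: list[dict] = []  # per read: flat filter -> (activation, pos)
    for s in range(0, len(seqs), batch_size):
        probs, cache = forward(
            params, config, tens[s : s + batch_size], lens[s : s + batch_size],
            return_cache=True,
        )
        mcache = cache["branches"][0]["multi"]
        B = len(probs)
        pooled_all = np.full((B, offsets[-1]), -np.inf)
        pos_all = np.zeros((B, offsets[-1]), dtype=np.int64)
        for mi in range(len(sizes)):
            _, z, mask, am, _ = mcache[mi]
            r = np.where(mask[:, :, None], np.maximum(z, 0.0), -np.inf)
            pooled = np.take_along_axis(r, am[:, None, :], axis=1)[:, 0, :]
            pooled_all[:, offsets[mi] : offsets[mi + 1]] = pooled
            pos_all[:, offsets[mi] : offsets[mi + 1]] = am
        for b in range(B):
            entry = {}
            if pool_winners_only:
                fbest = int(pooled_all[b].argmax())
                win_counter[fbest] += 1
                entry[fbest] = (float(pooled_all[b, fbest]), int(pos_all[b, fbest]))
            else:
                for f in np.flatnonzero(pooled_all[b] > 0):
                    win_counter[int(f)] += 1
                    entry[int(f)] = (float(pooled_all[b, f]), int(pos_all[b, f]))
            per_read.append(entry)

    top = [f for f, _ in win_counter.most_common(top_k_filters)]
    frags: list[ActivatedFragment] = []
    for ri, entry in enumerate(per_read):
        for f in top:
            if f not in entry:
                continue
            activation, pos = entry[f]
            if activation <= 0:
                continue
            mi = int(np.searchsorted(offsets, f, side="right") - 1)
            eff = _receptive_field(config, sizes[mi])
            fid = (mi, f - int(offsets[mi]))
            for j in range(3):
                pep = translate_frame(dataset.reads[ri].sequence, j)[
                    pos : pos + eff
                ]
                if pep:
                    frags.append(
                        ActivatedFragment(
                            fid, dataset.reads[ri].read_id, j, pep,
                            activation, pos,
                        )
                    )
    return frags


def fragment_consensus(
    fragments: list[ActivatedFragment], channel: int
) -> str:
    """Per-column majority residue over one channel's stacked fragments."""
    peps = [f.peptide for f in fragments if f.channel == channel]
    if not peps:
        return ""
    width = max(len(p) for p in peps)
    out = []
    for col in range(width):
        col_syms = [p[col] for p in peps if len(p) > col]
        out.append(Counter(col_syms).most_common(1)[0][0])
    return "".join(out)
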