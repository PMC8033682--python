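"""Canonical desk-scale experiments exercising the whole method.

These drive the full pipeline — family generation, read simulation,
training, calibration, detection, interpretation — at sizes a laptop CPU
handles in seconds to minutes, and return the summary numbers each
experiment is about. They are used by the acceptance script and the test
suite, and serve as worked examples of the API.

Study conditions (fixed defaults): proteins of 120 residues carrying one
planted 12-residue motif, within-family substitution rate 0.10, 24
members per family (a scaled-down homologous family) split 80/20 into train/test references before
simulation, full-length plus-strand reads, training error rates {0%, 10%}
with the 10:60:30 substitution:insertion:deletion mix, and the desk-scale
architecture (window 128 codons, 32 size-3 first-layer filters, second
layer sizes [4, 8, 12] x 24 filters, 64 hidden units).
"""

from __future__ import annotations

import numpy as np

from .encoding import encode_batch
from .evaluate import (
    detection_metrics,
    extract_activated_fragments,
    fragment_consensus,
    frame_order_experiment,
)
from .infer import calibrate_threshold, collect_scores, predict_batch
from .nn import ModelConfig, forward
from .simulate import (
    FamilySpec,
    LabeledDataset,
    ReadSimConfig,
    generate_families,
    generate_outliers,
    make_references,
    simulate_reads,
    split_members,
)
from .train import TrainConfig, train


def _accuracy(params, config, dataset: LabeledDataset, batch=256) -> float:
    tens, lens = encode_batch(dataset.sequences(), config.window)
    labels = dataset.labels()
    correct = 0
    for i in range(0, len(labels), batch):
        p = forward(params, config, tens[i : i + batch], lens[i : i + batch])
        correct += int(np.sum(p.argmax(axis=1) == labels[i : i + batch]))
    return correct / len(labels)


#: Fixed read length (nt) used by the desk-scale experiments: shorter than
#: the 360-nt references so start positions (hence frame offsets) vary
#: uniformly, while the interior motif margin keeps every read covering the
#: family motif.
READ_LENGTH = (300.0, 0.0)


def build_family_data(
    seed: int,
    n_families: int = 3,
    train_error_rates: tuple[float, ...] = (0.0,),
    test_error_rate: float = 0.0,
    train_coverage: float = 9.0,
    test_coverage: float = 5.0,
):
    """Families, split references and simulated train/test read sets."""
    spec = FamilySpec(n_families=n_families, seed=seed)
    fams = generate_families(spec)
    train_m, test_m = split_members(fams, seed=seed)
    refs_tr = make_references(fams, train_m, seed=seed + 1)
    refs_te = make_references(fams, test_m, seed=seed + 2)
    parts = [
        simulate_reads(
            refs_tr,
            ReadSimConfig(
                error_rate=r, coverage=train_coverage, seed=seed + 3 + k,
                read_length_model=READ_LENGTH,
            ),
        )
        for k, r in enumerate(train_error_rates)
    ]
    ds_tr = LabeledDataset(
        [r for p in parts for r in p.reads], refs_tr.label_names
    )
    ds_te = simulate_reads(
        refs_te,
        ReadSimConfig(
            error_rate=test_error_rate, coverage=test_coverage, seed=seed + 9,
            read_length_model=READ_LENGTH,
        ),
    )
    return fams, ds_tr, ds_te


def sanity_overfit(seed: int = 0, epochs: int = 10):
    """Three trivially separable families, error-free reads.

    The planted motifs are perfectly discriminative, so the classifier
    should essentially solve the task within a few epochs.
    """
    fams, ds_tr, ds_te = build_family_data(seed, n_families=3)
    config = ModelConfig.desk(n_classes=3)
    result = train(
        config, ds_tr, None, TrainConfig(epochs=epochs, seed=seed)
    )
    return {
        "families": fams,
        "config": config,
        "result": result,
        "train_set": ds_tr,
        "test_set": ds_te,
        "train_accuracy": _accuracy(result.params, config, ds_tr),
        "test_accuracy": _accuracy(result.params, config, ds_te),
    }


def augmentation_comparison(seed: int = 0, epochs: int = 12):
    """Error-augmented vs error-free training, judged on 10%-error reads.

    Trains one model on error-free reads only and one on the union of
    error-free and 10%-error reads (same per-rate coverage, same epochs),
    then compares their accuracy on a 10%-error test set.
    """
    _, ds_tr_free, ds_te = build_family_data(
        seed, n_families=5, train_error_rates=(0.0,),
        test_error_rate=0.10,
    )
    _, ds_tr_mix, _ = build_family_data(
        seed, n_families=5, train_error_rates=(0.0, 0.10),
        test_error_rate=0.10,
    )
    config = ModelConfig.desk(n_classes=5)
    tc = TrainConfig(epochs=epochs, seed=seed)
    r_free = train(config, ds_tr_free, None, tc)
    r_mix = train(config, ds_tr_mix, None, tc)
    return {
        "error_free_accuracy": _accuracy(r_free.params, config, ds_te),
        "augmented_accuracy": _accuracy(r_mix.params, config, ds_te),
    }


def outlier_exposure_comparison(
    seed: int = 0, epochs: int = 12, n_outliers_train: int = 500,
    n_outliers_eval: int = 300,
):
    """OE vs plain training: outlier max-softmax scores and detection F1.

    Both models see the same in-distribution reads; the OE model
    additionally sees decoy-family outlier reads through the KL-to-uniform
    auxiliary loss (lambda = 0.5). Held-out outliers come from decoy
    families generated with a different seed than the training outliers.
    Each model is calibrated on a holdout mixture and its detection F1 is
    measured on a disjoint 10%-in-distribution test mixture.
    """
    fams, ds_tr, ds_te = build_family_data(
        seed, n_families=5, train_error_rates=(0.0, 0.10),
        test_error_rate=0.10, test_coverage=10.0,
    )
    motifs = fams.motif_strings()
    spec = fams.spec
    out_train = generate_outliers(
        n_outliers_train, seed=seed + 101, avoid_motifs=motifs,
        family_spec=spec,
    )
    out_eval = generate_outliers(
        n_outliers_eval + len(ds_te) * 9, seed=seed + 202,
        avoid_motifs=motifs, family_spec=spec,
    )
    config = ModelConfig.desk(n_classes=5)
    r_plain = train(
        config, ds_tr, None, TrainConfig(epochs=epochs, seed=seed)
    )
    r_oe = train(
        config, ds_tr, out_train,
        TrainConfig(epochs=epochs, seed=seed, oe_enabled=True, oe_lambda=0.5),
    )

    # split evaluation material: calibration half / test half
    half_in = len(ds_te) // 2
    cal_in = LabeledDataset(ds_te.reads[:half_in], ds_te.label_names)
    test_in = LabeledDataset(ds_te.reads[half_in:], ds_te.label_names)
    # test mixture is ~10% in-distribution: 9 outliers per in-dist read
    n_cal_out = n_outliers_eval
    cal_out = LabeledDataset(out_eval.reads[:n_cal_out], [])
    test_out = LabeledDataset(
        out_eval.reads[n_cal_out : n_cal_out + 9 * len(test_in)], []
    )

    report = {}
    for tag, res in (("plain", r_plain), ("oe", r_oe)):
        s_in, s_out = collect_scores(res.params, config, cal_in, cal_out)
        cal = calibrate_threshold(s_in, s_out)
        mixture = LabeledDataset(
            test_in.reads + test_out.reads, ds_te.label_names
        )
        calls = predict_batch(
            res.params, config, mixture.reads, cal.threshold
        )
        truth = {r.read_id: r.true_label for r in mixture.reads}
        metrics = detection_metrics(calls, truth)
        out_scores = [
            r.max_softmax
            for r in predict_batch(res.params, config, test_out.reads)
            if r.status == "ok"
        ]
        report[tag] = {
            "mean_outlier_max_softmax": float(np.mean(out_scores)),
            "threshold": cal.threshold,
            "detection_f1": metrics.micro_f1,
            "detection_recall": metrics.recall,
            "detection_precision": metrics.precision,
        }
    return report


def frame_order_probe(sanity: dict) -> dict:
    """Channel-permutation robustness of a trained sanity model."""
    return frame_order_experiment(
        sanity["result"].params, sanity["config"], sanity["test_set"]
    )


def well_trained_study(seed: int = 0, epochs: int = 20):
    """Train a high-coverage model and probe its channel-order spread.

    Frame-order insensitivity is an emergent property that strengthens with
    training coverage, so the interpretability probes (channel permutation,
    motif recovery) use a model trained at three times the sanity coverage
    (27x) for 20 epochs, evaluated on an enlarged test simulation. Returns
    the trained study (families, model, test set) together with the
    accuracy per channel order and the spread ``delta``.
    """
    fams, ds_tr, ds_te = build_family_data(
        seed, n_families=3, train_coverage=27.0, test_coverage=15.0
    )
    config = ModelConfig.desk(n_classes=3)
    result = train(config, ds_tr, None, TrainConfig(epochs=epochs, seed=seed))
    study = {
        "families": fams,
        "config": config,
        "result": result,
        "test_set": ds_te,
        "test_accuracy": _accuracy(result.params, config, ds_te),
    }
    study.update(frame_order_experiment(result.params, config, ds_te))
    return study


def _longest_common_substring(a: str, b: str) -> int:
    best = 0
    for i in range(len(a)):
        for j in range(i + best + 1, len(a) + 1):
            if a[i:j] in b:
                best = j - i
            else:
                break
    return best


def motif_recovery(sanity: dict, min_match: int = 5) -> dict:
    """Does the top pool-winning filter read out the planted motifs?

    For each family, feeds that family's test reads, extracts the top
    filter's receptive-field peptide windows, stacks the windows from each
    read's protein-frame channel (reads start at arbitrary offsets, so the
    in-frame translation lands in channel ``(3 - offset) % 3``), and checks
    whether their per-column consensus shares a contiguous substring of at
    least ``min_match`` residues with the family's planted motif. Returns
    the per-family outcomes and the majority verdict.
    """
    fams = sanity["families"]
    params = sanity["result"].params
    config = sanity["config"]
    ds = sanity["test_set"]
    outcomes = []
    for fam_i, name in enumerate(ds.label_names):
        fam_reads = [r for r in ds.reads if r.true_label == fam_i]
        sub = LabeledDataset(fam_reads, ds.label_names)
        frags = extract_activated_fragments(params, config, sub, 1)
        inframe = {
            r.read_id: (3 - r.source_frame_offset) % 3 for r in fam_reads
        }
        aligned = [f for f in frags if f.channel == inframe[f.read_id]]
        motif = fams.motifs[fam_i][0][1]
        best = 0
        for ch in range(3):
            cons = fragment_consensus(
                [f for f in aligned if f.channel == ch], ch
            )
            if cons:
                best = max(best, _longest_common_substring(cons, motif))
        outcomes.append({"family": name, "longest_match": best})
    n_ok = sum(o["longest_match"] >= min_match for o in outcomes)
    return {
        "per_family": outcomes,
        "recovered_families": n_ok,
        "majority_recovered": n_ok >= (len(outcomes) + 1) // 2,
    }
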