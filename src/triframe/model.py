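"""High-level Model/Results interface.

:class:`DomainCNN` bundles a labeled read dataset (plus an optional outlier
set) with an architecture and an optimization recipe; ``fit()`` trains the
network and returns a :class:`DomainCNNResults` carrying the learned
parameters, the training diagnostics, and the downstream operations —
prediction, threshold calibration, open-set detection, evaluation and
filter interpretation — so a full analysis reads:

    model = DomainCNN(train_reads, outliers=outlier_reads)
    res = model.fit()
    res.calibrate(holdout_in, holdout_out)
    calls = res.detect(new_reads)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import evaluate as _evaluate
from . import infer as _infer
from . import io as _io
from .nn import ModelConfig, ModelParams
from .simulate import DnaRead, LabeledDataset
from .train import TrainConfig, TrainResult, train


def _default_window(dataset: LabeledDataset) -> int:
    longest = max((len(r.sequence) for r in dataset.reads), default=300)
    # headroom for insertion-driven length growth, rounded up to codons
    return min(1000, max(32, int(np.ceil(1.1 * longest / 3))))


class DomainCNN:
    """A domain classifier specification: data + architecture + recipe."""

    def __init__(
        self,
        data: LabeledDataset,
        outliers: LabeledDataset | None = None,
        config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
    ):
        if not data.reads:
            raise ValueError("training dataset is empty")
        self.data = data
        self.outliers = outliers
        if config is None:
            config = ModelConfig.desk(
                n_classes=len(data.label_names),
                window=_default_window(data),
            )
        if config.n_classes != len(data.label_names):
            raise ValueError("config.n_classes must match label_names")
        self.config = config
        self.train_config = train_config or TrainConfig(
            oe_enabled=outliers is not None
        )

    @classmethod
    def from_files(
        cls,
        reads_path,
        labels_path,
        outliers_path=None,
        config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
    ) -> "DomainCNN":
        reads = _io.read_sequences(reads_path)
        data = _io.apply_labels(reads, _io.read_labels(labels_path))
        outliers = None
        if outliers_path is not None:
            outliers = LabeledDataset(
                _io.read_sequences(outliers_path), []
            )
        return cls(data, outliers, config, train_config)

    def fit(self, seed: int | None = None) -> "DomainCNNResults":
        cfg = self.train_config
        if seed is not None:
            cfg = TrainConfig(
                **{**cfg.__dict__, "seed": seed}
            )
        result = train(self.config, self.data, self.outliers, cfg)
        return DomainCNNResults(self, result)


@dataclass
class DomainCNNResults:
    """Fitted classifier: learned parameters plus analysis operations."""

    model: DomainCNN
    train_result: TrainResult
    threshold: float = 0.0
    calibration: _infer.CalibrationResult | None = None

    @property
    def params(self) -> ModelParams:
        return self.train_result.params

    @property
    def config(self) -> ModelConfig:
        return self.model.config

    # --- downstream operations -------------------------------------------
    def predict(
        self, reads: list[DnaRead] | LabeledDataset, threshold=None
    ) -> list[_infer.PredictionResult]:
        if isinstance(reads, LabeledDataset):
            reads = reads.reads
        t = self.threshold if threshold is None else threshold
        return _infer.predict_batch(self.params, self.config, reads, t)

    def calibrate(
        self, holdout_in: LabeledDataset, holdout_out: LabeledDataset
    ) -> _infer.CalibrationResult:
        s_in, s_out = _infer.collect_scores(
            self.params, self.config, holdout_in, holdout_out
        )
        self.calibration = _infer.calibrate_threshold(s_in, s_out)
        self.threshold = self.calibration.threshold
        return self.calibration

    def detect(self, reads, threshold=None):
        return self.predict(reads, threshold)

    def evaluate(
        self, dataset: LabeledDataset, threshold=None
    ) -> _evaluate.MetricReport:
        calls = self.predict(dataset, threshold)
        truth = {r.read_id: r.true_label for r in dataset.reads}
        return _evaluate.detection_metrics(calls, truth)

    def frame_order_experiment(self, dataset: LabeledDataset) -> dict:
        return _evaluate.frame_order_experiment(
            self.params, self.config, dataset
        )

    def extract_fragments(self, dataset: LabeledDataset, top_k=1, **kw):
        return _evaluate.extract_activated_fragments(
            self.params, self.config, dataset, top_k, **kw
        )

    def save(self, path) -> None:
        _io.save_model(path, self.params, self.config)

    # --- reporting --------------------------------------------------------
    def summary(self) -> str:
        c = self.config
        tr = self.train_result
        lines = [
            "Domain CNN results",
            "=" * 54,
            f"variant:            {c.variant}",
            f"classes:            {c.n_classes} "
            f"({', '.join(self.model.data.label_names)})",
            f"window:             {c.window} codons ({3 * c.window} nt)",
            f"fixed conv layers:  {list(c.fixed_layers)}",
            f"multi-size layer:   {list(c.multi_specs)} (size, filters)",
            f"hidden units:       {c.hidden_units}",
            f"dropout:            {c.dropout_rate}",
            f"parameters:         {self.params.n_parameters():,}",
            f"training reads:     {len(self.model.data)}",
            f"outlier exposure:   "
            f"{'on (lambda=%.2g)' % self.model.train_config.oe_lambda if self.model.train_config.oe_enabled else 'off'}",
            f"epochs:             {len(tr.loss_trajectory)}",
            f"final loss:         {tr.loss_trajectory[-1]:.4f}",
            f"holdout accuracy:   {tr.holdout_accuracy[-1]:.4f}",
        ]
        if self.calibration is not None:
            cal = self.calibration
            lines += [
                f"softmax threshold:  {cal.threshold:.4f} "
                f"(F1={cal.f1:.4f}, P={cal.precision:.4f}, R={cal.recall:.4f})",
            ]
        return "\n".join(lines)
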