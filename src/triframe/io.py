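"""Sequence, label-table and model persistence.

Sequence files stay standard (FASTA/FASTQ via Biopython); labels ride in a
sidecar TSV (read_id, family, frame_offset) so headers need no convention
beyond an optional ``id|family`` fallback for reference files. Models are
saved as a single versioned ``.npz`` holding the weight arrays plus the
architecture as embedded JSON, so ``load_model`` reproduces bit-identical
predictions.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .nn import ModelConfig, ModelParams
from .simulate import DnaRead, LabeledDataset, OUTLIER, ReferenceSet

MODEL_FORMAT_VERSION = 1

_FORMAT_BY_EXT = {
    ".fa": "fasta", ".fasta": "fasta", ".fna": "fasta",
    ".fq": "fastq", ".fastq": "fastq",
}


def _sniff_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    try:
        return _FORMAT_BY_EXT[path.suffix.lower()]
    except KeyError:
        raise ValueError(f"cannot infer format from extension: {path}") from None


def read_sequences(path: str | Path, fmt: str | None = None) -> list[DnaRead]:
    """Read FASTA/FASTQ into DnaReads; U mapped to T, case-folded upper."""
    path = Path(path)
    fmt = _sniff_format(path, fmt)
    reads = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), fmt)):
            seq = str(rec.seq).upper().replace("U", "T")
            reads.append(DnaRead(rec.id, seq, OUTLIER))
    except ValueError as e:
        raise ValueError(f"malformed record at index {len(reads)}: {e}") from e
    return reads


def write_sequences(
    dataset: LabeledDataset, path: str | Path, fmt: str | None = None
) -> None:
    """Write reads as FASTA, or FASTQ with uniform dummy quality 'I'."""
    path = Path(path)
    fmt = _sniff_format(path, fmt)
    records = []
    for r in dataset.reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        if fmt == "fastq":
            rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)
        records.append(rec)
    SeqIO.write(records, str(path), fmt)


def write_labels(dataset: LabeledDataset, path: str | Path) -> None:
    rows = [
        {
            "read_id": r.read_id,
            "family": (
                dataset.label_names[r.true_label]
                if r.true_label != OUTLIER
                else "OUTLIER"
            ),
            "frame_offset": r.source_frame_offset,
        }
        for r in dataset.reads
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def apply_labels(reads: list[DnaRead], table: pd.DataFrame) -> LabeledDataset:
    """Attach a sidecar label table to reads read from FASTA/FASTQ."""
    names = sorted(set(table["family"]) - {"OUTLIER"})
    index = {n: i for i, n in enumerate(names)}
    by_id = dict(zip(table["read_id"], table["family"]))
    for r in reads:
        fam = by_id.get(r.read_id, "OUTLIER")
        r.true_label = index.get(fam, OUTLIER)
    return LabeledDataset(reads, names)


def write_references(refs: ReferenceSet, path: str | Path) -> None:
    """References as FASTA with the family after a '|' in the header."""
    records = [
        SeqRecord(
            Seq(seq),
            id=f"ref{i}|{refs.label_names[lab]}",
            description="",
        )
        for i, (seq, lab) in enumerate(zip(refs.sequences, refs.labels))
    ]
    SeqIO.write(records, str(path), "fasta")


def save_model(
    path: str | Path, params: ModelParams, config: ModelConfig
) -> None:
    arrays: dict[str, np.ndarray] = {}
    for i, (W, b) in enumerate(params.fixed):
        arrays[f"fixed{i}_W"], arrays[f"fixed{i}_b"] = W, b
    for i, (W, b) in enumerate(params.multi):
        arrays[f"multi{i}_W"], arrays[f"multi{i}_b"] = W, b
    arrays.update(Wh=params.Wh, bh=params.bh, Wo=params.Wo, bo=params.bo)
    np.savez(
        path,
        __version__=np.array(MODEL_FORMAT_VERSION),
        __config__=np.frombuffer(
            config.to_json().encode("utf-8"), dtype=np.uint8
        ),
        __seed__=np.array(params.seed),
        **arrays,
    )


def load_model(path: str | Path) -> tuple[ModelParams, ModelConfig]:
    try:
        with np.load(path) as z:
            data = {k: z[k] for k in z.files}
    except Exception as e:
        raise ValueError(f"cannot read model file {path}: {e}") from e
    if "__version__" not in data or int(data["__version__"]) != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version mismatch in {path}; "
            f"expected {MODEL_FORMAT_VERSION}"
        )
    config = ModelConfig.from_json(data["__config__"].tobytes().decode("utf-8"))
    fixed = []
    i = 0
    while f"fixed{i}_W" in data:
        fixed.append((data[f"fixed{i}_W"], data[f"fixed{i}_b"]))
        i += 1
    multi = []
    i = 0
    while f"multi{i}_W" in data:
        multi.append((data[f"multi{i}_W"], data[f"multi{i}_b"]))
        i += 1
    params = ModelParams(
        fixed, multi, data["Wh"], data["bh"], data["Wo"], data["bo"],
        seed=int(data["__seed__"]),
    )
    return params, config


def load_model_config(path: str | Path) -> ModelConfig:
    """Config-only load for inspection."""
    return load_model(path)[1]


def write_calibration(result, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "threshold": result.threshold,
                "f1": result.f1,
                "precision": result.precision,
                "recall": result.recall,
            },
            indent=2,
        )
    )


def write_predictions(results, path: str | Path) -> None:
    rows = [
        {
            "read_id": r.read_id,
            "label": r.predicted_label if r.predicted_label is not None else -1,
            "max_softmax": r.max_softmax,
            "accepted": r.accepted,
            "strand": r.strand,
            "fragment": r.fragment_index,
            "status": r.status,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_fragments_fasta(fragments, path: str | Path) -> None:
    """Activated fragments as FASTA for external logo tools."""
    records = [
        SeqRecord(
            Seq(f.peptide),
            id=f"filter{f.filter_id[0]}.{f.filter_id[1]}"
            f"|{f.read_id}|frame{f.channel}|act{f.activation:.4f}",
            description="",
        )
        for f in fragments
    ]
    SeqIO.write(records, str(path), "fasta")
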