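import numpy as np
import pytest

from triframe.nn import ModelConfig
from triframe.simulate import (
    FamilySpec,
    ReadSimConfig,
    generate_families,
    make_references,
    simulate_reads,
    split_members,
)
from triframe.train import TrainConfig, train


@pytest.fixture(scope="session")
def tiny_world():
    """A small trained classifier shared by inference/evaluation tests.

    Three families of 60-residue proteins with 10-residue motifs,
    error-free full-length reads, and a narrow network — enough signal to
    train to high accuracy in a few seconds.
    """
    spec = FamilySpec(
        n_families=3,
        protein_length=60,
        motif_length=10,
        motif_margin=15,
        members_per_family=6,
        seed=5,
    )
    fams = generate_families(spec)
    train_m, test_m = split_members(fams, seed=5)
    refs_tr = make_references(fams, train_m, seed=6)
    refs_te = make_references(fams, test_m, seed=7)
    ds_tr = simulate_reads(refs_tr, ReadSimConfig(0.0, coverage=12, seed=8))
    ds_te = simulate_reads(refs_te, ReadSimConfig(0.0, coverage=4, seed=9))
    config = ModelConfig(
        n_classes=3,
        fixed_layers=((12, 3),),
        multi_specs=((4, 12), (8, 12)),
        hidden_units=24,
        dropout_rate=0.2,
        window=64,
    )
    result = train(config, ds_tr, None, TrainConfig(epochs=20, seed=0))
    return {
        "families": fams,
        "config": config,
        "params": result.params,
        "result": result,
        "train_set": ds_tr,
        "test_set": ds_te,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
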