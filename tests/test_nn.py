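import numpy as np
import pytest

from triframe.encoding import encode_3frame, encode_batch
from triframe.nn import (
    ModelConfig,
    ShortReadError,
    backward,
    conv_feature,
    forward,
    init_model,
    zero_grads,
)
from triframe.train import objective_from_probs


def naive_conv(arr, filt, bias):
    """Triple-loop oracle for the 3-channel window dot-product."""
    C, n, A = arr.shape
    h = filt.shape[1]
    out = []
    for i in range(n - h + 1):
        s = bias
        for j in range(C):
            for r in range(h):
                for a in range(A):
                    s += filt[j, r, a] * arr[j, i + r, a]
        out.append(max(s, 0.0))
    return np.array(out)


class TestConvFeature:
    def test_zero_filter_gives_zero(self):
        arr = encode_3frame("ATGGCCTTA", window=3)
        c = conv_feature(arr, np.zeros((3, 2, 21)), 0.0)
        assert (c == 0).all()

    def test_indicator_filter_counts_motif_match(self):
        from triframe.alphabet import AA_TO_INDEX

        arr = encode_3frame("ATGGCC", window=2)
        filt = np.zeros((3, 1, 21))
        filt[0, 0, AA_TO_INDEX["M"]] = 1.0  # fires where channel 0 shows M
        c = conv_feature(arr, filt, 0.0)
        assert c.tolist() == [1.0, 0.0]

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(20):
            arr = rng.random((3, 9, 21))
            filt = rng.standard_normal((3, 4, 21))
            b = float(rng.standard_normal())
            np.testing.assert_allclose(
                conv_feature(arr, filt, b), naive_conv(arr, filt, b),
                atol=1e-6,
            )

    def test_oversized_filter_rejected(self, rng):
        with pytest.raises(ValueError):
            conv_feature(rng.random((3, 4, 21)), rng.random((3, 5, 21)), 0.0)


def small_config(variant="three_frame", **kw):
    defaults = dict(
        n_classes=4,
        fixed_layers=((6, 3),),
        multi_specs=((3, 5), (5, 4)),
        hidden_units=12,
        dropout_rate=0.0,
        window=30,
        variant=variant,
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


def random_batch(cfg, rng, B=3):
    C, n, A = cfg.input_channels, cfg.input_positions, cfg.input_alphabet
    batch = np.zeros((B, C, n, A), dtype=np.float32)
    lengths = np.array(
        [n] + [int(rng.integers(cfg.min_valid_positions, n + 1)) for _ in range(B - 1)]
    )
    for b in range(B):
        for c in range(C):
            idx = rng.integers(0, A, size=lengths[b])
            batch[b, c, np.arange(lengths[b]), idx] = 1
    return batch, lengths


class TestForward:
    def test_output_is_probability_simplex(self, rng):
        cfg = small_config()
        params = init_model(cfg, 0)
        batch, lengths = random_batch(cfg, rng)
        probs = forward(params, cfg, batch, lengths)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_eval_mode_is_deterministic(self, rng):
        cfg = small_config(dropout_rate=0.5)
        params = init_model(cfg, 0)
        batch, lengths = random_batch(cfg, rng)
        p1 = forward(params, cfg, batch, lengths)
        p2 = forward(params, cfg, batch, lengths)
        np.testing.assert_array_equal(p1, p2)

    def test_padding_beyond_valid_length_is_ignored(self, rng):
        """Junk rows past the valid length must not change the output."""
        cfg = small_config()
        params = init_model(cfg, 1)
        batch, lengths = random_batch(cfg, rng)
        lengths[:] = cfg.min_valid_positions + 2
        clean = forward(params, cfg, batch, lengths)
        dirty = batch.copy()
        dirty[:, :, lengths[0]:, :] = 1.0  # garbage in the padding region
        np.testing.assert_allclose(
            forward(params, cfg, dirty, lengths), clean, atol=1e-10
        )

    def test_short_input_rejected(self, rng):
        cfg = small_config()
        params = init_model(cfg, 0)
        batch, lengths = random_batch(cfg, rng)
        lengths[0] = cfg.min_valid_positions - 1
        with pytest.raises(ShortReadError):
            forward(params, cfg, batch, lengths)

    def test_shape_mismatch_rejected(self, rng):
        cfg = small_config()
        params = init_model(cfg, 0)
        with pytest.raises(ValueError, match="shape"):
            forward(params, cfg, np.zeros((1, 3, 10, 21)), np.array([10]))

    @pytest.mark.parametrize("variant", ["dna_onehot", "three_branch"])
    def test_variants_produce_simplex(self, variant, rng):
        cfg = small_config(variant=variant)
        params = init_model(cfg, 0)
        batch, lengths = random_batch(cfg, rng)
        probs = forward(params, cfg, batch, lengths)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_dna_onehot_geometry_triples_filter_sizes(self):
        cfg = small_config(variant="dna_onehot")
        assert cfg.input_positions == 3 * cfg.window
        assert cfg.input_alphabet == 4
        assert cfg.fixed_geometry[0][1] == 3 * cfg.fixed_layers[0][1]

    def test_three_branch_triples_pooled_features(self):
        assert (
            small_config(variant="three_branch").n_pooled_features
            == 3 * small_config().n_pooled_features
        )


class TestInit:
    def test_seed_determinism(self):
        cfg = small_config()
        a, b = init_model(cfg, 7), init_model(cfg, 7)
        for x, y in zip(a.flat(), b.flat()):
            np.testing.assert_array_equal(x, y)
        c = init_model(cfg, 8)
        assert any((x != y).any() for x, y in zip(a.flat(), c.flat()))

    def test_desk_model_parameter_budget(self):
        cfg = ModelConfig.desk(n_classes=5)
        assert init_model(cfg, 0).n_parameters() < 10**7

    def test_full_scale_config_builds(self):
        cfg = ModelConfig(n_classes=86)
        p = init_model(cfg, 0)
        assert p.n_parameters() < 10**7


@pytest.mark.parametrize(
    "variant,fixed",
    [
        ("three_frame", ((6, 3),)),
        ("three_frame", ((6, 3), (5, 2))),
        ("three_frame", ()),
        ("dna_onehot", ((6, 2),)),
        ("three_branch", ((6, 3),)),
    ],
)
def test_gradients_match_finite_differences(variant, fixed, rng):
    """Analytic backprop equals central finite differences for every variant."""
    cfg = small_config(variant=variant, fixed_layers=fixed)
    params = init_model(cfg, 0)
    batch, lengths = random_batch(cfg, rng)
    labels = rng.integers(0, cfg.n_classes, size=len(lengths))

    def loss():
        p = forward(params, cfg, batch, lengths)
        return objective_from_probs(p, labels, None, 0.0)

    grads = zero_grads(params)
    p, cache = forward(params, cfg, batch, lengths, return_cache=True)
    onehot = np.zeros_like(p)
    onehot[np.arange(len(labels)), labels] = 1.0
    backward(params, cfg, cache, (p - onehot) / len(labels), grads)

    flat_g = []
    for gW, gb in grads["fixed"]:
        flat_g += [gW, gb]
    for gW, gb in grads["multi"]:
        flat_g += [gW, gb]
    flat_g += [grads["Wh"], grads["bh"], grads["Wo"], grads["bo"]]

    eps = 1e-6
    for arr, g in zip(params.flat(), flat_g):
        fl, gl = arr.ravel(), g.ravel()
        for k in rng.choice(arr.size, size=min(4, arr.size), replace=False):
            orig = fl[k]
            fl[k] = orig + eps
            lp = loss()
            fl[k] = orig - eps
            lm = loss()
            fl[k] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - gl[k]) <= 1e-4 * max(1.0, abs(num))
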