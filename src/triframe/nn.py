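"""The domain-classification CNN, implemented in numpy.

Architecture: a stack of fixed-size convolutional layers (one by default)
over the 3-channel one-hot frame tensor, a multi-filter-size convolutional
layer whose per-filter feature maps are reduced by max-over-time pooling,
dropout after pooling, and a two-layer softmax classifier. The first-layer
filter consists of three ``h x 21`` matrices, one per reading-frame channel,
whose window dot-products are summed before the ReLU — so the three frames
are merged in the very first layer. Max-over-time pooling makes inference
length-independent: any input long enough to fit the largest filter works.

The network is small enough that plain matrix multiplication (im2col over
sliding windows) on a CPU trains it in seconds, so both the forward pass
and the analytic gradients are written here directly; gradients are checked
against finite differences in the test suite.

Variants:

``three_frame``
    the default described above (channels merged by the first layer).
``dna_onehot``
    nucleotide-level ``L x 4`` one-hot input with filter sizes tripled, so
    filters span the same genomic extent.
``three_branch``
    each frame channel is processed by its own branch using the matching
    slice ``w_j`` of the first-layer filter; all deeper parameters are
    shared between branches and the pooled features are concatenated
    before the classifier.

Padding neutrality: positions whose windows overlap zero-padding are masked
out of every layer and out of the max-pool, so learned biases cannot make
padding contribute — padding invariance is exact, not approximate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .alphabet import ALPHABET_SIZE

VARIANTS = ("three_frame", "dna_onehot", "three_branch")


class ShortReadError(ValueError):
    """Input shorter than the network's receptive field."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture description.

    fixed_layers
        Sequence of ``(filters, size)`` for the fixed-size convolutional
        stack; empty for a single-layer (multi-size only) network, two
        entries for the three-layer ablation.
    multi_specs
        Sequence of ``(size, filters)`` for the multi-filter-size layer.
    window
        Input span in codons (nucleotide window is ``3 x window``).
    """

    n_classes: int = 2
    fixed_layers: tuple[tuple[int, int], ...] = ((128, 3),)
    multi_specs: tuple[tuple[int, int], ...] = tuple(
        (s, 256) for s in (8, 12, 16, 20, 24, 28, 32, 36)
    )
    hidden_units: int = 512
    dropout_rate: float = 0.5
    window: int = 1000
    variant: str = "three_frame"

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        for f, h in self.fixed_layers:
            if f < 1 or h < 1:
                raise ValueError("fixed layer filters and size must be >= 1")
        for h, f in self.multi_specs:
            if f < 1 or h < 1:
                raise ValueError("multi-size filters and size must be >= 1")
        if self.variant == "three_branch" and not self.fixed_layers:
            raise ValueError("three_branch requires at least one fixed layer")

    # --- derived geometry -------------------------------------------------
    @property
    def input_channels(self) -> int:
        return 1 if self.variant == "dna_onehot" else 3

    @property
    def input_alphabet(self) -> int:
        return 4 if self.variant == "dna_onehot" else ALPHABET_SIZE

    @property
    def input_positions(self) -> int:
        return 3 * self.window if self.variant == "dna_onehot" else self.window

    def _scale(self, h: int) -> int:
        # dna_onehot filters are 3x as long: same genomic extent per filter
        return 3 * h if self.variant == "dna_onehot" else h

    @property
    def fixed_geometry(self) -> tuple[tuple[int, int], ...]:
        return tuple((f, self._scale(h)) for f, h in self.fixed_layers)

    @property
    def multi_geometry(self) -> tuple[tuple[int, int], ...]:
        return tuple((self._scale(h), f) for h, f in self.multi_specs)

    @property
    def n_pooled_features(self) -> int:
        base = sum(f for _, f in self.multi_geometry)
        return 3 * base if self.variant == "three_branch" else base

    @property
    def min_valid_positions(self) -> int:
        """Smallest number of valid input rows the network accepts."""
        rf = sum(h - 1 for _, h in self.fixed_geometry)
        return rf + max(h for h, _ in self.multi_geometry)

    @property
    def min_read_nt(self) -> int:
        """Shortest read (nucleotides) the network can classify."""
        m = self.min_valid_positions
        return m if self.variant == "dna_onehot" else 3 * m

    @classmethod
    def desk(cls, n_classes: int, window: int = 128, **kw) -> "ModelConfig":
        """Desk-scale configuration: same shape, ~8x fewer filters."""
        defaults = dict(
            n_classes=n_classes,
            fixed_layers=((32, 3),),
            multi_specs=((4, 24), (8, 24), (12, 24)),
            hidden_units=64,
            dropout_rate=0.5,
            window=window,
        )
        defaults.update(kw)
        return cls(**defaults)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_classes": self.n_classes,
                "fixed_layers": [list(t) for t in self.fixed_layers],
                "multi_specs": [list(t) for t in self.multi_specs],
                "hidden_units": self.hidden_units,
                "dropout_rate": self.dropout_rate,
                "window": self.window,
                "variant": self.variant,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        d["fixed_layers"] = tuple(tuple(t) for t in d["fixed_layers"])
        d["multi_specs"] = tuple(tuple(t) for t in d["multi_specs"])
        return cls(**d)


@dataclass
class ModelParams:
    """Learned weights; shapes are determined by a :class:`ModelConfig`.

    ``fixed[0][0]`` has shape ``(F, h, C, A)`` — per-channel filter slices
    ``w_j`` live on axis 2. Deeper fixed and multi-size weights have shape
    ``(F, h, F_prev)``.
    """

    fixed: list[tuple[np.ndarray, np.ndarray]]
    multi: list[tuple[np.ndarray, np.ndarray]]
    Wh: np.ndarray
    bh: np.ndarray
    Wo: np.ndarray
    bo: np.ndarray
    seed: int = 0

    def flat(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for W, b in self.fixed:
            out += [W, b]
        for W, b in self.multi:
            out += [W, b]
        out += [self.Wh, self.bh, self.Wo, self.bo]
        return out

    def n_parameters(self) -> int:
        return int(sum(a.size for a in self.flat()))


def init_model(config: ModelConfig, seed: int = 0) -> ModelParams:
    """He-normal initialization, reproducible given the seed."""
    rng = np.random.default_rng(seed)
    C, A = config.input_channels, config.input_alphabet
    branch = config.variant == "three_branch"

    def he(shape, fan_in):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(
            np.float64
        )

    fixed = []
    prev = C * A if not branch else A
    for li, (F, h) in enumerate(config.fixed_geometry):
        if li == 0:
            W = he((F, h, C, A), h * (A if branch else C * A))
        else:
            W = he((F, h, prev), h * prev)
        fixed.append((W, np.zeros(F)))
        prev = F
    multi = []
    for h, F in config.multi_geometry:
        d = prev if config.fixed_layers else (A if branch else C * A)
        multi.append((he((F, h, d), h * d), np.zeros(F)))
    nf = config.n_pooled_features
    Wh = he((config.hidden_units, nf), nf)
    Wo = he((config.n_classes, config.hidden_units), config.hidden_units)
    return ModelParams(
        fixed, multi, Wh, np.zeros(config.hidden_units),
        Wo, np.zeros(config.n_classes), seed=seed,
    )


def conv_feature(
    arr: np.ndarray, filt: np.ndarray, bias: float
) -> np.ndarray:
    """Feature map of one first-layer filter over a 3-frame tensor.

    ``c_i = ReLU( sum_j <w_j, arr[j, i:i+h-1, :]> + b )`` for every window
    ``i``; ``filt`` holds the three ``h x 21`` matrices ``w_j``.
    """
    C, n, A = arr.shape
    h = filt.shape[1]
    if filt.shape != (C, h, A):
        raise ValueError("filter shape must be (3, h, 21)")
    if h > n:
        raise ValueError("filter size exceeds the input window")
    win = _windows(arr.transpose(1, 0, 2).reshape(n, C * A)[None], h)
    c = win[0] @ filt.transpose(1, 0, 2).reshape(h * C * A) + bias
    return np.maximum(c, 0.0)


# --- forward / backward machinery ----------------------------------------


def _windows(x: np.ndarray, h: int) -> np.ndarray:
    """im2col: (B, n, D) -> (B, n-h+1, h*D) sliding windows (copies)."""
    v = np.lib.stride_tricks.sliding_window_view(x, h, axis=1)
    # v: (B, P, D, h) -> (B, P, h, D) -> flat
    B, P, D, _ = v.shape
    return np.ascontiguousarray(v.transpose(0, 1, 3, 2)).reshape(B, P, h * D)


def _stack_forward(x, valid, fixed_w, multi_w):
    """Conv stack + pooled features for one branch.

    x: (B, n, D) input; valid: (B,) valid row counts. Returns
    (pooled (B, nf), cache).
    """
    cache = {"fixed": [], "multi": []}
    cur, v = x, valid
    for W, b in fixed_w:
        F, h = W.shape[0], W.shape[1]
        Wf = W.reshape(F, -1)
        win = _windows(cur, h)
        z = win @ Wf.T + b
        v = np.maximum(v - h + 1, 0)
        P = z.shape[1]
        mask = np.arange(P)[None, :] < v[:, None]  # (B, P)
        a = np.maximum(z, 0.0) * mask[:, :, None]
        cache["fixed"].append((win, z, mask, W.shape))
        cur = a
    pooled_parts = []
    for W, b in multi_w:
        F, h = W.shape[0], W.shape[1]
        Wf = W.reshape(F, -1)
        vm = v - h + 1
        if np.any(vm < 1):
            raise ShortReadError(
                "input shorter than the largest filter span"
            )
        win = _windows(cur, h)
        z = win @ Wf.T + b
        P = z.shape[1]
        mask = np.arange(P)[None, :] < vm[:, None]
        r = np.maximum(z, 0.0)
        r_masked = np.where(mask[:, :, None], r, -np.inf)
        am = np.argmax(r_masked, axis=1)  # (B, F)
        pooled = np.take_along_axis(r_masked, am[:, None, :], axis=1)[:, 0, :]
        cache["multi"].append((win, z, mask, am, W.shape))
        pooled_parts.append(pooled)
    return np.concatenate(pooled_parts, axis=1), cache


def softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=-1, keepdims=True)


def forward(
    params: ModelParams,
    config: ModelConfig,
    batch: np.ndarray,
    lengths: np.ndarray,
    train: bool = False,
    dropout_rng: np.random.Generator | None = None,
    return_cache: bool = False,
):
    """Class-probability vectors for a batch of encoded inputs.

    batch: (B, C, n, A); lengths: (B,) valid position counts. In eval mode
    (train=False) dropout is disabled and the output is deterministic.
    Raises :class:`ShortReadError` if any input is shorter than the largest
    filter span.
    """
    B, C, n, A = batch.shape
    if (C, n, A) != (
        config.input_channels,
        config.input_positions,
        config.input_alphabet,
    ):
        raise ValueError(
            f"batch shape {(C, n, A)} does not match config "
            f"{(config.input_channels, config.input_positions, config.input_alphabet)}"
        )
    lengths = np.asarray(lengths, dtype=np.int64)
    branches = []
    if config.variant == "three_branch":
        W1, b1 = params.fixed[0]
        for j in range(3):
            fixed_w = [(W1[:, :, j, :], b1)] + params.fixed[1:]
            x = batch[:, j, :, :].astype(np.float64)
            branches.append((x, fixed_w))
    else:
        W1, b1 = params.fixed[0] if params.fixed else (None, None)
        fixed_w = []
        if params.fixed:
            F, h = W1.shape[0], W1.shape[1]
            fixed_w = [(W1.reshape(F, h, -1), b1)] + params.fixed[1:]
        x = (
            batch.transpose(0, 2, 1, 3)
            .reshape(B, n, C * A)
            .astype(np.float64)
        )
        branches.append((x, fixed_w))

    feats = []
    caches = []
    for x, fixed_w in branches:
        pooled, cache = _stack_forward(x, lengths, fixed_w, params.multi)
        feats.append(pooled)
        caches.append(cache)
    feat = np.concatenate(feats, axis=1)

    if train and config.dropout_rate > 0:
        if dropout_rng is None:
            raise ValueError("dropout in train mode requires an RNG")
        keep = 1.0 - config.dropout_rate
        dmask = (dropout_rng.random(feat.shape) < keep) / keep
        feat_d = feat * dmask
    else:
        dmask = None
        feat_d = feat

    zh = feat_d @ params.Wh.T + params.bh
    hdn = np.maximum(zh, 0.0)
    logits = hdn @ params.Wo.T + params.bo
    probs = softmax(logits)
    if not return_cache:
        return probs
    cache = {
        "branches": caches,
        "feat": feat,
        "feat_d": feat_d,
        "dmask": dmask,
        "zh": zh,
        "hdn": hdn,
        "logits": logits,
        "probs": probs,
        "lengths": lengths,
    }
    return probs, cache


def zero_grads(params: ModelParams):
    gfixed = [[np.zeros_like(W), np.zeros_like(b)] for W, b in params.fixed]
    gmulti = [[np.zeros_like(W), np.zeros_like(b)] for W, b in params.multi]
    return {
        "fixed": gfixed,
        "multi": gmulti,
        "Wh": np.zeros_like(params.Wh),
        "bh": np.zeros_like(params.bh),
        "Wo": np.zeros_like(params.Wo),
        "bo": np.zeros_like(params.bo),
    }


def backward(
    params: ModelParams,
    config: ModelConfig,
    cache: dict,
    dlogits: np.ndarray,
    grads: dict,
) -> None:
    """Accumulate parameter gradients for d(loss)/d(logits) = dlogits."""
    hdn, feat_d = cache["hdn"], cache["feat_d"]
    grads["Wo"] += dlogits.T @ hdn
    grads["bo"] += dlogits.sum(axis=0)
    dh = dlogits @ params.Wo
    dzh = dh * (cache["zh"] > 0)
    grads["Wh"] += dzh.T @ feat_d
    grads["bh"] += dzh.sum(axis=0)
    dfeat = dzh @ params.Wh
    if cache["dmask"] is not None:
        dfeat = dfeat * cache["dmask"]

    n_branch = len(cache["branches"])
    per = dfeat.shape[1] // n_branch
    for bi, bcache in enumerate(cache["branches"]):
        dpooled = dfeat[:, bi * per : (bi + 1) * per]
        _branch_backward(params, config, bi, bcache, dpooled, grads)


def _branch_backward(params, config, branch_i, cache, dpooled, grads):
    # multi-size layer
    da = None
    off = 0
    for mi, (W, b) in enumerate(params.multi):
        win, z, mask, am, Wshape = cache["multi"][mi]
        F, h = Wshape[0], Wshape[1]
        dp = dpooled[:, off : off + F]
        off += F
        B, P, _ = z.shape
        dz = np.zeros_like(z)
        zsel = np.take_along_axis(z, am[:, None, :], axis=1)[:, 0, :]
        contrib = dp * (zsel > 0)
        np.put_along_axis(dz, am[:, None, :], contrib[:, None, :], axis=1)
        dz *= mask[:, :, None]
        Wf = W.reshape(F, -1)
        grads["multi"][mi][0] += np.einsum("bpf,bpd->fd", dz, win).reshape(
            Wshape
        )
        grads["multi"][mi][1] += dz.sum(axis=(0, 1))
        if params.fixed:
            dwin = dz @ Wf
            D = Wshape[2]
            if da is None:
                da = np.zeros((B, P + h - 1, D))
            elif da.shape[1] < P + h - 1:  # mixed sizes: align to widest map
                pad = np.zeros((B, P + h - 1, D))
                pad[:, : da.shape[1], :] = da
                da = pad
            dw4 = dwin.reshape(B, P, h, D)
            for o in range(h):
                da[:, o : o + P, :] += dw4[:, :, o, :]

    # fixed stack, deepest first
    for li in range(len(params.fixed) - 1, -1, -1):
        win, z, mask, Wshape = cache["fixed"][li]
        dz = da * (z > 0) * mask[:, :, None]
        F, h = Wshape[0], Wshape[1]
        if li == 0 and config.variant == "three_branch":
            W, b = params.fixed[0]
            Wf = W[:, :, branch_i, :].reshape(F, -1)
            gW = np.einsum("bpf,bpd->fd", dz, win)
            grads["fixed"][0][0][:, :, branch_i, :] += gW.reshape(
                F, h, Wshape[2]
            )
        else:
            W, b = params.fixed[li]
            Wf = W.reshape(F, -1)
            gW = np.einsum("bpf,bpd->fd", dz, win)
            grads["fixed"][li][0] += gW.reshape(grads["fixed"][li][0].shape)
        grads["fixed"][li][1] += dz.sum(axis=(0, 1))
        if li > 0:
            B, P, _ = z.shape
            D = win.shape[2] // h
            dwin = dz @ Wf
            da = np.zeros((B, P + h - 1, D))
            dw4 = dwin.reshape(B, P, h, D)
            for o in range(h):
                da[:, o : o + P, :] += dw4[:, :, o, :]


def apply_grads_sgd(params: ModelParams, grads: dict, lr: float) -> None:
    """Plain SGD step (used by gradient-check tests)."""
    for (W, b), (gW, gb) in zip(params.fixed, grads["fixed"]):
        W -= lr * gW
        b -= lr * gb
    for (W, b), (gW, gb) in zip(params.multi, grads["multi"]):
        W -= lr * gW
        b -= lr * gb
    params.Wh -= lr * grads["Wh"]
    params.bh -= lr * grads["bh"]
    params.Wo -= lr * grads["Wo"]
    params.bo -= lr * grads["bo"]
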