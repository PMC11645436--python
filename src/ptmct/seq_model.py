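"""Sequence-based crosstalk classifier.

Two 11-residue embedding windows centred on the PTM sites are fused by a
two-layer cross-attention network (five heads, scale d = 256, residual +
layer norm per layer); the centre vector of the fused representation is
concatenated with the attention-map pair feature and classified by an
affine → batch-norm → leaky-ReLU → affine head with a 2-way softmax.

The N-terminal site always provides the query stream; the formulas are
asymmetric in the two sites and the canonical pair order makes the output
deterministic (users may average both orders if symmetry is wanted).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, BatchNorm, Tensor, as_tensor, parameter

WINDOW = 11
HALF = WINDOW // 2


@dataclass
class SeqTrainConfig:
    learning_rate: float = 1e-5
    max_epochs: int = 100
    patience: int = 5
    batch_size: int = 32
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


def build_window(emb, position: int) -> np.ndarray:
    """11 × D_e window of residue embeddings centred on ``position``
    (1-based); out-of-range rows are zero."""
    values = emb.values if hasattr(emb, "values") else np.asarray(emb)
    L, D = values.shape
    if not 1 <= position <= L:
        raise ValueError(f"position {position} outside [1, {L}]")
    out = np.zeros((WINDOW, D))
    for k, p in enumerate(range(position - HALF, position + HALF + 1)):
        if 1 <= p <= L:
            out[k] = values[p - 1]
    return out


class CrossAttentionLayer:
    """One cross-attention layer: multi-head attention of H on X_other,
    output projection, residual connection, layer normalisation."""

    def __init__(self, D_e: int, n_heads: int, d: int, rng):
        def init(*shape):
            return parameter(rng.standard_normal(shape) / np.sqrt(shape[0]))
        self.n_heads, self.d, self.D_e = n_heads, d, D_e
        self.W_Q = init(D_e, n_heads * d)
        self.W_K = init(D_e, n_heads * d)
        self.W_V = init(D_e, n_heads * d)
        self.b_Q = parameter(np.zeros(n_heads * d))
        self.b_K = parameter(np.zeros(n_heads * d))
        self.b_V = parameter(np.zeros(n_heads * d))
        self.W_O = init(n_heads * d, D_e)
        self.b_O = parameter(np.zeros(D_e))
        self.ln_gain = parameter(np.ones(D_e))
        self.ln_bias = parameter(np.zeros(D_e))

    def parameters(self):
        return [self.W_Q, self.W_K, self.W_V, self.b_Q, self.b_K, self.b_V,
                self.W_O, self.b_O, self.ln_gain, self.ln_bias]

    def __call__(self, h_prev: Tensor, x_other: Tensor) -> Tensor:
        B, W, D = h_prev.shape
        H, d = self.n_heads, self.d

        def split_heads(t):
            return t.reshape(B, W, H, d).swapaxes(1, 2)     # (B, H, W, d)

        q = split_heads(h_prev @ self.W_Q + self.b_Q)
        k = split_heads(x_other @ self.W_K + self.b_K)
        v = split_heads(x_other @ self.W_V + self.b_V)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d))
        attn = ad.softmax(scores, axis=-1)
        heads = (attn @ v).swapaxes(1, 2).reshape(B, W, H * d)
        f = heads @ self.W_O + self.b_O
        return ad.layer_norm(f + h_prev, self.ln_gain, self.ln_bias)


def cross_attention_layer(h_prev: np.ndarray, x_other: np.ndarray,
                          layer: CrossAttentionLayer) -> np.ndarray:
    """Functional single-sample wrapper used by the oracle tests."""
    h = as_tensor(h_prev[None])
    x = as_tensor(x_other[None])
    if h.shape[-1] != layer.D_e or x.shape[-1] != layer.D_e:
        raise ValueError("window width does not match layer dimensions")
    return layer(h, x).data[0]


class SeqModel:
    """Cross-attention sequence classifier (window pair + pair feature)."""

    def __init__(self, D_e: int, pair_dim: int, n_heads: int = 5,
                 d: int = 256, hidden: int = 128, n_layers: int = 2,
                 seed: int = 0, layout_hash: str = ""):
        rng = np.random.default_rng(seed)
        self.D_e, self.pair_dim = D_e, pair_dim
        self.n_heads, self.d, self.hidden = n_heads, d, hidden
        self.layout_hash = layout_hash
        self.layers = [CrossAttentionLayer(D_e, n_heads, d, rng)
                       for _ in range(n_layers)]
        in_dim = D_e + pair_dim
        self.W1 = parameter(rng.standard_normal((in_dim, hidden))
                            / np.sqrt(in_dim))
        self.b1 = parameter(np.zeros(hidden))
        self.bn = BatchNorm(hidden)
        self.W2 = parameter(rng.standard_normal((hidden, 2)) / np.sqrt(hidden))
        self.b2 = parameter(np.zeros(2))

    def parameters(self):
        out = []
        for layer in self.layers:
            out += layer.parameters()
        return out + [self.W1, self.b1, self.W2, self.b2] \
            + self.bn.parameters()

    def forward(self, xi: np.ndarray, xj: np.ndarray, xij: np.ndarray,
                training: bool = False) -> Tensor:
        """(B, 11, D_e) windows + (B, pair_dim) pair features -> (B, 2)
        class probabilities (rows sum to one)."""
        if xi.shape[-1] != self.D_e or xij.shape[-1] != self.pair_dim:
            raise ValueError("input dimensions do not match the model")
        h = as_tensor(xi)
        x_other = as_tensor(xj)
        for layer in self.layers:
            h = layer(h, x_other)
        h1 = h[:, HALF, :]                      # centre row (1-based row 6)
        h2 = ad.concat([h1, as_tensor(xij)], axis=-1)
        z = self.bn(h2 @ self.W1 + self.b1, training=training)
        logits = z.leaky_relu(0.01) @ self.W2 + self.b2
        return ad.softmax(logits, axis=-1)

    def predict_proba(self, xi, xj, xij) -> np.ndarray:
        """Positive-class probability for each sample."""
        return self.forward(np.asarray(xi), np.asarray(xj),
                            np.asarray(xij)).data[:, 1]

    # -- persistence --------------------------------------------------------
    def state(self) -> dict:
        arrays = {f"p{k}": p.data for k, p in enumerate(self.parameters())}
        arrays["running_mean"] = self.bn.running_mean
        arrays["running_var"] = self.bn.running_var
        return arrays

    def save(self, path) -> None:
        meta = dict(D_e=self.D_e, pair_dim=self.pair_dim,
                    n_heads=self.n_heads, d=self.d, hidden=self.hidden,
                    n_layers=len(self.layers), layout_hash=self.layout_hash)
        np.savez(path, __meta__=json.dumps(meta), **self.state())

    @classmethod
    def load(cls, path, expected_layout_hash: str | None = None) -> "SeqModel":
        blob = np.load(path, allow_pickle=False)
        meta = json.loads(str(blob["__meta__"]))
        if (expected_layout_hash is not None
                and meta["layout_hash"] != expected_layout_hash):
            raise ValueError("model was trained against a different "
                             "embedding layout")
        model = cls(meta["D_e"], meta["pair_dim"], meta["n_heads"],
                    meta["d"], meta["hidden"], meta["n_layers"],
                    layout_hash=meta["layout_hash"])
        for k, p in enumerate(model.parameters()):
            p.data = blob[f"p{k}"]
        model.bn.running_mean = blob["running_mean"]
        model.bn.running_var = blob["running_var"]
        return model


def seq_forward(model: SeqModel, xi: np.ndarray, xj: np.ndarray,
                xij: np.ndarray) -> np.ndarray:
    """Single-pair forward pass: returns the (P_neg, P_pos) probability pair."""
    return model.forward(xi[None], xj[None], np.asarray(xij)[None]).data[0]


def _aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import average_precision_score
    return float(average_precision_score(labels, scores))


def train_seq(xi: np.ndarray, xj: np.ndarray, xij: np.ndarray,
              labels: np.ndarray, config: SeqTrainConfig | None = None,
              model: SeqModel | None = None):
    """Train the sequence classifier with Adam on cross-entropy.

    A stratified 10% split is held out and monitored by AUPR; training stops
    after ``patience`` epochs without improvement and the best parameters
    are restored. Returns ``(model, log)`` with per-epoch losses.
    """
    config = config or SeqTrainConfig()
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(config.seed)
    if model is None:
        model = SeqModel(D_e=xi.shape[-1], pair_dim=xij.shape[-1],
                         seed=config.seed)

    n = len(labels)
    idx = np.arange(n)
    val_idx = []
    for cls in (0, 1):
        members = idx[labels == cls]
        members = rng.permutation(members)
        take = max(1, int(round(config.val_fraction * len(members))))
        val_idx.extend(members[:take])
    val_idx = np.array(sorted(val_idx))
    train_idx = np.setdiff1d(idx, val_idx)

    opt = Adam(model.parameters(), lr=config.learning_rate)
    log = {"train_loss": [], "val_aupr": []}
    best = (-np.inf, None, None)
    bad_epochs = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            if len(batch) < 2:
                continue        # batch norm needs > 1 sample
            probs = model.forward(xi[batch], xj[batch], xij[batch],
                                  training=True)
            eps = 1e-12
            picked = probs[np.arange(len(batch)), labels[batch]]
            loss = -(picked + eps).log().mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        scores = model.predict_proba(xi[val_idx], xj[val_idx], xij[val_idx])
        aupr = _aupr(scores, labels[val_idx])
        log["train_loss"].append(float(np.mean(losses)))
        log["val_aupr"].append(aupr)
        if aupr > best[0] + 1e-6:
            best = (aupr, [p.data.copy() for p in model.parameters()],
                    (model.bn.running_mean.copy(),
                     model.bn.running_var.copy()))
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    if best[1] is not None:
        for p, data in zip(model.parameters(), best[1]):
            p.data = data
        model.bn.running_mean, model.bn.running_var = best[2]
    return model, log
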