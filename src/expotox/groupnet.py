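"""GroupNet: a group-convolution CNN over exam-feature vectors.

The normalized feature vector of each examination record is laid out in its
column order as a 1-D signal, split into ``n_groups`` uniform segments
(groups), and each group is convolved independently by a stack of 1-D
convolutional units (8 kernels each, same padding, ReLU).  A 1x1 "clustered"
convolution (12 kernels) then fuses the concatenated group channels, followed
by max-pooling, dropout, a 372-unit fully connected layer and a softmax
output p_i = exp(Z_i) / sum_j exp(Z_j).

Splitting the channels into groups makes the convolutional trunk sparse: a
grouped layer holds 1/n_groups of the parameters of the dense convolution
that would mix all channels (see :func:`conv_param_counts`).

Two label reductions are supported: Label-Powerset (a single softmax over
observed label combinations) and Binary-Relevance (per-label 2-way heads
sharing the trunk), the latter optionally trained under the association loss
CL = loss_anchor + sum_i alpha_i loss_i with alpha the training-set Pearson
correlations between labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._nn import (Adam, Dense, Dropout, Flatten, GroupedConv1d, MaxPool1d,
                  ReLU, cross_entropy, softmax, softmax_ce_grad)
from .prep import AssociationLossSpec


@dataclass
class GroupNetConfig:
    """Architecture and training hyperparameters.

    Defaults follow the reference configuration: 8 kernels per convolutional
    unit, a single 1x1 clustered layer with 12 kernels, dropout 0.5, a
    372-neuron fully connected layer, learning rate 0.02, batch size 128 and
    20 training epochs.
    """

    n_groups: int = 4
    kernels_per_unit: int = 8
    conv_layers_per_group: int = 2
    kernel_size: int = 3
    clustered_kernels: int = 12
    pool_size: int = 2
    dropout_rate: float = 0.5
    fc_units: int = 372
    n_classes: int | None = None
    learning_rate: float = 0.02
    batch_size: int = 128
    epochs: int = 20
    seed: int = 0
    zero_init_head: bool = False

    def __post_init__(self):
        if self.n_groups < 1 or self.kernel_size % 2 != 1:
            raise ValueError("n_groups must be >= 1 and kernel_size odd")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


def conv_param_counts(cfg: GroupNetConfig) -> tuple[int, int]:
    """Parameter counts (weights + biases) of the group-module convolutions,
    grouped vs the dense convolution mixing all channels at each layer.

    The input signal is viewed as ``n_groups`` channels; the grouped trunk
    convolves each in isolation while the dense equivalent would mix them
    all, multiplying the weight count by ``n_groups``.
    """
    g, u, k = cfg.n_groups, cfg.kernels_per_unit, cfg.kernel_size
    grouped = dense = 0
    c_in = 1
    for _ in range(cfg.conv_layers_per_group):
        grouped += g * (u * c_in * k + u)
        dense += (u * g) * (c_in * g) * k + u * g
        c_in = u
    return grouped, dense


class _Network:
    """The assembled layer stack; owns parameters and the forward/backward
    passes including the group<->flat channel reshapes."""

    def __init__(self, n_features: int, heads: list[int],
                 cfg: GroupNetConfig, rng):
        g = cfg.n_groups
        self.seg = -(-n_features // g)          # ceil: segment length
        self.n_features = n_features
        self.cfg = cfg
        u = cfg.kernels_per_unit
        self.group_layers = []
        c_in = 1
        for _ in range(cfg.conv_layers_per_group):
            self.group_layers += [
                GroupedConv1d(g, c_in, u, cfg.kernel_size, rng), ReLU()]
            c_in = u
        self.cluster_layers = [
            GroupedConv1d(1, u * g, cfg.clustered_kernels, 1, rng), ReLU()]
        self.pool = MaxPool1d(cfg.pool_size)
        self.drop = Dropout(cfg.dropout_rate)
        self.flat = Flatten()
        flat_dim = cfg.clustered_kernels * (self.seg // cfg.pool_size)
        self.fc = Dense(flat_dim, cfg.fc_units, rng)
        self.fc_act = ReLU()
        self.heads = [Dense(cfg.fc_units, h, rng,
                            zero_init=cfg.zero_init_head) for h in heads]
        self.layers = (self.group_layers + self.cluster_layers
                       + [self.pool, self.drop, self.flat, self.fc,
                          self.fc_act] + self.heads)

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [gr for l in self.layers for gr in l.grads]

    def trunk_forward(self, X: np.ndarray, train: bool, rng) -> np.ndarray:
        B = X.shape[0]
        g, u = self.cfg.n_groups, self.cfg.kernels_per_unit
        pad = g * self.seg - self.n_features
        Xp = np.pad(X, ((0, 0), (0, pad))) if pad else X
        x = Xp.reshape(B, g, 1, self.seg)
        for l in self.group_layers:
            x = l.forward(x, train, rng)
        x = x.reshape(B, 1, g * u, self.seg)
        for l in self.cluster_layers:
            x = l.forward(x, train, rng)
        x = x[:, 0]                              # (B, clustered, seg)
        x = self.pool.forward(x, train, rng)
        x = self.drop.forward(x, train, rng)
        x = self.flat.forward(x, train, rng)
        x = self.fc.forward(x, train, rng)
        return self.fc_act.forward(x, train, rng)

    def trunk_backward(self, dh: np.ndarray) -> None:
        g, u = self.cfg.n_groups, self.cfg.kernels_per_unit
        d = self.fc_act.backward(dh)
        d = self.fc.backward(d)
        d = self.flat.backward(d)
        d = self.drop.backward(d)
        d = self.pool.backward(d)
        d = d[:, None]                           # restore group axis
        for l in reversed(self.cluster_layers):
            d = l.backward(d)
        d = d.reshape(d.shape[0], g, u, self.seg)
        for l in reversed(self.group_layers):
            d = l.backward(d)


@dataclass
class GroupNetResults:
    """Trained GroupNet: weights, training history, prediction interface."""

    model: "GroupNetClassifier"
    history: pd.DataFrame

    def predict_proba(self, X) -> np.ndarray | list[np.ndarray]:
        return self.model._proba(np.asarray(X, dtype=float))

    def predict(self, X):
        return self.model._predict(np.asarray(X, dtype=float))

    def summary(self) -> str:
        m = self.model
        grouped, dense = conv_param_counts(m.config)
        lines = [
            f"GroupNet ({m.mode.upper()} mode)",
            f"  features: {m.n_features}   groups: {m.config.n_groups}   "
            f"heads: {[h.W.shape[0] for h in m.net.heads]}",
            f"  group-module conv parameters: {grouped} "
            f"(dense equivalent would use {dense})",
            f"  epochs: {len(self.history)}   "
            f"final train loss: {self.history['loss'].iloc[-1]:.4f}",
        ]
        if "val_accuracy" in self.history:
            lines.append(
                f"  final val accuracy: "
                f"{self.history['val_accuracy'].iloc[-1]:.4f}")
        return "\n".join(lines)


class GroupNetClassifier:
    """Model object: built from a feature matrix and labels, ``fit`` trains
    the network with Adam and returns :class:`GroupNetResults`.

    Parameters
    ----------
    X : array (n, F)
        Normalized feature vectors (column order defines the 1-D layout).
    y : array
        LP mode: integer class per record.  BR mode: (n, l) binary matrix.
    mode : 'lp' or 'br'
    loss_spec : AssociationLossSpec, 'sum', or int
        BR-mode loss.  An :class:`AssociationLossSpec` trains under
        CL = loss_anchor + sum alpha_i loss_i; ``'sum'`` (default) sums the
        per-head cross-entropies; an integer trains on that head's plain
        cross-entropy alone.
    """

    def __init__(self, X, y, mode: str = "lp",
                 config: GroupNetConfig | None = None,
                 loss_spec: AssociationLossSpec | str | int = "sum"):
        if mode not in ("lp", "br"):
            raise ValueError("mode must be 'lp' or 'br'")
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or len(self.X) == 0:
            raise ValueError("X must be a non-empty (n, F) matrix")
        self.mode = mode
        self.n_features = self.X.shape[1]
        self.loss_spec = loss_spec
        if mode == "lp":
            self.y = np.asarray(y, dtype=int).ravel()
            n_classes = (config.n_classes if config and config.n_classes
                         else int(self.y.max()) + 1)
            self.head_sizes = [n_classes]
        else:
            self.y = np.asarray(y, dtype=int)
            if self.y.ndim != 2:
                raise ValueError("BR mode requires an (n, l) label matrix")
            self.head_sizes = [2] * self.y.shape[1]
        self.config = config or GroupNetConfig()
        self.net: _Network | None = None

    # -- inference ---------------------------------------------------------

    def _proba(self, X):
        if self.net is None:
            raise RuntimeError("model is not trained; call fit() first")
        h = self.net.trunk_forward(X, train=False, rng=None)
        probs = [softmax(head.forward(h)) for head in self.net.heads]
        return probs[0] if self.mode == "lp" else probs

    def _predict(self, X):
        probs = self._proba(X)
        if self.mode == "lp":
            return probs.argmax(axis=1)
        return np.column_stack([(p[:, 1] >= 0.5).astype(int) for p in probs])

    # -- training ----------------------------------------------------------

    def _loss_coefficients(self) -> np.ndarray:
        l = len(self.head_sizes)
        if isinstance(self.loss_spec, AssociationLossSpec):
            if len(self.loss_spec.alpha) != l:
                raise ValueError("loss spec length does not match label count")
            return self.loss_spec.coefficients()
        if self.loss_spec == "sum":
            return np.ones(l)
        raise TypeError("loss_spec must be AssociationLossSpec, 'sum' or int")

    def fit(self, X_val=None, y_val=None, epochs: int | None = None
            ) -> GroupNetResults:
        cfg = self.config
        epochs = epochs if epochs is not None else cfg.epochs
        rng = np.random.default_rng(cfg.seed)
        self.net = _Network(self.n_features, self.head_sizes, cfg, rng)
        opt = Adam(self.net.params, self.net.grads, lr=cfg.learning_rate)
        anchor_only = (self.loss_spec if isinstance(self.loss_spec, int)
                       and not isinstance(self.loss_spec, bool) else None)
        coef = None if anchor_only is not None else self._loss_coefficients()
        n = len(self.X)
        rows = []
        for epoch in range(epochs):
            order = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                h = self.net.trunk_forward(self.X[idx], train=True, rng=rng)
                if self.mode == "lp":
                    probs = softmax(self.net.heads[0].forward(h))
                    loss = cross_entropy(probs, self.y[idx])
                    dh = self.net.heads[0].backward(
                        softmax_ce_grad(probs, self.y[idx]))
                elif anchor_only is not None:
                    head = self.net.heads[anchor_only]
                    probs = softmax(head.forward(h))
                    loss = cross_entropy(probs, self.y[idx, anchor_only])
                    dh = head.backward(
                        softmax_ce_grad(probs, self.y[idx, anchor_only]))
                else:
                    loss = 0.0
                    dh = np.zeros_like(h)
                    for j, head in enumerate(self.net.heads):
                        probs = softmax(head.forward(h))
                        loss += coef[j] * cross_entropy(probs, self.y[idx, j])
                        dh += head.backward(
                            coef[j] * softmax_ce_grad(probs, self.y[idx, j]))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}; lower the "
                        "learning rate or check the input scaling")
                self.net.trunk_backward(dh)
                opt.step()
                epoch_loss += loss
                n_batches += 1
            row = {"epoch": epoch + 1, "loss": epoch_loss / n_batches}
            if X_val is not None:
                row["val_accuracy"] = self.score(X_val, y_val)
            rows.append(row)
        return GroupNetResults(model=self, history=pd.DataFrame(rows))

    def score(self, X, y) -> float:
        """LP: classification accuracy; BR: mean per-label accuracy."""
        pred = self._predict(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=int)
        if self.mode == "lp":
            return float((pred == y.ravel()).mean())
        return float((pred == y).mean())
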