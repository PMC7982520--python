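"""From-scratch LSTM sequence classifier with hand-derived backpropagation.

A single LSTM cell follows the classic gate equations, all acting on the
concatenation ``z_t = [h_{t-1}, I_t]`` of the previous hidden state and the
current input:

    f_t = sigmoid(W_f . z_t + b_f)          (forget gate)
    U_t = sigmoid(W_U . z_t + b_U)          (update gate)
    cbar_t = tanh(W_c . z_t + b_c)          (candidate value)
    C_t = f_t * C_{t-1} + U_t * cbar_t      (memory cell, * = Hadamard)
    O_t = sigmoid(W_o . z_t + b_o)          (output gate)
    h_t = O_t * tanh(C_t)

with ``h_0 = C_0 = 0``.  Networks are stacks of LSTM (sequence-to-label or
sequence-to-sequence), dropout (inverted scaling, identity at evaluation),
fully connected, tanh, and a softmax + cross-entropy classification head,
trained by stochastic gradient descent with momentum (SGDM):

    v <- momentum * v - lr * grad;  theta <- theta + v

Gradients for every weight and bias come from backpropagation through time
and are validated against central finite differences in the test suite -
that agreement, not any particular derivation, is the binding contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LSTMParams",
    "LSTMState",
    "NetworkConfig",
    "TrainConfig",
    "Network",
    "lstm_forward",
    "recurrent_config",
    "deep_lstm_config",
    "bp_config",
    "init_network",
    "network_forward",
    "loss_and_gradients",
    "train",
    "predict",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# Single-cell API
# ---------------------------------------------------------------------------

@dataclass
class LSTMParams:
    """Weights/biases of one LSTM cell; each W acts on [h_{t-1}, I_t]."""

    W_f: np.ndarray
    W_c: np.ndarray
    W_U: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_c: np.ndarray
    b_U: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        H = self.b_f.shape[0]
        for name in ("W_f", "W_c", "W_U", "W_o"):
            W = getattr(self, name)
            if W.shape[0] != H:
                raise ValueError(f"{name} rows ({W.shape[0]}) != hidden size ({H})")
            if W.shape[1] <= H:
                raise ValueError(f"{name} must act on [h, I]; needs > {H} columns")
        for name in ("b_c", "b_U", "b_o"):
            if getattr(self, name).shape != (H,):
                raise ValueError(f"{name} has wrong shape")

    @property
    def hidden_size(self) -> int:
        return self.b_f.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_f.shape[1] - self.hidden_size


@dataclass
class LSTMState:
    """Per-timestep gate/cell/hidden trajectories, each (T, H)."""

    f: np.ndarray
    U: np.ndarray
    O: np.ndarray
    cbar: np.ndarray
    C: np.ndarray
    h: np.ndarray


def lstm_forward(params: LSTMParams, sequence: np.ndarray) -> LSTMState:
    """Run one sequence (steps x features) through the cell equations."""
    sequence = np.asarray(sequence, dtype=np.float64)
    if sequence.ndim != 2 or sequence.shape[1] != params.input_size:
        raise ValueError(
            f"sequence must be (steps, {params.input_size}), got {sequence.shape}"
        )
    T = sequence.shape[0]
    H = params.hidden_size
    out = {k: np.zeros((T, H)) for k in ("f", "U", "O", "cbar", "C", "h")}
    h = np.zeros(H)
    C = np.zeros(H)
    for t in range(T):
        z = np.concatenate([h, sequence[t]])
        f = _sigmoid(params.W_f @ z + params.b_f)
        cbar = np.tanh(params.W_c @ z + params.b_c)
        U = _sigmoid(params.W_U @ z + params.b_U)
        O = _sigmoid(params.W_o @ z + params.b_o)
        C = f * C + U * cbar
        h = O * np.tanh(C)
        for k, v in (("f", f), ("U", U), ("O", O), ("cbar", cbar), ("C", C), ("h", h)):
            out[k][t] = v
    return LSTMState(**out)


# ---------------------------------------------------------------------------
# Layer stack
# ---------------------------------------------------------------------------

_KNOWN_KINDS = {"lstm", "dropout", "fully_connected", "tanh", "softmax", "classification"}


@dataclass(frozen=True)
class NetworkConfig:
    """Ordered layer stack ending in softmax + classification.

    Each entry is ``(kind, options)`` with kind in {"lstm", "dropout",
    "fully_connected", "tanh", "softmax", "classification"}.  Sequence
    networks must collapse to a single vector exactly once, via one LSTM
    layer in ``sequence_to_label`` mode.
    """

    layers: tuple[tuple[str, dict], ...]

    def __post_init__(self) -> None:
        kinds = [k for k, _ in self.layers]
        unknown = set(kinds) - _KNOWN_KINDS
        if unknown:
            raise ValueError(f"unknown layer kind(s): {sorted(unknown)}")
        if kinds[-2:] != ["softmax", "classification"]:
            raise ValueError("network must end with softmax + classification")
        lstm_modes = [o.get("mode", "sequence_to_label") for k, o in self.layers if k == "lstm"]
        if lstm_modes and lstm_modes.count("sequence_to_label") != 1:
            raise ValueError("exactly one LSTM layer must be sequence_to_label")

    @property
    def n_classes(self) -> int:
        return int(dict(self.layers)["classification"].get("n_classes", 2))


def recurrent_config(hidden: int = 80, dropout: float = 0.2, n_classes: int = 2) -> NetworkConfig:
    """LSTM(hidden, seq-to-label) -> dropout -> FC(n_classes) -> softmax."""
    return NetworkConfig(
        layers=(
            ("lstm", {"hidden": hidden, "mode": "sequence_to_label"}),
            ("dropout", {"rate": dropout}),
            ("fully_connected", {"units": n_classes}),
            ("softmax", {}),
            ("classification", {"n_classes": n_classes}),
        )
    )


def deep_lstm_config(
    front_hidden: int = 120, hidden: int = 80, dropout: float = 0.2, n_classes: int = 2
) -> NetworkConfig:
    """Sequence-to-sequence LSTM front-end feeding the standard classifier."""
    return NetworkConfig(
        layers=(
            ("lstm", {"hidden": front_hidden, "mode": "sequence_to_sequence"}),
            ("dropout", {"rate": dropout}),
            ("lstm", {"hidden": hidden, "mode": "sequence_to_label"}),
            ("dropout", {"rate": dropout}),
            ("fully_connected", {"units": n_classes}),
            ("softmax", {}),
            ("classification", {"n_classes": n_classes}),
        )
    )


def bp_config(hidden: tuple[int, ...] = (20, 10), n_classes: int = 2,
              output_units: int | None = None) -> NetworkConfig:
    """Plain feed-forward (back-propagation) classifier on flat features.

    ``output_units=1`` gives the literal single-unit head (a degenerate
    softmax); the default realizes the head with ``n_classes`` units so the
    softmax is informative.
    """
    layers: list[tuple[str, dict]] = []
    for h in hidden:
        layers += [("fully_connected", {"units": h}), ("tanh", {})]
    layers += [
        ("fully_connected", {"units": n_classes if output_units is None else output_units}),
        ("softmax", {}),
        ("classification", {"n_classes": n_classes}),
    ]
    return NetworkConfig(layers=tuple(layers))


@dataclass
class TrainConfig:
    """SGDM optimizer settings."""

    learning_rate: float = 0.001
    momentum: float = 0.9
    epochs: int = 20
    batch_size: int = 100
    shuffle: bool = True
    seed: int = 0
    val_every: int = 10

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")
        if not 0 <= self.learning_rate < 1:
            raise ValueError("learning rate must lie in [0, 1)")


# -- layer implementations --------------------------------------------------

class _LSTMLayer:
    def __init__(self, input_size: int, hidden: int, mode: str, rng: np.random.Generator):
        self.mode = mode
        self.H = hidden
        self.F = input_size
        lim = np.sqrt(6.0 / (hidden + input_size + hidden))
        self.params = {}
        for g in ("f", "c", "U", "o"):
            self.params[f"W_{g}"] = rng.uniform(-lim, lim, size=(hidden, hidden + input_size))
            self.params[f"b_{g}"] = np.zeros(hidden)
        self.out_size = hidden

    def as_lstm_params(self) -> LSTMParams:
        return LSTMParams(**{k: v for k, v in self.params.items()})

    def forward(self, X: np.ndarray, training: bool, rng) -> np.ndarray:
        # X: (B, T, F)
        B, T, _ = X.shape
        H = self.H
        p = self.params
        Wz = np.vstack([p["W_f"], p["W_c"], p["W_U"], p["W_o"]])        # (4H, H+F)
        bz = np.concatenate([p["b_f"], p["b_c"], p["b_U"], p["b_o"]])
        cache = {"X": X, "z": [], "f": [], "cbar": [], "U": [], "O": [],
                 "C": [], "tanhC": []}
        h = np.zeros((B, H))
        C = np.zeros((B, H))
        hs = np.empty((B, T, H))
        for t in range(T):
            z = np.concatenate([h, X[:, t, :]], axis=1)                 # (B, H+F)
            a = z @ Wz.T + bz
            f = _sigmoid(a[:, :H])
            cbar = np.tanh(a[:, H:2 * H])
            U = _sigmoid(a[:, 2 * H:3 * H])
            O = _sigmoid(a[:, 3 * H:])
            C_prev = C
            C = f * C_prev + U * cbar
            tanhC = np.tanh(C)
            h = O * tanhC
            hs[:, t, :] = h
            cache["z"].append(z)
            cache["f"].append(f)
            cache["cbar"].append(cbar)
            cache["U"].append(U)
            cache["O"].append(O)
            cache["C"].append(C_prev)
            cache["tanhC"].append(tanhC)
        self._cache = cache
        return hs[:, -1, :] if self.mode == "sequence_to_label" else hs

    def backward(self, dout: np.ndarray):
        c = self._cache
        X = c["X"]
        B, T, F = X.shape
        H = self.H
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dX = np.zeros_like(X)
        dh_next = np.zeros((B, H))
        dC_next = np.zeros((B, H))
        if self.mode == "sequence_to_label":
            seq_grad = None
            dh_next = dout.copy()
        else:
            seq_grad = dout
        for t in reversed(range(T)):
            dh = dh_next
            if seq_grad is not None:
                dh = dh + seq_grad[:, t, :]
            f, cbar, U, O = c["f"][t], c["cbar"][t], c["U"][t], c["O"][t]
            C_prev, tanhC, z = c["C"][t], c["tanhC"][t], c["z"][t]
            dO = dh * tanhC
            dC = dC_next + dh * O * (1.0 - tanhC ** 2)
            df = dC * C_prev
            dU = dC * cbar
            dcbar = dC * U
            dC_next = dC * f
            da_f = df * f * (1.0 - f)
            da_c = dcbar * (1.0 - cbar ** 2)
            da_U = dU * U * (1.0 - U)
            da_o = dO * O * (1.0 - O)
            grads["W_f"] += da_f.T @ z
            grads["W_c"] += da_c.T @ z
            grads["W_U"] += da_U.T @ z
            grads["W_o"] += da_o.T @ z
            grads["b_f"] += da_f.sum(axis=0)
            grads["b_c"] += da_c.sum(axis=0)
            grads["b_U"] += da_U.sum(axis=0)
            grads["b_o"] += da_o.sum(axis=0)
            dz = da_f @ p["W_f"] + da_c @ p["W_c"] + da_U @ p["W_U"] + da_o @ p["W_o"]
            dh_next = dz[:, :H]
            dX[:, t, :] = dz[:, H:]
        return dX, grads


class _DenseLayer:
    def __init__(self, input_size: int, units: int, rng: np.random.Generator):
        lim = np.sqrt(6.0 / (input_size + units))
        self.params = {"W": rng.uniform(-lim, lim, size=(units, input_size)),
                       "b": np.zeros(units)}
        self.out_size = units

    def forward(self, X: np.ndarray, training: bool, rng) -> np.ndarray:
        self._X = X
        return X @ self.params["W"].T + self.params["b"]

    def backward(self, dout: np.ndarray):
        grads = {"W": dout.T @ self._X, "b": dout.sum(axis=0)}
        return dout @ self.params["W"], grads


class _TanhLayer:
    params: dict = {}
    out_size = None

    def forward(self, X, training, rng):
        self._Y = np.tanh(X)
        return self._Y

    def backward(self, dout):
        return dout * (1.0 - self._Y ** 2), {}


class _DropoutLayer:
    params: dict = {}
    out_size = None

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, X, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return X
        if rng is None:
            raise ValueError("training-mode dropout needs a random generator")
        self._mask = (rng.random(X.shape) >= self.rate) / (1.0 - self.rate)
        return X * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout, {}
        return dout * self._mask, {}


class Network:
    """A configured layer stack with its parameters."""

    def __init__(self, config: NetworkConfig, input_features: int, seed: int = 0):
        self.config = config
        self.input_features = input_features
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.layers = []
        size = input_features
        for kind, opts in config.layers:
            if kind == "lstm":
                layer = _LSTMLayer(size, opts["hidden"], opts.get("mode", "sequence_to_label"), rng)
                size = layer.out_size
            elif kind == "fully_connected":
                layer = _DenseLayer(size, opts["units"], rng)
                size = layer.out_size
            elif kind == "dropout":
                layer = _DropoutLayer(opts.get("rate", 0.2))
            elif kind == "tanh":
                layer = _TanhLayer()
            elif kind in ("softmax", "classification"):
                continue  # realized jointly as the cross-entropy head
            self.layers.append(layer)
        self.n_classes = config.n_classes
        if size != self.n_classes:
            raise ValueError(
                f"final fully connected layer has {size} units for {self.n_classes} classes"
            )

    # -- parameter flattening (for SGDM and finite differences) ----------
    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                out[f"{i}.{name}"] = arr
        return out

    def forward(self, X: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Class probabilities per trial; rows sum to one."""
        out = np.asarray(X, dtype=np.float64)
        for layer in self.layers:
            out = layer.forward(out, training, rng)
        logits = out - out.max(axis=1, keepdims=True)
        ex = np.exp(logits)
        return ex / ex.sum(axis=1, keepdims=True)

    def loss_and_gradients(self, X: np.ndarray, labels: np.ndarray,
                           dropout_seed: int | None = None):
        """Mean cross-entropy over the batch and gradients for every parameter."""
        labels = np.asarray(labels, dtype=int)
        if labels.min() < 0 or labels.max() >= self.n_classes:
            raise ValueError(f"labels must lie in [0, {self.n_classes})")
        rng = None if dropout_seed is None else np.random.default_rng(dropout_seed)
        probs = self.forward(X, training=dropout_seed is not None, rng=rng)
        B = probs.shape[0]
        eps = 1e-300
        loss = float(-np.mean(np.log(probs[np.arange(B), labels] + eps)))
        dlogits = probs.copy()
        dlogits[np.arange(B), labels] -= 1.0
        dlogits /= B
        grads: dict[str, np.ndarray] = {}
        dout = dlogits
        for i in reversed(range(len(self.layers))):
            dout, layer_grads = self.layers[i].backward(dout)
            for name, g in layer_grads.items():
                grads[f"{i}.{name}"] = g
        return loss, grads


# ---------------------------------------------------------------------------
# Functional wrappers and training
# ---------------------------------------------------------------------------

def init_network(config: NetworkConfig, input_features: int, seed: int = 0) -> Network:
    return Network(config, input_features, seed)


def network_forward(net: Network, batch: np.ndarray, training_mode: bool = False,
                    seed: int | None = None) -> np.ndarray:
    rng = np.random.default_rng(seed) if training_mode else None
    return net.forward(batch, training=training_mode, rng=rng)


def loss_and_gradients(net: Network, batch: np.ndarray, labels: np.ndarray,
                       dropout_seed: int | None = None):
    return net.loss_and_gradients(batch, labels, dropout_seed=dropout_seed)


def predict(net: Network, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(argmax class indices, per-class probabilities) for ``X``."""
    if np.asarray(X).shape[-1] != (net.layers[0].F if isinstance(net.layers[0], _LSTMLayer)
                                   else net.layers[0].params["W"].shape[1]):
        raise ValueError("feature dimension does not match the trained network")
    probs = net.forward(X, training=False)
    return probs.argmax(axis=1), probs


def _accuracy(net: Network, X, y) -> float:
    labels, _ = predict(net, X)
    return float(np.mean(labels == y))


def train(
    net: Network,
    X: np.ndarray,
    y: np.ndarray,
    train_cfg: TrainConfig,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> tuple[Network, dict]:
    """SGDM training; runs exactly epochs * ceil(n / batch) iterations.

    Data are shuffled each epoch under the training seed and cut into
    batches (the last batch of an epoch may be smaller).  The history
    records the batch loss/accuracy each iteration and validation accuracy
    every ``val_every`` iterations plus at the end.  Identical seeds give
    bit-identical runs.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(train_cfg.seed)
    params = net.parameters()
    velocity = {k: np.zeros_like(v) for k, v in params.items()}
    per_epoch = int(np.ceil(n / train_cfg.batch_size))
    history = {"iteration": [], "loss": [], "train_accuracy": [],
               "val_iteration": [], "val_accuracy": []}
    it = 0
    for _epoch in range(train_cfg.epochs):
        order = rng.permutation(n) if train_cfg.shuffle else np.arange(n)
        for b in range(per_epoch):
            idx = order[b * train_cfg.batch_size:(b + 1) * train_cfg.batch_size]
            dropout_seed = int(rng.integers(0, 2 ** 31))
            loss, grads = net.loss_and_gradients(X[idx], y[idx], dropout_seed=dropout_seed)
            for k, p in params.items():
                g = grads.get(k)
                if g is None:
                    continue
                v = velocity[k]
                v *= train_cfg.momentum
                v -= train_cfg.learning_rate * g
                p += v
            batch_probs = net.forward(X[idx], training=False)
            batch_acc = float(np.mean(batch_probs.argmax(axis=1) == y[idx]))
            history["iteration"].append(it)
            history["loss"].append(loss)
            history["train_accuracy"].append(batch_acc)
            if X_val is not None and (it % train_cfg.val_every == 0):
                history["val_iteration"].append(it)
                history["val_accuracy"].append(_accuracy(net, X_val, y_val))
            it += 1
    if X_val is not None and (not history["val_iteration"] or history["val_iteration"][-1] != it - 1):
        history["val_iteration"].append(it - 1)
        history["val_accuracy"].append(_accuracy(net, X_val, y_val))
    history["n_iterations"] = it
    return net, history
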