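"""Comparison architectures sharing the decoding harness.

Six alternatives to the t-SNE + LSTM decoder, differing either in the
feature extractor (PCA, ICA, a sequence-to-sequence LSTM front-end) or in
the classifier head (RBF-kernel SVM, a plain back-propagation network, a
CNN on continuous-wavelet-transform scalograms).  All of them consume the
identical cross-validation folds from the evaluation harness so that
method comparisons are paired.

The linear-algebra primitives (SVD, FFT-based wavelets) come from
numpy/scipy/PyWavelets; the learning algorithms themselves - fixed-point
ICA, the SMO solver for the SVM dual, and the network training - are
implemented here and in :mod:`erpdecode.lstm`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import lstm as _lstm

__all__ = [
    "BaselineSpec",
    "pca_features",
    "ica_features",
    "svm_rbf",
    "SVMModel",
    "bp_classifier",
    "cwt_image",
    "cnn_classifier",
    "ConvNet",
]


@dataclass
class BaselineSpec:
    """A named comparison method plus its method-specific settings."""

    method: str
    settings: dict = field(default_factory=dict)

    _KNOWN = ("recurrent_tsne", "recurrent_pca", "recurrent_ica", "deep_lstm",
              "tsne_svm", "tsne_bp", "cwt_cnn")

    def __post_init__(self) -> None:
        if self.method not in self._KNOWN:
            raise ValueError(f"unknown method {self.method!r}; choose from {self._KNOWN}")


# ---------------------------------------------------------------------------
# Linear feature extractors
# ---------------------------------------------------------------------------

def pca_features(X: np.ndarray, k: int = 5) -> np.ndarray:
    """Project rows onto the top-k principal axes (deterministic signs).

    Rows are centered by the mean datapoint; each principal axis is
    oriented so its largest-magnitude loading is positive.
    """
    X = np.asarray(X, dtype=np.float64)
    n, m = X.shape
    if k >= min(n, m):
        raise ValueError(f"k={k} must be < min(n, m) = {min(n, m)}")
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    V = Vt[:k]
    flips = np.sign(V[np.arange(k), np.argmax(np.abs(V), axis=1)])
    V = V * flips[:, None]
    return Xc @ V.T


def ica_features(X: np.ndarray, k: int = 5, seed: int = 0,
                 tol: float = 1e-6, max_iter: int = 500) -> np.ndarray:
    """Fixed-point ICA with a tanh negentropy contrast (deflation order).

    Rows are whitened to k principal directions first; each unmixing vector
    is then iterated to convergence (change in direction < ``tol``) and
    Gram-Schmidt-orthogonalized against the previous ones.  Emits a warning
    and returns the best iterate when a component fails to converge.
    """
    X = np.asarray(X, dtype=np.float64)
    n, m = X.shape
    if k >= min(n, m):
        raise ValueError(f"k={k} must be < min(n, m) = {min(n, m)}")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    K = (Vt[:k] / s[:k, None]) * np.sqrt(n)      # whitening matrix
    Z = Xc @ K.T                                  # n x k, identity covariance
    rng = np.random.default_rng(seed)
    Wrows = np.zeros((k, k))
    for i in range(k):
        w = rng.standard_normal(k)
        w /= np.linalg.norm(w)
        converged = False
        for _ in range(max_iter):
            wx = Z @ w
            g = np.tanh(wx)
            g_prime = 1.0 - g ** 2
            w_new = (Z * g[:, None]).mean(axis=0) - g_prime.mean() * w
            w_new -= Wrows[:i].T @ (Wrows[:i] @ w_new)   # deflation
            norm = np.linalg.norm(w_new)
            if norm < 1e-12:
                w_new = rng.standard_normal(k)
                w_new -= Wrows[:i].T @ (Wrows[:i] @ w_new)
                norm = np.linalg.norm(w_new)
            w_new /= norm
            if 1.0 - abs(w_new @ w) < tol:
                w = w_new
                converged = True
                break
            w = w_new
        if not converged:
            warnings.warn(f"ICA component {i} did not converge; using best iterate")
        Wrows[i] = w
    return Z @ Wrows.T


# ---------------------------------------------------------------------------
# RBF-kernel support vector machine (SMO)
# ---------------------------------------------------------------------------

def _rbf_kernel(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    d2 = (
        np.einsum("ij,ij->i", A, A)[:, None]
        + np.einsum("ij,ij->i", B, B)[None, :]
        - 2.0 * A @ B.T
    )
    return np.exp(-gamma * np.maximum(d2, 0.0))


@dataclass
class SVMModel:
    support_X: np.ndarray
    support_coef: np.ndarray   # alpha_i * y_i
    bias: float
    gamma: float

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        K = _rbf_kernel(np.asarray(X, dtype=np.float64), self.support_X, self.gamma)
        return K @ self.support_coef + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)


def _smo_fit(K: np.ndarray, y: np.ndarray, C: float, tol: float,
             max_passes: int = 200, seed: int = 0) -> tuple[np.ndarray, float]:
    """Sequential minimal optimization on the soft-margin dual."""
    n = len(y)
    alpha = np.zeros(n)
    b = 0.0
    rng = np.random.default_rng(seed)
    # E_i = f(x_i) - y_i maintained incrementally
    E = -y.astype(np.float64)
    passes = 0
    while passes < max_passes:
        changed = 0
        for i in range(n):
            Ei = E[i]
            if (y[i] * Ei < -tol and alpha[i] < C) or (y[i] * Ei > tol and alpha[i] > 0):
                j = int(rng.integers(0, n - 1))
                j = j + 1 if j >= i else j
                Ej = E[j]
                ai_old, aj_old = alpha[i], alpha[j]
                if y[i] != y[j]:
                    L, H = max(0.0, aj_old - ai_old), min(C, C + aj_old - ai_old)
                else:
                    L, H = max(0.0, ai_old + aj_old - C), min(C, ai_old + aj_old)
                if H - L < 1e-12:
                    continue
                eta = 2.0 * K[i, j] - K[i, i] - K[j, j]
                if eta >= 0:
                    continue
                aj = np.clip(aj_old - y[j] * (Ei - Ej) / eta, L, H)
                if abs(aj - aj_old) < 1e-7:
                    continue
                ai = ai_old + y[i] * y[j] * (aj_old - aj)
                alpha[i], alpha[j] = ai, aj
                b1 = b - Ei - y[i] * (ai - ai_old) * K[i, i] - y[j] * (aj - aj_old) * K[i, j]
                b2 = b - Ej - y[i] * (ai - ai_old) * K[i, j] - y[j] * (aj - aj_old) * K[j, j]
                if 0 < ai < C:
                    b_new = b1
                elif 0 < aj < C:
                    b_new = b2
                else:
                    b_new = (b1 + b2) / 2.0
                dE = (y[i] * (ai - ai_old) * K[:, i]
                      + y[j] * (aj - aj_old) * K[:, j] + (b_new - b))
                E += dE
                b = b_new
                changed += 1
        passes = passes + 1 if changed == 0 else 0
    return alpha, b


def svm_rbf(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray | None = None,
    gamma: float | str = "scale",
    C: float = 1.0,
    tol: float = 1e-6,
    seed: int = 0,
) -> np.ndarray | SVMModel:
    """Soft-margin RBF-kernel SVM trained by SMO.

    ``train_y`` holds class indices {0, 1}.  Returns predicted test labels,
    or the fitted :class:`SVMModel` when ``test_X`` is None.
    """
    train_X = np.asarray(train_X, dtype=np.float64)
    train_y = np.asarray(train_y, dtype=int)
    if len(np.unique(train_y)) < 2:
        raise ValueError("training set must contain both classes")
    y_pm = np.where(train_y == 1, 1.0, -1.0)
    if gamma == "scale":
        var = train_X.var()
        gamma = 1.0 / (train_X.shape[1] * var) if var > 0 else 1.0
    K = _rbf_kernel(train_X, train_X, gamma)
    alpha, b = _smo_fit(K, y_pm, C=C, tol=tol, seed=seed)
    sv = alpha > 1e-12
    model = SVMModel(
        support_X=train_X[sv],
        support_coef=alpha[sv] * y_pm[sv],
        bias=b,
        gamma=float(gamma),
    )
    if test_X is None:
        return model
    return model.predict(test_X)


# ---------------------------------------------------------------------------
# Back-propagation network on flat features
# ---------------------------------------------------------------------------

def bp_classifier(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray | None = None,
    hidden: tuple[int, ...] = (20, 10),
    train_cfg: _lstm.TrainConfig | None = None,
    seed: int = 0,
) -> np.ndarray | _lstm.Network:
    """Dense 20 -> 10 -> softmax classifier trained by SGDM.

    The printed single-unit output head is realized as a 2-unit softmax so
    the output layer is trainable; pass ``hidden`` to change layer sizes.
    """
    train_cfg = train_cfg or _lstm.TrainConfig(seed=seed)
    net = _lstm.init_network(_lstm.bp_config(hidden=hidden),
                             input_features=np.asarray(train_X).shape[1], seed=seed)
    net, _ = _lstm.train(net, train_X, train_y, train_cfg)
    if test_X is None:
        return net
    labels, _ = _lstm.predict(net, test_X)
    return labels


# ---------------------------------------------------------------------------
# CWT scalograms + CNN
# ---------------------------------------------------------------------------

def cwt_image(
    trial: np.ndarray,
    sampling_rate: float = 1000.0,
    freq_range: tuple[float, float] = (1.0, 30.0),
    n_scales: int = 32,
    wavelet: str = "morl",
) -> np.ndarray:
    """Channel-averaged Morlet scalogram of one trial (channels x samples).

    Magnitudes are computed per channel on 32 log-spaced scales covering
    1-30 Hz (matching the filtered band) and averaged over channels into a
    single (n_scales, n_samples) image, low frequencies in the last rows.
    """
    import pywt

    trial = np.atleast_2d(np.asarray(trial, dtype=np.float64))
    if trial.size == 0:
        raise ValueError("empty trial")
    freqs = np.geomspace(freq_range[0], freq_range[1], n_scales)
    fc = pywt.central_frequency(wavelet)
    scales = fc * sampling_rate / freqs  # high frequency = small scale
    image = np.zeros((n_scales, trial.shape[1]))
    for ch in range(trial.shape[0]):
        coefs, _ = pywt.cwt(trial[ch], scales, wavelet,
                            sampling_period=1.0 / sampling_rate)
        image += np.abs(coefs)
    return image / trial.shape[0]


def cwt_frequencies(freq_range: tuple[float, float] = (1.0, 30.0),
                    n_scales: int = 32) -> np.ndarray:
    """Center frequency (Hz) of each scalogram row produced by cwt_image."""
    return np.geomspace(freq_range[0], freq_range[1], n_scales)


class _ConvLayer:
    """2-D convolution (valid, stride 1) over single-channel images."""

    def __init__(self, n_filters: int, size: int, rng: np.random.Generator):
        lim = np.sqrt(6.0 / (size * size + n_filters * size * size))
        self.params = {"W": rng.uniform(-lim, lim, size=(n_filters, size, size)),
                       "b": np.zeros(n_filters)}
        self.size = size

    def _im2col(self, X: np.ndarray) -> np.ndarray:
        B, H, W = X.shape
        k = self.size
        if H < k or W < k:
            raise ValueError(f"image {H}x{W} smaller than the {k}x{k} kernel")
        windows = np.lib.stride_tricks.sliding_window_view(X, (k, k), axis=(1, 2))
        return windows.reshape(B, (H - k + 1) * (W - k + 1), k * k)

    def forward(self, X, training, rng):
        self._X = X
        B, H, W = X.shape
        k = self.size
        cols = self._im2col(X)                                  # B, P, k*k
        Wf = self.params["W"].reshape(len(self.params["b"]), -1)  # F, k*k
        out = cols @ Wf.T + self.params["b"]                    # B, P, F
        self._cols = cols
        out = out.transpose(0, 2, 1).reshape(B, -1, H - k + 1, W - k + 1)
        return out

    def backward(self, dout):
        B, F, Ho, Wo = dout.shape
        d = dout.reshape(B, F, Ho * Wo).transpose(0, 2, 1)       # B, P, F
        grads = {
            "W": np.einsum("bpf,bpk->fk", d, self._cols).reshape(self.params["W"].shape),
            "b": d.sum(axis=(0, 1)),
        }
        Wf = self.params["W"].reshape(F, -1)
        dcols = d @ Wf                                           # B, P, k*k
        X = self._X
        dX = np.zeros_like(X)
        k = self.size
        p = 0
        for i in range(Ho):
            for j in range(Wo):
                dX[:, i:i + k, j:j + k] += dcols[:, p].reshape(B, k, k)
                p += 1
        return dX, grads


class _BatchNormLayer:
    """Per-feature-map batch normalization with learned scale/shift."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.params = {"gamma": np.ones(n_features), "beta": np.zeros(n_features)}
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def forward(self, X, training, rng):
        # X: (B, F, H, W); normalize over batch and spatial axes per map
        axes = (0, 2, 3)
        if training:
            mean = X.mean(axis=axes)
            var = X.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._Xhat = (X - mean[None, :, None, None]) / self._std[None, :, None, None]
        self._training = training
        return (self.params["gamma"][None, :, None, None] * self._Xhat
                + self.params["beta"][None, :, None, None])

    def backward(self, dout):
        gamma = self.params["gamma"]
        Xhat = self._Xhat
        axes = (0, 2, 3)
        grads = {"gamma": (dout * Xhat).sum(axis=axes), "beta": dout.sum(axis=axes)}
        dXhat = dout * gamma[None, :, None, None]
        if self._training:
            dX = (dXhat - dXhat.mean(axis=axes, keepdims=True)
                  - Xhat * (dXhat * Xhat).mean(axis=axes, keepdims=True))
            dX /= self._std[None, :, None, None]
        else:
            dX = dXhat / self._std[None, :, None, None]
        return dX, grads


class _ReluLayer:
    params: dict = {}

    def forward(self, X, training, rng):
        self._mask = X > 0
        return X * self._mask

    def backward(self, dout):
        return dout * self._mask, {}


class _FlattenDense:
    """Flatten the ReLU map and connect it directly to the class logits."""

    def __init__(self, in_shape: tuple[int, int, int], units: int, rng: np.random.Generator):
        n_in = int(np.prod(in_shape))
        lim = np.sqrt(6.0 / (n_in + units))
        self.params = {"W": rng.uniform(-lim, lim, size=(units, n_in)), "b": np.zeros(units)}
        self.in_shape = in_shape

    def forward(self, X, training, rng):
        self._shape = X.shape
        self._X = X.reshape(X.shape[0], -1)
        return self._X @ self.params["W"].T + self.params["b"]

    def backward(self, dout):
        grads = {"W": dout.T @ self._X, "b": dout.sum(axis=0)}
        return (dout @ self.params["W"]).reshape(self._shape), {**grads}


class ConvNet:
    """conv(20 x 5x5) -> batch-norm -> ReLU -> dense(2) -> softmax.

    No pooling layer: the dense layer connects directly to the rectified
    feature maps.
    """

    def __init__(self, image_shape: tuple[int, int], n_filters: int = 20,
                 kernel_size: int = 5, n_classes: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        H, W = image_shape
        self.conv = _ConvLayer(n_filters, kernel_size, rng)
        self.bn = _BatchNormLayer(n_filters)
        self.relu = _ReluLayer()
        self.dense = _FlattenDense(
            (n_filters, H - kernel_size + 1, W - kernel_size + 1), n_classes, rng
        )
        self.layers = [self.conv, self.bn, self.relu, self.dense]
        self.n_classes = n_classes

    def parameters(self) -> dict[str, np.ndarray]:
        return {f"{i}.{k}": v for i, l in enumerate(self.layers) for k, v in l.params.items()}

    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.asarray(X, dtype=np.float64)
        for layer in self.layers:
            out = layer.forward(out, training, None)
        logits = out - out.max(axis=1, keepdims=True)
        ex = np.exp(logits)
        return ex / ex.sum(axis=1, keepdims=True)

    def loss_and_gradients(self, X, labels):
        probs = self.forward(X, training=True)
        B = probs.shape[0]
        labels = np.asarray(labels, dtype=int)
        loss = float(-np.mean(np.log(probs[np.arange(B), labels] + 1e-300)))
        dout = probs.copy()
        dout[np.arange(B), labels] -= 1.0
        dout /= B
        grads = {}
        for i in reversed(range(len(self.layers))):
            dout, g = self.layers[i].backward(dout)
            for k, v in g.items():
                grads[f"{i}.{k}"] = v
        return loss, grads


def cnn_classifier(
    train_images: np.ndarray,
    train_y: np.ndarray,
    test_images: np.ndarray | None = None,
    train_cfg: _lstm.TrainConfig | None = None,
    n_filters: int = 20,
    kernel_size: int = 5,
    seed: int = 0,
) -> np.ndarray | ConvNet:
    """Train the scalogram CNN with the shared SGDM settings; predict tests."""
    train_images = np.asarray(train_images, dtype=np.float64)
    train_cfg = train_cfg or _lstm.TrainConfig(seed=seed)
    net = ConvNet(train_images.shape[1:], n_filters=n_filters,
                  kernel_size=kernel_size, seed=seed)
    rng = np.random.default_rng(train_cfg.seed)
    params = net.parameters()
    velocity = {k: np.zeros_like(v) for k, v in params.items()}
    n = train_images.shape[0]
    per_epoch = int(np.ceil(n / train_cfg.batch_size))
    for _epoch in range(train_cfg.epochs):
        order = rng.permutation(n) if train_cfg.shuffle else np.arange(n)
        for b in range(per_epoch):
            idx = order[b * train_cfg.batch_size:(b + 1) * train_cfg.batch_size]
            _, grads = net.loss_and_gradients(train_images[idx], np.asarray(train_y)[idx])
            for k, p in params.items():
                v = velocity[k]
                v *= train_cfg.momentum
                v -= train_cfg.learning_rate * grads[k]
                p += v
    if test_images is None:
        return net
    return net.forward(np.asarray(test_images, dtype=np.float64)).argmax(axis=1)
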