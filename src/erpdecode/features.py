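"""From epochs to LSTM-ready feature sequences, plus the scalp feature map.

Every (trial, channel) time series is one t-SNE datapoint; the resulting
5-dimensional embeddings are re-assembled per trial into an ordered
sequence over channels (montage order), which is what the sequence
classifier consumes.  Averaging the absolute embedding values per channel
and condition, normalized by the maximum over channels, gives a per-channel
scalp feature map.

Embedding is transductive by default (one joint t-SNE over all rows, an
unsupervised step, so labels never leak).  An inductive mode embeds only a
training subset and places held-out rows by a Gaussian-kernel
out-of-sample map, for leakage-free generalization measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import CLASS_ORDER, EpochSet
from .tsne import DatapointMatrix, Embedding, run_tsne

__all__ = [
    "FeatureSequence",
    "ScalpMap",
    "build_datapoints",
    "embed_trials",
    "out_of_sample_embed",
    "assemble_sequences",
    "scalp_feature_map",
    "encode_labels",
]


@dataclass
class FeatureSequence:
    """Per-trial sequences: (n_trials, steps, features)."""

    sequences: np.ndarray
    labels: np.ndarray | None
    orientation: str = "channels_as_steps"

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype=np.float64)
        if self.sequences.ndim != 3:
            raise ValueError("sequences must be (trials, steps, features)")
        if self.labels is not None and len(self.labels) != self.sequences.shape[0]:
            raise ValueError("label count must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.sequences.shape[0]

    def flat(self) -> np.ndarray:
        """Trials x (steps * features) matrix for flat-feature classifiers."""
        return self.sequences.reshape(self.n_trials, -1)


@dataclass
class ScalpMap:
    """Per condition: channel -> normalized feature value in [0, 1]."""

    values: dict[str, dict[str, float]]

    def to_table(self) -> str:
        lines = ["condition\tchannel\tvalue"]
        for cond, chans in self.values.items():
            lines += [f"{cond}\t{ch}\t{val:.6f}" for ch, val in chans.items()]
        return "\n".join(lines) + "\n"


def encode_labels(labels: np.ndarray) -> np.ndarray:
    """Map accept/reject strings onto fixed class indices (accept = 0)."""
    index = {name: i for i, name in enumerate(CLASS_ORDER)}
    return np.asarray([index[str(l)] for l in labels], dtype=int)


def build_datapoints(epochs: EpochSet) -> DatapointMatrix:
    """Stack every (trial, channel) time series as one datapoint row.

    Rows are trial-major: row = trial * n_channels + channel.
    """
    if epochs.n_trials == 0:
        raise ValueError("cannot build datapoints from an empty EpochSet")
    n, c, m = epochs.data.shape
    X = epochs.data.reshape(n * c, m)
    row_index = [(t, ch) for t in range(n) for ch in range(c)]
    return DatapointMatrix(X=X, row_index=row_index)


def embed_trials(
    X: DatapointMatrix,
    dims: int = 5,
    mode: str = "transductive",
    train_rows: np.ndarray | None = None,
    oos_bandwidth: float | str = "median",
    **tsne_kwargs,
) -> tuple[np.ndarray, Embedding]:
    """Embed every datapoint row into ``dims`` dimensions.

    ``transductive`` runs one joint t-SNE over all rows.  ``inductive``
    fits t-SNE on ``train_rows`` only and maps the remaining rows through
    :func:`out_of_sample_embed`.  Returns ``(coords, Embedding)`` where
    ``coords`` has one ``dims``-vector per row of ``X``.
    """
    if mode == "transductive":
        emb = run_tsne(X.X, dims=dims, **tsne_kwargs)
        return emb.Y.copy(), emb
    if mode != "inductive":
        raise ValueError(f"unknown mode {mode!r}")
    if train_rows is None:
        raise ValueError("inductive mode requires a training-row mask")
    train_rows = np.asarray(train_rows)
    if train_rows.dtype == bool:
        train_rows = np.flatnonzero(train_rows)
    n = X.X.shape[0]
    rest = np.setdiff1d(np.arange(n), train_rows)
    emb = run_tsne(X.X[train_rows], dims=dims, **tsne_kwargs)
    coords = np.empty((n, dims))
    coords[train_rows] = emb.Y
    if rest.size:
        if oos_bandwidth == "median":
            # half the median held-out/train distance: wide enough to average
            # several neighbors, narrow enough to stay local
            d2 = _cross_sq_dists(X.X[rest[: min(len(rest), 256)]], X.X[train_rows])
            oos_bandwidth = float(np.sqrt(np.median(d2)) / 2.0) or 1.0
        coords[rest] = out_of_sample_embed(X.X[train_rows], emb, X.X[rest], oos_bandwidth)
    return coords, emb


def _cross_sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    d2 = (
        np.einsum("ij,ij->i", A, A)[:, None]
        + np.einsum("ij,ij->i", B, B)[None, :]
        - 2.0 * A @ B.T
    )
    return np.maximum(d2, 0.0)


def out_of_sample_embed(
    train_X: np.ndarray,
    train_Y: Embedding | np.ndarray,
    new_X: np.ndarray,
    kernel_bandwidth: float,
) -> np.ndarray:
    """Gaussian-kernel interpolation of new points into an existing embedding.

    Each new point receives the kernel-weighted average of the training
    embeddings, with weights exp(-d^2 / (2 h^2)) computed from
    high-dimensional distances.  As h -> 0 a duplicate of a training point
    maps onto that point's embedding; as h -> infinity every point maps to
    the embedding centroid.
    """
    if kernel_bandwidth <= 0:
        raise ValueError("kernel bandwidth must be positive")
    Y = train_Y.Y if isinstance(train_Y, Embedding) else np.asarray(train_Y)
    if Y.shape[0] != np.asarray(train_X).shape[0]:
        raise ValueError("train_Y rows must correspond to train_X rows")
    d2 = _cross_sq_dists(new_X, train_X)
    logw = -d2 / (2.0 * kernel_bandwidth ** 2)
    logw -= logw.max(axis=1, keepdims=True)   # softmax-stable
    w = np.exp(logw)
    w /= w.sum(axis=1, keepdims=True)
    return w @ Y


def assemble_sequences(
    coords: np.ndarray,
    epochs: EpochSet,
    orientation: str = "channels_as_steps",
) -> FeatureSequence:
    """Reshape per-(trial, channel) feature vectors into per-trial sequences.

    The default orientation yields sequences of length n_channels (montage
    order) with the embedding dimensions as per-step features; the
    alternative ``embedding_as_steps`` transposes the two axes.
    """
    n, c = epochs.n_trials, epochs.n_channels
    coords = np.asarray(coords, dtype=np.float64)
    if coords.shape[0] != n * c:
        raise ValueError(
            f"expected one feature vector per (trial, channel): "
            f"{n * c} rows, got {coords.shape[0]}"
        )
    seq = coords.reshape(n, c, -1)
    if orientation == "embedding_as_steps":
        seq = seq.transpose(0, 2, 1)
    elif orientation != "channels_as_steps":
        raise ValueError(f"unknown orientation {orientation!r}")
    labels = None if epochs.labels is None else epochs.labels.copy()
    return FeatureSequence(sequences=seq, labels=labels, orientation=orientation)


def scalp_feature_map(coords: np.ndarray, epochs: EpochSet) -> ScalpMap:
    """Per-condition, per-channel normalized feature magnitudes.

    For each condition and channel: the mean over trials of the mean
    absolute value of the embedding vector, divided by the maximum over
    channels, so the hottest channel is exactly 1.
    """
    if epochs.labels is None:
        raise ValueError("scalp map requires labeled epochs")
    n, c = epochs.n_trials, epochs.n_channels
    per_row = np.abs(np.asarray(coords)).mean(axis=1).reshape(n, c)
    values: dict[str, dict[str, float]] = {}
    for cond in CLASS_ORDER:
        mask = epochs.labels.astype(str) == cond
        if not mask.any():
            warnings.warn(f"condition {cond!r} has no trials; omitted from scalp map")
            continue
        chan_vals = per_row[mask].mean(axis=0)
        peak = chan_vals.max()
        if peak > 0:
            chan_vals = chan_vals / peak
        values[cond] = {
            name: float(v) for name, v in zip(epochs.channel_names, chan_vals)
        }
    return ScalpMap(values=values)
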