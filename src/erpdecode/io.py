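"""Reading and writing epoched EEG data and channel montages.

The package-native *epoch archive* is a directory holding one delimited
numeric matrix (channels x samples, microvolts) per trial together with a
JSON manifest carrying the sampling rate, the epoch window, the channel
names, the per-trial labels and the subject identifier.  The format is
deliberately plain text: language neutral, diffable and lossless for
64-bit floats.

Continuous recordings can be read from EDF together with an event table
(CSV with ``onset_sample`` and ``label`` columns) from which fixed windows
around each event are extracted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EpochSet",
    "Montage",
    "FormatError",
    "ConsistencyError",
    "LabelError",
    "MontageError",
    "ACCEPT",
    "REJECT",
    "CLASS_ORDER",
    "expected_samples",
    "read_epochs",
    "write_epochs",
    "load_montage",
    "PRESET_MONTAGES",
]

#: Canonical label strings for the two behavioural outcomes.
ACCEPT = "accept"
REJECT = "reject"
#: Fixed class order used everywhere a class index is needed.
CLASS_ORDER = (ACCEPT, REJECT)

MANIFEST_NAME = "manifest.json"


class FormatError(ValueError):
    """The on-disk layout is not a valid epoch archive."""


class ConsistencyError(ValueError):
    """Manifest metadata and array shapes disagree."""


class LabelError(ValueError):
    """A label value outside the accepted vocabulary (or missing labels)."""


class MontageError(ValueError):
    """Unknown montage preset, missing channel or duplicate labels."""


def expected_samples(epoch_window: tuple[float, float], sampling_rate: float) -> int:
    """Number of samples a window of ``(start_ms, end_ms)`` spans at ``sampling_rate`` Hz."""
    start_ms, end_ms = epoch_window
    return int(round((end_ms - start_ms) / 1000.0 * sampling_rate))


@dataclass
class EpochSet:
    """Trials x channels x samples EEG array (microvolts) with metadata.

    Parameters
    ----------
    data
        3-D float array ``(n_trials, n_channels, n_samples)`` in microvolts.
    channel_names
        Ordered montage labels, one per channel, unique.
    sampling_rate
        Sampling frequency in Hz.
    epoch_window
        ``(start_ms, end_ms)`` relative to stimulus onset.
    labels
        Per-trial behavioural label (``"accept"`` / ``"reject"``) or ``None``
        for unlabeled data.
    subject_id
        Opaque subject identifier.
    """

    data: np.ndarray
    channel_names: list[str]
    sampling_rate: float
    epoch_window: tuple[float, float]
    labels: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ConsistencyError(
                f"data must be 3-D (trial, channel, sample), got shape {self.data.shape}"
            )
        self.channel_names = [str(c) for c in self.channel_names]
        if len(set(self.channel_names)) != len(self.channel_names):
            raise MontageError("channel names must be unique")
        if len(self.channel_names) != self.data.shape[1]:
            raise ConsistencyError(
                f"{len(self.channel_names)} channel names for {self.data.shape[1]} channels"
            )
        self.epoch_window = (float(self.epoch_window[0]), float(self.epoch_window[1]))
        n_expected = expected_samples(self.epoch_window, self.sampling_rate)
        if self.data.shape[2] != n_expected:
            raise ConsistencyError(
                f"window {self.epoch_window} ms at {self.sampling_rate} Hz implies "
                f"{n_expected} samples, data has {self.data.shape[2]}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != (self.data.shape[0],):
                raise ConsistencyError(
                    f"{self.labels.shape[0]} labels for {self.data.shape[0]} trials"
                )
            bad = sorted({l for l in self.labels} - set(CLASS_ORDER))
            if bad:
                raise LabelError(f"unknown label value(s): {bad}; expected {CLASS_ORDER}")

    # -- convenience ---------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Per-sample time stamps in ms relative to stimulus onset."""
        start, _ = self.epoch_window
        return start + np.arange(self.n_samples) * 1000.0 / self.sampling_rate

    def sample_index(self, t_ms: float) -> int:
        """Index of the sample at time ``t_ms`` (rounded to the grid)."""
        start, _ = self.epoch_window
        idx = int(round((t_ms - start) / 1000.0 * self.sampling_rate))
        if not 0 <= idx < self.n_samples + 1:
            raise ValueError(f"{t_ms} ms lies outside the epoch window {self.epoch_window}")
        return min(idx, self.n_samples - 1)

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise MontageError(f"channel {name!r} not present") from None

    def with_data(self, data: np.ndarray, channel_names: list[str] | None = None) -> "EpochSet":
        """Copy of this set with ``data`` (and optionally channels) replaced."""
        return EpochSet(
            data=data,
            channel_names=self.channel_names if channel_names is None else channel_names,
            sampling_rate=self.sampling_rate,
            epoch_window=self.epoch_window,
            labels=None if self.labels is None else self.labels.copy(),
            subject_id=self.subject_id,
        )

    def subset_trials(self, indices) -> "EpochSet":
        indices = np.asarray(indices, dtype=int)
        return EpochSet(
            data=self.data[indices],
            channel_names=list(self.channel_names),
            sampling_rate=self.sampling_rate,
            epoch_window=self.epoch_window,
            labels=None if self.labels is None else self.labels[indices],
            subject_id=self.subject_id,
        )


@dataclass(frozen=True)
class Montage:
    """A named, ordered set of electrode labels (10-20 / 10-10 nomenclature)."""

    name: str
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.channels:
            raise MontageError("montage must list at least one channel")
        if len(set(self.channels)) != len(self.channels):
            raise MontageError(f"duplicate labels in montage {self.name!r}")

    def __len__(self) -> int:
        return len(self.channels)


# Preset active-channel montages.  The presets follow standard 10-20/10-10
# coverage and are nested: active4 < active16 < active32 < active60.  They
# grow outward from the midline (4: Fz, Cz, Pz, Oz) through symmetric
# lateral expansions.  Any montage can be replaced by a user file with one
# label per line.
_ACTIVE4 = ("Fz", "Cz", "Pz", "Oz")
_ACTIVE16 = _ACTIVE4 + (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2", "T7", "T8",
)
_ACTIVE32 = _ACTIVE16 + (
    "F7", "F8", "FC3", "FC4", "FCz", "CP3", "CP4", "CPz",
    "FT7", "FT8", "TP7", "TP8", "P7", "P8", "AFz", "POz",
)
_ACTIVE60 = _ACTIVE32 + (
    "AF3", "AF4", "AF7", "AF8", "F1", "F2", "F5", "F6",
    "FC1", "FC2", "FC5", "FC6", "C1", "C2", "C5", "C6",
    "CP1", "CP2", "CP5", "CP6", "P1", "P2", "P5", "P6",
    "PO3", "PO4", "PO7", "PO8",
)

PRESET_MONTAGES: dict[str, tuple[str, ...]] = {
    "active4": _ACTIVE4,
    "active16": _ACTIVE16,
    "active32": _ACTIVE32,
    "active60": _ACTIVE60,
}


def load_montage(name_or_path: str | Path) -> Montage:
    """Load a preset montage (``active4``/``active16``/``active32``/``active60``)
    or a channel-list file with one electrode label per line."""
    key = str(name_or_path)
    if key in PRESET_MONTAGES:
        return Montage(name=key, channels=PRESET_MONTAGES[key])
    path = Path(name_or_path)
    if not path.exists():
        raise MontageError(
            f"{key!r} is neither a preset ({sorted(PRESET_MONTAGES)}) nor an existing file"
        )
    labels = tuple(
        line.strip() for line in path.read_text().splitlines() if line.strip()
    )
    return Montage(name=path.stem, channels=labels)


# ---------------------------------------------------------------------------
# Epoch archive
# ---------------------------------------------------------------------------

def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write an :class:`EpochSet` as an epoch archive directory.

    Lossless for 64-bit floats (values are printed with ``%.17g``).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": "erpdecode-epoch-archive",
        "version": 1,
        "n_trials": int(epochs.n_trials),
        "n_channels": int(epochs.n_channels),
        "n_samples": int(epochs.n_samples),
        "sampling_rate": float(epochs.sampling_rate),
        "epoch_window_ms": list(epochs.epoch_window),
        "channel_names": list(epochs.channel_names),
        "labels": None if epochs.labels is None else [str(l) for l in epochs.labels],
        "subject_id": epochs.subject_id,
    }
    (path / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2))
    for t in range(epochs.n_trials):
        np.savetxt(path / f"trial_{t:05d}.txt", epochs.data[t], fmt="%.17g")


def _read_archive(path: Path) -> EpochSet:
    manifest_path = path / MANIFEST_NAME
    if not manifest_path.exists():
        raise FormatError(f"no {MANIFEST_NAME} in {path}")
    manifest = json.loads(manifest_path.read_text())
    n_trials = int(manifest["n_trials"])
    n_channels = int(manifest["n_channels"])
    n_samples = int(manifest["n_samples"])
    data = np.empty((n_trials, n_channels, n_samples), dtype=np.float64)
    for t in range(n_trials):
        trial = np.loadtxt(path / f"trial_{t:05d}.txt", dtype=np.float64)
        trial = np.atleast_2d(trial)
        if trial.shape != (n_channels, n_samples):
            raise ConsistencyError(
                f"trial {t}: matrix shape {trial.shape} does not match manifest "
                f"({n_channels}, {n_samples})"
            )
        data[t] = trial
    labels = manifest.get("labels")
    return EpochSet(
        data=data,
        channel_names=manifest["channel_names"],
        sampling_rate=float(manifest["sampling_rate"]),
        epoch_window=tuple(manifest["epoch_window_ms"]),
        labels=None if labels is None else np.asarray(labels, dtype=object),
        subject_id=manifest.get("subject_id", ""),
    )


def _read_edf(path: Path, events: str | Path, epoch_window: tuple[float, float]) -> EpochSet:
    import pandas as pd

    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is an optional extra
        raise ImportError("reading EDF requires the 'mne' package") from exc

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    signal = raw.get_data() * 1e6  # mne returns volts; archive convention is microvolts
    table = pd.read_csv(events)
    if not {"onset_sample", "label"}.issubset(table.columns):
        raise FormatError("event table needs 'onset_sample' and 'label' columns")
    n_samples = expected_samples(epoch_window, fs)
    offset = int(round(epoch_window[0] / 1000.0 * fs))
    trials, labels = [], []
    for _, row in table.iterrows():
        start = int(row["onset_sample"]) + offset
        stop = start + n_samples
        if start < 0 or stop > signal.shape[1]:
            raise ConsistencyError(
                f"event at sample {row['onset_sample']} does not fit the recording"
            )
        trials.append(signal[:, start:stop])
        labels.append(str(row["label"]))
    return EpochSet(
        data=np.asarray(trials),
        channel_names=list(raw.ch_names),
        sampling_rate=fs,
        epoch_window=epoch_window,
        labels=np.asarray(labels, dtype=object),
        subject_id=path.stem,
    )


def read_epochs(
    path: str | Path,
    format: str = "archive",
    events: str | Path | None = None,
    epoch_window: tuple[float, float] = (-200.0, 800.0),
) -> EpochSet:
    """Read epoched EEG.

    ``format="archive"`` reads the package epoch archive.  ``format="edf"``
    reads a continuous EDF recording and epochs it around the events listed
    in ``events`` (CSV with ``onset_sample``, ``label``), extracting
    ``epoch_window`` ms around each onset.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "archive":
        return _read_archive(path)
    if format == "edf":
        if events is None:
            raise FormatError("format='edf' requires an event table")
        return _read_edf(path, events, epoch_window)
    raise FormatError(f"unknown format {format!r}; use 'archive' or 'edf'")
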