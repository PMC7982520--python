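"""Synthetic two-condition ERP epochs with controllable effect and noise.

Each trial is a sum of

* pink (1/f) background noise, realized by shaping white Gaussian noise in
  the frequency domain with a 1/sqrt(f) amplitude profile (DC bin zeroed)
  and scaling to a target RMS,
* white broadband noise,
* a 10 Hz oscillatory background with random phase per trial and channel,
* for the ``accept`` condition only, a Gaussian-windowed late positive
  deflection (center ``latency_ms``, FWHM ``width_ms``) scaled per channel
  by a topography over centro-parietal sites, and
* optionally, slow high-amplitude frontal deflections emulating ocular
  artifacts, injected per trial with a configurable probability.

This emulates the statistical structure a single-trial decision decoder
relies on - a class-dependent late positivity riding on realistic-looking
background activity - without claiming biophysical fidelity (no volume
conduction, no realistic blink morphology).  Everything is reproducible
from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ACCEPT, CLASS_ORDER, REJECT, EpochSet, expected_samples
from .io import PRESET_MONTAGES

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "default_topography",
    "generate_epochs",
    "summarize_truth",
    "paradigm_trial_counts",
]

#: Full-width-at-half-maximum to Gaussian-sigma conversion factor.
_FWHM = 2.355

#: Centro-parietal channels (and weights) carrying the late positivity by
#: default - 8 of the 16 channels of the ``active16`` montage, strongest at Pz.
_DEFAULT_EFFECT_WEIGHTS = {
    "Pz": 1.0, "Cz": 0.9, "P3": 0.8, "P4": 0.8,
    "C3": 0.6, "C4": 0.6, "Oz": 0.5, "Fz": 0.3,
}


def default_topography(channel_names: list[str]) -> np.ndarray:
    """Per-channel effect weights: centro-parietal maximum, zero elsewhere."""
    return np.asarray([_DEFAULT_EFFECT_WEIGHTS.get(c, 0.0) for c in channel_names])


@dataclass
class SynthConfig:
    """Study conditions for the synthetic ERP generator.

    Amplitudes are in microvolts, times in ms.  ``topography`` is a
    per-channel weight vector for the class effect; ``None`` selects the
    default centro-parietal profile over the chosen channels.
    """

    n_trials_per_class: int = 100
    channel_names: tuple[str, ...] = PRESET_MONTAGES["active16"]
    sampling_rate: float = 1000.0
    epoch_window: tuple[float, float] = (-200.0, 800.0)
    # class effect: late positive deflection on the accept condition
    effect_amplitude_uv: float = 8.0
    effect_latency_ms: float = 500.0
    effect_width_ms: float = 200.0
    topography: np.ndarray | None = None
    # background
    one_over_f_scale_uv: float = 3.0
    white_scale_uv: float = 2.0
    alpha_amplitude_uv: float = 2.0
    # ocular artifacts
    artifact_rate: float = 0.0
    artifact_amplitude_uv: float = 120.0
    seed: int = 0
    subject_id: str = "synth"

    def __post_init__(self) -> None:
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact rate must lie in [0, 1]")
        for name in ("one_over_f_scale_uv", "white_scale_uv", "alpha_amplitude_uv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.epoch_window[0] >= self.epoch_window[1]:
            raise ValueError("epoch window start must precede its end")
        if self.topography is not None:
            self.topography = np.asarray(self.topography, dtype=np.float64)
            if self.topography.shape != (len(self.channel_names),):
                raise ValueError("topography length must equal the channel count")


@dataclass
class GroundTruth:
    """Per-trial generative record aligned with the produced EpochSet."""

    labels: np.ndarray
    artifact: np.ndarray
    amplitude_uv: np.ndarray
    config: SynthConfig | None = field(default=None, repr=False)


def _pink_noise(rng: np.random.Generator, n_series: int, n_samples: int,
                rms: float) -> np.ndarray:
    """1/f-spectrum noise: white noise shaped by 1/sqrt(f), DC zeroed."""
    if rms == 0:
        return np.zeros((n_series, n_samples))
    spec = np.fft.rfft(rng.standard_normal((n_series, n_samples)), axis=1)
    f = np.fft.rfftfreq(n_samples)
    shaping = np.zeros_like(f)
    shaping[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return x / std * rms


def generate_epochs(config: SynthConfig) -> tuple[EpochSet, GroundTruth]:
    """Draw a labeled two-condition EpochSet plus its generative ground truth."""
    rng = np.random.default_rng(config.seed)
    n_chan = len(config.channel_names)
    n_samples = expected_samples(config.epoch_window, config.sampling_rate)
    n_per = int(config.n_trials_per_class)
    n_total = 2 * n_per

    labels = np.asarray([ACCEPT] * n_per + [REJECT] * n_per, dtype=object)
    order = rng.permutation(n_total)
    labels = labels[order]

    t_ms = config.epoch_window[0] + np.arange(n_samples) * 1000.0 / config.sampling_rate
    topo = (default_topography(list(config.channel_names))
            if config.topography is None else config.topography)

    sigma_ms = config.effect_width_ms / _FWHM
    component = np.exp(-0.5 * ((t_ms - config.effect_latency_ms) / max(sigma_ms, 1e-9)) ** 2)

    data = _pink_noise(rng, n_total * n_chan, n_samples,
                       config.one_over_f_scale_uv).reshape(n_total, n_chan, n_samples)
    if config.white_scale_uv > 0:
        data += config.white_scale_uv * rng.standard_normal((n_total, n_chan, n_samples))
    if config.alpha_amplitude_uv > 0:
        phases = rng.uniform(0, 2 * np.pi, size=(n_total, n_chan, 1))
        data += config.alpha_amplitude_uv * np.sin(
            2 * np.pi * 10.0 * t_ms[None, None, :] / 1000.0 + phases
        )

    amplitudes = np.where(labels == ACCEPT, config.effect_amplitude_uv, 0.0).astype(float)
    data += amplitudes[:, None, None] * topo[:, None] * component[None, None, :]

    # ocular artifacts: slow +-half-cosine on frontal channels
    frontal = np.asarray([
        1.0 if c.startswith("Fp") else (0.5 if c.startswith(("F", "AF")) else 0.0)
        for c in config.channel_names
    ])
    artifact_flags = rng.random(n_total) < config.artifact_rate
    if artifact_flags.any() and config.artifact_amplitude_uv > 0:
        span = (t_ms - t_ms[0]) / (t_ms[-1] - t_ms[0])
        slow = np.sin(np.pi * span)  # one slow half-wave across the epoch
        signs = rng.choice([-1.0, 1.0], size=int(artifact_flags.sum()))
        data[artifact_flags] += (
            signs[:, None, None] * config.artifact_amplitude_uv
            * frontal[None, :, None] * slow[None, None, :]
        )

    epochs = EpochSet(
        data=data,
        channel_names=list(config.channel_names),
        sampling_rate=config.sampling_rate,
        epoch_window=config.epoch_window,
        labels=labels,
        subject_id=config.subject_id,
    )
    truth = GroundTruth(
        labels=labels.copy(),
        artifact=artifact_flags,
        amplitude_uv=amplitudes,
        config=config,
    )
    return epochs, truth


def summarize_truth(epochs: EpochSet, truth: GroundTruth) -> pd.DataFrame:
    """Per-class empirical summary at the component's peak channel/latency.

    Reports, per condition, the trial count, the mean amplitude at the
    strongest-topography channel and the component latency, and the number
    of artifact-flagged trials.  Empty input gives an empty table.
    """
    if epochs.n_trials != len(truth.labels):
        raise ValueError("epochs and ground truth are misaligned")
    cfg = truth.config
    rows = []
    if epochs.n_trials and cfg is not None:
        topo = (default_topography(epochs.channel_names)
                if cfg.topography is None else cfg.topography)
        peak_ch = int(np.argmax(topo))
        peak_idx = epochs.sample_index(cfg.effect_latency_ms)
        for cond in CLASS_ORDER:
            mask = epochs.labels.astype(str) == cond
            if not mask.any():
                continue
            rows.append({
                "label": cond,
                "n_trials": int(mask.sum()),
                "mean_peak_uv": float(epochs.data[mask, peak_ch, peak_idx].mean()),
                "artifact_count": int(truth.artifact[mask].sum()),
            })
    return pd.DataFrame(rows, columns=["label", "n_trials", "mean_peak_uv", "artifact_count"])


def paradigm_trial_counts(n_brands: int = 14, n_products: int = 14,
                          n_practice: int = 20) -> dict[str, int]:
    """Trial arithmetic of the brand-extension paradigm.

    Every brand name is paired with every product name, giving the
    experimental trials; practice trials are added on top.
    """
    experimental = n_brands * n_products
    return {
        "experimental_trials": experimental,
        "practice_trials": n_practice,
        "total_trials": experimental + n_practice,
    }
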