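"""Preprocessing: Butterworth bandpass, epoching, feature construction.

The continuous recording is bandpass filtered (3rd-order Butterworth,
0.1-25 Hz) *before* epoching to keep filter transients out of the
windows.  One 800 ms epoch is extracted per flash onset; with a 175 ms
stimulus-onset asynchrony consecutive epochs overlap, which is intended.
The feature row of an epoch is the channel-major concatenation of the
analysis channels' samples (8 x 200 = 1600 features at 250 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .simulate import DEFAULT_CHANNELS, EEGRecording

__all__ = ["PreprocConfig", "EpochSet", "bandpass", "extract_epochs", "average_erps"]


@dataclass(frozen=True)
class PreprocConfig:
    band_low: float = 0.1
    band_high: float = 25.0
    filter_order: int = 3
    epoch_length: float = 0.8
    analysis_channels: tuple[str, ...] = DEFAULT_CHANNELS
    baseline_correction: str = "none"  # none | pre_stimulus_mean
    filter_mode: str = "zero_phase"  # zero_phase | causal

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.filter_mode not in ("zero_phase", "causal"):
            raise ValueError(f"unknown filter_mode {self.filter_mode!r}")
        if self.baseline_correction not in ("none", "pre_stimulus_mean"):
            raise ValueError(f"unknown baseline_correction {self.baseline_correction!r}")


@dataclass
class EpochSet:
    """Per-flash feature matrix with target labels.

    ``features`` is n_epochs x (n_channels * samples_per_epoch), channel-major:
    feature ``c * samples_per_epoch + t`` is channel ``c`` at sample ``t``.
    """

    features: np.ndarray
    labels: np.ndarray  # bool, True = target flash
    symbol_indices: np.ndarray
    block_indices: np.ndarray
    n_channels: int
    samples_per_epoch: int
    sampling_rate: float
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.features.shape[1] != self.n_channels * self.samples_per_epoch:
            raise ValueError("feature width != n_channels * samples_per_epoch")

    @property
    def n_epochs(self) -> int:
        return self.features.shape[0]

    def as_waveforms(self) -> np.ndarray:
        """Epochs as an (n_epochs, n_channels, samples_per_epoch) array."""
        return self.features.reshape(self.n_epochs, self.n_channels, self.samples_per_epoch)

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.features.tsv`` and ``<prefix>.labels.tsv``."""
        prefix = Path(prefix)
        np.savetxt(prefix.with_suffix(".features.tsv"), self.features, delimiter="\t")
        pd.DataFrame(
            {
                "is_target": self.labels.astype(int),
                "symbol_index": self.symbol_indices,
                "block_index": self.block_indices,
            }
        ).to_csv(prefix.with_suffix(".labels.tsv"), sep="\t", index=False)


def _design(config: PreprocConfig, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    if config.band_high >= nyq:
        raise ValueError(f"band_high {config.band_high} Hz >= Nyquist {nyq} Hz")
    return sps.butter(
        config.filter_order,
        [config.band_low, config.band_high],
        btype="bandpass",
        fs=fs,
        output="sos",
    )


def bandpass(recording: EEGRecording, config: PreprocConfig) -> EEGRecording:
    """Bandpass the continuous recording per channel.

    ``zero_phase`` applies the filter forward and backward (no group
    delay, doubled effective order); ``causal`` is a single forward pass
    as an online system would run.
    """
    sos = _design(config, recording.sampling_rate)
    if config.filter_mode == "zero_phase":
        filtered = sps.sosfiltfilt(sos, recording.samples, axis=1)
    else:
        filtered = sps.sosfilt(sos, recording.samples, axis=1)
    return EEGRecording(
        samples=np.ascontiguousarray(filtered),
        sampling_rate=recording.sampling_rate,
        channel_names=recording.channel_names,
        events=list(recording.events),
        meta={**recording.meta, "filtered": config.filter_mode},
    )


def extract_epochs(recording: EEGRecording, config: PreprocConfig) -> EpochSet:
    """Cut one post-stimulus window per flash event and build feature rows.

    Window is ``[onset, onset + epoch_length)``.  Raises if an analysis
    channel is missing or the recording ends before the last window.
    """
    fs = recording.sampling_rate
    spe = int(round(config.epoch_length * fs))
    try:
        ch_idx = [recording.channel_names.index(ch) for ch in config.analysis_channels]
    except ValueError as err:
        raise ValueError(f"analysis channel missing from recording: {err}") from None
    n_ch = len(ch_idx)
    data = recording.samples[ch_idx]
    rows, labels, syms, blocks = [], [], [], []
    n_per_block = {}
    for onset, symbol_index, is_target in recording.events:
        start = int(round(onset * fs))
        if start + spe > recording.n_samples:
            raise ValueError(
                f"epoch at onset {onset:.3f}s truncated: recording has "
                f"{recording.n_samples} samples, window needs {start + spe}"
            )
        win = data[:, start : start + spe]
        if config.baseline_correction == "pre_stimulus_mean":
            pre = data[:, max(0, start - spe // 8) : start]
            if pre.shape[1]:
                win = win - pre.mean(axis=1, keepdims=True)
        rows.append(win.reshape(-1))
        labels.append(is_target)
        syms.append(symbol_index)
        n_per_block[symbol_index] = n_per_block.get(symbol_index, 0) + 1
        blocks.append(n_per_block[symbol_index] - 1)
    return EpochSet(
        features=np.asarray(rows),
        labels=np.asarray(labels, dtype=bool),
        symbol_indices=np.asarray(syms, dtype=int),
        block_indices=np.asarray(blocks, dtype=int),
        n_channels=n_ch,
        samples_per_epoch=spe,
        sampling_rate=fs,
        channel_names=tuple(config.analysis_channels),
    )


def average_erps(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Grand-average target and non-target waveforms.

    Returns ``(target_mean, nontarget_mean)``, each of shape
    (n_channels, samples_per_epoch).  Raises if either class is empty.
    """
    wf = epochs.as_waveforms()
    if not epochs.labels.any() or epochs.labels.all():
        raise ValueError("need at least one target and one non-target epoch")
    return wf[epochs.labels].mean(axis=0), wf[~epochs.labels].mean(axis=0)
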