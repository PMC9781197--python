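"""Synthetic multi-channel EEG with embedded P300 responses.

The simulator produces continuous 8-channel EEG at 250 Hz for a given
flash schedule and attended symbol.  Each flash of the attended symbol
adds a positive event-related deflection peaking ~300 ms after flash
onset; non-target flashes evoke nothing.  The deflection amplitude
follows two empirical effects of the oddball paradigm:

* *prior-probability effect* — the rarer the target among the flashes,
  the larger the P300; amplitude scales as ``prior**(-exponent)``,
  anchored so a prior of 1/12 gives unit gain;
* *familiarity effect* — selections on the numbers-based phone-dial
  display evoke a slightly larger P300 than the appliance-symbol
  display, modeled as a constant multiplicative gain.

The template is a raised-cosine bump (smooth, compactly supported);
its projection onto each channel follows a fixed parietal-dominant
gain profile peaking at Pz.  Latency jitters from flash to flash.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .paradigm import FlashSchedule, ParadigmConfig, target_prior

__all__ = [
    "SimulationConfig",
    "EEGRecording",
    "p300_template",
    "effective_amplitude",
    "generate_background",
    "simulate_recording",
    "DEFAULT_CHANNELS",
    "DEFAULT_CHANNEL_GAINS",
]

#: Analysis montage: midline-parietal sites where the P300 is largest,
#: plus nearby frontal/occipital electrodes (10-20 names).
DEFAULT_CHANNELS = ("Fz", "Cz", "P3", "Pz", "P4", "PO7", "PO8", "Oz")

#: Relative ERP projection per channel, parietal-dominant (Pz = 1.0).
DEFAULT_CHANNEL_GAINS = (0.4, 0.7, 0.8, 1.0, 0.8, 0.6, 0.6, 0.5)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic EEG generator (amplitudes in microvolts)."""

    sampling_rate: float = 250.0
    n_channels: int = 8
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    noise_sigma: float = 10.0
    noise_model: str = "white"  # white | pink | ar1
    ar_coefficient: float = 0.95
    p300_peak_latency: float = 0.300
    p300_latency_jitter_sd: float = 0.020
    p300_width: float = 0.300
    p300_base_amplitude: float = 5.0
    channel_gains: tuple[float, ...] = DEFAULT_CHANNEL_GAINS
    prior_amplitude_exponent: float = 0.5
    familiarity_gain: float = 1.15
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 50.0:
            raise ValueError("sampling_rate must exceed 2 x 25 Hz")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.p300_base_amplitude < 0:
            raise ValueError("p300_base_amplitude must be non-negative")
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal n_channels")
        if len(self.channel_gains) != self.n_channels:
            raise ValueError("channel_gains length must equal n_channels")
        if self.noise_model not in ("white", "pink", "ar1"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


@dataclass
class EEGRecording:
    """A continuous multi-channel recording with flash-event markers.

    ``samples`` is channels x time in microvolts; ``events`` holds
    ``(onset_s, symbol_index, is_target)`` triples sorted by onset.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_names: tuple[str, ...]
    events: list[tuple[float, int, bool]]
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def validate(self) -> None:
        if np.isnan(self.samples).any():
            raise ValueError("recording contains NaNs")
        onsets = [e[0] for e in self.events]
        if onsets != sorted(onsets):
            raise ValueError("events must be sorted by onset")
        if self.events and self.duration < self.events[-1][0] + 0.8:
            raise ValueError("recording too short for the last event's epoch")


def p300_template(config: SimulationConfig) -> np.ndarray:
    """Sampled P300 waveform before channel gains, as a 1-D array.

    A raised-cosine bump of width ``p300_width`` centered at
    ``p300_peak_latency``, sampled at ``sampling_rate`` from t=0 to the
    end of its support; non-negative everywhere, peak value equal to
    ``p300_base_amplitude``.
    """
    fs = config.sampling_rate
    t_end = config.p300_peak_latency + config.p300_width / 2.0
    t = np.arange(0.0, t_end + 1.0 / fs, 1.0 / fs)
    return _template_at(t, config.p300_peak_latency, config)


def _template_at(t: np.ndarray, peak: float, config: SimulationConfig) -> np.ndarray:
    """Raised-cosine bump evaluated at times ``t`` for a given peak latency."""
    half = config.p300_width / 2.0
    x = (t - peak) / half
    out = np.zeros_like(t, dtype=float)
    inside = np.abs(x) < 1.0
    out[inside] = 0.5 * (1.0 + np.cos(np.pi * x[inside]))
    return config.p300_base_amplitude * out


def effective_amplitude(config: SimulationConfig, paradigm: ParadigmConfig) -> float:
    """Peak P300 amplitude (microvolts, before channel gains) under the
    paradigm's target prior and display.

    ``base * (prior / (1/12)) ** (-exponent)``, so a prior of 1/12 is the
    unit anchor and rarer targets yield larger deflections; multiplied by
    ``familiarity_gain`` on the numbers-based secondary display.
    """
    prior = target_prior(paradigm)
    amp = config.p300_base_amplitude * (prior * 12.0) ** (-config.prior_amplitude_exponent)
    if paradigm.display == "secondary_numbers":
        amp *= config.familiarity_gain
    return amp


def generate_background(
    duration: float,
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Zero-mean background noise, channels x time, SD ``noise_sigma``.

    ``white`` draws i.i.d. Gaussians; ``pink`` shapes white noise to a
    1/f amplitude spectrum; ``ar1`` runs a first-order autoregression.
    Pink and AR(1) traces are rescaled so the realized per-channel SD
    equals ``noise_sigma``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = int(round(duration * config.sampling_rate))
    sigma = config.noise_sigma
    if sigma == 0:
        return np.zeros((config.n_channels, n))
    if config.noise_model == "white":
        return rng.normal(0.0, sigma, size=(config.n_channels, n))
    if config.noise_model == "pink":
        white = rng.normal(0.0, 1.0, size=(config.n_channels, n))
        spec = np.fft.rfft(white, axis=1)
        freqs = np.fft.rfftfreq(n, d=1.0 / config.sampling_rate)
        shaping = np.ones_like(freqs)
        shaping[1:] = 1.0 / np.sqrt(freqs[1:])
        shaping[0] = 0.0  # zero mean
        x = np.fft.irfft(spec * shaping, n=n, axis=1)
    else:  # ar1
        a = config.ar_coefficient
        e = rng.normal(0.0, 1.0, size=(config.n_channels, n))
        x = np.empty_like(e)
        x[:, 0] = e[:, 0]
        for k in range(1, n):
            x[:, k] = a * x[:, k - 1] + e[:, k]
    x -= x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x * (sigma / sd)


def injected_signal(
    schedule: FlashSchedule,
    target_symbol: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_samples: int,
) -> np.ndarray:
    """Sum of channel-weighted, latency-jittered templates at target flashes."""
    fs = config.sampling_rate
    amp = effective_amplitude(config, schedule.config)
    scale = amp / config.p300_base_amplitude if config.p300_base_amplitude > 0 else 0.0
    gains = np.asarray(config.channel_gains)
    out = np.zeros((config.n_channels, n_samples))
    sd = config.p300_latency_jitter_sd
    for ev in schedule.events:
        if ev.symbol_index != target_symbol:
            continue
        jitter = 0.0
        if sd > 0:
            jitter = float(np.clip(rng.normal(0.0, sd), -3.0 * sd, 3.0 * sd))
        peak = config.p300_peak_latency + jitter
        start = int(round(ev.onset * fs))
        t_local = np.arange(n_samples - start) / fs
        bump = scale * _template_at(t_local, peak, config)
        out[:, start:] += gains[:, None] * bump[None, :]
    return out


def simulate_recording(
    schedule: FlashSchedule,
    target_symbol: int,
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> EEGRecording:
    """Simulate one selection: background noise plus P300s at target flashes.

    The recording extends 1 s past the last flash onset so an 800 ms
    epoch fits every event.  Exactly ``n_repetitions`` events are marked
    ``is_target`` (one per block).
    """
    n_symbols = schedule.config.n_symbols
    if not 0 <= target_symbol < n_symbols:
        raise ValueError(f"target_symbol {target_symbol} out of range 0..{n_symbols - 1}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    duration = schedule.events[-1].onset + 1.0
    n = int(round(duration * config.sampling_rate))
    # Fixed draw order (signal jitter first, then noise) keeps the same-seed
    # background identical across different amplitudes, so superposition
    # holds exactly: recording(A) - recording(0) == injected templates.
    signal = injected_signal(schedule, target_symbol, config, rng, n)
    background = generate_background(duration, config, rng)
    events = [
        (ev.onset, ev.symbol_index, ev.symbol_index == target_symbol)
        for ev in schedule.events
    ]
    rec = EEGRecording(
        samples=background + signal,
        sampling_rate=config.sampling_rate,
        channel_names=tuple(config.channel_names),
        events=events,
        meta={
            "target_symbol": int(target_symbol),
            "display": schedule.config.display,
            "seed": schedule.seed,
        },
    )
    rec.validate()
    return rec
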