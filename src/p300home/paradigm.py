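"""Flashing-paradigm configuration and stimulus scheduling.

A selection proceeds in *blocks*: within one block every symbol of the
4 x 3 matrix is intensified exactly once in random order (single-symbol
oddball flashing).  Blocks are repeated ``n_repetitions`` times, and the
decoder aggregates evidence across repetitions.  Consecutive flash onsets
are separated by ``flash_duration + blank_duration`` (the stimulus-onset
asynchrony); blocks follow each other without a gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParadigmError",
    "ParadigmConfig",
    "FlashEvent",
    "FlashSchedule",
    "make_block",
    "make_schedule",
    "selection_duration",
    "target_prior",
    "DEFAULT_PRIMARY_SYMBOLS",
    "DEFAULT_SECONDARY_SYMBOLS",
]


class ParadigmError(ValueError):
    """Raised for invalid paradigm configurations or schedules."""


#: Appliance-control symbols of the primary display (4 rows x 3 columns,
#: row-major).  Only the phone_call entry is structurally required; the
#: rest is a configurable default appliance layout.
DEFAULT_PRIMARY_SYMBOLS = (
    "tv_power", "light_power", "fan_power",
    "volume_up", "volume_down", "music_play",
    "music_stop", "door_toggle", "temp_up",
    "temp_down", "help_alarm", "phone_call",
)

#: Digit/call/return cells of the secondary (phone-dialing) display,
#: row-major: [1 2 3] [4 5 6] [7 8 9] [call 0 return].
DEFAULT_SECONDARY_SYMBOLS = (
    "1", "2", "3",
    "4", "5", "6",
    "7", "8", "9",
    "call", "0", "return",
)


@dataclass(frozen=True)
class ParadigmConfig:
    """All paradigm, timing and layout parameters of one display.

    Defaults reproduce the experimental timings: 100 ms intensification,
    75 ms blank, 12 symbols, 15 repetitions per selection.
    """

    n_rows: int = 4
    n_cols: int = 3
    flash_duration: float = 0.100
    blank_duration: float = 0.075
    n_repetitions: int = 15
    flash_scheme: str = "single_symbol"  # or "row_column"
    display: str = "primary_symbols"  # or "secondary_numbers"
    symbol_labels: tuple[str, ...] = DEFAULT_PRIMARY_SYMBOLS

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ParadigmError("matrix must have at least one row and column")
        if self.flash_duration <= 0 or self.blank_duration <= 0:
            raise ParadigmError("flash and blank durations must be positive")
        if self.n_repetitions < 1:
            raise ParadigmError("n_repetitions must be >= 1")
        if self.flash_scheme not in ("single_symbol", "row_column"):
            raise ParadigmError(f"unknown flash_scheme {self.flash_scheme!r}")
        if self.display not in ("primary_symbols", "secondary_numbers"):
            raise ParadigmError(f"unknown display {self.display!r}")
        if len(self.symbol_labels) != self.n_symbols:
            raise ParadigmError(
                f"need {self.n_symbols} symbol labels, got {len(self.symbol_labels)}"
            )
        if len(set(self.symbol_labels)) != len(self.symbol_labels):
            raise ParadigmError("symbol labels must be unique")

    @property
    def n_symbols(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def soa(self) -> float:
        """Stimulus-onset asynchrony in seconds (flash + blank)."""
        return self.flash_duration + self.blank_duration

    @classmethod
    def secondary(cls, **kwargs) -> "ParadigmConfig":
        """The numbers-based phone-dial display with default timings."""
        kwargs.setdefault("display", "secondary_numbers")
        kwargs.setdefault("symbol_labels", DEFAULT_SECONDARY_SYMBOLS)
        return cls(**kwargs)

    # -- config file round trip -------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "flash_duration": self.flash_duration,
            "blank_duration": self.blank_duration,
            "n_repetitions": self.n_repetitions,
            "flash_scheme": self.flash_scheme,
            "display": self.display,
            "symbol_labels": list(self.symbol_labels),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ParadigmConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["symbol_labels"] = tuple(data["symbol_labels"])
        return cls(**data)


@dataclass(frozen=True)
class FlashEvent:
    """One intensification: onset (s from schedule start), symbol, block."""

    onset: float
    symbol_index: int
    block_index: int
    duration: float


@dataclass(frozen=True)
class FlashSchedule:
    """An ordered sequence of flash events for one selection."""

    events: tuple[FlashEvent, ...]
    config: ParadigmConfig
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.events)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset for e in self.events])

    @property
    def symbol_indices(self) -> np.ndarray:
        return np.array([e.symbol_index for e in self.events], dtype=int)

    @property
    def block_indices(self) -> np.ndarray:
        return np.array([e.block_index for e in self.events], dtype=int)

    @property
    def duration(self) -> float:
        """Total schedule duration = last onset + one SOA."""
        return self.events[-1].onset + self.config.soa

    def validate(self) -> None:
        """Check schedule invariants; raise :class:`ParadigmError` if violated."""
        cfg = self.config
        if len(self.events) != cfg.n_symbols * cfg.n_repetitions:
            raise ParadigmError("event count != n_symbols * n_repetitions")
        onsets = self.onsets
        if not np.all(np.diff(onsets) > 0):
            raise ParadigmError("onsets must be strictly increasing")
        expected = np.arange(len(self.events)) * cfg.soa
        if not np.allclose(onsets, expected, atol=1e-9):
            raise ParadigmError("onsets must advance by one SOA per event")
        for b in range(cfg.n_repetitions):
            block = self.symbol_indices[self.block_indices == b]
            if sorted(block) != list(range(cfg.n_symbols)):
                raise ParadigmError(f"block {b} is not a permutation of all symbols")

    # -- event file round trip --------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": self.onsets,
                "symbol_index": self.symbol_indices,
                "block_index": self.block_indices,
                "duration_s": [e.duration for e in self.events],
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path, config: ParadigmConfig) -> "FlashSchedule":
        df = pd.read_csv(path, sep="\t")
        events = tuple(
            FlashEvent(
                onset=float(r.onset_s),
                symbol_index=int(r.symbol_index),
                block_index=int(r.block_index),
                duration=float(r.duration_s),
            )
            for r in df.itertuples()
        )
        return cls(events=events, config=config)


def make_block(n_symbols: int, rng: np.random.Generator) -> np.ndarray:
    """Return one intensification block: a uniform random permutation of
    symbol indices ``0 .. n_symbols-1`` (every symbol flashes exactly once).
    """
    if n_symbols < 2:
        raise ParadigmError("a flashing block needs at least 2 symbols")
    return rng.permutation(n_symbols)


def make_schedule(
    config: ParadigmConfig,
    rng: np.random.Generator | int | None = None,
) -> FlashSchedule:
    """Generate a randomized flash schedule for one selection.

    Blocks are independent permutations (no constraint at block
    boundaries); onsets start at 0 and advance by one SOA per event.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    events = []
    k = 0
    for b in range(config.n_repetitions):
        for sym in make_block(config.n_symbols, rng):
            events.append(
                FlashEvent(
                    onset=k * config.soa,
                    symbol_index=int(sym),
                    block_index=b,
                    duration=config.flash_duration,
                )
            )
            k += 1
    return FlashSchedule(events=tuple(events), config=config, seed=seed)


def selection_duration(config: ParadigmConfig) -> float:
    """Time in seconds to complete one symbol selection.

    ``n_symbols * SOA * n_repetitions``; with the default timings
    12 * 0.175 s * 15 = 31.5 s (one block takes 2.1 s).
    """
    return config.n_symbols * config.soa * config.n_repetitions


def target_prior(config: ParadigmConfig) -> float:
    """Prior probability that any given flash contains the attended symbol.

    Single-symbol flashing: 1/n_symbols (1/12 for the 4 x 3 matrix).
    Row/column flashing: 2/(n_rows + n_cols) (2/7 for 4 x 3) — each
    selection lights one row and one column containing the target out of
    ``n_rows + n_cols`` intensifications.  The P300 amplitude is inversely
    related to this prior, which is why single-symbol flashing is used.
    """
    if config.flash_scheme == "single_symbol":
        return 1.0 / config.n_symbols
    if config.flash_scheme == "row_column":
        return 2.0 / (config.n_rows + config.n_cols)
    raise ParadigmError(f"unknown flash_scheme {config.flash_scheme!r}")
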