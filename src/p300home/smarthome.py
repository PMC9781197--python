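"""Two-display smart-home command state machine.

Decoded symbols drive abstract home actions.  The primary display maps
12 symbols to appliance commands plus one phone-call entry; selecting
phone_call switches to the secondary numbers display, where digits build
a dial buffer, ``call`` connects the call, and ``return`` hangs up and
restores the primary display.  Every applied selection appends exactly
one structured record to the action log, so a logged sequence replays to
an identical final state.  No actual appliance or telephony I/O occurs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

from .paradigm import DEFAULT_PRIMARY_SYMBOLS, DEFAULT_SECONDARY_SYMBOLS

__all__ = ["CommandMap", "HomeState", "apply_selection", "replay"]

_DIGITS = set("0123456789")

#: Appliance action per primary symbol label.
DEFAULT_PRIMARY_ACTIONS = {
    "tv_power": ("tv", "toggle"),
    "light_power": ("light", "toggle"),
    "fan_power": ("fan", "toggle"),
    "volume_up": ("volume", "+1"),
    "volume_down": ("volume", "-1"),
    "music_play": ("music", "play"),
    "music_stop": ("music", "stop"),
    "door_toggle": ("door", "toggle"),
    "temp_up": ("thermostat", "+1"),
    "temp_down": ("thermostat", "-1"),
    "help_alarm": ("alarm", "raise"),
    "phone_call": ("phone", "open_dialer"),
}


@dataclass(frozen=True)
class CommandMap:
    """Symbol layouts of both displays and the primary appliance actions."""

    primary_layout: tuple[str, ...] = DEFAULT_PRIMARY_SYMBOLS
    secondary_layout: tuple[str, ...] = DEFAULT_SECONDARY_SYMBOLS
    primary_actions: dict = field(default_factory=lambda: dict(DEFAULT_PRIMARY_ACTIONS))
    phone_call_symbol: str = "phone_call"

    def __post_init__(self) -> None:
        if self.primary_layout.count(self.phone_call_symbol) != 1:
            raise ValueError("primary layout needs exactly one phone_call symbol")
        cells = set(self.secondary_layout)
        if not (_DIGITS <= cells and "call" in cells and "return" in cells):
            raise ValueError("secondary layout needs digits 0-9 plus call and return")
        if len(self.secondary_layout) != len(set(self.secondary_layout)):
            raise ValueError("secondary layout cells must be unique")

    @classmethod
    def load(cls, path: str | Path) -> "CommandMap":
        data = json.loads(Path(path).read_text())
        return cls(
            primary_layout=tuple(data["primary_layout"]),
            secondary_layout=tuple(data["secondary_layout"]),
            primary_actions={k: tuple(v) for k, v in data["primary_actions"].items()},
            phone_call_symbol=data.get("phone_call_symbol", "phone_call"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "primary_layout": list(self.primary_layout),
                    "secondary_layout": list(self.secondary_layout),
                    "primary_actions": {k: list(v) for k, v in self.primary_actions.items()},
                    "phone_call_symbol": self.phone_call_symbol,
                },
                indent=2,
            )
        )


@dataclass(frozen=True)
class HomeState:
    """Immutable snapshot of the home controller."""

    active_display: str = "primary_symbols"
    appliance_states: tuple = ()
    dial_buffer: str = ""
    call_active: bool = False
    action_log: tuple = ()

    def __post_init__(self) -> None:
        if not set(self.dial_buffer) <= _DIGITS:
            raise ValueError("dial_buffer may contain only digits")
        if self.call_active and self.active_display != "secondary_numbers":
            raise ValueError("an active call requires the secondary display")

    def appliances(self) -> dict:
        return dict(self.appliance_states)


def _log(state: HomeState, symbol: str, action: str, detail: str = "") -> tuple:
    entry = {
        "step": len(state.action_log),
        "display": state.active_display,
        "symbol": symbol,
        "action": action,
    }
    if detail:
        entry["detail"] = detail
    return state.action_log + (entry,)


def _apply_appliance(states: tuple, appliance: str, op: str) -> tuple:
    d = dict(states)
    if op == "toggle":
        d[appliance] = "on" if d.get(appliance, "off") == "off" else "off"
    elif op in ("+1", "-1"):
        d[appliance] = int(d.get(appliance, 0)) + (1 if op == "+1" else -1)
    else:
        d[appliance] = op
    return tuple(sorted(d.items()))


def apply_selection(state: HomeState, selected_symbol: int, cmap: CommandMap) -> HomeState:
    """Apply one decoded symbol selection and return the next state.

    Primary display: the phone_call symbol opens the dialer (secondary
    display, empty buffer); any other symbol emits its appliance action.
    Secondary display: a digit appends to the dial buffer; ``call``
    dials the buffer and marks the call active; ``return`` hangs up,
    clears the buffer, and restores the primary display.  While a call
    is active, further digit/call selections are logged as no-ops.
    """
    layout = (
        cmap.primary_layout
        if state.active_display == "primary_symbols"
        else cmap.secondary_layout
    )
    if not 0 <= selected_symbol < len(layout):
        raise IndexError(f"symbol index {selected_symbol} out of range for display")
    label = layout[selected_symbol]

    if state.active_display == "primary_symbols":
        if label == cmap.phone_call_symbol:
            return replace(
                state,
                active_display="secondary_numbers",
                dial_buffer="",
                action_log=_log(state, label, "open_dialer"),
            )
        appliance, op = cmap.primary_actions[label]
        new_states = _apply_appliance(state.appliance_states, appliance, op)
        detail = f"{appliance}={dict(new_states)[appliance]}"
        return replace(
            state,
            appliance_states=new_states,
            action_log=_log(state, label, f"{appliance}:{op}", detail),
        )

    # secondary display
    if label == "return":
        return replace(
            state,
            active_display="primary_symbols",
            dial_buffer="",
            call_active=False,
            action_log=_log(state, label, "hangup_and_return"),
        )
    if state.call_active:  # in-call: only return acts
        return replace(state, action_log=_log(state, label, "noop_in_call"))
    if label == "call":
        return replace(
            state,
            call_active=True,
            action_log=_log(state, label, "dial", state.dial_buffer),
        )
    return replace(
        state,
        dial_buffer=state.dial_buffer + label,
        action_log=_log(state, label, "append_digit", label),
    )


def replay(selections: Sequence[int], cmap: CommandMap | None = None) -> HomeState:
    """Replay a logged selection sequence from the initial state."""
    state = HomeState()
    cmap = cmap or CommandMap()
    for s in selections:
        state = apply_selection(state, s, cmap)
    return state


def write_action_log(state: HomeState, path: str | Path) -> None:
    """Dump the action log as JSON lines."""
    with open(path, "w") as fh:
        for entry in state.action_log:
            fh.write(json.dumps(entry) + "\n")
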