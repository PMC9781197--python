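"""Recording I/O: EDF export/import with a tab-separated event sidecar.

The writer emits plain EDF (fixed-width ASCII header, little-endian
int16 data records of one second each); no EDF-writing library is
bundled with the analysis stack, and the format is simple enough to
emit directly.  Reading goes through :func:`mne.io.read_raw_edf`, so
round-trips are independently checked against a mature EDF parser.
Signals are quantized to 16 bits over a symmetric per-channel physical
range; the final partial record is zero-padded, and the true sample
count is stored in the event sidecar so the reader can trim it.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import EEGRecording

__all__ = ["write_edf", "write_events", "read_recording", "save_recording", "load_recording"]


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: EEGRecording, path: str | Path) -> None:
    """Write the recording as an EDF file (16-bit quantization).

    One data record per second; the last record is zero-padded.  Each
    channel uses a symmetric physical range covering its extrema, so
    quantization error is at most range/65534 per sample.
    """
    fs = recording.sampling_rate
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    data = recording.samples
    n_ch, n_samp = data.shape
    n_records = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_records * spr))
    padded[:, :n_samp] = data

    phys_max = np.maximum(np.abs(padded).max(axis=1), 1e-3)
    dig_max, dig_min = 32767, -32767
    scaled = np.round(padded / phys_max[:, None] * dig_max).astype("<i2")

    header_bytes = 256 + 256 * n_ch
    with open(path, "wb") as fh:
        fh.write(_ascii("0", 8))
        fh.write(_ascii("X X X X", 80))  # local patient id (anonymous)
        fh.write(_ascii("Startdate X X X X", 80))
        fh.write(_ascii("01.01.00", 8))
        fh.write(_ascii("00.00.00", 8))
        fh.write(_ascii(header_bytes, 8))
        fh.write(_ascii("", 44))
        fh.write(_ascii(n_records, 8))
        fh.write(_ascii(1, 8))  # record duration, seconds
        fh.write(_ascii(n_ch, 4))
        for name in recording.channel_names:
            fh.write(_ascii(f"EEG {name}", 16))
        for _ in range(n_ch):
            fh.write(_ascii("AgAgCl electrode", 80))
        for _ in range(n_ch):
            fh.write(_ascii("uV", 8))
        for c in range(n_ch):
            fh.write(_ascii(f"{-phys_max[c]:.6g}"[:8], 8))
        for c in range(n_ch):
            fh.write(_ascii(f"{phys_max[c]:.6g}"[:8], 8))
        for _ in range(n_ch):
            fh.write(_ascii(dig_min, 8))
        for _ in range(n_ch):
            fh.write(_ascii(dig_max, 8))
        for _ in range(n_ch):
            fh.write(_ascii("", 80))  # prefiltering
        for _ in range(n_ch):
            fh.write(_ascii(spr, 8))
        for _ in range(n_ch):
            fh.write(_ascii("", 32))
        for r in range(n_records):
            fh.write(scaled[:, r * spr : (r + 1) * spr].tobytes())


def write_events(recording: EEGRecording, path: str | Path) -> None:
    """Write the event sidecar: onset_s, symbol_index, is_target.

    A leading comment line records the un-padded sample count so the EDF
    reader can trim the zero-padded final record.
    """
    df = pd.DataFrame(
        recording.events, columns=["onset_s", "symbol_index", "is_target"]
    )
    df["is_target"] = df["is_target"].astype(int)
    with open(path, "w") as fh:
        fh.write(f"# n_samples={recording.n_samples}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def save_recording(recording: EEGRecording, edf_path: str | Path, events_path: str | Path) -> None:
    write_edf(recording, edf_path)
    write_events(recording, events_path)


def read_recording(edf_path: str | Path, events_path: str | Path) -> EEGRecording:
    """Load an EDF + event-sidecar pair back into an :class:`EEGRecording`."""
    import mne

    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    samples = raw.get_data(units="uV")
    names = tuple(n.removeprefix("EEG ").strip() for n in raw.ch_names)

    n_samples = None
    with open(events_path) as fh:
        first = fh.readline()
        if first.startswith("# n_samples="):
            n_samples = int(first.split("=", 1)[1])
    df = pd.read_csv(events_path, sep="\t", comment="#", float_precision="round_trip")
    events = [
        (float(r.onset_s), int(r.symbol_index), bool(r.is_target))
        for r in df.itertuples()
    ]
    if n_samples is not None:
        samples = samples[:, :n_samples]
    return EEGRecording(
        samples=samples,
        sampling_rate=float(raw.info["sfreq"]),
        channel_names=names,
        events=events,
        meta={"source": str(edf_path)},
    )


load_recording = read_recording
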