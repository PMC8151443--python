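"""Minimal EDF (16-bit) writer for two-channel EEG recordings.

Only what the simulator needs: continuous signals, one-second data
records, physical dimension microvolts. Reading EDF goes through MNE
(:func:`sleepband.preprocess.read_recording`); this writer exists because
no installed library exports EDF.
"""

from __future__ import annotations

from datetime import datetime
from pathlib import Path

import numpy as np

from .preprocess import Recording

__all__ = ["write_edf"]


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r} ({width})")
    return b.ljust(width)


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a :class:`Recording` as EDF with 16-bit samples in µV.

    The sample rate must be an integer (samples per one-second data
    record). Amplitudes are scaled symmetrically to the signal's peak, so
    round-tripping is exact up to 16-bit quantization.
    """
    fs = recording.sample_rate
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sample rate")
    fs = int(fs)
    sig = recording.signal
    n_records = sig.shape[1] // fs
    sig = sig[:, : n_records * fs]

    peak = float(np.max(np.abs(sig))) if sig.size else 1.0
    phys = max(peak, 1e-6) * 1.0001
    dig_max, dig_min = 32767, -32768
    scale = dig_max / phys

    n_ch = 2
    header_bytes = 256 + 256 * n_ch
    now = datetime(2000, 1, 1)
    head = b"".join(
        [
            _field("0", 8),
            _field(f"X X X {recording.subject_id}"[:80], 80),
            _field("Startdate X X X X", 80),
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(str(header_bytes), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),  # record duration, seconds
            _field(str(n_ch), 4),
        ]
    )

    def per_channel(values: list[str], width: int) -> bytes:
        return b"".join(_field(v, width) for v in values)

    labels = [f"EEG {name}"[:16] for name in recording.channel_names]
    head += per_channel(labels, 16)
    head += per_channel(["" for _ in range(n_ch)], 80)  # transducer
    head += per_channel(["uV"] * n_ch, 8)
    head += per_channel([f"{-phys:.6g}"[:8]] * n_ch, 8)
    head += per_channel([f"{phys:.6g}"[:8]] * n_ch, 8)
    head += per_channel([str(dig_min)] * n_ch, 8)
    head += per_channel([str(dig_max)] * n_ch, 8)
    head += per_channel([""] * n_ch, 80)  # prefiltering
    head += per_channel([str(fs)] * n_ch, 8)
    head += per_channel([""] * n_ch, 32)  # reserved

    digital = np.clip(np.round(sig * scale), dig_min, dig_max).astype("<i2")
    # records: for each second, channel 1 block then channel 2 block
    blocks = digital.reshape(n_ch, n_records, fs).transpose(1, 0, 2)

    with open(path, "wb") as f:
        f.write(head)
        f.write(blocks.tobytes())
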