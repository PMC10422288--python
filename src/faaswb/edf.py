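"""Minimal plain-EDF (European Data Format) writer.

Writes the simplest widely readable dialect: classic EDF (not EDF+), 16-bit
samples, physical units microvolts, one data record per second.  Reading is
done elsewhere through :mod:`mne`; this module only needs to produce files
that any EDF reader accepts.

The fixed physical range ±3276.8/±3276.7 μV against the full 16-bit digital
range gives an exact 0.1 μV quantisation step, ample for scalp EEG.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

PHYS_MIN = -3276.8
PHYS_MAX = 3276.7
DIG_MIN = -32768
DIG_MAX = 32767
_SCALE = (PHYS_MAX - PHYS_MIN) / (DIG_MAX - DIG_MIN)  # exactly 0.1 μV/bit

#: Fixed start stamp so regenerated files are byte-identical under a seed.
DEFAULT_START = _dt.datetime(2023, 8, 7, 0, 0, 0)


def _field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field {value!r} exceeds {width} bytes")
    return b.ljust(width)


def write_edf(
    path: str | Path,
    data_uv: np.ndarray,
    fs: int,
    channel_names: list[str],
    patient_id: str = "X",
    recording_id: str = "X",
    start: _dt.datetime = DEFAULT_START,
) -> Path:
    """Write ``data_uv`` (channels × samples, microvolts) as a plain EDF file.

    The number of samples must be a whole number of seconds at ``fs`` since
    each data record spans exactly one second.  Values outside the ±3276.7 μV
    physical range are clipped.
    """
    path = Path(path)
    data_uv = np.atleast_2d(np.asarray(data_uv, dtype=float))
    n_ch, n_samp = data_uv.shape
    if n_ch != len(channel_names):
        raise ValueError("channel_names length does not match data rows")
    fs = int(fs)
    if fs <= 0 or n_samp % fs != 0:
        raise ValueError("recording must span a whole number of seconds")
    n_records = n_samp // fs

    header = b"".join(
        [
            _field("0", 8),
            _field(patient_id, 80),
            _field(recording_id, 80),
            _field(start.strftime("%d.%m.%y"), 8),
            _field(start.strftime("%H.%M.%S"), 8),
            _field(str(256 * (1 + n_ch)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),
            _field(str(n_ch), 4),
        ]
    )
    per_signal = b"".join(
        [
            b"".join(_field(name, 16) for name in channel_names),
            b"".join(_field("", 80) for _ in range(n_ch)),       # transducer
            b"".join(_field("uV", 8) for _ in range(n_ch)),
            b"".join(_field(str(PHYS_MIN), 8) for _ in range(n_ch)),
            b"".join(_field(str(PHYS_MAX), 8) for _ in range(n_ch)),
            b"".join(_field(str(DIG_MIN), 8) for _ in range(n_ch)),
            b"".join(_field(str(DIG_MAX), 8) for _ in range(n_ch)),
            b"".join(_field("", 80) for _ in range(n_ch)),       # prefilter
            b"".join(_field(str(fs), 8) for _ in range(n_ch)),   # samples/record
            b"".join(_field("", 32) for _ in range(n_ch)),
        ]
    )

    digital = np.rint(np.clip(data_uv, PHYS_MIN, PHYS_MAX) / _SCALE).astype("<i2")
    # records-major layout: for each second, each channel's fs samples
    records = digital.reshape(n_ch, n_records, fs).transpose(1, 0, 2)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        fh.write(records.tobytes())
    return path


def read_header_ids(path: str | Path) -> tuple[str, str]:
    """Return the (patient, recording) identification fields of an EDF file."""
    with open(path, "rb") as fh:
        head = fh.read(168)
    if len(head) < 168:
        raise ValueError(f"{path}: truncated EDF header")
    return head[8:88].decode("ascii").strip(), head[88:168].decode("ascii").strip()
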