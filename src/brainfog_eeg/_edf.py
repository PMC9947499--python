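"""Minimal EDF (European Data Format) writer.

Writes standard EDF: 256-byte fixed header, 256 bytes of per-signal header
fields, then contiguous int16 little-endian data records.  Each channel is
quantized to its own symmetric physical range, so the round-trip error is at
most one quantization step ``(pmax - pmin) / 65535``.

Only writing lives here; reading goes through mne's independent EDF reader.
The start date/time fields are fixed constants so that identical data
produces byte-identical files (reproducible run manifests).
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_edf", "edf_quantization_step"]


def _ascii(value: str, width: int) -> bytes:
    s = value[:width].ljust(width)
    b = s.encode("ascii")
    if len(b) != width:
        raise ValueError(f"field {value!r} not encodable in {width} ascii bytes")
    return b


def edf_quantization_step(data_row: np.ndarray) -> float:
    """The physical value of one digital step for a channel's data range."""
    pmax = float(np.max(np.abs(data_row)))
    pmax = pmax if pmax > 0 else 1.0
    return 2 * pmax / (32767 - (-32768))


def write_edf(
    path,
    data: np.ndarray,
    fs: float,
    channel_names: list[str],
    physical_dimension: str = "uV",
    patient_id: str = "X",
    recording_id: str = "synthetic",
) -> None:
    """Write ``(n_channels, n_samples)`` data in ``physical_dimension`` units.

    Record duration is 1 s when the sample count divides evenly by an
    integer sampling rate; otherwise the whole signal is stored as a single
    data record (valid EDF, handled by common readers).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (channels x samples)")
    n_channels, n_samples = data.shape
    if len(channel_names) != n_channels:
        raise ValueError("one channel name per data row required")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if n_samples == 0:
        raise ValueError("cannot write an empty recording")

    if float(fs).is_integer() and n_samples % int(fs) == 0:
        spr = int(fs)                      # samples per record
        n_records = n_samples // spr
        record_duration = "1"
    else:
        spr = n_samples
        n_records = 1
        record_duration = f"{n_samples / fs:.6g}"[:8]

    # per-channel symmetric physical range
    pmaxs = np.maximum(np.max(np.abs(data), axis=1), 1e-9)
    dmin, dmax = -32768, 32767

    header = b"".join([
        _ascii("0", 8),
        _ascii(patient_id, 80),
        _ascii(recording_id, 80),
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(str(256 * (n_channels + 1)), 8),
        _ascii("", 44),
        _ascii(str(n_records), 8),
        _ascii(record_duration, 8),
        _ascii(str(n_channels), 4),
    ])
    fields = [
        (16, [name for name in channel_names]),
        (80, ["" for _ in channel_names]),                      # transducer
        (8, [physical_dimension for _ in channel_names]),
        (8, [f"{-p:.6g}"[:8] for p in pmaxs]),                  # physical min
        (8, [f"{p:.6g}"[:8] for p in pmaxs]),                   # physical max
        (8, [str(dmin) for _ in channel_names]),
        (8, [str(dmax) for _ in channel_names]),
        (80, ["" for _ in channel_names]),                      # prefiltering
        (8, [str(spr) for _ in channel_names]),
        (32, ["" for _ in channel_names]),
    ]
    signal_header = b"".join(
        b"".join(_ascii(v, w) for v in values) for w, values in fields
    )

    # physical -> digital, channel-wise; the stated physical min/max are the
    # re-parsed header strings so the scaling a reader reconstructs is exact
    pmins_r = np.array([float(f"{-p:.6g}"[:8]) for p in pmaxs])
    pmaxs_r = np.array([float(f"{p:.6g}"[:8]) for p in pmaxs])
    gains = (dmax - dmin) / (pmaxs_r - pmins_r)
    digital = np.rint((data - pmins_r[:, None]) * gains[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(signal_header)
        for r in range(n_records):
            chunk = digital[:, r * spr:(r + 1) * spr]
            fh.write(chunk.tobytes())
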