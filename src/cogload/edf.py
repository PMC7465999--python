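"""Minimal European Data Format (EDF) writer and reader.

Supports the plain 16-bit EDF variant: one file holds several signals,
each with its own samples-per-record count, so mixed sampling rates
(e.g. 256 Hz EEG next to 32 Hz skin conductance) live in one file. This
is all the package needs to round-trip its own recordings; EDF+
annotations, discontinuous records and sub-second start times are out
of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EdfSignal", "write_edf", "read_edf"]

_HDR = 256  # bytes in the fixed part of the header


@dataclass
class EdfSignal:
    label: str
    sample_rate: float  # Hz; rate * record_duration must be an integer
    data: np.ndarray
    physical_dimension: str = ""


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def _num(x, width: int) -> bytes:
    s = f"{x:.10g}"[:width]
    return _field(s, width)


def write_edf(
    path,
    signals: list[EdfSignal],
    *,
    patient_id: str = "X",
    recording_id: str = "X",
    startdate: str = "01.01.00",
    starttime: str = "00.00.00",
    record_duration: float = 1.0,
) -> None:
    """Write signals to an EDF file, one data-record per second by default.

    Signals are linearly scaled to the int16 range; signals shorter than
    a whole number of records are edge-padded. All signals must span the
    same duration in seconds.
    """
    if not signals:
        raise ValueError("need at least one signal")
    durations = {round(len(s.data) / s.sample_rate, 6) for s in signals}
    if len(durations) != 1:
        raise ValueError(f"signals span different durations: {sorted(durations)}")
    total_s = durations.pop()
    n_records = int(np.ceil(total_s / record_duration))
    ns = len(signals)

    spr = []  # samples per record
    scaled = []
    phys = []
    for s in signals:
        k = s.sample_rate * record_duration
        if abs(k - round(k)) > 1e-9:
            raise ValueError(
                f"signal {s.label!r}: rate {s.sample_rate} Hz does not give an "
                f"integer sample count per {record_duration}-s record"
            )
        k = int(round(k))
        spr.append(k)
        x = np.asarray(s.data, dtype=float)
        need = n_records * k
        if x.size < need:  # edge-pad the final partial record
            x = np.concatenate([x, np.full(need - x.size, x[-1] if x.size else 0.0)])
        pmin, pmax = float(np.min(x)), float(np.max(x))
        if pmax <= pmin:
            pmax = pmin + 1.0
        phys.append((pmin, pmax))
        dig = np.round(
            (x - pmin) / (pmax - pmin) * (32767 - (-32768)) + (-32768)
        ).astype("<i2")
        scaled.append(dig)

    with open(path, "wb") as fh:
        fh.write(_field("0", 8))
        fh.write(_field(patient_id, 80))
        fh.write(_field(recording_id, 80))
        fh.write(_field(startdate, 8))
        fh.write(_field(starttime, 8))
        fh.write(_num(_HDR * (ns + 1), 8))
        fh.write(_field("", 44))
        fh.write(_num(n_records, 8))
        fh.write(_num(record_duration, 8))
        fh.write(_num(ns, 4))
        fh.write(b"".join(_field(s.label, 16) for s in signals))
        fh.write(b"".join(_field("", 80) for _ in signals))
        fh.write(b"".join(_field(s.physical_dimension, 8) for s in signals))
        fh.write(b"".join(_num(p[0], 8) for p in phys))
        fh.write(b"".join(_num(p[1], 8) for p in phys))
        fh.write(b"".join(_num(-32768, 8) for _ in signals))
        fh.write(b"".join(_num(32767, 8) for _ in signals))
        fh.write(b"".join(_field("", 80) for _ in signals))
        fh.write(b"".join(_num(k, 8) for k in spr))
        fh.write(b"".join(_field("", 32) for _ in signals))
        for rec in range(n_records):
            for dig, k in zip(scaled, spr):
                fh.write(dig[rec * k : (rec + 1) * k].tobytes())


def read_edf(path) -> list[EdfSignal]:
    """Read an EDF file written by :func:`write_edf` (or any plain EDF)."""
    with open(path, "rb") as fh:
        head = fh.read(_HDR)
        n_records = int(head[236:244].decode().strip())
        record_duration = float(head[244:252].decode().strip())
        ns = int(head[252:256].decode().strip())
        sig_head = fh.read(_HDR * ns)

        def col(offset: int, width: int) -> list[str]:
            base = offset * ns
            return [
                sig_head[base + i * width : base + (i + 1) * width].decode().strip()
                for i in range(ns)
            ]

        labels = col(0, 16)
        # field offsets within the per-signal header block, in bytes
        dims = [
            sig_head[(16 + 80) * ns + i * 8 : (16 + 80) * ns + (i + 1) * 8]
            .decode()
            .strip()
            for i in range(ns)
        ]

        def numcol(start: int) -> list[float]:
            return [
                float(sig_head[start * ns + i * 8 : start * ns + (i + 1) * 8].decode())
                for i in range(ns)
            ]

        pmin = numcol(16 + 80 + 8)
        pmax = numcol(16 + 80 + 8 + 8)
        dmin = numcol(16 + 80 + 8 + 8 + 8)
        dmax = numcol(16 + 80 + 8 + 8 + 8 + 8)
        spr = [int(v) for v in numcol(16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)]

        raw = np.frombuffer(fh.read(), dtype="<i2")

    rec_len = sum(spr)
    raw = raw[: n_records * rec_len].reshape(n_records, rec_len)
    out = []
    pos = 0
    for i in range(ns):
        dig = raw[:, pos : pos + spr[i]].reshape(-1).astype(float)
        pos += spr[i]
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        out.append(
            EdfSignal(
                label=labels[i],
                sample_rate=spr[i] / record_duration,
                data=(dig - dmin[i]) * gain + pmin[i],
                physical_dimension=dims[i],
            )
        )
    return out
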