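"""Minimal EDF (16-bit European Data Format) reader/writer.

Implements just enough of the EDF specification for round-tripping
multichannel recordings: fixed 256-byte main header, 256 bytes of
per-signal header fields, and int16 little-endian data records.  The
whole recording is stored as a single data record so that no padding is
required and ``read(write(x))`` returns exactly the written sample count.

Channel metadata that EDF has no field for (role, lead row, acquisition
scale) is carried in the 80-character transducer field as
``key=value;`` pairs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

# symmetric digital range: a physical value centred in its range maps to
# digital 0 exactly (one of the 2^16 codes is sacrificed)
_DIG_MIN = -32767
_DIG_MAX = 32767


class EDFError(ValueError):
    """Raised on malformed headers or out-of-range signal values."""


def _fmt8(x: float) -> str:
    """Format a number into at most 8 ASCII characters, EDF style.

    Fixed notation is preferred; exponent notation is used when the
    magnitude cannot be expressed in 8 characters otherwise.
    """
    for prec in range(8, -1, -1):
        s = f"{x:.{prec}g}"
        if len(s) <= 8 and "e" not in s and "E" not in s:
            return s
    for prec in range(2, -1, -1):
        s = f"{x:.{prec}e}"
        if len(s) <= 8:
            return s
    raise EDFError(f"cannot format {x!r} into 8 characters")


def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii")
    if len(b) > n:
        raise EDFError(f"field {s!r} exceeds {n} characters")
    return b.ljust(n)


@dataclass
class EdfSignal:
    label: str
    physical: np.ndarray  # physical units (whatever the caller uses)
    dimension: str = "uV"
    transducer: str = ""
    prefilter: str = ""
    phys_range: tuple[float, float] | None = field(default=None)


def write_edf(
    path: str | os.PathLike,
    signals: list[EdfSignal],
    sample_rate: float,
    patient_id: str = "X",
    recording_id: str = "recording",
) -> None:
    if not signals:
        raise EDFError("no signals to write")
    n_samples = {len(s.physical) for s in signals}
    if len(n_samples) != 1:
        raise EDFError("all signals must have the same length")
    n = n_samples.pop()
    if n == 0:
        raise EDFError("signals are empty")

    duration = n / sample_rate
    dur_str = _fmt8(duration)

    per_sig = []
    for sig in signals:
        x = np.asarray(sig.physical, dtype=float)
        if sig.phys_range is not None:
            lo, hi = sig.phys_range
            if x.min() < lo or x.max() > hi:
                raise EDFError(
                    f"signal {sig.label!r} exceeds declared physical range "
                    f"[{lo}, {hi}] (observed [{x.min():g}, {x.max():g}])"
                )
        else:
            lo, hi = float(x.min()), float(x.max())
            if lo == hi:  # flat signal: EDF needs phys_min < phys_max
                lo, hi = lo - 1.0, hi + 1.0
        # Round-trip consistency: scale from the *stored strings*.
        lo_s, hi_s = _fmt8(lo), _fmt8(hi)
        lo, hi = float(lo_s), float(hi_s)
        if lo >= hi:
            lo, hi = lo - 1.0, hi + 1.0
            lo_s, hi_s = _fmt8(lo), _fmt8(hi)
            lo, hi = float(lo_s), float(hi_s)
        gain = (hi - lo) / (_DIG_MAX - _DIG_MIN)
        dig = np.rint((x - lo) / gain) + _DIG_MIN
        dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")
        per_sig.append((sig, lo_s, hi_s, dig))

    ns = len(signals)
    header = b"".join(
        [
            _pad("0", 8),
            _pad(patient_id, 80),
            _pad(recording_id, 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (ns + 1)), 8),
            _pad("", 44),
            _pad("1", 8),  # one data record holds the whole session
            _pad(dur_str, 8),
            _pad(str(ns), 4),
        ]
    )
    fields: list[bytes] = []
    for width, getter in [
        (16, lambda t: t[0].label),
        (80, lambda t: t[0].transducer),
        (8, lambda t: t[0].dimension),
        (8, lambda t: t[1]),
        (8, lambda t: t[2]),
        (8, lambda t: str(_DIG_MIN)),
        (8, lambda t: str(_DIG_MAX)),
        (80, lambda t: t[0].prefilter),
        (8, lambda t: str(n)),
        (32, lambda t: ""),
    ]:
        for t in per_sig:
            fields.append(_pad(getter(t), width))

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(fields))
        for _, _, _, dig in per_sig:
            fh.write(dig.tobytes())


def read_edf(path: str | os.PathLike) -> tuple[list[EdfSignal], float]:
    """Read an EDF file written by :func:`write_edf` (single data record)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise EDFError("truncated EDF header")
        n_records = int(head[236:244].decode("ascii").strip())
        duration = float(head[244:252].decode("ascii").strip())
        ns = int(head[252:256].decode("ascii").strip())
        sig_head = fh.read(256 * ns)
        if len(sig_head) < 256 * ns:
            raise EDFError("truncated EDF signal header")

        def col(width: int, offset: int) -> list[str]:
            base = offset * ns
            return [
                sig_head[base + i * width : base + (i + 1) * width]
                .decode("ascii")
                .strip()
                for i in range(ns)
            ]

        # Offsets are cumulative byte offsets of each field block.
        labels = col(16, 0)
        transducers = [
            sig_head[16 * ns + i * 80 : 16 * ns + (i + 1) * 80].decode("ascii").strip()
            for i in range(ns)
        ]
        base = 16 * ns + 80 * ns
        dims = [sig_head[base + i * 8 : base + (i + 1) * 8].decode().strip() for i in range(ns)]
        base += 8 * ns
        pmin = [float(sig_head[base + i * 8 : base + (i + 1) * 8]) for i in range(ns)]
        base += 8 * ns
        pmax = [float(sig_head[base + i * 8 : base + (i + 1) * 8]) for i in range(ns)]
        base += 8 * ns
        dmin = [int(sig_head[base + i * 8 : base + (i + 1) * 8]) for i in range(ns)]
        base += 8 * ns
        dmax = [int(sig_head[base + i * 8 : base + (i + 1) * 8]) for i in range(ns)]
        base += 8 * ns + 80 * ns
        spr = [int(sig_head[base + i * 8 : base + (i + 1) * 8]) for i in range(ns)]

        signals: list[EdfSignal] = []
        out: list[np.ndarray] = []
        for rec in range(n_records):
            for i in range(ns):
                raw = np.frombuffer(fh.read(2 * spr[i]), dtype="<i2")
                gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
                phys = (raw.astype(float) - dmin[i]) * gain + pmin[i]
                if rec == 0:
                    out.append(phys)
                else:  # pragma: no cover - writer emits one record
                    out[i] = np.concatenate([out[i], phys])

    n = len(out[0])
    fs = n_records * n / duration if duration > 0 else 0.0
    if abs(fs - round(fs)) < 0.01:
        fs = float(round(fs))
    for i in range(ns):
        signals.append(
            EdfSignal(label=labels[i], physical=out[i], dimension=dims[i], transducer=transducers[i])
        )
    return signals, fs


def encode_transducer(**kv: object) -> str:
    return ";".join(f"{k}={v}" for k, v in kv.items())


def decode_transducer(s: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in s.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out
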