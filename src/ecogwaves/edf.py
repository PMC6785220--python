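"""Minimal EDF (European Data Format) reader/writer.

Supports the plain EDF subset this package needs: identical sampling rate
across channels, 16-bit samples, one or more fixed-duration data records.
Physical scaling is symmetric per channel, so round-trip error is bounded
by half a quantization step (range / 2^16).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np

_DIG_MIN = -32768
_DIG_MAX = 32767


def _fixed(text: str, width: int) -> bytes:
    b = str(text)[:width].encode("ascii")
    return b.ljust(width)


@dataclass
class EdfData:
    """In-memory contents of an EDF file."""

    signals: np.ndarray  # (n_channels, n_samples), physical units
    sample_rate: float
    labels: list[str]


def write_edf(path, signals: np.ndarray, sample_rate: float, labels=None) -> None:
    """Write a (n_channels, n_samples) float array as 16-bit EDF.

    Uses 1-second data records when the sample count divides evenly,
    otherwise a single record spanning the whole signal.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2:
        raise ValueError("signals must be 2-D (channels x samples)")
    n_ch, n_samp = signals.shape
    if n_samp == 0:
        raise ValueError("empty signal")
    if labels is None:
        labels = [f"ch{i:03d}" for i in range(n_ch)]
    if len(labels) != n_ch:
        raise ValueError("labels/channels length mismatch")

    spr = int(round(sample_rate))
    if spr > 0 and n_samp % spr == 0 and abs(sample_rate - spr) < 1e-9:
        n_records, samples_per_record, record_dur = n_samp // spr, spr, 1.0
    else:
        n_records, samples_per_record, record_dur = 1, n_samp, n_samp / sample_rate

    # symmetric physical range per channel; avoid zero span.  The range is
    # rounded to its 8-char header representation BEFORE quantizing so the
    # reader reconstructs with the same gain.
    span = np.maximum(np.abs(signals).max(axis=1), 1e-12)

    def _rounded_span(s: float) -> float:
        cand = float(f"{s:.6g}"[:8])
        if cand < s:  # rounding down would clip the extremes
            cand = float(f"{s * 1.01:.6g}"[:8])
        return cand

    span = np.array([_rounded_span(s) for s in span])
    gain = 2.0 * span / (_DIG_MAX - _DIG_MIN)
    digital = np.clip(
        np.round((signals + span[:, None]) / gain[:, None]) + _DIG_MIN,
        _DIG_MIN, _DIG_MAX,
    ).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header_bytes = 256 * (1 + n_ch)
    head = b"".join(
        [
            _fixed("0", 8),
            _fixed("X X X X", 80),
            _fixed("Startdate X X X X", 80),
            _fixed(now.strftime("%d.%m.%y"), 8),
            _fixed(now.strftime("%H.%M.%S"), 8),
            _fixed(str(header_bytes), 8),
            _fixed("", 44),
            _fixed(str(n_records), 8),
            _fixed(f"{record_dur:.6f}"[:8], 8),
            _fixed(str(n_ch), 4),
        ]
    )
    sig_head = b"".join(
        [
            b"".join(_fixed(lab, 16) for lab in labels),
            b"".join(_fixed("ECoG", 80) for _ in range(n_ch)),
            b"".join(_fixed("uV", 8) for _ in range(n_ch)),
            b"".join(_fixed(f"{-s:.6g}"[:8], 8) for s in span),
            b"".join(_fixed(f"{s:.6g}"[:8], 8) for s in span),
            b"".join(_fixed(str(_DIG_MIN), 8) for _ in range(n_ch)),
            b"".join(_fixed(str(_DIG_MAX), 8) for _ in range(n_ch)),
            b"".join(_fixed("", 80) for _ in range(n_ch)),
            b"".join(_fixed(str(samples_per_record), 8) for _ in range(n_ch)),
            b"".join(_fixed("", 32) for _ in range(n_ch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(head)
        fh.write(sig_head)
        # records are channel-blocked: all samples of ch0, then ch1, ...
        rec = digital.reshape(n_ch, n_records, samples_per_record)
        rec = np.ascontiguousarray(np.transpose(rec, (1, 0, 2)))
        fh.write(rec.tobytes())


def read_edf(path) -> EdfData:
    """Read an EDF file written by :func:`write_edf` (plain EDF subset)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError("truncated EDF header")
        n_records = int(head[236:244].decode().strip())
        record_dur = float(head[244:252].decode().strip())
        n_ch = int(head[252:256].decode().strip())
        sig = fh.read(256 * n_ch)
        labels = [sig[16 * i : 16 * (i + 1)].decode().strip() for i in range(n_ch)]
        off = 16 * n_ch + 80 * n_ch + 8 * n_ch
        pmin = np.array([float(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(n_ch)])
        off += 8 * n_ch
        pmax = np.array([float(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(n_ch)])
        off += 8 * n_ch
        dmin = np.array([float(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(n_ch)])
        off += 8 * n_ch
        dmax = np.array([float(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(n_ch)])
        off += 8 * n_ch + 80 * n_ch
        spr = np.array([int(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(n_ch)])
        if not np.all(spr == spr[0]):
            raise ValueError("heterogeneous sampling rates not supported")
        spr0 = int(spr[0])
        raw = np.frombuffer(fh.read(n_records * n_ch * spr0 * 2), dtype="<i2")

    raw = raw.reshape(n_records, n_ch, spr0)
    digital = np.transpose(raw, (1, 0, 2)).reshape(n_ch, n_records * spr0).astype(float)
    gain = (pmax - pmin) / (dmax - dmin)
    physical = (digital - dmin[:, None]) * gain[:, None] + pmin[:, None]
    return EdfData(signals=physical, sample_rate=spr0 / record_dur, labels=labels)
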