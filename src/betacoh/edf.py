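"""EDF+ reading and writing for synthetic and external recordings.

Implements the continuous EDF+ layout directly: a 256-byte fixed header,
256 bytes of per-signal headers, then 1 s data records of little-endian
int16 samples.  Movement onsets are stored as timestamped annotation lists
(TALs) in a dedicated "EDF Annotations" signal, one annotation per onset
with the text ``movement``.  Samples are quantized to the int16 range
between per-channel physical extremes, so a write/read roundtrip is exact
to one quantization step.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .containers import ContinuousRecording

_ANNOTATION_LABEL = "EDF Annotations"
_FORCE_LABEL = "Force"
_EVENT_TEXT = "movement"


def _fit8(v: float) -> str:
    """Format a float into <= 8 ASCII chars (EDF header numeric field)."""
    for fmt in (".6g", ".5g", ".4g", ".3g", ".2g"):
        s = format(v, fmt)
        if len(s) <= 8:
            return s
    return format(v, ".1g")[:8]


def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii")[:n]
    return b + b" " * (n - len(b))


def _annotation_records(
    n_records: int, record_dur: float, onset_times: np.ndarray
) -> list[bytes]:
    """One TAL byte string per record: the mandatory timekeeping TAL plus
    any movement annotations whose onset falls inside that record."""
    recs = []
    for r in range(n_records):
        t0 = r * record_dur
        chunk = f"+{t0:g}\x14\x14\x00".encode("ascii")
        for t in onset_times:
            if t0 <= t < t0 + record_dur:
                chunk += f"+{t:.4f}\x14{_EVENT_TEXT}\x14\x00".encode("ascii")
        recs.append(chunk)
    return recs


def write_edf(rec: ContinuousRecording, path) -> None:
    """Write a recording (EEG channels + optional force + onsets) to EDF+C.

    EEG channels carry physical dimension ``uV``; the force channel, if
    present, is appended with label ``Force`` and dimension ``N``.
    """
    path = Path(path)
    rate = rec.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(rate))  # samples per 1 s record per signal
    n_records = int(np.ceil(rec.n_samples / spr))

    signals = [rec.data[i] for i in range(rec.n_channels)]
    labels = list(rec.ch_names)
    dims = ["uV"] * rec.n_channels
    if rec.force is not None:
        signals.append(np.asarray(rec.force, dtype=float))
        labels.append(_FORCE_LABEL)
        dims.append("N")

    onset_times = rec.onset_times_s()
    ann_recs = _annotation_records(n_records, 1.0, onset_times)
    ann_spr = max(16, (max(len(b) for b in ann_recs) + 1) // 2 + 1)

    ns = len(signals) + 1  # + annotations signal
    phys = []
    digitized = []
    for sig in signals:
        lo, hi = float(np.min(sig)), float(np.max(sig))
        if hi <= lo:
            hi = lo + 1.0
        margin = 0.001 * (hi - lo)
        pmin = float(_fit8(lo - margin))
        pmax = float(_fit8(hi + margin))
        if pmax <= pmin:
            pmax = pmin + 1.0
        phys.append((pmin, pmax))
        scale = (pmax - pmin) / 65535.0
        d = np.round((sig - pmin) / scale - 32768.0)
        padded = np.full(n_records * spr, -32768, dtype=np.int16)
        padded[: len(sig)] = np.clip(d, -32768, 32767).astype(np.int16)
        digitized.append(padded)

    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate X X X X", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (1 + ns)), 8),
        _pad("EDF+C", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(ns), 4),
    ])

    def col(values, width):
        return b"".join(_pad(v, width) for v in values)

    all_labels = labels + [_ANNOTATION_LABEL]
    header += col(all_labels, 16)
    header += col([""] * ns, 80)  # transducer
    header += col(dims + [""], 8)
    header += col([_fit8(p[0]) for p in phys] + ["-1"], 8)
    header += col([_fit8(p[1]) for p in phys] + ["1"], 8)
    header += col(["-32768"] * len(signals) + ["-32768"], 8)
    header += col(["32767"] * len(signals) + ["32767"], 8)
    header += col([""] * ns, 80)  # prefiltering
    header += col([str(spr)] * len(signals) + [str(ann_spr)], 8)
    header += col([""] * ns, 32)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for d in digitized:
                fh.write(d[r * spr : (r + 1) * spr].tobytes())
            ann = ann_recs[r].ljust(2 * ann_spr, b"\x00")[: 2 * ann_spr]
            fh.write(ann)


def _parse_tals(raw: bytes) -> list[float]:
    times = []
    for tal in raw.split(b"\x00"):
        if not tal:
            continue
        fields = tal.split(b"\x14")
        if len(fields) < 2 or not any(f.strip() for f in fields[1:]):
            continue  # timekeeping TAL, no annotation text
        stamp = fields[0].split(b"\x15")[0]
        try:
            times.append(float(stamp))
        except ValueError:
            continue
    return times


def read_edf(path) -> ContinuousRecording:
    """Read an EDF/EDF+ file written by :func:`write_edf`.

    Signals come back in physical units; a ``Force`` signal is split out as
    the force channel and annotations become the onset list.  Missing files
    raise ``FileNotFoundError`` explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        n_records = int(head[236:244].decode().strip())
        record_dur = float(head[244:252].decode().strip())
        ns = int(head[252:256].decode().strip())
        sig_head = fh.read(256 * ns)
        labels = _col(sig_head, ns, 0, 16)
        # offsets in bytes within the per-signal header block
        # per-signal byte offsets: label 0, transducer 16, dim 96, then the
        # four 8-byte numeric columns, prefiltering 136, samples/record 216
        pmin = [float(v) for v in _col(sig_head, ns, 104, 8)]
        pmax = [float(v) for v in _col(sig_head, ns, 112, 8)]
        dmin = [float(v) for v in _col(sig_head, ns, 120, 8)]
        dmax = [float(v) for v in _col(sig_head, ns, 128, 8)]
        spr = [int(v) for v in _col(sig_head, ns, 216, 8)]

        chunks = [[] for _ in range(ns)]
        for _ in range(n_records):
            for k in range(ns):
                raw = fh.read(2 * spr[k])
                chunks[k].append(raw)

    onset_times: list[float] = []
    sigs = {}
    rate = None
    for k, lab in enumerate(labels):
        raw = b"".join(chunks[k])
        if lab == _ANNOTATION_LABEL:
            onset_times = _parse_tals(raw)
            continue
        d = np.frombuffer(raw, dtype="<i2").astype(np.float64)
        scale = (pmax[k] - pmin[k]) / (dmax[k] - dmin[k])
        sigs[lab] = pmin[k] + (d - dmin[k]) * scale
        rate = spr[k] / record_dur

    force = sigs.pop(_FORCE_LABEL, None)
    ch_names = [l for l in labels if l in sigs]
    data = np.stack([sigs[l] for l in ch_names])
    onsets = (
        np.round(np.asarray(onset_times) * rate).astype(np.int64)
        if onset_times else None
    )
    return ContinuousRecording(
        data=data, rate=rate, ch_names=ch_names, force=force, onsets=onsets,
    )


def _col(sig_head: bytes, ns: int, offset: int, width: int) -> list[str]:
    base = offset * ns
    return [
        sig_head[base + k * width : base + (k + 1) * width].decode().strip()
        for k in range(ns)
    ]
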