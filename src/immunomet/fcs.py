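"""Minimal FCS 3.0/3.1 list-mode reader and writer.

Supports the subset of the standard that flow instruments emit for unmixed
single-cell event data: a single DATA segment, ``$DATATYPE F`` (32-bit IEEE
float) or ``D`` (64-bit), little- or big-endian ``$BYTEORD``, list mode.
Analysis segments and multi-dataset files are ignored. The writer emits
FCS 3.0 float32 little-endian files and exists chiefly so synthetic fixtures
can be round-tripped through the same path real acquisitions take.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FCSFormatError", "read_fcs", "write_fcs"]

_DELIM = "/"


class FCSFormatError(ValueError):
    """Raised when a file does not parse as FCS; carries the byte offset."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (byte offset {offset})"
        super().__init__(message)
        self.offset = offset


def _parse_text_segment(raw: bytes, start: int) -> dict[str, str]:
    text = raw.decode("utf-8", errors="replace")
    if not text:
        raise FCSFormatError("empty TEXT segment", start)
    delim = text[0]
    # Split on the delimiter; the standard escapes a literal delimiter by
    # doubling it, which we honour by re-joining empty splits.
    parts = text[1:].split(delim)
    fields: list[str] = []
    buf = ""
    i = 0
    while i < len(parts):
        buf += parts[i]
        if i + 1 < len(parts) and parts[i + 1] == "" and i + 2 < len(parts):
            buf += delim  # escaped delimiter
            parts[i + 1] = "\x00skip"
            i += 1
            continue
        fields.append(buf)
        buf = ""
        i += 1
    fields = [f for f in fields if f != "\x00skip"]
    if fields and fields[-1] == "":
        fields = fields[:-1]
    if len(fields) % 2:
        raise FCSFormatError("odd number of TEXT keyword fields", start)
    return {fields[i].strip().upper(): fields[i + 1] for i in range(0, len(fields), 2)}


def read_fcs(path: str | Path) -> tuple[dict[str, str], pd.DataFrame]:
    """Read an FCS file.

    Returns ``(keywords, events)`` where *events* is a DataFrame with one row
    per event and one column per parameter, named from ``$PnS`` when present
    else ``$PnN``.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 58:
        raise FCSFormatError("file too short for an FCS header", 0)
    version = raw[0:6].decode("ascii", errors="replace")
    if not version.startswith("FCS3"):
        raise FCSFormatError(f"unsupported FCS version {version!r}", 0)

    def _offset(lo: int, hi: int) -> int:
        field = raw[lo:hi].decode("ascii", errors="replace").strip()
        try:
            return int(field) if field else 0
        except ValueError as exc:
            raise FCSFormatError(f"malformed header offset {field!r}", lo) from exc

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)
    if text_end <= text_start:
        raise FCSFormatError("TEXT segment offsets invalid", 10)
    kw = _parse_text_segment(raw[text_start : text_end + 1], text_start)
    # FCS3.x allows DATA offsets to live in TEXT when they overflow the header
    if data_start == 0 and "$BEGINDATA" in kw:
        data_start, data_end = int(kw["$BEGINDATA"]), int(kw["$ENDDATA"])

    n_par = int(kw.get("$PAR", 0))
    n_events = int(kw.get("$TOT", 0))
    dtype_code = kw.get("$DATATYPE", "F").upper()
    if dtype_code not in ("F", "D"):
        raise FCSFormatError(f"unsupported $DATATYPE {dtype_code!r}", text_start)
    mode = kw.get("$MODE", "L").upper()
    if mode != "L":
        raise FCSFormatError(f"unsupported $MODE {mode!r} (list mode only)", text_start)
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    np_dtype = np.dtype(("<" if little else ">") + ("f4" if dtype_code == "F" else "f8"))

    itemsize = np_dtype.itemsize
    expected = n_par * n_events * itemsize
    blob = raw[data_start : data_start + expected]
    if len(blob) != expected:
        raise FCSFormatError(
            f"DATA segment truncated: expected {expected} bytes, got {len(blob)}",
            data_start,
        )
    values = np.frombuffer(blob, dtype=np_dtype).reshape(n_events, n_par)
    names = []
    for i in range(1, n_par + 1):
        names.append(kw.get(f"$P{i}S") or kw.get(f"$P{i}N") or f"P{i}")
    return kw, pd.DataFrame(values.astype(np.float64), columns=names)


def write_fcs(path: str | Path, events: pd.DataFrame, extra_keywords: dict[str, str] | None = None) -> None:
    """Write a float32 little-endian FCS 3.0 list-mode file."""
    events = events.astype(np.float32)
    n_events, n_par = events.shape
    kw: dict[str, str] = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(events.columns, start=1):
        kw[f"$P{i}N"] = str(name)
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = str(int(max(1.0, float(np.nanmax(events[name])) if n_events else 1.0)) + 1)
    if extra_keywords:
        kw.update(extra_keywords)

    data = events.to_numpy(dtype="<f4").tobytes()
    header_len = 58
    # Fixed-point pass: TEXT length depends on the offsets written inside it.
    text_start = header_len
    text_len = 0
    text = b""
    for _ in range(5):
        data_start = text_start + text_len
        data_end = data_start + len(data) - 1
        kw["$BEGINDATA"] = str(data_start)
        kw["$ENDDATA"] = str(data_end)
        pieces = [_DELIM]
        for k, v in kw.items():
            pieces.append(f"{k}{_DELIM}{v}{_DELIM}")
        text = "".join(pieces).encode("ascii")
        if len(text) == text_len:
            break
        text_len = len(text)
    text_end = text_start + len(text) - 1
    data_start = text_start + len(text)
    data_end = data_start + len(data) - 1

    def _fmt(n: int) -> bytes:
        s = str(n)
        if len(s) > 8:
            s = "0"  # too large for the header; the TEXT copy governs
        return s.rjust(8).encode("ascii")

    header = b"FCS3.0    " + _fmt(text_start) + _fmt(text_end)
    header += _fmt(data_start if data_end <= 99_999_999 else 0)
    header += _fmt(data_end if data_end <= 99_999_999 else 0)
    header += _fmt(0) + _fmt(0)
    assert len(header) == header_len, len(header)
    Path(path).write_bytes(header + text + data)
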