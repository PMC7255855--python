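"""Minimal reader (and fixture writer) for FCS 3.0/3.1 cytometry files.

Covers the common case produced by acquisition software: list-mode
(``$MODE=L``) data with a single float (``$DATATYPE=F``/``D``) or
fixed-width integer (``I``) type and a uniform byte order.  Delimiter
escaping inside TEXT values (doubled delimiters) is not interpreted —
keyword values containing the delimiter itself are not supported.

``write_fcs`` emits a well-formed single-segment FCS 3.1 file and exists to
build synthetic fixtures; it is not a general-purpose converter.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np

__all__ = ["read_fcs", "write_fcs", "FcsError"]


class FcsError(ValueError):
    """Raised on malformed or unsupported FCS input."""


def _parse_text(segment: bytes) -> dict[str, str]:
    if not segment:
        raise FcsError("empty TEXT segment")
    delim = segment[0:1]
    parts = segment[1:].split(delim)
    if parts and parts[-1] == b"":
        parts = parts[:-1]
    if len(parts) % 2 != 0:
        raise FcsError("TEXT segment has an odd number of delimited tokens")
    out: dict[str, str] = {}
    for i in range(0, len(parts), 2):
        key = parts[i].decode("latin-1").strip().upper()
        out[key] = parts[i + 1].decode("latin-1")
    return out


def read_fcs(
    path: str | os.PathLike, channels: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Read the event matrix of an FCS 3.0/3.1 file.

    Parameters
    ----------
    channels
        Channel names to extract, matched against the short name ($PnN)
        first, then the description ($PnS).  The returned columns follow
        the *requested* order.  ``None`` returns all channels in file order.

    Returns
    -------
    (events, names) : events is a float matrix with one row per event;
    names are the short names of the returned channels.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    version = raw[0:6].decode("latin-1", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FcsError(f"unsupported FCS version {version!r} (need FCS3.0/3.1)")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
        data_start = int(raw[26:34])
        data_end = int(raw[34:42])
    except ValueError as e:
        raise FcsError(f"malformed FCS header offsets: {e}") from None

    text = _parse_text(raw[text_start : text_end + 1])
    # data offsets of 0 in the header mean "see TEXT keywords"
    if data_start == 0:
        data_start = int(text.get("$BEGINDATA", 0))
    if data_end == 0:
        data_end = int(text.get("$ENDDATA", 0))

    if text.get("$MODE", "L").upper() != "L":
        raise FcsError("only list-mode ($MODE=L) FCS files are supported")
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    dtype_code = text.get("$DATATYPE", "F").upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"

    names = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    descs = [text.get(f"$P{i}S", "") for i in range(1, n_par + 1)]
    bits = [int(text.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]

    if dtype_code == "F":
        if any(b != 32 for b in bits):
            raise FcsError("$DATATYPE=F requires 32-bit parameters")
        dt = np.dtype(endian + "f4")
    elif dtype_code == "D":
        if any(b != 64 for b in bits):
            raise FcsError("$DATATYPE=D requires 64-bit parameters")
        dt = np.dtype(endian + "f8")
    elif dtype_code == "I":
        widths = set(bits)
        if len(widths) != 1 or bits[0] not in (8, 16, 32):
            raise FcsError("$DATATYPE=I requires uniform 8/16/32-bit parameters")
        dt = np.dtype(endian + f"u{bits[0] // 8}")
    else:
        raise FcsError(f"unsupported $DATATYPE {dtype_code!r}")

    blob = raw[data_start : data_end + 1]
    need = n_tot * n_par * dt.itemsize
    if len(blob) < need:
        raise FcsError(
            f"DATA segment holds {len(blob)} bytes, need {need} for "
            f"{n_tot} events x {n_par} parameters"
        )
    events = (
        np.frombuffer(blob[:need], dtype=dt).reshape(n_tot, n_par).astype(np.float64)
    )

    if channels is None:
        return events, names

    cols: list[int] = []
    for ch in channels:
        if ch in names:
            cols.append(names.index(ch))
        elif ch in descs:
            cols.append(descs.index(ch))
        else:
            raise FcsError(
                f"unknown channel {ch!r}; available short names: {names}, "
                f"descriptions: {[d for d in descs if d]}"
            )
    return events[:, cols], [names[c] for c in cols]


def write_fcs(
    path: str | os.PathLike,
    events: np.ndarray,
    names: Sequence[str],
    descriptions: Sequence[str] | None = None,
) -> None:
    """Write a synthetic single-dataset FCS 3.1 file (float32, little-endian)."""
    events = np.asarray(events, dtype=np.float32)
    n_tot, n_par = events.shape
    if len(names) != n_par:
        raise FcsError("one channel name per column required")
    descriptions = list(descriptions) if descriptions else [""] * n_par

    kw: list[tuple[str, str]] = [
        ("$MODE", "L"),
        ("$DATATYPE", "F"),
        ("$BYTEORD", "1,2,3,4"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
        ("$NEXTDATA", "0"),
    ]
    for i, (nm, ds) in enumerate(zip(names, descriptions), start=1):
        kw.append((f"$P{i}N", nm))
        if ds:
            kw.append((f"$P{i}S", ds))
        kw.append((f"$P{i}B", "32"))
        kw.append((f"$P{i}E", "0,0"))
        kw.append((f"$P{i}R", str(int(np.ceil(max(1.0, float(events[:, i - 1].max(initial=0.0))))))))

    delim = "/"
    text = delim + delim.join(f"{k}{delim}{v}" for k, v in kw) + delim
    header_len = 58
    text_start = header_len
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + events.nbytes - 1
    header = (
        b"FCS3.1    "
        + f"{text_start:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + f"{data_start:>8d}".encode()
        + f"{data_end:>8d}".encode()
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    assert len(header) == header_len
    payload = header + text.encode("latin-1") + events.tobytes()
    with open(path, "wb") as fh:
        fh.write(payload)
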