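"""Event-table file I/O: minimal FCS 3.1 and CSV readers/writers.

Writes list-mode FCS 3.1 with single-precision float data ($DATATYPE F,
$MODE L, little-endian $BYTEORD), channel names in $PnN, and reads the
same subset back. Only the features of the standard that this pipeline
produces are supported (one dataset per file, no analysis segment, no
supplemental text). CSV event tables carry one header row of channel
names plus an ``is_bead`` flag column; FCS files carry channel values
only and the bead flag is re-derived by the bead scatter gate on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import PANEL_CHANNELS, FluorModel

__all__ = ["write_events", "read_events", "identify_beads"]

_DELIM = b"/"


def _text_segment(keywords: dict[str, str]) -> bytes:
    parts = [b""]
    for k, v in keywords.items():
        parts.append(k.encode("ascii"))
        parts.append(str(v).encode("ascii"))
    parts.append(b"")
    return _DELIM.join(parts)


def write_fcs(events, path) -> None:
    """Write an EventTable (cells and beads alike) as FCS 3.1."""
    data = events.data
    if data.columns.duplicated().any():
        raise ValueError("channel-name collision in event table")
    n_par = data.shape[1]
    n_tot = len(data)
    arr = np.ascontiguousarray(data.to_numpy(dtype="<f4"))
    payload = arr.tobytes()

    # offsets are written as fixed 12-digit zero-padded integers so that
    # substituting the real values cannot change the TEXT segment length
    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
        "$BEGINDATA": "0" * 12, "$ENDDATA": "0" * 12,
        "$BYTEORD": "1,2,3,4", "$DATATYPE": "F", "$MODE": "L",
        "$NEXTDATA": "0", "$PAR": str(n_par), "$TOT": str(n_tot),
    }
    for i, name in enumerate(data.columns, start=1):
        keywords[f"$P{i}N"] = str(name)
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        col = arr[:, i - 1]
        keywords[f"$P{i}R"] = str(int(np.ceil(col.max())) + 1 if n_tot else 1024)

    header_len = 58
    text_start = header_len
    text_end = text_start + len(_text_segment(keywords)) - 1
    data_start = text_end + 1
    data_end = data_start + len(payload) - 1 if payload else 0
    keywords["$BEGINDATA"] = f"{data_start:012d}"
    keywords["$ENDDATA"] = f"{data_end:012d}"
    text = _text_segment(keywords)
    assert len(text) == text_end - text_start + 1

    header = (b"FCS3.1    "
              + f"{text_start:8d}".encode() + f"{text_end:8d}".encode()
              + (f"{data_start:8d}".encode() if data_start <= 99_999_999 else b"       0")
              + (f"{data_end:8d}".encode() if 0 <= data_end <= 99_999_999 else b"       0")
              + f"{0:8d}".encode() + f"{0:8d}".encode())
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(payload)


def _parse_text(raw: bytes) -> dict[str, str]:
    delim = raw[:1].decode("ascii")
    fields = raw.decode("ascii").split(delim)[1:-1]
    return {fields[i]: fields[i + 1] for i in range(0, len(fields) - 1, 2)}


def read_fcs(path, panel: str, sample_id: str | None = None,
             fluor: FluorModel | None = None):
    """Read an FCS 3.1 file written by :func:`write_fcs`.

    The bead flag is reconstructed with :func:`identify_beads` when the
    panel's channels include SSC-A; pass ``fluor`` to override the bead
    gate threshold.
    """
    from .cyto_gating import EventTable

    raw = Path(path).read_bytes()
    version = raw[:6].decode("ascii")
    if not version.startswith("FCS3"):
        raise ValueError(f"unsupported FCS version {version!r}")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    kw = _parse_text(raw[text_start:text_end + 1])
    if kw.get("$DATATYPE") != "F" or kw.get("$MODE") != "L":
        raise ValueError("only list-mode float FCS data is supported")
    n_par, n_tot = int(kw["$PAR"]), int(kw["$TOT"])
    names = [kw[f"$P{i}N"] for i in range(1, n_par + 1)]
    data_start = int(kw["$BEGINDATA"])
    data_end = int(kw["$ENDDATA"])
    order = "<" if kw.get("$BYTEORD", "1,2,3,4") == "1,2,3,4" else ">"
    arr = np.frombuffer(raw[data_start:data_end + 1], dtype=f"{order}f4")
    arr = arr.reshape(n_tot, n_par) if n_tot else np.empty((0, n_par), dtype="f4")
    df = pd.DataFrame(arr.astype("float32"), columns=names)
    table = EventTable(sample_id or Path(path).stem, panel, df)
    table.is_bead = identify_beads(table, fluor)
    return table


def identify_beads(events, fluor: FluorModel | None = None) -> np.ndarray:
    """Bead gate: count beads sit far above cells on side scatter."""
    fluor = fluor or FluorModel()
    if "SSC-A" not in events.data.columns:
        return np.zeros(len(events.data), dtype=bool)
    return events.data["SSC-A"].to_numpy(dtype=float) > fluor.bead_gate_ssc


def write_csv(events, path) -> None:
    if events.data.columns.duplicated().any():
        raise ValueError("channel-name collision in event table")
    df = events.data.copy()
    df["is_bead"] = events.is_bead.astype(int)
    df.to_csv(path, index=False)


def read_csv(path, panel: str, sample_id: str | None = None):
    from .cyto_gating import EventTable

    df = pd.read_csv(path)
    is_bead = None
    if "is_bead" in df.columns:
        is_bead = df.pop("is_bead").to_numpy(dtype=bool)
    df = df.astype("float32")
    return EventTable(sample_id or Path(path).stem, panel, df, is_bead=is_bead)


def write_events(events, path, format: str = "csv") -> None:
    """Write one event table in the requested format (``fcs`` or ``csv``)."""
    if format == "fcs":
        write_fcs(events, path)
    elif format == "csv":
        write_csv(events, path)
    else:
        raise ValueError(f"unknown event-table format {format!r}")


def read_events(path, panel: str, format: str | None = None,
                sample_id: str | None = None, fluor: FluorModel | None = None):
    if format is None:
        format = "fcs" if str(path).lower().endswith(".fcs") else "csv"
    if format == "fcs":
        return read_fcs(path, panel, sample_id, fluor)
    if format == "csv":
        return read_csv(path, panel, sample_id)
    raise ValueError(f"unknown event-table format {format!r}")
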