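"""FCS 3.1 reading and writing for float list-mode data, plus label sidecars.

The writer emits the minimal standard-conformant subset used by synthetic
benchmark files: a 58-byte HEADER ("FCS3.1" + space padding + six 8-byte
ASCII segment offsets), a primary TEXT segment delimited by "/" (values
containing the delimiter are escaped by doubling), and a DATA segment of
little-endian float32 row-major list-mode events.  The reader accepts both
float widths ($DATATYPE F and D) and both byte orders, and fails loudly on
malformed headers or truncated data rather than truncating silently.

Ground truth travels in a sidecar CSV (``event_index,label``; event_index
is 0-based and matches FCS row order) so clustering tools see an
unmodified event file.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, UnsupportedFeatureError

DELIMITER = "/"
_HEADER_LEN = 58


@dataclass
class FcsDocument:
    """Parsed FCS file: version, TEXT keywords (ordered) and event data."""

    version: str
    text_keywords: dict
    data: np.ndarray

    @property
    def n_events(self) -> int:
        return int(self.text_keywords["$TOT"])

    @property
    def n_params(self) -> int:
        return int(self.text_keywords["$PAR"])

    @property
    def channel_names(self) -> list[str]:
        return [
            self.text_keywords[f"$P{i}N"] for i in range(1, self.n_params + 1)
        ]


def _escape(value: str) -> str:
    return value.replace(DELIMITER, DELIMITER * 2)


def _text_segment(keywords: dict) -> bytes:
    parts = [DELIMITER]
    for key, val in keywords.items():
        parts.append(_escape(str(key)))
        parts.append(DELIMITER)
        parts.append(_escape(str(val)))
        parts.append(DELIMITER)
    return "".join(parts).encode("ascii")


def write_fcs(events, path, channel_names=None, extra_keywords=None) -> None:
    """Write an event matrix as an FCS 3.1 file.

    ``events`` may be a LabeledDataset (its ``events`` attribute is used)
    or an (n_events x n_params) array of finite floats.  Channel names
    default to Ch1, Ch2, ...
    """
    data = np.asarray(getattr(events, "events", events), dtype=np.float64)
    if data.ndim != 2:
        raise ValueError("events must be a 2-D matrix (events x parameters)")
    if not np.all(np.isfinite(data)):
        raise ValueError("events contain NaN or Inf; FCS data must be finite")
    n_tot, n_par = data.shape
    if channel_names is None:
        channel_names = [f"Ch{i}" for i in range(1, n_par + 1)]
    if len(channel_names) != n_par:
        raise ValueError("channel_names length must equal the parameter count")
    payload = data.astype("<f4").tobytes(order="C")

    def build(begin_data: int, end_data: int) -> dict:
        kw = {
            "$BEGINANALYSIS": "0",
            "$ENDANALYSIS": "0",
            "$BEGINSTEXT": "0",
            "$ENDSTEXT": "0",
            "$BEGINDATA": str(begin_data),
            "$ENDDATA": str(end_data),
            "$BYTEORD": "1,2,3,4",
            "$DATATYPE": "F",
            "$MODE": "L",
            "$NEXTDATA": "0",
            "$PAR": str(n_par),
            "$TOT": str(n_tot),
        }
        for i, name in enumerate(channel_names, start=1):
            # +1 headroom on $PnR so the declared range covers the data
            rng = int(np.ceil(np.abs(data[:, i - 1]).max())) + 1 if n_tot else 1
            kw[f"$P{i}N"] = str(name)
            kw[f"$P{i}B"] = "32"
            kw[f"$P{i}E"] = "0,0"
            kw[f"$P{i}R"] = str(rng)
        if extra_keywords:
            kw.update({str(k): str(v) for k, v in extra_keywords.items()})
        return kw

    # offset digits depend on TEXT length and vice versa: iterate to fixpoint
    begin_data, end_data = 0, 0
    for _ in range(4):
        text = _text_segment(build(begin_data, end_data))
        new_begin = _HEADER_LEN + len(text)
        new_end = new_begin + len(payload) - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    text = _text_segment(build(begin_data, end_data))
    text_begin = _HEADER_LEN
    text_end = text_begin + len(text) - 1
    for off in (text_begin, text_end, begin_data, end_data):
        if off > 99_999_999:
            raise ValueError("segment offset exceeds the 8-digit HEADER field")
    header = (
        b"FCS3.1    "
        + f"{text_begin:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + f"{begin_data:>8d}".encode()
        + f"{end_data:>8d}".encode()
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    assert len(header) == _HEADER_LEN
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(payload)


def _parse_text(segment: bytes) -> dict:
    if not segment:
        raise FormatError("empty TEXT segment")
    try:
        s = segment.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise FormatError(f"TEXT segment is not valid text: {exc}") from exc
    delim = s[0]
    tokens: list[str] = []
    cur: list[str] = []
    i = 1
    while i < len(s):
        ch = s[i]
        if ch == delim:
            if i + 1 < len(s) and s[i + 1] == delim:
                cur.append(delim)
                i += 2
                continue
            tokens.append("".join(cur))
            cur = []
            i += 1
        else:
            cur.append(ch)
            i += 1
    if cur:
        raise FormatError("TEXT segment does not end with the delimiter")
    if len(tokens) % 2 != 0:
        raise FormatError("TEXT segment holds an odd number of tokens")
    keywords: dict = {}
    for key, val in zip(tokens[::2], tokens[1::2]):
        k = key.upper() if key.startswith("$") else key
        keywords[k] = val
    return keywords


def _header_offsets(raw: bytes):
    if len(raw) < _HEADER_LEN:
        raise FormatError("file shorter than the 58-byte FCS HEADER")
    version = raw[:6].decode("ascii", errors="replace")
    if not version.startswith("FCS3."):
        raise FormatError(f"unsupported or malformed FCS version field {version!r}")
    if raw[6:10] != b"    ":
        raise FormatError("HEADER bytes 7-10 must be spaces")
    offs = []
    for i in range(6):
        fld = raw[10 + 8 * i : 18 + 8 * i].decode("ascii", errors="replace").strip()
        if fld == "":
            fld = "0"
        if not fld.lstrip("-").isdigit():
            raise FormatError(f"HEADER offset field {i + 1} is not numeric: {fld!r}")
        offs.append(int(fld))
    return version, offs


def read_fcs(path) -> FcsDocument:
    """Parse an FCS 3.x file with float ($DATATYPE F or D) list-mode data."""
    with open(path, "rb") as fh:
        raw = fh.read()
    version, offs = _header_offsets(raw)
    text_begin, text_end, data_begin, data_end = offs[:4]
    if not (0 < text_begin <= text_end < len(raw)):
        raise FormatError("HEADER TEXT offsets fall outside the file")
    keywords = _parse_text(raw[text_begin : text_end + 1])
    for req in ("$PAR", "$TOT", "$DATATYPE", "$BYTEORD", "$MODE"):
        if req not in keywords:
            raise FormatError(f"required keyword {req} missing from TEXT")
    if keywords["$MODE"] != "L":
        raise UnsupportedFeatureError(
            f"only list mode ($MODE L) is supported, got {keywords['$MODE']!r}"
        )
    dtype_code = keywords["$DATATYPE"]
    if dtype_code == "F":
        width, code = 32, "f4"
    elif dtype_code == "D":
        width, code = 64, "f8"
    else:
        raise UnsupportedFeatureError(
            f"only $DATATYPE F or D supported, got {dtype_code!r}"
        )
    byteord = keywords["$BYTEORD"]
    if byteord == "1,2,3,4":
        endian = "<"
    elif byteord == "4,3,2,1":
        endian = ">"
    else:
        raise UnsupportedFeatureError(f"unsupported $BYTEORD {byteord!r}")
    n_par = int(keywords["$PAR"])
    n_tot = int(keywords["$TOT"])
    for i in range(1, n_par + 1):
        pnb = keywords.get(f"$P{i}B")
        if pnb is not None and int(pnb) != width:
            raise UnsupportedFeatureError(
                f"$P{i}B = {pnb} conflicts with $DATATYPE {dtype_code} ({width} bits)"
            )
    if data_begin == 0:
        data_begin = int(keywords.get("$BEGINDATA", "0"))
        data_end = int(keywords.get("$ENDDATA", "0"))
    need = n_par * n_tot * (width // 8)
    avail = data_end - data_begin + 1
    if data_begin <= 0 or data_end >= len(raw) or avail < need:
        raise FormatError(
            f"DATA segment truncated: need {need} bytes, segment holds "
            f"{max(avail, 0)} within a {len(raw)}-byte file"
        )
    data = np.frombuffer(
        raw, dtype=endian + code, count=n_par * n_tot, offset=data_begin
    ).reshape(n_tot, n_par)
    return FcsDocument(version=version, text_keywords=keywords, data=np.array(data))


def write_labels(labels, path) -> None:
    """Write the ground-truth sidecar: header ``event_index,label`` with
    0-based event_index matching FCS row order."""
    lab = np.asarray(labels, dtype=int).ravel()
    df = pd.DataFrame({"event_index": np.arange(len(lab)), "label": lab})
    df.to_csv(path, index=False)


def read_labels(path) -> np.ndarray:
    """Read a label sidecar, validating the contiguous 0-based index."""
    df = pd.read_csv(path)
    if list(df.columns) != ["event_index", "label"]:
        raise FormatError(
            f"label sidecar must have columns event_index,label; got {list(df.columns)}"
        )
    idx = df["event_index"].to_numpy()
    if not np.array_equal(idx, np.arange(len(df))):
        raise ConsistencyError(
            "event_index must be contiguous 0-based in row order"
        )
    return df["label"].to_numpy(dtype=int)


def validate_pair(fcs_path, labels_path) -> int:
    """Check an FCS file against its sidecar; returns the event count."""
    doc = read_fcs(fcs_path)
    labels = read_labels(labels_path)
    if len(labels) != doc.n_events:
        raise ConsistencyError(
            f"label sidecar has {len(labels)} rows for {doc.n_events} events"
        )
    return doc.n_events
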