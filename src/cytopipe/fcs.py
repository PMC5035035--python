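"""Reading and writing Flow Cytometry Standard (FCS) files.

Supports FCS 3.0/3.1 with list-mode data of type ``I`` (unsigned integer)
or ``F`` (single-precision float). Augmented files carrying analysis
results as extra parameters are always emitted as FCS 3.1, float32,
little-endian, which keeps a single well-tested writer path and stays
readable by mainstream cytometry software.

Compensation/spillover and FCS 2.0 vendor dialects are out of scope.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FcsSample",
    "CellId",
    "FcsParseError",
    "read_fcs",
    "write_fcs",
    "write_augmented_fcs",
    "select_markers",
    "make_cell_ids",
]


class FcsParseError(ValueError):
    """Raised when an FCS file violates the standard."""


@dataclass
class FcsSample:
    """One FCS file in memory: events x channels plus channel metadata."""

    path: str
    channel_short_names: list[str]        # $PnN
    channel_stain_names: list[str | None]  # $PnS, None when absent
    data: np.ndarray                      # (n_events, n_channels) float
    n_events: int                         # $TOT
    keywords: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.shape != (self.n_events, len(self.channel_short_names)):
            raise FcsParseError(
                f"data shape {self.data.shape} inconsistent with $TOT={self.n_events} "
                f"and $PAR={len(self.channel_short_names)}"
            )


@dataclass(frozen=True)
class CellId:
    """Provenance of one cell: source file plus its 1-based index there."""

    source_file: str
    index_in_file: int
    id: str


# --------------------------------------------------------------------------
# reading


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FcsParseError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # doubled delimiter escapes a literal delimiter inside a value
    parts = body.split(delim)
    tokens: list[bytes] = []
    cur = parts[0]
    i = 1
    while i < len(parts):
        if parts[i] == b"" and i + 1 < len(parts):
            cur = cur + delim + parts[i + 1]
            i += 2
        else:
            tokens.append(cur)
            cur = parts[i]
            i += 1
    tokens.append(cur)
    decoded = [t.decode("latin-1") for t in tokens]
    if len(decoded) % 2 != 0:
        raise FcsParseError("TEXT segment has an odd number of delimited tokens")
    kw: dict[str, str] = {}
    for key, value in zip(decoded[::2], decoded[1::2]):
        kw[key.strip().upper() if key.startswith("$") else key.strip()] = value
    return kw


def _require(kw: dict[str, str], key: str) -> str:
    if key not in kw:
        raise FcsParseError(f"required keyword {key} missing from TEXT segment")
    return kw[key]


def read_fcs(path: str | os.PathLike) -> FcsSample:
    """Read an FCS 3.0/3.1 file into an :class:`FcsSample`.

    Raises
    ------
    FcsParseError
        On a malformed header/TEXT segment (the message names the
        offending keyword) or when the decoded event count disagrees
        with ``$TOT``.
    NotImplementedError
        For ``$DATATYPE`` other than ``I`` or ``F``.
    """
    path = os.fspath(path)
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < 58:
        raise FcsParseError("file shorter than the 58-byte FCS header")
    version = blob[0:6].decode("latin-1")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FcsParseError(f"unsupported FCS version marker {version!r}")

    def _offset(lo: int, hi: int, what: str) -> int:
        txt = blob[lo:hi].decode("latin-1").strip()
        try:
            return int(txt) if txt else 0
        except ValueError as exc:
            raise FcsParseError(f"non-numeric {what} offset in header: {txt!r}") from exc

    text_beg = _offset(10, 18, "TEXT begin")
    text_end = _offset(18, 26, "TEXT end")
    data_beg = _offset(26, 34, "DATA begin")
    data_end = _offset(34, 42, "DATA end")
    if text_beg <= 0 or text_end <= text_beg:
        raise FcsParseError("invalid TEXT segment offsets in header")
    kw = _parse_text_segment(blob[text_beg : text_end + 1])

    # large files store data offsets only in TEXT
    if data_beg == 0:
        data_beg = int(_require(kw, "$BEGINDATA"))
    if data_end == 0:
        data_end = int(_require(kw, "$ENDDATA"))

    n_par = int(_require(kw, "$PAR"))
    n_tot = int(_require(kw, "$TOT"))
    datatype = _require(kw, "$DATATYPE").strip().upper()
    byteord = _require(kw, "$BYTEORD").strip()
    mode = kw.get("$MODE", "L").strip().upper()
    if mode != "L":
        raise NotImplementedError(f"$MODE={mode} not supported (list mode only)")
    if byteord in ("1,2,3,4", "2,1"):
        endian = "<"
    elif byteord in ("4,3,2,1", "1,2"):
        endian = ">"
    else:
        raise FcsParseError(f"unsupported $BYTEORD {byteord!r}")

    bits = [int(_require(kw, f"$P{i}B")) for i in range(1, n_par + 1)]
    short_names = [_require(kw, f"$P{i}N") for i in range(1, n_par + 1)]
    stain_names: list[str | None] = [kw.get(f"$P{i}S") or None for i in range(1, n_par + 1)]

    raw = blob[data_beg : data_end + 1]
    if datatype == "F":
        if any(b != 32 for b in bits):
            raise FcsParseError("$DATATYPE=F requires $PnB=32 for every parameter")
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "I":
        if len(set(bits)) != 1 or bits[0] not in (8, 16, 32):
            raise FcsParseError(
                f"$DATATYPE=I supported only for uniform $PnB in 8/16/32, got {bits}"
            )
        dtype = np.dtype(f"{endian}u{bits[0] // 8}")
    else:
        raise NotImplementedError(f"unsupported $DATATYPE {datatype!r} (only I and F)")

    n_expected = n_tot * n_par * dtype.itemsize
    if len(raw) < n_expected:
        raise FcsParseError(
            f"DATA segment holds {len(raw)} bytes but $TOT={n_tot} x $PAR={n_par} "
            f"requires {n_expected}"
        )
    values = np.frombuffer(raw[:n_expected], dtype=dtype).astype(np.float64)
    data = values.reshape(n_tot, n_par)
    return FcsSample(
        path=path,
        channel_short_names=short_names,
        channel_stain_names=stain_names,
        data=data,
        n_events=n_tot,
        keywords=kw,
    )


# --------------------------------------------------------------------------
# writing (always FCS 3.1, float32, little-endian)


def write_fcs(
    path: str | os.PathLike,
    data: np.ndarray,
    short_names: list[str],
    stain_names: list[str | None] | None = None,
    extra_keywords: dict[str, str] | None = None,
) -> str:
    """Write ``data`` (events x channels) as an FCS 3.1 float32 file."""
    path = os.fspath(path)
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (events x channels)")
    n_tot, n_par = data.shape
    if len(short_names) != n_par:
        raise ValueError("one short name per channel required")
    if stain_names is None:
        stain_names = [None] * n_par
    if len(stain_names) != n_par:
        raise ValueError("one stain name (or None) per channel required")

    delim = "/"
    kw: dict[str, str] = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i in range(n_par):
        name = short_names[i]
        if delim in name:
            raise ValueError(f"channel name {name!r} contains the delimiter {delim!r}")
        kw[f"$P{i + 1}N"] = name
        kw[f"$P{i + 1}B"] = "32"
        kw[f"$P{i + 1}E"] = "0,0"
        col = data[:, i]
        rng = float(np.max(col)) if n_tot else 1.0
        kw[f"$P{i + 1}R"] = str(int(np.ceil(max(rng, 1.0))) + 1)
        if stain_names[i]:
            kw[f"$P{i + 1}S"] = str(stain_names[i])
    if extra_keywords:
        for k, v in extra_keywords.items():
            if k.startswith("$") and k in kw:
                raise ValueError(f"refusing to override standard keyword {k}")
            kw[k] = str(v)

    # offsets appear inside TEXT, so reserve fixed-width fields and fill in
    placeholder = "0" * 10
    kw["$BEGINDATA"] = placeholder
    kw["$ENDDATA"] = placeholder
    kw["$BEGINANALYSIS"] = "0"
    kw["$ENDANALYSIS"] = "0"
    kw["$BEGINSTEXT"] = "0"
    kw["$ENDSTEXT"] = "0"

    def _render(kwd: dict[str, str]) -> bytes:
        parts = [delim]
        for k, v in kwd.items():
            v = str(v) if str(v) != "" else " "
            parts.append(f"{k}{delim}{v}{delim}")
        return "".join(parts).encode("latin-1")

    header_len = 58
    text = _render(kw)
    text_beg = header_len
    text_end = text_beg + len(text) - 1
    data_beg = text_end + 1
    data_end = data_beg + data.nbytes - 1
    kw["$BEGINDATA"] = str(data_beg).rjust(10, "0")
    kw["$ENDDATA"] = str(data_end).rjust(10, "0")
    text = _render(kw)
    assert text_end == text_beg + len(text) - 1  # fixed-width fill keeps size

    def _hdr_field(n: int) -> bytes:
        s = str(n)
        return (s if len(s) <= 8 else "0").rjust(8).encode("ascii")

    header = b"FCS3.1    "
    header += _hdr_field(text_beg) + _hdr_field(text_end)
    if data_end <= 99_999_999:
        header += _hdr_field(data_beg) + _hdr_field(data_end)
    else:
        header += _hdr_field(0) + _hdr_field(0)
    header += _hdr_field(0) + _hdr_field(0)  # no ANALYSIS segment
    assert len(header) == header_len

    payload = data.astype("<f4").tobytes()
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(payload)
    return path


def write_augmented_fcs(
    sample: FcsSample,
    new_params: dict[str, np.ndarray],
    out_path: str | os.PathLike,
) -> str:
    """Re-emit ``sample`` with analysis results appended as new parameters.

    Each entry of ``new_params`` becomes an extra channel (e.g. embedding
    coordinates or cluster labels) so the file can be opened in standard
    cytometry software with the results visible alongside the raw channels.
    """
    existing = set(sample.channel_short_names) | {
        s for s in sample.channel_stain_names if s
    }
    names = list(new_params.keys())
    if len(set(names)) != len(names):
        raise ValueError("new parameter names must be unique")
    for name in names:
        if not name:
            raise ValueError("new parameter names must be nonempty")
        if name in existing:
            raise ValueError(f"new parameter {name!r} collides with an existing channel")
        vec = np.asarray(new_params[name])
        if vec.shape != (sample.n_events,):
            raise ValueError(
                f"parameter {name!r} has length {vec.shape} but the sample has "
                f"{sample.n_events} events"
            )
    if names:
        extra = np.column_stack([np.asarray(new_params[n], dtype=np.float32) for n in names])
        data = np.hstack([sample.data.astype(np.float32), extra])
    else:
        data = sample.data.astype(np.float32)
    short = sample.channel_short_names + names
    stains = sample.channel_stain_names + [None] * len(names)
    return write_fcs(out_path, data, short, stains)


# --------------------------------------------------------------------------
# marker selection and cell identity


def select_markers(sample: FcsSample, selection: list[str]) -> np.ndarray:
    """Extract the columns named in ``selection``, in that order.

    Names are matched against the stain names ($PnS) first and fall back
    to the short names ($PnN); matching is exact after whitespace trim.
    """
    stain_index = {
        s.strip(): i for i, s in enumerate(sample.channel_stain_names) if s
    }
    short_index = {s.strip(): i for i, s in enumerate(sample.channel_short_names)}
    cols = []
    for name in selection:
        key = name.strip()
        if key in stain_index:
            cols.append(stain_index[key])
        elif key in short_index:
            cols.append(short_index[key])
        else:
            available = sorted(set(stain_index) | set(short_index))
            raise KeyError(
                f"marker {name!r} not found; available channels: {available}"
            )
    return sample.data[:, cols].copy()


def _strip_fcs_ext(filename: str) -> str:
    base = os.path.basename(filename)
    if base.endswith((".fcs", ".FCS")):
        base = base[:-4]
    return base


def make_cell_ids(source_file: str, n: int) -> list[CellId]:
    """Unique per-cell IDs: ``<file-stem>_<1-based index>``."""
    if n < 1:
        raise ValueError(f"need at least one event, got n={n}")
    stem = _strip_fcs_ext(source_file)
    return [
        CellId(source_file=source_file, index_in_file=i, id=f"{stem}_{i}")
        for i in range(1, n + 1)
    ]
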