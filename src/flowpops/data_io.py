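"""Reading and writing flow cytometry samples.

The core container is :class:`FlowSample`, an ``N x M`` matrix of fluorescence
intensities (rows = cells/events, columns = markers/channels) plus marker
names.  Two on-disk formats are supported:

* FCS list-mode files (versions 2.0 / 3.0 / 3.1), the instrument-native
  format; only uncompensated list-mode data with float or integer storage is
  handled.
* plain numeric CSV matrices, the canonical interchange format used by the
  test-suite and the CLI.

No transform is applied on load.  An optional arcsinh transform is provided
for users who want compressed fluorescence scales, but the clustering
pipeline itself operates on raw intensities by default.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "FlowSample",
    "FCSError",
    "FCSParseError",
    "EmptyFCSError",
    "CSVMatrixError",
    "read_fcs",
    "write_fcs",
    "read_csv_matrix",
    "write_csv_matrix",
    "write_labels_csv",
    "read_labels_csv",
    "transform_arcsinh",
]


class FCSError(Exception):
    """Base class for FCS reading problems."""


class FCSParseError(FCSError):
    """Header or data segment of an FCS file could not be parsed."""


class EmptyFCSError(FCSError):
    """FCS file contains zero events."""


class CSVMatrixError(Exception):
    """CSV matrix is ragged, empty or contains non-numeric cells."""


@dataclass
class FlowSample:
    """One subject's cell-by-marker fluorescence matrix.

    Parameters
    ----------
    sample_id
        Identifier for the sample (usually the file stem).
    marker_names
        ``M`` channel labels, in column order.
    values
        ``(N, M)`` float array of fluorescence intensities; all entries must
        be finite.
    subject_id
        Optional subject identifier for multi-subject cohorts.
    """

    sample_id: str
    marker_names: list[str]
    values: np.ndarray
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (cells x markers) array")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValueError(f"need at least one cell and one marker, got shape {self.values.shape}")
        if len(self.marker_names) != m:
            raise ValueError(
                f"{len(self.marker_names)} marker names for {m} columns"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at cell {bad[0]}, marker {self.marker_names[bad[1]]!r}"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def select_markers(self, names: list[str]) -> "FlowSample":
        """Return a copy restricted to the given markers, in the given order."""
        missing = [n for n in names if n not in self.marker_names]
        if missing:
            raise KeyError(f"unknown markers: {missing}")
        idx = [self.marker_names.index(n) for n in names]
        return replace(self, marker_names=list(names), values=self.values[:, idx])


# ---------------------------------------------------------------------------
# FCS list-mode I/O
# ---------------------------------------------------------------------------

def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FCSParseError("empty TEXT segment")
    delim = raw[0:1].decode("latin-1")
    parts = raw.decode("latin-1").split(delim)
    # parts[0] is empty (segment starts with the delimiter)
    kv = parts[1:]
    if len(kv) % 2 == 1 and kv[-1].strip() == "":
        kv = kv[:-1]
    out: dict[str, str] = {}
    for key, val in zip(kv[::2], kv[1::2]):
        out[key.strip().upper()] = val.strip()
    return out


def read_fcs(path: str | Path) -> FlowSample:
    """Read a list-mode FCS 2.0/3.0/3.1 file into a :class:`FlowSample`.

    All events are returned untransformed; channel names come from ``$PnN``
    (falling back to ``$PnS`` then ``Pn``) in file order.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    FCSParseError
        On a malformed header, TEXT segment or truncated data segment.
    EmptyFCSError
        If the file declares zero events.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    blob = path.read_bytes()
    if len(blob) < 58 or not blob[:3] == b"FCS":
        raise FCSParseError(f"{path}: not an FCS file")
    version = blob[:6].decode("latin-1", "replace")
    if version not in ("FCS2.0", "FCS3.0", "FCS3.1"):
        raise FCSParseError(f"{path}: unsupported FCS version {version!r}")
    try:
        text_start = int(blob[10:18])
        text_end = int(blob[18:26])
        data_start = int(blob[26:34])
        data_end = int(blob[34:42])
    except ValueError as exc:
        raise FCSParseError(f"{path}: malformed header offsets") from exc
    if text_end <= text_start or text_end >= len(blob):
        raise FCSParseError(f"{path}: TEXT segment offsets out of range")
    text = _parse_text_segment(blob[text_start : text_end + 1])

    if data_start == 0 and "$BEGINDATA" in text:
        data_start = int(text["$BEGINDATA"])
        data_end = int(text["$ENDDATA"])
    try:
        n_par = int(text["$PAR"])
        n_tot = int(text["$TOT"])
        datatype = text["$DATATYPE"].upper()
        byteord = text["$BYTEORD"]
    except KeyError as exc:
        raise FCSParseError(f"{path}: missing required keyword {exc}") from exc
    if text.get("$MODE", "L").upper() != "L":
        raise FCSParseError(f"{path}: only list mode ($MODE=L) is supported")
    if n_tot == 0:
        raise EmptyFCSError(f"{path}: file declares zero events")

    bits = {int(text.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)}
    if len(bits) != 1:
        raise FCSParseError(f"{path}: mixed per-channel bit widths not supported")
    nbytes = bits.pop() // 8
    little = byteord.startswith("1")
    order = "<" if little else ">"
    if datatype == "F":
        dtype = np.dtype(f"{order}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{order}f8")
    elif datatype == "I":
        dtype = np.dtype(f"{order}u{nbytes}")
    else:
        raise FCSParseError(f"{path}: unsupported $DATATYPE {datatype!r}")

    expected = n_par * n_tot * dtype.itemsize
    seg = blob[data_start : data_end + 1]
    if len(seg) < expected:
        raise FCSParseError(
            f"{path}: truncated data segment ({len(seg)} bytes, expected {expected})"
        )
    values = np.frombuffer(seg[:expected], dtype=dtype).astype(float).reshape(n_tot, n_par)
    names = [
        text.get(f"$P{i}N") or text.get(f"$P{i}S") or f"P{i}"
        for i in range(1, n_par + 1)
    ]
    return FlowSample(sample_id=path.stem, marker_names=names, values=values)


def write_fcs(sample: FlowSample, path: str | Path) -> None:
    """Write a minimal FCS 3.0 file (float32, little-endian list mode).

    Intended for fixtures and interchange with other cytometry software; not a
    full-featured writer.
    """
    path = Path(path)
    n, m = sample.values.shape
    data = np.ascontiguousarray(sample.values, dtype="<f4").tobytes()
    kv = {
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(m),
        "$TOT": str(n),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(sample.marker_names, start=1):
        kv[f"$P{i}N"] = name
        kv[f"$P{i}B"] = "32"
        kv[f"$P{i}R"] = "262144"
        kv[f"$P{i}E"] = "0,0"

    header_len = 58
    # iterate because BEGINDATA/ENDDATA lengths feed back into the offsets
    begin_data = end_data = 0
    for _ in range(4):
        kv["$BEGINDATA"] = str(begin_data)
        kv["$ENDDATA"] = str(end_data)
        kv["$BEGINANALYSIS"] = "0"
        kv["$ENDANALYSIS"] = "0"
        text = "/" + "".join(f"{k}/{v}/" for k, v in kv.items())
        text_start = header_len
        text_end = text_start + len(text) - 1
        new_begin = text_end + 1
        new_end = new_begin + len(data) - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end
    header = (
        b"FCS3.0    "
        + f"{text_start:8d}".encode()
        + f"{text_end:8d}".encode()
        + f"{begin_data:8d}".encode()
        + f"{end_data:8d}".encode()
        + f"{0:8d}".encode()
        + f"{0:8d}".encode()
    )
    path.write_bytes(header + text.encode("latin-1") + data)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_csv_matrix(path: str | Path, has_header: bool = True) -> FlowSample:
    """Read a rectangular numeric CSV into a :class:`FlowSample`.

    With ``has_header`` the first row supplies marker names; otherwise columns
    are named ``M1 .. Mm``.  Ragged rows and non-numeric cells raise
    :class:`CSVMatrixError` naming the offending row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh) if row and any(c.strip() for c in row)]
    if not rows:
        raise CSVMatrixError(f"{path}: empty file")
    if has_header:
        names = [c.strip() for c in rows[0]]
        body = rows[1:]
    else:
        names = [f"M{i + 1}" for i in range(len(rows[0]))]
        body = rows
    if not body:
        raise CSVMatrixError(f"{path}: no data rows")
    m = len(names)
    values = np.empty((len(body), m), dtype=float)
    for i, row in enumerate(body):
        if len(row) != m:
            raise CSVMatrixError(
                f"{path}: row {i + 1} has {len(row)} fields, expected {m}"
            )
        for j, cell in enumerate(row):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise CSVMatrixError(
                    f"{path}: non-numeric value {cell!r} at row {i + 1}, column {names[j]!r}"
                ) from None
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise CSVMatrixError(
            f"{path}: non-finite value at row {bad[0] + 1}, column {names[bad[1]]!r}"
        )
    return FlowSample(sample_id=path.stem, marker_names=names, values=values)


def write_csv_matrix(sample: FlowSample, path: str | Path) -> None:
    """Write a :class:`FlowSample` as CSV with a marker-name header row."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(sample.marker_names)
        for row in sample.values:
            writer.writerow([repr(float(v)) for v in row])


def write_labels_csv(labels: np.ndarray, path: str | Path) -> None:
    """Write per-cell population labels as ``cell_index,label`` CSV."""
    labels = np.asarray(labels, dtype=int)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cell_index", "label"])
        for i, lab in enumerate(labels):
            writer.writerow([i, int(lab)])


def read_labels_csv(path: str | Path) -> np.ndarray:
    """Read a ``cell_index,label`` CSV (or a single-column label list)."""
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh) if row]
    if not rows:
        raise CSVMatrixError(f"{path}: empty label file")
    start = 1 if not rows[0][-1].lstrip("-").isdigit() else 0
    return np.array([int(row[-1]) for row in rows[start:]], dtype=int)


def transform_arcsinh(sample: FlowSample, cofactor: float) -> FlowSample:
    """Apply the arcsinh transform ``v -> asinh(v / cofactor)`` elementwise.

    Common cofactors are 5 (mass cytometry) and 150 (flow); the transform is
    monotone, so it never reorders intensities.
    """
    if cofactor <= 0:
        raise ValueError(f"cofactor must be positive, got {cofactor}")
    return replace(sample, values=np.arcsinh(sample.values / cofactor))
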