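"""Readers and writers for landmark coordinate data.

Two interchange layouts are supported:

* **Flat matrix** (CSV/TSV): specimens in rows, coordinate variables in
  columns, landmark-major order ``x1, y1[, z1], x2, y2[, z2], ...``.  An
  optional header row and an optional first column of specimen IDs are
  auto-detected by default.  The mapping between a flat column index and a
  (landmark, axis) pair is ``column = landmark * n_dims + axis``.
* **TPS**: one ``LM=`` (2-D) or ``LM3=`` (3-D) block per specimen, with
  ``ID=`` / ``IMAGE=`` labels and a multiplicative ``SCALE=`` factor honored.
  Semi-landmark curve records (``CURVES=`` / ``POINTS=`` / ``OUTLINES=``) are
  rejected: sliding semi-landmarks are out of scope, and silently flattening
  them would misrepresent the data.

Both round-trip to full stored precision.  Missing or non-numeric cells are
hard errors — the analysis requires complete data, and imputation is never
attempted.
"""

from __future__ import annotations

import os

import numpy as np

from .containers import LandmarkConfigurationSet
from .exceptions import CompletenessError, DimensionalityError, FormatError

__all__ = [
    "read_flat_matrix",
    "write_flat_matrix",
    "read_tps",
    "write_tps",
    "to_flat_matrix",
    "from_flat_matrix",
    "read_any",
]

_FLOAT_FMT = "%.17g"


def _try_float(cell: str) -> float | None:
    try:
        return float(cell)
    except ValueError:
        return None


def _detect_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def from_flat_matrix(matrix, n_dims: int, specimen_ids=(),
                     landmark_ids=()) -> LandmarkConfigurationSet:
    """Reshape an (n, p*d) flat matrix into a configuration set."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise FormatError("flat matrix must be 2-dimensional")
    if n_dims not in (2, 3):
        raise DimensionalityError(f"n_dims must be 2 or 3, got {n_dims}")
    n, width = matrix.shape
    if width % n_dims:
        raise FormatError(
            f"{width} coordinate columns are not divisible by n_dims={n_dims}"
        )
    p = width // n_dims
    return LandmarkConfigurationSet(
        coords=matrix.reshape(n, p, n_dims),
        specimen_ids=specimen_ids,
        landmark_ids=landmark_ids,
    )


def to_flat_matrix(data: LandmarkConfigurationSet) -> np.ndarray:
    """Flatten a configuration set to the (n, p*d) landmark-major layout."""
    n, p, d = data.coords.shape
    return data.coords.reshape(n, p * d).copy()


def read_flat_matrix(path, n_dims: int, delimiter: str | None = None,
                     header: bool | str = "auto",
                     ids: bool | str = "auto") -> LandmarkConfigurationSet:
    """Read a delimited flat-matrix file of raw landmark coordinates.

    Parameters
    ----------
    path : file path
    n_dims : 2 or 3
        Physical dimensionality used to unflatten the columns.
    delimiter : str, optional
        Auto-detected (tab, else comma) when omitted.
    header, ids : bool or "auto"
        Whether the file carries a header row / a first column of specimen
        IDs.  With ``"auto"``, a non-numeric first row is taken as a header
        and a non-numeric first column as IDs.  Files whose specimen IDs are
        themselves numbers need ``ids=True`` explicitly.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    delimiter = delimiter or _detect_delimiter(lines[0])
    rows = [ln.split(delimiter) for ln in lines]

    if header == "auto":
        first = rows[0]
        header = any(_try_float(c) is None for c in first[1:]) and len(rows) > 1
    if header:
        rows = rows[1:]
    if not rows:
        raise FormatError(f"{path}: no data rows")
    if ids == "auto":
        ids = any(_try_float(r[0]) is None for r in rows)

    specimen_ids = []
    numeric_rows = []
    width = None
    for i, row in enumerate(rows):
        cells = row[1:] if ids else row
        if ids:
            specimen_ids.append(row[0].strip())
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise FormatError(
                f"{path}: row {i} has {len(cells)} coordinate cells, "
                f"expected {width}"
            )
        values = []
        for j, cell in enumerate(cells):
            if cell.strip() == "":
                raise CompletenessError(
                    f"{path}: empty cell at row {i}, column {j}; "
                    "coordinate data must be complete"
                )
            val = _try_float(cell)
            if val is None:
                raise CompletenessError(
                    f"{path}: non-numeric cell {cell!r} at row {i}, column {j}"
                )
            values.append(val)
        numeric_rows.append(values)

    matrix = np.array(numeric_rows, dtype=float)
    if matrix.shape[1] % n_dims:
        raise FormatError(
            f"{path}: {matrix.shape[1]} coordinate columns are not divisible "
            f"by n_dims={n_dims}"
        )
    return from_flat_matrix(matrix, n_dims,
                            specimen_ids=tuple(specimen_ids))


def write_flat_matrix(data: LandmarkConfigurationSet, path,
                      delimiter: str = ",", header: bool = True,
                      ids: bool = True) -> None:
    """Write a configuration set as a delimited flat-matrix file.

    Values are written with 17 significant digits so that reading the file
    back reproduces the array bit-for-bit.
    """
    matrix = to_flat_matrix(data)
    axes = "xyz"[: data.n_dims]
    with open(path, "w") as fh:
        if header:
            cols = [f"{lm}_{ax}" for lm in data.landmark_ids for ax in axes]
            if ids:
                cols = ["specimen", *cols]
            fh.write(delimiter.join(cols) + "\n")
        for sid, row in zip(data.specimen_ids, matrix):
            cells = [_FLOAT_FMT % v for v in row]
            if ids:
                cells = [sid, *cells]
            fh.write(delimiter.join(cells) + "\n")


_TPS_REJECTED = ("CURVES", "POINTS", "OUTLINES")


def read_tps(path) -> LandmarkConfigurationSet:
    """Read landmark configurations from a TPS file.

    Each ``LM=k`` (2-D) or ``LM3=k`` (3-D) block contributes one specimen; all
    blocks must agree in landmark count and dimensionality.  ``SCALE=`` is
    applied multiplicatively; ``ID=`` (preferred) or ``IMAGE=`` supplies the
    specimen label.
    """
    blocks: list[np.ndarray] = []
    labels: list[str] = []
    scales: list[float] = []
    dims: set[int] = set()

    current: list[list[float]] | None = None
    expected = 0
    label_id = label_image = None
    scale = 1.0

    def close_block():
        nonlocal current, label_id, label_image, scale
        if current is None:
            return
        if len(current) != expected:
            raise FormatError(
                f"{path}: block {len(blocks)} declares {expected} landmarks "
                f"but contains {len(current)}"
            )
        blocks.append(np.asarray(current, dtype=float))
        labels.append(label_id or label_image or f"specimen_{len(blocks) - 1}")
        scales.append(scale)
        current, label_id, label_image, scale = None, None, None, 1.0

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3=") or upper.startswith("LM="):
                close_block()
                d = 3 if upper.startswith("LM3=") else 2
                dims.add(d)
                if len(dims) > 1:
                    raise DimensionalityError(
                        f"{path}: mixed LM= and LM3= blocks (2-D and 3-D "
                        "configurations cannot be combined)"
                    )
                try:
                    expected = int(line.split("=", 1)[1])
                except ValueError as exc:
                    raise FormatError(f"{path}: bad landmark count in {line!r}") from exc
                current = []
            elif any(upper.startswith(key + "=") for key in _TPS_REJECTED):
                raise FormatError(
                    f"{path}: {line.split('=', 1)[0]} records (semi-landmark "
                    "curves) are not supported; only fixed landmarks are"
                )
            elif upper.startswith("ID="):
                label_id = line.split("=", 1)[1].strip()
            elif upper.startswith("IMAGE="):
                label_image = line.split("=", 1)[1].strip()
            elif upper.startswith("SCALE="):
                try:
                    scale = float(line.split("=", 1)[1])
                except ValueError as exc:
                    raise FormatError(f"{path}: bad SCALE in {line!r}") from exc
            elif "=" in line and _try_float(line.split()[0]) is None:
                continue  # unknown key=value line; tolerated
            else:
                if current is None:
                    raise FormatError(
                        f"{path}: coordinate line {line!r} outside an LM block"
                    )
                cells = line.replace(",", " ").split()
                vals = [_try_float(c) for c in cells]
                if any(v is None for v in vals):
                    raise CompletenessError(
                        f"{path}: non-numeric coordinate in line {line!r}"
                    )
                current.append(vals)  # type: ignore[arg-type]
    close_block()

    if not blocks:
        raise FormatError(f"{path}: no LM= blocks found")
    d = dims.pop()
    counts = {b.shape[0] for b in blocks}
    if len(counts) > 1:
        raise FormatError(
            f"{path}: unequal landmark counts across blocks: {sorted(counts)}"
        )
    widths = {b.shape[1] for b in blocks}
    if widths != {d}:
        raise FormatError(
            f"{path}: coordinate lines have {sorted(widths)} values per "
            f"landmark, expected {d}"
        )
    coords = np.stack([b * s for b, s in zip(blocks, scales)])
    return LandmarkConfigurationSet(coords=coords,
                                    specimen_ids=tuple(labels))


def write_tps(data: LandmarkConfigurationSet, path) -> None:
    """Write a configuration set as a TPS file (full precision, no SCALE)."""
    key = "LM3" if data.n_dims == 3 else "LM"
    with open(path, "w") as fh:
        for sid, config in zip(data.specimen_ids, data.coords):
            fh.write(f"{key}={data.n_landmarks}\n")
            for point in config:
                fh.write(" ".join(_FLOAT_FMT % v for v in point) + "\n")
            fh.write(f"ID={sid}\n")


def read_any(path, n_dims: int | None = None,
             fmt: str = "auto") -> LandmarkConfigurationSet:
    """Dispatch to :func:`read_tps` or :func:`read_flat_matrix` by extension."""
    if fmt == "auto":
        fmt = "tps" if os.path.splitext(str(path))[1].lower() == ".tps" else "csv"
    if fmt == "tps":
        return read_tps(path)
    if n_dims is None:
        raise DimensionalityError("reading a flat matrix requires n_dims")
    return read_flat_matrix(path, n_dims)
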